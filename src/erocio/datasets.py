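"""Seeded dataset generation for the three studies, plus HDF5 persistence.

A :class:`Dataset` holds flattened noiseless images (signal-present cases
first, then signal-absent), labels, the true signal parameters of the present
cases, and — for background-known-statistically tasks — the generative
background realizations, which the joint MCMC samplers use for chain
initialization and which make semi-online noise redraws possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .config import TaskConfig, default_config
from .imaging import GaussianNoiseModel, signal_image
from .object_models import (
    CLBRealization,
    LumpyModelParams,
    LumpyRealization,
    clb_image,
    lumpy_background_image,
    sample_clb,
    sample_lumpy,
)


@dataclass
class Dataset:
    """Labeled image set for one task: present cases first, then absent."""

    config: TaskConfig
    noiseless: np.ndarray  # (n, N) background (+ signal for present cases)
    labels: np.ndarray  # (n,) 1 = signal present, 0 = absent
    theta: np.ndarray  # (n_present, d) true parameters of present cases
    backgrounds: list = field(default_factory=list)  # realizations or None, len n
    images: np.ndarray | None = None  # (n, N) noisy measurements, if rendered

    @property
    def n_cases(self) -> int:
        return int(self.labels.size)

    @property
    def n_present(self) -> int:
        return int(self.labels.sum())

    def noise_model(self, seed: int | None = None) -> GaussianNoiseModel:
        return GaussianNoiseModel(
            sigma_n=self.config.sigma_n,
            seed=self.config.seed if seed is None else seed,
        )

    def render_noisy(self, counter: int = 0, seed: int | None = None) -> np.ndarray:
        """Noiseless images plus a fresh counter-indexed noise draw."""
        nm = self.noise_model(seed=seed)
        return self.noiseless + nm.sample(self.noiseless.shape, counter=counter)

    def split(self) -> tuple["Dataset", "Dataset"]:
        """(present-only, absent-only) views of the dataset."""
        pres = self.labels == 1
        d1 = Dataset(
            config=self.config,
            noiseless=self.noiseless[pres],
            labels=self.labels[pres],
            theta=self.theta,
            backgrounds=[b for b, p in zip(self.backgrounds, pres) if p],
            images=None if self.images is None else self.images[pres],
        )
        d0 = Dataset(
            config=self.config,
            noiseless=self.noiseless[~pres],
            labels=self.labels[~pres],
            theta=np.zeros((0, self.config.theta_dim)),
            backgrounds=[b for b, p in zip(self.backgrounds, pres) if not p],
            images=None if self.images is None else self.images[~pres],
        )
        return d1, d0


def _render_background(cfg: TaskConfig, rng: np.random.Generator):
    """One background realization and its image for the task's model."""
    bp = cfg.background_params()
    if bp is None:
        return None, np.zeros(cfg.grid().n_pixels)
    if isinstance(bp, LumpyModelParams):
        real = sample_lumpy(bp, rng, grid=cfg.grid())
        return real, lumpy_background_image(cfg.system(), real, bp)
    real = sample_clb(bp, rng, grid=cfg.grid())
    return real, clb_image(real, bp, grid=cfg.grid())


def generate_dataset(
    task: TaskConfig | str,
    n_present: int,
    n_absent: int,
    seed: int = 0,
    noiseless: bool = False,
    keep_backgrounds: bool = True,
) -> Dataset:
    """Generate a labeled dataset for one study.

    ``task`` is a :class:`TaskConfig` or one of the shipped task names.  With
    ``noiseless=True`` no measurement noise is added (SLO fitting and
    semi-online training both start from noiseless images); otherwise noisy
    measurements are rendered with the task noise level.  Fully seeded.
    """
    cfg = default_config(task) if isinstance(task, str) else task
    rng = np.random.default_rng(seed)
    n_pix = cfg.grid().n_pixels
    theta = cfg.sample_theta(n_present, rng) if n_present else np.zeros((0, cfg.theta_dim))

    clean = np.empty((n_present + n_absent, n_pix))
    backgrounds: list = []
    for i in range(n_present):
        real, b = _render_background(cfg, rng)
        backgrounds.append(real)
        s = signal_image(cfg.system(), cfg.signal_params_for(theta[i]))
        clean[i] = b + s
    for i in range(n_absent):
        real, b = _render_background(cfg, rng)
        backgrounds.append(real)
        clean[n_present + i] = b
    if not keep_backgrounds:
        backgrounds = [None] * (n_present + n_absent)

    labels = np.concatenate(
        [np.ones(n_present, dtype=int), np.zeros(n_absent, dtype=int)]
    )
    ds = Dataset(config=cfg, noiseless=clean, labels=labels, theta=theta, backgrounds=backgrounds)
    if not noiseless:
        nm = GaussianNoiseModel(sigma_n=cfg.sigma_n, seed=seed)
        ds.images = clean + nm.sample(clean.shape, counter=0)
    return ds


# --------------------------------------------------------------------------
# HDF5 persistence
# --------------------------------------------------------------------------

_VLEN = h5py.special_dtype(vlen=np.dtype("float64"))


def save_dataset(ds: Dataset, path) -> None:
    """Write a dataset (images, labels, theta, background params, config)."""
    import json

    with h5py.File(path, "w") as f:
        n = ds.config.n_rows, ds.config.n_cols
        f.create_dataset("noiseless", data=ds.noiseless.reshape(-1, *n))
        if ds.images is not None:
            f.create_dataset("images", data=ds.images.reshape(-1, *n))
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("theta", data=ds.theta)
        f.attrs["config"] = json.dumps(ds.config.to_dict())
        kinds = []
        lumpy_centers, clb_packed = [], []
        for real in ds.backgrounds:
            if isinstance(real, LumpyRealization):
                kinds.append(1)
                lumpy_centers.append(real.centers.ravel())
                clb_packed.append(np.zeros(0))
            elif isinstance(real, CLBRealization):
                kinds.append(2)
                lumpy_centers.append(np.zeros(0))
                clb_packed.append(_pack_clb(real))
            else:
                kinds.append(0)
                lumpy_centers.append(np.zeros(0))
                clb_packed.append(np.zeros(0))
        if any(k != 0 for k in kinds):
            f.create_dataset("background_kind", data=np.array(kinds, dtype=np.int8))
            f.create_dataset("lumpy_centers", data=np.array(lumpy_centers, dtype=object), dtype=_VLEN)
            f.create_dataset("clb_packed", data=np.array(clb_packed, dtype=object), dtype=_VLEN)


def _pack_clb(real: CLBRealization) -> np.ndarray:
    parts = [np.array([float(real.K)])]
    for k in range(real.K):
        off = real.blob_offsets[k]
        parts.append(np.array([real.cluster_centers[k, 0], real.cluster_centers[k, 1], float(off.shape[0])]))
        parts.append(off.ravel())
        parts.append(real.blob_angles[k])
    return np.concatenate(parts)


def _unpack_clb(buf: np.ndarray) -> CLBRealization:
    i = 0
    K = int(buf[i]); i += 1
    centers = np.zeros((K, 2))
    offsets, angles = [], []
    for k in range(K):
        centers[k] = buf[i : i + 2]
        n_k = int(buf[i + 2]); i += 3
        offsets.append(buf[i : i + 2 * n_k].reshape(n_k, 2)); i += 2 * n_k
        angles.append(buf[i : i + n_k]); i += n_k
    return CLBRealization(cluster_centers=centers, blob_offsets=offsets, blob_angles=angles)


def load_dataset(path) -> Dataset:
    import json

    with h5py.File(path, "r") as f:
        cfg = TaskConfig.from_dict(json.loads(f.attrs["config"]))
        clean = f["noiseless"][...].reshape(f["noiseless"].shape[0], -1)
        labels = f["labels"][...]
        theta = f["theta"][...]
        images = f["images"][...].reshape(clean.shape) if "images" in f else None
        backgrounds: list = [None] * labels.size
        if "background_kind" in f:
            kinds = f["background_kind"][...]
            lc = f["lumpy_centers"][...]
            cp = f["clb_packed"][...]
            for i, k in enumerate(kinds):
                if k == 1:
                    backgrounds[i] = LumpyRealization(centers=lc[i].reshape(-1, 2))
                elif k == 2:
                    backgrounds[i] = _unpack_clb(cp[i])
    return Dataset(config=cfg, noiseless=clean, labels=labels, theta=theta,
                   backgrounds=backgrounds, images=images)
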