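"""Task configurations for the three simulation studies.

Each :class:`TaskConfig` pins every constant of one study — imaging system,
signal model and its random-parameter prior, background model, noise level,
utility function, and dataset sizes — so that a study is reproducible from
the config plus a seed alone.  The three shipped studies are:

``bke_amplitude``
    SKS/BKE amplitude estimation: zero background, Gaussian signal of width 1
    fixed at the image centre, random amplitude A_s ~ N(9, 4^2), system
    h = 16, w_m = 3.87, noise sigma_n = 40, Gaussian utility sigma_u = 3.

``lumpy_location``
    SKS/BKS localization on a lumpy background (Nbar = 5, a = 10, w_b = 7),
    signal A_s = 6, w_s = 3 at a uniform random location in (16, 48)^2,
    system h = 40, w_m = 0.5, noise sigma_n = 320; quadratic (eps1 = 100 or
    200) or l1 (eps2 = 20) utility.

``clb_width``
    SKS/BKS width estimation on a clustered lumpy background (Kbar = 70,
    Nbar = 20, L_x = 5, L_y = 2, alpha = 2.1, beta = 0.5, sigma = 12,
    per-image min-max normalization), signal of peak amplitude 0.05 at the
    centre with width ~ Uniform(1, 6), noise sigma_n = 0.33, Gaussian
    utility sigma_u = 3.  The signal is the grid-sampled Gaussian (the CLB
    background is formed directly in image space, so no PRF is applied).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .eroc import UtilityFunction
from .imaging import GaussianSignalParams, ImagingSystem, PixelGrid
from .object_models import CLBModelParams, LumpyModelParams

TASK_NAMES = ("bke_amplitude", "lumpy_location", "clb_width")


@dataclass(frozen=True)
class TaskConfig:
    name: str
    n_rows: int = 64
    n_cols: int = 64
    h: float = 1.0
    w_m: float = 1.0
    sigma_n: float = 1.0
    # signal: fixed entries are numbers; the random entry is a prior spec dict
    signal: dict = field(default_factory=dict)
    background: dict = field(default_factory=lambda: {"kind": "none"})
    utility: dict = field(default_factory=lambda: {"kind": "gaussian", "param": 3.0})
    n_train_present: int = 150_000
    n_train_absent: int = 150_000
    n_val_present: int = 1000
    n_val_absent: int = 1000
    n_test_present: int = 1000
    n_test_absent: int = 1000
    seed: int = 0

    # -- derived model objects -------------------------------------------
    def grid(self) -> PixelGrid:
        return PixelGrid(self.n_rows, self.n_cols)

    def system(self) -> ImagingSystem:
        return ImagingSystem(grid=self.grid(), h=self.h, w_m=self.w_m)

    def utility_fn(self) -> UtilityFunction:
        return UtilityFunction(kind=self.utility["kind"], param=float(self.utility["param"]))

    def background_params(self) -> LumpyModelParams | CLBModelParams | None:
        kind = self.background.get("kind", "none")
        opts = {k: v for k, v in self.background.items() if k != "kind"}
        if kind == "none":
            return None
        if kind == "lumpy":
            return LumpyModelParams(**opts)
        if kind == "clb":
            return CLBModelParams(**opts)
        raise ValueError(f"unknown background kind {kind!r}")

    # -- random signal parameter theta -----------------------------------
    @property
    def theta_names(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.signal.items() if isinstance(v, dict))

    @property
    def theta_dim(self) -> int:
        d = 0
        for v in self.signal.values():
            if isinstance(v, dict):
                d += 2 if v.get("vector", False) else 1
        return d

    def sample_theta(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n parameter vectors from the task prior, shape (n, theta_dim)."""
        cols = []
        for key, v in self.signal.items():
            if not isinstance(v, dict):
                continue
            ncomp = 2 if v.get("vector", False) else 1
            for _ in range(ncomp):
                if v["dist"] == "normal":
                    cols.append(rng.normal(v["mu"], v["sigma"], size=n))
                elif v["dist"] == "uniform":
                    cols.append(rng.uniform(v["lo"], v["hi"], size=n))
                else:
                    raise ValueError(f"unknown prior dist {v['dist']!r}")
        return np.column_stack(cols)

    def theta_support(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) bounds per theta component; infinite for Gaussian priors."""
        lo, hi = [], []
        for v in self.signal.values():
            if not isinstance(v, dict):
                continue
            ncomp = 2 if v.get("vector", False) else 1
            for _ in range(ncomp):
                if v["dist"] == "uniform":
                    lo.append(v["lo"])
                    hi.append(v["hi"])
                else:
                    lo.append(-np.inf)
                    hi.append(np.inf)
        return np.array(lo), np.array(hi)

    def log_prior(self, theta: np.ndarray) -> float:
        """Log prior density of one theta vector (up to the uniform constant)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        lp = 0.0
        i = 0
        for v in self.signal.values():
            if not isinstance(v, dict):
                continue
            ncomp = 2 if v.get("vector", False) else 1
            for _ in range(ncomp):
                x = theta[i]
                if v["dist"] == "normal":
                    lp += -0.5 * ((x - v["mu"]) / v["sigma"]) ** 2
                else:
                    if not (v["lo"] < x < v["hi"]):
                        return -np.inf
                i += 1
        return lp

    def signal_params_for(self, theta) -> GaussianSignalParams:
        """Assemble the full signal parameter set for one theta vector."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        vals = {}
        i = 0
        for key, v in self.signal.items():
            if isinstance(v, dict):
                if v.get("vector", False):
                    vals[key] = (theta[i], theta[i + 1])
                    i += 2
                else:
                    vals[key] = float(theta[i])
                    i += 1
            else:
                vals[key] = tuple(v) if isinstance(v, (list, tuple)) else float(v)
        return GaussianSignalParams(A_s=vals["A_s"], w_s=vals["w_s"], r_s=tuple(np.atleast_1d(vals["r_s"])))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_sizes(self, **kwargs) -> "TaskConfig":
        return replace(self, **kwargs)


def bke_amplitude() -> TaskConfig:
    return TaskConfig(
        name="bke_amplitude",
        h=16.0,
        w_m=3.87,
        sigma_n=40.0,
        signal={
            "A_s": {"dist": "normal", "mu": 9.0, "sigma": 4.0},
            "w_s": 1.0,
            "r_s": [32.0, 32.0],
        },
        background={"kind": "none"},
        utility={"kind": "gaussian", "param": 3.0},
    )


def lumpy_location(utility_kind: str = "l1", utility_param: float = 20.0) -> TaskConfig:
    return TaskConfig(
        name="lumpy_location",
        h=40.0,
        w_m=0.5,
        sigma_n=320.0,
        signal={
            "A_s": 6.0,
            "w_s": 3.0,
            "r_s": {"dist": "uniform", "lo": 16.0, "hi": 48.0, "vector": True},
        },
        background={"kind": "lumpy", "N_bar": 5.0, "a": 10.0, "w_b": 7.0},
        utility={"kind": utility_kind, "param": utility_param},
    )


def clb_width() -> TaskConfig:
    return TaskConfig(
        name="clb_width",
        h=1.0,
        w_m=0.0,  # CLB study: signal is the grid-sampled Gaussian, no PRF
        sigma_n=0.33,
        signal={
            "A_s": 0.05,
            "w_s": {"dist": "uniform", "lo": 1.0, "hi": 6.0},
            "r_s": [32.0, 32.0],
        },
        background={
            "kind": "clb",
            "K_bar": 70.0,
            "N_bar": 20.0,
            "L_x": 5.0,
            "L_y": 2.0,
            "alpha_blob": 2.1,
            "beta": 0.5,
            "sigma_cluster": 12.0,
        },
        utility={"kind": "gaussian", "param": 3.0},
        n_train_present=200_000,
        n_train_absent=200_000,
    )


_FACTORIES = {
    "bke_amplitude": bke_amplitude,
    "lumpy_location": lumpy_location,
    "clb_width": clb_width,
}


def default_config(name: str, **kwargs) -> TaskConfig:
    """The shipped default configuration for one of the three studies."""
    if name not in _FACTORIES:
        raise ValueError(f"unknown task {name!r}; expected one of {TASK_NAMES}")
    return _FACTORIES[name](**kwargs)
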