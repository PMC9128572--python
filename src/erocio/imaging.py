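"""Linear continuous-to-discrete imaging model with Gaussian point-response functions.

The imaging system is an idealized parallel-hole collimator: a linear C-D
operator whose m-th measurement is the object integrated against an isotropic
Gaussian PRF of height ``h`` and width ``w_m`` centred on pixel ``m``.  For a
2D Gaussian object of amplitude ``A``, width ``w`` and centre ``r0``, the
measured image has the closed form

    [s]_m = A * h * w^2 / (w_m^2 + w^2)
            * exp(-||r_m - r0||^2 / (2 (w_m^2 + w^2)))

which is the only imaging physics used anywhere in this package.

Coordinate convention: pixel centres sit at integer coordinates 1..n in each
axis, images are stored flattened row-major (row = y, column = x), and the
measured image is treated as a plain 1-D vector throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PixelGrid:
    """Regular square pixel lattice with unit spacing.

    Pixel ``m = (row-1)*n_cols + (col-1)`` has centre ``(x=col, y=row)`` with
    ``col`` in 1..n_cols and ``row`` in 1..n_rows.
    """

    n_rows: int = 64
    n_cols: int = 64

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Physical support of the image, (x_lo, x_hi, y_lo, y_hi)."""
        return (0.5, self.n_cols + 0.5, 0.5, self.n_rows + 0.5)

    def pixel_centers(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) centres, row-major order."""
        cols = np.arange(1, self.n_cols + 1, dtype=float)
        rows = np.arange(1, self.n_rows + 1, dtype=float)
        X, Y = np.meshgrid(cols, rows)
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass(frozen=True)
class ImagingSystem:
    """Gaussian-PRF system: PRF height ``h`` and width ``w_m`` (pixels).

    ``w_m = 0`` denotes direct sampling of the object on the grid (used for
    tasks whose background model already lives in image space).
    """

    grid: PixelGrid = field(default_factory=PixelGrid)
    h: float = 1.0
    w_m: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("PRF height h must be positive")
        if self.w_m < 0:
            raise ValueError("PRF width w_m must be nonnegative")


@dataclass(frozen=True)
class GaussianSignalParams:
    """Parameters of the 2D Gaussian signal: amplitude, width, centre."""

    A_s: float
    w_s: float
    r_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.w_s <= 0:
            raise ValueError("signal width w_s must be positive")


def signal_image(sys: ImagingSystem, p: GaussianSignalParams) -> np.ndarray:
    """Measured image of a Gaussian signal through the Gaussian-PRF system.

    Returns the flattened image with
    ``[s]_m = A_s h w_s^2/(w_m^2+w_s^2) exp(-||r_m-r_s||^2 / (2(w_m^2+w_s^2)))``.
    """
    if p.w_s <= 0:
        raise ValueError("signal width w_s must be positive")
    w2 = sys.w_m**2 + p.w_s**2
    centers = sys.grid.pixel_centers()
    d2 = (centers[:, 0] - p.r_s[0]) ** 2 + (centers[:, 1] - p.r_s[1]) ** 2
    return p.A_s * sys.h * p.w_s**2 / w2 * np.exp(-d2 / (2.0 * w2))


def reference_signal(sys: ImagingSystem, w_s: float, r_s: tuple[float, float]) -> np.ndarray:
    """Unit-amplitude signal template (signal_image with A_s = 1)."""
    return signal_image(sys, GaussianSignalParams(A_s=1.0, w_s=w_s, r_s=tuple(r_s)))


@dataclass(frozen=True)
class GaussianNoiseModel:
    """i.i.d. zero-mean Gaussian measurement noise.

    Noise is drawn from a counter-based stream: ``sample(shape, counter)`` is a
    pure function of (seed, counter), so semi-online training can redraw fresh
    noise per epoch while remaining exactly reproducible.
    """

    sigma_n: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_n <= 0:
            raise ValueError("noise std sigma_n must be positive")

    def sample(self, shape: int | tuple[int, ...], counter: int = 0) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(int(counter),))
        )
        return rng.normal(0.0, self.sigma_n, size=shape)


def render_measurement(
    b: np.ndarray,
    s: np.ndarray | None,
    noise: GaussianNoiseModel,
    counter: int = 0,
) -> np.ndarray:
    """Measured image g = b + s + n (signal present) or g = b + n (absent)."""
    b = np.asarray(b, dtype=float)
    if s is not None:
        s = np.asarray(s, dtype=float)
        if s.shape != b.shape:
            raise ValueError(f"signal shape {s.shape} != background shape {b.shape}")
        clean = b + s
    else:
        clean = b
    return clean + noise.sample(clean.shape, counter=counter)


def save_image_png(image: np.ndarray, grid: PixelGrid, path) -> None:
    """Export one flattened image as a grayscale PNG (for documentation)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(np.asarray(image).reshape(grid.n_rows, grid.n_cols),
              cmap="gray", origin="lower")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def log_likelihood(g: np.ndarray, b: np.ndarray, s: np.ndarray, sigma_n: float) -> float:
    """Gaussian log-likelihood ln p(g | b, s) = -||g - b - s||^2 / (2 sigma_n^2).

    The additive normalization constant is fixed to 0; it is identical for all
    (b, s) at fixed g and cancels in every Metropolis-Hastings ratio.
    """
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    g = np.asarray(g, dtype=float)
    r = g - np.asarray(b, dtype=float) - np.asarray(s, dtype=float)
    if r.shape != g.shape:
        raise ValueError("shape mismatch between g, b, s")
    return -float(r.ravel() @ r.ravel()) / (2.0 * sigma_n**2)
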