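"""EROC analysis: utility functions, the EROC curve, and the AEROC estimator.

In a joint detection-estimation task an observer produces a test statistic
T(g) and, for cases called signal-present, a parameter estimate theta_hat(g).
The estimation ROC (EROC) curve plots the expected utility of the estimate on
true-positive decisions,

    U_TP(tau) = E[ u(theta_hat(g), theta) * step(T(g) - tau) | H1 ],

against the false-positive fraction FPF(tau) as the threshold tau sweeps.
The area under the curve (AEROC) is the figure of merit; with u == 1 it
reduces to the ordinary ROC AUC.  The nonparametric AEROC estimator used here
is the utility-weighted two-sample U-statistic

    AEROC = 1/(n0 n1) sum_i sum_j u_i [ 1(T1_i > T0_j) + 1/2 1(T1_i = T0_j) ],

the direct generalization of the Wilcoxon-Mann-Whitney AUC estimator; it
equals the trapezoidal area under the empirical EROC polyline.  Uncertainty
is conveyed by a seeded case-resampling bootstrap (percentile interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_UTILITY_KINDS = ("gaussian", "quadratic", "l1")


@dataclass(frozen=True)
class UtilityFunction:
    """Estimation utility u(theta_hat, theta).

    kind:
      - "gaussian":  exp(-||e||^2 / (2 sigma_u^2)), in (0, 1]
      - "quadratic": 1 - ||e||_2^2 / eps1 (may be negative)
      - "l1":        1 - ||e||_1 / eps2 (may be negative)
    ``param`` is sigma_u, eps1 or eps2 respectively.
    """

    kind: str
    param: float

    def __post_init__(self) -> None:
        if self.kind not in VALID_UTILITY_KINDS:
            raise ValueError(f"unknown utility kind {self.kind!r}")
        if self.param <= 0:
            raise ValueError("utility parameter must be positive")

    def __call__(self, theta_hat, theta) -> np.ndarray:
        return evaluate_utility(self, theta_hat, theta)


def evaluate_utility(u: UtilityFunction, theta_hat, theta) -> np.ndarray | float:
    """Evaluate u(theta_hat, theta); the last axis is the parameter dimension.

    A 1-D input is a single d-dimensional case; stacks of cases are (n, d)
    arrays (use (n, 1) for scalar parameters).  Inputs broadcast, so a single
    estimate can be scored against (J, d) posterior samples in one call.
    Returns a float for a single case, an array otherwise.
    """
    th = np.asarray(theta_hat, dtype=float)
    t = np.asarray(theta, dtype=float)
    if th.ndim == 0:
        th = th[None]
    if t.ndim == 0:
        t = t[None]
    e = th - t
    if u.kind == "gaussian":
        out = np.exp(-np.sum(e**2, axis=-1) / (2.0 * u.param**2))
    elif u.kind == "quadratic":
        out = 1.0 - np.sum(e**2, axis=-1) / u.param
    else:  # l1
        out = 1.0 - np.sum(np.abs(e), axis=-1) / u.param
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class EROCResult:
    """EROC polyline, AEROC point estimate, and 90% bootstrap CI."""

    fpf: np.ndarray
    u_tp: np.ndarray
    aeroc: float
    ci90: tuple[float, float] | None = None
    n0: int = 0
    n1: int = 0

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.fpf, self.u_tp])


def _check_classes(t0, t1):
    t0 = np.asarray(t0, dtype=float).ravel()
    t1 = np.asarray(t1, dtype=float).ravel()
    if t0.size == 0 or t1.size == 0:
        raise ValueError("both signal-absent and signal-present cases are required")
    return t0, t1


def eroc_curve(t0, t1, utilities_h1) -> tuple[np.ndarray, np.ndarray]:
    """Empirical EROC polyline over the pooled threshold sweep.

    ``t0``/``t1`` are test statistics of the signal-absent / signal-present
    cases; ``utilities_h1[i] = u(theta_hat_i, theta_i)``.  Thresholds are the
    distinct pooled T values plus +/- infinity sentinels; the decision rule is
    strict (T > tau).  Returns (fpf, u_tp) ordered from tau = +inf, the point
    (0, 0), down to tau = -inf, the point (1, mean utility).
    """
    t0, t1 = _check_classes(t0, t1)
    u1 = np.asarray(utilities_h1, dtype=float).ravel()
    if u1.shape != t1.shape:
        raise ValueError("utilities_h1 must align with the signal-present cases")
    taus = np.unique(np.concatenate([t0, t1]))  # ascending
    # strict ">" counts via searchsorted on sorted arrays
    t0s = np.sort(t0)
    order1 = np.argsort(t1, kind="stable")
    t1s = t1[order1]
    u_sorted = u1[order1]
    # suffix sums of utility over T1 > tau
    csum = np.concatenate([[0.0], np.cumsum(u_sorted)])
    fpf = (t0.size - np.searchsorted(t0s, taus, side="right")) / t0.size
    idx = np.searchsorted(t1s, taus, side="right")
    u_tp = (csum[-1] - csum[idx]) / t1.size
    # order from high tau (0,0) to low tau (1, mean u); append sentinels
    fpf = np.concatenate([[0.0], fpf[::-1], [1.0]])
    u_tp = np.concatenate([[0.0], u_tp[::-1], [float(np.mean(u1))]])
    return fpf, u_tp


def aeroc_point(t0, t1, utilities_h1) -> float:
    """Utility-weighted U-statistic AEROC with 1/2 weight on T1 = T0 ties."""
    t0, t1 = _check_classes(t0, t1)
    u1 = np.asarray(utilities_h1, dtype=float).ravel()
    t0s = np.sort(t0)
    n_less = np.searchsorted(t0s, t1, side="left")
    n_leq = np.searchsorted(t0s, t1, side="right")
    w = n_less + 0.5 * (n_leq - n_less)
    return float(np.sum(u1 * w) / (t0.size * t1.size))


def aeroc(
    t0,
    t1,
    utilities_h1,
    n_boot: int = 2000,
    seed: int = 0,
    ci: bool = True,
) -> tuple[float, tuple[float, float] | None]:
    """AEROC point estimate and 90% case-resampling bootstrap CI.

    H0 and H1 cases are resampled independently (``n_boot`` replicates, seeded
    percentile interval).  Set ``ci=False`` to skip the bootstrap.
    """
    t0, t1 = _check_classes(t0, t1)
    u1 = np.asarray(utilities_h1, dtype=float).ravel()
    est = aeroc_point(t0, t1, u1)
    if not ci:
        return est, None
    if t0.size < 2 or t1.size < 2:
        raise ValueError("need at least 2 cases per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        i0 = rng.integers(0, t0.size, size=t0.size)
        i1 = rng.integers(0, t1.size, size=t1.size)
        reps[b] = aeroc_point(t0[i0], t1[i1], u1[i1])
    lo, hi = np.percentile(reps, [5.0, 95.0])
    return est, (float(lo), float(hi))


def evaluate_observer(t0, t1, utilities_h1, n_boot: int = 2000, seed: int = 0) -> EROCResult:
    """Full EROC evaluation: curve, AEROC, and 90% CI in one call."""
    fpf, u_tp = eroc_curve(t0, t1, utilities_h1)
    est, ci90 = aeroc(t0, t1, utilities_h1, n_boot=n_boot, seed=seed)
    return EROCResult(
        fpf=fpf, u_tp=u_tp, aeroc=est, ci90=ci90,
        n0=np.asarray(t0).size, n1=np.asarray(t1).size,
    )


def curve_to_csv(result: EROCResult, path) -> None:
    """Write the (FPF, U_TP) polyline as a two-column CSV."""
    np.savetxt(
        path,
        result.curve,
        delimiter=",",
        header="fpf,u_tp",
        comments="",
    )


def summary_dict(result: EROCResult) -> dict:
    d = {"aeroc": result.aeroc, "n0": result.n0, "n1": result.n1}
    if result.ci90 is not None:
        d["ci90"] = list(result.ci90)
    return d


def plot_curves(results: dict[str, EROCResult], path=None, ax=None):
    """Plot one or more EROC curves; returns the matplotlib axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, res in results.items():
        ax.plot(res.fpf, res.u_tp, label=f"{name} (AEROC={res.aeroc:.3f})")
    ax.set_xlabel("false-positive fraction")
    ax.set_ylabel("expected utility of TP decisions")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax
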