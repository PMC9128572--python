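"""Config-driven reproduction of the three simulation studies.

``run_experiment`` wires the pipeline together: generate the seeded test set
for a task, apply the requested observers, and evaluate each with EROC/AEROC
(with bootstrap CIs), optionally writing per-case outputs, curve CSVs, a JSON
summary and a Markdown comparison report to a run directory.  Observer names:

* ``analytic_io``   closed-form SKS/BKE ideal observer (amplitude task only)
* ``slo``           scanning linear observer (fit on noiseless images)
* ``mcmc_io``       MCMC ideal-observer approximation (quadratic utility)
* ``subideal_cnn``  trained multi-task CNN, detection head only
* ``hybrid_cnn``    trained multi-task CNN combined with the MCMC sampler

Scale knobs (dataset sizes, chain lengths, training iterations) are explicit
arguments so studies can be run at full or reduced scale without touching
task parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TaskConfig, default_config
from .datasets import Dataset, generate_dataset
from .eroc import EROCResult, curve_to_csv, evaluate_observer, evaluate_utility
from .imaging import reference_signal, signal_image
from .observers import (
    AmplitudePrior,
    BoxPrior,
    MCMCConfig,
    MultiTaskCNN,
    MultiTaskNetSpec,
    TrainConfig,
    UnsupportedUtilityError,
    analytic_io_bke,
    fit_slo,
    hybrid_io_apply,
    mcmc_io_quadratic,
    make_matched_filter_init,
    rwmh_bke,
    rwmh_bks,
    slo_apply,
    subideal_apply,
    train_multitask,
)

OBSERVER_NAMES = ("analytic_io", "slo", "mcmc_io", "subideal_cnn", "hybrid_cnn")


def make_signal_family(cfg: TaskConfig):
    """theta -> signal image for the task's signal model."""
    sys = cfg.system()
    return lambda theta: signal_image(sys, cfg.signal_params_for(theta))


def make_theta_prior(cfg: TaskConfig):
    """Sampler/density object for the task's theta prior."""
    lo, hi = cfg.theta_support()
    if np.all(np.isfinite(lo)):
        return BoxPrior(lo=tuple(lo), hi=tuple(hi))
    spec = next(v for v in cfg.signal.values() if isinstance(v, dict))
    return AmplitudePrior(mu_A=spec["mu"], sigma_A=spec["sigma"])


def slo_theta_grid(cfg: TaskConfig, n_scalar: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """(theta_grid, log_prior) for the SLO scan.

    Location tasks scan the integer-pixel lattice inside the prior box;
    scalar tasks scan ``n_scalar`` uniform points over the prior support
    (mean +/- 3 sigma for a Gaussian prior, with the Gaussian log density).
    """
    lo, hi = cfg.theta_support()
    if lo.size == 2:  # location lattice
        xs = np.arange(np.floor(lo[0]) + 1.0, np.ceil(hi[0]))
        ys = np.arange(np.floor(lo[1]) + 1.0, np.ceil(hi[1]))
        X, Y = np.meshgrid(xs, ys)
        grid = np.column_stack([X.ravel(), Y.ravel()])
        return grid, np.zeros(grid.shape[0])
    if np.isfinite(lo[0]):
        grid = np.linspace(lo[0], hi[0], n_scalar)[:, None]
        return grid, np.zeros(n_scalar)
    prior = make_theta_prior(cfg)
    grid = np.linspace(prior.mu_A - 3 * prior.sigma_A, prior.mu_A + 3 * prior.sigma_A, n_scalar)
    lp = -0.5 * ((grid - prior.mu_A) / prior.sigma_A) ** 2
    return grid[:, None], lp


def fit_slo_for_task(
    cfg: TaskConfig,
    n_fit_present: int = 4000,
    n_fit_absent: int = 4000,
    seed: int = 0,
):
    """Generate noiseless fit images for the task and fit the SLO."""
    fit_ds = generate_dataset(
        cfg, n_fit_present, n_fit_absent, seed=seed, noiseless=True, keep_backgrounds=False
    )
    pres = fit_ds.labels == 1
    grid, lp = slo_theta_grid(cfg)
    return fit_slo(
        noiseless_present=fit_ds.noiseless[pres],
        theta_present=fit_ds.theta,
        noiseless_absent=fit_ds.noiseless[~pres],
        theta_grid=grid,
        sigma_n=cfg.sigma_n,
        signal_fn=make_signal_family(cfg),
        log_prior=lp,
    )


def _mcmc_cfg_for_task(cfg: TaskConfig, mcmc_cfg: MCMCConfig | None, seed: int) -> MCMCConfig:
    if mcmc_cfg is not None:
        return mcmc_cfg
    std = 3.0 if cfg.name == "bke_amplitude" else 4.0
    return MCMCConfig(proposal_std_theta=std, proposal_std_lump=4.0, seed=seed)


def make_posterior_sampler(cfg: TaskConfig, test_ds: Dataset, mcmc_cfg: MCMCConfig):
    """Per-case posterior sampler g -> theta samples for the hybrid observer."""
    prior = make_theta_prior(cfg)
    fam = make_signal_family(cfg)
    bp = cfg.background_params()
    mf_init = make_matched_filter_init(fam, prior)
    case_index = {"i": 0}

    def sampler(g):
        i = case_index["i"]
        cfg_i = MCMCConfig(
            n_samples=mcmc_cfg.n_samples, burn_in=mcmc_cfg.burn_in, thin=mcmc_cfg.thin,
            proposal_std_theta=mcmc_cfg.proposal_std_theta,
            proposal_std_lump=mcmc_cfg.proposal_std_lump, seed=mcmc_cfg.seed + i,
        )
        if bp is None:
            return rwmh_bke(g, prior, fam, cfg.sigma_n, cfg_i, theta0=mf_init(g))
        real = test_ds.backgrounds[i]
        samples, _ = rwmh_bks(
            g, prior, bp, cfg.sigma_n, cfg_i, cfg.system(), fam,
            init_realization=real, theta0=mf_init(g),
        )
        return samples

    return sampler, case_index


@dataclass
class ExperimentResult:
    name: str
    eroc: EROCResult
    outputs: pd.DataFrame
    error: str | None = None


def _observer_outputs(
    name: str,
    cfg: TaskConfig,
    test_ds: Dataset,
    seed: int,
    slo_fit: tuple[int, int],
    mcmc_cfg: MCMCConfig | None,
    net: MultiTaskCNN | None,
    net_spec: MultiTaskNetSpec | None,
    train_cfg: TrainConfig | None,
):
    images = test_ds.images
    pres = test_ds.labels == 1
    u = cfg.utility_fn()
    if name == "analytic_io":
        if cfg.background.get("kind") != "none":
            raise ValueError("analytic_io applies only to the BKE amplitude task")
        prior = make_theta_prior(cfg)
        p = cfg.signal_params_for(prior.initial())  # fixed task w_s and r_s
        s_ref = reference_signal(cfg.system(), w_s=p.w_s, r_s=p.r_s)
        t, a_hat = analytic_io_bke(images, s_ref, prior, cfg.sigma_n)
        return t, a_hat[:, None]
    if name == "slo":
        model = fit_slo_for_task(cfg, *slo_fit, seed=seed + 1)
        t, theta_hat = slo_apply(model, images)
        return t, theta_hat
    mcfg = _mcmc_cfg_for_task(cfg, mcmc_cfg, seed)
    if name == "mcmc_io":
        if cfg.background.get("kind") == "clb":
            raise UnsupportedUtilityError("MCMC-IO is not available for the CLB object model")
        prior = make_theta_prior(cfg)
        fam = make_signal_family(cfg)
        bp = cfg.background_params()
        mf_init = make_matched_filter_init(fam, prior)
        t = np.empty(test_ds.n_cases)
        th = np.empty((test_ds.n_cases, cfg.theta_dim))
        for i in range(test_ds.n_cases):
            ci = MCMCConfig(
                n_samples=mcfg.n_samples, burn_in=mcfg.burn_in, thin=mcfg.thin,
                proposal_std_theta=mcfg.proposal_std_theta,
                proposal_std_lump=mcfg.proposal_std_lump, seed=mcfg.seed + i,
            )
            t[i], th[i], _, _ = mcmc_io_quadratic(
                images[i], prior, bp, cfg.sigma_n, u, ci,
                sys=cfg.system(), signal_family=fam,
                init_realization=test_ds.backgrounds[i], theta0=mf_init(images[i]),
            )
        return t, th
    if name in ("subideal_cnn", "hybrid_cnn"):
        if net is None:
            if train_cfg is None or net_spec is None:
                raise ValueError(f"{name} requires a trained net or (net_spec, train_cfg)")
            train_ds = generate_dataset(
                cfg, cfg.n_train_present, cfg.n_train_absent, seed=seed + 2, noiseless=True
            )
            net, _ = train_multitask(train_ds, net_spec, train_cfg)
        if name == "subideal_cnn":
            return subideal_apply(net, images)
        sampler, idx = make_posterior_sampler(cfg, test_ds, mcfg)
        t = np.empty(test_ds.n_cases)
        th = np.empty((test_ds.n_cases, cfg.theta_dim))
        for i in range(test_ds.n_cases):
            idx["i"] = i
            t[i], th[i], _, _ = hybrid_io_apply(net, sampler, u, images[i])
        return t, th
    raise ValueError(f"unknown observer {name!r}; expected one of {OBSERVER_NAMES}")


def run_experiment(
    config: TaskConfig | str,
    observers=("analytic_io",),
    seed: int = 0,
    out_dir: str | Path | None = None,
    slo_fit: tuple[int, int] = (4000, 4000),
    mcmc_cfg: MCMCConfig | None = None,
    net: MultiTaskCNN | None = None,
    net_spec: MultiTaskNetSpec | None = None,
    train_cfg: TrainConfig | None = None,
    n_boot: int = 2000,
) -> dict[str, ExperimentResult]:
    """Generate the test set, apply observers, evaluate EROC/AEROC.

    Observer/task mismatches (e.g. MCMC-IO under an l1 utility) are reported
    in the result bundle rather than raised.  With an empty observer list the
    run is data-only.  Fully deterministic given the seed.
    """
    cfg = default_config(config) if isinstance(config, str) else config
    test_ds = generate_dataset(cfg, cfg.n_test_present, cfg.n_test_absent, seed=seed)
    u = cfg.utility_fn()
    pres = test_ds.labels == 1
    results: dict[str, ExperimentResult] = {}
    for name in observers:
        try:
            if name == "mcmc_io" and u.kind != "quadratic":
                raise UnsupportedUtilityError(
                    f"MCMC-IO requires the quadratic utility; task uses {u.kind!r}"
                )
            t, theta_hat = _observer_outputs(
                name, cfg, test_ds, seed, slo_fit, mcmc_cfg, net, net_spec, train_cfg
            )
        except UnsupportedUtilityError as exc:
            results[name] = ExperimentResult(
                name=name, eroc=None, outputs=pd.DataFrame(), error=str(exc)
            )
            continue
        utilities = np.asarray(
            evaluate_utility(u, np.atleast_2d(theta_hat)[pres], test_ds.theta)
        )
        eroc = evaluate_observer(t[~pres], t[pres], utilities, n_boot=n_boot, seed=seed)
        df = pd.DataFrame({"case_id": np.arange(test_ds.n_cases),
                           "label": test_ds.labels, "T": t})
        for j in range(np.atleast_2d(theta_hat).shape[1]):
            df[f"theta_hat_{j}"] = np.atleast_2d(theta_hat)[:, j]
        results[name] = ExperimentResult(name=name, eroc=eroc, outputs=df)

    if out_dir is not None:
        _write_results(Path(out_dir), cfg, results)
    return results


def compare_observers(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    """AEROC comparison table, sorted by descending AEROC.

    Observers whose 90% CIs overlap are flagged as statistically equivalent
    (listed by name in the ``equivalent_to`` column).
    """
    rows = []
    ok = {n: r for n, r in results.items() if r.error is None}
    for name, r in ok.items():
        lo, hi = r.eroc.ci90 if r.eroc.ci90 else (np.nan, np.nan)
        rows.append({"observer": name, "aeroc": r.eroc.aeroc, "ci_lo": lo, "ci_hi": hi})
    df = pd.DataFrame(rows).sort_values("aeroc", ascending=False).reset_index(drop=True)
    equiv = []
    for _, a in df.iterrows():
        names = [
            b["observer"]
            for _, b in df.iterrows()
            if b["observer"] != a["observer"]
            and a["ci_lo"] <= b["ci_hi"] and b["ci_lo"] <= a["ci_hi"]
        ]
        equiv.append(",".join(names))
    df["equivalent_to"] = equiv
    return df


def _write_results(out: Path, cfg: TaskConfig, results: dict[str, ExperimentResult]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    summary = {}
    for name, r in results.items():
        if r.error is not None:
            summary[name] = {"error": r.error}
            continue
        r.outputs.to_csv(out / f"{name}_outputs.csv", index=False)
        curve_to_csv(r.eroc, out / f"{name}_curve.csv")
        summary[name] = {
            "aeroc": r.eroc.aeroc,
            "ci90": list(r.eroc.ci90) if r.eroc.ci90 else None,
            "n0": r.eroc.n0,
            "n1": r.eroc.n1,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    table = compare_observers(results)
    lines = [f"# {cfg.name}", "", table.to_markdown(index=False), ""]
    for name, r in results.items():
        if r.error is not None:
            lines.append(f"- `{name}`: not applicable ({r.error})")
    (out / "report.md").write_text("\n".join(lines))
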