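"""Simulation-study harness: replicate execution and performance measures.

For each replicate a dataset is generated from a :class:`ScenarioConfig`,
the full 3-step BCH-GEE and the naive GEE are fitted under the requested
working correlation structures, and the class contrasts beta_1 - beta_2
and beta_2 - beta_3 together with phi, alpha_w, alpha_b, sandwich
variances and Wald p-values are recorded.  Replicate seeds derive
deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bchgee.classify import bch_weights, classification_error, modal_assign, \
    posterior_probs
from bchgee.datagen import ScenarioConfig, simulate_dataset
from bchgee.gee import expand_data, fit_naive_gee, fit_weighted_gee, wald_test
from bchgee.zip_lca import fit_zip_lca

__all__ = [
    "PerformanceReport",
    "performance_measures",
    "run_scenario",
    "type1_error",
]


def performance_measures(estimates, sandwich_vars, true_value) -> dict:
    """Summary row: %bias, MSE and variances on the x1000 reporting scale.

    ``pct_bias = 100 (mean(est) - true) / true``; when the true value is
    zero the raw bias (x1000, like MSE) is reported instead and
    ``pct_bias`` is NaN.  ``var_e`` is the empirical variance of the
    estimates, ``var_f`` the mean sandwich variance.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 estimates")
    sv = None if sandwich_vars is None else np.asarray(sandwich_vars, float)
    bias = float(est.mean() - true_value)
    row = {
        "true": float(true_value),
        "mean_estimate": float(est.mean()),
        "bias_x1000": 1000.0 * bias,
        "pct_bias": 100.0 * bias / true_value if true_value != 0 else np.nan,
        "mse_x1000": 1000.0 * float(np.mean((est - true_value) ** 2)),
        "var_e_x1000": 1000.0 * float(est.var(ddof=1)),
        "var_f_x1000": (np.nan if sv is None
                        else 1000.0 * float(sv.mean())),
        "n": int(est.size),
    }
    return row


def type1_error(pvalues, alpha: float = 0.05) -> tuple[float, float]:
    """Rejection rate at level ``alpha`` and its Monte-Carlo SE."""
    p = np.asarray(pvalues, dtype=float)
    rate = float((p < alpha).mean())
    mc_se = float(np.sqrt(rate * (1.0 - rate) / p.size))
    return rate, mc_se


@dataclass
class PerformanceReport:
    """Aggregated simulation results for one scenario."""

    scenario: str
    replicates: int
    n_failed: int
    table: pd.DataFrame
    failures: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_CONTRASTS = {
    "beta1-beta2": np.array([1.0, -1.0, 0.0, 0.0]),
    "beta2-beta3": np.array([0.0, 1.0, -1.0, 0.0]),
}


def _one_replicate(config: ScenarioConfig, seed, estimators, structures,
                   lca_starts: int, lca_tol: float) -> dict:
    """Generate one dataset and fit every estimator/structure combination."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    data_seed, lca_seed = ss.spawn(2)
    panel, children, paths = simulate_dataset(config, seed=data_seed)
    model = fit_zip_lca(panel, config.L, n_starts=lca_starts, tol=lca_tol,
                        seed=lca_seed)
    post = posterior_probs(model, panel)
    assign = modal_assign(post)
    out: dict = {}
    if "oracle" in estimators:
        # reference estimator on the true latent classes: exactly unbiased
        # for the contrasts, used as a control variate for bias estimation
        true_assign = pd.DataFrame({
            "school_id": panel["school_id"],
            "time": panel["time"],
            "assigned": paths.reshape(-1) + 1,
        })
        fit = fit_naive_gee(children, true_assign, config.L,
                            structure="independence")
        out[("oracle", "independence")] = _extract(fit)
    if "bch" in estimators:
        D = classification_error(post, assign)
        weights = bch_weights(D, assign)
        design = expand_data(children, assign, weights)
        for structure in structures:
            fit = fit_weighted_gee(design, structure=structure)
            out[("bch", structure)] = _extract(fit)
    if "naive" in estimators:
        for structure in structures:
            fit = fit_naive_gee(children, assign, config.L,
                                structure=structure)
            out[("naive", structure)] = _extract(fit)
    return out


def _extract(fit) -> dict:
    rec = {"phi": fit.phi, "alpha_w": fit.alpha_w, "alpha_b": fit.alpha_b,
           "converged": fit.converged}
    for name, c in _CONTRASTS.items():
        w = wald_test(fit, c)
        rec[name] = {"estimate": w.estimate, "var": w.se ** 2,
                     "pvalue": w.pvalue}
    return rec


def run_scenario(config: ScenarioConfig, estimators=("bch", "naive"),
                 structures=("independence",), replicates: int = 200,
                 seed: int = 0, workers: int = 1, lca_starts: int = 3,
                 lca_tol: float = 1e-7, alpha: float = 0.05
                 ) -> PerformanceReport:
    """Monte-Carlo evaluation of the estimators on one scenario.

    Data are generated once per replicate and shared by all estimators
    and correlation structures.  Failed replicates (e.g., a singular
    classification-error matrix) are logged with their seeds and excluded
    from the aggregation.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rep_seeds = root.spawn(replicates)
    results = []
    failures: list[str] = []

    def run_one(i):
        try:
            return _one_replicate(config, rep_seeds[i], estimators,
                                  structures, lca_starts, lca_tol)
        except Exception as exc:  # noqa: BLE001 - replicate-level logging
            return f"replicate {i}: {type(exc).__name__}: {exc}"

    if workers > 1:
        from joblib import Parallel, delayed
        raw = Parallel(n_jobs=workers)(delayed(run_one)(i)
                                       for i in range(replicates))
    else:
        raw = [run_one(i) for i in range(replicates)]
    for r in raw:
        (failures if isinstance(r, str) else results).append(r)
    if len(results) < 2:
        raise RuntimeError(
            f"fewer than 2 successful replicates; first failures: "
            f"{failures[:3]}")

    true_contrast = {
        "beta1-beta2": float(config.betas[0] - config.betas[1]),
        "beta2-beta3": float(config.betas[1] - config.betas[2]),
    }
    true_other = {"phi": config.total_variance, "alpha_w": config.alpha_w,
                  "alpha_b": config.alpha_b}
    rows = []
    combos = [(e, s) for e in estimators
              for s in (("independence",) if e == "oracle" else structures)]
    for estimator, structure in combos:
        recs = [r[(estimator, structure)] for r in results]
        for cname in _CONTRASTS:
            est = np.array([r[cname]["estimate"] for r in recs])
            sv = np.array([r[cname]["var"] for r in recs])
            pv = np.array([r[cname]["pvalue"] for r in recs])
            row = {"scenario": config.name, "estimator": estimator,
                   "structure": structure, "param": cname}
            row.update(performance_measures(est, sv, true_contrast[cname]))
            if estimator == "bch" and "oracle" in estimators:
                # control-variate bias estimate: subtract the exactly
                # unbiased true-class estimator replicate by replicate
                oracle = np.array(
                    [r[("oracle", "independence")][cname]["estimate"]
                     for r in results])
                true = true_contrast[cname]
                cv = est - oracle + true
                row["mean_estimate_cv"] = float(cv.mean())
                row["pct_bias_cv"] = (100.0 * (cv.mean() - true) / true
                                      if true != 0 else np.nan)
                row["bias_cv_x1000"] = 1000.0 * float(cv.mean() - true)
            rate, mc_se = type1_error(pv, alpha)
            row["reject_rate"] = rate
            row["reject_mc_se"] = mc_se
            rows.append(row)
        for pname in ("phi",) + (("alpha_w", "alpha_b")
                                 if structure == "exchangeable2" else ()):
            est = np.array([r[pname] for r in recs])
            row = {"scenario": config.name, "estimator": estimator,
                   "structure": structure, "param": pname}
            row.update(performance_measures(est, None, true_other[pname]))
            row["reject_rate"] = np.nan
            row["reject_mc_se"] = np.nan
            rows.append(row)
    return PerformanceReport(
        scenario=config.name,
        replicates=len(results),
        n_failed=len(failures),
        table=pd.DataFrame(rows),
        failures=failures[:20],
    )
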