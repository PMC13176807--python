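"""Step 1: measurement-invariant zero-inflated Poisson latent class model.

The latent class models for every time point are estimated jointly by EM:
class prevalences are time-specific, while the ZIP measurement parameters
(zero-inflation probability ``p`` and Poisson rate ``lambda`` per class and
indicator) are shared across time points (measurement invariance).  The
Markov dependence between successive classes is deliberately ignored here;
it is recovered later by the latent transition analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ZipLcaModel",
    "fit_zip_lca",
    "model_selection",
    "n_parameters",
    "zip_logpmf",
    "zip_pmf",
]

_LAMBDA_FLOOR = 1e-6
_P_CLIP = 1e-6


def zip_logpmf(u, p, lam):
    """Log mass of the zero-inflated Poisson, vectorised and broadcast.

    ``P(U=0) = p + (1-p) e^{-lam}`` and
    ``P(U=u) = (1-p) e^{-lam} lam^u / u!`` for ``u >= 1``.
    """
    u = np.asarray(u)
    if not np.issubdtype(u.dtype, np.integer):
        uf = np.asarray(u, dtype=float)
        if np.any(uf != np.floor(uf)):
            raise ValueError("counts must be integers")
        u = uf.astype(np.int64)
    if np.any(u < 0):
        raise ValueError("counts must be nonnegative")
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("zero-inflation probability must lie in [0, 1]")
    if np.any(lam <= 0):
        raise ValueError("Poisson rate must be positive")
    u, p, lam = np.broadcast_arrays(u, p, lam)
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_1mp = np.log1p(-p)
    pois = log_1mp + u * np.log(lam) - lam - gammaln(u + 1.0)
    zero_mass = np.logaddexp(log_p, log_1mp - lam)
    return np.where(u == 0, zero_mass, pois)


def zip_pmf(u, p, lam):
    """ZIP probability mass; see :func:`zip_logpmf`."""
    return np.exp(zip_logpmf(u, p, lam))


@dataclass
class ZipLcaModel:
    """Fitted pooled ZIP latent class model.

    ``prevalences[t, s]`` is the class-s probability at time point ``t``
    (0-based time index); ``zip_p`` and ``zip_lambda`` are ``(L, J)``
    measurement parameters shared across time.  Classes are ordered by
    decreasing total Poisson rate ``sum_j lambda_{j|s}``.
    """

    L: int
    J: int
    T: int
    prevalences: np.ndarray
    zip_p: np.ndarray
    zip_lambda: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_parameters: int
    degenerate: bool = False
    n_obs: int = 0

    def to_json(self, path) -> None:
        payload = {
            "L": self.L, "J": self.J, "T": self.T,
            "prevalences": self.prevalences.tolist(),
            "zip_p": self.zip_p.tolist(),
            "zip_lambda": self.zip_lambda.tolist(),
            "loglik": self.loglik, "n_iter": self.n_iter,
            "converged": self.converged, "n_parameters": self.n_parameters,
            "degenerate": self.degenerate, "n_obs": self.n_obs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ZipLcaModel":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("prevalences", "zip_p", "zip_lambda"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def n_parameters(L: int, J: int, T: int) -> int:
    """Free parameters: T(L-1) prevalences plus 2JL ZIP parameters."""
    return T * (L - 1) + 2 * J * L


def _panel_arrays(panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Extract (counts, time index 0-based, N_s, T) from a school panel."""
    cols = [c for c in panel.columns if c.startswith("u_")]
    if not cols:
        raise ValueError("panel has no count columns u_1..u_J")
    cols = sorted(cols, key=lambda c: int(c.split("_")[1]))
    times = np.sort(panel["time"].unique())
    T = len(times)
    n_schools = panel["school_id"].nunique()
    if len(panel) != n_schools * T:
        raise ValueError("panel is not balanced (one row per school-time)")
    tidx = np.searchsorted(times, panel["time"].to_numpy())
    counts = panel[cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        cf = counts.astype(float)
        if np.any(cf != np.floor(cf)) or np.any(cf < 0):
            raise ValueError("counts must be nonnegative integers")
        counts = cf.astype(np.int64)
    return counts, tidx, n_schools, T


def _component_loglik(counts: np.ndarray, zip_p: np.ndarray,
                      zip_lambda: np.ndarray) -> np.ndarray:
    """(N, L) log density of each observation under each class."""
    N = counts.shape[0]
    L = zip_p.shape[0]
    out = np.empty((N, L))
    for s in range(L):
        out[:, s] = zip_logpmf(counts, zip_p[s], zip_lambda[s]).sum(axis=1)
    return out


def _em_once(counts: np.ndarray, tidx: np.ndarray, T: int, resp0: np.ndarray,
             tol: float, max_iter: int) -> dict:
    """Run EM from an initial responsibility matrix; returns raw results."""
    N, J = counts.shape
    L = resp0.shape[1]
    is_zero = counts == 0
    resp = resp0
    # sufficient-statistic matrices: the class-conditional log density is
    #   comp[:, s] = Z @ zero_mass_s + NZ @ (log(1-p_s) - lam_s)
    #                + U @ log(lam_s) - const_row
    Zmat = is_zero.astype(float)
    NZmat = 1.0 - Zmat
    Umat = counts.astype(float)
    const_row = (NZmat * gammaln(Umat + 1.0)).sum(axis=1)

    def component_loglik(zip_p: np.ndarray, zip_lambda: np.ndarray) -> np.ndarray:
        zero_mass = np.logaddexp(np.log(zip_p),
                                 np.log1p(-zip_p) - zip_lambda)    # (L, J)
        nz = np.log1p(-zip_p) - zip_lambda
        return (Zmat @ zero_mass.T + NZmat @ nz.T
                + Umat @ np.log(zip_lambda).T - const_row[:, None])
    # initial M-step from the provided responsibilities (no structural-zero
    # split available yet: treat all zeros as Poisson zeros, p from excess)
    zip_lambda = np.empty((L, J))
    zip_p = np.empty((L, J))
    for s in range(L):
        w = resp[:, s][:, None]
        tot = w.sum()
        mean = (w * counts).sum(axis=0) / tot
        zip_lambda[s] = np.maximum(mean, 0.1)
        frac0 = (w * is_zero).sum(axis=0) / tot
        zip_p[s] = np.clip(frac0 - np.exp(-zip_lambda[s]), _P_CLIP, 1 - _P_CLIP)
    prev = np.full((T, L), 1.0 / L)

    ll_old = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        # E-step: class responsibilities and structural-zero posteriors
        comp = component_loglik(zip_p, zip_lambda)
        with np.errstate(divide="ignore"):
            log_prev = np.log(prev)
        joint = comp + log_prev[tidx]
        m = joint.max(axis=1)
        norm = m + np.log(np.exp(joint - m[:, None]).sum(axis=1))
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(joint - norm[:, None])
        # share of each zero attributable to structural zero inflation
        denom0 = zip_p + (1 - zip_p) * np.exp(-zip_lambda)      # (L, J)
        z_share = zip_p / denom0
        # M-step
        prev = np.vstack([
            resp[tidx == t].mean(axis=0) for t in range(T)
        ])
        tot = resp.sum(axis=0)                                  # (L,)
        wz = resp.T @ Zmat                                      # (L, J)
        wu = resp.T @ Umat
        wb = wz * z_share                                       # sum_i w_i b_ij
        zip_p = np.clip(wb / tot[:, None], _P_CLIP, 1 - _P_CLIP)
        zip_lambda = np.maximum(
            wu / np.maximum(tot[:, None] - wb, 1e-300), _LAMBDA_FLOOR)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            converged = True
            break
        ll_old = ll
    # final log-likelihood at the last parameter values
    joint = component_loglik(zip_p, zip_lambda)
    with np.errstate(divide="ignore"):
        joint = joint + np.log(prev)[tidx]
    ll = float(logsumexp(joint, axis=1).sum())
    trace.append(ll)
    return {"prevalences": prev, "zip_p": zip_p, "zip_lambda": zip_lambda,
            "loglik": ll, "n_iter": it, "converged": converged,
            "trace": trace}


def fit_zip_lca(panel: pd.DataFrame, L: int, n_starts: int = 20,
                tol: float = 1e-8, max_iter: int = 2000, seed=None,
                prevalence_floor: float = 1e-4) -> ZipLcaModel:
    """Maximum-likelihood fit of the pooled ZIP latent class model.

    Runs EM from ``n_starts`` random initialisations (random Dirichlet
    responsibilities) and keeps the best converged log-likelihood.  The
    observed-data log-likelihood is non-decreasing over EM iterations;
    convergence is declared when its relative change falls below ``tol``.
    Classes are relabelled by decreasing total Poisson rate.  A fit with
    any prevalence below ``prevalence_floor`` is flagged ``degenerate``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    counts, tidx, n_schools, T = _panel_arrays(panel)
    N = counts.shape[0]
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts if L > 1 else 1)):
        if L == 1:
            resp0 = np.ones((N, 1))
        elif start == 0:
            # informed start: quantile split on total counts (high-count
            # observations seeded into low-index classes, matching the
            # label ordering convention), softened toward uniform
            order = np.argsort(-counts.sum(axis=1), kind="stable")
            groups = np.empty(N, dtype=np.int64)
            groups[order] = np.minimum(np.arange(N) * L // N, L - 1)
            resp0 = np.full((N, L), 0.5 / L)
            resp0[np.arange(N), groups] += 0.5
        else:
            resp0 = rng.dirichlet(np.ones(L), size=N)
        res = _em_once(counts, tidx, T, resp0, tol, max_iter)
        if best is None or res["loglik"] > best["loglik"]:
            best = res
    order = np.argsort(-best["zip_lambda"].sum(axis=1))
    prev = best["prevalences"][:, order]
    model = ZipLcaModel(
        L=L, J=counts.shape[1], T=T,
        prevalences=prev,
        zip_p=best["zip_p"][order],
        zip_lambda=best["zip_lambda"][order],
        loglik=best["loglik"],
        n_iter=best["n_iter"],
        converged=best["converged"],
        n_parameters=n_parameters(L, counts.shape[1], T),
        degenerate=bool(prev.min() < prevalence_floor),
        n_obs=N,
    )
    return model


def model_selection(panel: pd.DataFrame, L_range, n_starts: int = 20,
                    tol: float = 1e-8, max_iter: int = 2000,
                    seed=None) -> pd.DataFrame:
    """Fit statistics over a range of class counts.

    Returns one row per ``L`` with log-likelihood, AIC, BIC (sample size
    ``N_s * T``), sample-size-adjusted BIC, relative entropy of the
    posteriors, and the share of the smallest class among the modal
    assignments at the first time point.  Fit failures are recorded in the
    ``error`` column rather than raised.
    """
    from bchgee.classify import modal_assign, posterior_probs
    from bchgee.datagen import compute_entropy

    rows = []
    _, _, n_schools, T = _panel_arrays(panel)
    n_obs = n_schools * T
    rng = np.random.default_rng(seed)
    for L in L_range:
        row = {"L": L, "loglik": np.nan, "aic": np.nan, "bic": np.nan,
               "abic": np.nan, "entropy": np.nan,
               "smallest_class_prop": np.nan, "converged": False,
               "degenerate": False, "error": ""}
        try:
            model = fit_zip_lca(panel, L, n_starts=n_starts, tol=tol,
                                max_iter=max_iter,
                                seed=rng.integers(2**31))
            k = model.n_parameters
            row["loglik"] = model.loglik
            row["aic"] = -2 * model.loglik + 2 * k
            row["bic"] = -2 * model.loglik + k * np.log(n_obs)
            row["abic"] = -2 * model.loglik + k * np.log((n_obs + 2) / 24.0)
            row["converged"] = model.converged
            row["degenerate"] = model.degenerate
            post = posterior_probs(model, panel)
            pcols = [f"p_{s + 1}" for s in range(L)]
            if L > 1:
                row["entropy"] = compute_entropy(post[pcols].to_numpy())
            assign = modal_assign(post)
            first = assign[assign["time"] == assign["time"].min()]
            shares = (first["assigned"].value_counts()
                      .reindex(range(1, L + 1), fill_value=0)
                      / len(first))
            row["smallest_class_prop"] = float(shares.min())
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
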