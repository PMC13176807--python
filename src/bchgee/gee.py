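"""Step 3b: BCH-weighted GEE for the multilevel distal outcome.

The child-level data are expanded L-fold (one copy per possible latent
class); each copy carries the class indicator of its copy index and the
BCH weight of the school's assigned class, so that solving the weighted
estimating equations

    S(beta) = sum_i X_i' V_i^{-1} W_i (Y_i - X_i beta) = 0

undoes the modal-assignment misclassification.  Two working correlation
structures are supported: independence, and a two-parameter exchangeable
structure with separate within school-time (``alpha_w``) and between
time-point (``alpha_b``) correlations, with zero correlation between
copies inside a time point.  Per-school systems are solved through the
block-plus-rank-one structure of the correlation matrix, never forming
dense per-school inverses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bchgee.classify import BchWeights, bch_weights, classification_error, \
    modal_assign, posterior_probs
from bchgee.zip_lca import ZipLcaModel

__all__ = [
    "ExpandedDesign",
    "GeeFit",
    "WaldTest",
    "bootstrap_se",
    "expand_data",
    "fit_naive_gee",
    "fit_weighted_gee",
    "sandwich_cov",
    "wald_test",
]

_PHI_FLOOR = 1e-8
STRUCTURES = ("independence", "exchangeable2")


# --------------------------------------------------------------------------
# expanded design
# --------------------------------------------------------------------------

@dataclass
class ExpandedDesign:
    """L-fold expanded outcome/design/weight arrays plus index maps.

    Rows are ordered by (school, time, child, copy); each child-time
    contributes ``L`` consecutive rows whose class-indicator block is the
    identity.  ``st_seg`` labels (school, time) segments, ``n_st`` the
    number of children per segment.  ``N_total`` is the number of
    children (not expanded rows).
    """

    y: np.ndarray
    X: np.ndarray
    w: np.ndarray
    L: int
    colnames: list[str]
    school: np.ndarray          # per row, 0..n_schools-1
    st_seg: np.ndarray          # per row, segment id
    copy: np.ndarray            # per row, 0..L-1
    n_st: np.ndarray            # children per segment
    seg_school: np.ndarray      # school of each segment
    N_total: int
    n_schools: int

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def _segcopy_perm(self) -> tuple[np.ndarray, np.ndarray]:
        """Row permutation sorting by (segment, copy) plus run starts."""
        if not hasattr(self, "_segcopy_cache"):
            key = self.st_seg * self.L + self.copy
            perm = np.argsort(key, kind="stable")
            starts = np.searchsorted(key[perm],
                                     np.arange(len(self.n_st) * self.L))
            self._segcopy_cache = (perm, starts)
        return self._segcopy_cache

    @property
    def _school_starts(self) -> np.ndarray:
        """Row index where each school's (contiguous) block begins."""
        if not hasattr(self, "_school_starts_cache"):
            self._school_starts_cache = np.searchsorted(
                self.school, np.arange(self.n_schools))
        return self._school_starts_cache

    @property
    def Nw_over_L(self) -> float:
        """Unordered within-pair count divided by L: sum n_st(n_st-1)/2."""
        return float((self.n_st * (self.n_st - 1)).sum()) / 2.0

    @property
    def Nb_over_L(self) -> float:
        """Unordered between-pair count divided by L."""
        n_school = np.bincount(self.seg_school, weights=self.n_st,
                               minlength=self.n_schools)
        sq = np.bincount(self.seg_school, weights=self.n_st.astype(float) ** 2,
                         minlength=self.n_schools)
        return float(self.L * (n_school ** 2 - sq).sum()) / 2.0


def _sorted_children(children: pd.DataFrame, covariate_cols) -> pd.DataFrame:
    req = {"school_id", "time", "y", *covariate_cols}
    missing = req - set(children.columns)
    if missing:
        raise ValueError(f"child table is missing columns {sorted(missing)}")
    return children.sort_values(
        ["school_id", "time"], kind="stable").reset_index(drop=True)


def _segments(tab: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Factorise (school, time) into contiguous segments on sorted rows."""
    key = tab[["school_id", "time"]]
    seg, uniques = pd.factorize(
        key["school_id"].astype(str) + "\x00" + key["time"].astype(str))
    n_st = np.bincount(seg)
    school_codes, _ = pd.factorize(tab["school_id"])
    seg_school = np.zeros(len(n_st), dtype=np.int64)
    seg_school[seg] = school_codes
    return seg, n_st, school_codes, seg_school


def expand_data(children: pd.DataFrame, assign: pd.DataFrame,
                weights: BchWeights, covariate_cols=("z",)) -> ExpandedDesign:
    """Build the L-fold expanded design with BCH weight rows.

    Every child row is replicated ``L`` times; copy ``l`` carries the
    class-``l`` indicator and the ``l``-th entry of the D* row belonging
    to the school's assigned class at that time point.
    """
    covariate_cols = list(covariate_cols)
    base = _sorted_children(children, covariate_cols)
    amap = assign[["school_id", "time", "assigned"]]
    merged = base.merge(amap, on=["school_id", "time"], how="left",
                        validate="many_to_one")
    if merged["assigned"].isna().any():
        bad = (merged.loc[merged["assigned"].isna(), ["school_id", "time"]]
               .drop_duplicates().to_records(index=False).tolist())
        raise ValueError(f"no class assignment for school-times: {bad[:10]}")
    L = weights.Dstar.shape[0]
    n = len(merged)
    seg, n_st, school_codes, seg_school = _segments(merged)

    rep = np.repeat(np.arange(n), L)
    copy = np.tile(np.arange(L), n)
    y = merged["y"].to_numpy(dtype=float)[rep]
    X = np.zeros((n * L, L + len(covariate_cols)))
    X[np.arange(n * L), copy] = 1.0
    for j, c in enumerate(covariate_cols):
        X[:, L + j] = merged[c].to_numpy(dtype=float)[rep]
    assigned = merged["assigned"].to_numpy(dtype=np.int64) - 1
    w = weights.Dstar[copy, assigned[rep]]
    return ExpandedDesign(
        y=y, X=X, w=w, L=L,
        colnames=[f"class_{s + 1}" for s in range(L)] + covariate_cols,
        school=school_codes[rep],
        st_seg=seg[rep],
        copy=copy,
        n_st=n_st,
        seg_school=seg_school,
        N_total=n,
        n_schools=int(school_codes.max()) + 1,
    )


def _naive_design(children: pd.DataFrame, assign: pd.DataFrame, L: int,
                  covariate_cols=("z",)) -> ExpandedDesign:
    """Single-copy design: modal class indicators, unit weights."""
    covariate_cols = list(covariate_cols)
    base = _sorted_children(children, covariate_cols)
    merged = base.merge(assign[["school_id", "time", "assigned"]],
                        on=["school_id", "time"], how="left",
                        validate="many_to_one")
    if merged["assigned"].isna().any():
        bad = (merged.loc[merged["assigned"].isna(), ["school_id", "time"]]
               .drop_duplicates().to_records(index=False).tolist())
        raise ValueError(f"no class assignment for school-times: {bad[:10]}")
    n = len(merged)
    seg, n_st, school_codes, seg_school = _segments(merged)
    X = np.zeros((n, L + len(covariate_cols)))
    X[np.arange(n), merged["assigned"].to_numpy(dtype=np.int64) - 1] = 1.0
    for j, c in enumerate(covariate_cols):
        X[:, L + j] = merged[c].to_numpy(dtype=float)
    return ExpandedDesign(
        y=merged["y"].to_numpy(dtype=float), X=X, w=np.ones(n), L=1,
        colnames=[f"class_{s + 1}" for s in range(L)] + covariate_cols,
        school=school_codes,
        st_seg=seg,
        copy=np.zeros(n, dtype=np.int64),
        n_st=n_st,
        seg_school=seg_school,
        N_total=n,
        n_schools=int(school_codes.max()) + 1,
    )


# --------------------------------------------------------------------------
# structured correlation solve
# --------------------------------------------------------------------------

def _r_solve(design: ExpandedDesign, alpha_w: float, alpha_b: float,
             rhs: np.ndarray) -> np.ndarray:
    """Apply R^{-1} to ``rhs`` for every school block at once.

    The school correlation matrix is block diagonal over time points,
    ``C_t = (1-a_w) I + J_{n_t} (x) (a_w I_L - a_b J_L)``, plus the
    rank-one between-time part ``a_b 1 1'``; the solve uses batched L x L
    systems per segment and a Sherman-Morrison step per school.
    """
    if alpha_w == 0.0 and alpha_b == 0.0:
        return rhs
    one_d = rhs.ndim == 1
    if one_d:
        rhs = rhs[:, None]
    L = design.L
    a = 1.0 - alpha_w
    if abs(a) <= 1e-12:
        raise np.linalg.LinAlgError("alpha_w = 1: working correlation singular")
    G = alpha_w * np.eye(L) - alpha_b * np.ones((L, L))
    n_seg = len(design.n_st)
    # the copy-sum direction of a within-time block has eigenvalue
    # a + n (alpha_w - L alpha_b), which changes sign as the cell size n
    # grows; reject cell sizes that land on the singularity
    eig_sum = a + design.n_st * (alpha_w - L * alpha_b)
    if np.min(np.abs(eig_sum)) < 1e-8:
        raise np.linalg.LinAlgError(
            "a school-time block of the working correlation is singular "
            "at the current (alpha_w, alpha_b)")
    seg_copy = design.st_seg * L + design.copy
    perm, starts = design._segcopy_perm

    # solve the block-diagonal part C for [rhs | 1] in one pass
    mat = np.column_stack([rhs, np.ones(rhs.shape[0])])
    q = mat.shape[1]
    s = np.add.reduceat(mat[perm], starts, axis=0).reshape(n_seg, L, q)
    A = a * np.eye(L)[None] + design.n_st[:, None, None] * G[None]
    sx = np.linalg.solve(A, s)                           # (n_seg, L, q)
    gs = (G @ sx).reshape(n_seg * L, q)
    cx = (mat - gs[seg_copy]) / a
    x, v = cx[:, :-1], cx[:, -1]

    # Sherman-Morrison for the between-time rank-one part alpha_b 1 1'
    sstarts = design._school_starts
    d = np.add.reduceat(v, sstarts)
    denom = 1.0 + alpha_b * d
    # the expanded-data correlation can be indefinite (the between-time
    # correlation couples all copy pairs); only invertibility is required
    if np.any(np.abs(denom) <= 1e-12):
        raise np.linalg.LinAlgError(
            "between-time correlation makes the working correlation singular")
    t = np.add.reduceat(x, sstarts, axis=0)
    out = x - (alpha_b * t / denom[:, None])[design.school] * v[:, None]
    return out[:, 0] if one_d else out


def _moment_alphas(design: ExpandedDesign, e: np.ndarray, phi: float,
                   p: int) -> tuple[float, float]:
    """Weighted moment estimators of alpha_w and alpha_b.

    Quadratic forms ``0.5 e' R_struct (W e)`` count each unordered pair
    once; denominators use the matching unordered pair counts so that
    with unit weights and a single copy these reduce to the textbook
    exchangeable moment estimator (with the ``-p`` correction).
    """
    f = design.w * e
    L = design.L
    n_seg = len(design.n_st)
    seg_copy = design.st_seg * L + design.copy
    se = np.bincount(seg_copy, weights=e, minlength=n_seg * L)
    sf = np.bincount(seg_copy, weights=f, minlength=n_seg * L)
    sef = np.bincount(seg_copy, weights=e * f, minlength=n_seg * L)
    quad_w = float((se * sf - sef).sum())
    alpha_w = 0.5 * quad_w / (phi * (design.Nw_over_L - p))

    se_st = se.reshape(n_seg, L).sum(axis=1)
    sf_st = sf.reshape(n_seg, L).sum(axis=1)
    se_school = np.bincount(design.seg_school, weights=se_st,
                            minlength=design.n_schools)
    sf_school = np.bincount(design.seg_school, weights=sf_st,
                            minlength=design.n_schools)
    quad_b = float((se_school * sf_school).sum() - (se_st * sf_st).sum())
    alpha_b = 0.5 * quad_b / (phi * (design.Nb_over_L - p))
    return alpha_w, alpha_b


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class GeeFit:
    """Converged weighted-GEE fit with sandwich covariance."""

    beta: np.ndarray
    cov: np.ndarray
    phi: float
    alpha_w: float
    alpha_b: float
    structure: str
    colnames: list[str]
    n_iter: int
    converged: bool
    score_norm: float
    N_total: int
    n_schools: int
    negative_weight_share: float = 0.0
    phi_floored: bool = False

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({"coef": self.colnames, "estimate": self.beta,
                             "se_sandwich": se})


def _school_scores(design: ExpandedDesign, g: np.ndarray) -> np.ndarray:
    """Per-school score contributions S_i = X_i' g_i, stacked (N_s, p)."""
    S = np.empty((design.n_schools, design.p))
    for j in range(design.p):
        S[:, j] = np.bincount(design.school, weights=design.X[:, j] * g,
                              minlength=design.n_schools)
    return S


def sandwich_cov(design: ExpandedDesign, beta: np.ndarray, phi: float,
                 alpha_w: float, alpha_b: float) -> tuple[np.ndarray, float]:
    """Robust covariance: bread^{-1} (sum_i S_i S_i') bread^{-T}.

    ``bread = sum_i X_i' V_i^{-1} W_i X_i`` and
    ``S_i = X_i' V_i^{-1} W_i (Y_i - X_i beta)``, with ``V = phi R``.
    Also returns the max-norm of the total score (which is ~0 at
    convergence).
    """
    X, y, w = design.X, design.y, design.w
    WX = X * w[:, None]
    Q = _r_solve(design, alpha_w, alpha_b, WX) / phi
    bread = X.T @ Q
    e = y - X @ beta
    g = _r_solve(design, alpha_w, alpha_b, w * e) / phi
    S = _school_scores(design, g)
    meat = S.T @ S
    score_norm = float(np.max(np.abs(S.sum(axis=0))))
    Binv = np.linalg.inv(bread)
    cov = Binv @ meat @ Binv.T
    cov = 0.5 * (cov + cov.T)
    return cov, score_norm


def fit_weighted_gee(design: ExpandedDesign, structure: str = "independence",
                     eps: float = 1e-6, max_iter: int = 100,
                     fixed_alphas: tuple[float, float] | None = None) -> GeeFit:
    """Solve the weighted estimating equations for the expanded design.

    Starts from the weighted working-independence solution and, for the
    two-parameter exchangeable structure, alternates residual/scale/
    correlation moment updates with generalized-least-squares beta
    updates until the max absolute change in beta falls below ``eps``.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown working correlation {structure!r}")
    X, y, w = design.X, design.y, design.w
    p = design.p
    if design.N_total <= p:
        raise ValueError(
            f"{design.N_total} children cannot identify {p} regression "
            f"parameters")
    WX = X * w[:, None]
    A0 = X.T @ WX
    b0 = X.T @ (w * y)
    beta = np.linalg.solve(A0, b0)
    beta += np.linalg.solve(A0, b0 - A0 @ beta)     # one refinement step

    phi_floored = False

    def scale(e: np.ndarray) -> float:
        nonlocal phi_floored
        phi = float((w * e * e).sum()) / (design.N_total - p)
        if phi < _PHI_FLOOR:
            phi_floored = True
            warnings.warn("estimated scale parameter fell below its floor",
                          RuntimeWarning, stacklevel=2)
            phi = _PHI_FLOOR
        return phi

    alpha_w = alpha_b = 0.0
    if structure == "independence":
        e = y - X @ beta
        phi = scale(e)
        n_iter, converged = 1, True
    else:
        converged = False
        n_iter = 0
        phi = 1.0
        delta_prev = np.inf
        damp = 1.0
        for n_iter in range(1, max_iter + 1):
            e = y - X @ beta
            phi = scale(e)
            if fixed_alphas is not None:
                alpha_w, alpha_b = fixed_alphas
            else:
                alpha_w, alpha_b = _moment_alphas(design, e, phi, p)
            Z = _r_solve(design, alpha_w, alpha_b,
                         np.column_stack([WX, w * y]))
            A = X.T @ Z[:, :p]
            b = X.T @ Z[:, p]
            beta_new = np.linalg.solve(A, b)
            beta_new += np.linalg.solve(A, b - A @ beta_new)
            delta = float(np.max(np.abs(beta_new - beta)))
            if delta < eps:
                beta = beta_new
                converged = True
                break
            # adaptive damping: shrink the step whenever the distance to
            # the solve target stops decreasing; this settles oscillations
            # of the alpha/beta alternation onto the fixed point
            if n_iter >= 3 and delta > 0.9 * delta_prev:
                damp = max(damp / 2.0, 1.0 / 32.0)
            elif delta < 0.5 * delta_prev:
                damp = min(damp * 1.5, 1.0)
            beta = beta + damp * (beta_new - beta)
            delta_prev = delta
        if not converged:
            warnings.warn(
                f"GEE did not converge in {max_iter} iterations "
                f"(last max |delta beta| = {delta:.3g})", RuntimeWarning,
                stacklevel=2)
    cov, score_norm = sandwich_cov(design, beta, phi, alpha_w, alpha_b)
    neg_share = float((w < 0).mean())
    return GeeFit(beta=beta, cov=cov, phi=phi, alpha_w=alpha_w,
                  alpha_b=alpha_b, structure=structure,
                  colnames=list(design.colnames), n_iter=n_iter,
                  converged=converged, score_norm=score_norm,
                  N_total=design.N_total, n_schools=design.n_schools,
                  negative_weight_share=neg_share, phi_floored=phi_floored)


def fit_naive_gee(children: pd.DataFrame, assign: pd.DataFrame, L: int,
                  covariate_cols=("z",), structure: str = "independence",
                  eps: float = 1e-6, max_iter: int = 100) -> GeeFit:
    """Unweighted GEE treating the modal assignments as observed classes.

    The comparison estimator: identical machinery with a single data copy
    and unit weights, so any difference from :func:`fit_weighted_gee`
    reflects the BCH misclassification adjustment.
    """
    design = _naive_design(children, assign, L, covariate_cols)
    return fit_weighted_gee(design, structure=structure, eps=eps,
                            max_iter=max_iter)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

@dataclass
class WaldTest:
    estimate: float
    se: float
    z: float
    pvalue: float


def wald_test(fit: GeeFit, contrast) -> WaldTest:
    """Two-sided Wald test of ``c' beta = 0`` using the sandwich variance."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit.beta.shape:
        raise ValueError("contrast length does not match coefficient vector")
    if not np.any(c):
        raise ValueError("contrast is identically zero")
    est = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    if var <= 0:
        raise ValueError("contrast has zero estimated variance")
    se = float(np.sqrt(var))
    z = est / se
    return WaldTest(estimate=est, se=se, z=z,
                    pvalue=float(2.0 * stats.norm.sf(abs(z))))


def bootstrap_se(panel: pd.DataFrame, children: pd.DataFrame,
                 model: ZipLcaModel, B: int = 500, seed=None,
                 structure: str = "independence", covariate_cols=("z",),
                 eps: float = 1e-6, max_iter: int = 100) -> dict:
    """Cluster bootstrap of the Step 2 + Step 3b pipeline.

    Schools are resampled with replacement (children travel with their
    school); the Step-1 measurement model stays fixed, so class meanings
    are identical across replicates.  Per replicate the posteriors,
    modal assignments, D, D* and the weighted GEE are all recomputed.
    Returns the per-coefficient SD over successful replicates together
    with replicate counts.
    """
    if B < 2:
        raise ValueError("bootstrap requires B >= 2 replicates")
    rng = np.random.default_rng(seed)
    schools = np.sort(panel["school_id"].unique())
    n = len(schools)
    panel_s = panel.sort_values(["school_id", "time"],
                                kind="stable").reset_index(drop=True)
    child_s = children.sort_values(["school_id", "time"],
                                   kind="stable").reset_index(drop=True)
    T = panel_s["time"].nunique()
    # contiguous row ranges per school
    p_start = np.searchsorted(panel_s["school_id"].to_numpy(), schools)
    c_ids = child_s["school_id"].to_numpy()
    c_start = np.searchsorted(c_ids, schools)
    c_stop = np.searchsorted(c_ids, schools, side="right")

    estimates = []
    n_failed = 0
    failures: list[str] = []
    for _ in range(B):
        draw = rng.integers(0, n, size=n)
        p_rows = (p_start[draw][:, None] + np.arange(T)[None]).reshape(-1)
        rep_panel = panel_s.iloc[p_rows].copy()
        rep_panel["school_id"] = np.repeat(np.arange(n), T)
        counts = c_stop[draw] - c_start[draw]
        c_rows = np.concatenate(
            [np.arange(c_start[d], c_stop[d]) for d in draw])
        rep_children = child_s.iloc[c_rows].copy()
        rep_children["school_id"] = np.repeat(np.arange(n), counts)
        try:
            post = posterior_probs(model, rep_panel)
            assign = modal_assign(post)
            D = classification_error(post, assign)
            weights = bch_weights(D, assign)
            design = expand_data(rep_children, assign, weights,
                                 covariate_cols)
            fit = fit_weighted_gee(design, structure=structure, eps=eps,
                                   max_iter=max_iter)
            if not fit.converged:
                raise RuntimeError("GEE did not converge")
            estimates.append(fit.beta)
        except Exception as exc:  # noqa: BLE001 - replicate-level failures
            n_failed += 1
            failures.append(f"{type(exc).__name__}: {exc}")
    if len(estimates) < 2:
        raise RuntimeError(
            f"fewer than 2 successful bootstrap replicates ({n_failed} failed)")
    est = np.vstack(estimates)
    return {
        "se": est.std(axis=0, ddof=1),
        "estimates": est,
        "n_success": len(estimates),
        "n_failed": n_failed,
        "failures": failures[:20],
    }
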