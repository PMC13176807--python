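"""Step 2: posterior probabilities, modal assignment, and BCH weights.

Given the Step-1 measurement model, each school-time is assigned to its
highest-posterior class.  The classification-error matrix ``D`` collects
``q_{r|s} = P(assigned = r | true = s)`` pooled over schools and time
points (measurement invariance makes the error structure time-constant);
its inverse ``D*`` supplies the BCH weights that undo the
misclassification in the distal-outcome model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from bchgee.zip_lca import ZipLcaModel, _panel_arrays, _component_loglik

__all__ = [
    "BchWeights",
    "bch_weights",
    "classification_error",
    "modal_assign",
    "posterior_probs",
]


def posterior_probs(model: ZipLcaModel, panel: pd.DataFrame) -> pd.DataFrame:
    """Posterior class probabilities P(S_t = s | U_t) per school-time.

    Bayes rule in log space with the model's time-specific prevalences and
    shared ZIP measurement parameters.  Returns a data frame with
    ``school_id, time, p_1 .. p_L``.
    """
    counts, tidx, _, T = _panel_arrays(panel)
    if T != model.T:
        raise ValueError(f"panel has {T} time points, model has {model.T}")
    if counts.shape[1] != model.J:
        raise ValueError("panel indicator count does not match model J")
    comp = _component_loglik(counts, model.zip_p, model.zip_lambda)
    with np.errstate(divide="ignore"):
        joint = comp + np.log(model.prevalences)[tidx]
    norm = logsumexp(joint, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"zero posterior density at row {i} "
            f"(school {panel['school_id'].iloc[i]}, time {panel['time'].iloc[i]})")
    post = np.exp(joint - norm[:, None])
    out = panel[["school_id", "time"]].copy()
    for s in range(model.L):
        out[f"p_{s + 1}"] = post[:, s]
    return out


def modal_assign(post: pd.DataFrame) -> pd.DataFrame:
    """Assign each school-time to its largest-posterior class (1-based).

    Ties are broken toward the lowest class index.
    """
    pcols = [c for c in post.columns if c.startswith("p_")]
    probs = post[pcols].to_numpy()
    out = post[["school_id", "time"]].copy()
    out["assigned"] = probs.argmax(axis=1) + 1
    return out


def classification_error(post: pd.DataFrame, assign: pd.DataFrame) -> np.ndarray:
    """Pooled L x L classification-error matrix D.

    ``D[r, s] = q_{r|s} = sum_{i,t} P(S=s|U_it) 1{C_it=r} / (N T P(S=s))``
    with the marginal ``P(S=s)`` estimated as the pooled mean posterior.
    Columns (true classes) sum to 1.
    """
    pcols = [c for c in post.columns if c.startswith("p_")]
    probs = post[pcols].to_numpy()
    L = probs.shape[1]
    merged = post.merge(assign, on=["school_id", "time"], validate="one_to_one")
    assigned = merged["assigned"].to_numpy() - 1
    probs = merged[pcols].to_numpy()
    marginal = probs.mean(axis=0)                       # P(S = s)
    if np.any(marginal <= 0):
        empty = np.flatnonzero(marginal <= 0) + 1
        raise ValueError(f"empty latent class(es): {empty.tolist()}")
    D = np.zeros((L, L))
    for r in range(L):
        D[r] = probs[assigned == r].sum(axis=0)
    D /= len(merged) * marginal
    return D


@dataclass
class BchWeights:
    """BCH weight matrix D* = D^{-1} and its per-unit weight vectors.

    ``rows`` aligns with ``assign``: row ``i`` holds the weight vector of
    the class assigned to that school-time.  Entries may be negative; the
    share of negative weights is reported in ``negative_share``.
    """

    D: np.ndarray
    Dstar: np.ndarray
    assign: pd.DataFrame
    rows: np.ndarray
    negative_share: float


def bch_weights(D: np.ndarray, assign: pd.DataFrame | None = None,
                condition_cap: float = 1e8) -> BchWeights:
    """Invert the classification-error matrix to obtain BCH weights.

    With ``D[r, s] = P(assigned r | true s)``, a subject assigned to
    class ``r`` receives the ``r``-th *column* of ``D* = D^{-1}`` as its
    weight vector over the L data copies: this is the unique choice with
    ``sum_r q_{r|s} w_r = e_s``, so the weighted copies are unbiased for
    the true-class cells.  (Equivalently, row ``r`` of the inverse of the
    true-by-assigned matrix ``D'``.)  Raises ``ValueError`` when D is
    singular or worse conditioned than ``condition_cap`` (typically
    caused by a vanishing class; refit with fewer classes).
    """
    D = np.asarray(D, dtype=float)
    L = D.shape[0]
    if D.shape != (L, L):
        raise ValueError("D must be square")
    cond = np.linalg.cond(D)
    if not np.isfinite(cond) or cond > condition_cap:
        raise ValueError(
            f"classification-error matrix is singular or near-singular "
            f"(condition number {cond:.3g}); BCH weights cannot be "
            f"computed -- consider a model with fewer classes")
    Dstar = np.linalg.inv(D)
    if assign is not None:
        rows = Dstar.T[assign["assigned"].to_numpy() - 1]
    else:
        rows = np.empty((0, L))
    total = rows.size if rows.size else Dstar.size
    neg = (rows < 0).sum() if rows.size else (Dstar < 0).sum()
    return BchWeights(D=D, Dstar=Dstar, assign=assign, rows=rows,
                      negative_share=float(neg) / float(total))
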