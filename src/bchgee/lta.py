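"""Step 3a: latent transition analysis with measurement fixed at D.

The assigned classes C_1..C_T are treated as noisy indicators of the true
latent classes: a hidden Markov model whose emission matrix is the Step-2
classification-error matrix, held fixed.  Only the initial class
probabilities and the transition probabilities are estimated, by EM with
forward-backward recursions (vectorised over schools, which share a
balanced design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LtaModel", "fit_lta", "fix_measurement", "measurement_from_logits"]

_CLIP = 1e-12


def fix_measurement(D: np.ndarray, clip: float = _CLIP) -> np.ndarray:
    """Baseline-category logits of the fixed measurement model.

    ``delta[l, s] = log(q_{l|s} / q_{L|s})`` with class L the reference.
    Zero cells are clipped to ``clip`` before taking logs.
    """
    D = np.asarray(D, dtype=float)
    Dc = np.clip(D, clip, None)
    return np.log(Dc) - np.log(Dc[-1:, :])


def measurement_from_logits(delta: np.ndarray) -> np.ndarray:
    """Inverse map: column-wise softmax reproducing the (clipped) D."""
    e = np.exp(delta - delta.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


@dataclass
class LtaModel:
    """Fitted latent transition model.

    ``transition`` is ``(L, L)`` when time-homogeneous, else
    ``(T-1, L, L)`` with one matrix per interval.  ``measurement_logits``
    are the fixed baseline-category logits derived from D.
    """

    L: int
    T: int
    initial_probs: np.ndarray
    transition: np.ndarray
    measurement_logits: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    time_homogeneous: bool

    @property
    def emission(self) -> np.ndarray:
        """Fixed P(C = r | S = s) matrix implied by the logits."""
        return measurement_from_logits(self.measurement_logits)

    def transition_at(self, interval: int) -> np.ndarray:
        return self.transition if self.time_homogeneous else self.transition[interval]


def _assign_matrix(assign: pd.DataFrame) -> np.ndarray:
    """(N_s, T) 0-based assigned-class array from the long table."""
    wide = assign.pivot(index="school_id", columns="time", values="assigned")
    if wide.isna().any().any():
        raise ValueError("assignment table is not balanced")
    return wide.to_numpy(dtype=np.int64) - 1


def fit_lta(assign: pd.DataFrame, D: np.ndarray, time_homogeneous: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> LtaModel:
    """EM fit of the hidden Markov chain underlying the assignments.

    The emission probabilities ``P(C_t = r | S_t = s) = q_{r|s}`` are held
    fixed at the classification errors; the observed-data log-likelihood
    is non-decreasing over iterations.  With ``D = I`` the estimates
    reduce to the empirical initial-share and transition-frequency MLEs
    of the assigned classes.
    """
    C = _assign_matrix(assign)
    N, T = C.shape
    delta = fix_measurement(D)
    B = measurement_from_logits(delta)          # B[r, s] = P(C=r | S=s)
    L = B.shape[0]
    if C.max() >= L:
        raise ValueError("assignment labels exceed the number of classes")
    # emission likelihood per (school, t, state s)
    em = B[C, :]                                # (N, T, L)

    pi = np.full(L, 1.0 / L)
    n_mats = 1 if time_homogeneous else T - 1
    tau = np.full((n_mats, L, L), 0.2 / max(L - 1, 1))
    tau[:, np.arange(L), np.arange(L)] = 0.8 if L > 1 else 1.0

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # forward pass with per-step scaling
        alpha = np.empty((N, T, L))
        scale = np.empty((N, T))
        a = pi * em[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / scale[:, 0][:, None]
        for t in range(1, T):
            trans = tau[0] if time_homogeneous else tau[t - 1]
            a = (alpha[:, t - 1] @ trans) * em[:, t, :]
            scale[:, t] = a.sum(axis=1)
            alpha[:, t] = a / scale[:, t][:, None]
        ll = float(np.log(scale).sum())
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            converged = True
            break
        ll_old = ll
        # backward pass
        beta = np.empty((N, T, L))
        beta[:, T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            trans = tau[0] if time_homogeneous else tau[t]
            b = (beta[:, t + 1] * em[:, t + 1, :]) @ trans.T
            beta[:, t] = b / scale[:, t + 1][:, None]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        # transition expectations
        xi_sum = np.zeros((n_mats, L, L))
        for t in range(T - 1):
            trans = tau[0] if time_homogeneous else tau[t]
            m = (alpha[:, t, :, None] * trans[None]
                 * (em[:, t + 1, :] * beta[:, t + 1])[:, None, :])
            m /= scale[:, t + 1][:, None, None]
            xi_sum[0 if time_homogeneous else t] += m.sum(axis=0)
        pi = gamma[:, 0].mean(axis=0)
        tau = xi_sum / np.maximum(xi_sum.sum(axis=2, keepdims=True), 1e-300)
    return LtaModel(
        L=L, T=T,
        initial_probs=pi,
        transition=tau[0] if time_homogeneous else tau,
        measurement_logits=delta,
        loglik=ll,
        n_iter=it,
        converged=converged,
        time_homogeneous=time_homogeneous,
    )
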