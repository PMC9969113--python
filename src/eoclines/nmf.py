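"""Non-negative matrix factorization with KL-divergence multiplicative updates.

V (genes x samples, non-negative) is approximated by W H with W (genes x r)
and H (r x samples) both non-negative. The updates are the classical
multiplicative scheme for the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij,

which is non-increasing under

    H <- H * (W^T (V / WH)) / (W^T 1),
    W <- W * ((V / WH) H^T) / (1 H^T).

Initial factors are drawn uniformly over the range of V ("random" seeding).
Zeros in V are floored at a small epsilon inside the updates only, so the
divergence stays finite; the reported residual sum of squares is always the
Frobenius residual against the unmodified V. A Frobenius-objective update
scheme is available behind the ``objective`` flag but is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

#: floor applied to zeros of V inside the KL updates
EPSILON = 1e-6

#: convergence: relative objective change below tol at this many consecutive
#: checks (one check every CHECK_INTERVAL iterations)
CHECK_INTERVAL = 10
CONSECUTIVE_CHECKS = 10


@dataclass
class Factorization:
    """One NMF solution with its objective trace and provenance."""

    W: np.ndarray
    H: np.ndarray
    r: int
    objective_trace: np.ndarray
    rss: float
    n_iter: int
    seed: int
    objective: str = "kl"

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])


def _validate_v(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    if not np.isfinite(V).all():
        raise ValueError("V must be finite")
    return V


def init_factors(
    V: np.ndarray, r: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random initialization over the range of V.

    Entries of W0 and H0 are drawn uniformly on [max(eps, min(V)), max(V)],
    the "random" seeding of NMF practice: starting values share the scale of
    the data, with a small epsilon guarding all-zero matrices.
    """
    V = _validate_v(V)
    if r < 1:
        raise ValueError("rank must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = max(EPSILON, float(V.min()))
    hi = float(V.max())
    if hi < lo:
        hi = lo
    W0 = rng.uniform(lo, hi, size=(V.shape[0], r))
    H0 = rng.uniform(lo, hi, size=(r, V.shape[1]))
    return W0, H0


def _kl_divergence(Vf: np.ndarray, WH: np.ndarray) -> float:
    return float(np.sum(Vf * np.log(Vf / WH) - Vf + WH))


def factorize(
    V: np.ndarray,
    r: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    objective: str = "kl",
) -> Factorization:
    """Run multiplicative-update NMF from one random initialization.

    Stops at ``max_iter`` or once the relative objective change stays below
    ``tol`` for ``CONSECUTIVE_CHECKS`` consecutive checks (every
    ``CHECK_INTERVAL`` iterations). The objective trace is recorded per
    iteration and is non-increasing up to floating-point tolerance.
    """
    V = _validate_v(V)
    if r >= min(V.shape):
        raise ValueError(f"rank {r} must be < min(V.shape) = {min(V.shape)}")
    if objective not in ("kl", "frobenius"):
        raise ValueError("objective must be 'kl' or 'frobenius'")
    zero_rows = ~(V > 0).any(axis=1)
    zero_cols = ~(V > 0).any(axis=0)
    if zero_rows.any() or zero_cols.any():
        raise ValueError(
            "V has all-zero rows or columns; epsilon-floor them (V.clip(min=eps)) "
            "before factorizing"
        )
    W, H = init_factors(V, r, seed)
    Vf = np.maximum(V, EPSILON)  # flooring inside the updates only
    trace = np.empty(max_iter)
    tiny = 1e-300
    good_checks = 0
    previous = np.inf
    n_iter = max_iter
    for it in range(max_iter):
        if objective == "kl":
            WH = W @ H + tiny
            trace[it] = _kl_divergence(Vf, WH)
            R = Vf / WH
            H *= (W.T @ R) / (W.sum(axis=0)[:, None] + tiny)
            WH = W @ H + tiny
            R = Vf / WH
            W *= (R @ H.T) / (H.sum(axis=1)[None, :] + tiny)
        else:
            WH = W @ H
            trace[it] = float(np.sum((Vf - WH) ** 2))
            H *= (W.T @ Vf) / (W.T @ WH + tiny)
            WH = W @ H
            W *= (Vf @ H.T) / (WH @ H.T + tiny)
        if (it + 1) % CHECK_INTERVAL == 0:
            current = trace[it]
            denom = abs(previous) if np.isfinite(previous) and previous != 0 else 1.0
            if np.isfinite(previous) and abs(previous - current) / denom < tol:
                good_checks += 1
            else:
                good_checks = 0
            previous = current
            if good_checks >= CONSECUTIVE_CHECKS:
                n_iter = it + 1
                break
    trace = trace[:n_iter]
    if not np.isfinite(trace).all() or not np.isfinite(W).all():
        raise FloatingPointError(
            "NMF diverged to non-finite values; check for all-zero rows/columns "
            "and epsilon-floor V"
        )
    fact = Factorization(
        W=W,
        H=H,
        r=r,
        objective_trace=trace,
        rss=rss(V, W, H),
        n_iter=n_iter,
        seed=seed if isinstance(seed, int) else -1,
        objective=objective,
    )
    return fact


def rss(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Frobenius residual sum of squares, sum((V - WH)^2)."""
    V = np.asarray(V, dtype=float)
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1]:
        raise ValueError("factor shapes do not match V")
    return float(np.sum((V - W @ H) ** 2))


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Assign each sample to the metagene with maximal coefficient (1-based).

    Ties are broken toward the lowest cluster index, with a logged warning.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H must be non-negative")
    labels = np.argmax(H, axis=0)
    maxima = H[labels, np.arange(H.shape[1])]
    ties = (H == maxima[None, :]).sum(axis=0) > 1
    if ties.any():
        logger.warning(
            "tied maximum coefficients for %d sample(s); assigned to the "
            "lowest cluster index",
            int(ties.sum()),
        )
    return labels + 1


def permute_matrix(V: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Independently permute the entries within each column of V.

    Column multisets (and hence column sums) are preserved; any association
    between genes and samples is destroyed — the permutation null used to
    detect overfitting in the rank survey.
    """
    V = np.asarray(V)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = V.copy()
    for j in range(V.shape[1]):
        out[:, j] = rng.permutation(out[:, j])
    return out


class KLNMF(TransformerMixin, BaseEstimator):
    """scikit-learn-style wrapper over the multiplicative-update NMF.

    X is samples x features (sklearn orientation); internally V = X.T is
    factorized as W H, with ``components_`` = W.T (n_components x features)
    and the transform returning H.T (samples x n_components). With
    ``n_restarts > 1`` the best-objective restart is kept.
    """

    def __init__(
        self,
        n_components: int = 5,
        max_iter: int = 2000,
        tol: float = 1e-6,
        objective: str = "kl",
        n_restarts: int = 1,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.objective = objective
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = check_array(X)
        best: Factorization | None = None
        for i in range(self.n_restarts):
            fact = factorize(
                X.T,
                self.n_components,
                seed=derive_seed(self.random_state, i),
                max_iter=self.max_iter,
                tol=self.tol,
                objective=self.objective,
            )
            if best is None or fact.final_objective < best.final_objective:
                best = fact
        assert best is not None
        self.factorization_ = best
        self.components_ = best.W.T
        self.reconstruction_err_ = best.final_objective
        self.labels_ = assign_clusters(best.H)
        self.n_features_in_ = X.shape[1]
        return best.H.T

    def transform(self, X):
        check_is_fitted(self, "factorization_")
        X = check_array(X)
        # fold new samples onto fixed W by running H-updates only
        W = self.factorization_.W
        V = np.maximum(_validate_v(X.T), EPSILON)
        rng = np.random.default_rng(self.random_state)
        H = rng.uniform(
            max(EPSILON, V.min()), max(V.max(), EPSILON), size=(self.n_components, V.shape[1])
        )
        tiny = 1e-300
        for _ in range(self.max_iter):
            WH = W @ H + tiny
            H_new = H * (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + tiny)
            if np.max(np.abs(H_new - H) / (H + tiny)) < self.tol:
                H = H_new
                break
            H = H_new
        return H.T


def derive_seed(master: int, index: int) -> int:
    """Counter-based derivation of per-restart seeds (stays below 2**31)."""
    return (int(master) * 1_000_003 + int(index)) % (2**31 - 1)
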