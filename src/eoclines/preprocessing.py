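"""Expression preprocessing: size factors, VST, MAD filtering, upper-quartile
normalization and parametric empirical-Bayes batch correction.

Two surfaces are provided. The functional surface operates on genes x samples
pandas DataFrames (the orientation count matrices are stored in) and records
the transform chain in ``DataFrame.attrs['transforms']``. The estimator
surface (`MedianRatioVST`, `MADFilter`, `UpperQuartileNormalizer`, `ComBat`)
follows scikit-learn conventions — X is samples x features — and composes
with sklearn pipelines; each estimator is a thin wrapper over the functions.

The VST used here is log2(count / size_factor + 1) with median-of-ratios size
factors: a monotone, deterministic variance-stabilizing surrogate adequate
for MAD-based gene ranking (the parametric dispersion-trend fit of dedicated
count packages is deliberately out of scope).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

#: MAD scale constant for consistency with the normal distribution.
NORMAL_MAD_CONSTANT = 1.4826


def _tag(df: pd.DataFrame, parent: pd.DataFrame | None, tag: str) -> pd.DataFrame:
    chain = list(parent.attrs.get("transforms", [])) if parent is not None else []
    df.attrs["transforms"] = chain + [tag]
    return df


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    Per sample, the median over all-positive genes of count / geometric mean
    of that gene across samples. Genes with a zero in any sample are ignored;
    if none remain, pass ``pseudocount > 0`` to include all genes.
    """
    values = counts.to_numpy(dtype=float) + pseudocount
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "re-run with pseudocount > 0 (e.g. size_factors(counts, pseudocount=0.5))"
        )
    log_values = np.log(values[positive])
    log_geomean = log_values.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_values - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_transform(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(count / size_factor + 1)."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    out = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy()[None, :] + 1.0)
    return _tag(
        pd.DataFrame(out, index=counts.index, columns=counts.columns), counts, "vst"
    )


@dataclass
class GeneFilterResult:
    """Outcome of MAD-based gene filtering."""

    kept_gene_ids: list[str]
    mad_values: pd.Series
    threshold: float
    scale_constant: float
    top_n: int | None = None

    @property
    def dropped_gene_ids(self) -> list[str]:
        kept = set(self.kept_gene_ids)
        return [g for g in self.mad_values.index if g not in kept]


def mad_filter(
    expr: pd.DataFrame,
    threshold: float = 1.5,
    scale_constant: float = NORMAL_MAD_CONSTANT,
    top_n: int | None = None,
) -> GeneFilterResult:
    """Keep genes whose median absolute deviation across samples is >= threshold.

    MAD = scale_constant * median(|x - median(x)|) per gene. With ``top_n``
    set, the threshold is ignored and the ``top_n`` highest-MAD genes are kept
    instead (the "most variable transcripts" reading of the filter, useful
    when the absolute cutoff does not transfer to a dataset's variance scale).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if expr.shape[1] < 2:
        raise ValueError("MAD filtering requires at least 2 samples")
    values = expr.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    mad = scale_constant * np.median(np.abs(values - med), axis=1)
    mad_series = pd.Series(mad, index=expr.index, name="mad")
    if top_n is not None:
        if not (0 < top_n <= expr.shape[0]):
            raise ValueError(f"top_n must be in 1..{expr.shape[0]}")
        order = np.argsort(-mad, kind="stable")[:top_n]
        kept = [expr.index[i] for i in sorted(order)]
        effective = float(mad[order].min())
    else:
        kept = [g for g, m in mad_series.items() if m >= threshold]
        effective = threshold
    return GeneFilterResult(
        kept_gene_ids=kept,
        mad_values=mad_series,
        threshold=effective,
        scale_constant=scale_constant,
        top_n=top_n,
    )


def upper_quartile_normalize(
    counts: pd.DataFrame, log2: bool = False
) -> pd.DataFrame:
    """Scale each sample by its 75th percentile of nonzero counts.

    Columns are divided by their upper quartile and rescaled by the global
    mean of the upper quartiles so magnitudes stay count-like. Quantiles use
    linear interpolation (type 7). Optionally log2(x + 1)-transforms after.
    """
    values = counts.to_numpy(dtype=float)
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        nonzero = values[values[:, j] > 0, j]
        if nonzero.size == 0:
            raise ValueError(
                f"sample {counts.columns[j]!r} has no nonzero counts; "
                "cannot upper-quartile normalize"
            )
        uq[j] = np.percentile(nonzero, 75)
    out = values / uq[None, :] * uq.mean()
    tag = "uq"
    if log2:
        out = np.log2(out + 1.0)
        tag = "uq_log"
    return _tag(
        pd.DataFrame(out, index=counts.index, columns=counts.columns), counts, tag
    )


def _combat_core(
    Y: np.ndarray, batch_codes: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, dict]:
    """Parametric EB location/scale adjustment on a genes x samples array.

    Gene-wise standardization, per-batch location parameters shrunk toward a
    normal prior and scale parameters toward an inverse-gamma prior with
    moment-matched hyperpriors; iterative EB estimates to relative tolerance
    ``tol``. Assumes every gene has positive pooled variance.
    """
    n_batches = batch_codes.max() + 1
    n_per = np.bincount(batch_codes, minlength=n_batches).astype(float)
    N = Y.shape[1]

    # batch means and pooled (batch-centered) variance
    batch_mean = np.stack(
        [Y[:, batch_codes == b].mean(axis=1) for b in range(n_batches)], axis=1
    )
    stand_mean = batch_mean @ (n_per / N)
    resid = Y - batch_mean[:, batch_codes]
    pooled_var = (resid**2).sum(axis=1) / N
    Z = (Y - stand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    gamma_star = np.empty_like(batch_mean)
    delta_star = np.empty_like(batch_mean)
    for b in range(n_batches):
        Zb = Z[:, batch_codes == b]
        nb = Zb.shape[1]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g = gamma_hat.copy()
        d = delta_hat.copy()
        sum_sq = ((Zb - gamma_hat[:, None]) ** 2).sum(axis=1)
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + d * gamma_bar) / (nb * tau2 + d)
            sum_sq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior + 0.5 * sum_sq) / (nb / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(g_new - g) / (np.abs(g) + 1e-30)),
                np.max(np.abs(d_new - d) / (np.abs(d) + 1e-30)),
            )
            g, d = g_new, d_new
            if change < tol:
                break
        gamma_star[:, b] = g
        delta_star[:, b] = d

    adjusted = (Z - gamma_star[:, batch_codes]) / np.sqrt(delta_star[:, batch_codes])
    out = adjusted * np.sqrt(pooled_var)[:, None] + stand_mean[:, None]
    params = {
        "stand_mean": stand_mean,
        "pooled_var": pooled_var,
        "gamma_star": gamma_star,
        "delta_star": delta_star,
    }
    return out, params


def combat_adjust(
    expr: pd.DataFrame,
    batches: pd.Series | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Empirical-Bayes batch correction (parametric location/scale model).

    ``batches`` assigns every sample (column) to a batch; each batch needs at
    least 2 samples. With a single batch the data are returned unchanged.
    Genes with zero pooled variance are passed through unadjusted with a
    warning. The grand per-gene mean is preserved up to numerical tolerance.
    """
    if isinstance(batches, pd.Series):
        batches = batches.reindex(expr.columns)
        if batches.isna().any():
            missing = list(expr.columns[batches.isna()])[:3]
            raise ValueError(f"batch labels missing for samples {missing}")
        labels = batches.to_numpy()
    else:
        labels = np.asarray(batches)
        if labels.shape[0] != expr.shape[1]:
            raise ValueError("batch labels must match number of samples")
    uniques, codes = np.unique(labels, return_inverse=True)
    if uniques.size == 1:
        return _tag(expr.copy(), expr, "combat_adjusted")
    counts_per = np.bincount(codes)
    if (counts_per < 2).any():
        small = uniques[counts_per < 2]
        raise ValueError(
            f"singleton batch(es) {list(small)}: no within-batch variance estimate"
        )

    Y = expr.to_numpy(dtype=float)
    batch_mean = np.stack(
        [Y[:, codes == b].mean(axis=1) for b in range(uniques.size)], axis=1
    )
    pooled_var = ((Y - batch_mean[:, codes]) ** 2).sum(axis=1) / Y.shape[1]
    degenerate = pooled_var <= 1e-30
    out = Y.copy()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) passed through "
            "unadjusted",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = ~degenerate
    if ok.any():
        out[ok], _ = _combat_core(Y[ok], codes, tol=tol, max_iter=max_iter)
    result = pd.DataFrame(out, index=expr.index, columns=expr.columns)
    return _tag(result, expr, "combat_adjusted")


# ---------------------------------------------------------------------------
# scikit-learn estimator surface (X is samples x features)
# ---------------------------------------------------------------------------


class MedianRatioVST(TransformerMixin, BaseEstimator):
    """Size-factor normalization + log2(x + 1), sklearn-oriented.

    ``fit`` freezes per-gene log geometric means on the training samples;
    ``transform`` computes each sample's median-of-ratios factor against that
    reference, so new samples are normalized consistently with the fit data.
    """

    def __init__(self, pseudocount: float = 0.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        V = X.T + self.pseudocount
        positive = (V > 0).all(axis=1)
        if not positive.any():
            raise ValueError(
                "no gene positive in all samples; set pseudocount > 0"
            )
        self.reference_mask_ = positive
        self.log_geomean_ = np.log(V[positive]).mean(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "log_geomean_")
        X = check_array(X)
        V = X.T + self.pseudocount
        ratios = np.log(np.maximum(V[self.reference_mask_], 1e-300)) - (
            self.log_geomean_[:, None]
        )
        factors = np.exp(np.median(ratios, axis=0))
        return np.log2(X / factors[:, None] + 1.0)


class MADFilter(TransformerMixin, BaseEstimator):
    """Select features by median absolute deviation across samples."""

    def __init__(
        self,
        threshold: float = 1.5,
        scale_constant: float = NORMAL_MAD_CONSTANT,
        top_n: int | None = None,
    ):
        self.threshold = threshold
        self.scale_constant = scale_constant
        self.top_n = top_n

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        df = pd.DataFrame(X.T)
        result = mad_filter(
            df,
            threshold=self.threshold,
            scale_constant=self.scale_constant,
            top_n=self.top_n,
        )
        self.mad_values_ = result.mad_values.to_numpy()
        kept = set(result.kept_gene_ids)
        self.support_ = np.array([i in kept for i in df.index])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


class UpperQuartileNormalizer(TransformerMixin, BaseEstimator):
    """Per-sample upper-quartile scaling, rescaled to the fit-data mean UQ."""

    def __init__(self, log2: bool = False):
        self.log2 = log2

    @staticmethod
    def _uq(X: np.ndarray) -> np.ndarray:
        uq = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            nonzero = X[i, X[i] > 0]
            if nonzero.size == 0:
                raise ValueError(f"sample at row {i} has no nonzero counts")
            uq[i] = np.percentile(nonzero, 75)
        return uq

    def fit(self, X, y=None):
        X = check_array(X)
        self.mean_uq_ = float(self._uq(X).mean())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_uq_")
        X = check_array(X)
        out = X / self._uq(X)[:, None] * self.mean_uq_
        return np.log2(out + 1.0) if self.log2 else out


class ComBat(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes batch correction, sklearn-oriented.

    Batch labels are passed to ``fit``/``fit_transform`` as the ``batch``
    keyword; ``transform`` re-applies the fitted per-batch adjustments (new
    samples must belong to batches seen during fit).
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, batch=None):
        self.fit_transform(X, y, batch=batch)
        return self

    def fit_transform(self, X, y=None, batch=None):
        if batch is None:
            raise ValueError("ComBat requires batch labels: fit(X, batch=...)")
        X = check_array(X, ensure_min_samples=2)
        df = pd.DataFrame(X.T)
        df.columns = range(X.shape[0])
        adjusted = combat_adjust(
            df, np.asarray(batch), tol=self.tol, max_iter=self.max_iter
        )
        self.batches_ = np.unique(np.asarray(batch))
        self.n_features_in_ = X.shape[1]
        return adjusted.to_numpy().T

    def transform(self, X, batch=None):
        check_is_fitted(self, "batches_")
        if batch is None:
            raise ValueError("ComBat.transform requires batch labels")
        # refit-free re-application is not supported; ComBat is a
        # cohort-level adjustment, so transform == fit_transform on the data.
        return self.fit_transform(X, batch=batch)
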