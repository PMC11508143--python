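"""Count normalization, variance stabilization and high-variance gene filtering.

Sequencing-depth normalization follows the median-of-ratios scheme: each
sample's size factor is the median, over genes with a strictly positive
geometric mean, of that sample's count divided by the gene's geometric mean
across samples. The variance-stabilizing transform is the dependency-free
stand-in ``x = log2(k/s + 1)``; downstream analysis only consumes
correlations of the stabilized values, so the exact dispersion-trend VST is
deliberately out of scope. Finally, only genes whose expression variance
reaches a high percentile (default the 95th) of the per-gene variance
distribution are kept for network construction.

Functional API operates on genes x samples DataFrames (the on-disk layout);
the sklearn-style estimators operate on samples x genes matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Genes whose geometric mean across samples is zero (any zero count) are
    excluded from the medians. Raises if no gene is usable.
    """
    k = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    usable = np.all(np.isfinite(logk), axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has all-positive counts; size factors are undefined "
            "(consider adding pseudo-counts)"
        )
    log_geo_mean = logk[usable].mean(axis=1)
    ratios = np.exp(logk[usable] - log_geo_mean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def vst_transform(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilizing stand-in: ``x[i,j] = log2(k[i,j]/s[j] + 1)``."""
    s = size_factors.reindex(counts.columns)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise ValueError(f"size factors missing for sample(s): {missing}")
    if (s <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return np.log2(counts.div(s, axis=1) + 1.0)


def variance_threshold(x: pd.DataFrame, percentile: float) -> float:
    """The linear-interpolation (type-7) percentile of per-gene variances."""
    if not 0 <= percentile < 100:
        raise ValueError(f"percentile must be in [0, 100), got {percentile}")
    variances = x.var(axis=1, ddof=1).to_numpy()
    return float(np.percentile(variances, percentile, method="linear"))


def filter_by_variance(x: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Keep genes whose sample variance is >= the percentile-th quantile.

    Variance is the unbiased sample variance across ALL samples. With n
    distinct variances this retains ceil(n * (1 - percentile/100)) genes.
    Gene order is preserved.
    """
    if x.shape[1] < 2:
        raise ValueError("variance filtering needs at least 2 samples")
    cut = variance_threshold(x, percentile)
    variances = x.var(axis=1, ddof=1)
    keep = variances >= cut
    if percentile > 0:
        # never retain flat genes unless the quantile itself is 0
        keep &= (variances > 0) | (cut == 0)
    return x.loc[keep]


class SizeFactorNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios depth normalization plus log2 variance stabilization.

    Works on samples x genes matrices (sklearn orientation). ``fit`` learns
    the per-gene log geometric means from the training counts; ``transform``
    computes each incoming sample's size factor against that reference and
    returns ``log2(k/s + 1)``.

    Parameters
    ----------
    allow_real : bool, default False
        Accept non-integer counts (pre-normalized input).

    Attributes
    ----------
    log_geo_means_ : ndarray of shape (n_genes,)
        Reference log geometric mean per gene (NaN where unusable).
    size_factors_ : pd.Series
        Size factors of the training samples.
    """

    def __init__(self, allow_real: bool = False):
        self.allow_real = allow_real

    def _validate(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        values = X.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.allow_real and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers (set allow_real=True to relax)")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        counts = X.T  # genes x samples
        k = counts.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logk = np.log(k)
        usable = np.all(np.isfinite(logk), axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has all-positive counts; size factors are undefined"
            )
        log_geo_means = np.full(counts.shape[0], np.nan)
        log_geo_means[usable] = logk[usable].mean(axis=1)
        self.gene_ids_ = np.asarray(counts.index)
        self.log_geo_means_ = log_geo_means
        self.size_factors_ = self._factors_for(counts)
        self.n_features_in_ = counts.shape[0]
        return self

    def _factors_for(self, counts: pd.DataFrame) -> pd.Series:
        usable = np.isfinite(self.log_geo_means_)
        k = counts.to_numpy(dtype=float)[usable]
        with np.errstate(divide="ignore"):
            ratios = np.exp(np.log(k) - self.log_geo_means_[usable][:, None])
        # a zero count in a usable gene gives ratio 0, matching the
        # median-of-ratios convention of ratio k/geomean
        s = np.median(ratios, axis=0)
        if (s <= 0).any():
            raise ValueError("a sample produced a non-positive size factor")
        return pd.Series(s, index=counts.columns, name="size_factor")

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "log_geo_means_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} genes, expected {self.n_features_in_}"
            )
        s = self._factors_for(X.T)
        return np.log2(X.div(s, axis=0) + 1.0)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_ids_")
        return np.asarray(self.gene_ids_, dtype=object)


class VarianceFilter(BaseEstimator, TransformerMixin):
    """Select genes whose variance reaches a percentile of the variance vector.

    samples x genes orientation. The threshold is the type-7
    (linear-interpolation) percentile of the per-gene unbiased sample
    variances, and selection is variance >= threshold.

    Attributes
    ----------
    variances_ : ndarray, per-gene sample variance.
    threshold_ : float, the variance cutoff actually applied.
    support_ : boolean mask of retained genes.
    """

    def __init__(self, percentile: float = 95.0):
        self.percentile = percentile

    def fit(self, X, y=None):
        if not 0 <= self.percentile < 100:
            raise ValueError(f"percentile must be in [0, 100), got {self.percentile}")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("variance filtering needs at least 2 samples")
        variances = X.var(axis=0, ddof=1).to_numpy()
        self.threshold_ = float(
            np.percentile(variances, self.percentile, method="linear")
        )
        keep = variances >= self.threshold_
        if self.percentile > 0:
            keep &= (variances > 0) | (self.threshold_ == 0)
        self.variances_ = variances
        self.support_ = keep
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]
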