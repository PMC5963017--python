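"""Low-count filtering, TMM scaling factors, and log-CPM.

TMM (trimmed mean of M-values) estimates a relative scaling factor per
sample from a doubly trimmed, precision-weighted mean of gene-wise log
count-fraction ratios against a reference sample. Factors are rescaled to
geometric mean 1, so they perturb, rather than replace, library sizes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, NormFactors

__all__ = ["filter_low_count", "tmm_factors", "log_cpm", "TMMLogCPM"]


def filter_low_count(cm: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Drop genes whose mean count across all samples is below ``min_mean``.

    A gene with mean exactly ``min_mean`` is kept (the cutoff removes genes
    with *less than* ``min_mean`` reads on average).
    """
    means = cm.counts.mean(axis=1)
    keep = means >= min_mean
    if not keep.any():
        raise ValueError(f"low-count filter at min_mean={min_mean} removed every gene")
    return CountMatrix(cm.counts.loc[keep], cm.sample_meta)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        warnings.warn("sample shares no expressed genes with the TMM reference; factor set to 1")
        return 0.0
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # binomial delta-method variance of M
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    if np.allclose(m, 0, atol=1e-10):  # identical count fractions
        return 0.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("TMM trimming removed every gene; factor set to 1")
        return 0.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """TMM scaling factors for every sample of a count matrix.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those across samples. Per non-reference sample,
    gene-wise M (log2 ratio of count fractions) and A (mean log2 abundance)
    values over genes expressed in both are doubly trimmed — ``trim_m`` from
    each M tail and ``trim_a`` from each A tail — and the factor is two to
    the precision-weighted mean of the retained M values.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = cm.counts.to_numpy().astype(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive total count")

    q75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])]) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    log_f = np.zeros(cm.n_samples)
    for j in range(cm.n_samples):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                             trim_m, trim_a)
    factors = 2.0 ** (log_f - log_f.mean())  # geometric mean 1
    return NormFactors(
        pd.Series(lib.astype(np.int64), index=cm.sample_ids, name="lib_size"),
        pd.Series(factors, index=cm.sample_ids, name="tmm_factor"),
    )


def log_cpm(cm: CountMatrix, nf: NormFactors, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes.

    value = log2((count + prior) / (effective library size + 1) * 1e6)
    """
    if list(nf.sample_ids) != cm.sample_ids:
        raise ValueError("normalization factors do not match the count matrix samples")
    eff = nf.effective_lib_size.to_numpy()
    vals = np.log2((cm.counts.to_numpy() + prior) / (eff + 1.0) * 1e6)
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


class TMMLogCPM(BaseEstimator, TransformerMixin):
    """Transformer: raw counts (n_samples, n_genes) -> filtered log-CPM.

    Composes the low-count filter, TMM factor estimation, and the log-CPM
    transform. Follows scikit-learn's sample-major orientation so it can sit
    in a Pipeline; the functional API in this module is gene-major.

    Attributes
    ----------
    gene_mask_ : boolean array of retained genes
    lib_size_ : per-sample library sizes (computed on retained genes)
    tmm_factor_ : per-sample TMM factors
    """

    def __init__(self, min_mean: float = 10.0, trim_m: float = 0.30,
                 trim_a: float = 0.05, prior: float = 0.5):
        self.min_mean = min_mean
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior = prior

    def _as_count_matrix(self, X) -> CountMatrix:
        X = np.asarray(X)
        genes = [f"g{i}" for i in range(X.shape[1])]
        samples = [f"s{j}" for j in range(X.shape[0])]
        meta = pd.DataFrame(
            {"genotype": "NA", "dose": "NA", "tissue": "NA"}, index=samples
        )
        return CountMatrix(pd.DataFrame(X.T, index=genes, columns=samples), meta)

    def fit(self, X, y=None):
        cm = self._as_count_matrix(X)
        means = cm.counts.mean(axis=1).to_numpy()
        self.gene_mask_ = means >= self.min_mean
        filtered = filter_low_count(cm, self.min_mean)
        nf = tmm_factors(filtered, self.trim_m, self.trim_a)
        self.lib_size_ = nf.lib_size.to_numpy()
        self.tmm_factor_ = nf.tmm_factor.to_numpy()
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
        return self

    def transform(self, X):
        X = np.asarray(X)[:, self.gene_mask_]
        eff = self.lib_size_ * self.tmm_factor_
        return np.log2((X + self.prior) / (eff[:, None] + 1.0) * 1e6)
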