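"""Precision-weighted gene-wise linear models with empirical-Bayes
moderated t-statistics.

The modelling chain is the classic one for bulk RNA-seq counts:

1. log-CPM transform of TMM-normalized counts;
2. a mean-variance trend fitted to sqrt(residual sd) vs average log-count,
   giving each observation an inverse predicted-variance precision weight;
3. gene-wise weighted least squares on a common design matrix;
4. shrinkage of gene-wise residual variances s^2 toward a prior variance
   s0^2 estimated by matching moments of log s^2 to a scaled-F law, with
   the moderated t referred to a t distribution on d0 + df_resid degrees
   of freedom;
5. Benjamini-Hochberg control of the false discovery rate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, DEResult, EBayesPrior, NormFactors
from .norm import filter_low_count, log_cpm, tmm_factors

__all__ = [
    "DesignSpec",
    "NAMED_CONTRASTS",
    "voom_weights",
    "fit_linear",
    "contrast_fit",
    "ebayes_moderate",
    "bh_adjust",
    "run_contrast",
    "pca_outlier_screen",
    "VoomLimmaDE",
]

#: The study's named two-group comparisons as (test cell, reference cell)
#: on the genotype:dose factor. E is the blood-tissue instance of D.
NAMED_CONTRASTS = {
    "A": ("disease:veh", "WT:veh"),
    "B": ("disease:high", "disease:veh"),
    "C": ("disease:low", "disease:veh"),
    "D": ("WT:high", "WT:veh"),
    "E": ("WT:high", "WT:veh"),
}

_SD_FLOOR = 1e-4  # floor on predicted sqrt(residual sd) in the voom trend
_S2_FLOOR = 1e-8  # floor on residual variances before moderation


@dataclass
class DesignSpec:
    """A design matrix over samples plus named contrast vectors."""

    design: pd.DataFrame  # samples x coefficients
    contrasts: dict

    def __post_init__(self) -> None:
        X = self.design.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(self.design)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
        for name, vec in self.contrasts.items():
            if len(vec) != X.shape[1]:
                raise ValueError(f"contrast {name!r} has length {len(vec)}, "
                                 f"design has {X.shape[1]} columns")

    @classmethod
    def two_group(cls, meta: pd.DataFrame, test: str, ref: str,
                  name: str = "contrast") -> "DesignSpec":
        """Group-means design restricted to the two genotype:dose cells."""
        groups = meta["genotype"].astype(str) + ":" + meta["dose"].astype(str)
        for cell in (test, ref):
            if (groups == cell).sum() == 0:
                raise ValueError(f"no samples in group {cell!r}")
        keep = groups.isin([test, ref])
        design = pd.DataFrame(
            {
                "test": (groups[keep] == test).astype(float),
                "ref": (groups[keep] == ref).astype(float),
            },
            index=groups.index[keep],
        )
        return cls(design, {name: np.array([1.0, -1.0])})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.design.index)


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    X = design.to_numpy(dtype=float)
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [design.columns[i] for i in np.where(diag <= tol)[0]]


def voom_weights(logcpm: pd.DataFrame, counts: CountMatrix, nf: NormFactors,
                 design: DesignSpec, span: float = 0.5) -> pd.DataFrame:
    """Precision weights from the fitted mean-variance trend.

    Unweighted gene-wise fits give residual standard deviations; their
    square roots are smoothed against average log2 count by lowess with the
    given span, and each observation's weight is the predicted sd at its
    fitted log-count raised to the power -4 (an inverse predicted variance
    of the log-CPM value).
    """
    ids = design.sample_ids
    y = logcpm[ids].to_numpy()
    X = design.design.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("fewer than 1 residual degree of freedom")

    beta, _, _, _ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    s = np.sqrt((resid ** 2).sum(axis=1) / (n - p))

    eff = nf.effective_lib_size.loc[ids].to_numpy()
    # average log2 count per gene; log2 lib offset converts CPM back to counts
    sx = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.maximum(s, _SD_FLOOR ** 2))

    if np.ptp(sx) < 1e-12 or np.ptp(sy) < 1e-12:
        pred_all = np.full_like(fitted, max(sy.mean(), _SD_FLOOR))
    else:
        trend = lowess(sy, sx, frac=span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        fitted_logcount = fitted + np.log2(eff + 1.0)[None, :] - np.log2(1e6)
        pred_all = np.interp(fitted_logcount, tx, ty)  # clamped at the ends
    pred_all = np.maximum(pred_all, _SD_FLOOR)
    w = pred_all ** -4.0
    return pd.DataFrame(w, index=logcpm.index, columns=ids)


@dataclass
class LinearFit:
    """Per-gene weighted least-squares results on a shared design."""

    design: DesignSpec
    coef: pd.DataFrame  # genes x coefficients
    s2: pd.Series  # residual variance
    df_resid: int
    xtwx_inv: np.ndarray  # (genes, p, p) unscaled coefficient covariance


def fit_linear(logcpm: pd.DataFrame, weights: pd.DataFrame | None,
               design: DesignSpec) -> LinearFit:
    """Weighted least squares per gene; s2 = weighted RSS / df_resid."""
    ids = design.sample_ids
    y = logcpm[ids].to_numpy()
    X = design.design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than design columns")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = weights[ids].to_numpy()
        if w.shape != y.shape or (w <= 0).any():
            raise ValueError("weights must be positive and conformable")

    xtwx = np.einsum("ni,gn,nj->gij", X, w, X)
    xtwy = np.einsum("ni,gn,gn->gi", X, w, y)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gij,gj->gi", xtwx_inv, xtwy)
    resid = y - (beta @ X.T)
    rss = (w * resid ** 2).sum(axis=1)
    df = n - p
    return LinearFit(
        design=design,
        coef=pd.DataFrame(beta, index=logcpm.index, columns=design.design.columns),
        s2=pd.Series(rss / df, index=logcpm.index, name="s2"),
        df_resid=df,
        xtwx_inv=xtwx_inv,
    )


def contrast_fit(fit: LinearFit, contrast: str | np.ndarray):
    """Effect and unscaled standard error of one contrast per gene."""
    c = fit.design.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast)
    effect = fit.coef.to_numpy() @ c
    var_unscaled = np.einsum("i,gij,j->g", c, fit.xtwx_inv, c)
    stdev_unscaled = np.sqrt(np.maximum(var_unscaled, 0.0))
    return (pd.Series(effect, index=fit.coef.index, name="effect"),
            pd.Series(stdev_unscaled, index=fit.coef.index, name="stdev_unscaled"))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df_resid: float) -> EBayesPrior:
    """Moment-match log s2 to a scaled-F law to get (d0, s0^2).

    With s2_g ~ s0^2 * F(df_resid, d0), E[log s2] and Var[log s2] involve
    digamma/trigamma of the half-dfs; the excess variance of log s2 over
    trigamma(df/2) identifies d0 through the trigamma inverse.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), _S2_FLOOR)
    if s2.size < 10:
        raise ValueError("prior estimation needs at least 10 genes")
    z = np.log(s2)
    e = z - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df_resid / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        warnings.warn("no excess variance in log s2; using complete shrinkage (d0 = inf)")
        d0 = np.inf
        s0_sq = np.exp(emean)
    return EBayesPrior(float(d0), float(s0_sq))


def ebayes_moderate(s2, df_resid: float, effect=None, stdev_unscaled=None,
                    prior: EBayesPrior | None = None):
    """Moderated t-statistics from shrunken residual variances.

    Returns ``(prior, t_mod, p)``. When ``prior`` is given it is used
    directly (d0 = 0 reproduces the ordinary t; d0 = inf replaces every
    variance by s0^2); otherwise it is estimated from the s2 distribution.
    ``effect`` and ``stdev_unscaled`` may be omitted to only estimate the
    prior.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), _S2_FLOOR)
    if prior is None:
        prior = estimate_prior(s2, df_resid)
    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    if effect is None:
        return prior, None, None
    effect = np.asarray(effect, dtype=float)
    stdev_unscaled = np.asarray(stdev_unscaled, dtype=float)
    t_mod = effect / (stdev_unscaled * np.sqrt(s2_post))
    df_total = df_resid + d0
    if np.isinf(df_total):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t_mod), df_total)
    return prior, t_mod, np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(cm: CountMatrix, contrast: str, min_mean: float = 10.0,
                 span: float = 0.5, trim_m: float = 0.30, trim_a: float = 0.05,
                 prior_count: float = 0.5) -> DEResult:
    """Filter -> TMM -> log-CPM -> voom -> WLS -> moderation -> BH for one
    named two-group contrast (one of A-E, or ``'test:cell/ref:cell'``)."""
    if contrast in NAMED_CONTRASTS:
        test, ref = NAMED_CONTRASTS[contrast]
    elif "/" in contrast:
        test, ref = contrast.split("/", 1)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    groups = cm.group_labels()
    keep = groups.isin([test, ref])
    if (groups == test).sum() == 0 or (groups == ref).sum() == 0:
        raise ValueError(f"contrast {contrast!r} needs samples in {test!r} and {ref!r}")
    sub = cm.subset_samples(groups.index[keep])

    est = VoomLimmaDE(min_mean=min_mean, span=span, trim_m=trim_m,
                      trim_a=trim_a, prior_count=prior_count)
    est.fit(sub.counts.to_numpy().T, (cm.group_labels()[keep] == test).to_numpy())

    genes = np.asarray(sub.gene_ids)[est.gene_mask_]
    table = pd.DataFrame(
        {
            "log2fc": est.log2fc_,
            "avg_expr": est.avg_expr_,
            "s2": est.s2_,
            "df_resid": est.df_resid_,
            "t_ord": est.t_ord_,
            "t_mod": est.t_,
            "p": est.pvalues_,
            "adj_p": est.adj_pvalues_,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(contrast, table, EBayesPrior(est.d0_, est.s0_sq_))


class VoomLimmaDE(BaseEstimator):
    """Two-group moderated-t differential expression estimator.

    scikit-learn-style: ``fit(X, y)`` with X raw counts of shape
    (n_samples, n_genes) and y a boolean/binary vector marking the test
    group. Fitted attributes (per retained gene): ``log2fc_``, ``t_``,
    ``pvalues_``, ``adj_pvalues_``, plus the variance-prior
    hyperparameters ``d0_`` and ``s0_sq_``.
    """

    def __init__(self, min_mean: float = 10.0, span: float = 0.5,
                 trim_m: float = 0.30, trim_a: float = 0.05,
                 prior_count: float = 0.5):
        self.min_mean = min_mean
        self.span = span
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior_count = prior_count

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y).astype(bool)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of samples")
        samples = [f"s{j}" for j in range(X.shape[0])]
        genes = [f"g{i}" for i in range(X.shape[1])]
        meta = pd.DataFrame(
            {
                "genotype": np.where(y, "test", "ref"),
                "dose": "NA",
                "tissue": "NA",
            },
            index=samples,
        )
        cm = CountMatrix(pd.DataFrame(X.T, index=genes, columns=samples), meta)

        filtered = filter_low_count(cm, self.min_mean)
        self.gene_mask_ = cm.counts.mean(axis=1).to_numpy() >= self.min_mean
        nf = tmm_factors(filtered, self.trim_m, self.trim_a)
        logcpm = log_cpm(filtered, nf, self.prior_count)

        design = DesignSpec(
            pd.DataFrame({"test": y.astype(float), "ref": (~y).astype(float)},
                         index=samples),
            {"effect": np.array([1.0, -1.0])},
        )
        w = voom_weights(logcpm, filtered, nf, design, self.span)
        fit = fit_linear(logcpm, w, design)
        effect, stdev_unscaled = contrast_fit(fit, "effect")

        s2 = np.maximum(fit.s2.to_numpy(), _S2_FLOOR)
        prior, t_mod, p = ebayes_moderate(
            s2, fit.df_resid, effect.to_numpy(), stdev_unscaled.to_numpy()
        )
        self.log2fc_ = effect.to_numpy()
        self.avg_expr_ = logcpm.mean(axis=1).to_numpy()
        self.s2_ = s2
        self.df_resid_ = fit.df_resid
        self.t_ord_ = effect.to_numpy() / (stdev_unscaled.to_numpy() * np.sqrt(s2))
        self.t_ = t_mod
        self.pvalues_ = p
        self.adj_pvalues_ = bh_adjust(p)
        self.d0_ = prior.d0
        self.s0_sq_ = prior.s0_sq
        self.n_features_in_ = X.shape[1]
        return self


def pca_outlier_screen(logcpm: pd.DataFrame, k_sd: float = 3.0) -> list[str]:
    """Flag samples farther than ``k_sd`` robust SDs from the centroid in
    the first two principal components (screening only; nothing is removed).
    """
    if logcpm.shape[1] < 4:
        raise ValueError("PCA screening needs at least 4 samples")
    X = logcpm.to_numpy().T
    X = X - X.mean(axis=0)
    if np.allclose(X, 0):
        return []
    pcs = PCA(n_components=2, svd_solver="full").fit_transform(X)
    center = np.median(pcs, axis=0)
    mad = scipy.stats.median_abs_deviation(pcs, axis=0, scale="normal")
    mad = np.where(mad > 1e-12, mad, np.maximum(pcs.std(axis=0), 1e-12))
    z = (pcs - center) / mad
    dist = np.sqrt((z ** 2).sum(axis=1))
    flagged = np.asarray(logcpm.columns)[dist > k_sd]
    return sorted(flagged.tolist())
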