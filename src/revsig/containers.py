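"""Core in-memory containers shared across the pipeline.

Counts are always genes x samples; gene and sample identifiers are opaque,
case-sensitive strings. Validation happens at construction so downstream
code can assume well-formed objects.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FeatureCountTable",
    "GeneSet",
    "GeneSetCollection",
    "Signature",
    "NormFactors",
    "DEResult",
    "EBayesPrior",
    "DEGList",
    "DUEJResult",
    "ReversalResult",
]

REQUIRED_META = ("genotype", "dose", "tissue")


class FormatError(ValueError):
    """Raised when a tabular artifact violates its format contract."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


def _check_integer_counts(df: pd.DataFrame, what: str = "count") -> pd.DataFrame:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric {what} values")
    if np.isnan(values.astype(float)).any():
        r, c = np.argwhere(np.isnan(values.astype(float)))[0]
        raise FormatError(f"missing {what} at gene={df.index[r]!r}, sample={df.columns[c]!r}")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative {what} {values[r, c]} at gene={df.index[r]!r}, sample={df.columns[c]!r}"
        )
    if not np.allclose(values, np.round(values)):
        bad = ~np.isclose(values, np.round(values))
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-integer {what} {values[r, c]} at gene={df.index[r]!r}, sample={df.columns[c]!r}"
        )
    return df.round().astype(np.int64)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample annotations.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids, columns =
        sample ids.
    sample_meta
        DataFrame indexed by sample id with at least the columns
        ``genotype``, ``dose`` and ``tissue``; ``study_id`` is optional.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        self.counts = _check_integer_counts(self.counts)
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples missing from sample sheet: {missing}")
        absent = [c for c in REQUIRED_META if c not in self.sample_meta.columns]
        if absent:
            raise FormatError(f"sample sheet lacks required columns: {absent}")
        # align meta to count columns (drops extraneous sheet rows)
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)].copy()
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.sample_meta.loc[sample_ids])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.sample_meta)

    def group_labels(self) -> pd.Series:
        """Genotype and dose combined into one factor, e.g. ``disease:veh``."""
        meta = self.sample_meta
        return meta["genotype"].astype(str) + ":" + meta["dose"].astype(str)


@dataclass
class FeatureCountTable:
    """Exon/junction counts nested under genes.

    ``counts`` is indexed by a (gene_id, feature_id) MultiIndex; columns are
    samples. ``feature_type`` maps each (gene, feature) to 'exon' or
    'junction'.
    """

    counts: pd.DataFrame
    feature_type: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.nlevels != 2:
            raise FormatError("feature counts need a (gene_id, feature_id) index")
        _check_unique(self.counts.index, "(gene, feature) pairs")
        self.counts = _check_integer_counts(self.counts, "feature count")
        self.feature_type = self.feature_type.reindex(self.counts.index)
        bad = set(self.feature_type.dropna().unique()) - {"exon", "junction"}
        if bad:
            raise FormatError(f"unknown feature types: {sorted(bad)}")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples missing from sample sheet: {missing}")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)].copy()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index.get_level_values(0).unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def gene_counts(self, gene_id: str) -> pd.DataFrame:
        return self.counts.xs(gene_id, level=0, drop_level=True)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    direction: str = "none"  # 'up' | 'down' | 'none'
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if self.direction not in ("up", "down", "none"):
            raise FormatError(f"bad direction {self.direction!r} for set {self.name!r}")


class GeneSetCollection:
    """Named gene sets with optional up/down direction tags (GMT-backed)."""

    def __init__(self, sets: list[GeneSet] | None = None):
        self.sets: dict[str, GeneSet] = {}
        for s in sets or []:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class Signature:
    """Per-gene vector of signed DE scores (moderated t) for one contrast."""

    label: str
    scores: pd.Series
    provenance: str = "single-study"  # 'single-study' | 'meta'

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "signature genes")
        self.scores = self.scores.astype(float)
        if not np.isfinite(self.scores.to_numpy()).all():
            raise FormatError(f"non-finite scores in signature {self.label!r}")
        if self.provenance not in ("single-study", "meta"):
            raise FormatError(f"bad provenance {self.provenance!r}")

    @property
    def n_genes(self) -> int:
        return len(self.scores)


@dataclass
class NormFactors:
    """Library sizes and TMM scaling factors, geometric-mean-1 normalized."""

    lib_size: pd.Series
    tmm_factor: pd.Series

    def __post_init__(self) -> None:
        self.tmm_factor = self.tmm_factor.reindex(self.lib_size.index).astype(float)
        if (self.tmm_factor <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.lib_size <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.tmm_factor

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lib_size.index)


@dataclass(frozen=True)
class EBayesPrior:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0 and np.isfinite(self.s0_sq)):
            raise ValueError("s0_sq must be positive and finite")


@dataclass
class DEResult:
    """Gene-wise differential expression table for one named contrast.

    ``table`` columns: log2fc, avg_expr, s2, df_resid, t_ord, t_mod, p,
    adj_p (index = gene ids).
    """

    contrast: str
    table: pd.DataFrame
    prior: EBayesPrior | None = None

    REQUIRED = ("log2fc", "avg_expr", "s2", "df_resid", "t_ord", "t_mod", "p", "adj_p")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table lacks columns {missing}")
        _check_unique(self.table.index, "DE genes")

    def to_signature(self, provenance: str = "single-study") -> Signature:
        return Signature(self.contrast, self.table["t_mod"].copy(), provenance)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DEGList:
    """Up/down differentially expressed gene lists with thresholds used."""

    label: str
    up: frozenset
    down: frozenset
    fc_min: float
    adjp_max: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down")


@dataclass
class DUEJResult:
    """Differential exon/junction usage result.

    ``feature_table`` index: (gene_id, feature_id); columns: coef (usage
    interaction log-fold-change), lrt, df, p, adj_p. ``gene_table`` index:
    gene_id; columns: min_adj_p, top_feature, n_features_tested.
    """

    contrast: str
    feature_table: pd.DataFrame
    gene_table: pd.DataFrame
    skipped: dict = field(default_factory=dict)

    def significant_genes(self, alpha: float = 0.05) -> list[str]:
        tab = self.gene_table
        return list(tab.index[tab["min_adj_p"] < alpha])


@dataclass
class ReversalResult:
    """Cosine and directional-enrichment evidence that a treatment signature
    opposes a disease signature."""

    cosine: float
    n_shared_genes: int
    perm_p: float
    directional: pd.DataFrame  # index=set name; es, nes, perm_p, adj_p, direction_ok
    reversed_verdict: bool

    def to_dict(self) -> dict:
        return {
            "cosine": float(self.cosine),
            "n_shared_genes": int(self.n_shared_genes),
            "perm_p": float(self.perm_p),
            "directional": {
                name: {k: (None if pd.isna(v) else (bool(v) if k == "direction_ok" else float(v)))
                       for k, v in row.items()}
                for name, row in self.directional.to_dict("index").items()
            },
            "reversed": bool(self.reversed_verdict),
        }
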