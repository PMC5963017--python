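"""Readers and writers for count matrices, sample sheets, GMT gene sets,
signatures and feature-count tables.

Dialects: TSV files are tab-separated UTF-8 with a header row; the first
column of a count file is literally ``gene_id``. MatrixMarket output is a
coordinate .mtx plus plain-text row (gene) and column (sample) index files.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CountMatrix,
    FeatureCountTable,
    FormatError,
    GeneSet,
    GeneSetCollection,
    Signature,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "read_feature_counts",
    "write_feature_counts",
]


def write_sample_sheet(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{path}: sample sheet needs a 'sample_id' column")
    return meta.set_index("sample_id")


def write_counts(cm: CountMatrix, path: str, fmt: str = "tsv",
                 sample_sheet: str | None = None) -> None:
    """Write counts as TSV (default) or MatrixMarket triplet files.

    For ``fmt='mtx'`` the gene and sample index files are written next to
    the .mtx as ``<stem>.genes.tsv`` / ``<stem>.samples.tsv``.
    """
    if fmt == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        scipy.io.mmwrite(stem + ".mtx", scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        with open(stem + ".genes.tsv", "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with open(stem + ".samples.tsv", "w") as fh:
            fh.write("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if sample_sheet is not None:
        write_sample_sheet(cm.sample_meta, sample_sheet)


def read_counts(path: str, sample_sheet: str, fmt: str = "tsv") -> CountMatrix:
    """Read a count matrix plus its sample sheet into a validated CountMatrix."""
    meta = read_sample_sheet(sample_sheet)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "gene_id":
            raise FormatError(f"{path}: first column must be 'gene_id'")
        df = df.set_index("gene_id")
    elif fmt == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        mat = scipy.io.mmread(stem + ".mtx")
        genes = _read_index(stem + ".genes.tsv")
        samples = _read_index(stem + ".samples.tsv")
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if mat.shape != (len(genes), len(samples)):
            raise FormatError(
                f"{path}: matrix shape {mat.shape} does not match index files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise FormatError(f"{path}: samples absent from sample sheet: {missing}")
    return CountMatrix(df, meta)


def _read_index(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB gene1 TAB gene2 ...

    Duplicate genes within a set are deduplicated; a ``_UP`` / ``_DOWN``
    suffix on the set name becomes the direction tag.
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            direction = "none"
            if name.endswith("_UP"):
                direction = "up"
            elif name.endswith("_DOWN"):
                direction = "down"
            coll.add(GeneSet(name, genes, direction, desc))
    return coll


def write_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description or '.'}\t{genes}\n")


def write_signature(sig: Signature, path: str) -> None:
    sig.scores.rename("score").to_csv(path, sep="\t", index_label="gene_id")


def read_signature(path: str, label: str | None = None,
                   provenance: str = "single-study") -> Signature:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "score"]:
        raise FormatError(f"{path}: signature needs columns gene_id, score")
    return Signature(label or os.path.basename(path), df.set_index("gene_id")["score"],
                     provenance)


def write_feature_counts(fct: FeatureCountTable, path: str,
                         sample_sheet: str | None = None) -> None:
    out = fct.counts.copy()
    out.insert(0, "feature_type", fct.feature_type.to_numpy())
    out.to_csv(path, sep="\t", index_label=["gene_id", "feature_id"])
    if sample_sheet is not None:
        write_sample_sheet(fct.sample_meta, sample_sheet)


def read_feature_counts(path: str, sample_sheet: str) -> FeatureCountTable:
    meta = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "feature_id", "feature_type"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: feature counts need columns {sorted(need)}")
    df = df.set_index(["gene_id", "feature_id"])
    ftype = df.pop("feature_type")
    return FeatureCountTable(df, ftype, meta)
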