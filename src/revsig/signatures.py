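"""Disease/treatment signature assembly: DEG selection by fold-change and
FDR thresholds, Stouffer meta-analysis of two studies, and directional
reversal gene sets.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .containers import DEGList, DEResult, FormatError, GeneSet, GeneSetCollection, Signature

__all__ = ["select_degs", "meta_signature", "make_reversal_sets"]


def select_degs(de: DEResult, fc_min: float = 1.25, adjp_max: float = 0.05) -> DEGList:
    """Split a DE result into up/down DEG lists.

    A gene is *up* if its linear fold change 2^log2FC exceeds ``fc_min`` and
    its BH-adjusted p-value is below ``adjp_max``; *down* if the linear fold
    change is below 1/``fc_min`` at the same significance. Thresholds are
    strict inequalities.
    """
    if fc_min <= 1.0:
        raise ValueError("fc_min must exceed 1 (it is a linear fold-change threshold)")
    tab = de.table
    fc = 2.0 ** tab["log2fc"]
    sig = tab["adj_p"] < adjp_max
    up = frozenset(tab.index[(fc > fc_min) & sig])
    down = frozenset(tab.index[(fc < 1.0 / fc_min) & sig])
    return DEGList(de.contrast, up, down, fc_min, adjp_max)


def _signed_z(p: pd.Series, t_sign: pd.Series) -> pd.Series:
    p = p.clip(lower=np.finfo(float).tiny, upper=1.0)
    z = scipy.stats.norm.isf(p / 2.0)
    return pd.Series(np.sign(t_sign.to_numpy()) * z, index=p.index)


def meta_signature(sig_a: Signature, sig_b: Signature, p_a: pd.Series, p_b: pd.Series,
                   n_a: int | None = None, n_b: int | None = None,
                   label: str | None = None, min_shared: int = 100) -> Signature:
    """Stouffer combination of two studies' DE evidence into one signature.

    Each study's two-sided p-value and t-sign become a signed normal score
    z = sign(t) * Phi^-1(1 - p/2); the combined score is the (optionally
    sample-size weighted) Stouffer sum. Genes absent from either study are
    excluded.
    """
    shared = sig_a.scores.index.intersection(sig_b.scores.index)
    if len(shared) == 0:
        raise ValueError("the two signatures share no genes")
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes; need >= {min_shared}")
    z_a = _signed_z(p_a.loc[shared], sig_a.scores.loc[shared])
    z_b = _signed_z(p_b.loc[shared], sig_b.scores.loc[shared])
    if n_a is not None and n_b is not None:
        w_a, w_b = np.sqrt(n_a), np.sqrt(n_b)
    else:
        w_a = w_b = 1.0
    combined = (w_a * z_a + w_b * z_b) / np.sqrt(w_a ** 2 + w_b ** 2)
    return Signature(label or f"meta({sig_a.label},{sig_b.label})",
                     combined.sort_index(), provenance="meta")


def make_reversal_sets(disease_degs: DEGList) -> GeneSetCollection:
    """Directional gene sets (<label>_UP / <label>_DOWN) from disease DEGs,
    for querying a treatment ranking: reversal means the _UP set is pushed
    down by treatment and the _DOWN set pushed up."""
    coll = GeneSetCollection()
    label = disease_degs.label
    if disease_degs.up:
        coll.add(GeneSet(f"{label}_UP", frozenset(disease_degs.up), "up",
                         f"genes up in {label}"))
    else:
        warnings.warn(f"no up-regulated DEGs for {label}; _UP set omitted")
    if disease_degs.down:
        coll.add(GeneSet(f"{label}_DOWN", frozenset(disease_degs.down), "down",
                         f"genes down in {label}"))
    else:
        warnings.warn(f"no down-regulated DEGs for {label}; _DOWN set omitted")
    if len(coll) == 0:
        raise FormatError(f"no DEGs in either direction for {label}")
    return coll
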