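"""Preranked gene-set enrichment (weighted Kolmogorov-Smirnov-like running
sum with a gene-permutation null) and hypergeometric over-representation.

The running-sum statistic walks the score-ranked gene list; hits add their
weighted score share, misses subtract a constant, and the enrichment score
(ES) is the signed maximal deviation from zero. Significance comes from
re-drawing same-size random gene sets from the ranking (gene-tag
permutation), the only null available without sample labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneSetCollection, Signature
from .de import bh_adjust

__all__ = [
    "rank_signature",
    "enrichment_score",
    "preranked_test",
    "overrep_test",
    "EnrichmentTable",
]


def rank_signature(sig: Signature) -> pd.Series:
    """Scores sorted by decreasing value; ties broken by gene id
    (lexicographic) for determinism."""
    df = sig.scores.rename("score").rename_axis("gene_id").reset_index()
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        kind="mergesort")
    return df.set_index("gene_id")["score"]


def _es_from_positions(pos: np.ndarray, w_abs: np.ndarray, n: int, weight_p: float):
    """ES from sorted 0-based hit positions in a ranking of length n.

    ``w_abs`` are |score|^p at every rank. Returns (es, extremum_index_in_hits,
    is_positive). The running sum is piecewise linear between hits, so its
    extrema occur just after a hit (maxima) or just before one (minima).
    """
    k = pos.size
    w_hit = w_abs[pos]
    total = w_hit.sum()
    if total <= 0:  # all hit scores zero: fall back to unweighted steps
        w_hit = np.ones(k)
        total = float(k)
    miss_pen = 1.0 / (n - k)
    cum = np.cumsum(w_hit) / total
    j = np.arange(k)
    after = cum - (pos - j) * miss_pen
    before = after - w_hit / total
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = after[i_max]
    es_neg = before[i_min]
    if es_pos >= -es_neg - 1e-12:  # ties (within fp noise) -> positive
        return float(es_pos), i_max, True
    return float(es_neg), i_min, False


def enrichment_score(ranked: pd.Series, geneset, weight_p: float = 1.0):
    """Enrichment score of one gene set in a ranked list.

    Returns ``(es, leading_edge)`` where the leading edge holds the set's
    genes at or before the running-sum extremum (at or after it, for a
    negative ES), in ranking order.
    """
    genes = np.asarray(ranked.index)
    n = genes.size
    member = np.isin(genes, list(geneset.genes if hasattr(geneset, "genes") else geneset))
    k = int(member.sum())
    if k == 0 or k == n:
        raise ValueError(f"gene set covers {k} of {n} ranked genes; ES is undefined")
    w_abs = np.abs(ranked.to_numpy()) ** weight_p
    pos = np.flatnonzero(member)
    es, i_ext, positive = _es_from_positions(pos, w_abs, n, weight_p)
    leading = genes[pos[: i_ext + 1]] if positive else genes[pos[i_ext:]]
    return es, list(leading)


def _null_es(rng: np.random.Generator, n: int, k: int, w_abs: np.ndarray,
             n_perm: int, weight_p: float) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets (vectorized)."""
    out = np.empty(n_perm)
    # random k-subsets via partial argsort of uniform keys, in blocks
    block = max(1, min(n_perm, int(2e6 / max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, n))
        pos = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
        w_hit = w_abs[pos]
        totals = w_hit.sum(axis=1)
        zero = totals <= 0
        if zero.any():
            w_hit[zero] = 1.0
            totals[zero] = k
        miss_pen = 1.0 / (n - k)
        cum = np.cumsum(w_hit, axis=1) / totals[:, None]
        j = np.arange(k)[None, :]
        after = cum - (pos - j) * miss_pen
        before = after - w_hit / totals[:, None]
        es_pos = after.max(axis=1)
        es_neg = before.min(axis=1)
        out[done:done + b] = np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)
        done += b
    return out


@dataclass
class EnrichmentTable:
    """Per-set preranked enrichment results."""

    table: pd.DataFrame  # index=set name; es, nes, n_hits, perm_p, adj_p
    leading_edge: dict


def preranked_test(ranked: pd.Series, sets: GeneSetCollection, n_perm: int = 1000,
                   seed: int = 0, weight_p: float = 1.0) -> EnrichmentTable:
    """Permutation test of every gene set against one ranked list.

    NES divides each ES by the mean |null ES| of matching sign; the
    permutation p-value is two-sided by sign class with +1 smoothing, and
    BH adjustment runs across the sets tested in this call.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value floor of "
                      f"{1.0 / (n_perm + 1):.3g}")
    genes = np.asarray(ranked.index)
    n = genes.size
    w_abs = np.abs(ranked.to_numpy()) ** weight_p
    rng = np.random.default_rng(seed)

    rows, leading = [], {}
    for gs in sets:
        member = np.isin(genes, list(gs.genes))
        k = int(member.sum())
        if k == 0 or k == n:
            rows.append((gs.name, np.nan, np.nan, k, np.nan))
            continue
        pos = np.flatnonzero(member)
        es, i_ext, positive = _es_from_positions(pos, w_abs, n, weight_p)
        leading[gs.name] = list(genes[pos[: i_ext + 1]] if positive else genes[pos[i_ext:]])
        null = _null_es(rng, n, k, w_abs, n_perm, weight_p)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        perm_p = (1.0 + n_extreme) / (1.0 + n_same) if n_same else 1.0
        denom = np.abs(null[same_sign]).mean() if n_same else np.abs(null).mean()
        nes = es / denom if denom > 0 else np.nan
        rows.append((gs.name, es, nes, k, perm_p))

    tab = pd.DataFrame(rows, columns=["set", "es", "nes", "n_hits", "perm_p"])
    tab = tab.set_index("set")
    ok = tab["perm_p"].notna()
    adj = pd.Series(np.nan, index=tab.index)
    if ok.any():
        adj[ok] = bh_adjust(tab.loc[ok, "perm_p"].to_numpy())
    tab["adj_p"] = adj
    return EnrichmentTable(tab, leading)


def overrep_test(deg: set, universe: set, sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in a DEG
    list, BH-adjusted across sets.

    The tail probability is P(overlap >= observed) under random draws of
    |deg| genes from the universe; sets are intersected with the universe
    first.
    """
    deg, universe = set(deg), set(universe)
    if not deg <= universe:
        raise ValueError("DEG list must be a subset of the universe")
    m, n_draw = len(universe), len(deg)
    rows = []
    for gs in sets:
        members = set(gs.genes) & universe
        big_k = len(members)
        if big_k == 0:
            rows.append((gs.name, 0, 0, np.nan, 1.0))
            continue
        k = len(members & deg)
        p = float(scipy.stats.hypergeom.sf(k - 1, m, big_k, n_draw))
        a, b = k, big_k - k
        c, d = n_draw - k, m - big_k - (n_draw - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((gs.name, big_k, k, odds, min(p, 1.0)))
    tab = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "odds_ratio", "p"])
    tab = tab.set_index("set")
    tab["adj_p"] = bh_adjust(tab["p"].to_numpy())
    return tab
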