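"""Signature-reversal scoring: does a treatment signature oppose a disease
signature?

Two complementary views: (i) the cosine similarity of the two moderated-t
vectors over their shared genes — negative cosine means treatment pushes
expression against the disease direction — with a gene-permutation null;
and (ii) directional preranked enrichment of the disease up/down DEG sets
in the treatment ranking, where reversal requires the up set to be
negatively enriched and the down set positively.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, ReversalResult, Signature
from .de import bh_adjust
from .enrich import preranked_test, rank_signature

__all__ = ["cosine_reversal", "cosine_null", "directional_reversal", "reversal_report"]

MIN_SHARED = 10


def _shared_vectors(disease: Signature, treatment: Signature):
    shared = disease.scores.index.intersection(treatment.scores.index).sort_values()
    if len(shared) < MIN_SHARED:
        raise ValueError(f"only {len(shared)} shared genes (< {MIN_SHARED}); "
                         "cosine is unstable")
    d = disease.scores.loc[shared].to_numpy()
    t = treatment.scores.loc[shared].to_numpy()
    return shared, d, t


def cosine_reversal(disease: Signature, treatment: Signature):
    """Cosine similarity over the shared-gene intersection.

    Returns ``(cosine, n_shared)``; a negative cosine indicates reversal.
    """
    shared, d, t = _shared_vectors(disease, treatment)
    denom = np.linalg.norm(d) * np.linalg.norm(t)
    if denom == 0:
        raise ValueError("a signature with all-zero scores has no direction")
    return float(d @ t / denom), len(shared)


def cosine_null(disease: Signature, treatment: Signature, n_perm: int = 10000,
                seed: int = 0, alternative: str = "reversal") -> float:
    """Permutation p-value for the observed cosine.

    The gene-to-score assignment of the treatment signature is permuted
    ``n_perm`` times; with the default one-sided ``'reversal'`` alternative
    the p-value counts permuted cosines at least as negative as observed
    (with +1 smoothing, so the floor is 1/(n_perm + 1)).
    """
    _, d, t = _shared_vectors(disease, treatment)
    denom = np.linalg.norm(d) * np.linalg.norm(t)
    if denom == 0:
        raise ValueError("a signature with all-zero scores has no direction")
    obs = float(d @ t / denom)
    rng = np.random.default_rng(seed)
    n = d.size
    count = 0
    block = max(1, min(n_perm, int(2e6 / n)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = np.argsort(rng.random((b, n)), axis=1)
        cos_perm = (t[perm] @ d) / denom
        if alternative == "reversal":
            count += int((cos_perm <= obs).sum())
        elif alternative == "concordance":
            count += int((cos_perm >= obs).sum())
        else:  # two-sided on |cos|
            count += int((np.abs(cos_perm) >= abs(obs)).sum())
        done += b
    return (1.0 + count) / (n_perm + 1.0)


def directional_reversal(disease_sets: GeneSetCollection, treatment: Signature,
                         n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
                         weight_p: float = 1.0) -> pd.DataFrame:
    """Enrichment of disease up/down sets in the treatment ranking.

    Per directional set: ES, NES, permutation p, BH-adjusted p across the
    tested family, and whether the enrichment direction is the one reversal
    requires (up-tagged set enriched negatively, down-tagged positively).
    Sets with zero overlap are reported untestable (NaN).
    """
    ranked = rank_signature(treatment)
    enr = preranked_test(ranked, disease_sets, n_perm=n_perm, seed=seed,
                         weight_p=weight_p)
    tab = enr.table.copy()
    direction = pd.Series({gs.name: gs.direction for gs in disease_sets})
    expected_sign = direction.map({"up": -1.0, "down": 1.0, "none": np.nan})
    tab["direction"] = direction
    tab["direction_ok"] = np.sign(tab["es"]) == expected_sign
    # re-adjust across the family actually tested here
    ok = tab["perm_p"].notna()
    tab.loc[ok, "adj_p"] = bh_adjust(tab.loc[ok, "perm_p"].to_numpy())
    return tab


def reversal_report(disease: Signature, treatment: Signature,
                    disease_sets: GeneSetCollection, n_perm_cosine: int = 10000,
                    n_perm_sets: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> ReversalResult:
    """Full reversal assessment of one treatment signature.

    The verdict is 'reversed' only when both directional sets are
    significant (BH-adjusted p < alpha) with the reversal-consistent
    enrichment sign.
    """
    cos, n_shared = cosine_reversal(disease, treatment)
    perm_p = cosine_null(disease, treatment, n_perm=n_perm_cosine, seed=seed)
    tab = directional_reversal(disease_sets, treatment, n_perm=n_perm_sets,
                               seed=seed + 1, alpha=alpha)
    directional = tab[tab["direction"].isin(["up", "down"])]
    testable = directional["perm_p"].notna()
    verdict = bool(
        len(directional) >= 2
        and testable.all()
        and (directional["adj_p"] < alpha).all()
        and directional["direction_ok"].all()
    )
    return ReversalResult(cos, n_shared, perm_p,
                          tab[["es", "nes", "perm_p", "adj_p", "direction_ok"]],
                          verdict)
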