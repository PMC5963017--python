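"""Synthetic negative-binomial count data with planted disease and
dose-dependent drug-reversal effects.

The generator emulates the structure of a chronic-treatment rodent design:
two genotypes (WT and a disease model) crossed with three treatment arms
(vehicle, low dose, high dose). A configurable fraction of genes carries a
disease log2 fold change drawn from N(0, sd^2); in treated disease samples
a subset of those genes is pulled back toward baseline, with the pull
strength kappa in [0, 1] encoding dose (treated mean = baseline *
2^(lfc * (1 - kappa)); kappa = 1 is full reversal). Gene-wise NB dispersions
and library sizes are lognormal. Everything is driven by one integer seed
and is bit-reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix, FeatureCountTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_two_studies",
    "simulate_feature_counts",
]

GENOTYPES = ("WT", "disease")
DOSES = ("veh", "low", "high")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the count simulation.

    Defaults give a bulk-RNA-seq-like matrix: 2,000 genes, 8 samples per
    genotype x dose cell, lognormal baseline means and dispersions in the
    typical bulk range, ~10 million reads per library, 10% of genes carrying
    a disease effect of which 80% are dose-dependently reversed.
    """

    n_genes: int = 2000
    n_per_group: int = 8
    baseline_mean_log: float = 5.0  # natural-log mean of per-gene expected counts
    baseline_sd_log: float = 1.5
    dispersion_meanlog: float = -1.5
    dispersion_sdlog: float = 0.5
    libsize_log_mean: float = float(np.log(1e7))
    libsize_sigma: float = 0.25
    frac_disease: float = 0.1
    disease_lfc_sd: float = 1.0
    reversal_frac: float = 0.8
    kappa_by_dose: dict = field(default_factory=lambda: {"low": 0.3, "high": 0.8})
    tissue: str = "striatum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValueError("n_genes and n_per_group must be positive")
        for name in ("frac_disease", "reversal_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("baseline_sd_log", "dispersion_sdlog", "libsize_sigma",
                     "disease_lfc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for dose, kappa in self.kappa_by_dose.items():
            if dose not in DOSES:
                raise ValueError(f"unknown dose label {dose!r}")
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"kappa for dose {dose!r} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted effects, for downstream recovery checks."""

    disease_genes: frozenset
    disease_lfc: pd.Series  # over disease genes
    reversed_genes: frozenset
    usage_shift_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.reversed_genes <= self.disease_genes:
            raise ValueError("reversed genes must be a subset of disease genes")


def _draw_gene_params(cfg: SimulationConfig, rng: np.random.Generator):
    mu = rng.lognormal(cfg.baseline_mean_log, cfg.baseline_sd_log, cfg.n_genes)
    phi = rng.lognormal(cfg.dispersion_meanlog, cfg.dispersion_sdlog, cfg.n_genes)
    return mu, phi


def _plant_effects(cfg: SimulationConfig, rng: np.random.Generator,
                   gene_ids: list[str], lfc_values: np.ndarray | None = None):
    n_disease = int(round(cfg.frac_disease * cfg.n_genes))
    idx = rng.choice(cfg.n_genes, size=n_disease, replace=False)
    idx.sort()
    disease_genes = [gene_ids[i] for i in idx]
    if lfc_values is None:
        lfc_values = rng.normal(0.0, cfg.disease_lfc_sd, n_disease)
    n_rev = int(round(cfg.reversal_frac * n_disease))
    rev_pick = rng.choice(n_disease, size=n_rev, replace=False) if n_disease else np.array([], int)
    reversed_genes = frozenset(disease_genes[i] for i in rev_pick)
    lfc = pd.Series(lfc_values, index=disease_genes, name="lfc")
    return idx, lfc, reversed_genes


def _sample_design(cfg: SimulationConfig, doses=DOSES) -> pd.DataFrame:
    rows = []
    for g in GENOTYPES:
        for d in doses:
            for r in range(cfg.n_per_group):
                rows.append((f"{g}_{d}_{r + 1}", g, d, cfg.tissue))
    meta = pd.DataFrame(rows, columns=["sample_id", "genotype", "dose", "tissue"])
    return meta.set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB with Var = mu + phi mu^2 (size r = 1/phi)."""
    r = 1.0 / np.maximum(phi, 1e-12)
    mean = np.maximum(mean, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, mean.shape), p)


def _expected_means(cfg: SimulationConfig, mu: np.ndarray, idx: np.ndarray,
                    lfc: pd.Series, reversed_genes: frozenset,
                    gene_ids: list[str], meta: pd.DataFrame) -> np.ndarray:
    """Per-gene, per-sample expected counts before library-size scaling."""
    lfc_full = np.zeros(cfg.n_genes)
    lfc_full[idx] = lfc.to_numpy()
    is_rev = np.zeros(cfg.n_genes, dtype=bool)
    rev_set = set(reversed_genes)
    for i in idx:
        if gene_ids[i] in rev_set:
            is_rev[i] = True

    means = np.empty((cfg.n_genes, len(meta)))
    for j, (_, row) in enumerate(meta.iterrows()):
        eff = np.zeros(cfg.n_genes)
        if row["genotype"] == "disease":
            eff = lfc_full.copy()
            kappa = cfg.kappa_by_dose.get(row["dose"], 0.0)
            if row["dose"] != "veh" and kappa > 0:
                eff[is_rev] = lfc_full[is_rev] * (1.0 - kappa)
        means[:, j] = mu * 2.0 ** eff
    return means


def _scale_to_libsizes(cfg: SimulationConfig, rng: np.random.Generator,
                       means: np.ndarray) -> np.ndarray:
    lib = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_sigma, means.shape[1])
    return means * (lib / means.sum(axis=0))[None, :]


def simulate_counts(config: SimulationConfig, noise_seed: int | None = None):
    """Simulate one count matrix with planted disease and reversal effects.

    Returns ``(CountMatrix, GroundTruth)``. Identical config (including
    seed) gives bit-identical output. When ``noise_seed`` is given, gene
    parameters and planted effects still come from ``config.seed`` but
    library sizes and count noise come from ``noise_seed`` — two calls with
    the same config and different noise seeds are independent cohorts
    measuring the same ground truth (e.g. a disease-signature cohort and a
    treatment cohort).
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    mu, phi = _draw_gene_params(config, rng)
    idx, lfc, reversed_genes = _plant_effects(config, rng, gene_ids)
    meta = _sample_design(config)
    means = _expected_means(config, mu, idx, lfc, reversed_genes, gene_ids, meta)
    noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
    means = _scale_to_libsizes(config, noise_rng, means)
    counts = _nb_draw(noise_rng, means, phi[:, None])
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=meta.index), meta)
    truth = GroundTruth(frozenset(lfc.index), lfc, reversed_genes)
    return cm, truth


def simulate_two_studies(config: SimulationConfig, shared_effect_corr: float,
                         n_per_group_b: int | None = None):
    """Two independent case/control cohorts measuring one disease effect.

    The two studies' planted disease log2FCs for each gene are a draw from
    a bivariate normal with the stated correlation; noise, dispersions and
    library sizes are independent. Only vehicle-arm samples are generated
    (case/control cohorts have no dosing). Returns
    ``((CountMatrix, CountMatrix), GroundTruth)`` where the truth carries
    study A's lfc vector.
    """
    if not 0.0 <= shared_effect_corr <= 1.0:
        raise ValueError("shared_effect_corr must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    idx, lfc_a, reversed_genes = _plant_effects(config, rng, gene_ids)
    sd = config.disease_lfc_sd
    if shared_effect_corr == 1.0:
        lfc_b_vals = lfc_a.to_numpy().copy()
    else:
        cov = sd ** 2 * np.array([[1.0, shared_effect_corr], [shared_effect_corr, 1.0]])
        # condition B on A to reuse A's draw
        a = lfc_a.to_numpy()
        cond_mean = shared_effect_corr * a
        cond_sd = sd * np.sqrt(1.0 - shared_effect_corr ** 2)
        lfc_b_vals = rng.normal(cond_mean, cond_sd)
        del cov
    lfc_b = pd.Series(lfc_b_vals, index=lfc_a.index)

    def one_study(lfc: pd.Series, study_id: str, n_per_group: int, seed_rng):
        cfg = replace(config, n_per_group=n_per_group)
        mu, phi = _draw_gene_params(cfg, seed_rng)
        meta = _sample_design(cfg, doses=("veh",))
        meta = meta.rename(index=lambda s: f"{study_id}_{s}")
        meta["study_id"] = study_id
        means = _expected_means(cfg, mu, idx, lfc, frozenset(), gene_ids, meta)
        means = _scale_to_libsizes(cfg, seed_rng, means)
        counts = _nb_draw(seed_rng, means, phi[:, None])
        return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=meta.index), meta)

    cm_a = one_study(lfc_a, "studyA", config.n_per_group, rng)
    cm_b = one_study(lfc_b, "studyB", n_per_group_b or config.n_per_group, rng)
    truth = GroundTruth(frozenset(lfc_a.index), lfc_a, frozenset())
    truth.disease_lfc_b = lfc_b  # second cohort's planted vector, for checks
    return (cm_a, cm_b), truth


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_feature_counts(config: SimulationConfig, features_per_gene: int = 4,
                            usage_shift_frac: float = 0.1,
                            usage_shift_delta: float = 1.0,
                            dirichlet_conc: float = 50.0):
    """Exon/junction-level counts with planted usage shifts.

    Per gene, the total count is distributed across ``features_per_gene``
    features by a Dirichlet-multinomial around gene-specific expected usage
    proportions. For usage-shift genes, one randomly chosen feature's
    expected proportion is moved by ``usage_shift_delta`` on the logit scale
    in the treated-disease condition; gene totals are unchanged in
    expectation. Two sample groups are produced: disease:veh (reference) and
    disease:high (treated).
    """
    if features_per_gene < 1:
        raise ValueError("features_per_gene must be positive")
    if not 0.0 <= usage_shift_frac <= 1.0:
        raise ValueError("usage_shift_frac must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    mu, phi = _draw_gene_params(config, rng)

    n_shift = int(round(usage_shift_frac * config.n_genes))
    if features_per_gene < 2 and n_shift > 0:
        warnings.warn("single-feature genes cannot carry a usage shift; none planted")
        n_shift = 0
    shift_idx = np.sort(rng.choice(config.n_genes, size=n_shift, replace=False))
    shift_genes = frozenset(gene_ids[i] for i in shift_idx)
    shifted_feature = {i: int(rng.integers(features_per_gene)) for i in shift_idx}

    rows = []
    for g in ("veh", "high"):
        for r in range(config.n_per_group):
            rows.append((f"disease_{g}_{r + 1}", "disease", g, config.tissue,
                         "treated" if g == "high" else "control"))
    meta = pd.DataFrame(rows, columns=["sample_id", "genotype", "dose", "tissue",
                                       "condition"]).set_index("sample_id")
    treated = (meta["condition"] == "treated").to_numpy()

    base_props = rng.dirichlet(np.full(features_per_gene, 2.0), size=config.n_genes)
    base_props = np.clip(base_props, 1e-4, None)
    base_props /= base_props.sum(axis=1, keepdims=True)

    # gene-level expression effect in the treated condition (no usage change):
    # exercises the usage test's specificity against pure expression shifts
    expr_idx, expr_lfc, _ = _plant_effects(config, rng, gene_ids)
    mu_mat = np.tile(mu[:, None], (1, len(meta)))
    mu_mat[np.ix_(expr_idx, np.flatnonzero(treated))] *= (
        2.0 ** expr_lfc.to_numpy()[:, None])

    lib = rng.lognormal(config.libsize_log_mean, config.libsize_sigma, len(meta))
    scale = lib / mu.sum()
    totals = _nb_draw(rng, mu_mat * scale[None, :], phi[:, None])

    counts = np.zeros((config.n_genes * features_per_gene, len(meta)), dtype=np.int64)
    index = pd.MultiIndex.from_tuples(
        [(g, f"{g}:f{k + 1}") for g in gene_ids for k in range(features_per_gene)],
        names=["gene_id", "feature_id"],
    )
    for i in range(config.n_genes):
        props_ctrl = base_props[i]
        if i in shifted_feature:
            k = shifted_feature[i]
            pj = props_ctrl[k]
            pj_new = _expit(_logit(pj) + usage_shift_delta)
            props_trt = props_ctrl * (1.0 - pj_new) / (1.0 - pj)
            props_trt[k] = pj_new
        else:
            props_trt = props_ctrl
        for j in range(len(meta)):
            p = props_trt if treated[j] else props_ctrl
            p_sample = rng.dirichlet(dirichlet_conc * p)
            counts[i * features_per_gene:(i + 1) * features_per_gene, j] = (
                rng.multinomial(totals[i, j], p_sample)
            )

    types = np.where(np.arange(len(index)) % 2 == 0, "exon", "junction")
    fct = FeatureCountTable(
        pd.DataFrame(counts, index=index, columns=meta.index),
        pd.Series(types, index=index, name="feature_type"),
        meta,
    )
    truth = GroundTruth(frozenset(expr_lfc.index), expr_lfc, frozenset(),
                        usage_shift_genes=shift_genes)
    truth.shifted_feature = {gene_ids[i]: f"{gene_ids[i]}:f{k + 1}"
                             for i, k in shifted_feature.items()}
    truth.usage_shift_delta = usage_shift_delta
    return fct, truth
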