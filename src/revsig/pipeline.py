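"""End-to-end orchestration: simulate -> normalize -> DE on the named
contrasts -> signatures -> reversal -> enrichment -> usage, from one config,
with a machine-readable JSON report (the synthetic analogue of a study's
summary tables: DEG counts per contrast, reversal verdicts, DUEJ counts).
"""
from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .containers import CountMatrix
from .de import NAMED_CONTRASTS, run_contrast
from .io import write_counts, write_gmt, write_signature
from .reversal import reversal_report
from .signatures import make_reversal_sets, select_degs
from .sim import SimulationConfig, simulate_counts, simulate_feature_counts
from .usage import duej_reversal, duej_test

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("revsig")


@dataclass
class PipelineConfig:
    """One config drives the whole pipeline; every threshold the analysis
    uses is surfaced here with its conventional default."""

    seed: int = 0
    tissues: tuple = ("striatum",)
    blood_tissue: str | None = None  # simulate an extra WT-only tissue for contrast E
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_mean: float = 10.0
    fc_min: float = 1.25
    adjp_max: float = 0.05
    duej_alpha: float = 0.05
    n_perm_cosine: int = 10000
    n_perm_sets: int = 1000
    features_per_gene: int = 4
    usage_shift_frac: float = 0.1
    usage_shift_delta: float = 1.0
    run_usage: bool = True
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        cfg = cls(**d)
        if sim:
            cfg.sim = SimulationConfig(**sim)
        if isinstance(cfg.tissues, list):
            cfg.tissues = tuple(cfg.tissues)
        return cfg


def _contrasts_for(tissue_is_blood: bool) -> list[str]:
    return ["E"] if tissue_is_blood else ["A", "B", "C", "D"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage per tissue and return the JSON-able report.

    When ``config.outdir`` is set, per-stage TSVs (counts, signatures, DEG
    GMTs) and ``report.json`` are written there.
    """
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    tissues = list(config.tissues)
    if config.blood_tissue:
        tissues.append(config.blood_tissue)
    children = ss.spawn(len(tissues) + 1)
    usage_seed = int(children[-1].generate_state(1)[0] % (2 ** 31))

    report: dict = {
        "seed": config.seed,
        "version": __version__,
        "params": {
            "min_mean": config.min_mean,
            "fc_min": config.fc_min,
            "adjp_max": config.adjp_max,
            "duej_alpha": config.duej_alpha,
            "n_perm_cosine": config.n_perm_cosine,
            "n_perm_sets": config.n_perm_sets,
            "sim": {k: (dict(v) if isinstance(v, dict) else v)
                    for k, v in asdict(config.sim).items()},
        },
        "contrasts": {},
        "reversal": {},
        "duej": {},
    }

    for tissue, child in zip(tissues, children[:-1]):
        is_blood = tissue == config.blood_tissue
        tissue_seed = int(child.generate_state(1)[0] % (2 ** 31))
        sim_cfg = replace(config.sim, tissue=tissue, seed=tissue_seed)
        log.info("stage=simulate tissue=%s seed=%d", tissue, tissue_seed)
        cm, truth = simulate_counts(sim_cfg)
        if outdir:
            write_counts(cm, str(outdir / f"counts_{tissue}.tsv"),
                         sample_sheet=str(outdir / f"samples_{tissue}.tsv"))

        de_results = {}
        report["contrasts"][tissue] = {}
        for name in _contrasts_for(is_blood):
            log.info("stage=de tissue=%s contrast=%s", tissue, name)
            de = run_contrast(cm, name, min_mean=config.min_mean)
            de_results[name] = de
            degs = select_degs(de, config.fc_min, config.adjp_max)
            n_sig = int((de.table["adj_p"] < config.adjp_max).sum())
            report["contrasts"][tissue][name] = {
                "n_genes": int(len(de.table)),
                "n_significant": n_sig,
                "n_deg_up": len(degs.up),
                "n_deg_down": len(degs.down),
            }
            if outdir:
                de.table.to_csv(outdir / f"de_{tissue}_{name}.tsv", sep="\t",
                                index_label="gene_id")

        if is_blood:
            continue

        disease_de = de_results["A"]
        disease_sig = disease_de.to_signature()
        disease_degs = select_degs(disease_de, config.fc_min, config.adjp_max)
        report["reversal"][tissue] = {}
        if disease_degs.up and disease_degs.down:
            sets = make_reversal_sets(disease_degs)
            if outdir:
                write_gmt(sets, str(outdir / f"reversal_sets_{tissue}.gmt"))
                write_signature(disease_sig, str(outdir / f"signature_{tissue}_A.tsv"))
            for name, dose in (("C", "low"), ("B", "high")):
                log.info("stage=reversal tissue=%s dose=%s", tissue, dose)
                treat_sig = de_results[name].to_signature()
                res = reversal_report(
                    disease_sig, treat_sig, sets,
                    n_perm_cosine=config.n_perm_cosine,
                    n_perm_sets=config.n_perm_sets,
                    seed=tissue_seed + 17, alpha=config.adjp_max,
                )
                report["reversal"][tissue][dose] = res.to_dict()
                if outdir:
                    write_signature(treat_sig,
                                    str(outdir / f"signature_{tissue}_{name}.tsv"))
        else:
            log.warning("tissue=%s: disease DEG list one-sided; reversal skipped", tissue)

        if config.run_usage:
            log.info("stage=usage tissue=%s", tissue)
            usage_cfg = replace(sim_cfg, seed=usage_seed)
            fct, usage_truth = simulate_feature_counts(
                usage_cfg, features_per_gene=config.features_per_gene,
                usage_shift_frac=config.usage_shift_frac,
                usage_shift_delta=config.usage_shift_delta,
            )
            duej = duej_test(fct, "condition", alpha=config.duej_alpha)
            sig_genes = duej.significant_genes(config.duej_alpha)
            planted = set(usage_truth.usage_shift_genes)
            report["duej"][tissue] = {
                "n_genes_tested": int(len(duej.gene_table)),
                "n_significant": len(sig_genes),
                "n_planted": len(planted),
                "n_recovered": len(planted & set(sig_genes)),
                "skipped": duej.skipped,
            }
            if outdir:
                duej.feature_table.to_csv(outdir / f"duej_{tissue}.tsv", sep="\t")

    report["wall_time_s"] = round(time.time() - t0, 3)
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(_strip_volatile(report), indent=2, sort_keys=True) + "\n")
    return report


def _strip_volatile(report: dict) -> dict:
    out = {k: v for k, v in report.items() if k != "wall_time_s"}
    return out


def setup_logging(verbose: bool = True, logfile: str | None = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(message)s",
        handlers=handlers,
        force=True,
    )
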