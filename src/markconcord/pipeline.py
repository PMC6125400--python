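"""End-to-end orchestration: simulate -> consensus -> differential ->
annotate -> concordance -> enrichment, as one reproducible, audited run.

The pipeline runs the full downstream analysis on a synthetic two-mark
experiment: an H3K4me3-like narrow landscape and an H3K27me3-like broad
landscape over one shared gene annotation, with a matched expression table.
Exclusive H3K4me3 gains in treatment are read as "increase" and gains in
control as "decrease" when building gene-level statuses, mirroring how a
treatment-only active-mark peak is reported.

Outputs under ``outdir``: the simulated inputs (per-replicate BED files,
genes.tsv, expression.tsv, truth tables), per-stage TSV tables, a
machine-readable ``summary.json`` and a ``run.log`` carrying the package
version, the effective configuration and its hash.  Identical config and
seed give byte-identical summaries.  A completed run directory is not
recomputed unless ``force`` is set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotation import (
    INTERGENIC,
    associate_peaks_to_genes,
    association_table,
    summarize_annotation,
)
from .concordance import (
    DECREASE,
    GAIN_IN_CONTROL,
    GAIN_IN_TREATMENT,
    INCREASE,
    assemble_gene_status,
    build_concordance_matrix,
    collapse_gene_status,
    find_concordant_genes,
    select_de_genes,
)
from .differential import (
    DifferentialPeak,
    call_exclusive_peaks,
    differential_table,
    summarize_directions,
)
from .enrichment import gene_set_enrichment
from .intervals import build_consensus, summarize_overlap_fractions, support_histogram
from .io_formats import write_expression_table, write_gene_models, write_peak_bed
from .synthetic import (
    SimConfig,
    TruthTable,
    simulate_annotation,
    simulate_expression,
    simulate_peak_experiment,
)

logger = logging.getLogger(__name__)

K4 = "H3K4me3"
K27 = "H3K27me3"

#: gene-status vocabulary for an exclusive call on the active mark
_K4_FROM_EXCLUSIVE = {GAIN_IN_TREATMENT: INCREASE, GAIN_IN_CONTROL: DECREASE}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one pipeline run.

    ``k4`` / ``k27`` are the per-mark simulation configs (seeds derived from
    the run seed when built through :meth:`from_dict`).  Analysis parameters
    mirror the module defaults: 1 bp minimum overlap, strictly-exclusive
    differential calls, p < 0.01 expression cut.
    """

    outdir: Path
    seed: int = 0
    k4: SimConfig = field(default_factory=SimConfig)
    k27: SimConfig = field(default_factory=SimConfig)
    min_bp: int = 1
    max_other: int = 0
    p_cut: float = 0.01
    fdr_cut: float = 0.1
    effect_size: float = 1.0
    null_sd: float = 0.2
    version: str = __version__

    _KEYS = {
        "outdir", "seed", "k4", "k27", "min_bp", "max_other",
        "p_cut", "fdr_cut", "effect_size", "null_sd", "version",
    }

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - cls._KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config requires 'outdir'")
        seed = int(raw.get("seed", 0))
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}

        def sim(section: str, defaults: dict) -> SimConfig:
            sub = dict(raw.get(section, {}))
            bad = set(sub) - sim_fields
            if bad:
                raise ValueError(f"unknown {section} key(s): {sorted(bad)}")
            for k in ("peak_width_range", "gene_length_range"):
                if k in sub:
                    sub[k] = tuple(sub[k])
            if "partial_support_spec" in sub:
                sub["partial_support_spec"] = tuple(
                    tuple(x) for x in sub["partial_support_spec"]
                )
            return SimConfig(**{**defaults, **sub})

        # the two marks get distinct derived seeds so their landscapes differ
        # 160 genes so each mark's half of the annotation links all 35
        # planted exclusive regions and still leaves null genes
        k4 = sim(
            "k4",
            dict(mark=K4, seed=2 * seed, peak_width_range=(200, 800), n_genes=160),
        )
        k27 = sim(
            "k27",
            dict(mark=K27, seed=2 * seed + 1, peak_width_range=(1000, 3000),
                 n_shared_peaks=300, n_genes=160),
        )
        kwargs = {
            k: raw[k]
            for k in ("min_bp", "max_other", "p_cut", "fdr_cut", "effect_size", "null_sd")
            if k in raw
        }
        return cls(outdir=Path(raw["outdir"]), seed=seed, k4=k4, k27=k27, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_landscape(outdir: Path, landscape: dict, mark: str) -> None:
    for cond, reps in landscape.items():
        for rep_id, peaks in reps.items():
            write_peak_bed(peaks, outdir / f"{mark}_{rep_id}.bed")


def _mark_stage(
    cfg: RunConfig, mark: str, sim_cfg: SimConfig, genes, outdir: Path
) -> tuple[dict, TruthTable, list[DifferentialPeak], dict]:
    """Simulate one mark's landscape and run consensus + exclusive calling."""
    landscape, truth = simulate_peak_experiment(sim_cfg, genes)
    _write_landscape(outdir, landscape, mark)
    truth.to_tsv(outdir / f"truth_{mark}.tsv")

    summary: dict[str, Any] = {}
    diffs: list[DifferentialPeak] = []
    cond_a, cond_b = sim_cfg.condition_a, sim_cfg.condition_b
    consensus = {}
    for cond in (cond_a, cond_b):
        consensus[cond] = build_consensus(landscape[cond], cond, min_bp=cfg.min_bp)
    for own, other, direction in (
        (cond_b, cond_a, GAIN_IN_TREATMENT),
        (cond_a, cond_b, GAIN_IN_CONTROL),
    ):
        hist = support_histogram(consensus[own], landscape[other], min_bp=cfg.min_bp)
        summary[f"consensus_{own}"] = {
            "total": hist.total,
            "support_counts": hist.counts,
            "support_percent": summarize_overlap_fractions(hist),
        }
        diffs.extend(
            call_exclusive_peaks(
                consensus[own], landscape[other], direction=direction,
                mark=mark, max_other=cfg.max_other, min_bp=cfg.min_bp,
            )
        )
    n_inc, n_dec, pct_dec = summarize_directions(diffs)
    summary["exclusive"] = {
        "gain_in_treatment": n_inc,
        "gain_in_control": n_dec,
        "total": n_inc + n_dec,
        "pct_gain_in_control": pct_dec,
    }
    differential_table(diffs).to_csv(outdir / f"diff_{mark}.tsv", sep="\t", index=False)
    return landscape, truth, diffs, summary


def _gene_status_from_diffs(
    diffs: list[DifferentialPeak], genes, translate: Mapping[str, str] | None = None
) -> tuple[dict[str, str], list[str], list]:
    """Annotate differential peaks and collapse to gene -> direction."""
    assocs = associate_peaks_to_genes([d.interval for d in diffs], genes)
    by_interval = {d.interval: d for d in diffs}
    genic = [a for a in assocs if a.region_class != INTERGENIC]
    for a in genic:
        by_interval[a.interval].gene_associated = True
    for d in diffs:
        if d.gene_associated is None:
            d.gene_associated = False
    peaks_by_gene: dict[str, list[DifferentialPeak]] = {}
    for a in genic:
        peaks_by_gene.setdefault(a.gene_id, []).append(by_interval[a.interval])
    status, conflicts = collapse_gene_status(peaks_by_gene)
    if translate:
        status = {g: translate[s] for g, s in status.items()}
    return status, conflicts, assocs


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages; return (and write) the machine-readable summary."""
    outdir = Path(config.outdir)
    summary_path = outdir / "summary.json"
    if summary_path.exists() and not force:
        logger.info("run directory %s already complete; skipping (use force)", outdir)
        return json.loads(summary_path.read_text())
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict[str, Any] = {
        "version": config.version,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
    }
    stage = "simulate_annotation"
    try:
        genes = simulate_annotation(replace(config.k4, seed=config.seed))
        write_gene_models(genes, outdir / "genes.tsv")
        # each mark links its own half of the annotation so no gene carries
        # two planted regions when the truths are combined for expression
        genes_k4, genes_k27 = genes[0::2], genes[1::2]

        stage = "H3K4me3_peaks"
        land4, truth4, diffs4, sum4 = _mark_stage(
            config, K4, config.k4, genes_k4, outdir
        )
        summary[K4] = sum4

        stage = "H3K27me3_peaks"
        land27, truth27, diffs27, sum27 = _mark_stage(
            config, K27, config.k27, genes_k27, outdir
        )
        summary[K27] = sum27

        stage = "expression"
        import pandas as pd

        combined_truth = TruthTable(
            pd.concat([truth4.regions, truth27.regions], ignore_index=True)
        )
        expr = simulate_expression(
            replace(config.k4, seed=config.seed),
            combined_truth,
            genes,
            effect_size=config.effect_size,
            null_sd=config.null_sd,
        )
        write_expression_table(expr, outdir / "expression.tsv")

        stage = "annotation"
        k4_status, k4_conf, assoc4 = _gene_status_from_diffs(
            diffs4, genes, translate=_K4_FROM_EXCLUSIVE
        )
        k27_status, k27_conf, assoc27 = _gene_status_from_diffs(diffs27, genes)
        association_table(assoc4).to_csv(outdir / f"annot_{K4}.tsv", sep="\t", index=False)
        association_table(assoc27).to_csv(outdir / f"annot_{K27}.tsv", sep="\t", index=False)
        summary["annotation"] = {
            K4: summarize_annotation(assoc4),
            K27: summarize_annotation(assoc27),
        }

        stage = "concordance"
        de = select_de_genes(expr, p_cut=config.p_cut)
        matrix = build_concordance_matrix(
            k4_status, k27_status, de, conflicts=[*k4_conf, *k27_conf]
        )
        statuses = assemble_gene_status(k4_status, k27_status, de)
        concordant = find_concordant_genes(statuses)
        matrix.k4_by_k27.to_csv(outdir / "matrix_k4_by_k27.tsv", sep="\t")
        matrix.k4_by_expr.to_csv(outdir / "matrix_k4_by_expr.tsv", sep="\t")
        matrix.k27_by_expr.to_csv(outdir / "matrix_k27_by_expr.tsv", sep="\t")
        concordant.to_csv(outdir / "concordant_genes.tsv", sep="\t", index=False)
        (outdir / "conflicts.tsv").write_text(
            "".join(f"{g}\n" for g in matrix.conflicts)
        )
        summary["concordance"] = {
            "n_de_genes": len(de),
            "k4_by_k27": matrix.k4_by_k27.to_dict(),
            "dual_mark_genes": matrix.dual_mark_genes,
            "n_conflicts": len(matrix.conflicts),
            "n_testable": int(len(concordant)),
            "n_concordant": int(concordant["concordant"].sum()) if len(concordant) else 0,
        }

        stage = "enrichment"
        universe = [g.gene_id for g in genes]
        prior_sets = {
            "planted_k4_genes": set(truth4.linked["gene_id"]),
            "planted_k27_genes": set(truth27.linked["gene_id"]),
        }
        query = sorted(set(k4_status) | set(k27_status))
        enrich = gene_set_enrichment(query, prior_sets, universe, correction="BH")
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = enrich.to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text(
        f"markconcord {config.version}\nconfig_hash {config.config_hash}\n"
        f"stages completed: simulate, consensus, diffpeaks, annotate, concord, enrich\n"
    )
    return summary
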