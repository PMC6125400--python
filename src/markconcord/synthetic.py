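"""Synthetic replicate peak landscapes and expression tables with planted truth.

The generator emulates the structure of a two-condition (control vs ethanol)
replicated ChIP-seq experiment as seen by the downstream pipeline:

* *shared* peaks present in both conditions, each replicate carrying the peak
  independently with probability ``1 - drop_prob`` and with per-replicate
  positional jitter on both ends;
* *condition-exclusive* peaks present in every replicate of one condition and
  in no replicate of the other — the planted ground truth for the stringent
  differential criterion;
* *partially supported* peaks present in all replicates of one condition and
  exactly ``k`` of the other, populating the middle of the replicate-support
  spectrum.

Planted regions are mutually separated by a buffer of twice the maximum peak
width, and jitter is clipped at 4 standard deviations, so an exclusive region
can never drift into overlap with an other-condition peak: the planted truth
stays exact under noise.  Exclusive regions are linked to genes by placing
them inside the gene's proximal-promoter window (more than 100 bp from the
TSS base, so they classify as promoter, not TSS), which makes annotation
recovery testable.  The matched expression table couples direction to the
planted mark changes: an H3K4me3 gain in treatment pushes expression up, an
H3K27me3 gain in treatment pushes it down, and unlinked genes are null with
exactly uniform p-values.

All randomness flows from ``numpy.random.default_rng([seed, stage])`` with a
fixed stage key per generator (0 genes, 1 peaks, 2 expression, 3 counts), so
each stage is reproducible on its own.
"""

from __future__ import annotations

import math
from bisect import bisect_right, insort
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PROMOTER_UPSTREAM, TSS_WINDOW
from .io_formats import ExpressionRecord, GeneModel, Peak

_STAGE_GENES, _STAGE_PEAKS, _STAGE_EXPR, _STAGE_COUNTS = 0, 1, 2, 3

SHARED = "shared"
EXCLUSIVE_A = "exclusive_A"
EXCLUSIVE_B = "exclusive_B"


class SizingError(ValueError):
    """The requested structures do not fit in the configured genome."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults mirror a 4+4-replicate two-mark design at desk scale: a large
    body of shared peaks with high inter-condition overlap, a few dozen
    planted condition-exclusive peaks, a partial-support spectrum, 20 bp
    end jitter and a 10% per-replicate miss rate for shared peaks.
    """

    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 60
    n_replicates_per_condition: int = 4
    n_shared_peaks: int = 1000
    n_exclusive_a: int = 25
    n_exclusive_b: int = 10
    partial_support_spec: tuple[tuple[int, int], ...] = ((30, 3), (20, 2), (10, 1))
    peak_width_range: tuple[int, int] = (200, 800)
    jitter_sd: float = 20.0
    drop_prob: float = 0.1
    gene_length_range: tuple[int, int] = (2000, 10_000)
    condition_a: str = "control"
    condition_b: str = "ethanol"
    mark: str = "H3K27me3"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.chrom_length, self.n_genes,
            self.n_shared_peaks, self.n_exclusive_a, self.n_exclusive_b,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need >= 1 replicate per condition")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.drop_prob < 1.0:
            raise ValueError("drop_prob must lie in [0, 1)")
        for lo, hi in (self.peak_width_range, self.gene_length_range):
            if not 1 <= lo <= hi:
                raise ValueError("width/length ranges need 1 <= min <= max")
        for n_peaks, k in self.partial_support_spec:
            if n_peaks < 0 or not 0 <= k <= self.n_replicates_per_condition:
                raise ValueError(
                    "partial_support_spec entries need n_peaks >= 0 and "
                    "0 <= k <= n_replicates_per_condition"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def replicates_a(self) -> list[str]:
        return [f"{self.condition_a}_{i + 1}" for i in range(self.n_replicates_per_condition)]

    @property
    def replicates_b(self) -> list[str]:
        return [f"{self.condition_b}_{i + 1}" for i in range(self.n_replicates_per_condition)]


@dataclass
class TruthTable:
    """Planted ground truth: one row per region.

    Columns: region_id, chrom, start, end, klass (shared / exclusive_A /
    exclusive_B / partial_<k>), owner (condition holding all replicates; ''
    for shared), k_other, gene_id ('' if unlinked), mark,
    expr_direction (up / down / null).
    """

    regions: pd.DataFrame

    COLUMNS = (
        "region_id", "chrom", "start", "end", "klass", "owner",
        "k_other", "gene_id", "mark", "expr_direction",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.regions.columns)
        if missing:
            raise ValueError(f"truth table missing column(s) {sorted(missing)}")

    def of_class(self, klass: str) -> pd.DataFrame:
        return self.regions[self.regions["klass"] == klass]

    @property
    def exclusive_a(self) -> pd.DataFrame:
        return self.of_class(EXCLUSIVE_A)

    @property
    def exclusive_b(self) -> pd.DataFrame:
        return self.of_class(EXCLUSIVE_B)

    @property
    def linked(self) -> pd.DataFrame:
        return self.regions[self.regions["gene_id"] != ""]

    def to_tsv(self, path: str | Path) -> None:
        self.regions.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"gene_id": str})
        return cls(df)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_MARGIN = 20_000      # bp kept free at each chromosome end
_MIN_GENE_GAP = 12_000  # bp between consecutive gene bodies
_MAX_GENE_GAP = 20_000


def simulate_annotation(config: SimConfig) -> list[GeneModel]:
    """Non-overlapping genes with random strand and randomized lengths and
    intergenic gaps, distributed round-robin across chromosomes."""
    if config.n_genes == 0:
        return []
    rng = _rng(config.seed, _STAGE_GENES)
    worst_per_gene = config.gene_length_range[1] + _MAX_GENE_GAP
    per_chrom = -(-config.n_genes // config.n_chroms) if config.n_chroms else 0
    usable_per_chrom = config.chrom_length - 2 * _MARGIN
    if config.n_chroms == 0 or per_chrom * worst_per_gene > usable_per_chrom:
        required = per_chrom * worst_per_gene + 2 * _MARGIN
        raise SizingError(
            f"{config.n_genes} genes over {config.n_chroms} chromosome(s) need "
            f"chrom_length >= {required:,} bp, got {config.chrom_length:,}; "
            "enlarge chrom_length or n_chroms"
        )
    genes: list[GeneModel] = []
    pos = {c: _MARGIN for c in config.chrom_names}
    for i in range(config.n_genes):
        chrom = config.chrom_names[i % config.n_chroms]
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        gap = int(rng.integers(_MIN_GENE_GAP, _MAX_GENE_GAP + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos[chrom]
        genes.append(GeneModel(f"G{i + 1:04d}", chrom, start, start + length, strand))
        pos[chrom] = start + length + gap
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# peak landscape
# ---------------------------------------------------------------------------

class _Placer:
    """Random placement of buffered, mutually disjoint intervals."""

    def __init__(self, config: SimConfig, rng: np.random.Generator, buffer: int):
        self.config = config
        self.rng = rng
        self.buffer = buffer
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in config.chrom_names
        }

    def reserve(self, chrom: str, start: int, end: int) -> None:
        insort(self.occupied[chrom], (start, end))

    def _free(self, chrom: str, start: int, end: int) -> bool:
        occ = self.occupied[chrom]
        i = bisect_right(occ, (start, -1))
        if i > 0 and occ[i - 1][1] > start - self.buffer:
            return False
        if i < len(occ) and occ[i][0] < end + self.buffer:
            return False
        return True

    def place(self, width: int, retries: int = 2000) -> tuple[str, int, int]:
        cfg = self.config
        lo, hi = _MARGIN, cfg.chrom_length - _MARGIN - width
        if hi <= lo:
            raise SizingError("chromosomes too short for the requested peak width")
        for _ in range(retries):
            chrom = cfg.chrom_names[int(self.rng.integers(cfg.n_chroms))]
            start = int(self.rng.integers(lo, hi))
            if self._free(chrom, start, start + width):
                self.reserve(chrom, start, start + width)
                return chrom, start, start + width
        raise SizingError(
            "could not place a region after bounded retries; "
            "enlarge chrom_length or n_chroms, or plant fewer regions"
        )


def _jitter_interval(
    start: int, end: int, sd: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Independent Normal(0, sd) jitter on both ends, clipped at +-4 sd,
    clamped to width >= 1."""
    if sd == 0:
        return start, end
    clip = 4.0 * sd
    ds = int(round(float(np.clip(rng.normal(0.0, sd), -clip, clip))))
    de = int(round(float(np.clip(rng.normal(0.0, sd), -clip, clip))))
    s, e = start + ds, end + de
    if e <= s:
        e = s + 1
    return s, e


def simulate_peak_experiment(
    config: SimConfig, genes: Sequence[GeneModel]
) -> tuple[dict[str, dict[str, list[Peak]]], TruthTable]:
    """Generate per-replicate peak calls for both conditions plus the truth.

    Returns ``({condition: {replicate_id: [Peak, ...]}}, TruthTable)``.
    Exclusive regions are linked round-robin to genes (one region per gene,
    placed in the gene's promoter window); shared and partial regions are
    placed in free intergenic space.  See the module docstring for the noise
    model and the separation guarantees.
    """
    rng = _rng(config.seed, _STAGE_PEAKS)
    w_lo, w_hi = config.peak_width_range
    buffer = 2 * w_hi
    n_partial = sum(n for n, _ in config.partial_support_spec)
    n_regions = config.n_shared_peaks + config.n_exclusive_a + config.n_exclusive_b + n_partial
    footprint = n_regions * (w_hi + 2 * buffer) + len(genes) * (
        config.gene_length_range[1] + PROMOTER_UPSTREAM + 2 * buffer
    )
    capacity = config.n_chroms * (config.chrom_length - 2 * _MARGIN)
    if footprint > 0.7 * capacity:
        raise SizingError(
            f"~{footprint:,} bp of buffered regions requested but only "
            f"{capacity:,} usable bp available; enlarge the genome"
        )

    placer = _Placer(config, rng, buffer)
    for g in genes:
        ps = min(g.start, g.promoter_window()[0], g.tss - TSS_WINDOW)
        pe = max(g.end, g.promoter_window()[1], g.tss + TSS_WINDOW + 1)
        placer.reserve(g.chrom, ps, pe)

    def promoter_placement(gene: GeneModel, width: int) -> tuple[str, int, int]:
        # inside the promoter window, > 100 bp from the TSS base, so a
        # noise-free annotation run classifies the region as `promoter`
        w = min(width, 1200)
        t = gene.tss
        if gene.strand == "+":
            return gene.chrom, t - 1500, t - 1500 + w
        return gene.chrom, t + 1501 - w, t + 1501

    rows: list[dict] = []
    gene_cycle = iter(genes)

    def plant(klass: str, owner: str, k_other: int, link: bool) -> None:
        width = int(rng.integers(w_lo, w_hi + 1))
        gene = next(gene_cycle, None) if link else None
        if gene is not None:
            chrom, start, end = promoter_placement(gene, width)
        else:
            chrom, start, end = placer.place(width)
        if config.mark == "H3K4me3":
            up_owner = config.condition_b  # treatment-only active mark -> up
        else:
            up_owner = config.condition_a  # treatment-only repressive mark -> down
        expr = "null"
        if gene is not None and klass in (EXCLUSIVE_A, EXCLUSIVE_B):
            expr = "up" if owner == up_owner else "down"
        rows.append(
            {
                "region_id": f"{config.mark}_{klass}_{len(rows) + 1:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "klass": klass,
                "owner": owner,
                "k_other": k_other,
                "gene_id": gene.gene_id if gene is not None else "",
                "mark": config.mark,
                "expr_direction": expr,
            }
        )

    for _ in range(config.n_exclusive_a):
        plant(EXCLUSIVE_A, config.condition_a, 0, link=True)
    for _ in range(config.n_exclusive_b):
        plant(EXCLUSIVE_B, config.condition_b, 0, link=True)
    for n_peaks, k in config.partial_support_spec:
        for j in range(n_peaks):
            owner = config.condition_a if j % 2 == 0 else config.condition_b
            plant(f"partial_{k}", owner, k, link=False)
    for _ in range(config.n_shared_peaks):
        plant(SHARED, "", config.n_replicates_per_condition, link=False)

    truth = TruthTable(pd.DataFrame(rows, columns=list(TruthTable.COLUMNS)))

    reps = {
        config.condition_a: config.replicates_a,
        config.condition_b: config.replicates_b,
    }
    landscape: dict[str, dict[str, list[Peak]]] = {
        cond: {r: [] for r in rep_ids} for cond, rep_ids in reps.items()
    }

    for row in rows:
        klass, owner = row["klass"], row["owner"]
        for cond, rep_ids in reps.items():
            if klass == SHARED:
                present = [rng.random() >= config.drop_prob for _ in rep_ids]
            elif klass in (EXCLUSIVE_A, EXCLUSIVE_B):
                present = [cond == owner] * len(rep_ids)
            else:  # partial_<k>
                if cond == owner:
                    present = [True] * len(rep_ids)
                else:
                    chosen = set(
                        rng.choice(len(rep_ids), size=row["k_other"], replace=False).tolist()
                    )
                    present = [i in chosen for i in range(len(rep_ids))]
            for rep_id, here in zip(rep_ids, present):
                if not here:
                    continue
                s, e = _jitter_interval(row["start"], row["end"], config.jitter_sd, rng)
                landscape[cond][rep_id].append(
                    Peak(row["chrom"], s, e, name=row["region_id"],
                         replicate_id=rep_id, condition=cond)
                )

    for cond in landscape:
        for rep_id in landscape[cond]:
            landscape[cond][rep_id].sort(key=lambda p: (p.chrom, p.start, p.end))
    return landscape, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimConfig,
    truth: TruthTable,
    genes: Sequence[GeneModel],
    effect_size: float = 1.0,
    null_sd: float = 0.2,
) -> list[ExpressionRecord]:
    """Expression table whose differential genes are the truth-linked ones.

    Per gene, ``n = n_replicates_per_condition`` control and treatment sample
    values are drawn Normal with a mean shift of +-``effect_size`` for genes
    linked to planted mark changes (sign per the truth's ``expr_direction``)
    and 0 otherwise.  The per-sample SD is ``null_sd * sqrt(n/2)`` so the
    reported log fold-change is distributed Normal(shift, null_sd); p-values
    come from a two-sided two-sample t-test, hence exactly uniform for null
    genes.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = _rng(config.seed, _STAGE_EXPR)
    known = {g.gene_id for g in genes}
    linked = truth.linked
    unknown = sorted(set(linked["gene_id"]) - known)
    if unknown:
        raise ValueError(f"truth table references unknown gene_id(s): {unknown}")
    dupes = linked["gene_id"][linked["gene_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"multiple planted regions link the same gene(s): {dupes}")
    shift_by_gene = {
        r.gene_id: (effect_size if r.expr_direction == "up"
                    else -effect_size if r.expr_direction == "down" else 0.0)
        for r in linked.itertuples(index=False)
    }
    n = config.n_replicates_per_condition
    sample_sd = null_sd * math.sqrt(n / 2.0)
    gene_ids = [g.gene_id for g in genes]
    shifts = np.array([shift_by_gene.get(g, 0.0) for g in gene_ids])
    ctrl = rng.normal(0.0, sample_sd, size=(len(gene_ids), n))
    trt = rng.normal(0.0, sample_sd, size=(len(gene_ids), n)) + shifts[:, None]
    log_fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    pvals = stats.ttest_ind(trt, ctrl, axis=1).pvalue
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
    return [
        ExpressionRecord(g, float(f), float(p))
        for g, f, p in zip(gene_ids, log_fc, pvals)
    ]


# ---------------------------------------------------------------------------
# count matrix (for the count-based differential test)
# ---------------------------------------------------------------------------

def simulate_count_matrix(
    n_regions: int,
    n_planted: int = 0,
    fold_change: float = 1.0,
    n_per_condition: int = 4,
    seed: int = 0,
    treatment: str = "ethanol",
    control: str = "control",
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Poisson region x sample count matrix with optional planted fold changes.

    Per-region baseline rates are Uniform(100, 1000); the first ``n_planted``
    regions have their treatment-sample rates multiplied by ``fold_change``.
    Returns (counts, design map, planted region ids).  Region ids are
    synthetic ``chrS:start-end`` coordinates so downstream calls carry
    intervals.
    """
    if n_planted > n_regions:
        raise ValueError("n_planted cannot exceed n_regions")
    rng = _rng(seed, _STAGE_COUNTS)
    samples = [f"{control}_{i + 1}" for i in range(n_per_condition)] + [
        f"{treatment}_{i + 1}" for i in range(n_per_condition)
    ]
    design = {s: (control if s.startswith(control) else treatment) for s in samples}
    lam = rng.uniform(100.0, 1000.0, size=n_regions)
    lam_mat = np.tile(lam[:, None], (1, 2 * n_per_condition))
    lam_mat[:n_planted, n_per_condition:] *= fold_change
    counts = rng.poisson(lam_mat)
    ids = [f"chrS:{i * 2000}-{i * 2000 + 1000}" for i in range(n_regions)]
    df = pd.DataFrame(counts, index=ids, columns=samples)
    planted = ids[:n_planted]
    return df, design, planted
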