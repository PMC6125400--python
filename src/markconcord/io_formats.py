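"""Readers and writers for the external file formats of the pipeline.

All genomic coordinates are 0-based half-open (the BED convention) everywhere
inside the package; human-readable reports that print 1-based inclusive
coordinates say so in a header note.  Formats handled here:

* peak calls         -- BED3/BED5, one file per replicate
* gene models        -- TSV with columns gene_id, chrom, start, end, strand
* expression table   -- TSV with columns gene_id, log_fc, p_value
* gene lists         -- plain text, one gene symbol per line
* count matrices     -- TSV, regions x samples, first column region id
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

_BED_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """A malformed line in a BED peak file, reported with its line number."""


@dataclass(frozen=True, order=True)
class Peak:
    """One called peak interval from one replicate (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = field(default=None, compare=False)
    replicate_id: str = field(default="", compare=False)
    condition: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Peak.chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"Peak requires start < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"Peak.score must be non-negative, got {self.score}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """One gene interval with strand; defines the TSS and promoter windows.

    The TSS of a + strand gene is its start base; for a - strand gene it is
    the last base of the half-open interval, i.e. ``end - 1``.  All distance
    computations anchor on that base.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("GeneModel.gene_id must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"GeneModel {self.gene_id}: start < end required, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"GeneModel {self.gene_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        """Coordinate of the TSS base (start for +, end-1 for -)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter_window(self, upstream: int = 2000, downstream: int = 200) -> tuple[int, int]:
        """Strand-aware proximal-promoter interval, half-open genomic coords.

        Covers ``upstream`` bp 5' of the TSS through ``downstream`` bp into the
        gene.  For a - strand gene "upstream" extends rightward on the genome.
        """
        if self.strand == "+":
            return (self.start - upstream, self.start + downstream)
        return (self.end - downstream, self.end + upstream)


@dataclass(frozen=True)
class ExpressionRecord:
    """Differential-expression summary for one gene: signed log fold-change
    (treatment vs control) and an unadjusted p-value."""

    gene_id: str
    log_fc: float
    p_value: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.log_fc):
            raise ValueError(f"{self.gene_id}: log_fc must be finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"{self.gene_id}: p_value must lie in (0, 1], got {self.p_value}"
            )


# ---------------------------------------------------------------------------
# peaks (BED)
# ---------------------------------------------------------------------------

def read_peak_bed(
    path: str | Path, replicate_id: str = "", condition: str = ""
) -> list[Peak]:
    """Read a BED3/BED5 peak file into peaks sorted by (chrom, start, end).

    Track, browser and ``#`` comment lines and blank lines are skipped.
    Malformed data lines (fewer than 3 fields, non-integer coordinates,
    start >= end) raise :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate in {fields[1:3]}"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start must be < end, got {start} >= {end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            try:
                peaks.append(
                    Peak(chrom, start, end, name, score, replicate_id, condition)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    if not peaks:
        logger.warning("BED file %s contained no peaks", path)
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_peak_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED (BED5 when any score is set, else BED3/BED4)."""
    peaks = list(peaks)
    with_score = any(p.score is not None for p in peaks)
    with_name = with_score or any(p.name for p in peaks)
    with Path(path).open("w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end)]
            if with_name:
                cols.append(p.name or ".")
            if with_score:
                cols.append("0" if p.score is None else format(p.score, "g"))
            fh.write("\t".join(cols) + "\n")


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Force a chromosome name to 'chr'-prefixed (style='chr') or bare (style='bare')."""
    bare = name[3:] if name.startswith("chr") else name
    return f"chr{bare}" if style == "chr" else bare


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, start, end, strand).

    gene_ids must be unique; duplicates raise with the offending ids listed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene_id(s): {dupes}")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read the expression TSV (gene_id, log_fc, p_value); rows with missing
    values are rejected, p-values validated to (0, 1]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log_fc", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df[list(required)].isna().any().any():
        bad = df.index[df[list(required)].isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing values in row(s) {bad}")
    return [
        ExpressionRecord(r.gene_id, float(r.log_fc), float(r.p_value))
        for r in df.itertuples(index=False)
    ]


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.log_fc, r.p_value) for r in records],
        columns=["gene_id", "log_fc", "p_value"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lists and count matrices
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and '#' lines skipped."""
    out: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Region x sample count matrix; first column is the region id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_design(path: str | Path) -> dict[str, str]:
    """Sample -> condition design table (TSV columns: sample, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: design needs columns sample, condition")
    return dict(zip(df["sample"], df["condition"]))
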