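"""Independent brute-force oracles used only by the tests.

Everything here works per base (explicit coordinate sets) or per pair
(exhaustive scans), sharing no code path with the package's interval
algebra, so agreement is meaningful evidence of correctness.
"""

from __future__ import annotations

from itertools import combinations

from markconcord.io_formats import GeneModel, Peak

Interval = tuple[str, int, int]


def _bases(iv: Interval) -> set[tuple[str, int]]:
    chrom, start, end = iv
    return {(chrom, b) for b in range(start, end)}


def bitmap_overlaps(a: Interval, b: Interval, min_bp: int = 1) -> bool:
    return len(_bases(a) & _bases(b)) >= min_bp


def bitmap_merge(intervals: list[Interval]) -> list[Interval]:
    """Reconstruct maximal runs from the union-of-bases bitmap."""
    covered = set()
    for iv in intervals:
        covered |= _bases(iv)
    out: list[Interval] = []
    for chrom in sorted({c for c, _ in covered}):
        bases = sorted(b for c, b in covered if c == chrom)
        run_start = prev = bases[0]
        for b in bases[1:]:
            if b != prev + 1:
                out.append((chrom, run_start, prev + 1))
                run_start = b
            prev = b
        out.append((chrom, run_start, prev + 1))
    return out


def overlap_components(intervals: list[Interval]) -> list[Interval]:
    """Candidate regions as connected components of the >=1-bp-overlap graph
    (abutting intervals share no base, so they stay in separate components)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if bitmap_overlaps(intervals[i], intervals[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[Interval]] = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(find(i), []).append(iv)
    return sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
        for g in groups.values()
    )


def brute_consensus(
    replicates: dict[str, list[Peak]], min_bp: int = 1
) -> list[Interval]:
    """Pooled overlap-graph candidates kept iff every replicate overlaps them."""
    pooled = [p.interval for peaks in replicates.values() for p in peaks]
    if not pooled:
        return []
    out = []
    for cand in overlap_components(pooled):
        if all(
            any(bitmap_overlaps(cand, p.interval, min_bp) for p in peaks)
            for peaks in replicates.values()
        ):
            out.append(cand)
    return out


def brute_support(
    regions: list[Interval], replicates_other: dict[str, list[Peak]], min_bp: int = 1
) -> list[int]:
    return [
        sum(
            1
            for peaks in replicates_other.values()
            if any(bitmap_overlaps(r, p.interval, min_bp) for p in peaks)
        )
        for r in regions
    ]


def brute_classify(peak: Interval, gene: GeneModel, tss_window: int = 100,
                   upstream: int = 2000, downstream: int = 200) -> str:
    """Per-base reimplementation of the region-class precedence."""
    chrom, start, end = peak
    assert chrom == gene.chrom
    tss = gene.start if gene.strand == "+" else gene.end - 1
    peak_bases = set(range(start, end))
    if min(abs(b - tss) for b in peak_bases) <= tss_window:
        return "tss"
    if gene.strand == "+":
        prom = set(range(gene.start - upstream, gene.start + downstream))
    else:
        prom = set(range(gene.end - downstream, gene.end + upstream))
    if peak_bases & prom:
        return "promoter"
    if peak_bases & set(range(gene.start, gene.end)):
        return "gene_body"
    return "intergenic"


def enum_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(|draw ∩ prior| >= k) by enumerating all C(N, n) draws (N <= 12)."""
    assert N <= 12, "enumeration oracle only for tiny N"
    universe = list(range(N))
    prior = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(prior & set(draw)) >= k:
            hits += 1
    return hits / total
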