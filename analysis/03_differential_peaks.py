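#!/usr/bin/env python
"""Call differential peaks two ways and score them against the planted truth.

Route 1 (broad-mark rule): a region is differential only if present in all
four replicates of one condition and overlapped by zero replicates of the
other.  Route 2 (narrow-mark stand-in): per-region t-test on log2 CPM of a
simulated count matrix with Benjamini-Hochberg control.  Writes
results/diff_<mark>.tsv and results/diff_counts.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import (
    CONTROL, FDR_CUT, K4, K27, RESULTS, SEED, SIM_DIR, TREATMENT,
    load_landscape, require,
)

from markconcord.differential import (
    GAIN_IN_CONTROL,
    GAIN_IN_TREATMENT,
    call_exclusive_peaks,
    differential_table,
    score_differential_binding,
    summarize_directions,
)
from markconcord.intervals import build_consensus, overlaps
from markconcord.synthetic import TruthTable, simulate_count_matrix


def exclusive_route(mark: str) -> None:
    landscape = load_landscape(mark)
    truth = TruthTable.from_tsv(SIM_DIR / f"truth_{mark}.tsv")
    diffs = []
    for own, other, direction in (
        (TREATMENT, CONTROL, GAIN_IN_TREATMENT),
        (CONTROL, TREATMENT, GAIN_IN_CONTROL),
    ):
        cons = build_consensus(landscape[own], own)
        diffs.extend(
            call_exclusive_peaks(cons, landscape[other], direction=direction, mark=mark)
        )
    n_t, n_c, pct = summarize_directions(diffs)
    differential_table(diffs).to_csv(RESULTS / f"diff_{mark}.tsv", sep="\t", index=False)
    planted = [
        (r.chrom, r.start, r.end)
        for frame in (truth.exclusive_a, truth.exclusive_b)
        for r in frame.itertuples(index=False)
    ]
    recovered = {
        iv for d in diffs for iv in planted if overlaps(d.interval, iv)
    }
    extra = sum(
        1 for d in diffs if not any(overlaps(d.interval, iv) for iv in planted)
    )
    print(
        f"{mark}: {n_t + n_c} exclusive peaks ({n_t} treatment-only + {n_c} "
        f"control-only; {pct}% control-only); recovered {len(recovered)}/"
        f"{len(planted)} planted exclusives, {extra} call(s) outside the truth"
    )


def count_route() -> None:
    # sparse signal: plain CPM normalisation assumes differential regions are
    # a negligible share of the library, so only a couple of regions are
    # planted here (a heavy planted burden shifts every null region's CPM)
    counts, design, planted = simulate_count_matrix(
        1000, 2, 8.0, seed=SEED + 100, treatment=TREATMENT, control=CONTROL
    )
    calls = score_differential_binding(
        counts, design, treatment=TREATMENT, control=CONTROL,
        fdr_cut=FDR_CUT, mark=K4,
    )
    differential_table(calls).to_csv(RESULTS / "diff_counts.tsv", sep="\t", index=False)
    hit = sum(1 for d in calls if d.region_id in set(planted))
    false = len(calls) - hit
    print(
        f"count-based stand-in: {len(calls)} regions at FDR<={FDR_CUT} "
        f"({hit}/{len(planted)} planted 8-fold regions, {false} false call(s); "
        f"realized FDP {false / len(calls):.3f})"
    )


def main() -> None:
    require(SIM_DIR / "genes.tsv", "01_simulate_experiment.py")
    RESULTS.mkdir(parents=True, exist_ok=True)
    for mark in (K4, K27):
        exclusive_route(mark)
    count_route()


if __name__ == "__main__":
    main()
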