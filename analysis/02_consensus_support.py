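#!/usr/bin/env python
"""Build per-condition consensus regions and cross-condition support histograms.

For each mark and condition, pools the four replicates' peaks, keeps regions
supported by every replicate, and tallies how many replicates of the *other*
condition overlap each region — the replicate-support spectrum that motivates
the strict exclusive criterion for broad marks.  Writes
results/support_<mark>_<condition>.tsv (k, count, percent).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
from common import CONTROL, K4, K27, RESULTS, SIM_DIR, TREATMENT, load_landscape, require

from markconcord.intervals import build_consensus, summarize_overlap_fractions, support_histogram


def main() -> None:
    require(SIM_DIR / "genes.tsv", "01_simulate_experiment.py")
    RESULTS.mkdir(parents=True, exist_ok=True)
    for mark in (K4, K27):
        landscape = load_landscape(mark)
        for cond, other in ((CONTROL, TREATMENT), (TREATMENT, CONTROL)):
            cons = build_consensus(landscape[cond], cond)
            hist = support_histogram(cons, landscape[other])
            pct = summarize_overlap_fractions(hist)
            table = pd.DataFrame(
                {"k": range(len(hist.counts)), "count": hist.counts, "percent": pct}
            )
            out = RESULTS / f"support_{mark}_{cond}.tsv"
            table.to_csv(out, sep="\t", index=False)
            full = pct[-1]
            zero = pct[0]
            print(
                f"{mark} {cond}: {hist.total} consensus regions; "
                f"{full}% overlap all {hist.n_other} {other} replicates, "
                f"{zero}% overlap none (candidate exclusives) -> {out.name}"
            )


if __name__ == "__main__":
    main()
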