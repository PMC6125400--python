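"""Shared study configuration for the numbered analysis drivers.

One synthetic two-mark experiment at desk scale: 4+4 replicates per mark,
a narrow active mark (H3K4me3-like, 200-800 bp peaks, 1,000 shared regions)
and a broad repressive mark (H3K27me3-like, 1-3 kb peaks, 300 shared
regions), 25 control-exclusive and 10 treatment-exclusive planted regions
per mark, 20 bp end jitter and a 10 % per-replicate miss rate on shared
peaks.  All drivers derive their inputs from these settings, so running
01..07 in order reproduces every table under results/.
"""

from dataclasses import replace
from pathlib import Path

from markconcord.io_formats import read_peak_bed
from markconcord.synthetic import SimConfig

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

K4, K27 = "H3K4me3", "H3K27me3"
CONTROL, TREATMENT = "control", "ethanol"

BASE = SimConfig(n_genes=160, seed=SEED)
CONFIGS = {
    K4: replace(BASE, mark=K4, seed=2 * SEED, peak_width_range=(200, 800)),
    K27: replace(
        BASE, mark=K27, seed=2 * SEED + 1,
        peak_width_range=(1000, 3000), n_shared_peaks=300,
    ),
}

P_CUT = 0.01
FDR_CUT = 0.1
EFFECT_SIZE = 1.0
NULL_SD = 0.2


def replicate_ids(condition: str) -> list[str]:
    return [f"{condition}_{i + 1}" for i in range(BASE.n_replicates_per_condition)]


def load_landscape(mark: str) -> dict[str, dict[str, list]]:
    """Re-read one mark's per-replicate BED files written by driver 01."""
    out = {}
    for cond in (CONTROL, TREATMENT):
        out[cond] = {
            rep: read_peak_bed(SIM_DIR / f"{mark}_{rep}.bed", rep, cond)
            for rep in replicate_ids(cond)
        }
    return out


def require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise SystemExit(f"missing {path}; run analysis/{producer} first")
    return path
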