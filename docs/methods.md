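# Methods

## Model and procedure

`markconcord` analyses a two-condition (control vs ethanol-treated),
replicated ChIP-seq design for two histone marks with opposite regulatory
semantics: H3K4me3 (narrow, at active promoters, more signal ⇒ more
transcription) and H3K27me3 (broad repressive domains, more signal ⇒ less
transcription). All interval arithmetic is 0-based half-open; two intervals
overlap when they share at least `min_bp` bases (default 1), so abutting
intervals neither overlap nor merge.

**Consensus and the exclusive criterion.** For one condition, all
replicates' peaks are pooled and merged into candidate regions; a candidate
is a *consensus region* iff every replicate contributes ≥ 1 overlapping
peak. This construction is symmetric in replicate order (no anchor
replicate) and idempotent. Each consensus region of condition *A* is then
scored by its *support*: the number of *B* replicates with ≥ 1 overlapping
peak, giving the 0‥n support histogram. A region is called
condition-exclusive when its support is ≤ `max_other` (default 0): present
in all replicates of one condition, absent from every replicate of the
other. This occupancy rule trades power for a near-zero false-positive
rate, which suits broad marks where peak boundaries are unstable and
count-based models are hard to calibrate.

**Count-based stand-in.** For narrow marks the package provides a simple
count test: library-size normalisation to counts-per-million, effect = mean
log₂(CPM + 0.5) difference, two-sided two-sample *t*-test per region,
Benjamini–Hochberg across regions, calls at FDR ≤ 0.1. It is not an
negative-binomial differential-binding model: dispersion is not shared
across regions, and plain CPM normalisation assumes differential regions are
a negligible fraction of the library. When a large share of the library is
truly differential, total-count scaling shifts every null region's CPM in
the opposite direction and the false-discovery rate inflates (the analysis
drivers demonstrate this and therefore plant only a sparse signal);
median-ratio or trimmed-mean normalisation would be the fix but is out of
scope here.

**Annotation.** The TSS base of a + strand gene is its start; of a − strand
gene the last base of the half-open interval (end − 1). "Upstream" follows
gene orientation, so the proximal promoter [TSS−2000, TSS+200) maps to
genomic [end−200, end+2000) for − strand genes. A (peak, gene) pair is
classified with precedence **tss** (some peak base within 100 bp of the TSS
base; overlap counts as distance 0) > **promoter** (≥ 1 bp overlap with the
promoter window) > **gene_body** (≥ 1 bp overlap with the gene interval) >
**intergenic**. A peak is associated with every gene whose windows it
touches, nearest TSS first, at most `max_multi` (default 3); a peak touching
none is assigned to the single nearest gene (by absolute TSS distance; ties
broken by smaller gene start, then gene id) as intergenic. Reported
distances are signed in gene orientation: negative upstream, positive
downstream.

**Concordance.** Gene-level mark statuses are obtained by collapsing a
gene's associated differential peaks: one direction ⇒ that status; mixed
directions for one mark ⇒ the gene goes to a conflicts report and is
excluded. Expression status comes from an unadjusted *p* < 0.01 filter with
direction from the sign of the log fold-change (no magnitude threshold;
records with log-FC exactly 0 are excluded with a warning). Predicted
expression: K4 increase ⇒ up, K4 decrease ⇒ down, K27 treatment-only gain ⇒
down, K27 control-only gain ⇒ up; agreeing marks give their shared
direction, disagreeing marks give `ambiguous`, no mark change gives `none`.
A gene is *testable* when it has observed expression and an unambiguous
prediction; it is *concordant* when the two match. The contingency output
is three gene-level cross-tabulations (k4 × k27, k4 × expression,
k27 × expression) plus an explicit dual-mark gene list, rather than a single
hybrid table mixing peak counts and gene counts.

**Enrichment.** Overlap of a query gene list with a prior set inside an
explicit universe is scored by the upper-tail hypergeometric probability
P(X ≥ k) (observed k included), computed with `scipy.stats.hypergeom`;
multiple sets are corrected by BH or Bonferroni. The universe must be given
by the caller — overlap p-values are undefined without one, so there is
deliberately no default such as "all annotated genes".

## Synthetic data: what it emulates and what it does not

The generator plants, on a configurable genome (default 4 × 5 Mb), three
region classes per mark: shared peaks (present in both conditions; each
replicate carries a copy independently with probability 1 − `drop_prob`),
condition-exclusive peaks (all replicates of one condition, none of the
other), and partially supported peaks (all of one condition, exactly *k* of
the other) filling the middle of the support spectrum. Every replicate copy
gets independent Normal(0, `jitter_sd`) jitter on both ends, clipped at
±4 SD and clamped to width ≥ 1.

Key structural guarantees, relied on by the tests:

* all planted regions are mutually separated by a buffer of 2 × the maximum
  peak width, and jitter is clipped well below that buffer, so a planted
  exclusive region can never drift into overlap with an other-condition
  peak — the truth table stays exact under noise;
* exclusive regions never drop and are placed inside the promoter window of
  a linked gene (> 100 bp from the TSS base, so a noise-free annotation run
  classifies them as `promoter`), making annotation recovery checkable;
* the matched expression table gives linked genes a mean log-FC shift of
  ±`effect_size` with the sign dictated by the mark semantics, and null
  genes mean 0; per-sample SD is `null_sd · √(n/2)` so the reported log-FC
  is Normal(shift, `null_sd`), and p-values from the two-sample *t*-test are
  exactly uniform for null genes.

Defaults are chosen once as plausible desk-scale study conditions: 4 + 4
replicates, 1,000 shared peaks (narrow mark; 300 for the broad mark whose
1–3 kb widths need more room), 25 control-exclusive + 10
treatment-exclusive regions, a (30 × k=3, 20 × k=2, 10 × k=1) partial
spectrum, `jitter_sd` 20 bp, `drop_prob` 0.1, `effect_size` 1.0, `null_sd`
0.2. The drop/jitter values echo the qualitative shape of real replicate
concordance spectra; they are not fitted to any dataset.

What the generator does **not** model: read-level signal (no FASTQ/BAM, no
fragment-size or GC structure), peak-shape differences beyond width ranges,
partial boundary shifts of broad domains, correlated replicate failures,
batch structure in expression, and mark changes without expression coupling
other than the null class. Passing tests therefore demonstrate the
correctness of the set/interval logic and the statistical calibration of
the stand-in tests under idealised noise — not performance on real
libraries, where boundary instability and library-composition effects
dominate.

## Numerical and design choices

* **Randomness**: every generator draws from
  `numpy.random.default_rng([seed, stage])` with fixed stage keys (0 genes,
  1 peaks, 2 expression, 3 counts), so each stage is independently
  reproducible and regenerating one stage does not shift another's stream.
* **Rounding**: report percentages round half-up (not banker's) via
  `decimal`, at 2 decimals for support spectra and to integers for direction
  percentages.
* **Coordinates**: BED in, BED semantics throughout; chromosome names are
  compared as exact strings, with an explicit `--normalize-chr` CLI option
  rather than silent prefix handling.
* **Degenerate inputs**: empty BED ⇒ empty list with a warning; malformed
  BED lines fail with the line number; duplicate gene ids, bad strands,
  p-values outside (0, 1] and missing fields are rejected at parse time;
  zero-variance regions in the count test get p = 1 rather than NaN;
  consensus of zero replicates, empty gene annotations, empty universes and
  empty histograms are errors.
* **Exclusive calls per direction are counted on their own condition's
  consensus coordinates** (treatment-only peaks on the treatment consensus,
  control-only on the control consensus), since the two conditions' merged
  widths differ.
* **Support counting is per merged consensus region**, not per original
  peak, when several of one condition's peaks overlap one region of the
  other.
* **Pipeline**: the two marks use derived seeds (2·seed, 2·seed + 1) and
  link disjoint halves of one shared gene annotation, so no gene carries
  planted regions of both marks and the combined truth stays unambiguous;
  exclusive H3K4me3 gains in treatment are translated to gene-status
  "increase" (and control gains to "decrease") when building the
  concordance matrix. Runs are re-entrant: a directory with a completed
  `summary.json` is not recomputed without `force`.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: landscapes of
≤ 1,000 shared peaks, 100-instance brute-force oracle sweeps with ≤ 50
intervals per replicate, 100 × 1,000-region count-test calibrations, and a
10,000-gene uniformity check. The whole suite completes in well under a
minute on one CPU; the acceptance script in a few seconds.

## Known limitations

* The count-based test is a labelled stand-in; its FDR control degrades
  under heavy library-composition shifts (see above).
* Gene models are one interval per gene id; isoform collapsing (longest vs
  union) is left to the user upstream.
* The exclusive criterion's sensitivity on real data depends on upstream
  peak-caller consistency, which the simulator idealises via the drop/jitter
  model.
* Enrichment p-values are only as meaningful as the supplied universe; no
  attempt is made to reconstruct platform universes automatically.
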