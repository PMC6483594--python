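# Methods

## Decay model

Paused Pol II on a reporter decays under triptolide by first-order
kinetics. With treatment time *t* (minutes) and pausing half-life *h*,
the expected retained fraction of pause signal is `2^(−t/h)`; inverting
a single measured retention ratio gives `h = −t·ln2/ln(retention)`.
The estimator assumes (i) initiation is fully blocked, (ii) the control
library measures the steady state at *t = 0*, and (iii) both libraries
of a pair come from one transfection pool, so the plasmid:genome ratio
is shared and reads-per-million normalization to the **genome-aligned**
read count cancels both sequencing depth and transfection efficiency.
Plasmid-aligned reads are deliberately excluded from the RPM
denominator: they scale with transfection efficiency, genome reads do
not. Equal-read-count normalization slightly underestimates true
signal changes (total genomic Pol II also drops a little under
triptolide); relative differences between constructs are preserved and
no correction is applied.

Retention ≥ 1 carries no decay information (noise, or a half-life far
exceeding the treatment); the half-life is then reported as
right-censored at `5·t`. This multiple is an explicit reporting
convention, not an estimate. Retention may exceed 1; only the
inversion censors.

`Total_Pol_sig` is the strand-combined windowed signal, width 301 bp
(odd, so the window is symmetric), centered on the reporter TSS — the
only landmark shared across constructs. Replicate pairs are combined
by computing the mutant/wild-type ratio per replicate and averaging;
the SEM over per-replicate ratios is reported. When replicate lists
are unpaired (unequal lengths) each mutant ratio is divided by the
mean wild-type ratio.

## Stop-base profiles

Reads are reduced to their 5′ ends (exonuclease stop bases), filtered
to unique alignments on the target reference, and deduplicated by the
key (reference, position, strand, barcode) — first occurrence kept,
which makes deduplication idempotent and order-preserving; selection
among exact duplicates is content-free. Profiles are dense per-position
count arrays per strand (reporter plasmids are kilobases, not genomes).
Profile similarity is Pearson correlation over the concatenated
plus/minus counts in a window; constant vectors are rejected rather
than silently returning NaN.

## Element annotation

Biological promoter coordinates have no zero (−1 precedes +1);
internally everything is 0-based with `tss_index` marking the +1 base.
Annotation scans IUPAC consensi with at most one mismatch, each fully
contained in its canonical window:

| element | consensus | window | notes |
|---|---|---|---|
| TATA box | STATAWAWR | −40..−20 | one window for class definition and combination analyses |
| initiator | TCAKTY | anchored −2..+4 | no positional wiggle; the mismatch may fall on any position including the +1 A |
| pausing | CSARCSSA, KCGGTTSK, KCGRWCG | +15..+40 | per-motif windows configurable |

Ties between window matches break by fewest mismatches, then proximity
to the window center; only the best match sets the presence flag. N
never matches any code; promoters with N in a scanned window are
annotated but flagged. `inr_variant` (G/nonG) requires an initiator
match, while the raw +2 base is recorded unconditionally — the
class-frequency analysis reads the raw base, the combination analysis
conditions on the initiator. Promoter classes: TATA box present and
half-life < 30 min ("TATA"), no TATA box and half-life ≥ 60 min
("stably paused"); the classes are disjoint by construction and
promoters between the thresholds are unclassified. Censored
("≥ bound") half-lives enter medians at their bound and are flagged.

## Statistics

The Wilcoxon rank-sum test uses midranks for ties; for pooled sizes
≤ 12 the two-sided p comes from exact enumeration of all rank
assignments, otherwise from the normal approximation with
tie-corrected variance and a 0.5 continuity correction. The
G-at-+2 2×2 class comparison uses Fisher's exact test (two-sided) —
exact and assumption-free at these table sizes. No multiple-testing
correction is applied across combination pairs (raw p-values are
reported). Position frequency matrices count bases per column
(N excluded column-wise); column information content is
`2 + Σ_b f log2 f` bits against a uniform background, no small-sample
correction (intended n is hundreds of promoters). Medians are plain
order statistics (even n: mean of the central pair).

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, with defaults chosen as the study conditions:

* **Promoters**: i.i.d. background at a chosen GC fraction (default
  0.4, A/T-rich as fly promoters are), length 300, TSS at index 150.
  Elements are planted as concrete consensus instances with exactly 0
  or 1 mismatches at canonical offsets (TATA at −31, initiator at −2,
  pausing element at +25). For cohort simulation the background is
  rejection-sampled until annotation recovers exactly the planted
  combination, so group membership round-trips deterministically.
  Chance background matches do occur on unconstrained sequences —
  mostly to the degenerate pausing consensi over their wide window —
  at roughly 20–35% per promoter; the package treats this as a
  property of degenerate motifs, not an error.
* **Half-lives**: log-normal, parameterized by the median (location =
  ln median, log-sd = dispersion, default 0.5). Default per-combination
  medians in minutes: Inr-G 44, Inr-nonG 14, pausing 18, TATA 13,
  TATA+Inr-G 59, TATA+Inr-nonG 11, Inr-G+pausing 60, Inr-nonG+pausing
  14 — the observed genome-wide medians for those combinations.
* **Reads**: pause molecules at Normal(+35, 4) truncated to +30..+50;
  each emits a plus-strand stop base at position −10 or a minus-strand
  one at +10 (probability 0.5 each), a simplified footprint whose
  strand peaks straddle the pause site. Initiation reads are
  plus-strand Normal(TSS, 2). Realized counts are Poisson; under
  triptolide the pause mean is multiplied by `2^(−t/h)` and initiation
  drops to zero (the transient initiation-site increase observed at
  short-half-life promoters is not modeled by default — it has no
  established magnitude, and omitting it keeps the retention statistic
  interpretable). PCR duplicates re-emit a read with identical
  (position, strand, barcode) at rate 0.1.
* **Barcodes**: one fixed 4-mer from {CTGA, TGAC, GACT, ACTG} plus a
  random tail; only the composite string matters for deduplication.
  The tail length defaults to 10 nt so that distinct molecules stopping
  at the same base essentially never collide at the simulator's
  intended depths (up to ~10⁵ reads over ~20 positions): with a 4-mer
  tail the ~4096-string space saturates, deduplication collapses
  distinct molecules preferentially in the deeper control library, and
  the retention ratio acquires an upward bias of order 10%. A shorter
  tail remains available (`barcode_random_len`) for studying exactly
  that saturation effect.
* **Library pairs**: control and treated share one `SimReadParams`
  (one transfection pool, one plasmid:genome ratio); per-library
  sequencing depth differs via `depth_factor`, which scales plasmid and
  genome reads jointly and must cancel in the retention ratio.
* **qPCR**: Ct = base − log2(template amount) with the reporter DNA at
  `copy_number_ratio` times the genomic template and cDNA templates
  scaled by expression times one shared reverse-transcription
  efficiency; the `2^(ΔCt)` ratio estimator then cancels copy number
  and RT efficiency exactly, and Gaussian Ct noise (per well) leaves
  the estimator unbiased in the geometric mean.

What the generator does **not** emulate: base-call errors, fragment
length variation, chromatin context, mappability, crosslinking bias,
genome-wide background reads, or motif position preferences beyond the
single canonical offset. Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed generative model, not
robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use 10⁵ pause reads per
library, 20–50 simulated library pairs, cohorts of 100–200 promoters
per combination, and the genome-scale class sizes 490/132 for the
G-at-+2 comparison. Monte-Carlo quantities with per-draw sampling
noise comparable to their tolerance (group medians at n=100,
proportions at n=132) are judged on the median over 3–5 independent
draws rather than a single draw. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give identical
outputs. Truncated normals are drawn by rejection; positions round to
the nearest integer and clip to the reference. Degenerate inputs fail
loudly: zero control signal, non-positive half-lives, constant
correlation vectors, even window widths, double normalization and
unknown group labels all raise `ValueError`.

## Known limitations

Single-timepoint inversion cannot distinguish half-lives much longer
than the treatment time (hence censoring), and its relative error
grows as retention approaches 1 from below. The exclusive-model
combination groups discard promoters carrying three or more elements.
IUPAC matching is binary per position; no weight-matrix scoring. Only
sense-strand promoters are supported.
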