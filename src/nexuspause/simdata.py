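"""Synthetic promoters, cohorts and reporter-ChIP-nexus-like reads.

The generator emulates the statistical structure the analysis assumes:

* promoter sequences with core-promoter elements planted at their
  canonical positions on an i.i.d. background of chosen GC content;
* paused Pol II half-lives drawn log-normally around per-combination
  medians (defaults are the observed genome-wide medians in minutes:
  Inr-G 44, Inr-nonG 14, pausing 18, TATA 13, TATA+Inr-G 59);
* stop-base reads with an initiation peak at the TSS and a pause peak
  at +30..+50 whose expected count decays as 2^(-t/h) under triptolide,
  Poisson-realized, with PCR duplicates sharing (position, strand,
  barcode) and paired control/treated libraries sharing one
  transfection pool (identical plasmid:genome ratio, library-specific
  sequencing depth);
* qPCR Ct tables consistent with the 2^(dCt) relative-expression
  equations, so the estimator recovers the planted expression
  independent of plasmid copy number.

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coords import bio_to_index
from .elements import IUPAC_SETS
from .io_formats import (HalfLifeRecord, ReadRecord, write_fasta,
                         write_halflife_table)
from .reporter_assays import QpcrSample

FIXED_BARCODES = ("CTGA", "TGAC", "GACT", "ACTG")
BASES = "ACGT"

# canonical consensus per element kind
CONSENSI = {
    "TATA": "STATAWAWR",
    "INR": "TCAKTY",
    "PAUSE": "CSARCSSA",
}

# canonical planting offsets (biological position of the first base)
CANONICAL_OFFSETS = {"TATA": -31, "INR": -2, "PAUSE": 25}

# observed genome-wide median paused Pol II half-lives per combination (min)
DEFAULT_MEDIANS = {
    "Inr-G": 44.0,
    "Inr-nonG": 14.0,
    "pausing": 18.0,
    "TATA": 13.0,
    "TATA+Inr-G": 59.0,
    "TATA+Inr-nonG": 11.0,
    "Inr-G+pausing": 60.0,
    "Inr-nonG+pausing": 14.0,
}

DEFAULT_DISPERSION = 0.5  # log-scale sd of the half-life distribution


@dataclass(frozen=True)
class ElementSpec:
    """One element to plant: kind, consensus, biological start offset."""

    kind: str
    consensus_id: str = ""
    planted_offset: int = 0
    planted_mismatches: int = 0
    force_plus2: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in CONSENSI:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.planted_mismatches not in (0, 1):
            raise ValueError("planted_mismatches must be 0 or 1")
        if not self.consensus_id:
            object.__setattr__(self, "consensus_id", CONSENSI[self.kind])
        if self.planted_offset == 0 and self.kind != "INR":
            object.__setattr__(self, "planted_offset", CANONICAL_OFFSETS[self.kind])
        if self.kind == "INR" and self.planted_offset == 0:
            object.__setattr__(self, "planted_offset", -2)


@dataclass
class SimTruth:
    """Ground truth for one synthetic promoter."""

    promoter_id: str
    elements: list[ElementSpec]
    true_halflife_min: float
    expected_retention: float
    gc_background: float
    tss_index: int = 0
    length: int = 0
    group_label: str = ""

    def __post_init__(self) -> None:
        if not self.true_halflife_min > 0:
            raise ValueError("true_halflife_min must be positive")
        if not (0 < self.expected_retention <= 1):
            raise ValueError("expected_retention must lie in (0, 1]")


@dataclass
class SimReadParams:
    """Read-generation parameters for one library pair."""

    n_pause_reads: float = 10_000.0
    n_init_reads: float = 2_000.0
    pause_center: int = 35          # biological position
    pause_sd: float = 4.0
    pause_bounds: tuple[int, int] = (30, 50)
    init_sd: float = 2.0
    footprint_halfwidth: int = 10
    strand_split: float = 0.5
    duplicate_rate: float = 0.1
    barcode_random_len: int = 10
    genome_reads: float = 1_000_000.0
    depth_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pause_reads < 0 or self.n_init_reads < 0 or self.genome_reads < 0:
            raise ValueError("expected read counts must be >= 0")
        if not 0 <= self.strand_split <= 1:
            raise ValueError("strand_split must be a probability")
        if not self.pause_bounds[0] <= self.pause_center <= self.pause_bounds[1]:
            raise ValueError("pause_center must lie within pause_bounds")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be positive")


def _sample_word(consensus: str, rng: np.random.Generator) -> list[str]:
    return [rng.choice(sorted(IUPAC_SETS[c])) for c in consensus]


def _plant_word(spec: ElementSpec, tss_index: int,
                rng: np.random.Generator) -> tuple[int, str]:
    """Draw a concrete instance of the consensus honoring the spec."""
    consensus = spec.consensus_id
    start = bio_to_index(spec.planted_offset, tss_index)
    word = _sample_word(consensus, rng)
    forced_idx: int | None = None
    if spec.kind == "INR" and spec.force_plus2 is not None:
        forced_idx = bio_to_index(2, tss_index) - start
        if not 0 <= forced_idx < len(word):
            raise ValueError("+2 lies outside the planted initiator window")
        word[forced_idx] = spec.force_plus2
    mm = sum(b not in IUPAC_SETS[c] for b, c in zip(word, consensus))
    if mm > spec.planted_mismatches:
        raise ValueError(
            f"forced base {spec.force_plus2!r} already violates the consensus; "
            f"requires planted_mismatches >= {mm}"
        )
    if spec.planted_mismatches == 1 and mm == 0:
        candidates = [i for i in range(len(word)) if i != forced_idx
                      and len(IUPAC_SETS[consensus[i]]) < 4]
        i = int(rng.choice(candidates))
        off_bases = sorted(set(BASES) - IUPAC_SETS[consensus[i]])
        word[i] = str(rng.choice(off_bases))
    return start, "".join(word)


def make_promoter(spec: list[ElementSpec], length: int = 300,
                  tss_offset: int = 150, gc: float = 0.4, seed: int = 0,
                  true_halflife_min: float = 60.0, treat_min: float = 0.0,
                  promoter_id: str = "synthetic") -> tuple[str, SimTruth]:
    """Generate one promoter sequence with planted elements.

    ``tss_offset`` is the 0-based index of the +1 base.  Background
    bases are i.i.d. with the given GC fraction; each planted element
    is a concrete instance of its IUPAC consensus with exactly
    ``planted_mismatches`` violations.  Planted windows must fit and
    must not overlap.
    """
    if length < 120:
        raise ValueError("length must be >= 120")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(list(BASES), size=length, p=p))

    occupied: list[tuple[int, int]] = []
    for es in spec:
        start, word = _plant_word(es, tss_offset, rng)
        end = start + len(word)
        if start < 0 or end > length:
            raise ValueError(f"planted window {es.kind} at {es.planted_offset} "
                             "falls outside the sequence")
        for s, e in occupied:
            if start < e and s < end:
                raise ValueError("planted element windows overlap")
        occupied.append((start, end))
        seq[start:end] = list(word)

    retention = 2.0 ** (-treat_min / true_halflife_min)
    truth = SimTruth(
        promoter_id=promoter_id, elements=list(spec),
        true_halflife_min=true_halflife_min, expected_retention=retention,
        gc_background=gc, tss_index=tss_offset, length=length,
    )
    return "".join(seq), truth


def sample_halflife(combination_label: str,
                    median_table: dict[str, float] | None = None,
                    dispersion: float = DEFAULT_DISPERSION,
                    seed: int | np.random.Generator = 0) -> float:
    """Draw a half-life (minutes) from a median-parameterized log-normal.

    location = ln(median) so the distribution's median equals the table
    entry exactly; ``dispersion`` is the log-scale standard deviation.
    """
    table = DEFAULT_MEDIANS if median_table is None else median_table
    if combination_label not in table:
        raise ValueError(f"unknown combination label {combination_label!r}")
    if not dispersion >= 0:
        raise ValueError("dispersion must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return float(table[combination_label] * math.exp(dispersion * rng.standard_normal()))


def _barcodes(rng: np.random.Generator, n: int, random_len: int = 10) -> list[str]:
    # composite = one fixed 4-mer + a random part; only the composite
    # string matters for dedup.  The random part is long enough that
    # distinct molecules stopping at the same base essentially never
    # share a barcode at the simulator's intended depths, so dedup
    # removes exactly the injected PCR duplicates.
    if n == 0:
        return []
    fixed = rng.integers(len(FIXED_BARCODES), size=n)
    tails = np.asarray(list(BASES))[rng.integers(4, size=(n, random_len))]
    return [FIXED_BARCODES[f] + "".join(t) for f, t in zip(fixed, tails)]


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=(size - filled) * 2)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def simulate_nexus_reads(truth: SimTruth, params: SimReadParams,
                         condition: str = "control", treat_min: float = 0.0,
                         seed: int = 0) -> tuple[list[ReadRecord], int]:
    """Simulate one reporter-ChIP-nexus library for one promoter.

    Pause molecules sit at Normal(pause_center, pause_sd) truncated to
    pause_bounds; each emits a plus-strand stop base at
    position - footprint_halfwidth (probability ``strand_split``) or a
    minus-strand stop base at position + footprint_halfwidth.
    Initiation reads are plus-strand around the TSS.  Under triptolide
    the expected pause count decays by 2^(-t/h) and initiation drops to
    zero; realized counts are Poisson.  PCR duplicates are re-emitted
    with identical (position, strand, barcode).  Returns the plasmid
    reads and the library's unique genome-aligned read count.
    """
    if condition not in ("control", "triptolide"):
        raise ValueError(f"unknown condition {condition!r}")
    if treat_min < 0:
        raise ValueError("treat_min must be >= 0")
    if condition == "control" and treat_min != 0:
        raise ValueError("control libraries have treat_min = 0")
    rng = np.random.default_rng(seed)

    decay = 2.0 ** (-treat_min / truth.true_halflife_min) if condition == "triptolide" else 1.0
    mean_pause = params.n_pause_reads * decay * params.depth_factor
    mean_init = (params.n_init_reads * params.depth_factor
                 if condition == "control" else 0.0)

    n_pause = rng.poisson(mean_pause)
    n_init = rng.poisson(mean_init)

    tss = truth.tss_index
    ref = truth.promoter_id
    L = truth.length
    reads: list[ReadRecord] = []

    lo = bio_to_index(params.pause_bounds[0], tss)
    hi = bio_to_index(params.pause_bounds[1], tss)
    center = bio_to_index(params.pause_center, tss)
    positions = np.rint(
        _truncated_normal(rng, center, params.pause_sd, lo, hi, n_pause)
    ).astype(int)
    on_plus = rng.random(n_pause) < params.strand_split
    pause_barcodes = _barcodes(rng, n_pause, params.barcode_random_len)
    for pos, plus, bc in zip(positions, on_plus, pause_barcodes):
        if plus:
            p5 = max(0, pos - params.footprint_halfwidth)
            strand = "+"
        else:
            p5 = min(L - 1, pos + params.footprint_halfwidth)
            strand = "-"
        reads.append(ReadRecord(ref, int(p5), strand, bc))

    init_pos = np.rint(rng.normal(tss, params.init_sd, size=n_init)).astype(int)
    init_pos = np.clip(init_pos, 0, L - 1)
    init_barcodes = _barcodes(rng, n_init, params.barcode_random_len)
    for pos, bc in zip(init_pos, init_barcodes):
        reads.append(ReadRecord(ref, int(pos), "+", bc))

    if params.duplicate_rate > 0:
        dup_mask = rng.random(len(reads)) < params.duplicate_rate
        reads.extend(r for r, d in zip(list(reads), dup_mask) if d)

    genome_read_count = int(rng.poisson(params.genome_reads * params.depth_factor))
    return reads, genome_read_count


def simulate_library_pair(truth: SimTruth, params: SimReadParams,
                          treat_min: float, seed: int = 0,
                          depth_factors: tuple[float, float] = (1.0, 1.0)):
    """Control + triptolide libraries from one shared transfection pool.

    Both libraries share ``params`` (one plasmid:genome ratio); only the
    per-library sequencing depth differs via ``depth_factors``.
    Returns ((control_reads, control_genome), (treated_reads,
    treated_genome)).
    """
    ctrl = simulate_nexus_reads(
        truth, replace(params, depth_factor=params.depth_factor * depth_factors[0]),
        "control", 0.0, seed=seed)
    trt = simulate_nexus_reads(
        truth, replace(params, depth_factor=params.depth_factor * depth_factors[1]),
        "triptolide", treat_min, seed=seed + 1)
    return ctrl, trt


# label -> elements planted (mutually exclusive planting)
GROUP_ELEMENTS: dict[str, tuple[ElementSpec, ...]] = {
    "none": (),
    "TATA": (ElementSpec("TATA"),),
    "Inr-G": (ElementSpec("INR", force_plus2="G"),),
    "Inr-nonG": (ElementSpec("INR", force_plus2="T"),),
    "pausing": (ElementSpec("PAUSE"),),
    "TATA+Inr-G": (ElementSpec("TATA"), ElementSpec("INR", force_plus2="G")),
    "TATA+Inr-nonG": (ElementSpec("TATA"), ElementSpec("INR", force_plus2="T")),
    "Inr-G+pausing": (ElementSpec("INR", force_plus2="G"), ElementSpec("PAUSE")),
    "Inr-nonG+pausing": (ElementSpec("INR", force_plus2="T"), ElementSpec("PAUSE")),
}


@dataclass
class SimCohort:
    sequences: dict[str, str]
    halflives: list[HalfLifeRecord]
    truths: list[SimTruth]
    tss_index: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.promoter_id, t.group_label, t.true_halflife_min,
                 t.expected_retention, t.gc_background, t.tss_index)
                for t in self.truths
            ],
            columns=["promoter_id", "group_label", "true_halflife_min",
                     "expected_retention", "gc_background", "tss_index"],
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "promoters.fasta")
        write_halflife_table(self.halflives, outdir / "halflives.tsv")
        self.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_cohort(n_per_group: int, groups: list[str],
                    median_table: dict[str, float] | None = None,
                    dispersion: float = DEFAULT_DISPERSION,
                    seed: int = 0, length: int = 300, tss_offset: int = 150,
                    gc: float = 0.4) -> SimCohort:
    """Simulate a promoter cohort with group-conditional half-lives.

    Each promoter carries exactly the elements of its group label
    (mutually exclusive planting) and a log-normal half-life around the
    group median.  Backgrounds that happen to contain a chance match to
    any other element are rejection-sampled away, so annotation
    round-trips to exactly the planted combination.
    """
    from .elements import annotate_promoter  # deferred: avoids cycle at import

    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    table = DEFAULT_MEDIANS if median_table is None else median_table
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    halflives: list[HalfLifeRecord] = []
    truths: list[SimTruth] = []
    for label in groups:
        if label not in GROUP_ELEMENTS:
            raise ValueError(f"unknown group label {label!r}")
        wanted = frozenset(label.split("+")) if label != "none" else frozenset()
        for i in range(n_per_group):
            pid = f"{label.replace('+', '_')}_{i:04d}"
            h = sample_halflife(label, table, dispersion, rng)
            for _attempt in range(200):
                sub_seed = int(rng.integers(2**31 - 1))
                seq, truth = make_promoter(
                    list(GROUP_ELEMENTS[label]), length=length,
                    tss_offset=tss_offset, gc=gc, seed=sub_seed,
                    true_halflife_min=h, promoter_id=pid)
                if annotate_promoter(pid, seq, tss_offset).features() == wanted:
                    break
            else:  # pragma: no cover - would need a pathological background
                raise RuntimeError(f"could not draw a clean background for {label}")
            truth.group_label = label
            sequences[pid] = seq
            halflives.append(HalfLifeRecord(pid, h))
            truths.append(truth)
    return SimCohort(sequences, halflives, truths, tss_offset)


def simulate_qpcr(true_relative_expression: float, copy_number_ratio: float = 50.0,
                  noise_sd_ct: float = 0.0, seed: int = 0,
                  base_ct: float = 25.0) -> QpcrSample:
    """Simulate one qPCR sample (GFP/RpL30 x DNA/cDNA Ct values).

    Ct = base - log2(template amount); the reporter DNA template is
    ``copy_number_ratio`` times the genomic one, the cDNA templates are
    expression x template x one shared RT efficiency, so the
    relative-expression estimator cancels both copy number and RT
    efficiency and recovers ``true_relative_expression`` exactly at
    zero noise.
    """
    if true_relative_expression <= 0 or copy_number_ratio <= 0:
        raise ValueError("expression and copy-number ratio must be positive")
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be >= 0")
    rng = np.random.default_rng(seed)
    rt = 0.25  # shared reverse-transcription efficiency; cancels
    amounts = {
        "gfp_dna": copy_number_ratio,
        "gfp_cdna": true_relative_expression * copy_number_ratio * rt,
        "rpl30_dna": 1.0,
        "rpl30_cdna": 1.0 * rt,
    }
    ct = {k: base_ct - math.log2(v) + rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0
          else base_ct - math.log2(v)
          for k, v in amounts.items()}
    return QpcrSample(ct_gfp_dna=ct["gfp_dna"], ct_gfp_cdna=ct["gfp_cdna"],
                      ct_rpl30_dna=ct["rpl30_dna"], ct_rpl30_cdna=ct["rpl30_cdna"])
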