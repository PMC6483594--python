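"""Auxiliary reporter quantifications.

5'-RNA start-site mapping (a RACE-like readout: the first base of each
sequenced read is the reverse-transcriptase stop base, i.e. the RNA 5'
end) and qPCR relative expression of the reporter over the endogenous
RpL30 locus, corrected for plasmid copy number via the DNA Ct values:

    GFP_expression    = 2^(Ct(GFP DNA) - Ct(GFP cDNA))
    RpL30_expression  = 2^(Ct(RpL30 DNA) - Ct(RpL30 cDNA))
    relative          = GFP_expression / RpL30_expression
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coords import index_to_bio
from .io_formats import ReadRecord


@dataclass(frozen=True)
class QpcrSample:
    """Ct values of one biological qPCR replicate."""

    ct_gfp_dna: float
    ct_gfp_cdna: float
    ct_rpl30_dna: float
    ct_rpl30_cdna: float

    def __post_init__(self) -> None:
        for name in ("ct_gfp_dna", "ct_gfp_cdna", "ct_rpl30_dna", "ct_rpl30_cdna"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class StartSiteHistogram:
    """Histogram of RNA 5'-end positions in biological coordinates."""

    counts: dict[int, int]
    modal_position: int
    frac_within_k: float
    k: int
    n_minus_strand: int = 0  # QC: antisense reads, not part of the histogram

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def map_5prime_starts(reads: list[ReadRecord], tss_index: int,
                      k: int = 3) -> StartSiteHistogram:
    """Map deduplicated read 5' ends to transcription start positions.

    Only plus-strand reads are considered (RNA 5' ends lie on the sense
    strand of the reporter); minus-strand reads are counted for QC.
    The modal position breaks ties toward +1; ``frac_within_k`` is the
    fraction of 5' ends within +-k bases of the +1.
    """
    counts: dict[int, int] = {}
    n_minus = 0
    for r in reads:
        if r.strand == "-":
            n_minus += 1
            continue
        pos = index_to_bio(r.five_prime_pos, tss_index)
        counts[pos] = counts.get(pos, 0) + 1
    if not counts:
        raise ValueError("no plus-strand reads to map")
    max_count = max(counts.values())
    modal = min((p for p, c in counts.items() if c == max_count),
                key=lambda p: (abs(p - 1), p))
    total = sum(counts.values())
    # biological window +-k around +1 skips the nonexistent position 0
    near = sum(c for p, c in counts.items() if -k <= p <= k + 1 and p != 0)
    return StartSiteHistogram(counts=counts, modal_position=modal,
                              frac_within_k=near / total, k=k,
                              n_minus_strand=n_minus)


def qpcr_relative_expression(sample: QpcrSample) -> float:
    """Reporter expression relative to RpL30, copy-number corrected."""
    gfp = 2.0 ** (sample.ct_gfp_dna - sample.ct_gfp_cdna)
    rpl30 = 2.0 ** (sample.ct_rpl30_dna - sample.ct_rpl30_cdna)
    return gfp / rpl30


def qpcr_summary(samples: list[QpcrSample]) -> tuple[list[float], float]:
    """Per-replicate relative expression and its geometric mean."""
    if not samples:
        raise ValueError("no qPCR samples")
    values = [qpcr_relative_expression(s) for s in samples]
    gmean = float(np.exp(np.mean(np.log(values))))
    return values, gmean
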