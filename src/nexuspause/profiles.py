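"""Strand-separated exonuclease stop-base profiles.

A ChIP-nexus read marks the lambda-exonuclease stop base at its 5' end;
piling up 5' ends per strand gives a base-pair-resolution footprint of
crosslinked Pol II.  This module filters to uniquely aligned reads,
removes PCR duplicates by barcode, builds dense per-position count
arrays, normalizes to reads per million, and compares profiles by
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io_formats import ReadRecord


@dataclass
class StopBaseProfile:
    """Per-position counts of read 5' ends on one reference, by strand."""

    reference: str
    length: int
    plus_counts: np.ndarray
    minus_counts: np.ndarray
    normalized: bool = False
    norm_factor: float = 1.0
    genome_read_count: int = 0

    def __post_init__(self) -> None:
        self.plus_counts = np.asarray(self.plus_counts, dtype=float)
        self.minus_counts = np.asarray(self.minus_counts, dtype=float)
        if len(self.plus_counts) != self.length or len(self.minus_counts) != self.length:
            raise ValueError("count arrays must have length == profile length")
        if (self.plus_counts < 0).any() or (self.minus_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.normalized and not self.norm_factor > 0:
            raise ValueError("normalized profile requires norm_factor > 0")

    @property
    def total(self) -> float:
        return float(self.plus_counts.sum() + self.minus_counts.sum())


def filter_unique(reads: list[ReadRecord], reference: str) -> list[ReadRecord]:
    """Keep only uniquely aligned reads on the given reference.

    Order is preserved; nothing else is touched.
    """
    return [r for r in reads if r.unique and r.reference == reference]


def dedup_reads(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Remove PCR duplicates sharing (reference, position, strand, barcode).

    Reads from distinct molecules that stop at the same base carry
    different ChIP-nexus barcodes and are all retained; only exact key
    duplicates collapse.  The first occurrence wins and input order is
    preserved, so the operation is idempotent.
    """
    seen: set[tuple[str, int, str, str]] = set()
    out: list[ReadRecord] = []
    for r in reads:
        key = (r.reference, r.five_prime_pos, r.strand, r.barcode)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def build_profile(reads: list[ReadRecord], reference: str, length: int) -> StopBaseProfile:
    """Pile up read 5' ends into strand-separated count arrays.

    Expects reads already filtered and deduplicated; the sum of both
    arrays equals the number of reads.
    """
    plus = np.zeros(length, dtype=float)
    minus = np.zeros(length, dtype=float)
    for r in reads:
        if r.five_prime_pos >= length:
            raise ValueError(
                f"read at {r.five_prime_pos} outside reference of length {length}"
            )
        (plus if r.strand == "+" else minus)[r.five_prime_pos] += 1
    return StopBaseProfile(reference=reference, length=length,
                           plus_counts=plus, minus_counts=minus)


def normalize_rpm(profile: StopBaseProfile, genome_read_count: int) -> StopBaseProfile:
    """Normalize a profile to reads per million genome-aligned reads.

    The denominator is the library's unique genome-aligned read count,
    not genome+plasmid: plasmid reads scale with transfection efficiency
    while genome reads track sequencing depth only, so paired libraries
    from one transfection pool become directly comparable.
    """
    if profile.normalized:
        raise ValueError("profile is already normalized")
    if genome_read_count <= 0:
        raise ValueError("genome_read_count must be positive")
    factor = genome_read_count / 1e6
    return replace(
        profile,
        plus_counts=profile.plus_counts / factor,
        minus_counts=profile.minus_counts / factor,
        normalized=True,
        norm_factor=factor,
        genome_read_count=genome_read_count,
    )


def profile_correlation(a: StopBaseProfile, b: StopBaseProfile,
                        window: tuple[int, int] | None = None) -> float:
    """Pearson correlation of two profiles over a 0-based window.

    Plus and minus counts inside [start, end) are concatenated into one
    vector per profile.  A constant vector makes the correlation
    undefined and raises.
    """
    if a.length != b.length:
        raise ValueError("profiles must share a reference length")
    start, end = (0, a.length) if window is None else window
    if start < 0 or end > a.length or start >= end:
        raise ValueError(f"window ({start}, {end}) outside profile bounds")
    va = np.concatenate([a.plus_counts[start:end], a.minus_counts[start:end]])
    vb = np.concatenate([b.plus_counts[start:end], b.minus_counts[start:end]])
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("degenerate profile: constant signal in window")
    return float(stats.pearsonr(va, vb).statistic)


def profile_from_reads(reads: list[ReadRecord], reference: str, length: int,
                       genome_read_count: int | None = None) -> StopBaseProfile:
    """Convenience chain: filter unique -> dedup -> pile up -> optional RPM."""
    clean = dedup_reads(filter_unique(reads, reference))
    prof = build_profile(clean, reference, length)
    if genome_read_count is not None:
        prof = normalize_rpm(prof, genome_read_count)
    return prof
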