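"""Cohort-level statistics: half-life stratification by element
combination, rank tests, promoter class definitions, and sequence
composition summaries (position frequency matrices, information
content, G-at-+2 proportions).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coords import bio_to_index
from .elements import CombinationGroup, PromoterAnnotation
from .io_formats import HalfLifeRecord

BASES = ("A", "C", "G", "T")


def stratify(groups: list[CombinationGroup]) -> pd.DataFrame:
    """Tabulate (label, n, median half-life) per combination group.

    Medians are plain order-statistic medians (even n: mean of the two
    central values); the table is sorted by median descending, empty
    groups (median undefined) last.
    """
    if not groups:
        raise ValueError("no groups to stratify")
    rows = [(g.label, g.n, g.median_min) for g in groups]
    df = pd.DataFrame(rows, columns=["label", "n", "median_min"])
    return df.sort_values("median_min", ascending=False,
                          na_position="last").reset_index(drop=True)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (two-sided).

    Returns ``(rank_sum_statistic, p)`` where the statistic is the sum
    of midranks of sample ``a`` in the pooled data.  Small problems
    (n_a + n_b <= 12) are solved by exact enumeration of all rank
    assignments; larger ones use the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.  If every
    pooled value is identical the samples are indistinguishable and
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        ranks = sps.rankdata(pooled)
        return float(ranks[: len(a)].sum()), 1.0

    ranks = sps.rankdata(pooled)  # midranks for ties
    w = float(ranks[: len(a)].sum())
    na, nb = len(a), len(b)
    n = na + nb

    if n <= 12:
        # exact: the statistic's null distribution over all C(n, na)
        # equally likely assignments of pooled ranks to sample a
        mean_w = na * (n + 1) / 2.0
        obs_dev = abs(w - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            ws = ranks[list(combo)].sum()
            total += 1
            if abs(ws - mean_w) >= obs_dev - 1e-12:
                count += 1
        return w, count / total

    mean_w = na * (n + 1) / 2.0
    # tie correction: subtract sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    dev = abs(w - mean_w)
    z = max(0.0, dev - 0.5) / math.sqrt(var_w)  # continuity correction
    p = 2.0 * sps.norm.sf(z)
    return w, min(1.0, float(p))


def define_classes(annotations: list[PromoterAnnotation],
                   halflives: list[HalfLifeRecord],
                   tata_max_min: float = 30.0,
                   stable_min_min: float = 60.0) -> tuple[list[str], list[str]]:
    """Split promoters into TATA and stably paused classes.

    TATA class: TATA box present and paused Pol II half-life shorter
    than ``tata_max_min`` (default 30 min).  Stable class: no detectable
    TATA box and half-life of at least ``stable_min_min`` (default
    60 min).  The classes are disjoint by construction; promoters in
    neither class are simply unclassified.
    """
    hl = {r.promoter_id: r.halflife_min for r in halflives}
    tata_class, stable_class = [], []
    for ann in annotations:
        h = hl.get(ann.promoter_id)
        if h is None:
            continue
        if ann.has_tata and h < tata_max_min:
            tata_class.append(ann.promoter_id)
        elif not ann.has_tata and h >= stable_min_min:
            stable_class.append(ann.promoter_id)
    return tata_class, stable_class


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over aligned promoter windows.

    ``counts`` is 4 x L (rows A, C, G, T); ``info_content`` is the
    per-column information in bits under a uniform background,
    2 + sum_b f log2 f with 0 log 0 := 0.  Columns exclude sequences
    with N at that position, so column sums may differ.
    """

    window_bio: tuple[int, int]
    counts: np.ndarray
    n_sequences: int

    @property
    def frequencies(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, self.counts / col, 0.0)

    @property
    def info_content(self) -> np.ndarray:
        f = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.window_bio
        positions = [p for p in range(lo, hi + 1) if p != 0]
        df = pd.DataFrame(self.counts.T, columns=list(BASES))
        df.insert(0, "position_bio", positions)
        df["info_bits"] = self.info_content
        return df


def pfm_and_logo(sequences: list[str], tss_indices: list[int],
                 window_bio: tuple[int, int]) -> PositionFrequencyMatrix:
    """Build a PFM (and logo heights) over a biological window.

    Sequences not covering the window are excluded with a warning;
    N bases are excluded column-wise.
    """
    import logging
    logger = logging.getLogger("nexuspause")

    lo, hi = window_bio
    positions = [p for p in range(lo, hi + 1) if p != 0]
    L = len(positions)
    counts = np.zeros((4, L), dtype=int)
    used = 0
    for seq, tss in zip(sequences, tss_indices):
        seq = seq.upper()
        idx = [bio_to_index(p, tss) for p in positions]
        if idx[0] < 0 or idx[-1] >= len(seq):
            logger.warning("sequence of length %d does not cover window %s; skipped",
                           len(seq), window_bio)
            continue
        used += 1
        for j, i in enumerate(idx):
            base = seq[i]
            if base in BASES:
                counts[BASES.index(base), j] += 1
    return PositionFrequencyMatrix(window_bio=window_bio, counts=counts,
                                   n_sequences=used)


def g2_frequency_test(class_a_sequences: list[str], class_a_tss: list[int],
                      class_b_sequences: list[str], class_b_tss: list[int],
                      ) -> tuple[float, float, float]:
    """Compare the frequency of a literal G at biological +2 between classes.

    Returns (proportion in class a, proportion in class b, two-sided
    Fisher exact p on the 2x2 G / not-G x class table).
    """
    if not class_a_sequences or not class_b_sequences:
        raise ValueError("both classes must be non-empty")

    def count_g(seqs, tsss):
        g = 0
        for seq, tss in zip(seqs, tsss):
            i = bio_to_index(2, tss)
            if i >= len(seq):
                raise ValueError("sequence does not cover biological +2")
            g += seq.upper()[i] == "G"
        return g, len(seqs)

    ga, na = count_g(class_a_sequences, class_a_tss)
    gb, nb = count_g(class_b_sequences, class_b_tss)
    table = [[ga, na - ga], [gb, nb - gb]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return ga / na, gb / nb, float(p)


def subsample_ids(ids: list[str], k: int, seed: int) -> list[str]:
    """Seeded uniform subsample (for visualization-parity subsets)."""
    rng = np.random.default_rng(seed)
    if k >= len(ids):
        return list(ids)
    return [ids[i] for i in sorted(rng.choice(len(ids), size=k, replace=False))]
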