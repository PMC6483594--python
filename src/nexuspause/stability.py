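"""Paused Pol II stability quantification on reporter promoters.

Triptolide blocks new initiation, so the Pol II signal remaining on a
reporter after a treatment of t minutes reflects first-order decay of
the paused polymerase: retention = 2^(-t/h) where h is the pausing
half-life.  Because treated and control libraries come from one
transfection pool and are normalized to genome reads per million, the
ratio of windowed total signal (Total_Pol_sig, 301 bp around the TSS)
is independent of transfection efficiency and sequencing depth, and h
can be back-calculated from a single timepoint:

    h = -t * ln 2 / ln(retention)

Retention at or above 1 carries no decay information; the half-life is
then reported as right-censored at 5*t (a documented convention, since
retention -> 1 makes h unbounded).

Note: equal-read-count normalization slightly underestimates the true
signal change, because total Pol II on the genome itself drops a little
under triptolide; relative differences between constructs are
preserved, and no correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profiles import StopBaseProfile

CENSOR_MULTIPLE = 5.0  # censored half-life reported as >= CENSOR_MULTIPLE * treat_min


@dataclass
class StabilityResult:
    """Stability quantification of one reporter construct."""

    construct_id: str
    treat_min: float
    total_sig_control: float
    total_sig_treated: float
    retention_ratio: float
    relative_to_wt: float = float("nan")
    sem: float = float("nan")
    est_halflife_min: float = float("nan")
    halflife_censored: bool = False

    def summary(self) -> str:
        hl = (
            f">= {self.est_halflife_min:.1f} (censored)"
            if self.halflife_censored else f"{self.est_halflife_min:.1f}"
        )
        lines = [
            f"Paused Pol II stability: {self.construct_id}",
            "=" * 44,
            f"  triptolide treatment      {self.treat_min:g} min",
            f"  Total_Pol_sig control     {self.total_sig_control:.3f}",
            f"  Total_Pol_sig treated     {self.total_sig_treated:.3f}",
            f"  retention ratio           {self.retention_ratio:.4f}",
            f"  est. half-life (min)      {hl}",
        ]
        if not math.isnan(self.relative_to_wt):
            lines.append(f"  stability rel. to WT      {self.relative_to_wt:.3f}"
                         f" (SEM {self.sem:.3f})")
        return "\n".join(lines)


def window_signal(profile: StopBaseProfile, center: int, width: int = 301) -> float:
    """Total strand-combined signal in an odd-width window around ``center``.

    The window is clipped to the reference bounds; the profile must be
    RPM-normalized so windows are comparable across libraries.
    """
    if width <= 0 or width % 2 == 0:
        raise ValueError(f"width must be odd and positive, got {width}")
    if not profile.normalized:
        raise ValueError("profile must be RPM-normalized before windowing")
    half = (width - 1) // 2
    lo = max(0, center - half)
    hi = min(profile.length, center + half + 1)
    return float(profile.plus_counts[lo:hi].sum() + profile.minus_counts[lo:hi].sum())


def retention_ratio(sig_treated: float, sig_control: float) -> float:
    """Treated / control Total_Pol_sig from one transfection pool."""
    if sig_control <= 0:
        raise ValueError(
            f"control Total_Pol_sig must be positive (got {sig_control}): "
            "unusable control library"
        )
    return sig_treated / sig_control


def relative_stability(mutant_ratios: list[float],
                       wt_ratios: list[float]) -> tuple[float, float]:
    """Mutant stability relative to wild type, with replicate SEM.

    When replicate lists have equal length they are paired by experiment
    (same transfection date): the per-replicate value is
    mutant_ratio / wt_ratio and the result is its mean and SEM.
    Unequal lengths fall back to dividing each mutant ratio by the mean
    wild-type ratio.  Wild type evaluated against itself gives 1 exactly.
    """
    if not mutant_ratios or not wt_ratios:
        raise ValueError("need at least one replicate per construct")
    mut = np.asarray(mutant_ratios, dtype=float)
    wt = np.asarray(wt_ratios, dtype=float)
    if len(mut) == len(wt):
        per_rep = mut / wt
    else:
        per_rep = mut / wt.mean()
    rel = float(per_rep.mean())
    sem = float(per_rep.std(ddof=1) / math.sqrt(len(per_rep))) if len(per_rep) > 1 else 0.0
    return rel, sem


def estimate_halflife(retention: float, treat_min: float) -> tuple[float, bool]:
    """Invert first-order decay: retention = 2^(-t/h)  =>  h.

    Returns ``(halflife_min, censored)``.  Retention >= 1 is consistent
    with no decay within noise, so the half-life is censored at
    ``CENSOR_MULTIPLE * treat_min`` (a lower bound).
    """
    if treat_min <= 0:
        raise ValueError("treat_min must be positive")
    if retention <= 0:
        raise ValueError("retention must be positive; zero signal is uninformative")
    if retention >= 1:
        return CENSOR_MULTIPLE * treat_min, True
    return -treat_min * math.log(2) / math.log(retention), False


class TriptolideDecay:
    """Single-timepoint decay model for paired control/treated libraries.

    Model-object wrapper over the stability functions: construct from
    two RPM-normalized profiles (or precomputed window signals), call
    :meth:`fit` to obtain a :class:`StabilityResult`.
    """

    def __init__(self, control: StopBaseProfile, treated: StopBaseProfile,
                 tss_index: int, treat_min: float, construct_id: str = "construct",
                 window_width: int = 301):
        self.control = control
        self.treated = treated
        self.tss_index = tss_index
        self.treat_min = treat_min
        self.construct_id = construct_id
        self.window_width = window_width

    @classmethod
    def from_reads(cls, control_reads, treated_reads, reference: str, length: int,
                   control_genome_reads: int, treated_genome_reads: int,
                   tss_index: int, treat_min: float, **kw) -> "TriptolideDecay":
        from .profiles import profile_from_reads
        ctrl = profile_from_reads(control_reads, reference, length, control_genome_reads)
        trt = profile_from_reads(treated_reads, reference, length, treated_genome_reads)
        return cls(ctrl, trt, tss_index, treat_min, **kw)

    def fit(self) -> StabilityResult:
        sig_c = window_signal(self.control, self.tss_index, self.window_width)
        sig_t = window_signal(self.treated, self.tss_index, self.window_width)
        ratio = retention_ratio(sig_t, sig_c)
        hl, censored = estimate_halflife(ratio, self.treat_min)
        return StabilityResult(
            construct_id=self.construct_id,
            treat_min=self.treat_min,
            total_sig_control=sig_c,
            total_sig_treated=sig_t,
            retention_ratio=ratio,
            est_halflife_min=hl,
            halflife_censored=censored,
        )
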