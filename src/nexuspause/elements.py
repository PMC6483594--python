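"""Core-promoter-element annotation by positional IUPAC consensus matching.

Elements are called by scanning degenerate consensi against fixed
promoter windows with at most one mismatch: the TATA box (STATAWAWR)
fully inside biological -40..-20, the initiator (TCAKTY) anchored at
-2..+4 with the A at +1, and three downstream pausing-element consensi
(CSARCSSA, KCGGTTSK, KCGRWCG) inside +15..+40 by default.  The initiator
is further classified by whether the +2 base is literally G (Inr-G vs
Inr-nonG), the variant that distinguishes stably paused promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coords import bio_to_index, index_to_bio
from .io_formats import HalfLifeRecord, PipelineConfig

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

# labels used for combination analyses
COMBINATION_FEATURES = ("TATA", "Inr-G", "Inr-nonG", "pausing")


@dataclass(frozen=True)
class ElementMatch:
    kind: str                 # TATA | INR | PAUSE
    consensus_id: str
    start_bio: int            # biological position of the first consensus base
    mismatches: int
    matched_seq: str

    def __post_init__(self) -> None:
        if self.mismatches > 1:
            raise ValueError("matches are restricted to <= 1 mismatch")
        if len(self.matched_seq) != len(self.consensus_id):
            raise ValueError("matched_seq length must equal consensus length")


@dataclass
class PromoterAnnotation:
    promoter_id: str
    sequence: str
    tss_index: int
    matches: list[ElementMatch] = field(default_factory=list)
    has_tata: bool = False
    has_inr: bool = False
    has_pause: bool = False
    inr_variant: str = "absent"   # G | nonG | absent
    base_plus2: str = "N"
    has_n_in_windows: bool = False

    def features(self) -> frozenset[str]:
        """The combination features this promoter carries."""
        feats = set()
        if self.has_tata:
            feats.add("TATA")
        if self.has_inr:
            feats.add("Inr-G" if self.inr_variant == "G" else "Inr-nonG")
        if self.has_pause:
            feats.add("pausing")
        return frozenset(feats)


def iupac_mismatches(seq: str, consensus: str) -> int:
    """Count positions of ``seq`` outside the IUPAC code set of ``consensus``.

    N in the query never matches any code (unknown base = mismatch).
    """
    if len(seq) != len(consensus):
        raise ValueError(
            f"length mismatch: sequence {len(seq)} vs consensus {len(consensus)}"
        )
    mm = 0
    for base, code in zip(seq.upper(), consensus.upper()):
        try:
            allowed = IUPAC_SETS[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} in consensus") from None
        if base not in ("A", "C", "G", "T"):
            if base != "N":
                raise ValueError(f"invalid base {base!r} in sequence")
            mm += 1
        elif base not in allowed:
            mm += 1
    return mm


def scan_element(sequence: str, tss_index: int, kind: str, consensus: str,
                 window_bio: tuple[int, int], max_mm: int = 1) -> list[ElementMatch]:
    """Find consensus matches fully contained in a biological window.

    Returns matches with at most ``max_mm`` mismatches sorted by
    (mismatches, distance of the match start from the window center):
    the best-supported, most central match comes first.
    """
    sequence = sequence.upper()
    lo_bio, hi_bio = window_bio
    k = len(consensus)
    lo_idx = bio_to_index(lo_bio, tss_index)
    hi_idx = bio_to_index(hi_bio, tss_index)
    if lo_idx < 0 or hi_idx >= len(sequence):
        raise ValueError(
            f"window {window_bio} outside sequence of length {len(sequence)}"
        )
    center = (lo_idx + hi_idx) / 2
    matches = []
    for start in range(lo_idx, hi_idx - k + 2):  # match fully inside window
        word = sequence[start:start + k]
        mm = iupac_mismatches(word, consensus)
        if mm <= max_mm:
            matches.append(
                ElementMatch(
                    kind=kind,
                    consensus_id=consensus,
                    start_bio=index_to_bio(start, tss_index),
                    mismatches=mm,
                    matched_seq=word,
                )
            )
    matches.sort(key=lambda m: (m.mismatches,
                                abs(bio_to_index(m.start_bio, tss_index) - center)))
    return matches


def annotate_promoter(promoter_id: str, sequence: str, tss_index: int,
                      config: PipelineConfig | None = None) -> PromoterAnnotation:
    """Annotate one promoter with TATA / Inr / pausing-element calls.

    The +2 base is recorded unconditionally (class frequency analyses
    read the raw genomic base); ``inr_variant`` is set only when an Inr
    match is present (combination analyses condition on the Inr).
    """
    cfg = config or PipelineConfig()
    sequence = sequence.upper()
    if tss_index < 40 or tss_index + 4 >= len(sequence):
        raise ValueError(
            "sequence too short: need 40 bp upstream and 4 bp downstream of the TSS"
        )
    ann = PromoterAnnotation(promoter_id=promoter_id, sequence=sequence,
                             tss_index=tss_index)
    ann.base_plus2 = sequence[bio_to_index(2, tss_index)]

    for kind, flag in (("TATA", "has_tata"), ("INR", "has_inr"), ("PAUSE", "has_pause")):
        best_per_consensus = []
        for motif in cfg.motifs[kind]:
            lo, hi = motif.window_bio
            hi_idx = bio_to_index(hi, tss_index)
            if hi_idx >= len(sequence):  # downstream window may be clipped
                hi = index_to_bio(len(sequence) - 1, tss_index)
            window_seq = sequence[bio_to_index(lo, tss_index):
                                  bio_to_index(hi, tss_index) + 1]
            if "N" in window_seq:
                ann.has_n_in_windows = True
            found = scan_element(sequence, tss_index, kind, motif.consensus,
                                 (lo, hi), cfg.max_mismatches)
            if found:
                best_per_consensus.append(found[0])
        if best_per_consensus:
            best_per_consensus.sort(key=lambda m: m.mismatches)
            ann.matches.extend(best_per_consensus)
            setattr(ann, flag, True)

    if ann.has_inr:
        ann.inr_variant = "G" if ann.base_plus2 == "G" else "nonG"
    return ann


@dataclass
class CombinationGroup:
    """Promoters sharing one element combination, with their half-lives."""

    label: str
    elements: frozenset[str]
    mode: str
    member_ids: list[str] = field(default_factory=list)
    halflives_min: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.member_ids)

    @property
    def median_min(self) -> float | None:
        if not self.halflives_min:
            return None
        import statistics
        return float(statistics.median(self.halflives_min))


def _default_combinations() -> list[frozenset[str]]:
    singles = [frozenset([f]) for f in COMBINATION_FEATURES]
    pairs = []
    feats = list(COMBINATION_FEATURES)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if {feats[i], feats[j]} == {"Inr-G", "Inr-nonG"}:
                continue  # mutually exclusive by construction
            pairs.append(frozenset([feats[i], feats[j]]))
    return singles + pairs


def group_by_combination(annotations: list[PromoterAnnotation],
                         halflives: list[HalfLifeRecord],
                         mode: str = "exclusive",
                         combinations: list[frozenset[str]] | None = None,
                         ) -> list[CombinationGroup]:
    """Group promoters by core-promoter-element combination.

    ``exclusive`` (mutually exclusive model): a promoter belongs to a
    combination only if it carries exactly those elements and no other.
    ``inclusive``: the listed elements must be present, any others are
    allowed.  Inclusive groups therefore contain their exclusive
    counterparts.
    """
    if mode not in ("exclusive", "inclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    hl = {r.promoter_id: r.halflife_min for r in halflives}
    combos = combinations if combinations is not None else _default_combinations()
    groups = []
    for combo in combos:
        label = "+".join(sorted(combo))
        g = CombinationGroup(label=label, elements=combo, mode=mode)
        for ann in annotations:
            if ann.promoter_id not in hl:
                continue
            feats = ann.features()
            member = feats == combo if mode == "exclusive" else combo <= feats
            if member:
                g.member_ids.append(ann.promoter_id)
                g.halflives_min.append(hl[ann.promoter_id])
        groups.append(g)
    return groups
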