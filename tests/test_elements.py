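"""Element annotation tests, checked against a brute-force IUPAC scanner."""

import itertools

import numpy as np
import pytest

from nexuspause import (
    ElementSpec,
    HalfLifeRecord,
    PipelineConfig,
    annotate_promoter,
    group_by_combination,
    iupac_mismatches,
    make_promoter,
    scan_element,
)
from nexuspause.coords import bio_to_index, index_to_bio
from nexuspause.elements import IUPAC_SETS, PromoterAnnotation


def brute_force_scan(sequence, tss_index, consensus, window_bio, max_mm=1):
    """Independent oracle: enumerate every start, count set-membership
    violations naively."""
    hits = []
    lo = bio_to_index(window_bio[0], tss_index)
    hi = bio_to_index(window_bio[1], tss_index)
    k = len(consensus)
    for start in range(lo, hi - k + 2):
        word = sequence[start:start + k]
        mm = 0
        for b, c in zip(word, consensus):
            allowed = IUPAC_SETS[c]
            if b not in allowed:
                mm += 1
        if mm <= max_mm:
            hits.append((index_to_bio(start, tss_index), mm))
    return sorted(hits)


class TestCoords:
    def test_no_zero_and_adjacency(self):
        assert index_to_bio(150, 150) == 1
        assert index_to_bio(149, 150) == -1
        assert bio_to_index(1, 150) == 150
        assert bio_to_index(-1, 150) == 149
        with pytest.raises(ValueError):
            bio_to_index(0, 150)

    def test_roundtrip(self):
        for idx in range(0, 300, 7):
            assert bio_to_index(index_to_bio(idx, 150), 150) == idx


class TestIupacMismatches:
    @pytest.mark.parametrize("seq,consensus,expected", [
        ("TCAGTT", "TCAKTY", 0),   # G in K={G,T}, T in Y={C,T}
        ("GTATAAAAG", "STATAWAWR", 0),
        ("TAAGTC", "TCAKTY", 1),   # single violation at the C position
        ("TCATTC", "TCAKTY", 0),   # T also satisfies K
        ("AAAAAA", "TCAKTY", 5),  # only the A position matches
        ("TCANTT", "TCAKTY", 1),   # N never matches
    ])
    def test_counts(self, seq, consensus, expected):
        assert iupac_mismatches(seq, consensus) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            iupac_mismatches("ACGT", "TCAKTY")

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            iupac_mismatches("ACGTAA", "TCAXTY")

    def test_exact_word_counts_by_exhaustive_enumeration(self):
        """|{6-mers matching TCAKTY exactly}| = |K||Y| = 4;
        |{9-mers matching STATAWAWR}| = |S||W||W||R| = 16."""
        for consensus, expected in (("TCAKTY", 4), ("STATAWAWR", 16)):
            n = sum(
                iupac_mismatches("".join(w), consensus) == 0
                for w in itertools.product("ACGT", repeat=len(consensus))
            )
            assert n == expected


class TestScanElement:
    def test_planted_tata_found_exactly(self):
        seq, _ = make_promoter([ElementSpec("TATA")], seed=3)
        hits = scan_element(seq, 150, "TATA", "STATAWAWR", (-40, -20))
        assert hits and hits[0].mismatches == 0
        assert hits[0].start_bio == -31

    def test_canonical_tata_insertion_with_flanks(self):
        # TATAAAA inserted 31 bp upstream; flanks complete STATAWAWR
        seq = list("ACGT" * 75)
        word = "GTATAAAAG"
        start = bio_to_index(-32, 150)
        seq[start:start + 9] = list(word)
        hits = scan_element("".join(seq), 150, "TATA", "STATAWAWR", (-40, -20))
        assert hits[0].mismatches == 0
        assert hits[0].matched_seq == word

    def test_all_A_sequence_has_no_tata_match(self):
        # STATAWAWR needs T at two fixed positions: >= 2 mismatches
        assert scan_element("A" * 300, 150, "TATA", "STATAWAWR", (-40, -20)) == []

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            tss = 80
            window = (-40, -20)
            mine = sorted(
                (m.start_bio, m.mismatches)
                for m in scan_element(seq, tss, "TATA", "STATAWAWR", window)
            )
            assert mine == brute_force_scan(seq, tss, "STATAWAWR", window)

    def test_best_match_sorted_first(self):
        seq = list("A" * 300)
        tss = 150
        # one perfect and one 1-mismatch initiator-like word in a wide window
        for start_bio, word in ((20, "TCAGTT"), (30, "TCAGTA")):
            i = bio_to_index(start_bio, tss)
            seq[i:i + 6] = list(word)
        hits = scan_element("".join(seq), tss, "INR", "TCAKTY", (15, 40))
        assert [h.mismatches for h in hits[:2]] == [0, 1]

    def test_window_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="window"):
            scan_element("ACGT" * 10, 20, "TATA", "STATAWAWR", (-40, -20))


class TestAnnotatePromoter:
    def test_planted_inr_g(self):
        seq, _ = make_promoter([ElementSpec("INR", force_plus2="G")], seed=5)
        ann = annotate_promoter("p", seq, 150)
        assert ann.has_inr and ann.inr_variant == "G" and ann.base_plus2 == "G"

    def test_planted_inr_nong(self):
        seq, _ = make_promoter([ElementSpec("INR", force_plus2="T")], seed=5)
        ann = annotate_promoter("p", seq, 150)
        assert ann.has_inr and ann.inr_variant == "nonG"

    def test_literal_tcagtt_and_tcattt_at_minus2(self):
        base = list("A" * 300)
        for word, variant in (("TCAGTT", "G"), ("TCATTT", "nonG")):
            seq = list(base)
            i = bio_to_index(-2, 150)
            seq[i:i + 6] = list(word)
            ann = annotate_promoter("p", "".join(seq), 150)
            assert ann.has_inr and ann.inr_variant == variant

    def test_base_plus2_recorded_without_inr(self):
        ann = annotate_promoter("p", "A" * 300, 150)
        assert not ann.has_inr
        assert ann.inr_variant == "absent"
        assert ann.base_plus2 == "A"

    def test_planting_scanning_roundtrip_all_kinds(self):
        seq, truth = make_promoter(
            [ElementSpec("TATA"), ElementSpec("INR", force_plus2="G"),
             ElementSpec("PAUSE")], seed=9)
        ann = annotate_promoter("p", seq, 150)
        assert ann.has_tata and ann.has_inr and ann.has_pause
        assert ann.features() == frozenset({"TATA", "Inr-G", "pausing"})

    def test_one_mismatch_plantings_are_recovered(self):
        rng = np.random.default_rng(17)
        found = 0
        n = 200
        for i in range(n):
            kind = ["TATA", "INR", "PAUSE"][i % 3]
            es = ElementSpec(kind, planted_mismatches=1)
            seq, _ = make_promoter([es], seed=int(rng.integers(2**31)))
            ann = annotate_promoter("p", seq, 150)
            found += getattr(ann, {"TATA": "has_tata", "INR": "has_inr",
                                   "PAUSE": "has_pause"}[kind])
        assert found == n

    def test_background_match_rate_is_low(self):
        """Element-free promoters rarely contain chance TATA/Inr/pause matches."""
        clean = 0
        for seed in range(200):
            seq, _ = make_promoter([], length=300, gc=0.5, seed=seed)
            ann = annotate_promoter("p", seq, 150)
            clean += not (ann.has_tata or ann.has_inr or ann.has_pause)
        # Inr is anchored to one hexamer window; TATA/pause windows are
        # short; chance hits at <=1 mismatch stay rare
        assert clean / 200 > 0.5

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            annotate_promoter("p", "ACGT" * 10, 20)

    def test_n_in_scanned_window_flagged(self):
        # N inside the TATA window (-40..-20 => indexes 110..130 for tss 150)
        seq = "A" * 120 + "N" + "A" * 179
        ann = annotate_promoter("p", seq, 150)
        assert ann.has_n_in_windows
        # N outside every scanned window leaves the flag unset
        seq2 = "A" * 50 + "N" + "A" * 249
        assert not annotate_promoter("p", seq2, 150).has_n_in_windows


def _ann(pid, tata=False, inr=None, pause=False):
    """Hand-built annotation carrying only combination features."""
    a = PromoterAnnotation(promoter_id=pid, sequence="", tss_index=0)
    a.has_tata = tata
    a.has_pause = pause
    if inr is not None:
        a.has_inr = True
        a.inr_variant = inr
    return a


class TestGroupByCombination:
    @pytest.fixture
    def toy(self):
        anns = [
            _ann("a", inr="G"),
            _ann("b", inr="G", pause=True),
            _ann("c", tata=True),
            _ann("d", tata=True, inr="G", pause=True),
            _ann("e", inr="nonG"),
            _ann("f", pause=True),
        ]
        hls = [HalfLifeRecord(p, 10.0 * (i + 1)) for i, p in enumerate("abcdef")]
        return anns, hls

    def test_exclusive_sizes_by_hand_enumeration(self, toy):
        anns, hls = toy
        groups = {g.label: g for g in group_by_combination(anns, hls, "exclusive")}
        assert groups["Inr-G"].member_ids == ["a"]
        assert groups["Inr-G+pausing"].member_ids == ["b"]
        assert groups["TATA"].member_ids == ["c"]
        assert groups["Inr-nonG"].member_ids == ["e"]
        assert groups["pausing"].member_ids == ["f"]
        # d carries three features: in no pairwise exclusive group
        assert all("d" not in g.member_ids for g in groups.values())

    def test_inclusive_contains_exclusive(self, toy):
        anns, hls = toy
        excl = {g.label: set(g.member_ids)
                for g in group_by_combination(anns, hls, "exclusive")}
        incl = {g.label: set(g.member_ids)
                for g in group_by_combination(anns, hls, "inclusive")}
        for label in excl:
            assert excl[label] <= incl[label]

    def test_triple_feature_promoter_in_inclusive_pair_only(self, toy):
        anns, hls = toy
        incl = {g.label: g for g in group_by_combination(anns, hls, "inclusive")}
        assert "d" in incl["Inr-G+TATA"].member_ids
        excl = {g.label: g for g in group_by_combination(anns, hls, "exclusive")}
        assert "d" not in excl["Inr-G+TATA"].member_ids

    def test_unknown_mode_rejected(self, toy):
        anns, hls = toy
        with pytest.raises(ValueError, match="mode"):
            group_by_combination(anns, hls, "both")

    def test_exclusive_groups_disjoint(self, toy):
        anns, hls = toy
        groups = group_by_combination(anns, hls, "exclusive")
        seen = [pid for g in groups for pid in g.member_ids]
        assert len(seen) == len(set(seen))
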