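import numpy as np
import pytest

from nexuspause import ElementSpec, ReadRecord, make_promoter


@pytest.fixture
def toy_reads():
    return [
        ReadRecord("rep", 10, "+", "CTGAAAAAA"),
        ReadRecord("rep", 10, "+", "CTGAAAAAA"),   # PCR duplicate of the first
        ReadRecord("rep", 10, "+", "TGACAAAAA"),   # same stop base, new molecule
        ReadRecord("rep", 40, "-", "GACTAAAAA"),
        ReadRecord("rep", 12, "+", "ACTGAAAAA", unique=False),
        ReadRecord("other", 5, "+", "CTGACCCCC"),
    ]


@pytest.fixture
def inr_g_promoter():
    seq, truth = make_promoter(
        [ElementSpec("INR", force_plus2="G")],
        length=300, tss_offset=150, gc=0.4, seed=11,
        true_halflife_min=60.0, promoter_id="rep",
    )
    return seq, truth


def random_reads(n, rng=None, reference="rep", max_pos=200):
    rng = rng or np.random.default_rng(0)
    barcodes = ["CTGA" + "".join(rng.choice(list("ACGT"), size=3)) for _ in range(n)]
    return [
        ReadRecord(
            reference,
            int(rng.integers(max_pos)),
            "+" if rng.random() < 0.5 else "-",
            barcodes[i],
        )
        for i in range(n)
    ]
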