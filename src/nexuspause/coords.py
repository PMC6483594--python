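"""Promoter coordinate conventions.

Biological promoter positions have no zero: the base 5' of the TSS is -1
and the TSS itself is +1.  All file formats and arrays use 0-based
half-open coordinates; biological positions exist only at the API and
report level.  ``tss_index`` is always the 0-based index of the +1 base.
"""

from __future__ import annotations


def index_to_bio(index: int, tss_index: int) -> int:
    """Convert a 0-based sequence index to a biological position."""
    offset = index - tss_index
    return offset + 1 if offset >= 0 else offset


def bio_to_index(pos: int, tss_index: int) -> int:
    """Convert a biological position (no zero) to a 0-based index."""
    if pos == 0:
        raise ValueError("biological position 0 does not exist (-1 precedes +1)")
    return tss_index + pos - 1 if pos > 0 else tss_index + pos
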