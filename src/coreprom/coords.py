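"""Promoter coordinate conventions.

Core sequences span positions -50..+50 relative to the transcription start
site with the TSS at +1 and **no position 0** (standard promoter-biology
numbering).  A 100-base core sequence therefore maps string index ``i`` to
promoter position ``i - 50`` for the upstream half (``i`` in 0..49) and
``i - 49`` for the downstream half (``i`` in 50..99).
"""

from __future__ import annotations

CORE_LEN = 100
CORE_START = -50  # first promoter position covered by the core sequence
CORE_END = 50     # last promoter position covered by the core sequence


def pos_to_index(pos: int) -> int:
    """Map a promoter position (-50..+50, no 0) to a core-sequence index."""
    if pos == 0 or pos < CORE_START or pos > CORE_END:
        raise ValueError(f"position {pos} outside core coordinates -50..+50 (no 0)")
    return pos + 50 if pos < 0 else pos + 49


def index_to_pos(i: int) -> int:
    """Map a core-sequence index (0..99) to a promoter position."""
    if not 0 <= i < CORE_LEN:
        raise ValueError(f"index {i} outside 0..{CORE_LEN - 1}")
    return i - 50 if i <= 49 else i - 49


def span_indices(start_pos: int, length: int) -> range:
    """Core-sequence index range of a motif occupying ``length`` consecutive
    promoter positions beginning at ``start_pos`` (skipping 0)."""
    i0 = pos_to_index(start_pos)
    if i0 + length > CORE_LEN:
        raise ValueError(
            f"span of length {length} at position {start_pos} leaves the core sequence"
        )
    return range(i0, i0 + length)
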