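"""TSS-anchored scanning of core-promoter elements.

Scans 100-base core sequences (positions -50..+50, TSS at +1, no 0) for the
seven element classes used throughout the analysis:

========== ========= =================================================
class      pattern   positional rule (transcribed strand)
========== ========= =================================================
TATA       TATAW     first T fixed at -31 (configurable +/- tolerance)
TATA_like  WWWW      any window fully inside -40..-20
BREu       SRCGCC    occupying -37..-32, exact match
BREu_like  SRCGCC    same window, at most one mismatch
BREd       RTDKKKK   occupying -25..-19, only scored when TATA present
INR        YYANWY    central A anywhere in -4..+5
DPE        RGWYVT    start anchored in +28..+32
========== ========= =================================================

All classes use presence/absence semantics per promoter (overlapping hits of
one class count once); every hit anchor is nonetheless recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import CORE_LEN, index_to_pos, pos_to_index

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

MOTIF_CLASSES = ("TATA", "TATA_like", "BREu", "BREu_like", "BREd", "INR", "DPE")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(seq: str, pattern: str, max_mismatch: int = 0) -> tuple[bool, int]:
    """Compare ``seq`` against an IUPAC ``pattern`` of the same length.

    A position mismatches iff the sequence base is not in the degenerate
    expansion of the pattern symbol.  Returns ``(matched, mismatches)`` with
    ``matched`` true iff the mismatch count is at most ``max_mismatch``.
    """
    if len(seq) != len(pattern):
        raise ValueError(f"sequence length {len(seq)} != pattern length {len(pattern)}")
    mm = 0
    for base, sym in zip(seq, pattern):
        try:
            allowed = IUPAC[sym]
        except KeyError:
            raise ValueError(f"non-IUPAC symbol {sym!r} in pattern {pattern!r}") from None
        if base not in allowed:
            if base not in "ACGT":
                raise ValueError(f"non-nucleotide symbol {base!r} in sequence")
            mm += 1
    return mm <= max_mismatch, mm


@dataclass(frozen=True)
class MotifDef:
    """One element class: IUPAC pattern plus its positional anchor rule.

    ``anchor`` semantics by ``anchor_kind``:
      * ``fixed``      — pattern start at exactly ``anchor[0]`` (+/- ``tolerance``)
      * ``start_window`` — pattern start anywhere in ``anchor`` (inclusive)
      * ``contained``  — whole pattern inside the ``anchor`` interval
      * ``base_window`` — pattern position ``anchor_base`` in ``anchor``
    ``requires`` names a class that must be present before this one is scored
    (BREd is only evaluated on TATA promoters).
    """

    name: str
    pattern: str
    anchor_kind: str
    anchor: tuple[int, int]
    max_mismatch: int = 0
    anchor_base: int = 0
    tolerance: int = 0
    requires: str | None = None

    def __post_init__(self):
        for sym in self.pattern:
            if sym not in IUPAC:
                raise ValueError(f"non-IUPAC symbol {sym!r} in pattern for {self.name}")

    def start_indices(self) -> list[int]:
        """Core-sequence indices at which a window may legally start."""
        L = len(self.pattern)
        if self.anchor_kind == "fixed":
            i0 = pos_to_index(self.anchor[0])
            starts = range(max(0, i0 - self.tolerance), i0 + self.tolerance + 1)
        elif self.anchor_kind == "start_window":
            starts = range(pos_to_index(self.anchor[0]), pos_to_index(self.anchor[1]) + 1)
        elif self.anchor_kind == "contained":
            lo, hi = pos_to_index(self.anchor[0]), pos_to_index(self.anchor[1])
            starts = range(lo, hi - L + 2)
        elif self.anchor_kind == "base_window":
            lo, hi = pos_to_index(self.anchor[0]), pos_to_index(self.anchor[1])
            starts = range(lo - self.anchor_base, hi - self.anchor_base + 1)
        else:
            raise ValueError(f"unknown anchor kind {self.anchor_kind!r}")
        return [s for s in starts if 0 <= s and s + L <= CORE_LEN]


def default_motif_defs(bred_max_mismatch: int = 0, tata_tolerance: int = 0) -> dict[str, MotifDef]:
    """The seven element classes with their standard windows.

    ``bred_max_mismatch`` exposes the relaxed one-mismatch BREd mode;
    ``tata_tolerance`` widens the fixed -31 TATA anchor by +/- that many bases.
    """
    return {
        "TATA": MotifDef("TATA", "TATAW", "fixed", (-31, -31), tolerance=tata_tolerance),
        "TATA_like": MotifDef("TATA_like", "WWWW", "contained", (-40, -20)),
        "BREu": MotifDef("BREu", "SRCGCC", "fixed", (-37, -37)),
        "BREu_like": MotifDef("BREu_like", "SRCGCC", "fixed", (-37, -37), max_mismatch=1),
        "BREd": MotifDef("BREd", "RTDKKKK", "fixed", (-25, -25),
                         max_mismatch=bred_max_mismatch, requires="TATA"),
        "INR": MotifDef("INR", "YYANWY", "base_window", (-4, 5), anchor_base=2),
        "DPE": MotifDef("DPE", "RGWYVT", "start_window", (28, 32)),
    }


@dataclass
class MotifAnnotation:
    """Per-promoter presence calls with hit anchors and mismatch counts."""

    promoter_id: str
    present: dict[str, bool] = field(default_factory=dict)
    hits: dict[str, list[int]] = field(default_factory=dict)  # anchor promoter positions
    mismatches: dict[str, int] = field(default_factory=dict)  # best (fewest) among hits

    def size(self, classes) -> int:
        return sum(bool(self.present.get(c)) for c in classes)


def scan_sequence(core_seq: str, mdef: MotifDef) -> tuple[list[int], int | None]:
    """All legal hit anchors of one class in a core sequence.

    Returns (anchor promoter positions, best mismatch count or None).
    """
    hits: list[int] = []
    best: int | None = None
    L = len(mdef.pattern)
    for i in mdef.start_indices():
        ok, mm = iupac_match(core_seq[i:i + L], mdef.pattern, mdef.max_mismatch)
        if ok:
            anchor_i = i + (mdef.anchor_base if mdef.anchor_kind == "base_window" else 0)
            hits.append(index_to_pos(anchor_i))
            best = mm if best is None else min(best, mm)
    return hits, best


def scan_promoter(rec, defs: dict[str, MotifDef] | None = None) -> MotifAnnotation:
    """Scan one promoter record for every element class.

    ``rec`` needs ``promoter_id`` and a valid 100-base ``core_seq`` stored in
    transcribed orientation.  Conditional classes (BREd) are scored absent
    when their prerequisite class is absent.
    """
    defs = defs if defs is not None else default_motif_defs()
    seq = rec.core_seq
    if len(seq) != CORE_LEN or any(b not in "ACGT" for b in seq):
        raise ValueError(f"promoter {rec.promoter_id}: malformed 100-base core sequence")
    ann = MotifAnnotation(promoter_id=rec.promoter_id)
    # two passes so `requires` can reference any unconditional class
    for name, mdef in defs.items():
        if mdef.requires is None:
            hits, best = scan_sequence(seq, mdef)
            ann.present[name] = bool(hits)
            ann.hits[name] = hits
            if best is not None:
                ann.mismatches[name] = best
    for name, mdef in defs.items():
        if mdef.requires is not None:
            if ann.present.get(mdef.requires, False):
                hits, best = scan_sequence(seq, mdef)
            else:
                hits, best = [], None
            ann.present[name] = bool(hits)
            ann.hits[name] = hits
            if best is not None:
                ann.mismatches[name] = best
    return ann


def scan_cohort(records, defs: dict[str, MotifDef] | None = None) -> list[MotifAnnotation]:
    defs = defs if defs is not None else default_motif_defs()
    return [scan_promoter(r, defs) for r in records]


def motif_frequency(annotations: list[MotifAnnotation],
                    classes=MOTIF_CLASSES) -> pd.DataFrame:
    """Per-class hit counts and percentages over a cohort.

    Also reports ``TATA_like_excl`` / ``BREu_like_excl``: like-class carriers
    that are not consensus carriers, for pie-chart style exclusive tallies.
    """
    if not annotations:
        raise ValueError("no annotations")
    n = len(annotations)
    rows = []
    for c in classes:
        k = sum(bool(a.present.get(c)) for a in annotations)
        rows.append((c, k, 100.0 * k / n))
    for like, cons in (("TATA_like", "TATA"), ("BREu_like", "BREu")):
        if like in classes and cons in classes:
            k = sum(bool(a.present.get(like)) and not a.present.get(cons) for a in annotations)
            rows.append((f"{like}_excl", k, 100.0 * k / n))
    return pd.DataFrame(rows, columns=["motif", "count", "percent"]).set_index("motif")


def gc_content(records, region: tuple[int, int] = (-50, 50)) -> float:
    """Pooled G+C fraction of a promoter-coordinate interval over a cohort."""
    lo, hi = region
    if lo > hi:
        raise ValueError("empty region")
    ilo, ihi = pos_to_index(lo), pos_to_index(hi)
    gc = total = 0
    for rec in records:
        piece = rec.core_seq[ilo:ihi + 1]
        gc += piece.count("G") + piece.count("C")
        total += len(piece)
    if total == 0:
        raise ValueError("no records")
    return gc / total


def nucleotide_frequency_matrix(records) -> pd.DataFrame:
    """100 x 4 base-frequency table indexed by promoter position; rows sum to 1."""
    if not records:
        raise ValueError("no records")
    counts = np.zeros((CORE_LEN, 4))
    order = {b: j for j, b in enumerate("ACGT")}
    for rec in records:
        for i, b in enumerate(rec.core_seq):
            counts[i, order[b]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, columns=list("ACGT"),
                        index=pd.Index([index_to_pos(i) for i in range(CORE_LEN)],
                                       name="position"))
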