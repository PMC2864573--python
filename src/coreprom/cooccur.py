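"""Motif combination counting and co-occurrence fractions.

The default class set collapses consensus and like classes into four groups
(TATA-class = TATA or TATA-like, BREu-class = BREu or BREu-like, INR, DPE):
reported "at least one core promoter motif" frequencies are only consistent
with like-motifs counting toward the tally.  The raw seven-class tally is
available by passing ``classes`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .motifscan import MOTIF_CLASSES, MotifAnnotation

COLLAPSED_CLASSES = {
    "TATA_class": ("TATA", "TATA_like"),
    "BREu_class": ("BREu", "BREu_like"),
    "INR": ("INR",),
    "DPE": ("DPE",),
}


def _presence(ann: MotifAnnotation, cls) -> bool:
    members = COLLAPSED_CLASSES.get(cls, (cls,))
    for m in members:
        if m not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {m!r}")
    return any(ann.present.get(m, False) for m in members)


@dataclass
class CombinationReport:
    classes: tuple
    sizes: pd.Series          # per promoter_id: number of present classes
    histogram: pd.Series      # combination size -> promoter count (0,1,2,>=3)
    class_counts: pd.Series   # per class: carrier count
    pair_counts: pd.DataFrame  # class x class carrier-intersection counts
    n_promoters: int

    def count_at_least(self, k: int) -> int:
        return int((self.sizes >= k).sum())

    def count_exactly(self, k: int) -> int:
        return int((self.sizes == k).sum())


def combination_counts(annotations: list[MotifAnnotation],
                       classes=tuple(COLLAPSED_CLASSES)) -> CombinationReport:
    """Per-promoter motif-combination sizes and their cohort histogram.

    ``classes`` may mix collapsed groups (``TATA_class``, ``BREu_class``)
    with raw scanner classes.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    if not annotations:
        raise ValueError("no annotations")
    flags = pd.DataFrame(
        {cls: [_presence(a, cls) for a in annotations] for cls in classes},
        index=pd.Index([a.promoter_id for a in annotations], name="promoter_id"))
    sizes = flags.sum(axis=1).rename("combination_size")
    max_size = len(classes)
    histogram = pd.Series(
        {k: int((sizes == k).sum()) for k in range(max_size + 1)},
        name="n_promoters")
    class_counts = flags.sum(axis=0).rename("carriers")
    pair = pd.DataFrame(
        flags.T.astype(int) @ flags.astype(int),
        index=list(classes), columns=list(classes))
    return CombinationReport(tuple(classes), sizes, histogram, class_counts,
                             pair, len(annotations))


def cooccur_fraction(annotations: list[MotifAnnotation],
                     reference: str, second: str) -> float:
    """Percentage of reference-motif promoters also carrying the second motif
    (the reference set alone is 100%)."""
    ref = [a for a in annotations if _presence(a, reference)]
    if not ref:
        raise ValueError(f"no promoter carries the reference class {reference!r}")
    both = sum(_presence(a, second) for a in ref)
    return 100.0 * both / len(ref)


def cooccur_matrix(annotations: list[MotifAnnotation],
                   classes=MOTIF_CLASSES) -> pd.DataFrame:
    """Carrier-intersection counts for every class pair (symmetric); the
    diagonal holds per-class carrier counts."""
    flags = pd.DataFrame(
        {cls: [_presence(a, cls) for a in annotations] for cls in classes}).astype(int)
    return pd.DataFrame(flags.T @ flags, index=list(classes), columns=list(classes))
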