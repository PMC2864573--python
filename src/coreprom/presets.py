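"""Shipped cohort blueprints.

Each preset encodes the motif composition of one promoter group from the
study as exact integer planting counts, so that fixture-mode generation
followed by scanning reproduces the group's reported percentages:

* ``top100``          — the 100 most strongly TFIIB-bound promoters
                        (TATA 24, TATA-like 66 total, INR 17, BREu 3,
                        BREu-like 17 total).
* ``high_tfiib``      — upper 5th percentile of TFIIB occupancy (TATA 5,
                        TATA-like 29, BREu 2, BREu-like 19, INR 12; 61% GC).
* ``low_tfiib``       — 45th-50th percentile (n=500 so the 1.4% TATA
                        frequency is an exact count of 7; 62% GC).
* ``tfiib_dominated`` — top 100 genes by TFIIB/NC2 ratio (TATA 39, TATA-like
                        63 total, BREu 6, INR 20, DPE 11; at least one of the
                        four collapsed classes in 81, exactly two in 27,
                        three in 11).
* ``nc2_dominated``   — top 100 genes by NC2/TFIIB ratio (TATA 1, sparse
                        elements, GC-rich background, no triple combinations).
* ``cooccur_inr``     — 100 INR promoters, 94 also TATA-like, 56 also TATA.
* ``cooccur_dpe``     — 100 DPE promoters, 89 also TATA-like, 67 also TATA.
* ``profile_minus50`` — no plantings; narrow PIC footprint centered at -50
                        for binding-profile mode recovery.

Anchor choices are canonical: TATA at -31, standalone TATA-like W-runs at
-26 (clear of both the BREu window and the TATA anchor), BREu/BREu-like at
-37, INR with its central A at +1, DPE at +30.
"""

from __future__ import annotations

from .synthcohort import CohortBlueprint, Footprint, OccupancyModel

_ANCHORS = {"TATA": -31, "TATA_like": -26, "BREu": -37, "BREu_like": -37,
            "INR": 1, "DPE": 30}

PRESET_NAMES = ("top100", "high_tfiib", "low_tfiib", "tfiib_dominated",
                "nc2_dominated", "cooccur_inr", "cooccur_dpe", "profile_minus50")


def _plant(cls, indices):
    a = _ANCHORS[cls]
    return [(i, cls, a) for i in indices]


def _scale_indices(indices, n_from: int, n_to: int):
    """Proportionally rescale a planting index set when a preset is generated
    at a different cohort size (used for stochastic recoveries at large n)."""
    k = round(len(indices) * n_to / n_from)
    lo = min(indices)
    return range(round(lo * n_to / n_from), round(lo * n_to / n_from) + k)


def _spec(name: str) -> dict:
    if name == "top100":
        return dict(n=100, gc=0.61, plants=(
            _plant("TATA", range(0, 24)) + _plant("TATA_like", range(24, 66))
            + _plant("BREu", range(0, 3)) + _plant("BREu_like", range(3, 17))
            + _plant("INR", range(0, 17))))
    if name == "high_tfiib":
        return dict(n=100, gc=0.61, plants=(
            _plant("TATA", range(0, 5)) + _plant("TATA_like", range(5, 29))
            + _plant("BREu", range(0, 2)) + _plant("BREu_like", range(2, 19))
            + _plant("INR", range(0, 12))))
    if name == "low_tfiib":
        return dict(n=500, gc=0.62, plants=(
            _plant("TATA", range(0, 7)) + _plant("TATA_like", range(7, 100))
            + _plant("BREu", range(0, 12)) + _plant("BREu_like", range(12, 105))
            + _plant("INR", range(0, 50))))
    if name == "tfiib_dominated":
        # joint design: triples 0-10, pairs 11-37, singles 38-80, empty 81-99
        return dict(n=100, gc=0.55, focused=0.69, cage_mean=948.0, plants=(
            _plant("TATA", range(0, 39)) + _plant("TATA_like", range(39, 63))
            + _plant("BREu", range(0, 6))
            + _plant("BREu_like", [6, 7, *range(11, 31), *range(63, 71)])
            + _plant("INR", [*range(0, 4), *range(8, 11), *range(31, 36), *range(71, 79)])
            + _plant("DPE", [*range(4, 11), 36, 37, 79, 80])))
    if name == "nc2_dominated":
        # pairs 0-3, singles 4-37, empty 38-99; no triples
        return dict(n=100, gc=0.65, focused=0.32, cage_mean=279.0, plants=(
            _plant("TATA", [0]) + _plant("TATA_like", range(1, 16))
            + _plant("BREu", [2]) + _plant("BREu_like", [3, *range(16, 26)])
            + _plant("INR", [0, 1, *range(26, 37)]) + _plant("DPE", [37])))
    if name == "cooccur_inr":
        return dict(n=100, gc=0.55, plants=(
            _plant("INR", range(0, 100)) + _plant("TATA", range(0, 56))
            + _plant("TATA_like", range(56, 94))))
    if name == "cooccur_dpe":
        return dict(n=100, gc=0.55, plants=(
            _plant("DPE", range(0, 100)) + _plant("TATA", range(0, 67))
            + _plant("TATA_like", range(67, 89))))
    if name == "profile_minus50":
        return dict(n=200, gc=0.61, plants=[],
                    footprint=Footprint(center=-50.0, spread=15.0))
    raise KeyError(name)


def load_preset(name: str, n: int | None = None, seed: int = 0) -> CohortBlueprint:
    """Blueprint for a shipped preset.

    ``n`` overrides the preset's cohort size; planting counts are rescaled
    proportionally (exact compositions are only guaranteed at the native n).
    """
    try:
        spec = _spec(name)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    n_native = spec["n"]
    plants = spec["plants"]
    if n is not None and n != n_native:
        scaled = []
        by_cls: dict[str, list[int]] = {}
        for idx, cls, _ in plants:
            by_cls.setdefault(cls, []).append(idx)
        for cls, idxs in by_cls.items():
            for i in _scale_indices(idxs, n_native, n):
                scaled.append((i, cls, _ANCHORS[cls]))
        plants, n_native = scaled, n
    return CohortBlueprint(
        n_promoters=n_native,
        background_gc=spec["gc"],
        motif_table=list(plants),
        footprint=spec.get("footprint", Footprint()),
        focused_fraction=spec.get("focused", 0.6),
        cage_mean_tags=spec.get("cage_mean", 500.0),
        occupancy_model=OccupancyModel(),
        seed=seed,
        name=name,
    )
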