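"""Seeded synthetic promoter cohorts.

Emulates the data structure of a promoter tiling-array occupancy study:
100-base TSS-anchored core sequences with planted core-promoter elements,
15-probe probesets tiling ~1.5 kb around each TSS carrying two-factor
(TFIIB/NC2) log2 ChIP/input signals with a PIC footprint, expression values
monotonically coupled to occupancy, and CAGE-like tag-count vectors with
focused or dispersed start-site shapes.

Fixture mode (``scrub=True``, the default) enforces a plant-then-scrub
contract: background windows that accidentally match any scanned element
class at a legal scan position are resampled until no unplanned hit remains,
with planted bases frozen.  Scanner counts on such a cohort equal the
planted counts exactly, so preset cohorts can encode printed motif
compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import CORE_LEN, pos_to_index
from .motifscan import IUPAC, MotifDef, default_motif_defs, iupac_match

FACTORS = ("TFIIB", "NC2")
REPLICATES = (1, 2)
PROBE_OFFSETS = tuple(range(-700, 701, 100))  # 15 probes tiling 1.5 kb

MAX_SCRUB_ROUNDS = 200
MAX_PLANT_RETRIES = 50


class BlueprintError(ValueError):
    """A cohort blueprint violates one of its invariants."""


class ScrubError(RuntimeError):
    """Background scrubbing failed to converge; no partial fixture is returned."""


@dataclass
class OccupancyModel:
    """Bivariate log-normal promoter occupancy: per-factor location/spread on
    the log2 scale with an inter-factor correlation."""

    loc: dict = field(default_factory=lambda: {"TFIIB": 1.0, "NC2": 1.0})
    spread: dict = field(default_factory=lambda: {"TFIIB": 1.0, "NC2": 1.0})
    correlation: float = 0.8


@dataclass
class ExpressionModel:
    """Expression = coeff * log2-occupancy(TFIIB) + Gaussian noise; a fraction
    of probesets carries an Affymetrix-style 'present' detection call."""

    coeff: float = 1.0
    noise_sd: float = 0.5
    present_rate: float = 0.9


@dataclass
class Footprint:
    """Gaussian PIC footprint over probe offsets: the log2 probe signal is
    occupancy times the footprint density (max-normalized) at the probe's
    TSS offset."""

    center: float = -50.0
    spread: float = 150.0
    baseline: float = 0.0

    def density(self, offsets) -> np.ndarray:
        o = np.asarray(offsets, dtype=float)
        return np.exp(-((o - self.center) ** 2) / (2.0 * self.spread ** 2))


@dataclass
class CohortBlueprint:
    """Full generative specification of one synthetic cohort."""

    n_promoters: int
    background_gc: float = 0.55
    motif_table: list = field(default_factory=list)  # (promoter_index, class, anchor_pos)
    occupancy_model: OccupancyModel = field(default_factory=OccupancyModel)
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    footprint: Footprint = field(default_factory=Footprint)
    replicate_noise: float = 0.3
    tss_shape_table: list | None = None  # per-promoter 'focused'/'dispersed'
    focused_fraction: float = 0.6
    cage_mean_tags: float = 500.0
    seed: int = 0
    scrub: bool = True
    name: str = "custom"


@dataclass
class PromoterRecord:
    """One TSS-anchored promoter; ``core_seq`` is stored in transcribed
    orientation and covers positions -50..+50 (TSS at +1, no position 0)."""

    promoter_id: str
    strand: str
    core_seq: str
    probe_offsets: tuple = PROBE_OFFSETS


@dataclass
class SyntheticCohort:
    promoters: list
    signals: pd.DataFrame      # promoter_id, probe_index, offset, factor, replicate, log2_ratio
    occupancy: pd.DataFrame    # promoter_id x factor, latent log2 occupancy
    expression: pd.DataFrame   # promoter_id, signal, present
    cage_tags: dict            # promoter_id -> {position: count}
    tss_shapes: dict           # promoter_id -> 'focused' | 'dispersed'
    truth: CohortBlueprint

    @property
    def promoter_ids(self) -> list:
        return [p.promoter_id for p in self.promoters]


# ---------------------------------------------------------------------------
# blueprint validation

def _legal_anchor(cls: str, anchor: int, defs: dict[str, MotifDef]) -> bool:
    """Anchor is the pattern start, or the anchored base for base_window
    classes (INR), in promoter coordinates."""
    mdef = defs[cls]
    try:
        i = pos_to_index(anchor)
    except ValueError:
        return False
    if mdef.anchor_kind == "base_window":
        return i in {s + mdef.anchor_base for s in mdef.start_indices()}
    return i in set(mdef.start_indices())


def _planted_span(cls: str, anchor: int, defs: dict[str, MotifDef]) -> range:
    mdef = defs[cls]
    L = len(mdef.pattern)
    i0 = pos_to_index(anchor)
    if mdef.anchor_kind == "base_window":
        i0 -= mdef.anchor_base
    return range(i0, i0 + L)


def validate_blueprint(bp: CohortBlueprint, defs: dict[str, MotifDef] | None = None) -> None:
    defs = defs if defs is not None else default_motif_defs()
    if bp.n_promoters < 1:
        raise BlueprintError("n_promoters must be >= 1")
    if not 0.0 <= bp.background_gc <= 1.0:
        raise BlueprintError("background_gc must lie in [0, 1]")
    if not -1.0 <= bp.occupancy_model.correlation <= 1.0:
        raise BlueprintError("occupancy correlation must lie in [-1, 1]")
    if bp.tss_shape_table is not None and len(bp.tss_shape_table) != bp.n_promoters:
        raise BlueprintError("tss_shape_table length must equal n_promoters")
    per_prom: dict[int, list] = {}
    for entry in bp.motif_table:
        idx, cls, anchor = entry
        if cls not in defs:
            raise BlueprintError(f"unknown motif class {cls!r}")
        if not 0 <= idx < bp.n_promoters:
            raise BlueprintError(f"promoter index {idx} outside cohort of {bp.n_promoters}")
        if not _legal_anchor(cls, anchor, defs):
            raise BlueprintError(
                f"anchor {anchor} is outside the legal scan window of class {cls}")
        per_prom.setdefault(idx, []).append((cls, anchor))
    for idx, plants in per_prom.items():
        classes = [c for c, _ in plants]
        if len(set(classes)) != len(classes):
            raise BlueprintError(f"promoter {idx}: class planted twice")
        if "BREd" in classes and "TATA" not in classes:
            raise BlueprintError(
                f"promoter {idx}: BREd planted without TATA "
                "(violates: BREd is only scored on TATA promoters)")
        spans = {c: set(_planted_span(c, a, defs)) for c, a in plants}
        items = list(spans.items())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if items[i][1] & items[j][1]:
                    raise BlueprintError(
                        f"promoter {idx}: planted windows of {items[i][0]} and "
                        f"{items[j][0]} overlap")


# ---------------------------------------------------------------------------
# sequence generation

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_BASES = np.array(list("ACGT"))


def _instantiate(pattern: str, rng: np.random.Generator, gc: float,
                 force_mismatches: int = 0) -> str:
    """Draw a concrete instance of an IUPAC pattern.  Degenerate symbols are
    resolved uniformly (N from the background composition); if
    ``force_mismatches`` is set, exactly that many positions are mutated to a
    base outside their symbol's expansion."""
    out = []
    for sym in pattern:
        allowed = sorted(IUPAC[sym])
        if sym == "N":
            out.append(str(rng.choice(_BASES, p=_base_probs(gc))))
        else:
            out.append(allowed[rng.integers(len(allowed))])
    if force_mismatches:
        positions = rng.choice(len(pattern), size=force_mismatches, replace=False)
        for p in np.atleast_1d(positions):
            bad = sorted(set("ACGT") - IUPAC[pattern[p]])
            out[p] = bad[rng.integers(len(bad))]
    return "".join(out)


def _allowed_classes(planted: set[str]) -> set[str]:
    allowed = set(planted)
    if "TATA" in planted:
        allowed.add("TATA_like")   # TATAW is itself a W-run inside -40..-20
    if "BREu" in planted:
        allowed.add("BREu_like")
    return allowed


def _generate_core_seq(plants: list, rng: np.random.Generator, gc: float,
                       defs: dict[str, MotifDef], scrub: bool) -> str:
    """One core sequence with the given (class, anchor) plantings.

    Retries instantiation when a planted instance itself constitutes an
    unplanned hit on a fully frozen window, then scrubs the background.
    """
    planted_classes = {c for c, _ in plants}
    allowed = _allowed_classes(planted_classes)
    for _ in range(MAX_PLANT_RETRIES):
        seq = rng.choice(_BASES, size=CORE_LEN, p=_base_probs(gc)).astype("U1")
        frozen = np.zeros(CORE_LEN, dtype=bool)
        for cls, anchor in plants:
            mdef = defs[cls]
            force = 1 if cls == "BREu_like" else 0
            inst = _instantiate(mdef.pattern, rng, gc, force_mismatches=force)
            span = _planted_span(cls, anchor, defs)
            for k, i in enumerate(span):
                seq[i] = inst[k]
                frozen[i] = True
        if not scrub:
            return "".join(seq)
        frozen_conflict = _has_frozen_conflict(seq, frozen, allowed, defs)
        if frozen_conflict:
            continue  # re-instantiate the plantings
        _scrub(seq, frozen, allowed, rng, gc, defs)
        return "".join(seq)
    raise ScrubError("planted instances kept producing unplanned hits on frozen windows")


def _iter_disallowed(seq, allowed: set[str], defs: dict[str, MotifDef]):
    """Yield (class, start_index, length) of every unplanned hit at a legal
    scan position.  Conditional classes are only checked when their
    prerequisite is allowed (a scrubbed prerequisite is absent anyway)."""
    s = "".join(seq)
    for name, mdef in defs.items():
        if name in allowed:
            continue
        if mdef.requires is not None and mdef.requires not in allowed:
            continue
        L = len(mdef.pattern)
        for i in mdef.start_indices():
            ok, _ = iupac_match(s[i:i + L], mdef.pattern, mdef.max_mismatch)
            if ok:
                yield name, i, L


def _has_frozen_conflict(seq, frozen, allowed, defs) -> bool:
    for _, i, L in _iter_disallowed(seq, allowed, defs):
        if frozen[i:i + L].all():
            return True
    return False


def _scrub(seq, frozen, allowed, rng, gc, defs) -> None:
    probs = _base_probs(gc)
    for _ in range(MAX_SCRUB_ROUNDS):
        dirty = False
        for _, i, L in _iter_disallowed(seq, allowed, defs):
            free = [j for j in range(i, i + L) if not frozen[j]]
            if not free:
                raise ScrubError(
                    "unplanned hit on a fully frozen window cannot be repaired")
            for j in free:
                seq[j] = rng.choice(_BASES, p=probs)
            dirty = True
        if not dirty:
            return
    raise ScrubError(f"scrubbing did not converge within {MAX_SCRUB_ROUNDS} rounds")


# ---------------------------------------------------------------------------
# cohort generation

def sample_footprint_offsets(footprint: Footprint, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` probe offsets (bp, integers) from the footprint density."""
    return np.rint(rng.normal(footprint.center, footprint.spread, size=n)).astype(int)


def generate_cohort(bp: CohortBlueprint,
                    defs: dict[str, MotifDef] | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from a blueprint.

    Deterministic given ``bp.seed``.  In fixture mode every scanner count on
    the result equals the planted count (plant-then-scrub); scrub failure
    raises :class:`ScrubError` rather than returning a partial cohort.
    """
    defs = defs if defs is not None else default_motif_defs()
    validate_blueprint(bp, defs)
    ss = np.random.SeedSequence(bp.seed)
    seq_rng, occ_rng, sig_rng, expr_rng, tag_rng, shape_rng = (
        np.random.default_rng(s) for s in ss.spawn(6))

    n = bp.n_promoters
    ids = [f"prom{idx:05d}" for idx in range(n)]
    strands = np.where(seq_rng.random(n) < 0.5, "+", "-")

    per_prom: dict[int, list] = {}
    for idx, cls, anchor in bp.motif_table:
        per_prom.setdefault(idx, []).append((cls, anchor))
    promoters = []
    for idx in range(n):
        seq = _generate_core_seq(per_prom.get(idx, []), seq_rng,
                                 bp.background_gc, defs, bp.scrub)
        promoters.append(PromoterRecord(ids[idx], str(strands[idx]), seq))

    # latent log2 occupancy, bivariate normal across the two factors
    om = bp.occupancy_model
    rho = om.correlation
    cov = np.array([
        [om.spread["TFIIB"] ** 2, rho * om.spread["TFIIB"] * om.spread["NC2"]],
        [rho * om.spread["TFIIB"] * om.spread["NC2"], om.spread["NC2"] ** 2]])
    z = occ_rng.multivariate_normal([om.loc["TFIIB"], om.loc["NC2"]], cov, size=n)
    occupancy = pd.DataFrame(z, columns=list(FACTORS), index=pd.Index(ids, name="promoter_id"))

    dens = bp.footprint.density(PROBE_OFFSETS)
    rows = []
    for f_i, factor in enumerate(FACTORS):
        mean = bp.footprint.baseline + np.outer(z[:, f_i], dens)  # n x 15
        for rep in REPLICATES:
            vals = mean + sig_rng.normal(0.0, bp.replicate_noise, size=mean.shape)
            for pi in range(n):
                for probe_index, off in enumerate(PROBE_OFFSETS):
                    rows.append((ids[pi], probe_index, off, factor, rep,
                                 vals[pi, probe_index]))
    signals = pd.DataFrame(rows, columns=["promoter_id", "probe_index", "offset",
                                          "factor", "replicate", "log2_ratio"])

    em = bp.expression_model
    expr_vals = em.coeff * z[:, 0] + expr_rng.normal(0.0, em.noise_sd, size=n)
    present = expr_rng.random(n) < em.present_rate
    expression = pd.DataFrame({"promoter_id": ids, "signal": expr_vals,
                               "present": present})

    if bp.tss_shape_table is not None:
        shapes = list(bp.tss_shape_table)
    else:
        shapes = ["focused" if u < bp.focused_fraction else "dispersed"
                  for u in shape_rng.random(n)]
    cage: dict[str, dict[int, int]] = {}
    for pid, shape in zip(ids, shapes):
        total = 1 + int(tag_rng.poisson(max(bp.cage_mean_tags - 1, 0)))
        cage[pid] = _cage_vector(total, shape)
    tss_shapes = dict(zip(ids, shapes))

    return SyntheticCohort(promoters, signals, occupancy, expression, cage,
                           tss_shapes, bp)


def _cage_vector(total: int, shape: str) -> dict[int, int]:
    """Tag counts by TSS-relative position.  Focused: one dominant site at +1
    holding >=80% of tags.  Dispersed: three modes >=25 bp apart, each 20-40%
    of tags."""
    if shape == "focused":
        dom = max(int(round(0.85 * total)), 1)
        rest = total - dom
        v = {1: dom}
        if rest:
            v[-1] = rest - rest // 2
            v[2] = rest // 2
        return {k: c for k, c in v.items() if c > 0}
    if shape == "dispersed":
        n1 = int(round(0.35 * total))
        n2 = int(round(0.35 * total))
        n3 = total - n1 - n2
        return {k: c for k, c in zip((-60, -20, 30), (n1, n2, n3)) if c > 0}
    raise BlueprintError(f"unknown TSS shape label {shape!r}")


def cohort_digest(cohort: SyntheticCohort) -> bytes:
    """Stable byte serialization of a cohort, for determinism checks."""
    parts = []
    for p in cohort.promoters:
        parts.append(f"{p.promoter_id}\t{p.strand}\t{p.core_seq}")
    parts.append(cohort.signals.round(12).to_csv(index=False))
    parts.append(cohort.occupancy.round(12).to_csv())
    parts.append(cohort.expression.round(12).to_csv(index=False))
    for pid in sorted(cohort.cage_tags):
        tags = ",".join(f"{k}:{v}" for k, v in sorted(cohort.cage_tags[pid].items()))
        parts.append(f"{pid}\t{cohort.tss_shapes[pid]}\t{tags}")
    return "\n".join(parts).encode()
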