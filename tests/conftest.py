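import numpy as np
import pytest

from coreprom import motifscan
from coreprom.presets import load_preset
from coreprom.synthcohort import CohortBlueprint, generate_cohort

# canonical planting anchors reused across tests (clear of each other's windows)
ANCHORS = {"TATA": -31, "TATA_like": -26, "BREu": -37, "BREu_like": -37,
           "BREd": -25, "INR": 1, "DPE": 30}


def make_blueprint(plantings, n=None, gc=0.5, seed=0, **kw) -> CohortBlueprint:
    """plantings: list of per-promoter class lists, e.g. [["TATA"], [], ["INR"]]."""
    n = len(plantings) if n is None else n
    table = [(i, cls, ANCHORS[cls]) for i, classes in enumerate(plantings)
             for cls in classes]
    return CohortBlueprint(n_promoters=n, background_gc=gc, motif_table=table,
                           seed=seed, **kw)


@pytest.fixture(scope="session")
def top100_cohort():
    return generate_cohort(load_preset("top100", seed=11))


@pytest.fixture(scope="session")
def top100_annotations(top100_cohort):
    return motifscan.scan_cohort(top100_cohort.promoters)


@pytest.fixture(scope="session")
def dominated_cohort():
    return generate_cohort(load_preset("tfiib_dominated", seed=11))


@pytest.fixture(scope="session")
def dominated_annotations(dominated_cohort):
    return motifscan.scan_cohort(dominated_cohort.promoters)


def random_seq(rng, gc=0.5, length=100) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


# --- independent brute-force scanner oracle -------------------------------
# Re-derives every class call from the literal positional rules, enumerating
# all windows directly over promoter positions; shares no code with
# coreprom.motifscan beyond the (spec-level) position<->index convention.

_EXP = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "D": "AGT", "V": "ACG", "N": "ACGT"}


def _oidx(pos):
    return pos + 50 if pos < 0 else pos + 49


def _omm(seq, i, pattern):
    return sum(seq[i + k] not in _EXP[s] for k, s in enumerate(pattern))


def brute_scan(seq: str) -> dict:
    """Presence of the seven classes by exhaustive window enumeration."""
    out = {}
    out["TATA"] = _omm(seq, _oidx(-31), "TATAW") == 0
    positions = [p for p in range(-50, 51) if p != 0]
    tl = False
    for s in range(len(positions) - 3):
        window = positions[s:s + 4]
        if all(-40 <= p <= -20 for p in window):
            if all(seq[_oidx(p)] in "AT" for p in window):
                tl = True
    out["TATA_like"] = tl
    out["BREu"] = _omm(seq, _oidx(-37), "SRCGCC") == 0
    out["BREu_like"] = _omm(seq, _oidx(-37), "SRCGCC") <= 1
    out["BREd"] = out["TATA"] and _omm(seq, _oidx(-25), "RTDKKKK") == 0
    inr = False
    for a_pos in [p for p in range(-4, 6) if p != 0]:
        start = _oidx(a_pos) - 2
        if 0 <= start and start + 6 <= 100 and _omm(seq, start, "YYANWY") == 0:
            inr = True
    out["INR"] = inr
    dpe = False
    for s_pos in range(28, 33):
        if _omm(seq, _oidx(s_pos), "RGWYVT") == 0:
            dpe = True
    out["DPE"] = dpe
    return out


@pytest.fixture(scope="session")
def sampling_cohort():
    """Large motif-free cohort in sampling mode (no scrubbing) for the
    occupancy/expression statistics."""
    bp = CohortBlueprint(n_promoters=2000, background_gc=0.55, seed=31,
                         scrub=False)
    return generate_cohort(bp)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
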