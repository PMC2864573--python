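"""Tiling-array signal processing.

Probe-level log2 ChIP/input ratios are centered by subtracting the Tukey
biweight mean of all probes on the array; the median of each promoter's
15-probe probeset is its occupancy score.  Peaks are maximal runs of
consecutive positions exceeding mean + k standard deviations; TSS-aligned
average binding profiles report the fraction of high-score probes per 10-bp
bin corrected for probe availability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SignalTrack:
    """Per-probe signal values for one factor/replicate.

    ``df`` columns: promoter_id, probe_index, offset, value.  Offsets are
    strand-oriented (negative = upstream of the TSS).
    """

    df: pd.DataFrame
    scaled: bool = False

    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()


def track_from_signals(signals: pd.DataFrame, factor: str, replicate: int) -> SignalTrack:
    """Extract one factor/replicate layer of a cohort signal table."""
    sub = signals[(signals["factor"] == factor) & (signals["replicate"] == replicate)]
    if sub.empty:
        raise ValueError(f"no signals for factor={factor!r} replicate={replicate}")
    df = sub[["promoter_id", "probe_index", "offset", "log2_ratio"]].rename(
        columns={"log2_ratio": "value"}).reset_index(drop=True)
    return SignalTrack(df)


def biweight_mean(values, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate.

    With M the median and S the median absolute deviation, weights are
    w_i = (1 - u_i^2)^2 for |u_i| < 1 (else 0) where u_i = (x_i - M)/(c*S + eps);
    the result is the weighted mean, falling back to M when every weight is 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight_mean of empty input")
    m = float(np.median(x))
    s = float(np.median(np.abs(x - m)))
    u = (x - m) / (c * s + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    if w.sum() == 0.0:
        return m
    return float(np.sum(w * x) / np.sum(w))


def scale_track(track: SignalTrack, c: float = 5.0, eps: float = 1e-4) -> SignalTrack:
    """Center a track by subtracting the biweight mean of all probe values."""
    shift = biweight_mean(track.values(), c=c, eps=eps)
    df = track.df.copy()
    df["value"] = df["value"] - shift
    return SignalTrack(df, scaled=True)


def promoter_score(track: SignalTrack, promoter_id: str, n_probes: int = 15) -> float:
    """Median of one promoter's probeset values."""
    vals = track.df.loc[track.df["promoter_id"] == promoter_id, "value"]
    if len(vals) != n_probes:
        raise ValueError(
            f"promoter {promoter_id}: expected {n_probes} probes, found {len(vals)}")
    return float(vals.median())


def promoter_scores(track: SignalTrack, n_probes: int = 15) -> pd.Series:
    """Median probeset score for every promoter in the track."""
    counts = track.df.groupby("promoter_id").size()
    bad = counts[counts != n_probes]
    if len(bad):
        raise ValueError(
            f"promoter {bad.index[0]}: expected {n_probes} probes, found {bad.iloc[0]}")
    return track.df.groupby("promoter_id")["value"].median().rename("score")


@dataclass(frozen=True)
class PeakCallConfig:
    """Stringency of the threshold-run peak caller: the cut-off is the series
    mean plus ``k`` (population) standard deviations, and a peak needs at
    least ``min_run`` consecutive above-threshold positions."""

    k: float = 1.0
    min_run: int = 2

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class Peak:
    start: int
    end: int     # inclusive
    apex: int
    height: float


def call_peaks(scores, config: PeakCallConfig = PeakCallConfig()) -> list[Peak]:
    """Maximal runs of >= min_run consecutive positions with score strictly
    above mean + k*sd.  Apex is the position of the run maximum (leftmost on
    ties).  A zero-variance series yields no peaks."""
    if isinstance(scores, pd.Series):
        positions = np.asarray(scores.index)
        x = scores.to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        positions = np.arange(len(x))
    if len(x) < config.min_run:
        raise ValueError(f"need at least min_run={config.min_run} positions")
    t = x.mean() + config.k * x.std()  # population sd (n denominator)
    above = x > t
    peaks: list[Peak] = []
    i = 0
    while i < len(x):
        if above[i]:
            j = i
            while j + 1 < len(x) and above[j + 1]:
                j += 1
            if j - i + 1 >= config.min_run:
                run = x[i:j + 1]
                apex_rel = int(np.argmax(run))  # leftmost maximum
                peaks.append(Peak(int(positions[i]), int(positions[j]),
                                  int(positions[i + apex_rel]), float(run.max())))
            i = j + 1
        else:
            i += 1
    return peaks


@dataclass
class ConcordanceReport:
    pearson_r: float
    overlap_fraction: float
    n_top_a: int
    n_top_b: int


def _top_set(scores: pd.Series, pct: float) -> set:
    """Ids at or above the (100-pct)th percentile; boundary ties included."""
    thr = np.percentile(scores.to_numpy(dtype=float), 100.0 - pct)
    return set(scores.index[scores >= thr])


def concordance(scores_a: pd.Series, scores_b: pd.Series,
                top_pct_a: float = 5.0, top_pct_b: float = 10.0) -> ConcordanceReport:
    """Replicate agreement: Pearson r over paired promoter scores plus the
    fraction of one replicate's top percentile recovered in the other's
    (wider) top percentile."""
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("replicate score maps cover different promoters")
    if len(scores_a) < 3:
        raise ValueError("need at least 3 promoters")
    b = scores_b.reindex(scores_a.index)
    r = float(stats.pearsonr(scores_a.to_numpy(), b.to_numpy())[0])
    top_a = _top_set(scores_a, top_pct_a)
    top_b = _top_set(scores_b, top_pct_b)
    return ConcordanceReport(r, len(top_a & top_b) / len(top_a), len(top_a), len(top_b))


def bin_offset(offset: int, width: int = 10) -> int:
    """Nearest multiple of ``width`` (ties toward 0)."""
    a = abs(offset)
    q, r = divmod(a, width)
    if r > width // 2:
        q += 1
    return int(np.sign(offset)) * q * width


@dataclass
class BindingProfile:
    """Average binding profile over 10-bp bins around aligned TSSs."""

    table: pd.DataFrame  # bin_center, available, high, fraction
    mode: str

    def modal_bin(self) -> int:
        t = self.table
        best = t[t["fraction"] == t["fraction"].max()]
        return int(best["bin_center"].iloc[0])


def build_profile(high_probes, all_probes, mode: str = "fraction",
                  width: int = 10) -> BindingProfile:
    """Fraction of high-score probes per bin, corrected for probe
    availability: fraction(bin) = high(bin) / available(bin); bins with no
    available probes are omitted.  ``max1`` mode rescales so the maximum
    fraction equals 1 (score maxima set to 1)."""
    high = set(high_probes)
    allp = set(all_probes)
    if not high <= allp:
        raise ValueError("high_probes must be a subset of all_probes")
    if mode not in ("fraction", "max1"):
        raise ValueError(f"unknown profile mode {mode!r}")
    avail: dict[int, int] = {}
    hi: dict[int, int] = {}
    for _, off in allp:
        b = bin_offset(off, width)
        avail[b] = avail.get(b, 0) + 1
    for _, off in high:
        b = bin_offset(off, width)
        hi[b] = hi.get(b, 0) + 1
    rows = [(b, avail[b], hi.get(b, 0), hi.get(b, 0) / avail[b])
            for b in sorted(avail)]
    table = pd.DataFrame(rows, columns=["bin_center", "available", "high", "fraction"])
    if mode == "max1":
        m = table["fraction"].max()
        if m > 0:
            table["fraction"] = table["fraction"] / m
    return BindingProfile(table, mode)


def top_percentile_probes(track: SignalTrack, pct: float = 5.0) -> set:
    """Probes whose value is at or above the (100-pct)th percentile of all
    probe values in the track (ties included), as (promoter_id, offset)."""
    if not 0 < pct < 100:
        raise ValueError("pct must lie in (0, 100)")
    vals = track.values()
    if vals.size == 0:
        raise ValueError("empty track")
    thr = np.percentile(vals, 100.0 - pct)
    sub = track.df[track.df["value"] >= thr]
    return set(zip(sub["promoter_id"], sub["offset"]))


def all_probes(track: SignalTrack) -> set:
    return set(zip(track.df["promoter_id"], track.df["offset"]))
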