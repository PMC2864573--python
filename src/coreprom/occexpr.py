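"""Occupancy-expression statistics.

Correlation of promoter occupancy with steady-state mRNA levels (sliding
window means, quantile distribution tables), TFIIB/NC2 ratio curves over
expression percentiles, dominated-gene selection, the bootstrap two-sample
Kolmogorov-Smirnov test and the Wilcoxon-Mann-Whitney rank-sum test on probe
positions, and focused/dispersed TSS shape classification of CAGE-like tag
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


@dataclass
class RatioCurve:
    """Mean TFIIB and NC2 enrichment (linear scale) per expression-percentile
    bin, and their ratio."""

    table: pd.DataFrame  # bin_lo, bin_hi, mean_tfiib, mean_nc2, ratio


@dataclass
class TssShape:
    promoter_id: str
    class4: str  # single | dominant | broad | multimodal
    class2: str  # focused | dispersed
    tag_total: int


def _align(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if set(a.index) != set(b.index):
        raise ValueError("inputs cover different gene sets")
    b = b.reindex(a.index)
    return a.to_numpy(dtype=float), b.to_numpy(dtype=float)


def sliding_window_expression(occupancy: pd.Series, expression: pd.Series,
                              step: float = 0.1, min_genes: int = 10
                              ) -> tuple[pd.DataFrame, float]:
    """Mean expression in consecutive occupancy windows of width ``step``.

    Genes are sorted by occupancy; windows with fewer than ``min_genes``
    members are merged with the next window.  Returns the per-window curve
    (occupancy midpoint, mean expression, n genes) and its Pearson r.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    occ, expr = _align(occupancy, expression)
    order = np.argsort(occ, kind="stable")
    occ, expr = occ[order], expr[order]
    edges = np.arange(occ[0], occ[-1] + step, step)
    rows = []
    buf_occ: list[float] = []
    buf_expr: list[float] = []
    for lo in edges:
        hi = lo + step
        sel = (occ >= lo) & (occ < hi) if hi < occ[-1] + step else (occ >= lo)
        buf_occ.extend(occ[sel])
        buf_expr.extend(expr[sel])
        if len(buf_occ) >= min_genes:
            rows.append((float(np.mean(buf_occ)), float(np.mean(buf_expr)), len(buf_occ)))
            buf_occ, buf_expr = [], []
    if buf_occ:  # trailing remainder merges into the last window
        if rows:
            m_occ, m_expr, n = rows.pop()
            tot = n + len(buf_occ)
            rows.append(((m_occ * n + sum(buf_occ)) / tot,
                         (m_expr * n + sum(buf_expr)) / tot, tot))
        else:
            rows.append((float(np.mean(buf_occ)), float(np.mean(buf_expr)), len(buf_occ)))
    if len(rows) < 2:
        raise ValueError("fewer than 2 populated windows; decrease min_genes or step")
    curve = pd.DataFrame(rows, columns=["occupancy_mid", "mean_expression", "n_genes"])
    r = float(stats.pearsonr(curve["occupancy_mid"], curve["mean_expression"])[0])
    return curve, r


def quantile_distribution(occupancy: pd.Series, expression: pd.Series,
                          n_quantiles: int = 10
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Expression-quantile composition of occupancy deciles.

    Rows are occupancy deciles (1 = lowest), columns expression quantiles;
    each row sums to 1.  Also returns, per occupancy decile, the fraction of
    genes expressed above the overall expression median.
    """
    occ, expr = _align(occupancy, expression)
    if len(occ) < n_quantiles:
        raise ValueError("need at least n_quantiles genes")
    occ_decile = pd.qcut(pd.Series(occ).rank(method="first"), 10, labels=False) + 1
    expr_q = pd.qcut(pd.Series(expr).rank(method="first"), n_quantiles, labels=False) + 1
    tab = pd.crosstab(occ_decile, expr_q, normalize="index")
    tab.index.name = "occupancy_decile"
    tab.columns.name = "expression_quantile"
    med = np.median(expr)
    above = pd.Series(expr > med).groupby(occ_decile).mean()
    above.index.name = "occupancy_decile"
    return tab, above.rename("fraction_above_median")


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| via pooled sorting (fast path for bootstrap)."""
    data = np.concatenate([a, b])
    idx = np.argsort(data, kind="mergesort")
    flag = np.concatenate([np.full(a.size, 1.0 / a.size),
                           np.full(b.size, -1.0 / b.size)])[idx]
    cdf_diff = np.cumsum(flag)
    # ties: evaluate only at the last occurrence of each value
    sorted_vals = data[idx]
    last = np.r_[sorted_vals[1:] != sorted_vals[:-1], True]
    return float(np.abs(cdf_diff[last]).max())


def ks_boot(sample_a, sample_b, n_boot: int = 999,
            seed: int | np.random.Generator = 0) -> TestResult:
    """Bootstrap two-sample Kolmogorov-Smirnov test.

    D is the classical sup-ECDF-difference statistic; the p-value is
    (1 + #{D* >= D}) / (n_boot + 1) with D* computed on the pooled data
    resampled with replacement into the original group sizes.  The bootstrap
    null makes the test valid in the presence of ties.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_obs = _ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n_tot = pooled.size
    exceed = 0
    for _ in range(n_boot):
        resampled = pooled[rng.integers(0, n_tot, size=n_tot)]
        if _ks_statistic(resampled[:a.size], resampled[a.size:]) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return TestResult(d_obs, p, a.size, b.size, "ks_boot")


def ranksum_positions(positions_a, positions_b) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test (normal approximation with tie
    and continuity corrections) on two position vectors."""
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), a.size, b.size,
                      "mann-whitney")


def ratio_curve(tfiib: pd.Series, nc2: pd.Series, expression: pd.Series,
                bin_pct: int = 5) -> RatioCurve:
    """TFIIB/NC2 ratio per expression-percentile bin.

    Genes are ranked by expression into bins of width ``bin_pct`` percent;
    log2 enrichments are converted to the linear scale (2^x) before
    averaging, so every bin mean and ratio is strictly positive.
    """
    if 100 % bin_pct != 0:
        raise ValueError("bin_pct must divide 100")
    t, n = _align(tfiib, nc2)
    _, e = _align(tfiib, expression)
    n_bins = 100 // bin_pct
    bins = pd.qcut(pd.Series(e).rank(method="first"), n_bins, labels=False)
    lt, ln = 2.0 ** t, 2.0 ** n
    rows = []
    for bi in range(n_bins):
        sel = (bins == bi).to_numpy()
        mt, mn = float(lt[sel].mean()), float(ln[sel].mean())
        if mn <= 0:
            raise ValueError("non-positive NC2 bin mean")
        rows.append((bi * bin_pct, (bi + 1) * bin_pct, mt, mn, mt / mn))
    return RatioCurve(pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "mean_tfiib", "mean_nc2", "ratio"]))


def select_dominated(tfiib: pd.Series, nc2: pd.Series, expression: pd.Series,
                     cutoff_pct: float = 60.0, top_n: int = 100
                     ) -> tuple[list, list]:
    """TFIIB- and NC2-dominated gene sets.

    Eligible genes sit at or above the ``cutoff_pct`` percentile in TFIIB
    occupancy, NC2 occupancy and expression; per-gene ratio is linear
    TFIIB / linear NC2.  Returns the ``top_n`` highest-ratio ids and the
    ``top_n`` lowest-ratio ids; rank ties break by gene id.
    """
    t, n = _align(tfiib, nc2)
    _, e = _align(tfiib, expression)
    ids = np.asarray(tfiib.index)
    eligible = np.ones(len(ids), dtype=bool)
    for track in (t, n, e):
        eligible &= track >= np.percentile(track, cutoff_pct)
    n_elig = int(eligible.sum())
    if n_elig < top_n:
        raise ValueError(f"only {n_elig} eligible genes for top_n={top_n}")
    ratio = 2.0 ** (t[eligible] - n[eligible])
    elig_ids = ids[eligible]
    order_hi = sorted(range(n_elig), key=lambda i: (-ratio[i], elig_ids[i]))
    order_lo = sorted(range(n_elig), key=lambda i: (ratio[i], elig_ids[i]))
    hi = [elig_ids[i] for i in order_hi[:top_n]]
    lo = [elig_ids[i] for i in order_lo[:top_n]]
    return hi, lo


def classify_tss_shape(tags: dict, promoter_id: str = "",
                       single_span: int = 4, dominant_frac: float = 0.5,
                       mode_sep: int = 25, mode_frac: float = 0.2) -> TssShape:
    """Classify a per-position tag-count vector.

    ``single``: every tag within a ``single_span``-bp span; else ``dominant``
    if the top position holds >= ``dominant_frac`` of tags; else
    ``multimodal`` if >= 2 local maxima >= ``mode_sep`` bp apart each hold
    >= ``mode_frac`` of tags; else ``broad``.  Single/dominant promoters are
    focused, broad/multimodal dispersed.
    """
    tags = {int(p): int(c) for p, c in tags.items() if c > 0}
    total = sum(tags.values())
    if total < 1:
        raise ValueError("empty tag vector")
    positions = sorted(tags)
    if positions[-1] - positions[0] < single_span:
        cls = "single"
    elif max(tags.values()) / total > dominant_frac:
        cls = "dominant"
    else:
        modes = [p for p in positions
                 if tags[p] >= mode_frac * total
                 and all(tags[p] >= tags.get(p + d, 0) for d in (-2, -1, 1, 2))]
        spaced = [p for i, p in enumerate(modes)
                  if i == 0 or p - modes[i - 1] >= mode_sep]
        cls = "multimodal" if _count_spaced(modes, mode_sep) >= 2 else "broad"
    class2 = "focused" if cls in ("single", "dominant") else "dispersed"
    return TssShape(promoter_id, cls, class2, total)


def _count_spaced(modes: list[int], sep: int) -> int:
    """Largest subset of mode positions pairwise >= sep apart (greedy)."""
    count, last = 0, None
    for p in modes:
        if last is None or p - last >= sep:
            count += 1
            last = p
    return count


def mean_tags(cage_tags: dict, ids=None) -> float:
    """Arithmetic mean of per-promoter tag totals over ``ids`` (default all)."""
    ids = list(cage_tags) if ids is None else list(ids)
    if not ids:
        raise ValueError("no promoter ids")
    return float(np.mean([sum(cage_tags[i].values()) for i in ids]))
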