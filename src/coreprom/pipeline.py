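"""End-to-end pipeline: generation -> scaling -> scoring -> scanning ->
statistics -> reports, driven by a validated configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chipsignal, cooccur, io, motifscan, occexpr
from .presets import PRESET_NAMES, load_preset
from .synthcohort import FACTORS, REPLICATES, generate_cohort


@dataclass
class PipelineConfig:
    preset: str | None = "top100"
    blueprint_path: str | None = None
    out_dir: str = "coreprom_out"
    seed: int = 0
    n_promoters: int | None = None   # override preset size
    top_pct: float = 5.0             # high-score probe / concordance percentile
    top_pct_wide: float = 10.0       # wider replicate percentile for overlap
    cutoff_pct: float = 60.0         # dominated-set eligibility percentile
    bin_pct: int = 5                 # expression-bin width for ratio curves
    top_n: int = 10                  # dominated-set size (synthetic scale)
    peak_k: tuple = (1.0, 2.0, 2.5)
    min_run: int = 2
    n_boot: int = 199
    bred_max_mismatch: int = 0
    tata_tolerance: int = 0

    def validate(self) -> None:
        if self.preset is None and self.blueprint_path is None:
            raise ValueError("config needs a preset name or a blueprint path")
        if self.preset is not None and self.preset not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {self.preset!r}; valid: {', '.join(PRESET_NAMES)}")
        if 100 % self.bin_pct != 0:
            raise ValueError(f"bin_pct={self.bin_pct} must divide 100")
        if not 0 < self.top_pct < 100 or not 0 < self.top_pct_wide < 100:
            raise ValueError("top percentiles must lie in (0, 100)")
        if not 0 <= self.cutoff_pct < 100:
            raise ValueError("cutoff_pct must lie in [0, 100)")
        if any(k <= 0 for k in self.peak_k):
            raise ValueError("peak stringencies must be > 0")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "peak_k" in doc:
            doc["peak_k"] = tuple(doc["peak_k"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing all module outputs under ``config.out_dir``.

    Deterministic given the config seed.  Returns a report bundle (dict of
    in-memory results); raises :class:`StageError` naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    summary: list[str] = [f"coreprom {__version__}", f"seed: {config.seed}"]
    for f in fields(config):
        if f.name in ("out_dir", "blueprint_path"):
            continue  # paths vary between otherwise-identical runs
        summary.append(f"config.{f.name}: {getattr(config, f.name)}")

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:  # noqa: BLE001 - named-stage reporting
                raise StageError(name, err) from err
        return wrap

    def _generate():
        if config.blueprint_path:
            bp = io.blueprint_from_yaml(config.blueprint_path)
            bp.seed = config.seed
        else:
            bp = load_preset(config.preset, n=config.n_promoters, seed=config.seed)
        cohort = generate_cohort(bp)
        io.write_cohort(cohort, out)
        return cohort

    cohort = stage("generate")(_generate)
    bundle["cohort"] = cohort
    summary.append(f"cohort: {cohort.truth.name}, n={cohort.truth.n_promoters}")

    def _signals():
        scores = {}
        for factor in FACTORS:
            for rep in REPLICATES:
                track = chipsignal.track_from_signals(cohort.signals, factor, rep)
                scaled = chipsignal.scale_track(track)
                scores[(factor, rep)] = chipsignal.promoter_scores(scaled)
        tab = pd.DataFrame({f"{f}_rep{r}": s for (f, r), s in scores.items()})
        tab.to_csv(out / "promoter_scores.tsv", sep="\t", float_format="%.6f")
        return scores

    scores = stage("scale_score")(_signals)
    bundle["scores"] = scores

    def _concordance():
        lines = []
        reports = {}
        for factor in FACTORS:
            rep = chipsignal.concordance(scores[(factor, 1)], scores[(factor, 2)],
                                         config.top_pct, config.top_pct_wide)
            reports[factor] = rep
            lines.append(f"{factor}: pearson_r={rep.pearson_r:.4f} "
                         f"overlap={rep.overlap_fraction:.4f} "
                         f"(top {config.top_pct}% of {rep.n_top_a} in top "
                         f"{config.top_pct_wide}%)")
        (out / "concordance.txt").write_text("\n".join(lines) + "\n")
        return reports

    bundle["concordance"] = stage("concordance")(_concordance)

    def _peaks():
        rows = []
        for factor in FACTORS:
            track = chipsignal.track_from_signals(cohort.signals, factor, 1)
            scaled = chipsignal.scale_track(track)
            for k in config.peak_k:
                cfg = chipsignal.PeakCallConfig(k=k, min_run=config.min_run)
                for pid, grp in scaled.df.groupby("promoter_id"):
                    series = pd.Series(grp["value"].to_numpy(),
                                       index=grp["offset"].to_numpy())
                    for p in chipsignal.call_peaks(series, cfg):
                        rows.append((factor, pid, p.start, p.end, p.apex,
                                     round(p.height, 6), k))
        tab = pd.DataFrame(rows, columns=["factor", "promoter_id", "start", "end",
                                          "apex", "height", "k"])
        tab.to_csv(out / "peaks.tsv", sep="\t", index=False)
        return tab

    peaks = stage("peaks")(_peaks)
    bundle["peaks"] = peaks
    for k in config.peak_k:
        summary.append(f"peaks at k={k}: {int((peaks['k'] == k).sum())}")

    def _profile():
        track = chipsignal.track_from_signals(cohort.signals, "TFIIB", 1)
        scaled = chipsignal.scale_track(track)
        high = chipsignal.top_percentile_probes(scaled, config.top_pct)
        prof = chipsignal.build_profile(high, chipsignal.all_probes(scaled))
        prof.table.to_csv(out / "binding_profile.tsv", sep="\t", index=False,
                          float_format="%.6f")
        return prof

    prof = stage("profile")(_profile)
    bundle["profile"] = prof
    summary.append(f"profile modal bin: {prof.modal_bin()}")

    def _scan():
        defs = motifscan.default_motif_defs(config.bred_max_mismatch,
                                            config.tata_tolerance)
        anns = motifscan.scan_cohort(cohort.promoters, defs)
        rows = []
        for a in anns:
            row = {"promoter_id": a.promoter_id}
            for c in motifscan.MOTIF_CLASSES:
                row[c] = int(bool(a.present.get(c)))
                row[f"{c}_pos"] = a.hits.get(c, [None])[0] if a.hits.get(c) else ""
                row[f"{c}_mm"] = a.mismatches.get(c, "")
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "motif_annotations.tsv", sep="\t", index=False)
        freq = motifscan.motif_frequency(anns)
        freq.to_csv(out / "motif_frequency.tsv", sep="\t", float_format="%.2f")
        gc = motifscan.gc_content(cohort.promoters)
        motifscan.nucleotide_frequency_matrix(cohort.promoters).to_csv(
            out / "base_frequency.tsv", sep="\t", float_format="%.4f")
        return anns, freq, gc

    anns, freq, gc = stage("scan")(_scan)
    bundle["annotations"], bundle["frequency"], bundle["gc"] = anns, freq, gc
    summary.append(f"gc_content: {100 * gc:.2f}%")
    for cls in ("TATA", "TATA_like", "INR", "DPE"):
        summary.append(f"motif {cls}: count={int(freq.loc[cls, 'count'])} "
                       f"({freq.loc[cls, 'percent']:.1f}%)")

    def _occexpr():
        expr = cohort.expression
        present = expr[expr["present"]].set_index("promoter_id")["signal"]
        tfiib = ((scores[("TFIIB", 1)] + scores[("TFIIB", 2)]) / 2).loc[present.index]
        nc2 = ((scores[("NC2", 1)] + scores[("NC2", 2)]) / 2).loc[present.index]
        res: dict = {}
        curve, r = occexpr.sliding_window_expression(tfiib, present)
        curve.to_csv(out / "sliding_window.tsv", sep="\t", index=False,
                     float_format="%.6f")
        res["sliding_r"] = r
        qtab, above = occexpr.quantile_distribution(tfiib, present)
        qtab.to_csv(out / "quantile_distribution.tsv", sep="\t", float_format="%.4f")
        res["above_median_top_decile"] = float(above.iloc[-1])
        top = present[tfiib >= tfiib.quantile(0.9)]
        ks = occexpr.ks_boot(top.to_numpy(), present.to_numpy(),
                             n_boot=config.n_boot, seed=config.seed)
        res["ks"] = ks
        rc = occexpr.ratio_curve(tfiib, nc2, present, config.bin_pct)
        rc.table.to_csv(out / "ratio_curve.tsv", sep="\t", index=False,
                        float_format="%.6f")
        res["ratio_curve"] = rc
        top_n = min(config.top_n, max(1, len(present) // 4))
        hi, lo = occexpr.select_dominated(tfiib, nc2, present,
                                          config.cutoff_pct, top_n)
        pd.DataFrame({"tfiib_dominated": hi, "nc2_dominated": lo}).to_csv(
            out / "dominated_sets.tsv", sep="\t", index=False)
        res["dominated"] = (hi, lo)
        shapes = [occexpr.classify_tss_shape(cohort.cage_tags[pid], pid)
                  for pid in cohort.promoter_ids]
        pd.DataFrame([(s.promoter_id, s.class4, s.class2, s.tag_total)
                      for s in shapes],
                     columns=["promoter_id", "class4", "class2", "tag_total"]).to_csv(
            out / "tss_shapes.tsv", sep="\t", index=False)
        res["focused_fraction"] = np.mean([s.class2 == "focused" for s in shapes])
        res["mean_tags"] = occexpr.mean_tags(cohort.cage_tags)
        lines = [f"sliding-window r: {r:.4f}",
                 f"KS (top decile vs all): D={ks.statistic:.4f} p={ks.p_value:.4g} "
                 f"(n={ks.n_a}/{ks.n_b}, n_boot={config.n_boot})",
                 f"mean CAGE tags: {res['mean_tags']:.1f}",
                 f"focused fraction: {res['focused_fraction']:.3f}"]
        (out / "occexpr_report.txt").write_text("\n".join(lines) + "\n")
        return res

    occ_res = stage("occexpr")(_occexpr)
    bundle["occexpr"] = occ_res
    summary.append(f"sliding-window r: {occ_res['sliding_r']:.4f}")

    def _cooccur():
        rep = cooccur.combination_counts(anns)
        rep.histogram.rename_axis("combination_size").to_csv(
            out / "combination_histogram.tsv", sep="\t")
        cooccur.cooccur_matrix(anns).to_csv(out / "cooccur_matrix.tsv", sep="\t")
        return rep

    comb = stage("cooccur")(_cooccur)
    bundle["combinations"] = comb
    summary.append(f"promoters with >=1 motif (collapsed classes): "
                   f"{comb.count_at_least(1)} of {comb.n_promoters}")

    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    bundle["summary"] = summary
    return bundle
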