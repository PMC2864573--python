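"""Text-format import/export: FASTA core sequences, BED6 TSS annotation,
TSV signal/expression/tag tables, and YAML blueprints."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import CORE_LEN
from .synthcohort import (CohortBlueprint, ExpressionModel, Footprint,
                          OccupancyModel, PromoterRecord, SyntheticCohort)

# synthetic genomic layout used for BED export: one 2-kb slot per promoter
_SLOT = 2000
_TSS_IN_SLOT = 1000


def write_fasta(promoters, path) -> None:
    """Core sequences, one record per promoter, header ``promoter_id|strand``."""
    recs = [SeqRecord(Seq(p.core_seq), id=f"{p.promoter_id}|{p.strand}",
                      description="") for p in promoters]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[PromoterRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, _, strand = rec.id.partition("|")
        out.append(PromoterRecord(pid, strand or "+", str(rec.seq).upper()))
    return out


def write_bed(promoters, path) -> None:
    """BED6 TSS annotation on a synthetic coordinate layout (0-based,
    half-open, one 2-kb slot per promoter)."""
    rows = []
    for i, p in enumerate(promoters):
        tss = i * _SLOT + _TSS_IN_SLOT
        rows.append(("synthetic", tss, tss + 1, p.promoter_id, 0, p.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_signals(signals: pd.DataFrame, path) -> None:
    signals.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tags(cage_tags: dict, path) -> None:
    rows = [(pid, off, cnt) for pid in sorted(cage_tags)
            for off, cnt in sorted(cage_tags[pid].items())]
    pd.DataFrame(rows, columns=["promoter_id", "offset", "count"]).to_csv(
        path, sep="\t", index=False)


def read_tags(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, int]] = {}
    for pid, off, cnt in df.itertuples(index=False):
        out.setdefault(pid, {})[int(off)] = int(cnt)
    return out


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Export every cohort container; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "promoters.fasta",
        "bed": outdir / "tss.bed",
        "signals": outdir / "probe_signals.tsv",
        "expression": outdir / "expression.tsv",
        "tags": outdir / "cage_tags.tsv",
    }
    write_fasta(cohort.promoters, paths["fasta"])
    write_bed(cohort.promoters, paths["bed"])
    write_signals(cohort.signals, paths["signals"])
    write_expression(cohort.expression, paths["expression"])
    write_tags(cohort.cage_tags, paths["tags"])
    return paths


def blueprint_to_yaml(bp: CohortBlueprint, path) -> None:
    doc = dataclasses.asdict(bp)
    doc["motif_table"] = [list(t) for t in bp.motif_table]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def blueprint_from_yaml(path) -> CohortBlueprint:
    doc = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(CohortBlueprint)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown blueprint keys: {sorted(unknown)}")
    doc["motif_table"] = [tuple(t) for t in doc.get("motif_table", [])]
    for key, cls in (("occupancy_model", OccupancyModel),
                     ("expression_model", ExpressionModel),
                     ("footprint", Footprint)):
        if key in doc and isinstance(doc[key], dict):
            doc[key] = cls(**doc[key])
    return CohortBlueprint(**doc)


def validate_inputs(fasta=None, signals=None, expression=None, tags=None,
                    n_probes: int = 15) -> pd.DataFrame:
    """Schema checks on input files.

    Returns a per-file report (file, status, detail); status is ``pass``,
    ``fail`` (schema violation, first offender named) or ``warn``
    (id-join orphans).
    """
    rows = []
    ids: set[str] = set()
    if fasta is not None:
        status, detail = "pass", ""
        for rec in read_fasta(fasta):
            ids.add(rec.promoter_id)
            if len(rec.core_seq) != CORE_LEN:
                status, detail = "fail", (
                    f"record {rec.promoter_id}: {len(rec.core_seq)} bases, expected {CORE_LEN}")
                break
            if any(b not in "ACGT" for b in rec.core_seq):
                status, detail = "fail", f"record {rec.promoter_id}: non-ACGT base"
                break
        rows.append(("fasta", status, detail))
    if signals is not None:
        df = read_signals(signals)
        need = {"promoter_id", "probe_index", "offset", "factor", "replicate", "log2_ratio"}
        missing = need - set(df.columns)
        if missing:
            rows.append(("signals", "fail", f"missing columns {sorted(missing)}"))
        else:
            counts = df.groupby(["promoter_id", "factor", "replicate"]).size()
            bad = counts[counts != n_probes]
            if len(bad):
                key = bad.index[0]
                rows.append(("signals", "fail",
                             f"probeset {key}: {bad.iloc[0]} probes, expected {n_probes}"))
            else:
                orphans = set(df["promoter_id"]) - ids if ids else set()
                if orphans:
                    rows.append(("signals", "warn",
                                 f"orphan promoter id {sorted(orphans)[0]}"))
                else:
                    rows.append(("signals", "pass", ""))
    if expression is not None:
        df = read_expression(expression)
        need = {"promoter_id", "signal", "present"}
        missing = need - set(df.columns)
        if missing:
            rows.append(("expression", "fail", f"missing columns {sorted(missing)}"))
        else:
            orphans = set(df["promoter_id"]) - ids if ids else set()
            if orphans:
                rows.append(("expression", "warn",
                             f"orphan promoter id {sorted(orphans)[0]}"))
            else:
                rows.append(("expression", "pass", ""))
    if tags is not None:
        df = pd.read_csv(tags, sep="\t")
        need = {"promoter_id", "offset", "count"}
        missing = need - set(df.columns)
        if missing:
            rows.append(("tags", "fail", f"missing columns {sorted(missing)}"))
        elif (df["count"] < 0).any():
            rows.append(("tags", "fail", "negative tag count"))
        else:
            rows.append(("tags", "pass", ""))
    return pd.DataFrame(rows, columns=["file", "status", "detail"])
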