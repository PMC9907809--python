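"""Tab-separated interchange formats for count tables, scores, and hits.

All files are UTF-8 TSV with '.' decimals and '*' for stop codons, mirroring
the layout of the published screen spreadsheet: one row per variant per
sample for count tables (a ``WT`` row carries the reference-sequence count),
and one row per amino-acid variant with per-replicate columns for scores.
Writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .calls import GroupSummary
from .counting import AACountTable, CountTable
from .enrichment import EnrichmentRecord
from .library import CodonVariant, ResidueVariant, parse_variant_name

__all__ = [
    "write_count_tables",
    "read_count_tables",
    "write_aa_count_tables",
    "read_aa_count_tables",
    "write_scores",
    "read_scores",
    "write_hits",
    "write_group_stats",
    "write_manifest",
]

WT_LABEL = "WT"


# -- codon-level count tables -------------------------------------------


def write_count_tables(tables: list[CountTable], path) -> None:
    rows = []
    for t in tables:
        meta = dict(
            sample_id=t.sample_id,
            condition=t.condition,
            replicate=t.replicate,
            total_reads=t.total_reads,
            rejected_reads=t.rejected_reads,
        )
        rows.append(
            {**meta, "position": 0, "ref_codon": WT_LABEL,
             "alt_codon": WT_LABEL, "reads": t.wt_count}
        )
        for cv in sorted(t.counts):
            rows.append(
                {**meta, "position": cv.position, "ref_codon": cv.ref_codon,
                 "alt_codon": cv.alt_codon, "reads": t.counts[cv]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_tables(path) -> list[CountTable]:
    df = pd.read_csv(path, sep="\t", dtype={"ref_codon": str, "alt_codon": str})
    required = {"sample_id", "condition", "replicate", "position",
                "ref_codon", "alt_codon", "reads", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    tables = []
    for (sample, cond, rep), g in df.groupby(
        ["sample_id", "condition", "replicate"], sort=True
    ):
        counts: dict[CodonVariant, int] = {}
        wt = 0
        for row in g.itertuples():
            if row.ref_codon == WT_LABEL:
                wt = int(row.reads)
            else:
                cv = CodonVariant(int(row.position), row.ref_codon, row.alt_codon)
                counts[cv] = int(row.reads)
        tables.append(
            CountTable(
                sample_id=str(sample),
                condition=str(cond),
                replicate=int(rep),
                counts=counts,
                wt_count=wt,
                total_reads=int(g["total_reads"].iloc[0]),
                rejected_reads=int(g["rejected_reads"].iloc[0])
                if "rejected_reads" in g
                else 0,
            )
        )
    return tables


# -- amino-acid count tables --------------------------------------------


def write_aa_count_tables(tables: list[AACountTable], path) -> None:
    rows = []
    for t in tables:
        meta = dict(
            sample_id=t.sample_id,
            condition=t.condition,
            replicate=t.replicate,
            total_reads=t.total_reads,
        )
        rows.append({**meta, "variant": WT_LABEL, "reads_sum": t.wt_count})
        for rv in sorted(t.aa_counts):
            rows.append({**meta, "variant": rv.name, "reads_sum": t.aa_counts[rv]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_aa_count_tables(path) -> list[AACountTable]:
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    required = {"sample_id", "condition", "replicate", "variant",
                "reads_sum", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"aa count table missing columns: {sorted(missing)}")
    tables = []
    for (sample, cond, rep), g in df.groupby(
        ["sample_id", "condition", "replicate"], sort=True
    ):
        aa_counts: dict[ResidueVariant, int] = {}
        wt = 0
        for row in g.itertuples():
            if row.variant == WT_LABEL:
                wt = int(row.reads_sum)
            else:
                aa_counts[parse_variant_name(row.variant)] = int(row.reads_sum)
        tables.append(
            AACountTable(
                sample_id=str(sample),
                condition=str(cond),
                replicate=int(rep),
                aa_counts=aa_counts,
                wt_count=wt,
                total_reads=int(g["total_reads"].iloc[0]),
            )
        )
    return tables


# -- enrichment scores ---------------------------------------------------


def write_scores(records: list[EnrichmentRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "variant": r.variant.name,
            "position": r.variant.position,
            "ref_aa": r.variant.ref_aa,
            "alt_aa": r.variant.alt_aa,
            "class": r.vclass,
            "n_replicates": r.n_replicates,
            "control_dropout": r.control_dropout,
            "log2fc_mean": math.nan if r.log2fc_mean is None else r.log2fc_mean,
        }
        for i in range(r.n_replicates):
            row[f"frac_ctrl_{i + 1}"] = r.frac_ctrl[i]
            row[f"frac_sel_{i + 1}"] = r.frac_sel[i]
            row[f"log2fc_{i + 1}"] = r.log2fc_reps[i]
            row[f"floored_{i + 1}"] = r.floored[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores(path) -> list[EnrichmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    if "variant" not in df.columns or "log2fc_mean" not in df.columns:
        raise ValueError("scores table missing variant/log2fc_mean columns")
    records = []
    for row in df.itertuples():
        n = int(row.n_replicates)
        mean = float(row.log2fc_mean)
        records.append(
            EnrichmentRecord(
                variant=parse_variant_name(row.variant),
                frac_ctrl=tuple(
                    float(getattr(row, f"frac_ctrl_{i + 1}")) for i in range(n)
                ),
                frac_sel=tuple(
                    float(getattr(row, f"frac_sel_{i + 1}")) for i in range(n)
                ),
                log2fc_reps=tuple(
                    float(getattr(row, f"log2fc_{i + 1}")) for i in range(n)
                ),
                floored=tuple(
                    bool(getattr(row, f"floored_{i + 1}")) for i in range(n)
                ),
                log2fc_mean=None if math.isnan(mean) else mean,
                control_dropout=bool(row.control_dropout),
                n_replicates=n,
            )
        )
    return records


# -- hit tables and reports ----------------------------------------------


def write_hits(
    records: list[EnrichmentRecord],
    hits: set[ResidueVariant],
    codons: dict,
    path,
) -> None:
    """One row per scored variant with hit and proline-only flags."""
    proline_only = {pos: c.proline_only for pos, c in codons.items()}
    rows = []
    for r in records:
        rows.append(
            {
                "variant": r.variant.name,
                "position": r.variant.position,
                "class": r.vclass,
                "log2fc_mean": math.nan if r.log2fc_mean is None else r.log2fc_mean,
                "control_dropout": r.control_dropout,
                "hit": r.variant in hits,
                "proline_only_codon": proline_only.get(r.variant.position, False)
                and r.variant in hits,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_group_stats(summary: GroupSummary, path, extra: dict | None = None) -> None:
    payload = summary.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
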