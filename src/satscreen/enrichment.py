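"""Read-fraction normalisation and log2 fold-change scoring with dropout floor.

Each variant's abundance in a sample is its read fraction (reads / total
nucleotide reads of the sample). The enrichment score of a variant is

    log2FC = log2( frac_selected / frac_control )

computed per replicate pair and combined across replicates (arithmetic mean
by default). Variants that fall below the detection threshold after selection
are assigned the relative abundance corresponding to ``floor_reads`` reads
(default 2) in that sample, so the log2FC stays finite; such replicate values
carry a ``floored`` flag. Variants undetected in every control replicate
cannot be scored and are emitted with a ``control_dropout`` flag instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .counting import AACountTable
from .library import ResidueVariant

__all__ = ["read_fraction", "log2fc", "EnrichmentRecord", "score_screen"]


def read_fraction(reads_sum: float, total_reads: float) -> float:
    """Reads of one variant normalised by the sample's total read count."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= reads_sum <= total_reads:
        raise ValueError("reads_sum must lie in [0, total_reads]")
    return reads_sum / total_reads


def log2fc(
    frac_sel: float,
    frac_ctrl: float,
    total_sel: float,
    floor_reads: float = 2,
) -> tuple[float, bool]:
    """log2 fold-change of one replicate pair, with the dropout floor.

    Selected fractions below ``floor_reads / total_sel`` (i.e. variants not
    detected, or detected below the threshold, after selection) are raised to
    that floor. Returns ``(value, floored)``.
    """
    if frac_ctrl <= 0:
        raise ValueError("frac_ctrl must be positive (control dropout is "
                         "handled by score_screen)")
    if total_sel <= 0:
        raise ValueError("total_sel must be positive")
    floor_frac = floor_reads / total_sel
    floored = frac_sel < floor_frac
    effective = floor_frac if floored else frac_sel
    return math.log2(effective / frac_ctrl), floored


@dataclass
class EnrichmentRecord:
    """Per amino-acid variant enrichment across replicate pairs.

    ``log2fc_reps`` holds one value per replicate pair; replicates where the
    variant was absent from the control are NaN and excluded from the mean.
    ``log2fc_mean`` is the combined score (arithmetic mean of the finite
    per-replicate values, or the pooled-count estimate when scoring was run
    with ``combine="pooled"``); it is None for control dropouts.
    """

    variant: ResidueVariant
    frac_ctrl: tuple[float, ...]
    frac_sel: tuple[float, ...]
    log2fc_reps: tuple[float, ...]
    floored: tuple[bool, ...]
    log2fc_mean: float | None
    control_dropout: bool
    n_replicates: int

    @property
    def vclass(self) -> str:
        return self.variant.vclass


def _paired(tables: list[AACountTable], condition: str) -> dict[int, AACountTable]:
    by_rep: dict[int, AACountTable] = {}
    for t in tables:
        if t.condition != condition:
            raise ValueError(
                f"expected {condition} table, got {t.condition} ({t.sample_id})"
            )
        if t.replicate in by_rep:
            raise ValueError(f"duplicate {condition} replicate {t.replicate}")
        if t.total_reads <= 0:
            raise ValueError(f"sample {t.sample_id} has no reads")
        by_rep[t.replicate] = t
    return by_rep


def score_screen(
    selective: list[AACountTable],
    control: list[AACountTable],
    floor_reads: float = 2,
    combine: str = "mean",
) -> list[EnrichmentRecord]:
    """Score every observed amino-acid variant of one screen.

    Selective and control tables are paired replicate-to-replicate (replicate
    numbers must match). ``combine`` selects the across-replicate rule:
    ``"mean"`` (default) averages per-replicate log2FC values; ``"pooled"``
    sums counts over replicates first and takes a single log2 ratio (floor
    applied to the pooled selected count).
    """
    if not selective or not control:
        raise ValueError("need at least one replicate per condition")
    if combine not in ("mean", "pooled"):
        raise ValueError(f"unknown combine rule: {combine!r}")
    sel = _paired(selective, "selective")
    ctrl = _paired(control, "control")
    if set(sel) != set(ctrl):
        raise ValueError(
            f"replicate mismatch: selective {sorted(sel)} vs control {sorted(ctrl)}"
        )
    reps = sorted(sel)

    observed: set[ResidueVariant] = set()
    for t in list(sel.values()) + list(ctrl.values()):
        observed.update(v for v, c in t.aa_counts.items() if c > 0)

    records: list[EnrichmentRecord] = []
    for variant in sorted(observed):
        c_sel = [sel[r].aa_counts.get(variant, 0) for r in reps]
        c_ctrl = [ctrl[r].aa_counts.get(variant, 0) for r in reps]
        f_sel = tuple(
            read_fraction(c, sel[r].total_reads) for c, r in zip(c_sel, reps)
        )
        f_ctrl = tuple(
            read_fraction(c, ctrl[r].total_reads) for c, r in zip(c_ctrl, reps)
        )
        dropout = all(c == 0 for c in c_ctrl)
        lfc: list[float] = []
        floored: list[bool] = []
        for fs, fc, r in zip(f_sel, f_ctrl, reps):
            if fc == 0:
                lfc.append(math.nan)
                floored.append(False)
            else:
                value, fl = log2fc(fs, fc, sel[r].total_reads, floor_reads)
                lfc.append(value)
                floored.append(fl)
        if dropout:
            mean = None
        elif combine == "mean":
            finite = [x for x in lfc if math.isfinite(x)]
            mean = sum(finite) / len(finite)
        else:  # pooled
            n_sel = sum(sel[r].total_reads for r in reps)
            n_ctrl = sum(ctrl[r].total_reads for r in reps)
            pooled_sel = read_fraction(sum(c_sel), n_sel)
            pooled_ctrl = read_fraction(sum(c_ctrl), n_ctrl)
            mean, _ = log2fc(pooled_sel, pooled_ctrl, n_sel, floor_reads)
        records.append(
            EnrichmentRecord(
                variant=variant,
                frac_ctrl=f_ctrl,
                frac_sel=f_sel,
                log2fc_reps=tuple(lfc),
                floored=tuple(floored),
                log2fc_mean=mean,
                control_dropout=dropout,
                n_replicates=len(reps),
            )
        )
    return records
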