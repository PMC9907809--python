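"""Hit calling, per-codon summaries, cross-screen filtering, class statistics.

Enriched hits are missense variants whose combined log2FC clears a cutoff
(default 1). Depleted hits are missense variants statistically
indistinguishable from the nonsense class: by default, at or below the upper
Tukey fence (q3 + 1.5*IQR) of the nonsense log2FC distribution. A variant
drawn from the nonsense distribution itself falls inside that fence with
probability ~0.996 under normality, so genuinely null-like variants are
recovered essentially always; the stricter median + 0.5*IQR rule (which by
order statistics alone rejects ~25-30% of true nonsense-like values) remains
available via ``rule="median_iqr"``.

Group statistics follow the standard screen readout: per-class median and
quartiles of the combined log2FC, a one-way ANOVA across classes, and
pairwise Welch tests against a reference class with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import EnrichmentRecord
from .library import ResidueVariant

__all__ = [
    "HitCallParams",
    "call_enriched",
    "call_depleted",
    "CodonHits",
    "codon_summary",
    "cross_screen_filter",
    "ClassStats",
    "PairwiseComparison",
    "GroupSummary",
    "group_stats",
    "ScreenResult",
]

VCLASSES = ("synonymous", "missense", "nonsense")


@dataclass(frozen=True)
class HitCallParams:
    """Tunable hit-calling thresholds for one screen."""

    enrichment_cutoff: float = 1.0
    depletion_rule: str = "tukey_fence"  # or "median_iqr"
    fence_k: float = 1.5
    iqr_scale: float = 0.5
    exclude_proline_only: bool = False

    def __post_init__(self) -> None:
        if self.enrichment_cutoff <= 0:
            raise ValueError("enrichment_cutoff must be positive")
        if self.depletion_rule not in ("tukey_fence", "median_iqr"):
            raise ValueError(f"unknown depletion rule: {self.depletion_rule!r}")


def _scored(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    if not records:
        raise ValueError("empty record set")
    return [
        r
        for r in records
        if not r.control_dropout
        and r.log2fc_mean is not None
        and np.isfinite(r.log2fc_mean)
    ]


def call_enriched(
    records: list[EnrichmentRecord], params: HitCallParams | None = None
) -> set[ResidueVariant]:
    """Missense variants with combined log2FC at or above the cutoff.

    Synonymous and nonsense variants are never returned as hits; control
    dropouts are excluded.
    """
    params = params or HitCallParams()
    return {
        r.variant
        for r in _scored(records)
        if r.vclass == "missense" and r.log2fc_mean >= params.enrichment_cutoff
    }


def call_depleted(
    records: list[EnrichmentRecord], params: HitCallParams | None = None
) -> set[ResidueVariant]:
    """Missense variants indistinguishable from the nonsense class.

    The nonsense class provides the reference distribution of "no signaling"
    log2FC values; a missense variant is depleted when its combined log2FC
    does not exceed the configured upper bound of that distribution.
    """
    params = params or HitCallParams()
    scored = _scored(records)
    nonsense = np.array(
        [r.log2fc_mean for r in scored if r.vclass == "nonsense"], dtype=float
    )
    if nonsense.size == 0:
        raise ValueError("no nonsense variants to serve as reference distribution")
    q1, med, q3 = np.percentile(nonsense, [25, 50, 75])
    iqr = q3 - q1
    if params.depletion_rule == "tukey_fence":
        threshold = q3 + params.fence_k * iqr
    else:
        threshold = med + params.iqr_scale * iqr
    return {
        r.variant
        for r in scored
        if r.vclass == "missense" and r.log2fc_mean <= threshold
    }


@dataclass(frozen=True)
class CodonHits:
    position: int
    variants: frozenset[ResidueVariant]
    proline_only: bool


def codon_summary(hits: set[ResidueVariant]) -> dict[int, CodonHits]:
    """Group hits by codon position and flag proline-only positions."""
    by_pos: dict[int, set[ResidueVariant]] = {}
    for v in hits:
        by_pos.setdefault(v.position, set()).add(v)
    return {
        pos: CodonHits(
            position=pos,
            variants=frozenset(vs),
            proline_only=all(v.alt_aa == "P" for v in vs),
        )
        for pos, vs in sorted(by_pos.items())
    }


def cross_screen_filter(
    depleted: set[ResidueVariant], lof_im_hits: set[ResidueVariant]
) -> set[ResidueVariant]:
    """Candidates specifically defective at the outer membrane.

    From the variants depleted in the growth screen, remove proline
    substitutions (secondary-structure disruptors) and anything that already
    scored as a suppressor in the inner-membrane loss-of-function screen.
    """
    return {
        v for v in depleted if v.alt_aa != "P" and v not in lof_im_hits
    }


@dataclass(frozen=True)
class ClassStats:
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class PairwiseComparison:
    group: str
    reference: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupSummary:
    classes: dict[str, ClassStats]
    anova_F: float
    anova_p: float
    reference: str
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": {
                k: {"n": c.n, "median": c.median, "q1": c.q1, "q3": c.q3}
                for k, c in self.classes.items()
            },
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "reference": self.reference,
            "pairwise": [
                {
                    "group": p.group,
                    "reference": p.reference,
                    "statistic": p.statistic,
                    "p_raw": p.p_raw,
                    "p_adjusted": p.p_adjusted,
                }
                for p in self.pairwise
            ],
        }


def group_stats(
    records: list[EnrichmentRecord],
    reference: str = "synonymous",
    adjust: str = "bonferroni",
) -> GroupSummary:
    """Variant-class summaries: quartiles, one-way ANOVA, pairwise tests.

    Requires at least two classes with at least two scored members each.
    Pairwise comparisons are Welch t-tests of each class against the
    reference class, Bonferroni-adjusted.
    """
    if adjust != "bonferroni":
        raise ValueError(f"unknown adjustment: {adjust!r}")
    scored = _scored(records)
    groups: dict[str, np.ndarray] = {}
    for vclass in VCLASSES:
        values = np.array(
            [r.log2fc_mean for r in scored if r.vclass == vclass], dtype=float
        )
        if values.size:
            groups[vclass] = values
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError(
            "one-way ANOVA needs >=2 classes with >=2 scored members each"
        )
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every present class needs >=2 members for ANOVA")
    f_stat, p = stats.f_oneway(*groups.values())

    classes = {}
    for vclass, values in groups.items():
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        classes[vclass] = ClassStats(
            n=int(values.size), median=float(med), q1=float(q1), q3=float(q3)
        )

    pairwise: list[PairwiseComparison] = []
    if reference in groups:
        others = [k for k in groups if k != reference]
        m = len(others)
        for other in others:
            t, p_raw = stats.ttest_ind(
                groups[other], groups[reference], equal_var=False
            )
            pairwise.append(
                PairwiseComparison(
                    group=other,
                    reference=reference,
                    statistic=float(t),
                    p_raw=float(p_raw),
                    p_adjusted=float(min(1.0, p_raw * m)),
                )
            )
    return GroupSummary(
        classes=classes,
        anova_F=float(f_stat),
        anova_p=float(p),
        reference=reference,
        pairwise=pairwise,
    )


@dataclass
class ScreenResult:
    """Bundle of everything called for one screen."""

    screen_id: str
    records: list[EnrichmentRecord]
    hits: set[ResidueVariant]
    codons: dict[int, CodonHits]
    groups: GroupSummary

    @classmethod
    def from_records(
        cls,
        screen_id: str,
        records: list[EnrichmentRecord],
        params: HitCallParams | None = None,
        direction: str = "enriched",
    ) -> "ScreenResult":
        params = params or HitCallParams()
        if direction == "enriched":
            hits = call_enriched(records, params)
        elif direction == "depleted":
            hits = call_depleted(records, params)
        else:
            raise ValueError(f"unknown direction: {direction!r}")
        return cls(
            screen_id=screen_id,
            records=records,
            hits=hits,
            codons=codon_summary(hits),
            groups=group_stats(records),
        )
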