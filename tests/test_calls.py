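"""Hit calling, codon summaries, cross-screen filtering, class statistics."""

import math

import numpy as np
import pytest

from satscreen import (
    HitCallParams,
    call_depleted,
    call_enriched,
    codon_summary,
    cross_screen_filter,
    group_stats,
)
from satscreen.library import ResidueVariant

from .conftest import make_record


def test_call_enriched_cutoff_one():
    records = [
        make_record(55, "A", "K", 1.2),
        make_record(56, "L", "F", 0.9),
        make_record(57, "G", "V", -3.0),
    ]
    hits = call_enriched(records)
    assert hits == {ResidueVariant(55, "A", "K")}


def test_call_enriched_never_returns_other_classes():
    records = [
        make_record(55, "A", "A", 5.0),   # synonymous
        make_record(56, "L", "*", 5.0),   # nonsense
        make_record(57, "G", "G", 3.0),
    ]
    assert call_enriched(records) == set()


def test_call_enriched_excludes_dropouts_and_errors():
    records = [make_record(55, "A", "K", None, dropout=True),
               make_record(56, "L", "F", 2.0)]
    assert call_enriched(records) == {ResidueVariant(56, "L", "F")}
    with pytest.raises(ValueError, match="empty"):
        call_enriched([])


def test_call_enriched_monotone_in_cutoff(rng):
    records = [
        make_record(50 + i, "A", "K", float(x))
        for i, x in enumerate(rng.normal(0, 2, size=60))
    ]
    previous = None
    for cutoff in (0.5, 1.0, 1.5, 2.0, 3.0):
        hits = call_enriched(records, HitCallParams(enrichment_cutoff=cutoff))
        if previous is not None:
            assert hits <= previous
        previous = hits


def _nonsense_reference():
    # five nonsense values: median -4, q1 -4.5, q3 -3.5, IQR 1
    return [
        make_record(60 + i, "A", "*", v)
        for i, v in enumerate([-5.0, -4.5, -4.0, -3.5, -3.0])
    ]


def test_call_depleted_below_all_nonsense():
    records = _nonsense_reference() + [make_record(70, "A", "K", -6.0)]
    assert call_depleted(records) == {ResidueVariant(70, "A", "K")}


def test_call_depleted_rejects_clearly_functional():
    # missense at 0 while nonsense median is -4 (IQR 1): not depleted under
    # either rule (fence threshold -2, median rule threshold -3.5)
    records = _nonsense_reference() + [make_record(70, "A", "K", 0.0)]
    assert call_depleted(records) == set()
    assert call_depleted(
        records, HitCallParams(depletion_rule="median_iqr")
    ) == set()


def test_call_depleted_rule_thresholds():
    records = _nonsense_reference() + [
        make_record(70, "A", "K", -2.1),   # just inside the Tukey fence
        make_record(71, "A", "K", -1.9),   # just outside
    ]
    fence_hits = call_depleted(records)
    assert fence_hits == {ResidueVariant(70, "A", "K")}
    # the stricter rule (median + IQR/2 = -3.5) takes neither
    assert call_depleted(
        records, HitCallParams(depletion_rule="median_iqr")
    ) == set()


def test_call_depleted_needs_nonsense_reference():
    with pytest.raises(ValueError, match="nonsense"):
        call_depleted([make_record(70, "A", "K", -6.0)])


def test_codon_summary_proline_flags():
    p60 = ResidueVariant(60, "A", "P")
    k60 = ResidueVariant(60, "A", "K")
    assert codon_summary({p60})[60].proline_only
    summary = codon_summary({p60, k60})
    assert not summary[60].proline_only


def test_codon_summary_partitions_hits(rng):
    hits = {
        ResidueVariant(50 + int(rng.integers(10)), "A", alt)
        for alt in "KLMNPQRSTVWY"
    }
    summary = codon_summary(hits)
    assert sum(len(c.variants) for c in summary.values()) == len(hits)
    for pos, c in summary.items():
        assert all(v.position == pos for v in c.variants)


def test_cross_screen_filter_example():
    a55y = ResidueVariant(55, "A", "Y")
    a55k = ResidueVariant(55, "A", "K")
    x60p = ResidueVariant(60, "G", "P")
    assert cross_screen_filter({a55y, a55k, x60p}, {a55k}) == {a55y}


def test_cross_screen_filter_identity_and_disjointness():
    depleted = {ResidueVariant(62, "P", "A"), ResidueVariant(64, "R", "E")}
    assert cross_screen_filter(depleted, set()) == depleted
    lof_im = {ResidueVariant(62, "P", "A")}
    out = cross_screen_filter(depleted | {ResidueVariant(70, "A", "P")}, lof_im)
    assert out & lof_im == set()
    assert all(v.alt_aa != "P" for v in out)


def _records_from_groups(syn, mis, non):
    records = []
    for i, v in enumerate(syn):
        records.append(make_record(50 + i, "A", "A", float(v)))
    for i, v in enumerate(mis):
        records.append(make_record(50 + i, "A", "K", float(v)))
    for i, v in enumerate(non):
        records.append(make_record(50 + i, "A", "*", float(v)))
    return records


def test_group_stats_identical_groups_give_zero_F():
    gs = group_stats(_records_from_groups([1, 2, 3], [1, 2, 3], []))
    assert gs.anova_F == 0.0


def test_group_stats_matches_hand_evaluated_F():
    # {0,0,0} vs {1,1,1}: between-group SS = 1.5 (1 df), within SS = 0 -> inf
    gs = group_stats(_records_from_groups([0, 0, 0], [1, 1, 1], []))
    assert math.isinf(gs.anova_F)
    # a case with finite F, hand evaluation of the sums-of-squares formulas:
    # groups {0,1,2} and {2,3,4}: grand mean 2, SSB = 3*(1-2)^2 + 3*(3-2)^2 = 6,
    # SSW = 2 + 2 = 4, F = (6/1)/(4/4) = 6
    gs = group_stats(_records_from_groups([0, 1, 2], [2, 3, 4], []))
    assert gs.anova_F == pytest.approx(6.0, abs=1e-12)


def test_group_stats_quartiles_match_sort_oracle(rng):
    values = rng.normal(size=31)
    gs = group_stats(_records_from_groups(values, rng.normal(size=8), []))
    stats = gs.classes["synonymous"]

    def quantile(sorted_v, q):
        # linear interpolation between order statistics
        h = (len(sorted_v) - 1) * q
        lo, hi = int(math.floor(h)), int(math.ceil(h))
        return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

    sv = sorted(values)
    assert stats.q1 == pytest.approx(quantile(sv, 0.25), abs=1e-12)
    assert stats.median == pytest.approx(quantile(sv, 0.5), abs=1e-12)
    assert stats.q3 == pytest.approx(quantile(sv, 0.75), abs=1e-12)
    assert stats.q1 <= stats.median <= stats.q3


def test_F_statistic_shift_and_scale_invariance(rng):
    syn = rng.normal(size=20)
    non = rng.normal(loc=2, size=15)
    base = group_stats(_records_from_groups(syn, [], non)).anova_F
    shifted = group_stats(_records_from_groups(syn + 7.5, [], non + 7.5)).anova_F
    scaled = group_stats(_records_from_groups(syn * 3.2, [], non * 3.2)).anova_F
    assert shifted == pytest.approx(base, rel=1e-9)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_group_stats_pairwise_adjustment():
    gs = group_stats(
        _records_from_groups([0.0, 0.1, -0.1], [2.0, 2.2, 1.9], [-4.0, -4.1, -3.8])
    )
    assert {p.group for p in gs.pairwise} == {"missense", "nonsense"}
    for p in gs.pairwise:
        assert p.reference == "synonymous"
        assert p.p_adjusted == pytest.approx(min(1.0, p.p_raw * 2), abs=1e-15)


def test_group_stats_requires_two_usable_classes():
    with pytest.raises(ValueError):
        group_stats(_records_from_groups([1, 2], [], []))
    with pytest.raises(ValueError):
        group_stats(_records_from_groups([1, 2], [3], []))  # singleton class
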