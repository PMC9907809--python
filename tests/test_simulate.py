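"""Competitive-growth simulator: activities, growth, sampling, determinism."""

import numpy as np
import pytest

from satscreen import (
    SimConfig,
    assign_activities,
    default_library,
    generate_screen,
    parse_variant_name,
    run_screen,
    sequence_pool,
    simulate_pool,
    synthetic_rcsf_cds,
)
from satscreen.io import write_aa_count_tables
from satscreen.simulate import MissenseActivityModel, lof_im_model, lof_om_model


def test_synthetic_cds_is_deterministic_and_pinned():
    cds = synthetic_rcsf_cds()
    assert cds == synthetic_rcsf_cds()
    assert len(cds) == 134 * 3
    lib = default_library()
    assert lib.protein[54] == "A"   # Ala55
    assert lib.protein[131] == "T"  # Thr132
    assert lib.protein[15] == "C"   # lipidated Cys16


def test_assign_activities_class_defaults(full_library):
    profile = assign_activities(full_library, rng=0)
    for v in full_library.aa_variants():
        a = profile.activity(v)
        if v.vclass == "synonymous":
            assert a == 1.0
        elif v.vclass == "nonsense":
            # truncations at the two most C-terminal positions keep function
            assert a == (1.0 if v.position >= 133 else 0.0)
        else:
            assert a >= 0


def test_assign_activities_planted_overrides(full_library):
    profile = assign_activities(full_library, planted={"T132I": 1.8}, rng=0)
    assert profile.activity(parse_variant_name("T132I")) == 1.8
    with pytest.raises(ValueError, match="outside library"):
        assign_activities(full_library, planted={"M1K": 1.0})
    with pytest.raises(ValueError, match="outside library"):
        assign_activities(full_library, planted={"A999K": 1.0})


def test_missense_mixture_model(rng):
    model = MissenseActivityModel()
    draws = model.sample(rng, 5000)
    assert np.all(draws >= 0)
    neutral = np.mean(draws == 1.0)
    assert 0.7 < neutral < 0.8
    with pytest.raises(ValueError, match="sum to 1"):
        MissenseActivityModel(p_neutral=0.9, p_lof=0.2, p_gof=0.05)


def test_neutral_growth_preserves_frequencies(rng):
    p0 = rng.dirichlet(np.ones(30))
    out = simulate_pool(p0, np.ones(30), generations=11)
    np.testing.assert_allclose(out, p0, rtol=1e-12)


def test_two_variant_doubling_ratio():
    out = simulate_pool(np.array([0.5, 0.5]), np.array([1.0, 0.0]), 11)
    assert out[0] / out[1] == pytest.approx(2**11, rel=1e-12)


def test_growth_matches_per_generation_oracle(rng):
    """Closed form equals an explicit generation-by-generation doubling loop."""
    n = 40
    p0 = rng.dirichlet(np.ones(n))
    w = rng.uniform(0, 2, size=n)
    generations = 9
    closed = simulate_pool(p0, w, generations)
    pop = p0.copy()
    for _ in range(generations):
        pop = pop * 2.0**w
        pop = pop / pop.sum()
    np.testing.assert_allclose(closed, pop, rtol=1e-9)


def test_simulate_pool_validation():
    with pytest.raises(ValueError, match="not all zero"):
        simulate_pool(np.zeros(3), np.ones(3), 5)
    with pytest.raises(ValueError, match="non-negative"):
        simulate_pool(np.ones(3) / 3, np.array([1.0, -0.1, 1.0]), 5)


def test_sequence_pool_point_mass_and_sum(rng):
    counts = sequence_pool(np.array([0.0, 1.0, 0.0]), 1000, rng)
    assert counts[1] == 1000 and counts.sum() == 1000
    counts = sequence_pool(rng.dirichlet(np.ones(10)), 12345, rng)
    assert counts.sum() == 12345


def test_sequence_pool_binomial_moments():
    depth = 1_000_000
    counts = sequence_pool(np.array([0.5, 0.5]), depth, np.random.default_rng(5))
    sd = np.sqrt(depth * 0.25)
    assert abs(counts[0] - depth / 2) < 5 * sd


def test_sequence_pool_reproducible():
    p = np.array([0.2, 0.3, 0.5])
    a = sequence_pool(p, 10_000, np.random.default_rng(42))
    b = sequence_pool(p, 10_000, np.random.default_rng(42))
    np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def small_screen_config():
    lib = default_library()
    return SimConfig.for_screen("LOF_IM", library=lib, seed=3, depth=200_000)


def test_generate_screen_shapes(small_screen_config):
    data = generate_screen(small_screen_config)
    assert len(data.selective) == len(data.control) == 3
    for t in data.selective + data.control:
        assert t.total_reads == 200_000
        assert t.assigned_reads == 200_000  # multinomial over variants + WT
    assert data.manifest["screen_id"] == "LOF_IM"


def test_generate_screen_byte_identical_given_seed(small_screen_config, tmp_path):
    a = generate_screen(small_screen_config)
    b = generate_screen(small_screen_config)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_aa_count_tables(a.selective + a.control, pa)
    write_aa_count_tables(b.selective + b.control, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_neutral_screen_class_medians_near_zero():
    """With every activity mapped to fitness 1, all classes sit at log2FC ~ 0."""
    lib = default_library()
    profile = assign_activities(lib, rng=0)
    neutral = lof_om_model(w0=1.0, k=0.0)  # w = 1 regardless of activity
    config = SimConfig.for_screen(
        "LOF_OM", library=lib, activities=profile, seed=9, depth=500_000
    )
    config.fitness = neutral
    _, records = run_screen(config)
    means = np.array([
        r.log2fc_mean for r in records
        if not r.control_dropout and r.log2fc_mean is not None
    ])
    assert abs(np.median(means)) < 0.05


def test_planted_sweep_wins_at_long_outgrowth(full_library):
    """A strongly activated variant outcompetes everything by generation 11."""
    planted = {"T132I": 2.2}
    profile = assign_activities(full_library, planted=planted, rng=4)
    config = SimConfig.for_screen(
        "GOF_OM", library=full_library, activities=profile, seed=4
    )
    variants = full_library.aa_variants()
    a = np.array([profile.activity(v) for v in variants] + [1.0])
    w = config.fitness.selective_fitness(a)
    start = np.full(len(a), 1.0 / len(a))
    final = simulate_pool(start, w, config.generations)
    assert variants[int(np.argmax(final))] == parse_variant_name("T132I")


def test_lof_im_replicate_scores_track_fitness_differences():
    """Scored log2FC gaps approximate G*(w_i - w_j) at finite depth."""
    lib = default_library()
    profile = assign_activities(lib, rng=12)
    config = SimConfig.for_screen(
        "LOF_IM", library=lib, activities=profile, seed=12, depth=1_000_000
    )
    _, records = run_screen(config)
    by_class = {}
    for r in records:
        if not r.control_dropout and r.log2fc_mean is not None:
            by_class.setdefault(r.vclass, []).append(r.log2fc_mean)
    syn = np.median(by_class["synonymous"])
    non = np.median(by_class["nonsense"])
    model = lof_im_model()
    # nonsense (a=0, w=1) vs synonymous (a=1, w=1-s_tox): gap = G * s_tox
    expected_gap = config.generations * model.s_tox
    assert non - syn == pytest.approx(expected_gap, rel=0.1)
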