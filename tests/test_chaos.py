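import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvchaos import chaos
from hrvchaos.chaos import (
    EntropyParams,
    PartitionSpec,
    approximate_entropy,
    build_partition,
    chaos_degree,
    chaos_indicator_ratio,
    compute_chaos_indices,
    higuchi_fd,
    improved_chaos_degree,
    poincare_descriptors,
    sample_entropy,
    transition_statistics,
)
from oracles import apen_bruteforce, sampen_bruteforce

random_series = st.integers(min_value=0, max_value=2**31 - 1).map(
    lambda s: np.random.default_rng(s).normal(800, 50, 120)
)


class TestEntropies:
    def test_constant_series_returns_zero(self):
        x = np.full(50, 800.0)
        assert approximate_entropy(x) == 0.0
        assert sample_entropy(x) == 0.0

    @pytest.mark.parametrize("seed,n", [(1, 20), (2, 35), (3, 50)])
    def test_apen_matches_bruteforce(self, seed, n):
        x = np.random.default_rng(seed).normal(800, 50, n)
        r = 0.2 * np.std(x, ddof=1)
        assert approximate_entropy(x) == pytest.approx(
            apen_bruteforce(list(x), 2, r), abs=1e-10
        )

    def test_apen_alternation_matches_bruteforce(self):
        x = np.tile([800.0, 850.0], 50)
        r = 0.2 * np.std(x, ddof=1)
        assert approximate_entropy(x) == pytest.approx(
            apen_bruteforce(list(x), 2, r), abs=1e-10
        )

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_sampen_matches_bruteforce(self, seed):
        # smooth oscillation + noise guarantees (m+1)-template matches exist
        rng = np.random.default_rng(seed)
        x = 800 + 60 * np.sin(np.arange(30) * 0.5) + rng.normal(0, 10, 30)
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x) == pytest.approx(
            sampen_bruteforce(list(x), 2, r), abs=1e-10
        )

    def test_sampen_no_matches_gives_nan(self):
        # white gaussian draw with no (m+1)-template matches within r
        x = np.random.default_rng(6).normal(800, 50, 60)
        assert math.isnan(sample_entropy(x))

    def test_affine_invariance(self):
        x = np.random.default_rng(7).normal(800, 50, 50)
        assert approximate_entropy(x) == pytest.approx(
            approximate_entropy(3 * x + 1000), abs=1e-10
        )
        assert sample_entropy(x) == pytest.approx(
            sample_entropy(3 * x + 1000), abs=1e-10
        )

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.array([1.0, 2.0, 3.0]))


class TestHiguchi:
    def test_linear_ramp_dimension_one(self):
        assert higuchi_fd(np.arange(500.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        x = np.random.default_rng(8).normal(0, 1, 420)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.15)

    def test_affine_invariance(self):
        x = np.random.default_rng(9).normal(800, 50, 200)
        assert higuchi_fd(x) == pytest.approx(higuchi_fd(2.5 * x + 300), abs=1e-9)

    def test_constant_series_is_one(self):
        assert higuchi_fd(np.full(100, 800.0)) == 1.0


class TestPoincare:
    def test_sd1_equals_population_sdsd_over_sqrt2(self):
        from hrvchaos.time_domain import sdsd_population

        x = np.random.default_rng(10).normal(800, 50, 200)
        sd1, _, _ = poincare_descriptors(x)
        assert sd1 == pytest.approx(sdsd_population(x) / math.sqrt(2), abs=1e-10)

    def test_iid_ratio_near_one(self):
        x = np.random.default_rng(11).normal(800, 50, 5000)
        _, _, ratio = poincare_descriptors(x)
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_linear_series_zero_sd1(self):
        x = 800.0 + 5.0 * np.arange(100)
        sd1, sd2, _ = poincare_descriptors(x)
        assert sd1 == pytest.approx(0.0, abs=1e-9)
        assert sd2 > 0

    def test_constant_series_ratio_sentinel(self):
        sd1, sd2, ratio = poincare_descriptors(np.full(10, 800.0))
        assert sd2 == 0 and math.isnan(ratio)


class TestPartition:
    def test_two_sigma_interval(self):
        # sample with mean exactly 800 and sample sd exactly 50
        x = np.array([800 - 50 / math.sqrt(2), 800 + 50 / math.sqrt(2)] * 2)
        x = 800 + (x - 800) * 50 / np.std(x, ddof=1)
        part = build_partition(x, n_cells=20)
        assert part.a == pytest.approx(800 - 2 * np.std(x, ddof=1))
        assert part.b == pytest.approx(800 + 2 * np.std(x, ddof=1))
        assert part.cell_width == pytest.approx((part.b - part.a) / 20)

    def test_boundary_assignment(self):
        part = PartitionSpec(700.0, 900.0, 20)
        idx = part.cell_index(np.array([700.0, 900.0, 699.9, 900.1]))
        assert idx[0] == 0 and idx[1] == 19
        assert idx[2] == -1 and idx[3] == -1

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_partition(np.full(10, 800.0), 20)


class TestTransitions:
    def test_two_state_alternation_counts(self):
        # values alternate between cell 0 and cell 1 of [0, 0.2)/[0.2, 0.4]
        x = np.array([0.1, 0.3, 0.1, 0.3, 0.1, 0.3])
        part = PartitionSpec(0.0, 0.4, 2)
        model = transition_statistics(x, part)
        assert model.m_transitions == 5
        assert model.p_ij[0, 1] == pytest.approx(3 / 5)
        assert model.p_ij[1, 0] == pytest.approx(2 / 5)
        assert model.p_ij[0, 0] == model.p_ij[1, 1] == 0
        assert model.p_i[0] == pytest.approx(3 / 5)

    @settings(max_examples=25, deadline=None)
    @given(random_series)
    def test_normalisation_and_q_bound(self, x):
        part = build_partition(x, 10, 4)
        model = transition_statistics(x, part)
        assert model.p_i.sum() == pytest.approx(1.0, abs=1e-12)
        assert model.p_ij.sum() == pytest.approx(1.0, abs=1e-12)
        occupied = model.p_ij > 0
        assert np.all(model.q_ij[occupied] >= 1 / 4 - 1e-12)
        rows = model.p_i > 0
        np.testing.assert_allclose(model.p_j_given_i[rows].sum(axis=1), 1.0, atol=1e-12)


class TestChaosDegree:
    def test_deterministic_cycle_zero(self):
        x = np.array([0.1, 0.3, 0.1, 0.3, 0.1, 0.3, 0.1])
        model = transition_statistics(x, PartitionSpec(0.0, 0.4, 2))
        assert chaos_degree(model) == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_approaches_log_n(self):
        u = np.random.default_rng(1).uniform(0, 1, 5001)
        model = transition_statistics(u, PartitionSpec(0.0, 1.0, 20))
        assert chaos_degree(model) == pytest.approx(math.log(20), abs=0.08)

    @settings(max_examples=25, deadline=None)
    @given(random_series)
    def test_entropy_bounds(self, x):
        part = build_partition(x, 20)
        cd = chaos_degree(transition_statistics(x, part))
        assert -1e-12 <= cd <= math.log(20) + 1e-12


class TestImprovedChaosDegree:
    def test_icd_equals_cd_minus_log_q_on_single_subcell_data(self):
        # values sit on cell centres, so every occupied transition lands in
        # exactly one subcell of its destination cell
        rng = np.random.default_rng(2)
        centres = np.array([0.125, 0.375, 0.625, 0.875])
        x = centres[rng.integers(0, 4, 500)]
        part = PartitionSpec(0.0, 1.0, 4, q_subcells=4)
        cd = chaos_degree(transition_statistics(x, part))
        icd = improved_chaos_degree(x, part)
        assert icd == pytest.approx(cd - math.log(4), abs=1e-12)
        assert cd > 0  # transitions are genuinely stochastic here

    def test_logistic_map_lyapunov(self):
        from hrvchaos.synthetic import logistic_map_series

        orbit = logistic_map_series(4.0, 0.2, 10_000)
        icd = improved_chaos_degree(orbit, PartitionSpec(0.0, 1.0, 100, 4))
        assert icd == pytest.approx(math.log(2), abs=0.1)

    @settings(max_examples=25, deadline=None)
    @given(random_series)
    def test_icd_never_exceeds_cd(self, x):
        part = build_partition(x, 10, 4)
        cd = chaos_degree(transition_statistics(x, part))
        icd = improved_chaos_degree(x, part)
        assert icd <= cd + 1e-12


class TestIndicatorRatio:
    def test_identity(self):
        assert chaos_indicator_ratio(1.5, 1.5) == 1.0

    def test_zero_rest_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            chaos_indicator_ratio(0.0, 1.0)


class TestFullBlock:
    def test_constant_series_flagged_not_crashed(self):
        ci = compute_chaos_indices(np.full(450, 800.0))
        assert ci.apen == 0.0 and ci.sampen == 0.0
        assert ci.sd1 == 0.0 and ci.sd2 == 0.0
        assert math.isnan(ci.sd1_sd2) and "sd1_sd2" in ci.flags
        assert math.isnan(ci.cd) and "cd" in ci.flags
        assert math.isnan(ci.icd) and "icd" in ci.flags

    def test_affine_invariance_of_all_six(self):
        x = np.random.default_rng(3).normal(800, 50, 420)
        a = compute_chaos_indices(x)
        b = compute_chaos_indices(2.0 * x + 500.0)
        for name in ("apen", "sampen", "fractal_dimension", "sd1_sd2", "cd", "icd"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-8), name


def test_chaos_indices_track_lyapunov_across_logistic_family():
    """ICD, CD, ApEn and SampEn rank logistic-map orbits like the Lyapunov
    exponent across r in {3.5, ..., 4.0}."""
    from scipy.stats import spearmanr

    from hrvchaos.synthetic import logistic_map_series, numeric_lyapunov

    rs = [3.5, 3.6, 3.7, 3.8, 3.9, 4.0]
    part = PartitionSpec(0.0, 1.0, 100, 4)
    lyap, icds, cds, apens, sampens = [], [], [], [], []
    for i, r in enumerate(rs):
        orbit = logistic_map_series(r, 0.3 + 0.01 * i, 10_000)
        icds.append(improved_chaos_degree(orbit, part))
        cds.append(chaos_degree(transition_statistics(orbit, part)))
        sub = orbit[:1500]
        apens.append(approximate_entropy(sub))
        sampens.append(sample_entropy(sub))
        lyap.append(numeric_lyapunov(r, seed=i))
    for name, vals in [("icd", icds), ("cd", cds), ("apen", apens), ("sampen", sampens)]:
        rho = spearmanr(vals, lyap).statistic
        assert rho >= 0.8, f"{name}: spearman {rho}"
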