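"""Unit and property tests for the closed-form Poisson loading model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from barnyard.model import (
    DropletCounts,
    EstimationError,
    InconsistentCountsError,
    PoissonLoad,
    UnidentifiableTotalError,
    ValidationError,
    bootstrap_interval,
    doublet_approximation,
    estimate_from_counts,
    estimator_standard_error,
    expected_counts,
    infer_rates,
    infer_total_droplets,
    multiplet_frequency,
    prob_multiplet,
    prob_nonempty,
)

from conftest import ALL_M_EXAMPLES, EQUAL_MIX_EXAMPLES


# strategy for valid, non-degenerate observable triples: N12 >= 1 and strictly
# below both per-type counts (so all rates are finite)
valid_counts = st.tuples(
    st.integers(min_value=1, max_value=5000),      # n12
    st.integers(min_value=1, max_value=100_000),   # extra type-1-only
    st.integers(min_value=1, max_value=100_000),   # extra type-2-only
).map(lambda t: DropletCounts(n_type1=t[0] + t[1], n_type2=t[0] + t[2], n_mixed=t[0]))


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            DropletCounts(-1, 5, 0)

    def test_mixed_exceeding_per_type_rejected(self):
        with pytest.raises(ValidationError):
            DropletCounts(5, 20, 10)

    def test_fractional_counts_accepted(self):
        c = DropletCounts(2050.5, 2050.0, 100.0)
        assert c.n_nonempty == pytest.approx(4000.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            PoissonLoad(mu1=-0.1, mu2=0.5, n_droplets=100)

    def test_zero_droplets_rejected(self):
        with pytest.raises(ValidationError):
            PoissonLoad(mu1=0.1, mu2=0.1, n_droplets=0)


class TestProbabilities:
    @pytest.mark.parametrize(
        "mu1, mu2, expected",
        [
            (0.0, 0.0, 0.0),
            (0.05001, 0.05001, 1 - math.exp(-0.10002)),
            (math.log(2), math.log(2), 0.75),
        ],
    )
    def test_prob_nonempty(self, mu1, mu2, expected):
        assert prob_nonempty(PoissonLoad(mu1, mu2, 1)) == pytest.approx(expected, abs=1e-12)

    def test_prob_multiplet_zero_load(self):
        assert prob_multiplet(PoissonLoad(0, 0, 1)) == 0.0

    def test_prob_multiplet_against_pmf_sum(self):
        # independent oracle: sum the Poisson pmf from k=2 upward, at the
        # loading implied by a 40% droplet-miss rate per type (mu = -2 ln 0.6)
        mu1 = mu2 = -math.log(0.6)
        expected = sum(poisson.pmf(k, mu1 + mu2) for k in range(2, 51))
        assert prob_multiplet(PoissonLoad(mu1, mu2, 1)) == pytest.approx(
            expected, abs=1e-10
        )
        assert expected == pytest.approx(0.27221, abs=5e-5)

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=10.0))
    def test_multiplet_nested_in_nonempty(self, mu1, mu2):
        load = PoissonLoad(mu1, mu2, 1)
        assert 0.0 <= prob_multiplet(load) <= prob_nonempty(load) < 1.0


class TestMultipletFrequency:
    def test_oracle_equivalence_truncated_pmf(self):
        # M must equal [sum_{k>=2} pmf] / [sum_{k>=1} pmf] for random loads
        rng = np.random.default_rng(42)
        for _ in range(200):
            mu = rng.uniform(1e-6, 5.0)
            split = rng.uniform(0, 1)
            load = PoissonLoad(mu * split, mu * (1 - split), 1)
            ks = np.arange(0, 61)
            pmf = poisson.pmf(ks, mu)
            oracle = pmf[2:].sum() / pmf[1:].sum()
            assert multiplet_frequency(load) == pytest.approx(oracle, abs=1e-10)

    def test_depends_only_on_rate_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mu = rng.uniform(0.01, 5.0)
            f = rng.uniform(0, 1)
            a = multiplet_frequency(PoissonLoad(mu * f, mu * (1 - f), 1))
            b = multiplet_frequency(PoissonLoad(mu, 0.0, 1))
            assert a == pytest.approx(b, rel=1e-12)

    def test_strictly_increasing_in_rate_sum(self):
        grid = np.linspace(0.01, 5.0, 100)
        ms = [multiplet_frequency(PoissonLoad(mu, 0, 1)) for mu in grid]
        assert all(b > a for a, b in zip(ms, ms[1:]))

    def test_small_mu_limit_is_half_mu(self):
        for mu in (1e-3, 1e-5, 1e-7):
            assert multiplet_frequency(PoissonLoad(mu, 0, 1)) == pytest.approx(
                mu / 2, rel=1e-2
            )

    def test_zero_load_raises(self):
        with pytest.raises(EstimationError):
            multiplet_frequency(PoissonLoad(0, 0, 1))

    @pytest.mark.parametrize(
        "mu1, mu2, expected",
        [(0.5108, 0.5108, 0.425), (1.0986, 0.02564, 0.459)],
    )
    def test_worked_examples(self, mu1, mu2, expected):
        assert round(multiplet_frequency(PoissonLoad(mu1, mu2, 1)), 3) == expected


class TestRateInversion:
    @pytest.mark.parametrize(
        "counts, expected_n",
        [((2050, 2050, 100), 42_025.0), ((3950, 150, 100), 5_925.0)],
    )
    def test_total_droplets(self, counts, expected_n):
        assert infer_total_droplets(DropletCounts(*counts)) == pytest.approx(expected_n)

    def test_total_droplets_is_fractional(self):
        assert infer_total_droplets(DropletCounts(2005, 2005, 10)) == pytest.approx(402_002.5)

    def test_zero_mixed_unidentifiable(self):
        with pytest.raises(UnidentifiableTotalError, match="n_mixed"):
            infer_rates(DropletCounts(10, 10, 0))

    def test_saturated_mixed_inconsistent(self):
        # N12 = N1 = N2 gives N = N1, implying an infinite rate
        with pytest.raises(InconsistentCountsError):
            infer_rates(DropletCounts(10, 10, 10))

    def test_equal_mix_rates(self):
        load = infer_rates(DropletCounts(2050, 2050, 100))
        expected = -math.log(39_975 / 42_025)
        assert load.mu1 == pytest.approx(expected, rel=1e-12)
        assert load.mu2 == pytest.approx(expected, rel=1e-12)
        assert load.mu1 == pytest.approx(0.05001, abs=5e-6)

    def test_unequal_mix_rates(self):
        load = infer_rates(DropletCounts(3850, 250, 100))
        assert load.mu1 == pytest.approx(-math.log(0.6), rel=1e-9)
        assert load.mu2 == pytest.approx(0.02632, abs=5e-6)

    @given(valid_counts)
    def test_swap_symmetry(self, counts):
        load = infer_rates(counts)
        swapped = infer_rates(counts.swapped())
        assert (load.mu1, load.mu2) == (swapped.mu2, swapped.mu1)
        assert load.n_droplets == swapped.n_droplets

    @settings(max_examples=200)
    @given(valid_counts)
    def test_expected_counts_round_trip(self, counts):
        back = expected_counts(infer_rates(counts))
        assert back.n_type1 == pytest.approx(counts.n_type1, rel=1e-9)
        assert back.n_type2 == pytest.approx(counts.n_type2, rel=1e-9)
        assert back.n_mixed == pytest.approx(counts.n_mixed, rel=1e-9)

    def test_expected_counts_zero_load(self):
        c = expected_counts(PoissonLoad(0, 0, 1000))
        assert (c.n_type1, c.n_type2, c.n_mixed) == (0.0, 0.0, 0.0)

    def test_expected_counts_forward(self):
        c = expected_counts(PoissonLoad(0.05001, 0.05001, 42_025))
        assert c.n_type1 == pytest.approx(2050, abs=0.2)
        assert c.n_mixed == pytest.approx(100, abs=0.02)


class TestEstimateFromCounts:
    @pytest.mark.parametrize("n1, n2, n12, expected_m", ALL_M_EXAMPLES)
    def test_reproduces_worked_examples(self, n1, n2, n12, expected_m):
        est = estimate_from_counts(DropletCounts(n1, n2, n12))
        assert round(est.multiplet_frequency, 3) == expected_m

    @pytest.mark.parametrize("n1, n2, n12, _, expected_approx", EQUAL_MIX_EXAMPLES)
    def test_doublet_approximation_examples(self, n1, n2, n12, _, expected_approx):
        assert round(doublet_approximation(DropletCounts(n1, n2, n12)), 3) == expected_approx

    @given(valid_counts)
    def test_type_swap_invariance(self, counts):
        a = estimate_from_counts(counts)
        b = estimate_from_counts(counts.swapped())
        assert a.multiplet_frequency == pytest.approx(b.multiplet_frequency, rel=1e-12)
        assert a.doublet_approximation == b.doublet_approximation

    @given(valid_counts)
    def test_estimate_in_unit_interval(self, counts):
        est = estimate_from_counts(counts)
        assert 0.0 < est.multiplet_frequency < 1.0
        assert est.doublet_approximation == pytest.approx(
            2 * counts.n_mixed / counts.n_nonempty
        )

    def test_approximation_close_at_low_load(self):
        # at low loading the shortcut and exact answer agree to within 2%
        for n1, n2, n12 in [(2005, 2005, 10), (2050, 2050, 100)]:
            est = estimate_from_counts(DropletCounts(n1, n2, n12))
            rel = abs(est.multiplet_frequency - est.doublet_approximation) / (
                est.multiplet_frequency
            )
            assert rel <= 0.02

    def test_approximation_overestimates_at_high_load(self):
        est = estimate_from_counts(DropletCounts(2500, 2500, 1000))
        assert est.doublet_approximation > est.multiplet_frequency

    def test_error_messages_name_offenders(self):
        with pytest.raises(UnidentifiableTotalError, match="n_mixed"):
            estimate_from_counts(DropletCounts(100, 100, 0))
        with pytest.raises(InconsistentCountsError, match="n_type2"):
            estimate_from_counts(DropletCounts(200, 100, 100))


class TestUncertainty:
    def test_delta_method_se_matches_simulation(self):
        # empirical SD over replicates should agree with the analytic SE
        load = PoissonLoad(0.1, 0.1, 20_000)
        se = estimator_standard_error(load)
        rng = np.random.default_rng(3)
        p1 = p2 = 1 - math.exp(-0.1)
        reps = []
        for _ in range(300):
            draws = rng.multinomial(
                20_000,
                [(1 - p1) * (1 - p2), p1 * (1 - p2), (1 - p1) * p2, p1 * p2],
            )
            _, a, b, ab = draws
            est = estimate_from_counts(DropletCounts(a + ab, b + ab, ab))
            reps.append(est.multiplet_frequency)
        assert np.std(reps) == pytest.approx(se, rel=0.25)

    def test_bootstrap_deterministic(self, equal_mix_low_load):
        a = bootstrap_interval(equal_mix_low_load, n_boot=200, seed=11)
        b = bootstrap_interval(equal_mix_low_load, n_boot=200, seed=11)
        assert a == b

    def test_bootstrap_contains_point_estimate(self, equal_mix_low_load):
        est = estimate_from_counts(equal_mix_low_load)
        ci = bootstrap_interval(equal_mix_low_load, n_boot=500, level=0.95, seed=1)
        assert ci.lower < est.multiplet_frequency < ci.upper
        assert ci.lower < 0.049 + 0.01 and ci.upper > 0.049 - 0.01

    def test_bootstrap_interval_narrows_with_level(self, equal_mix_low_load):
        wide = bootstrap_interval(equal_mix_low_load, n_boot=500, level=0.95, seed=2)
        narrow = bootstrap_interval(equal_mix_low_load, n_boot=500, level=0.2, seed=2)
        assert narrow.upper - narrow.lower < wide.upper - wide.lower

    def test_bootstrap_validates_arguments(self, equal_mix_low_load):
        with pytest.raises(ValidationError):
            bootstrap_interval(equal_mix_low_load, n_boot=10)
        with pytest.raises(ValidationError):
            bootstrap_interval(equal_mix_low_load, level=1.5)
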