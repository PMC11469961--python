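import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.random import default_rng
from scipy import stats as sps

from polyburst import (
    AmplitudeMixture,
    AmplitudeModel,
    DerepressionConfig,
    ThreeStateParams,
    TranscriptDistribution,
    distribution_distance,
    fit_halflife,
    fit_p_op,
    sample_amplitude,
    simulate_cell,
    simulate_derepression,
    simulate_population,
)
from polyburst.errors import ValidationError
from polyburst.expression import divide_transcripts


class TestAmplitudeMixture:
    def test_pure_poisson_recovery(self):
        x = default_rng(0).poisson(3.0, 5000)
        model = AmplitudeMixture().fit(x).model_
        assert model.mean() == pytest.approx(3.0, abs=0.1)

    def test_degenerate_sample_falls_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est = AmplitudeMixture().fit(np.ones(50))
        assert est.single_component_
        assert est.pois_mean_ == pytest.approx(1.0)
        assert est.w_nb_ == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            AmplitudeMixture().fit([1, 2, 3, 4, 5])

    def test_nb_dominant_mixture_mean_recovered(self):
        rng = default_rng(1)
        true = AmplitudeModel(w_nb=0.7, nb_size=2.0, nb_prob=0.3, pois_mean=1.0)
        draws = np.where(
            rng.random(5000) < true.w_nb,
            rng.negative_binomial(true.nb_size, true.nb_prob, 5000),
            rng.poisson(true.pois_mean, 5000),
        )
        model = AmplitudeMixture().fit(draws).model_
        assert model.mean() == pytest.approx(true.mean(), rel=0.05)


class TestSampleAmplitude:
    def test_zero_truncated_poisson_mean(self):
        model = AmplitudeModel(w_nb=0.0, pois_mean=3.0)
        rng = default_rng(2)
        draws = [sample_amplitude(model, rng) for _ in range(100_000)]
        expected = 3.0 / (1.0 - np.exp(-3.0))
        assert np.mean(draws) == pytest.approx(expected, abs=0.02)

    def test_never_returns_zero(self):
        model = AmplitudeModel(w_nb=1.0, nb_size=0.5, nb_prob=0.8)
        rng = default_rng(3)
        assert min(sample_amplitude(model, rng) for _ in range(2000)) >= 1

    def test_reproducible_with_fixed_rng(self):
        model = AmplitudeModel()
        a = [sample_amplitude(model, default_rng(4)) for _ in range(10)]
        b = [sample_amplitude(model, default_rng(4)) for _ in range(10)]
        assert a == b


class TestSimulateCell:
    def test_p_op_zero_always_silent(self):
        params = ThreeStateParams(p_op=0.0)
        assert all(simulate_cell(params, default_rng(i)) == 0 for i in range(20))

    def test_deterministic_hand_count(self, unit_amplitude_params):
        # 2 cycles x 3 alleles x 1 ON x 1 transcript, no loss anywhere
        counts = [
            simulate_cell(unit_amplitude_params, default_rng(i)) for i in range(10)
        ]
        assert counts == [6] * 10

    def test_conservation_without_loss(self, unit_amplitude_params):
        params = dataclasses.replace(
            unit_amplitude_params,
            amplitude=AmplitudeModel(w_nb=0.0, pois_mean=3.0),
            lambda_on=4.0,
        )
        # retention 1 and infinite half-life: survivors == produced, so the
        # count is bounded by the maximal possible production
        for i in range(5):
            n = simulate_cell(params, default_rng(i))
            assert n >= 2 * params.n_alleles  # at least 1 per permissive cycle

    def test_division_retention_is_binomial_half(self):
        rng = default_rng(5)
        n = 20
        post = np.array(
            [divide_transcripts(np.zeros(n), 0.5, rng).size for _ in range(10_000)]
        )
        obs = np.bincount(post, minlength=n + 1)
        exp = sps.binom.pmf(np.arange(n + 1), n, 0.5) * len(post)
        mask = exp > 5
        chi2 = ((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum()
        assert sps.chi2.sf(chi2, mask.sum() - 1) > 0.01


class TestSimulatePopulation:
    def test_point_mass_at_zero_without_entry(self):
        dist = simulate_population(ThreeStateParams(p_op=0.0), 200, seed=6)
        assert dist.counts[0] == 200
        assert dist.n_cells == 200

    def test_fixed_seed_identical_histogram(self):
        params = ThreeStateParams(p_op=0.2)
        a = simulate_population(params, 300, seed=7)
        b = simulate_population(params, 300, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_mean_monotone_in_p_op(self):
        means = [
            simulate_population(
                ThreeStateParams(p_op=p), 1500, seed=8
            ).mean()
            for p in (0.05, 0.15, 0.3, 0.6)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_mean_monotone_in_half_life(self):
        means = [
            simulate_population(
                ThreeStateParams(p_op=0.3, half_life_h=hl), 1500, seed=9
            ).mean()
            for hl in (1.0, 3.0, 9.0)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestDistributionDistance:
    def test_identical_distributions_zero(self):
        d = TranscriptDistribution(np.array([10, 5, 2]))
        assert distribution_distance(d, d) == 0.0

    def test_disjoint_point_masses_two(self):
        a = TranscriptDistribution(np.array([100]))
        b = TranscriptDistribution(np.array([0, 0, 50]))
        assert distribution_distance(a, b) == pytest.approx(2.0)

    def test_half_overlap_arithmetic(self):
        a = TranscriptDistribution(np.array([50, 50]))
        b = TranscriptDistribution(np.array([100]))
        assert distribution_distance(a, b) == pytest.approx(1.0)

    def test_empty_distribution_rejected(self):
        a = TranscriptDistribution(np.array([1]))
        with pytest.raises(ValidationError):
            distribution_distance(a, TranscriptDistribution(np.array([0, 0])))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_metric_axioms_on_random_triples(self, seed):
        rng = default_rng(seed)
        dists = [
            TranscriptDistribution(rng.integers(0, 20, size=rng.integers(1, 8)))
            for _ in range(3)
        ]
        for d in dists:
            if d.n_cells == 0:
                return
        a, b, c = dists
        dab = distribution_distance(a, b)
        assert dab == pytest.approx(distribution_distance(b, a))
        assert dab <= distribution_distance(a, c) + distribution_distance(c, b) + 1e-12


class TestFitPop:
    def test_single_point_grid(self):
        target = simulate_population(ThreeStateParams(p_op=0.1), 200, seed=10)
        p_star, profile = fit_p_op(
            target, ThreeStateParams(), [0.07], n_cells=200, n_rep=2, seed=11
        )
        assert p_star == 0.07
        assert len(profile) == 1

    def test_profile_covers_grid(self):
        target = simulate_population(ThreeStateParams(p_op=0.1), 300, seed=12)
        grid = [0.05, 0.1, 0.2]
        _, profile = fit_p_op(
            target, ThreeStateParams(), grid, n_cells=300, n_rep=2, seed=13
        )
        assert [p for p, _ in profile] == grid

    def test_recovery_moderate_size(self):
        target = simulate_population(ThreeStateParams(p_op=0.1), 2000, seed=14)
        p_star, _ = fit_p_op(
            target,
            ThreeStateParams(),
            [0.05, 0.1, 0.2],
            n_cells=1000,
            n_rep=3,
            seed=15,
        )
        assert p_star == 0.1


class TestDerepression:
    def test_zero_extra_window_matches_untreated(self):
        params = ThreeStateParams(p_op=0.1)
        cfg = DerepressionConfig(p_treated=0.1, extra_h=0.0)
        treated = simulate_derepression(params, cfg, 5000, seed=16)
        untreated = simulate_population(params, 5000, seed=17)
        assert distribution_distance(treated, untreated) < 0.05

    def test_same_probability_only_adds_extra_production(self):
        params = ThreeStateParams(p_op=0.2)
        base = simulate_population(params, 4000, seed=18)
        same_p = simulate_derepression(
            params, DerepressionConfig(p_treated=0.2, extra_h=4.0), 4000, seed=18
        )
        raised = simulate_derepression(
            params, DerepressionConfig(p_treated=0.6, extra_h=4.0), 4000, seed=18
        )
        assert base.mean() < same_p.mean() < raised.mean()


class TestFitHalflife:
    def test_two_point_exact(self):
        assert fit_halflife([(0.0, 100.0), (4.0, 50.0)]) == pytest.approx(4.0)

    def test_three_point_exact(self):
        tau = 2.7
        series = [(0.0, 100.0), (tau, 50.0), (2 * tau, 25.0)]
        assert fit_halflife(series) == pytest.approx(tau)

    def test_non_positive_counts_rejected(self):
        with pytest.raises(ValidationError):
            fit_halflife([(0.0, 100.0), (4.0, 0.0)])
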