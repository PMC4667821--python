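"""Birth-death node-age density, likelihood, and the two ML fits."""

import math

import numpy as np
import pytest

from conftest import naive_log_likelihood
from phyloskew import (
    BirthDeathError,
    BirthDeathParams,
    InsufficientDataError,
    draw_node_ages,
    fit_sampling_proportion,
    fit_speciation_extinction,
    log_likelihood,
    p1,
    prob_unsampled,
    v,
)

CRIT = BirthDeathParams(2.0, 1.0, 1.0)


class TestDensityFunctions:
    def test_prob_unsampled_examples(self):
        # full sampling, no extinction: every lineage leaves descendants
        assert prob_unsampled(3.7, BirthDeathParams(1.0, 0.0, 1.0)) == pytest.approx(1.0)
        # at t=0 the factor collapses to the sampling proportion
        assert prob_unsampled(0.0, BirthDeathParams(4.0, 1.5, 0.3)) == pytest.approx(0.3)
        assert prob_unsampled(1.0, CRIT) == pytest.approx(1.0 / (2.0 - math.exp(-1.0)))

    def test_p1_examples(self):
        assert p1(2.0, BirthDeathParams(1.0, 0.0, 1.0)) == pytest.approx(math.exp(-2.0))
        assert p1(0.0, BirthDeathParams(4.0, 1.5, 0.3)) == pytest.approx(0.3)
        P = 1.0 / (2.0 - math.exp(-1.0))
        assert p1(1.0, CRIT) == pytest.approx(P * P * math.exp(-1.0))

    def test_v_examples(self):
        assert v(1.0, BirthDeathParams(1.0, 0.0, 1.0)) == pytest.approx(1 - math.exp(-1))
        assert v(0.0, CRIT) == 0.0
        P = 1.0 / (2.0 - math.exp(-1.0))
        assert v(1.0, CRIT) == pytest.approx(1.0 - P * math.exp(-1.0))

    def test_yule_closed_forms_to_machine_precision(self):
        ts = np.linspace(0.01, 5.0, 40)
        for lam in (0.5, 1.0, 17.0):
            params = BirthDeathParams(lam, 0.0, 1.0)
            np.testing.assert_allclose(p1(ts, params), np.exp(-lam * ts), atol=1e-12)
            np.testing.assert_allclose(v(ts, params), -np.expm1(-lam * ts), atol=1e-12)

    def test_v_monotone_in_range(self):
        ts = np.linspace(0.0, 3.0, 50)
        vals = v(ts, BirthDeathParams(5.0, 2.0, 0.4))
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < 1.0)

    def test_derivative_of_v_is_density_kernel(self):
        h = 1e-6
        for lam in (1.0, 5.0, 20.0):
            for frac in (0.0, 0.3, 0.6, 0.9):
                for rho in (0.05, 0.5, 1.0):
                    params = BirthDeathParams(lam, lam * frac, rho)
                    for t in (0.05, 0.5, 2.0):
                        numeric = (v(t + h, params) - v(t - h, params)) / (2 * h)
                        assert numeric == pytest.approx(
                            lam * p1(t, params), abs=1e-6, rel=1e-5
                        )


class TestLogLikelihood:
    def test_single_pair_closed_form(self):
        # one free age under a Yule process is truncated-exponential
        expected = math.log(math.exp(-1.0) / (1.0 - math.exp(-2.0)))
        assert log_likelihood([2.0, 1.0], BirthDeathParams(1.0, 0.0, 1.0)) == (
            pytest.approx(expected)
        )

    def test_two_species_empty_product(self):
        assert log_likelihood([0.8], CRIT) == 0.0

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(42)
        params = BirthDeathParams(2.0, 1.0, 0.5)
        for _ in range(5):
            rest = rng.uniform(0.01, 0.9, size=30)
            times = np.concatenate([[1.0], rest])
            ours = log_likelihood(times, params)
            naive = naive_log_likelihood(list(times), 2.0, 1.0, 0.5)
            assert ours == pytest.approx(naive, abs=1e-10)

    def test_exchangeable_in_non_root_times(self):
        rng = np.random.default_rng(3)
        rest = rng.uniform(0.05, 0.9, size=20)
        base = log_likelihood(np.concatenate([[1.0], rest]), CRIT)
        for _ in range(3):
            rng.shuffle(rest)
            assert log_likelihood(np.concatenate([[1.0], rest]), CRIT) == (
                pytest.approx(base, rel=1e-12)
            )

    def test_ordering_violation_rejected(self):
        with pytest.raises(BirthDeathError, match="ordering"):
            log_likelihood([1.0, 1.0, 0.5], CRIT)
        with pytest.raises(BirthDeathError):
            log_likelihood([1.0, 0.2, 1.5], CRIT)


class TestSpeciationExtinctionFit:
    def test_yule_simulation_recovery(self):
        truth = BirthDeathParams(5.0, 0.0, 1.0)
        ages = np.concatenate(
            [[1.0], draw_node_ages(499, truth, 1.0, np.random.default_rng(2))]
        )
        res = fit_speciation_extinction(ages, seed=0)
        assert res.converged
        assert res.params.lam == pytest.approx(5.0, rel=0.10)
        # extinction near the zero boundary
        assert res.params.mu < 0.5 * res.params.lam * 0.2

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_speciation_extinction([1.0, 0.5])

    def test_reported_loglik_is_the_maximized_one(self):
        ages = np.concatenate(
            [[1.0], draw_node_ages(99, BirthDeathParams(8, 2, 1), 1.0,
                                   np.random.default_rng(4))]
        )
        res = fit_speciation_extinction(ages, seed=0)
        assert res.llf == pytest.approx(
            log_likelihood(ages, res.params), abs=1e-6
        )
        # a perturbed parameter point cannot beat the reported maximum
        worse = BirthDeathParams(res.params.lam * 1.3, res.params.mu, 1.0)
        assert log_likelihood(ages, worse) < res.llf

    def test_summary_and_flat_serialization(self, tmp_path):
        ages = np.concatenate(
            [[1.0], draw_node_ages(49, BirthDeathParams(8, 2, 1), 1.0,
                                   np.random.default_rng(5))]
        )
        res = fit_speciation_extinction(ages, seed=0)
        text = res.summary()
        assert "lam" in text and "log-likelihood" in text
        out = tmp_path / "fit.txt"
        res.write_flat(out)
        content = out.read_text()
        assert "lam = " in content and "loglik = " in content


class TestSamplingProportionFit:
    def test_full_tree_at_truth_is_nearly_fully_sampled(self, shark_scale_tree):
        res = fit_sampling_proportion(
            shark_scale_tree.divergence_times(), 17.0, 6.0, seed=0
        )
        assert res.converged
        assert res.params.rho > 0.6

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_sampling_proportion([1.0], 2.0, 1.0)

    def test_invalid_fixed_rates(self):
        with pytest.raises(BirthDeathError):
            fit_sampling_proportion([1.0, 0.5], 1.0, 2.0)

    def test_uniform_subsample_recovers_sampling_fraction(self, shark_scale_tree):
        # average over replicates: a 20% binomial subsample should look
        # 20%-sampled to the model
        from phyloskew import sample_community_random

        rhos = []
        for i in range(40):
            members = sample_community_random(shark_scale_tree, 0.2, seed=500 + i,
                                              min_size=11)
            sub = shark_scale_tree.induced_subtree(members)
            res = fit_sampling_proportion(sub.divergence_times(), 17.0, 6.0, seed=0)
            rhos.append(res.params.rho)
        assert np.mean(rhos) == pytest.approx(0.2, abs=0.06)
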