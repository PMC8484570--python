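"""Bayesian inference: preprocessing, log-posteriors, sampler, Rhat, retention."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

import driftarch as da
from driftarch.infer import (
    DEFAULT_FREQ_FLOOR,
    drift_model_logpost,
    rhat,
    simple_model_logpost,
    _LOG_PRIOR_CONST,
)


class TestPreprocess:
    def test_fixation_exclusion(self):
        data = da.preprocess(np.array([0.0, 0.3, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert len(data) == 1
        assert data.f[0] == pytest.approx(0.3)
        assert data.beta[0] == 2.0
        assert list(data.kept_idx) == [1]

    def test_floor_clamps_rare_frequencies(self):
        data = da.preprocess(np.array([0.00005, 0.3]), np.array([1.0, 1.0]), floor=0.0001)
        np.testing.assert_allclose(data.f, [0.0001, 0.3])
        # the unclamped frequency is preserved for the drift likelihood
        np.testing.assert_allclose(data.f_raw, [0.00005, 0.3])

    def test_symmetric_upper_tail_clamp(self):
        data = da.preprocess(np.array([0.99999]), np.array([1.0]), floor=1e-4)
        assert data.f[0] == pytest.approx(1 - 1e-4)

    def test_idempotent_on_interior_data(self):
        f = np.array([0.2, 0.5, 0.8])
        data = da.preprocess(f, np.ones(3))
        np.testing.assert_array_equal(data.f, f)
        np.testing.assert_array_equal(data.f_raw, f)

    def test_all_fixed_is_an_error(self):
        with pytest.raises(ValueError, match="fixed"):
            da.preprocess(np.array([0.0, 1.0]), np.array([1.0, 2.0]))

    @pytest.mark.parametrize("floor", [0.0, 0.5, -1e-3])
    def test_floor_domain(self, floor):
        with pytest.raises(ValueError):
            da.preprocess(np.array([0.3]), np.array([1.0]), floor=floor)


class TestSimpleModelLogpost:
    @pytest.mark.parametrize("S,sig", [(2.5, 1.0), (-2.5, 1.0), (0.0, -0.1), (0.0, 2.5)])
    def test_outside_prior_support(self, S, sig, tiny_inference_data):
        assert simple_model_logpost(S, sig, tiny_inference_data) == -np.inf

    def test_single_snp_standard_normal_at_zero(self):
        data = da.InferenceData(f=np.array([0.5]), beta=np.array([0.0]))
        expected = _LOG_PRIOR_CONST + np.log(1.0 / np.sqrt(2 * np.pi))
        assert simple_model_logpost(0.0, 1.0, data) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("S,sig", [(-1.0, 1.0), (0.7, 0.4), (-1.9, 1.8)])
    def test_matches_scipy_term_by_term(self, S, sig, tiny_inference_data):
        d = tiny_inference_data
        sd = sig * (d.f * (1 - d.f)) ** (S / 2)
        expected = _LOG_PRIOR_CONST + stats.norm.logpdf(d.beta, 0.0, sd).sum()
        assert simple_model_logpost(S, sig, d) == pytest.approx(expected, rel=1e-10)


class TestDriftModelLogpost:
    @pytest.fixture()
    def five_snp_data(self):
        f = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        beta = np.array([0.5, -1.0, 0.2, 1.5, -0.3])
        return da.preprocess(f, beta, fst=0.1)

    def test_outside_prior_support(self, five_snp_data):
        p = np.full(5, 0.4)
        assert drift_model_logpost(2.5, 1.0, p, five_snp_data) == -np.inf
        assert drift_model_logpost(0.0, -0.1, p, five_snp_data) == -np.inf

    def test_latent_frequency_floor_is_a_hard_wall(self, five_snp_data):
        p = np.array([0.4, 0.4, 0.4, 0.4, 1e-6])  # below the 1e-4 floor
        assert drift_model_logpost(0.0, 1.0, p, five_snp_data) == -np.inf

    def test_matches_scipy_term_by_term(self, five_snp_data):
        d = five_snp_data
        S, sig = -0.8, 1.2
        p = np.array([0.15, 0.25, 0.55, 0.65, 0.85])
        a = p * 9.0
        b = (1 - p) * 9.0
        sd = sig * (p * (1 - p)) ** (S / 2)
        expected = (
            _LOG_PRIOR_CONST
            + stats.beta.logpdf(d.f_raw, a, b).sum()
            + stats.norm.logpdf(d.beta, 0.0, sd).sum()
        )
        assert drift_model_logpost(S, sig, p, d) == pytest.approx(expected, rel=1e-10)

    def test_zero_drift_limit_profiles_to_simple_model(self):
        # as fst -> 0 the drift term pins p at f; the profile log-posterior over p
        # then tracks the simple model up to an (S, sigma)-independent constant
        rng = np.random.default_rng(3)
        f = rng.uniform(0.1, 0.9, size=10)
        beta = rng.normal(0, 1, size=10)
        data = da.preprocess(f, beta, fst=1e-6)

        def profile(S, sig):
            total = 0.0
            for i in range(len(f)):
                one = da.InferenceData(f=data.f[i: i + 1], beta=data.beta[i: i + 1],
                                       fst=1e-6, f_raw=data.f_raw[i: i + 1])
                res = optimize.minimize_scalar(
                    lambda p: -drift_model_logpost(S, sig, np.array([p]), one),
                    bounds=(data.f[i] - 1e-4, data.f[i] + 1e-4), method="bounded",
                    options={"xatol": 1e-12},
                )
                total += -res.fun
            return total

        pairs = [(-1.0, 1.0), (0.0, 1.0), (-0.5, 0.6), (1.0, 1.5)]
        prof = np.array([profile(S, sig) for S, sig in pairs])
        simp = np.array([simple_model_logpost(S, sig, data) for S, sig in pairs])
        diffs = prof - simp  # should be the same constant for all pairs
        assert np.max(diffs) - np.min(diffs) < 0.1


class TestRhat:
    def test_identical_chains_give_one_with_warning(self):
        chains = np.tile(np.full(100, 3.0), (2, 1))
        with pytest.warns(RuntimeWarning):
            assert rhat(chains) == 1.0

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 10_000))
        assert abs(rhat(chains) - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500))
        chains[1] += 10.0
        assert rhat(chains) > 1.2

    def test_split_detects_within_chain_drift(self):
        # a trend inside every chain inflates split-Rhat even when chains agree
        trend = np.linspace(0, 10, 1000)
        rng = np.random.default_rng(2)
        chains = trend + rng.normal(0, 0.1, size=(2, 1000))
        assert rhat(chains) > 1.2

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        chains = rng.normal(size=(4, 400)) + rng.normal(size=(4, 1))
        ours = rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, None]),
                               method="split")["x"].values.squeeze())
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            rhat(np.zeros((2, 3)))


class TestFit:
    def test_deterministic_under_seed(self, tiny_inference_data):
        a = da.fit("simple", tiny_inference_data, n_chains=2, n_iter=200, seed=5)
        b = da.fit("simple", tiny_inference_data, n_chains=2, n_iter=200, seed=5)
        c = da.fit("simple", tiny_inference_data, n_chains=2, n_iter=200, seed=6)
        np.testing.assert_array_equal(a.S, b.S)
        np.testing.assert_array_equal(a.sigma_beta, b.sigma_beta)
        assert not np.array_equal(a.S, c.S)

    def test_prior_support_hard_walls(self, tiny_inference_data):
        res = da.fit("simple", tiny_inference_data, n_chains=4, n_iter=500, seed=1)
        assert np.all((res.S > -2) & (res.S < 2))
        assert np.all((res.sigma_beta > 0) & (res.sigma_beta < 2))

    def test_drift_draws_respect_latent_floor(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.05, 0.95, size=50)
        beta = rng.normal(0, 2, size=50)
        data = da.preprocess(f, beta, fst=0.1)
        res = da.fit("drift", data, n_chains=2, n_iter=200, seed=2)
        assert res.p is not None
        assert np.all(res.p >= DEFAULT_FREQ_FLOOR)
        assert np.all(res.p <= 1 - DEFAULT_FREQ_FLOOR)
        assert np.all((res.S > -2) & (res.S < 2))

    def test_retained_flag_tracks_rhat(self, tiny_inference_data):
        res = da.fit("simple", tiny_inference_data, n_chains=4, n_iter=1000, seed=3)
        assert res.retained == (res.rhat_S < 1.2)

    def test_validation_errors(self, tiny_inference_data):
        with pytest.raises(ValueError):
            da.fit("unknown", tiny_inference_data)
        with pytest.raises(ValueError):
            da.fit("simple", tiny_inference_data, n_chains=1)
        with pytest.raises(ValueError):
            da.fit("simple", tiny_inference_data, n_iter=100)
        with pytest.raises(ValueError):
            da.fit("drift", tiny_inference_data)  # no fst on data

    def test_simple_recovery_s_zero(self):
        # S=0 decouples effects from frequency; an easy, identifiable posterior
        rng = np.random.default_rng(10)
        f = rng.uniform(0.01, 0.99, size=1000)
        beta = rng.normal(0, 1.0, size=1000)
        data = da.preprocess(f, beta)
        res = da.fit("simple", data, n_chains=4, n_iter=1000, seed=11)
        lo, hi = res.ci_S()
        assert lo < 0.0 < hi
        assert abs(res.median_S()) < 0.2
        assert res.median_sigma_beta() == pytest.approx(1.0, abs=0.1)


class TestReplicateRuns:
    @staticmethod
    def _easy_generator(i, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.01, 0.99, size=2000)
        beta = rng.normal(0, 1.0, size=2000)
        return da.preprocess(f, beta)

    def test_identifiable_problem_all_retained(self):
        report = da.replicate_runs("simple", self._easy_generator, n_replicates=5,
                                   seed=1, n_chains=4, n_iter=500)
        assert report.fraction_retained == 1.0
        assert np.all(np.abs(report.retained_medians) < 0.25)
        assert 0.0 <= report.fraction_rhat_below_102 <= 1.0

    def test_infinite_cut_retains_everything(self):
        report = da.replicate_runs("simple", self._easy_generator, n_replicates=3,
                                   retention_cut=np.inf, seed=2, n_chains=2, n_iter=200)
        assert report.fraction_retained == 1.0
        assert not report.all_failed

    def test_zero_retained_reports_failure_without_raising(self):
        report = da.RetentionReport(results=[], retention_cut=1.2, n_replicates=1)
        assert report.all_failed
        assert report.fraction_retained == 0.0


@given(st.integers(0, 2**31 - 1))
def test_preprocess_never_emits_boundary_frequencies(seed):
    rng = np.random.default_rng(seed)
    f = rng.choice([0.0, 1.0, 0.5, 1e-6, 1 - 1e-6], size=10)
    if np.all((f == 0.0) | (f == 1.0)):
        return
    data = da.preprocess(f, np.ones(10))
    assert np.all((data.f >= DEFAULT_FREQ_FLOOR) & (data.f <= 1 - DEFAULT_FREQ_FLOOR))
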