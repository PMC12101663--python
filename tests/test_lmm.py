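import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adaptref import (
    LmmRangeState,
    LongitudinalSeries,
    NotFittedError,
    PopulationModel,
    SubjectSummary,
    fit_population_em,
    lmm_range,
    update_subject_variance,
)
from adaptref.lmm import marginal_loglik
from adaptref.simulation import ScenarioSpec, lmm_flag_path, simulate_population

Z975 = 1.9599639845400545  # Phi^{-1}(0.975)


def _recovery_data(between_sd, ratio, seed, n_subjects=120):
    spec = ScenarioSpec(
        between_sd=between_sd, ratio=ratio, n_subjects_pop=n_subjects,
        n_per_subject=100, seed=seed,
    )
    return simulate_population(spec)


class TestFit:
    def test_constant_data_degenerate(self):
        control = [
            LongitudinalSeries("a", np.full(5, 5.0)),
            LongitudinalSeries("b", np.full(5, 5.0)),
        ]
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = fit_population_em(control)
        assert model.mu == pytest.approx(5.0)
        assert model.degenerate
        assert model.tau2 <= 1e-8
        assert all(v <= 1e-8 for v in model.sigma2_by_subject.values())

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="two subjects"):
            fit_population_em([LongitudinalSeries("a", np.array([1.0, 2.0]))])

    def test_needs_repeated_measurements(self):
        control = [
            LongitudinalSeries("a", np.array([1.0])),
            LongitudinalSeries("b", np.array([2.0])),
        ]
        with pytest.raises(ValueError, match="two or more"):
            fit_population_em(control)

    def test_parameter_recovery_homoscedastic(self):
        # mu=5, tau=1, sigma_i=1 for all; I=120, n_i=100
        model = fit_population_em(_recovery_data(1.0, 1.0, seed=2))
        mean_s2 = float(np.mean(list(model.sigma2_by_subject.values())))
        assert model.converged
        assert model.mu == pytest.approx(5.0, rel=0.05)
        assert model.tau2 == pytest.approx(1.0, rel=0.05)
        assert mean_s2 == pytest.approx(1.0, rel=0.05)

    def test_parameter_recovery_smaller_within_sd(self):
        # sigma_i = 0.5 for all: mean sigma2 should recover 0.25
        model = fit_population_em(_recovery_data(1.0, 0.5, seed=2))
        mean_s2 = float(np.mean(list(model.sigma2_by_subject.values())))
        assert mean_s2 == pytest.approx(0.25, rel=0.05)

    def test_parameter_recovery_large_population(self):
        # at I=1000 the between-variance estimate has ~4.5% sampling sd;
        # a 15% tolerance is ~3 sd
        model = fit_population_em(_recovery_data(1.0, 1.0, seed=7, n_subjects=1000))
        assert model.mu == pytest.approx(5.0, rel=0.02)
        assert model.tau2 == pytest.approx(1.0, rel=0.15)

    def test_reml_oracle_agreement(self):
        # independent route: restricted-ML fit of the homoscedastic
        # random-intercept model on the same data
        import statsmodels.formula.api as smf

        pop = _recovery_data(1.0, 1.0, seed=2)
        model = fit_population_em(pop)
        df = pd.DataFrame(
            [{"subject": s.subject_id, "y": y} for s in pop for y in s.values]
        )
        reml = smf.mixedlm("y ~ 1", df, groups=df["subject"]).fit(reml=True)
        assert model.mu == pytest.approx(reml.params["Intercept"], rel=0.02)
        assert model.tau2 == pytest.approx(float(reml.cov_re.iloc[0, 0]), rel=0.02)

    def test_loglik_nondecreasing(self, rng):
        control = [
            LongitudinalSeries(
                f"s{i}",
                rng.normal(5 + rng.standard_normal(), 0.2 + rng.random(), size=12),
            )
            for i in range(15)
        ]
        model = fit_population_em(control)
        trace = np.asarray(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9 * (1.0 + np.abs(trace[:-1])))

    def test_unbalanced_series_supported(self, rng):
        control = [
            LongitudinalSeries(f"s{i}", rng.normal(5, 1, size=n))
            for i, n in enumerate([1, 2, 5, 30, 30])
        ]
        # EM is genuinely slow here (singleton subjects make the likelihood
        # flat in the tau2/sigma2 trade-off), hence the looser tolerance
        model = fit_population_em(control, rtol=1e-7, max_iter=5000)
        assert model.converged
        assert len(model.sigma2_by_subject) == 5

    def test_honest_convergence_flag(self):
        model = fit_population_em(_recovery_data(1.0, 1.0, seed=2), max_iter=1)
        assert not model.converged
        assert model.n_iter == 1

    def test_posterior_variance_identity(self, normal_collection):
        model = fit_population_em(normal_collection)
        for s in normal_collection:
            m_i, v_i = model.posterior_by_subject[s.subject_id]
            s2 = model.sigma2_by_subject[s.subject_id]
            assert v_i == pytest.approx(
                1.0 / (1.0 / model.tau2 + len(s) / s2), rel=1e-10
            )

    def test_loglik_closed_form_matches_multivariate_normal(self, rng):
        # brute-force oracle: dense compound-symmetric MVN density
        values = rng.normal(5, 1, size=6)
        n = np.array([6.0]); ybar = np.array([values.mean()])
        ss = np.array([float(np.sum((values - values.mean()) ** 2))])
        mu, tau2, s2 = 4.8, 0.9, 1.3
        cov = np.full((6, 6), tau2) + np.eye(6) * s2
        expected = stats.multivariate_normal(np.full(6, mu), cov).logpdf(values)
        got = marginal_loglik(n, ybar, ss, mu, tau2, np.array([s2]))
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_serialisation_round_trip(self, tmp_path, normal_collection):
        model = fit_population_em(normal_collection)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PopulationModel.from_json(path)
        assert back.mu == model.mu
        assert back.tau2 == model.tau2
        assert back.sigma2_by_subject == model.sigma2_by_subject
        assert back.converged == model.converged


class TestWorkingVariance:
    def test_no_history_gives_pooled(self, simple_model):
        assert update_subject_variance(
            simple_model, SubjectSummary.empty()
        ) == pytest.approx(simple_model.sigma2_pooled)
        assert update_subject_variance(
            simple_model, SubjectSummary.from_values([7.0])
        ) == pytest.approx(simple_model.sigma2_pooled)

    def test_direct_formula_long_history(self, simple_model, rng):
        values = rng.normal(5, 2, size=100)
        hist = SubjectSummary.from_values(values)
        s2 = float(np.var(values, ddof=1))
        expected = (3.0 * simple_model.sigma2_pooled + 99.0 * s2) / (3.0 + 99.0)
        got = update_subject_variance(simple_model, hist)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_pooling_limit(self, simple_model, rng):
        values = rng.normal(5, 2, size=50)
        hist = SubjectSummary.from_values(values)
        got = update_subject_variance(simple_model, hist, pseudo_obs=0.0)
        assert got == pytest.approx(hist.ss / (hist.n - 1), rel=1e-12)

    def test_requires_model(self):
        with pytest.raises(NotFittedError):
            update_subject_variance(None, SubjectSummary.empty())


class TestRange:
    def test_population_interval_at_first_occasion(self, simple_model):
        state = LmmRangeState.for_new_subject(simple_model)
        r = lmm_range(simple_model, state, alpha=0.05)
        half = Z975 * math.sqrt(2.0)
        assert r.lower == pytest.approx(5.0 - half, abs=1e-9)
        assert r.upper == pytest.approx(5.0 + half, abs=1e-9)
        # 5-dp tabulated z gives the same bounds to ~1e-4
        assert r.upper == pytest.approx(5.0 + 1.95996 * math.sqrt(2.0), abs=1e-4)
        assert r.occasion == 1

    def test_hand_evaluation_second_occasion(self, simple_model):
        state = LmmRangeState(n_history=1, history_mean=7.0, sigma2=1.0)
        r = lmm_range(simple_model, state, alpha=0.05)
        assert (r.lower + r.upper) / 2 == pytest.approx(6.0, rel=1e-12)
        assert r.upper == pytest.approx(6.0 + Z975 * math.sqrt(1.5), abs=1e-9)
        assert r.lower == pytest.approx(6.0 - Z975 * math.sqrt(1.5), abs=1e-9)
        assert r.occasion == 2

    def test_infinite_shrinkage_limit(self, simple_model):
        import dataclasses

        tiny = dataclasses.replace(simple_model, tau2=1e-12)
        state = LmmRangeState(n_history=50, history_mean=9.0, sigma2=1.0)
        r = lmm_range(tiny, state, alpha=0.05)
        assert (r.lower + r.upper) / 2 == pytest.approx(tiny.mu, abs=1e-4)

    def test_large_history_limit_is_subject_interval(self, simple_model):
        state = LmmRangeState(n_history=10**7, history_mean=8.0, sigma2=0.25)
        r = lmm_range(simple_model, state, alpha=0.05)
        assert (r.lower + r.upper) / 2 == pytest.approx(8.0, abs=1e-4)
        assert r.width == pytest.approx(2 * Z975 * 0.5, rel=1e-4)

    def test_first_occasion_equals_population_prediction(self, simple_model):
        # j=1: centre mu, width z*sqrt(tau2 + sigma2) exactly
        state = LmmRangeState(n_history=0, history_mean=0.0, sigma2=0.25)
        r = lmm_range(simple_model, state, alpha=0.05)
        assert r.width == pytest.approx(2 * Z975 * math.sqrt(1.25), rel=1e-12)

    def test_upper_only(self, simple_model):
        state = LmmRangeState.for_new_subject(simple_model)
        r = lmm_range(simple_model, state, alpha=0.05, sidedness="upper_only")
        assert r.lower == 0.0
        assert r.upper == pytest.approx(
            5.0 + stats.norm.ppf(0.95) * math.sqrt(2.0), abs=1e-9
        )

    def test_requires_model(self, simple_model):
        state = LmmRangeState.for_new_subject(simple_model)
        with pytest.raises(NotFittedError):
            lmm_range(None, state, alpha=0.05)

    @given(
        mu=st.floats(min_value=-50, max_value=50),
        tau2=st.floats(min_value=1e-4, max_value=100),
        sigma2=st.floats(min_value=1e-4, max_value=100),
        ybar=st.floats(min_value=-50, max_value=50),
        nh=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=200)
    def test_shrinkage_ordering(self, mu, tau2, sigma2, ybar, nh):
        model = PopulationModel(
            mu=mu, tau2=tau2, sigma2_by_subject={}, sigma2_pooled=sigma2,
            posterior_by_subject={}, converged=True, n_iter=1,
        )
        state = LmmRangeState(n_history=nh, history_mean=ybar, sigma2=sigma2)
        r = lmm_range(model, state, alpha=0.05)
        centre = (r.lower + r.upper) / 2
        if nh == 0:
            assert centre == pytest.approx(mu, rel=1e-9, abs=1e-9)
        else:
            assert min(mu, ybar) - 1e-9 <= centre <= max(mu, ybar) + 1e-9


class TestSelfCoverage:
    def test_late_occasion_exceedance_near_alpha(self, simple_model):
        # data generated from the model's own parameters: by occasion >= 31
        # the exclusion rate is close to nominal
        import dataclasses

        model = dataclasses.replace(simple_model, sigma2_pooled=0.25)
        rng = np.random.default_rng(4242)
        n_subj, n_occ, alpha = 1500, 60, 0.05
        rates = []
        for _ in range(n_subj):
            mu_i = model.mu + math.sqrt(model.tau2) * rng.standard_normal()
            values = mu_i + 0.5 * rng.standard_normal(n_occ)
            flags = lmm_flag_path(values, model, alpha, start=31)
            rates.append(np.nanmean(flags))
        assert float(np.mean(rates)) == pytest.approx(alpha, abs=0.015)
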