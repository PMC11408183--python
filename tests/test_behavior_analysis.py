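"""Zero-inflation diagnostics, ZIP-GLMM engine, and response simulation."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from songtool.behavior_analysis import (
    ModelSpec,
    SimulationParams,
    all_zero_subjects,
    check_zero_inflation,
    fit_combined_steps,
    fit_zip_glmm,
    make_study_frame,
    reduce_zero_inflation_by_aic,
    simulate_responses,
    zip_log_pmf,
)


def _poisson_obs(n_subjects=20, lam_log=0.7, seed=0, **kw):
    trials = make_study_frame(n_subjects=n_subjects, seed=seed, **kw)
    params = SimulationParams(beta={"intercept": lam_log})
    return simulate_responses(trials, params, seed=seed + 500)


class TestCheckZeroInflation:
    def test_pure_poisson_ratio_near_one(self):
        trials = make_study_frame(n_subjects=63, seed=1)  # ~1000 trials
        params = SimulationParams(beta={"intercept": np.log(2.0)})
        obs = simulate_responses(trials, params, seed=11)
        report = check_zero_inflation(obs, "calls", fixed_effects=())
        assert 0.8 <= report.ratio <= 1.2
        assert not report.degenerate

    def test_structural_zeros_flagged(self):
        # 50% structural zeros over Poisson(2). The fitted Poisson
        # absorbs the zeros into its mean (lambda_hat -> 1), so the
        # asymptotic ratio is (0.5 + 0.5 e^-2) / e^-1 ~ 1.543.
        trials = make_study_frame(n_subjects=252, seed=2)
        params = SimulationParams(beta={"intercept": np.log(2.0)},
                                  gamma={"intercept": 0.0})
        obs = simulate_responses(trials, params, seed=12)
        report = check_zero_inflation(obs, "calls", fixed_effects=())
        assert report.ratio == pytest.approx(1.543, abs=0.13)
        assert report.inflated

    def test_all_zero_degenerate(self):
        trials = make_study_frame(n_subjects=4, seed=3)
        obs = simulate_responses(
            trials, SimulationParams(beta={"intercept": 0.0},
                                     gamma={"intercept": 20.0}), seed=13)
        report = check_zero_inflation(obs, "calls")
        assert report.degenerate and np.isnan(report.ratio)


class TestEngineReductions:
    def test_matches_poisson_irls_without_re_and_zi(self):
        """With no random effects and no zero inflation the ZIP-GLMM is a
        plain Poisson GLM; compare against statsmodels IRLS."""
        import statsmodels.api as sm
        from songtool.behavior_analysis import _design

        obs = _poisson_obs(n_subjects=30)
        spec = ModelSpec(response="calls", zero_inflation="none",
                         random_intercepts=())
        fit = fit_zip_glmm(obs, spec)
        X, _ = _design(obs, spec.fixed_effects)
        oracle = sm.GLM(obs["calls"].to_numpy(float), X,
                        family=sm.families.Poisson()).fit()
        ours = fit.coefficients.loc["conditional", "estimate"].to_numpy()
        assert np.max(np.abs(ours - oracle.params)) < 1e-4
        assert np.max(np.abs(
            fit.coefficients.loc["conditional", "se"].to_numpy()
            - oracle.bse)) < 1e-4

    def test_matches_statsmodels_zip_without_re(self):
        from statsmodels.discrete.count_model import ZeroInflatedPoisson
        from songtool.behavior_analysis import _design

        trials = make_study_frame(n_subjects=30, seed=4)
        params = SimulationParams(beta={"intercept": 1.0,
                                        "stimulus_type": -0.4},
                                  gamma={"intercept": logit(0.3)})
        obs = simulate_responses(trials, params, seed=14)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=(), random_intercepts=())
        fit = fit_zip_glmm(obs, spec)
        X, _ = _design(obs, ("stimulus_type",))
        oracle = ZeroInflatedPoisson(obs["calls"].to_numpy(), X,
                                     exog_infl=np.ones((len(obs), 1))).fit(disp=0)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        # statsmodels orders [inflate, count]; compare count part
        ours = fit.coefficients.loc["conditional", "estimate"].to_numpy()
        assert np.max(np.abs(ours - oracle.params[1:])) < 1e-3

    def test_zip_pmf_reduces_to_poisson_at_extreme_gamma(self):
        from scipy.stats import poisson
        y = np.arange(0, 12)
        lam = np.full_like(y, 2.3, dtype=float)
        pi = expit(np.full_like(lam, -20.0))
        assert np.allclose(zip_log_pmf(y, lam, pi),
                           poisson.logpmf(y, 2.3), atol=1e-7)

    def test_no_zero_inflation_data_drives_pi_to_zero(self):
        trials = make_study_frame(n_subjects=25, seed=5)
        params = SimulationParams(beta={"intercept": 1.2},
                                  re_sds={"subject": 0.3})
        obs = simulate_responses(trials, params, seed=15)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=(), random_intercepts=("subject",))
        fit = fit_zip_glmm(obs, spec)
        pi_hat = expit(fit.coef("intercept", part="zero_inflation")["estimate"])
        assert pi_hat < 0.05


class TestAgainstGlmmTMB:
    def test_crossed_zip_glmm_matches_glmmtmb(self, tmp_path):
        """Independent cross-check of the Laplace ML fit against the R
        reference implementation on one simulated dataset."""
        trials = make_study_frame(n_subjects=15, n_owners=6, seed=6)
        params = SimulationParams(
            beta={"intercept": 1.0, "stimulus_type": -0.4},
            gamma={"intercept": logit(0.25)},
            re_sds={"subject": 0.4, "song_owner": 0.3,
                    "subject:song_owner": 0.3})
        obs = simulate_responses(trials, params, seed=16)
        csv = tmp_path / "obs.csv"
        obs.to_csv(csv, index=False)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=())
        fit = fit_zip_glmm(obs, spec)

        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(glmmTMB))
obs <- read.csv('{csv}')
obs$stimulus_type <- relevel(factor(obs$stimulus_type), ref='father')
m <- glmmTMB(calls ~ stimulus_type + (1|subject_id) + (1|song_owner_id) +
             (1|subject_id:song_owner_id),
             ziformula = ~1, family = poisson, data = obs)
cat(fixef(m)$cond, fixef(m)$zi, as.numeric(logLik(m)),
    sqrt(VarCorr(m)$cond$subject_id[1,1]), sep='\\n')
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        b0, b1, zi, ll, sd_subj = map(float, out.stdout.split())
        assert fit.coef("intercept")["estimate"] == pytest.approx(b0, abs=2e-3)
        assert fit.coef("stimulus_type[non_imprinted]")["estimate"] == \
            pytest.approx(b1, abs=2e-3)
        assert fit.coef("intercept", "zero_inflation")["estimate"] == \
            pytest.approx(zi, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-2)
        assert fit.re_sd["subject"] == pytest.approx(sd_subj, abs=5e-3)


class TestSimulator:
    def test_same_seed_identical(self):
        trials = make_study_frame(n_subjects=6, seed=7)
        params = SimulationParams(beta={"intercept": 0.5},
                                  re_sds={"subject": 0.5})
        a = simulate_responses(trials, params, seed=99)
        b = simulate_responses(trials, params, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_certain_structural_zero_gives_all_zeros(self):
        trials = make_study_frame(n_subjects=6, seed=8)
        params = SimulationParams(beta={"intercept": 2.0},
                                  gamma={"intercept": 30.0})  # pi = 1
        obs = simulate_responses(trials, params, seed=100)
        assert (obs["calls"] == 0).all()

    def test_mean_converges_to_exp_beta0(self):
        # n = 10 000 trials, no REs, no zero inflation
        trials = make_study_frame(n_subjects=625, seed=9)
        beta0 = 0.8
        obs = simulate_responses(
            trials, SimulationParams(beta={"intercept": beta0}), seed=101)
        lam = np.exp(beta0)
        se = np.sqrt(lam / len(obs))
        assert abs(obs["calls"].mean() - lam) < 3 * se


class TestDegenerateResponses:
    def test_all_zero_response_raises_with_advice(self):
        trials = make_study_frame(n_subjects=6, seed=10)
        obs = simulate_responses(
            trials, SimulationParams(beta={"intercept": 1.0},
                                     gamma={"intercept": 30.0}), seed=102)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=())
        with pytest.raises(ValueError, match="all zero"):
            fit_zip_glmm(obs, spec)

    def test_silent_subject_excluded_only_by_flag(self):
        trials = make_study_frame(n_subjects=8, seed=11)
        params = SimulationParams(beta={"intercept": 1.5},
                                  re_sds={"subject": 0.2})
        obs = simulate_responses(trials, params, seed=103)
        silent = obs["subject_id"] == "S001"
        obs.loc[silent, "calls"] = 0
        assert all_zero_subjects(obs, "calls") == ["S001"]
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=())
        kept = fit_zip_glmm(obs, spec)
        dropped = fit_zip_glmm(obs, spec, exclude_all_zero_subjects=True)
        assert kept.n_obs == len(obs)
        assert dropped.n_obs == len(obs) - silent.sum()


class TestAicReduction:
    def test_well_conditioned_full_model_returned(self):
        trials = make_study_frame(n_subjects=25, seed=12,
                                  sessions_per_comparison=2)
        params = SimulationParams(beta={"intercept": 1.0},
                                  gamma={"intercept": logit(0.3)},
                                  re_sds={"subject": 0.3})
        obs = simulate_responses(trials, params, seed=104)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=("stimulus_type",),
                         random_intercepts=("subject",))
        out_spec, fit = reduce_zero_inflation_by_aic(obs, spec)
        assert out_spec == spec
        assert fit.converged

    def test_degenerate_zi_covariate_pruned(self):
        # single-session data makes session_order constant, hence collinear
        # with the zero-inflation intercept; the full model cannot converge
        trials = make_study_frame(n_subjects=25, seed=13,
                                  sessions_per_comparison=2)
        trials = trials[trials["session_order"] == 1].reset_index(drop=True)
        params = SimulationParams(beta={"intercept": 1.2},
                                  gamma={"intercept": logit(0.35)},
                                  re_sds={"subject": 0.3})
        obs = simulate_responses(trials, params, seed=105)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=("stimulus_type", "session_order"),
                         random_intercepts=("subject",))
        out_spec, fit = reduce_zero_inflation_by_aic(obs, spec)
        assert "session_order" not in out_spec.zero_inflation
        assert fit.converged

    def test_no_zero_inflation_terms_rejected(self):
        obs = _poisson_obs(n_subjects=6)
        spec = ModelSpec(response="calls", zero_inflation="none")
        with pytest.raises(ValueError):
            reduce_zero_inflation_by_aic(obs, spec)


class TestCombinedSteps:
    def test_single_step_data_rejected(self):
        trials = make_study_frame(n_subjects=6, seed=14)
        obs = simulate_responses(
            trials, SimulationParams(beta={"intercept": 1.0}), seed=106)
        with pytest.raises(ValueError, match="both experiment steps"):
            fit_combined_steps(obs)

    def test_missing_step_column_rejected(self):
        trials = make_study_frame(n_subjects=6, seed=15)
        obs = simulate_responses(
            trials, SimulationParams(beta={"intercept": 1.0}), seed=107)
        with pytest.raises(ValueError, match="step"):
            fit_combined_steps(obs.drop(columns=["step"]))

    def test_interaction_term_added(self):
        trials = make_study_frame(n_subjects=12, seed=16,
                                  steps=("artificial", "natural"))
        params = SimulationParams(beta={"intercept": 1.0, "step": -1.0},
                                  re_sds={"subject": 0.3})
        obs = simulate_responses(trials, params, seed=108)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=(), random_intercepts=("subject",))
        fit = fit_combined_steps(obs, spec=spec)
        terms = fit.coefficients.loc["conditional"].index
        assert "step[natural]" in terms
        assert "step[natural]:stimulus_type[non_imprinted]" in terms


class TestInnerOptimizerContract:
    def test_inner_mode_improves_on_zero_start(self):
        """The damped Newton mode search never returns a worse joint
        density than its starting point (line-search contract)."""
        from songtool.behavior_analysis import _build_problem

        trials = make_study_frame(n_subjects=10, seed=17)
        params = SimulationParams(beta={"intercept": 1.0},
                                  gamma={"intercept": logit(0.3)},
                                  re_sds={"subject": 0.6})
        obs = simulate_responses(trials, params, seed=109)
        spec = ModelSpec(response="calls", fixed_effects=("stimulus_type",),
                         zero_inflation=(), random_intercepts=("subject",))
        problem, _, _ = _build_problem(obs, spec)
        theta = problem.default_start()
        beta, gamma, log_sd = problem.unpack(theta)
        sds = np.exp(log_sd)
        prec = problem.rand.prior_precision(sds)
        sds_exp = problem.rand.expand_sds(sds)
        eta_fixed = problem.X @ beta
        zeta = problem.Xz @ gamma
        g_start, _, _ = problem._joint(np.zeros(problem.rand.q), eta_fixed,
                                       zeta, prec, sds_exp)
        b_hat, g_hat, _ = problem._inner_mode(eta_fixed, zeta, prec, sds_exp)
        assert g_hat >= g_start
        # and the gradient at the mode vanishes
        _, d1, _ = problem._joint(b_hat, eta_fixed, zeta, prec, sds_exp)
        grad = problem.rand.Z.T @ d1 - prec * b_hat
        assert np.max(np.abs(grad)) < 1e-6
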