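"""Fit the zero-inflated Poisson GLMM to simulated playback counts.

Simulates a playback study in which females call more to their father's
song (a -0.43 conditional effect on the log scale), checks for zero
inflation, and fits the standard model: stimulus type, trial order and
session order as fixed effects, subject / song owner / pairing as
crossed random intercepts, and the same covariates in the
zero-inflation formula (pruned by AIC if the full model fails).
"""

from scipy.special import logit

from songtool import (
    ModelSpec,
    SimulationParams,
    check_zero_inflation,
    reduce_zero_inflation_by_aic,
    simulate_responses,
)
from songtool.behavior_analysis import make_study_frame

trials = make_study_frame(n_subjects=24, n_owners=10,
                          sessions_per_comparison=4, seed=5)
truth = SimulationParams(
    beta={"intercept": 1.0, "stimulus_type": -0.43,
          "trial_order": -0.12, "session_order": 0.3},
    gamma={"intercept": logit(0.3)},
    re_sds={"subject": 0.5, "song_owner": 0.3, "subject:song_owner": 0.3})
obs = simulate_responses(trials, truth, seed=6)

report = check_zero_inflation(obs, "calls")
print(f"observed zeros: {report.n_zeros_observed}, "
      f"Poisson-expected: {report.n_zeros_expected:.1f}, "
      f"ratio {report.ratio:.2f} -> "
      f"{'zero-inflated' if report.inflated else 'not inflated'}")

spec, fit = reduce_zero_inflation_by_aic(obs, ModelSpec(response="calls"))
print(f"\nconditional model (AIC {fit.aic:.1f}, converged={fit.converged}):")
print(fit.coefficients.loc["conditional"].round(3).to_string())
print("random-effect sd:", {k: round(v, 3) for k, v in fit.re_sd.items()})
print()
print("The stimulus_type[non_imprinted] row is the familiarity effect: "
      "a negative estimate with p < 0.05 means significantly more calls "
      "to the father's song than to the non-imprinted song, after "
      "adjusting for trial/session order and excess zeros (true value "
      "here: -0.43).")
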