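"""Trial-level behavioural analysis: zero-inflation checks and ZIP-GLMMs.

The observational unit is one playback trial per subject, carrying the
design covariates (stimulus type, trial order within session, session
order, experiment step) and non-negative behavioural counts (calls,
hops, bill wipes, fluffs). Data live in a pandas DataFrame with the
columns of :data:`OBSERVATION_COLUMNS`.

Models
------
Counts are analysed with zero-inflated Poisson GLMMs: a logit model
for structural zeros (fixed effects only) mixed with a log-link
Poisson model for the counts, the latter carrying crossed Gaussian
random intercepts for subject, song owner and their pairing. Inference
focuses on the conditional (count) part: Wald z tests on its
coefficients. Estimation is by maximum likelihood with the random
effects integrated out by a Laplace approximation (see
:mod:`songtool._zipglmm`).

Coding conventions
------------------
``stimulus_type`` is coded with *father* as the reference level, so a
preference for father songs appears as a negative coefficient on the
``non_imprinted`` indicator. ``step`` is coded with *artificial* as the
reference, so stronger responding to artificial (simplified) songs
appears as a negative coefficient on the ``natural`` indicator.
``trial_order`` and ``session_order`` enter as numeric covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from songtool._zipglmm import RandomStructure, ZipGlmmProblem, zip_log_pmf
from songtool.experiment_design import (
    DesignConfig,
    counterbalance,
    trial_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OBSERVATION_COLUMNS", "ModelSpec", "FitResult", "SimulationParams",
    "ZeroInflationReport", "check_zero_inflation", "fit_zip_glmm",
    "reduce_zero_inflation_by_aic", "fit_combined_steps",
    "simulate_responses", "make_study_frame", "all_zero_subjects",
    "zip_log_pmf",
]

#: Column layout of a trial-observation table.
OBSERVATION_COLUMNS = (
    "subject_id", "song_owner_id", "stimulus_type", "trial_order",
    "session_order", "step", "calls", "hops", "bill_wipes", "fluffs",
)

RESPONSES = ("calls", "hops", "bill_wipes", "fluffs")

FIXED_EFFECT_TERMS = ("stimulus_type", "trial_order", "session_order",
                      "step", "step:stimulus_type")
RANDOM_FACTORS = ("subject", "song_owner", "subject:song_owner")

_STIMULUS_REF = "father"
_STEP_REF = "artificial"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed effects, random intercepts, ZI formula.

    ``zero_inflation`` is either ``"none"`` (plain Poisson GLMM, as used
    for fluffing) or a tuple of fixed-effect terms for the
    structural-zero logit model (the empty tuple means intercept-only
    zero inflation). The default mirrors the standard analysis: all
    fixed effects in both parts, crossed random intercepts for subject,
    song owner and their pairing.
    """

    response: str = "calls"
    fixed_effects: tuple[str, ...] = ("stimulus_type", "trial_order",
                                      "session_order")
    random_intercepts: tuple[str, ...] = RANDOM_FACTORS
    zero_inflation: str | tuple[str, ...] = ("stimulus_type", "trial_order",
                                             "session_order")

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if not self.fixed_effects:
            raise ValueError("fixed_effects must be non-empty")
        for t in self.fixed_effects:
            if t not in FIXED_EFFECT_TERMS:
                raise ValueError(f"unknown fixed effect {t!r}")
        for r in self.random_intercepts:
            if r not in RANDOM_FACTORS:
                raise ValueError(f"unknown random factor {r!r}")
        if self.zero_inflation != "none":
            for t in self.zero_inflation:
                if t not in FIXED_EFFECT_TERMS:
                    raise ValueError(f"unknown zero-inflation term {t!r}")


@dataclass(frozen=True)
class SimulationParams:
    """True parameters for the response simulator.

    ``beta``/``gamma`` map term names (including ``"intercept"``) to
    conditional-model and zero-inflation coefficients; missing terms
    are zero. ``gamma=None`` means no structural zeros. ``re_sds`` maps
    random-factor names to standard deviations of their Gaussian
    intercepts.
    """

    beta: dict[str, float]
    gamma: dict[str, float] | None = None
    re_sds: dict[str, float] = field(default_factory=dict)


@dataclass
class FitResult:
    """Estimates and inference from one (ZIP-)GLMM fit.

    ``coefficients`` has one row per (part, term) with columns
    estimate / se / z / p, where part is ``conditional`` or
    ``zero_inflation``; Wald inference throughout. ``re_sd`` maps
    random-factor names to estimated intercept standard deviations.
    """

    coefficients: pd.DataFrame
    re_sd: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_params: int
    spec: ModelSpec
    message: str = ""

    def coef(self, term: str, part: str = "conditional") -> pd.Series:
        """The row for one coefficient, e.g. ``coef("stimulus_type")``."""
        return self.coefficients.loc[(part, term)]

    def wald_ci(self, term: str, part: str = "conditional",
                level: float = 0.95) -> tuple[float, float]:
        row = self.coef(term, part)
        half = norm.ppf(0.5 + level / 2) * row["se"]
        return float(row["estimate"] - half), float(row["estimate"] + half)


@dataclass
class ZeroInflationReport:
    """Observed vs Poisson-expected zeros for one response."""

    n_zeros_observed: int
    n_zeros_expected: float
    ratio: float
    inflated: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# design matrices

def _term_column(df: pd.DataFrame, term: str) -> tuple[np.ndarray, str]:
    if term == "intercept":
        return np.ones(len(df)), "intercept"
    if term == "stimulus_type":
        vals = df["stimulus_type"].astype(str)
        return (vals != _STIMULUS_REF).to_numpy(float), "stimulus_type[non_imprinted]"
    if term == "trial_order":
        return df["trial_order"].to_numpy(float), "trial_order"
    if term == "session_order":
        return df["session_order"].to_numpy(float), "session_order"
    if term == "step":
        if "step" not in df.columns:
            raise ValueError("observations lack a 'step' column")
        vals = df["step"].astype(str)
        return (vals != _STEP_REF).to_numpy(float), "step[natural]"
    if term == "step:stimulus_type":
        a, _ = _term_column(df, "step")
        b, _ = _term_column(df, "stimulus_type")
        return a * b, "step[natural]:stimulus_type[non_imprinted]"
    raise ValueError(f"unknown term {term!r}")


def _design(df: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for term in ("intercept",) + tuple(terms):
        col, name = _term_column(df, term)
        cols.append(col)
        names.append(name)
    return np.column_stack(cols), names


def _random_codes(df: pd.DataFrame,
                  factors: tuple[str, ...]) -> dict[str, np.ndarray]:
    codes = {}
    for f in factors:
        if f == "subject":
            key = df["subject_id"].astype(str)
        elif f == "song_owner":
            key = df["song_owner_id"].astype(str)
        elif f == "subject:song_owner":
            key = df["subject_id"].astype(str) + ":" + df["song_owner_id"].astype(str)
        else:
            raise ValueError(f"unknown random factor {f!r}")
        code, levels = pd.factorize(key, sort=True)
        if len(levels) < 2:
            raise ValueError(
                f"random factor {f!r} has {len(levels)} level(s); need >= 2")
        codes[f] = code
    return codes


def _build_problem(df: pd.DataFrame, spec: ModelSpec) -> tuple[ZipGlmmProblem,
                                                               list[str], list[str]]:
    y = df[spec.response].to_numpy()
    if not np.issubdtype(y.dtype, np.number) or np.any(y < 0) or \
            np.any(y != np.floor(y)):
        raise ValueError(f"{spec.response} must hold non-negative integer counts")
    y = y.astype(float)
    if np.all(y == 0):
        raise ValueError(
            f"response {spec.response!r} is all zero; the model is not "
            "identifiable — exclude these data explicitly (see "
            "all_zero_subjects / exclude_all_zero_subjects)")
    X, x_names = _design(df, spec.fixed_effects)
    if spec.zero_inflation == "none":
        Xz, z_names = None, []
    else:
        Xz, z_names = _design(df, tuple(spec.zero_inflation))
    rand = RandomStructure.build(_random_codes(df, tuple(spec.random_intercepts))
                                 if spec.random_intercepts else {})
    return ZipGlmmProblem(y=y, X=X, Xz=Xz, rand=rand), x_names, z_names


# ---------------------------------------------------------------------------
# public operations

def check_zero_inflation(obs: pd.DataFrame, response: str = "calls",
                         fixed_effects: tuple[str, ...] = ("stimulus_type",
                                                           "trial_order",
                                                           "session_order"),
                         tolerance: float = 1.05) -> ZeroInflationReport:
    """Ratio of observed zeros to zeros expected under a Poisson GLM.

    Fits a plain Poisson regression with the model's fixed effects and
    compares the observed number of zero counts with
    ``sum_i exp(-lambda_hat_i)``. A ratio above ``tolerance`` (default
    1.05) flags zero inflation. An all-zero response is degenerate: the
    ratio is undefined and the report says so.
    """
    import statsmodels.api as sm

    if len(obs) == 0:
        raise ValueError("need at least one observation")
    y = obs[response].to_numpy(float)
    n_zero = int(np.sum(y == 0))
    if np.all(y == 0):
        return ZeroInflationReport(n_zeros_observed=n_zero,
                                   n_zeros_expected=float("nan"),
                                   ratio=float("nan"), inflated=False,
                                   degenerate=True)
    X, _ = _design(obs, fixed_effects)
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    expected = float(np.sum(np.exp(-fit.mu)))
    ratio = n_zero / expected if expected > 0 else float("inf")
    return ZeroInflationReport(n_zeros_observed=n_zero,
                               n_zeros_expected=expected, ratio=ratio,
                               inflated=bool(ratio > tolerance))


def all_zero_subjects(obs: pd.DataFrame, response: str = "calls") -> list[str]:
    """Subjects whose response is zero in every trial (non-responders)."""
    totals = obs.groupby("subject_id")[response].sum()
    return sorted(totals.index[totals == 0].tolist())


def fit_zip_glmm(obs: pd.DataFrame, spec: ModelSpec,
                 exclude_all_zero_subjects: bool = False,
                 theta0: np.ndarray | None = None) -> FitResult:
    """Fit a zero-inflated Poisson GLMM by Laplace-approximate ML.

    See the module docstring for the model. With
    ``exclude_all_zero_subjects=True``, subjects that never responded
    are dropped before fitting (the sensitivity re-fit for a completely
    silent subject); they are reported in the log either way.

    Non-convergence never fails silently: the returned
    :class:`FitResult` carries ``converged=False`` plus the optimizer
    message, and standard errors are NaN if the curvature is not
    positive definite. An all-zero response raises with advice to
    exclude it.
    """
    silent = all_zero_subjects(obs, spec.response)
    if silent:
        logger.info("subjects with all-zero %s: %s", spec.response,
                    ", ".join(silent))
    if exclude_all_zero_subjects and silent:
        obs = obs[~obs["subject_id"].isin(silent)]
    problem, x_names, z_names = _build_problem(obs, spec)
    res = problem.fit(theta0=theta0)
    theta = res.x
    loglik = -problem.nll(theta)
    k = problem.n_params
    aic = 2 * k - 2 * loglik

    # Wald covariance of (beta, gamma) from the observed information of
    # the Laplace marginal likelihood. Variance components at the zero
    # boundary leave the Hessian flat along their log-sd directions, so
    # the fixed-effect block is inverted via the Schur complement with a
    # pseudo-inverse over the log-sd block; genuinely unidentified
    # fixed effects (e.g. collinear designs) still fail the check.
    k_fix = problem.n_beta + problem.n_gamma
    se = np.full(k, np.nan)
    converged = bool(res.success) and np.isfinite(loglik)
    try:
        H = problem.hessian(theta)
        if not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError("non-finite Hessian")
        Hff = H[:k_fix, :k_fix]
        if k_fix < k:
            Hfs = H[:k_fix, k_fix:]
            Hss_pinv = np.linalg.pinv(H[k_fix:, k_fix:], rcond=1e-10)
            S = Hff - Hfs @ Hss_pinv @ Hfs.T
        else:
            S = Hff
        eigvals = np.linalg.eigvalsh(S)
        if eigvals.min() <= 0 or eigvals.max() / eigvals.min() > 1e12:
            raise np.linalg.LinAlgError("fixed-effect information not PD")
        se[:k_fix] = np.sqrt(np.diag(np.linalg.inv(S)))
    except np.linalg.LinAlgError:
        converged = False

    beta, gamma, log_sd = problem.unpack(theta)
    rows = []
    for i, name in enumerate(x_names):
        est, s = beta[i], se[i]
        z = est / s if s and np.isfinite(s) else np.nan
        rows.append(("conditional", name, est, s, z,
                     2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan))
    for j, name in enumerate(z_names):
        i = problem.n_beta + j
        est, s = gamma[j], se[i]
        z = est / s if s and np.isfinite(s) else np.nan
        rows.append(("zero_inflation", name, est, s, z,
                     2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan))
    coeffs = pd.DataFrame(rows, columns=["part", "term", "estimate", "se",
                                         "z", "p"]).set_index(["part", "term"])
    re_sd = {name: float(np.exp(ls))
             for name, ls in zip(problem.rand.factor_names, log_sd)}
    return FitResult(coefficients=coeffs, re_sd=re_sd, loglik=float(loglik),
                     aic=float(aic), converged=bool(converged), n_obs=len(obs),
                     n_params=k, spec=spec, message=str(res.message))


def reduce_zero_inflation_by_aic(obs: pd.DataFrame, spec: ModelSpec,
                                 **fit_kwargs) -> tuple[ModelSpec, FitResult]:
    """Fit the full model; on failure, prune the zero-inflation formula.

    If the full model converges it is returned unchanged. Otherwise
    zero-inflation terms are removed one at a time, last-listed term
    first (down to intercept-only and finally no zero inflation), each
    candidate is refit, and the converged candidate with the lowest AIC
    wins. If nothing converges, raises with per-candidate diagnostics.
    """
    if spec.zero_inflation == "none" or not spec.zero_inflation:
        raise ValueError("spec must start with non-empty zero_inflation terms")
    full = fit_zip_glmm(obs, spec, **fit_kwargs)
    if full.converged:
        return spec, full
    logger.info("full zero-inflation model did not converge (%s); pruning",
                full.message)
    terms = list(spec.zero_inflation)
    candidates: list[str | tuple[str, ...]] = [
        tuple(terms[:i]) for i in range(len(terms) - 1, -1, -1)]
    candidates.append("none")
    fits, failures = [], []
    for zi in candidates:
        cand = replace(spec, zero_inflation=zi)
        try:
            fit = fit_zip_glmm(obs, cand, **fit_kwargs)
        except Exception as exc:  # keep trying remaining candidates
            failures.append(f"zi={zi!r}: {exc}")
            continue
        if fit.converged:
            fits.append((cand, fit))
        else:
            failures.append(f"zi={zi!r}: not converged ({fit.message})")
    if not fits:
        raise RuntimeError(
            "no zero-inflation reduction converged:\n  " + "\n  ".join(failures))
    return min(fits, key=lambda cf: cf[1].aic)


def fit_combined_steps(obs: pd.DataFrame, response: str = "calls",
                       spec: ModelSpec | None = None,
                       **fit_kwargs) -> FitResult:
    """Fit the two-step model with a step x stimulus-type interaction.

    Observations must span both experiment steps (natural and
    artificial songs). ``step`` and ``step:stimulus_type`` are added to
    the conditional fixed effects of ``spec`` (default: the standard
    calls model); a non-significant interaction means the familiarity
    effect is consistent across natural and simplified songs.
    """
    if "step" not in obs.columns:
        raise ValueError("observations lack a 'step' column")
    steps = set(obs["step"].astype(str))
    if len(steps) < 2:
        raise ValueError(f"need both experiment steps, got {sorted(steps)}")
    spec = spec or ModelSpec(response=response)
    extra = tuple(t for t in ("step", "step:stimulus_type")
                  if t not in spec.fixed_effects)
    spec = replace(spec, response=response,
                   fixed_effects=spec.fixed_effects + extra)
    return fit_zip_glmm(obs, spec, **fit_kwargs)


# ---------------------------------------------------------------------------
# simulation

def make_study_frame(n_subjects: int = 4, n_owners: int | None = None,
                     steps: tuple[str, ...] = ("artificial",),
                     sessions_per_comparison: int = 2,
                     cfg: DesignConfig | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Trial-level design covariates for a simulated study.

    Builds counterbalanced playback schedules for ``n_subjects``
    subjects, assigns each subject a father and a non-imprinted song
    owner drawn from a pool of ``n_owners`` males (default: two per
    subject), and replicates the design for each experiment step. The
    result has the :data:`OBSERVATION_COLUMNS` design columns, ready
    for :func:`simulate_responses`.
    """
    cfg = cfg or DesignConfig(sessions_per_comparison=sessions_per_comparison)
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    df = trial_frame(counterbalance(subjects, cfg))
    if n_owners is None:
        n_owners = 2 * n_subjects
    if n_owners < 2:
        raise ValueError("need at least two song owners")
    # A male can be one female's father and another's non-imprinted
    # stimulus, so owner identity is crossed with stimulus type rather
    # than confounded with it.
    owners = np.array([f"M{i + 1:03d}" for i in range(n_owners)])
    fathers = {s: owners[rng.integers(0, n_owners)] for s in subjects}
    others = {}
    for s in subjects:
        o = owners[rng.integers(0, n_owners)]
        while o == fathers[s]:
            o = owners[rng.integers(0, n_owners)]
        others[s] = o
    df["song_owner_id"] = [
        fathers[s] if st == _STIMULUS_REF else others[s]
        for s, st in zip(df["subject_id"], df["stimulus_type"])]
    frames = []
    for step in steps:
        step_df = df.copy()
        step_df["step"] = step
        frames.append(step_df)
    out = pd.concat(frames, ignore_index=True)
    return out[["subject_id", "song_owner_id", "stimulus_type", "trial_order",
                "session_order", "step"]]


def simulate_responses(trials: pd.DataFrame, params: SimulationParams,
                       seed: int, response: str = "calls") -> pd.DataFrame:
    """Draw zero-inflated Poisson counts for a trial design.

    Random intercepts are drawn once per level of each factor in
    ``params.re_sds``; then for every trial ``log lam = x'beta + z'b``
    and ``logit pi = x'gamma`` (``pi = 0`` when ``gamma`` is None), and
    the count is Poisson(lam) with probability 1-pi, else a structural
    zero. Fully reproducible from ``seed``. Count columns other than
    ``response`` are filled with zeros so the result matches
    :data:`OBSERVATION_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    df = trials.copy()

    def _linpred(coef: dict[str, float]) -> np.ndarray:
        lp = np.zeros(len(df))
        for term, value in coef.items():
            col, _ = _term_column(df, term)
            lp += value * col
        return lp

    eta = _linpred(params.beta)
    codes = _random_codes(df, tuple(params.re_sds)) if params.re_sds else {}
    for factor, sd in params.re_sds.items():
        code = codes[factor]
        effects = rng.normal(0.0, sd, size=int(code.max()) + 1)
        eta += effects[code]
    lam = np.exp(np.clip(eta, -30, 30))
    counts = rng.poisson(lam)
    if params.gamma is not None:
        pi = expit(_linpred(params.gamma))
        counts = np.where(rng.random(len(df)) < pi, 0, counts)
    for col in RESPONSES:
        df[col] = 0
    df[response] = counts.astype(int)
    if "step" not in df.columns:
        df["step"] = "artificial"
    return df[list(OBSERVATION_COLUMNS)]
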