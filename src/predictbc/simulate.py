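"""Synthetic registry-like cohorts drawn exactly from a coefficient set.

Covariates are sampled from configurable marginal laws chosen to mimic a
UK cancer-registry case mix (the published development cohort's margins,
e.g. an ER-positive fraction of 4718/5738); event times are generated by
inverting the model's own cumulative hazards, so the simulator is
calibrated-in-the-large against the scoring engine by construction.

Latent breast-cancer and other-cause death times are drawn independently
given covariates - exactly the independence the competing-risks formulas
Rb = H_B(1-H_O), Ro = H_O(1-H_B) assume.  Beyond the supported horizon the
baseline log cumulative hazard is continued linearly in ln t (simulation
only; administrative censoring at 10 years means the extrapolation never
affects shipped-horizon statistics).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError
from .model import (
    COHORT_COLUMNS,
    ER_NEG,
    ER_POS,
    OTHER,
    HORIZON,
    BaselineLogCumhaz,
    ModelCoefficients,
    default_model,
    linear_predictor,
    mortality_index,
    treatment_log_hr_total,
)

__all__ = [
    "CovariateConfig",
    "CensoringConfig",
    "sample_covariates",
    "extended_log_cumhaz",
    "invert_cumhaz",
    "simulate_outcomes",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal sampling laws for a synthetic registry cohort.

    Defaults emulate an early-2000s UK registry case mix: age truncated
    normal on [25, 79]; tumour size log-normal (median ~20 mm); positive
    nodes a zero-inflated negative binomial (structural node-negative mass
    plus 1 + NB for node-positive disease); screening detection concentrated
    in the mammography invitation ages.  These are configuration values, not
    claims about the real joint distribution.
    """

    age_mean: float = 58.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (25.0, 79.0)
    size_log_mean: float = math.log(20.0)
    size_log_sd: float = 0.55
    size_bounds: tuple[float, float] = (1.0, 90.0)
    nodes_zero_prob: float = 0.55
    nodes_nb_mean: float = 3.5
    nodes_nb_size: float = 1.2
    grade_probs: tuple[float, float, float] = (0.20, 0.45, 0.35)
    screen_prob: float = 0.35
    screen_ages: tuple[float, float] = (50.0, 71.0)
    screen_prob_outside: float = 0.05
    er_positive_prob: float = 4718.0 / 5738.0
    chemo_prob: float = 0.35
    hormone_prob_er_pos: float = 0.70

    def validate(self) -> None:
        probs = {
            "nodes_zero_prob": self.nodes_zero_prob,
            "screen_prob": self.screen_prob,
            "screen_prob_outside": self.screen_prob_outside,
            "er_positive_prob": self.er_positive_prob,
            "chemo_prob": self.chemo_prob,
            "hormone_prob_er_pos": self.hormone_prob_er_pos,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.grade_probs):
            raise ConfigurationError("grade_probs must be non-negative and sum to 1")
        if not (self.age_bounds[0] < self.age_bounds[1] and self.age_bounds[0] > 0):
            raise ConfigurationError("age_bounds must be an increasing positive pair")
        if self.size_bounds[0] < 1.0:
            raise ConfigurationError("size_bounds[0] must be >= 1 mm")
        if self.age_sd <= 0 or self.size_log_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if self.nodes_nb_mean <= 0 or self.nodes_nb_size <= 0:
            raise ConfigurationError("negative-binomial parameters must be positive")


@dataclass(frozen=True)
class CensoringConfig:
    """Administrative censoring horizon plus optional random censoring."""

    admin_years: float = 10.0
    random_rate: float = 0.0  # exponential dropout rate per year (0 = none)

    def validate(self) -> None:
        if self.admin_years <= 0:
            raise ConfigurationError("admin_years must be > 0")
        if self.random_rate < 0:
            raise ConfigurationError("random_rate must be >= 0")


def sample_covariates(
    n: int,
    config: CovariateConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ``n`` patients' covariates (outcome columns left empty)."""
    config = config or CovariateConfig()
    config.validate()
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    size = np.clip(
        rng.lognormal(config.size_log_mean, config.size_log_sd, size=n),
        config.size_bounds[0],
        config.size_bounds[1],
    )
    nb_p = config.nodes_nb_size / (config.nodes_nb_size + config.nodes_nb_mean)
    nodes = np.where(
        rng.random(n) < config.nodes_zero_prob,
        0,
        1 + rng.negative_binomial(config.nodes_nb_size, nb_p, size=n),
    )
    grade = rng.choice([1, 2, 3], size=n, p=config.grade_probs)
    in_band = (age >= config.screen_ages[0]) & (age < config.screen_ages[1])
    p_screen = np.where(in_band, config.screen_prob, config.screen_prob_outside)
    screen = (rng.random(n) < p_screen).astype(int)
    er = np.where(rng.random(n) < config.er_positive_prob, "pos", "neg")
    chemo = (rng.random(n) < config.chemo_prob).astype(int)
    hormone = ((rng.random(n) < config.hormone_prob_er_pos) & (er == "pos")).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "size_mm": size,
            "nodes": nodes.astype(int),
            "grade": grade.astype(int),
            "screen": screen,
            "er": er,
            "chemo": chemo,
            "hormone": hormone,
            "time_years": np.full(n, np.nan),
            "event": np.full(n, "", dtype=object),
        },
        columns=list(COHORT_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Inverse-transform event times
# ---------------------------------------------------------------------------

_EXTRAP_LO = 1e-6
_EXTRAP_HI = 60.0


def extended_log_cumhaz(t, baseline: BaselineLogCumhaz) -> np.ndarray:
    """Baseline log cumulative hazard with linear-in-ln(t) continuation.

    Exact on the supported horizon [1, 10]; outside it the curve is continued
    with the boundary slope d B / d ln t, which keeps it monotone wherever
    the boundary slope is positive (true for all shipped baselines).
    """
    t = np.asarray(t, dtype=float)
    lo, hi = HORIZON
    out = np.empty(t.shape, dtype=float)
    mid = (t >= lo) & (t <= hi)
    out[mid] = baseline(t[mid])
    below = t < lo
    if below.any():
        out[below] = baseline(np.array(lo)) + baseline.derivative_lnt(np.array(lo)) * (
            np.log(t[below]) - math.log(lo)
        )
    above = t > hi
    if above.any():
        out[above] = baseline(np.array(hi)) + baseline.derivative_lnt(np.array(hi)) * (
            np.log(t[above]) - math.log(hi)
        )
    return out


def invert_cumhaz(
    u,
    index,
    baseline: BaselineLogCumhaz,
    t_bounds: tuple[float, float] = (_EXTRAP_LO, _EXTRAP_HI),
    tol: float = 1e-8,
):
    """Smallest t with exp(index) * Lambda0(t) >= -ln(u) (inverse transform).

    Solves B(t) = ln(-ln u) - index by vectorised bisection on the extended
    monotone baseline; returns +inf where the target is never reached within
    ``t_bounds`` (a beyond-horizon marker) and the lower bound where the
    target is already exceeded there.
    """
    scalar = np.isscalar(u)
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    idx = np.broadcast_to(np.asarray(index, dtype=float), u_arr.shape)
    if np.any((u_arr <= 0) | (u_arr >= 1) | ~np.isfinite(u_arr)):
        raise InvalidInputError("u", "uniform deviates must lie strictly in (0, 1)")
    y = np.log(-np.log(u_arr)) - idx
    t_lo, t_hi = t_bounds
    out = np.full(u_arr.shape, np.inf)
    reached = extended_log_cumhaz(np.full(u_arr.shape, t_hi), baseline) >= y
    immediate = extended_log_cumhaz(np.full(u_arr.shape, t_lo), baseline) >= y
    out[immediate] = t_lo
    active = reached & ~immediate
    lo = np.full(u_arr.shape, t_lo)
    hi = np.full(u_arr.shape, t_hi)
    n_iter = int(math.ceil(math.log2((t_hi - t_lo) / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        ge = extended_log_cumhaz(mid, baseline) >= y
        hi = np.where(active & ge, mid, hi)
        lo = np.where(active & ~ge, mid, lo)
    out[active] = hi[active]
    return float(out[0]) if scalar else out


def simulate_outcomes(
    covariates: pd.DataFrame,
    model: ModelCoefficients | None = None,
    censoring: CensoringConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    cause_rule: str = "first",
) -> pd.DataFrame:
    """Fill ``time_years``/``event`` by competing-risks inverse transform.

    Independent latent breast and other-cause times are drawn per patient
    from the model's cumulative hazards at the patient's treated PI and MI.
    ``cause_rule`` selects how the latent pair becomes one observed record:

    ``"first"``
        Observed time = min(latent times, censoring); cause = argmin (deaths
        take precedence over censoring at exact ties, breast over other -
        ties have probability zero for continuous times).  This realises the
        model's cause-specific hazards exactly, so Cox refits on such data
        recover the generating coefficients; it is the realistic registry
        process and the default.

    ``"exclusive"``
        A breast death is recorded (at T_b) only when T_b <= c < T_o, an
        other-cause death (at T_o) only when T_o <= c < T_b, where c is the
        patient's censoring time; everyone else is censored at c, including
        the small double-death mass (probability H_B*H_O at the horizon)
        that the published competing-risks accounting Rb = H_B(1-H_O),
        Ro = H_O(1-H_B) assigns to neither cause.  Observed death counts at
        the administrative horizon then equal summed Rb/Ro in expectation -
        use this mode to exercise calibration machinery against the scorer.

    The two rules differ because Rb/Ro are not the cumulative incidence of
    any single event-time process; see the methods note.
    """
    model = model or default_model()
    if cause_rule not in ("first", "exclusive"):
        raise ConfigurationError("cause_rule must be 'first' or 'exclusive'")
    censoring = censoring or CensoringConfig()
    censoring.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_latent, rng_censor = (np.random.default_rng(s) for s in ss.spawn(2))

    n = len(covariates)
    df = covariates.copy()
    er = df["er"].astype(str).to_numpy()
    if np.any((er == "neg") & (df["hormone"].to_numpy(dtype=float) > 0)):
        raise InvalidInputError("hormone", "hormone therapy flagged for an ER-negative record")

    pi = np.empty(n)
    for endpoint, mask in ((ER_POS, er == "pos"), (ER_NEG, er == "neg")):
        if not mask.any():
            continue
        sub = df.loc[mask]
        p = linear_predictor(sub, endpoint, model)
        p = p + sub["chemo"].to_numpy(dtype=float) * treatment_log_hr_total(("chemotherapy",), endpoint, model)
        if endpoint == ER_POS:
            p = p + sub["hormone"].to_numpy(dtype=float) * treatment_log_hr_total(("hormone",), endpoint, model)
        pi[mask] = p
    mi = mortality_index(df["age"].to_numpy(dtype=float), model)

    u = rng_latent.random((n, 2))
    t_breast = np.empty(n)
    for endpoint, mask in ((ER_POS, er == "pos"), (ER_NEG, er == "neg")):
        if mask.any():
            t_breast[mask] = invert_cumhaz(u[mask, 0], pi[mask], model.baseline_for(endpoint))
    t_other = invert_cumhaz(u[:, 1], mi, model.baseline_for(OTHER))

    c = np.full(n, float(censoring.admin_years))
    if censoring.random_rate > 0:
        c = np.minimum(c, rng_censor.exponential(1.0 / censoring.random_rate, size=n))

    if cause_rule == "first":
        time = np.minimum.reduce([t_breast, t_other, c])
        event = np.where(
            (t_breast <= t_other) & (t_breast <= c),
            "breast",
            np.where(t_other <= c, "other", "censored"),
        )
    else:
        breast = (t_breast <= c) & (t_other > c)
        other = (t_other <= c) & (t_breast > c)
        time = np.where(breast, t_breast, np.where(other, t_other, c))
        event = np.where(breast, "breast", np.where(other, "other", "censored"))
    df["time_years"] = time
    df["event"] = event
    return df


def simulate_cohort(
    n: int,
    model: ModelCoefficients | None = None,
    covariates: CovariateConfig | None = None,
    censoring: CensoringConfig | None = None,
    seed: int = 0,
    cause_rule: str = "first",
) -> pd.DataFrame:
    """Covariates + outcomes in one call, one master seed.

    The master seed is split into independent substreams for covariates and
    for outcomes (latent times / random censoring), so the same covariate
    panel is reproducible regardless of the censoring configuration.
    """
    ss = np.random.SeedSequence(seed)
    ss_cov, ss_out = ss.spawn(2)
    cov = sample_covariates(n, covariates, seed=ss_cov)
    return simulate_outcomes(cov, model, censoring, seed=ss_out, cause_rule=cause_rule)
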