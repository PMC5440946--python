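"""Model-development machinery.

Proportional-hazards estimation with fractional-polynomial covariates,
sequential backward elimination, multivariable fractional-polynomial (MFP)
function selection, the Breslow baseline cumulative hazard, and
fractional-polynomial smoothing of the log cumulative hazard.

The Cox partial likelihood is maximised by Newton-Raphson with step-halving
and Breslow handling of tied event times (consistent with the Breslow
baseline estimator; the simulator produces continuous times so ties are
rare).  Convergence is declared when the relative change in the partial
log-likelihood falls below 1e-9, with a cap of 100 iterations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FittingError, InvalidInputError
from .model import (
    ER_NEG,
    ER_POS,
    OTHER,
    BaselineLogCumhaz,
    BaselineTerm,
    FPTerm,
    ModelCoefficients,
    check_covariates,
    normalize_endpoint,
)

__all__ = [
    "STANDARD_GRID",
    "VariableSpec",
    "FPSpec",
    "CoxFit",
    "CumhazSteps",
    "SmoothFit",
    "design_matrix",
    "cox_partial_loglik",
    "fit_cox_fixed_terms",
    "backward_eliminate",
    "mfp_select",
    "breslow_cumhaz",
    "smooth_log_cumhaz",
    "refit_endpoint",
]

#: The conventional fractional-polynomial power grid (0 means natural log).
STANDARD_GRID = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

MAX_ITER = 100
REL_TOL = 1e-9


# ---------------------------------------------------------------------------
# Transform specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSpec:
    """FP transform of one model variable.

    ``powers`` lists the chosen FP powers; a repeated power p contributes the
    basis pair {x^p, x^p ln x} (for p = 0: {ln x, (ln x)^2}).  An empty tuple
    marks an eliminated variable.  ``fp`` marks variables whose functional
    form is subject to MFP selection (continuous factors); indicator and
    ordinal factors keep ``powers=(1,)`` fixed.
    """

    variable: str
    powers: tuple[float, ...] = (1.0,)
    shift: float = 0.0
    scale: float = 1.0
    centers: tuple[float, ...] = ()
    fp: bool = True

    @property
    def retained(self) -> bool:
        return len(self.powers) > 0

    def basis_terms(self) -> list[tuple[float, bool]]:
        """(power, log_times) per basis column, applying the repeat rule."""
        seen: dict[float, int] = {}
        out = []
        for p in self.powers:
            n = seen.get(p, 0)
            if n >= 2:
                raise FittingError(f"power {p} repeated more than twice for {self.variable}")
            out.append((p, n == 1))
            seen[p] = n + 1
        return out

    def column_names(self) -> list[str]:
        names = []
        for j, (p, logt) in enumerate(self.basis_terms()):
            tag = "log" if p == 0 else f"p{p:g}"
            names.append(f"{self.variable}_{tag}" + ("_xln" if logt else ""))
        return names

    def columns(self, raw: np.ndarray) -> np.ndarray:
        """Centered basis columns (n x k) for raw covariate values."""
        x = (np.asarray(raw, dtype=float) + self.shift) / self.scale
        basis = self.basis_terms()
        needs_pos = any(p <= 0 or logt for p, logt in basis)
        if needs_pos and np.any(x <= 0):
            raise InvalidInputError(
                self.variable, "non-positive value under a log/negative-power transform"
            )
        centers = self.centers if self.centers else (0.0,) * len(basis)
        if len(centers) != len(basis):
            raise FittingError(f"centers/powers length mismatch for {self.variable}")
        cols = np.empty((x.size, len(basis)))
        for j, ((p, logt), c) in enumerate(zip(basis, centers)):
            b = np.log(x) if p == 0 else x ** p
            if logt:
                b = b * np.log(x)
            cols[:, j] = b - c
        return cols


@dataclass(frozen=True)
class FPSpec:
    """Ordered collection of variable transforms defining a design matrix."""

    variables: tuple[VariableSpec, ...]

    def retained(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.retained)

    def replace(self, variable: str, new: VariableSpec) -> "FPSpec":
        return FPSpec(tuple(new if v.variable == variable else v for v in self.variables))

    def drop(self, variable: str) -> "FPSpec":
        return self.replace(
            variable,
            next(
                dataclasses.replace(v, powers=(), centers=())
                for v in self.variables
                if v.variable == variable
            ),
        )

    @classmethod
    def from_model(cls, model: ModelCoefficients, endpoint: str) -> "FPSpec":
        """Reconstruct the transform spec behind a fitted model's FP terms."""
        endpoint = normalize_endpoint(endpoint)
        groups: dict[str, list[FPTerm]] = {}
        for term in model.terms_for(endpoint):
            groups.setdefault(term.variable, []).append(term)
        specs = []
        for variable, terms in groups.items():
            powers = []
            centers = []
            for t in terms:
                powers.append(t.power)
                centers.append(t.center)
            is_fp = variable not in ("grade", "screen", "chemo", "hormone")
            specs.append(
                VariableSpec(
                    variable=variable,
                    powers=tuple(powers),
                    shift=terms[0].shift,
                    scale=terms[0].scale,
                    centers=tuple(centers),
                    fp=is_fp,
                )
            )
        return cls(tuple(specs))


def design_matrix(cohort: pd.DataFrame, spec: FPSpec) -> tuple[np.ndarray, list[str]]:
    """Stacked centered FP basis columns for all retained variables."""
    blocks, names = [], []
    for v in spec.retained():
        if v.variable not in cohort.columns:
            raise InvalidInputError(v.variable, "column missing from cohort")
        blocks.append(v.columns(cohort[v.variable].to_numpy(dtype=float)))
        names.extend(v.column_names())
    if not blocks:
        return np.empty((len(cohort), 0)), []
    return np.hstack(blocks), names


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------


def _risk_set_parts(X, time, event):
    """Sort ascending and precompute tie-group bookkeeping."""
    order = np.argsort(time, kind="stable")
    t = np.asarray(time, dtype=float)[order]
    d = np.asarray(event).astype(bool)[order]
    Xs = np.asarray(X, dtype=float)[order]
    first = np.r_[True, t[1:] != t[:-1]]
    group = np.cumsum(first) - 1
    starts = np.flatnonzero(first)
    n_groups = starts.size
    dcount = np.bincount(group[d], minlength=n_groups)
    return t, d, Xs, group, starts, dcount


def _loglik_parts(Xs, d, starts, dcount, beta, need_derivs=True):
    n, p = Xs.shape
    eta = Xs @ beta if p else np.zeros(n)
    r = np.exp(eta)
    S0 = np.cumsum(r[::-1])[::-1][starts]
    ev = dcount > 0
    llf = float(eta[d].sum() - (dcount[ev] * np.log(S0[ev])).sum())
    if not need_derivs or p == 0:
        return llf, None, None
    S1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1][starts]
    S2 = np.cumsum((r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1][starts]
    m = S1[ev] / S0[ev, None]
    grad = Xs[d].sum(axis=0) - (dcount[ev, None] * m).sum(axis=0)
    info = np.einsum("g,gij->ij", dcount[ev], S2[ev] / S0[ev, None, None]) - np.einsum(
        "g,gi,gj->ij", dcount[ev], m, m
    )
    return llf, grad, info


def cox_partial_loglik(X, time, event, beta) -> float:
    """Breslow-ties Cox partial log-likelihood at ``beta`` (oracle-friendly)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    _, d, Xs, _, starts, dcount = _risk_set_parts(X, time, event)
    llf, _, _ = _loglik_parts(Xs, d, starts, dcount, np.atleast_1d(np.asarray(beta, dtype=float)), need_derivs=False)
    return llf


@dataclass
class CoxFit:
    """A fitted proportional-hazards model with FP covariates."""

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_path: list[float]
    n: int
    n_events: int
    converged: bool
    iterations: int
    spec: FPSpec
    endpoint: str
    truncate_years: float


@dataclass
class CumhazSteps:
    """Breslow step-function estimate of the baseline cumulative hazard."""

    times: np.ndarray
    cumhaz: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumhaz = np.asarray(self.cumhaz, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise FittingError("step times must be strictly increasing")
        if self.cumhaz.size and (np.any(np.diff(self.cumhaz) < 0) or self.cumhaz[0] < 0):
            raise FittingError("cumulative hazard must be non-negative and non-decreasing")

    def evaluate(self, times) -> np.ndarray:
        """Step-function value at arbitrary times (0 before the first event)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.times, times, side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]


def _newton_cox(X, time, event, max_iter=MAX_ITER, tol=REL_TOL):
    n, p = X.shape
    # Centering columns leaves the partial likelihood invariant but keeps
    # exp(eta) well-conditioned for extreme FP columns.
    mean = X.mean(axis=0) if p else np.zeros(0)
    Xc = X - mean
    _, d, Xs, _, starts, dcount = _risk_set_parts(Xc, time, event)
    beta = np.zeros(p)
    llf, grad, info = _loglik_parts(Xs, d, starts, dcount, beta)
    path = [llf]
    converged = p == 0
    iterations = 0
    for it in range(1, max_iter + 1):
        if p == 0:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(40):  # step-halving: never accept a likelihood decrease
            cand = beta + scale * step
            cand_llf, cand_grad, cand_info = _loglik_parts(Xs, d, starts, dcount, cand)
            if np.isfinite(cand_llf) and cand_llf >= llf - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta, new_llf, grad, info = cand, cand_llf, cand_grad, cand_info
        path.append(new_llf)
        iterations = it
        if abs(new_llf - llf) <= tol * (abs(llf) + 1.0):
            llf = new_llf
            converged = True
            break
        llf = new_llf
    if p:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        cov = np.zeros((0, 0))
        se = np.zeros(0)
    return beta, se, cov, llf, path, converged, iterations


_ENDPOINT_CAUSE = {ER_NEG: "breast", ER_POS: "breast", OTHER: "other"}


def _fitting_frame(cohort: pd.DataFrame, endpoint: str, truncate_years: float):
    """Endpoint subset with the competing cause censored and time truncated."""
    endpoint = normalize_endpoint(endpoint)
    df = cohort
    if endpoint in (ER_NEG, ER_POS) and "er" in df.columns:
        want = "neg" if endpoint == ER_NEG else "pos"
        df = df.loc[df["er"].astype(str) == want]
    if df.empty:
        raise FittingError(f"no patients for endpoint {endpoint}")
    time = df["time_years"].to_numpy(dtype=float)
    cause = df["event"].astype(str).to_numpy()
    event = (cause == _ENDPOINT_CAUSE[endpoint]) & (time <= truncate_years)
    time = np.minimum(time, truncate_years)
    if np.any(~np.isfinite(time) | (time < 0)):
        raise InvalidInputError("time_years", "follow-up must be finite and >= 0")
    return df, time, event


def fit_cox_fixed_terms(
    cohort: pd.DataFrame,
    spec: FPSpec,
    endpoint: str,
    truncate_years: float = 10.0,
) -> CoxFit:
    """Maximum partial likelihood fit of a fixed FP transform specification.

    Deaths from the competing cause are censored; follow-up is truncated at
    ``truncate_years`` (events beyond it are censored there), matching the
    10-year event-counting convention of the development analysis.
    """
    endpoint = normalize_endpoint(endpoint)
    df, time, event = _fitting_frame(cohort, endpoint, truncate_years)
    check_covariates(df, endpoint)
    n_events = int(event.sum())
    if n_events < 2:
        raise FittingError(f"need at least 2 events of cause {_ENDPOINT_CAUSE[endpoint]!r}, got {n_events}")
    X, names = design_matrix(df, spec)
    beta, se, cov, llf, path, converged, iterations = _newton_cox(X, time, event)
    return CoxFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        loglik=llf,
        loglik_path=path,
        n=len(df),
        n_events=n_events,
        converged=converged,
        iterations=iterations,
        spec=spec,
        endpoint=endpoint,
        truncate_years=truncate_years,
    )


# ---------------------------------------------------------------------------
# Variable and function selection
# ---------------------------------------------------------------------------


def backward_eliminate(
    cohort: pd.DataFrame,
    spec: FPSpec,
    endpoint: str,
    alpha: float = 0.05,
    truncate_years: float = 10.0,
) -> tuple[FPSpec, CoxFit]:
    """Sequential backward elimination by likelihood-ratio tests.

    Repeatedly refits without each retained variable and drops the least
    significant one (LRT against the reduced model, df = number of basis
    columns) until every remaining variable is significant at ``alpha``.
    """
    if not 0 < alpha <= 1:
        raise FittingError("alpha must lie in (0, 1]")
    current = spec
    fit = fit_cox_fixed_terms(cohort, current, endpoint, truncate_years)
    while True:
        candidates = []
        for v in current.retained():
            reduced = current.drop(v.variable)
            if not reduced.retained():
                red_llf = cox_partial_loglik(
                    np.empty((fit.n, 0)), *_time_event(cohort, endpoint, truncate_years), np.zeros(0)
                )
                red_fit = None
            else:
                red_fit = fit_cox_fixed_terms(cohort, reduced, endpoint, truncate_years)
                red_llf = red_fit.loglik
            lrt = 2.0 * (fit.loglik - red_llf)
            df_ = len(v.column_names())
            p = stats.chi2.sf(max(lrt, 0.0), df_)
            candidates.append((p, v.variable, reduced, red_fit))
        if not candidates:
            break
        p_max, variable, reduced, red_fit = max(candidates, key=lambda c: c[0])
        if p_max > alpha:
            current = reduced
            fit = red_fit if red_fit is not None else fit_cox_fixed_terms(
                cohort, current, endpoint, truncate_years
            )
            if not current.retained():
                break
        else:
            break
    return current, fit


def _time_event(cohort, endpoint, truncate_years):
    _, time, event = _fitting_frame(cohort, endpoint, truncate_years)
    return time, event


def _fp1_candidates(grid):
    return [(p,) for p in grid]


def _fp2_candidates(grid):
    out = []
    for i, p1 in enumerate(grid):
        for p2 in grid[i:]:
            out.append((p1, p2))
    return out


def mfp_select(
    cohort: pd.DataFrame,
    spec: FPSpec,
    endpoint: str,
    alpha: float = 0.05,
    grid: Sequence[float] = STANDARD_GRID,
    cycles: int = 1,
    truncate_years: float = 10.0,
) -> tuple[FPSpec, CoxFit]:
    """Multivariable fractional-polynomial function selection (closed test).

    For each continuous variable in turn, holding the others at their current
    transforms, the best-deviance FP2 is compared with (a) the null model
    (variable excluded, 4 df), (b) the linear function (3 df) and (c) the
    best FP1 (2 df), all at level ``alpha`` on partial-likelihood deviance
    differences with the conventional degrees of freedom.  A single pass over
    the variables is the default; set ``cycles`` to iterate until stable.
    """
    grid = tuple(grid)
    current = spec

    def dev(s: FPSpec) -> float:
        if not s.retained():
            time, event = _time_event(cohort, endpoint, truncate_years)
            n = time.size
            return -2.0 * cox_partial_loglik(np.empty((n, 0)), time, event, np.zeros(0))
        return -2.0 * fit_cox_fixed_terms(cohort, s, endpoint, truncate_years).loglik

    for _ in range(max(1, cycles)):
        changed = False
        for v in current.variables:
            if not v.fp or (not v.retained and cycles == 1):
                continue
            base = dataclasses.replace(v, centers=())

            def with_powers(powers):
                return current.replace(
                    v.variable, dataclasses.replace(base, powers=tuple(powers))
                )

            d_null = dev(current.drop(v.variable))
            d_lin = dev(with_powers((1.0,)))
            fp1 = min(_fp1_candidates(grid), key=lambda pw: dev(with_powers(pw)))
            d_fp1 = dev(with_powers(fp1))
            fp2 = min(_fp2_candidates(grid), key=lambda pw: dev(with_powers(pw)))
            d_fp2 = dev(with_powers(fp2))

            if stats.chi2.sf(max(d_null - d_fp2, 0.0), 4) > alpha:
                chosen: tuple[float, ...] = ()
            elif stats.chi2.sf(max(d_lin - d_fp2, 0.0), 3) > alpha:
                chosen = (1.0,)
            elif stats.chi2.sf(max(d_fp1 - d_fp2, 0.0), 2) > alpha:
                chosen = fp1
            else:
                chosen = fp2
            if chosen != v.powers:
                changed = True
            current = (
                current.drop(v.variable)
                if not chosen
                else current.replace(v.variable, dataclasses.replace(base, powers=chosen))
            )
        if not changed:
            break
    if current.retained():
        fit = fit_cox_fixed_terms(cohort, current, endpoint, truncate_years)
    else:
        raise FittingError("MFP selection eliminated every variable")
    return current, fit


# ---------------------------------------------------------------------------
# Baseline hazard: Breslow steps and FP smoothing
# ---------------------------------------------------------------------------


def breslow_cumhaz(fit: CoxFit, cohort: pd.DataFrame) -> CumhazSteps:
    """Breslow estimator of the baseline cumulative hazard.

    The increment at each distinct event time is d_j / sum_{at risk} exp(PI_i)
    with covariates entered exactly as in the fit, so "baseline" means all
    centered transform columns equal to zero.
    """
    df, time, event = _fitting_frame(cohort, fit.endpoint, fit.truncate_years)
    X, _ = design_matrix(df, fit.spec)
    t, d, Xs, group, starts, dcount = _risk_set_parts(X, time, event)
    if not d.any():
        return CumhazSteps(np.empty(0), np.empty(0))
    r = np.exp(Xs @ fit.coefficients) if X.shape[1] else np.ones(len(t))
    S0 = np.cumsum(r[::-1])[::-1][starts]
    if np.any(S0 <= 0):
        raise FittingError("empty risk set at an event time")
    ev = dcount > 0
    times = t[starts][ev]
    increments = dcount[ev] / S0[ev]
    return CumhazSteps(times, np.cumsum(increments))


@dataclass
class SmoothFit:
    """A smoothed baseline: FP2-in-time least squares on the log scale."""

    baseline: BaselineLogCumhaz
    powers: tuple[float, ...]
    rss: float
    n_points: int


def _time_basis(t: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(t)]
    seen: dict[float, int] = {}
    for p in powers:
        rep = seen.get(p, 0) == 1
        b = np.log(t) if p == 0 else t ** p
        if rep:
            b = b * np.log(t)
        cols.append(b)
        seen[p] = seen.get(p, 0) + 1
    return np.column_stack(cols)


def smooth_log_cumhaz(
    steps: CumhazSteps,
    grid: Sequence[float] = STANDARD_GRID,
    monotone_range: tuple[float, float] = (1.0, 10.0),
    at_times: np.ndarray | None = None,
) -> SmoothFit:
    """Least-squares FP2 smoothing of ln(cumulative hazard) against time.

    With ``at_times`` (one follow-up time per patient) the regression runs
    over the baseline cumulative hazard evaluated at each patient's own time,
    mirroring the per-patient derivation of the published baselines; patient
    times before the first event (where the step function is still zero)
    carry no information and are dropped.  Without it, each distinct event
    time contributes one equally weighted point.

    The FP2 power pair is chosen from the grid by residual sum of squares;
    candidates whose implied cumulative hazard is not non-decreasing on a
    dense grid over ``monotone_range`` are discarded (refit with the
    restricted candidate set), so the returned curve is usable as a baseline.
    """
    if at_times is None:
        t, H = steps.times, steps.cumhaz
        w = np.ones_like(t)
    else:
        at = np.asarray(at_times, dtype=float)
        vals = steps.evaluate(at)
        keep = vals > 0
        t, counts = np.unique(at[keep], return_counts=True)
        H = steps.evaluate(t)
        w = counts.astype(float)
    if np.unique(t).size < 5:
        raise FittingError("need at least 5 distinct event times to smooth")
    if np.any(H <= 0):
        raise FittingError("cumulative hazard must be positive to take logs")
    y = np.log(H)
    sw = np.sqrt(w)
    dense = np.linspace(monotone_range[0], monotone_range[1], 400)
    results = []
    for powers in _fp2_candidates(tuple(grid)):
        A = _time_basis(t, powers)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        rss = float(np.sum(w * (A @ coef - y) ** 2))
        results.append((rss, powers, coef))
    results.sort(key=lambda r: r[0])
    for rss, powers, coef in results:
        fitted = _time_basis(dense, powers) @ coef
        if np.all(np.diff(fitted) >= -1e-10):
            seen: dict[float, int] = {}
            terms = []
            for p, c in zip(powers, coef[1:]):
                rep = seen.get(p, 0) == 1
                terms.append(BaselineTerm(power=p, coefficient=float(c), log_times=rep))
                seen[p] = seen.get(p, 0) + 1
            baseline = BaselineLogCumhaz(intercept=float(coef[0]), terms=tuple(terms))
            return SmoothFit(baseline=baseline, powers=powers, rss=rss, n_points=t.size)
    raise FittingError("no monotone FP2 smoothing found on the grid")


# ---------------------------------------------------------------------------
# End-to-end refit helper
# ---------------------------------------------------------------------------


def refit_endpoint(
    cohort: pd.DataFrame,
    endpoint: str,
    base_model: ModelCoefficients | None = None,
    select_fp: bool = False,
    alpha: float = 0.05,
    truncate_years: float = 10.0,
) -> tuple[ModelCoefficients, CoxFit, SmoothFit]:
    """Fit one endpoint and splice the result into a full coefficient set.

    Starts from the shipped transform spec (Table-convention scaling and
    centering), optionally reselects FP functions by MFP, fits the Cox model,
    derives the Breslow baseline and smooths its logarithm.  Returns a new
    ModelCoefficients with the endpoint's terms and baseline replaced.
    """
    from .model import default_model  # local import to avoid cycle at module load

    base_model = base_model or default_model()
    endpoint = normalize_endpoint(endpoint)
    spec = FPSpec.from_model(base_model, endpoint)
    if select_fp:
        spec, fit = mfp_select(cohort, spec, endpoint, alpha=alpha, truncate_years=truncate_years)
    else:
        fit = fit_cox_fixed_terms(cohort, spec, endpoint, truncate_years)
    steps = breslow_cumhaz(fit, cohort)
    _, follow_up, _ = _fitting_frame(cohort, endpoint, truncate_years)
    smooth = smooth_log_cumhaz(steps, at_times=follow_up)

    terms = []
    i = 0
    for v in fit.spec.retained():
        centers = v.centers if v.centers else (0.0,) * len(v.basis_terms())
        for (p, logt), c, colname in zip(v.basis_terms(), centers, v.column_names()):
            terms.append(
                FPTerm(
                    name=colname,
                    variable=v.variable,
                    power=p,
                    shift=v.shift,
                    scale=v.scale,
                    log_times=logt,
                    center=c,
                    coefficient=float(fit.coefficients[i]),
                )
            )
            i += 1
    blocks = {
        ER_NEG: base_model.er_negative,
        ER_POS: base_model.er_positive,
        OTHER: base_model.other_mortality,
    }
    blocks[endpoint] = tuple(terms)
    baselines = dict(base_model.baselines)
    baselines[endpoint] = smooth.baseline
    model = ModelCoefficients(
        er_negative=blocks[ER_NEG],
        er_positive=blocks[ER_POS],
        other_mortality=blocks[OTHER],
        baselines=baselines,
        treatments=base_model.treatments,
        name=f"{base_model.name}+refit:{endpoint}",
        description=base_model.description,
    )
    return model, fit, smooth
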