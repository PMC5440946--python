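"""Deterministic scoring engine for the PREDICT v2 breast cancer model.

The model predicts absolute breast-cancer-specific and other-cause mortality
for women with early invasive breast cancer, from routinely collected
prognostic factors.  Separate Cox models are used for ER-negative and
ER-positive disease; continuous factors enter through fractional-polynomial
(FP) transforms and the baseline cumulative hazard is a smooth parametric
function of time whose logarithm is itself a fractional polynomial.

For a patient with prognostic index ``PI`` (breast endpoint) and mortality
index ``MI`` (other-cause endpoint, a function of age alone), the
cause-specific cumulative risks at horizon ``t`` are

    H_B = 1 - exp(-exp(PI) * Lambda_B0(t))
    H_O = 1 - exp(-exp(MI) * Lambda_O0(t))

where ``Lambda_0(t) = exp(B(t))`` and ``B`` is the smoothed baseline log
cumulative hazard.  The two causes compete, giving adjusted risks

    Rb = H_B * (1 - H_O)        (breast cancer death)
    Ro = H_O * (1 - H_B)        (other-cause death)

Treatment benefit is computed by adding externally estimated treatment log
hazard ratios (adjuvant hormone therapy, chemotherapy) to ``PI`` and taking
differences of ``Rb`` on the competing-risks scale.

The shipped default coefficients (``default_model()``) encode the published
v2 model digit for digit; predictions are supported on t in [1, 10] years.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HorizonError, InvalidInputError, SchemaError

__all__ = [
    "ER_NEG",
    "ER_POS",
    "OTHER",
    "HORIZON",
    "FPTerm",
    "BaselineTerm",
    "BaselineLogCumhaz",
    "ModelCoefficients",
    "PatientRecord",
    "RiskPrediction",
    "TreatmentBenefit",
    "default_model",
    "normalize_endpoint",
    "fp_transform",
    "prognostic_index",
    "linear_predictor",
    "mortality_index",
    "baseline_log_cumhaz",
    "cumulative_baseline_hazard",
    "absolute_mortality",
    "score_patient",
    "score_cohort",
    "treatment_benefit",
    "cohort_from_records",
]

#: Endpoint identifiers.
ER_NEG = "breast_er_negative"
ER_POS = "breast_er_positive"
OTHER = "other"

#: Supported prediction horizon in years.  Below ~1 year the printed baseline
#: polynomials are not guaranteed monotone and the model was only reported at
#: 5 and 10 years, so scoring refuses to extrapolate outside this window.
HORIZON = (1.0, 10.0)

#: Order in which cumulative treatment benefit is decomposed for display.
TREATMENT_ORDER = ("hormone", "chemotherapy")

_ENDPOINT_ALIASES = {
    ER_NEG: ER_NEG,
    ER_POS: ER_POS,
    OTHER: OTHER,
    "er_neg": ER_NEG,
    "er_pos": ER_POS,
    "neg": ER_NEG,
    "pos": ER_POS,
    "other_mortality": OTHER,
}


def normalize_endpoint(endpoint: str) -> str:
    try:
        return _ENDPOINT_ALIASES[str(endpoint).lower()]
    except KeyError:
        raise ConfigurationError(f"unknown endpoint {endpoint!r}") from None


# ---------------------------------------------------------------------------
# Model coefficient containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FPTerm:
    """One fractional-polynomial basis term of a prognostic model.

    The raw covariate ``v`` is first mapped to ``x = (v + shift) / scale``
    (Table-convention rescaling, e.g. age/10, size/100, (nodes+1)/10), then
    transformed as ``x**power`` (``power == 0`` meaning ``ln x``; with
    ``log_times`` the basis is ``x**power * ln x``), and finally the
    ``center`` constant is subtracted so the reference patient scores exactly
    zero on the term.  ``coefficient`` is the log hazard ratio per unit of
    the transformed value.
    """

    name: str
    variable: str
    power: float = 1.0
    shift: float = 0.0
    scale: float = 1.0
    log_times: bool = False
    center: float = 0.0
    coefficient: float = 0.0

    def basis(self, values) -> np.ndarray:
        """Evaluate the centered transform on raw covariate values."""
        x = (np.asarray(values, dtype=float) + self.shift) / self.scale
        needs_positive = self.power < 0 or self.power == 0 or self.log_times
        if needs_positive and np.any(x <= 0):
            raise InvalidInputError(
                self.variable,
                f"must be > {-self.shift} for the {self.name!r} transform",
            )
        if self.power == 0:
            b = np.log(x)
            if self.log_times:  # (ln x)^2, the repeated-power-0 basis
                b = b * np.log(x)
        else:
            b = x ** self.power
            if self.log_times:
                b = b * np.log(x)
        return b - self.center

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BaselineTerm:
    power: float
    coefficient: float
    log_times: bool = False

    def value(self, t: np.ndarray) -> np.ndarray:
        if self.power == 0:
            b = np.log(t)
            if self.log_times:
                b = b * np.log(t)
        else:
            b = t ** self.power
            if self.log_times:
                b = b * np.log(t)
        return self.coefficient * b

    def dlnt(self, t: np.ndarray) -> np.ndarray:
        """Derivative with respect to ln t (used for extrapolation slopes)."""
        if self.power == 0:
            d = np.ones_like(t) if not self.log_times else 2.0 * np.log(t)
        else:
            d = self.power * t ** self.power
            if self.log_times:
                d = d * np.log(t) + t ** self.power
        return self.coefficient * d


@dataclass(frozen=True)
class BaselineLogCumhaz:
    """Smoothed baseline *log* cumulative hazard: B(t) = a0 + sum c_k b_k(t).

    The cumulative baseline hazard used by the risk formulas is ``exp(B(t))``.
    """

    intercept: float
    terms: tuple[BaselineTerm, ...]

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.intercept, dtype=float)
        for term in self.terms:
            out = out + term.value(t)
        return out

    def derivative_lnt(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=float)
        for term in self.terms:
            out = out + term.dlnt(t)
        return out

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [dataclasses.asdict(term) for term in self.terms],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaselineLogCumhaz":
        return cls(
            intercept=float(d["intercept"]),
            terms=tuple(
                BaselineTerm(
                    power=float(t["power"]),
                    coefficient=float(t["coefficient"]),
                    log_times=bool(t.get("log_times", False)),
                )
                for t in d["terms"]
            ),
        )


@dataclass(frozen=True)
class Treatment:
    name: str
    log_hr: float
    applies_to: frozenset
    source: str = ""

    def to_dict(self) -> dict:
        return {
            "log_hr": self.log_hr,
            "applies_to": sorted(self.applies_to),
            "source": self.source,
        }


_SCHEMA_VERSION = 1
_REQUIRED_BLOCKS = ("er_negative", "er_positive", "other_mortality", "baselines", "treatments")


@dataclass(frozen=True)
class ModelCoefficients:
    """Complete coefficient set: FP terms per endpoint, baselines, treatments."""

    er_negative: tuple[FPTerm, ...]
    er_positive: tuple[FPTerm, ...]
    other_mortality: tuple[FPTerm, ...]
    baselines: Mapping[str, BaselineLogCumhaz]
    treatments: Mapping[str, Treatment]
    name: str = "custom"
    description: str = ""
    schema_version: int = _SCHEMA_VERSION

    def terms_for(self, endpoint: str) -> tuple[FPTerm, ...]:
        endpoint = normalize_endpoint(endpoint)
        if endpoint == ER_NEG:
            return self.er_negative
        if endpoint == ER_POS:
            return self.er_positive
        return self.other_mortality

    def baseline_for(self, endpoint: str) -> BaselineLogCumhaz:
        return self.baselines[normalize_endpoint(endpoint)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "name": self.name,
            "description": self.description,
            "er_negative": [t.to_dict() for t in self.er_negative],
            "er_positive": [t.to_dict() for t in self.er_positive],
            "other_mortality": [t.to_dict() for t in self.other_mortality],
            "baselines": {k: v.to_dict() for k, v in self.baselines.items()},
            "treatments": {k: v.to_dict() for k, v in self.treatments.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelCoefficients":
        version = d.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise SchemaError(f"unsupported model schema version {version!r}")
        missing = [b for b in _REQUIRED_BLOCKS if b not in d]
        if missing:
            raise SchemaError(f"model file missing block(s): {', '.join(missing)}")

        def _terms(block):
            return tuple(
                FPTerm(
                    name=str(t["name"]),
                    variable=str(t["variable"]),
                    power=float(t["power"]),
                    shift=float(t.get("shift", 0.0)),
                    scale=float(t.get("scale", 1.0)),
                    log_times=bool(t.get("log_times", False)),
                    center=float(t.get("center", 0.0)),
                    coefficient=float(t["coefficient"]),
                )
                for t in d[block]
            )

        baselines = {
            normalize_endpoint(k): BaselineLogCumhaz.from_dict(v)
            for k, v in d["baselines"].items()
        }
        for endpoint in (ER_NEG, ER_POS, OTHER):
            if endpoint not in baselines:
                raise SchemaError(f"model file missing baseline for {endpoint}")
        treatments = {
            str(k): Treatment(
                name=str(k),
                log_hr=float(v["log_hr"]),
                applies_to=frozenset(normalize_endpoint(e) for e in v["applies_to"]),
                source=str(v.get("source", "")),
            )
            for k, v in d["treatments"].items()
        }
        model = cls(
            er_negative=_terms("er_negative"),
            er_positive=_terms("er_positive"),
            other_mortality=_terms("other_mortality"),
            baselines=baselines,
            treatments=treatments,
            name=str(d.get("name", "custom")),
            description=str(d.get("description", "")),
        )
        for term in model.er_negative + model.er_positive + model.other_mortality:
            if not math.isfinite(term.coefficient):
                raise SchemaError(f"non-finite coefficient for term {term.name!r}")
        return model

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ModelCoefficients":
        try:
            return cls.from_dict(json.loads(text))
        except json.JSONDecodeError as exc:
            raise SchemaError(f"model file is not valid JSON: {exc}") from exc


_DEFAULT_CACHE: dict = {}


def default_model() -> ModelCoefficients:
    """The shipped v2 coefficient set (Table-exact terms and baselines)."""
    if "model" not in _DEFAULT_CACHE:
        text = resources.files("predictbc.data").joinpath("predict_v2.json").read_text()
        _DEFAULT_CACHE["model"] = ModelCoefficients.from_json(text)
    return _DEFAULT_CACHE["model"]


# ---------------------------------------------------------------------------
# Patient records and cohorts
# ---------------------------------------------------------------------------

#: Canonical cohort column order (the CSV schema of :mod:`predictbc.io`).
COHORT_COLUMNS = (
    "age",
    "size_mm",
    "nodes",
    "grade",
    "screen",
    "er",
    "chemo",
    "hormone",
    "time_years",
    "event",
)


@dataclass
class PatientRecord:
    """One patient's prognostic factors, treatment flags and outcome.

    ``time_years``/``event`` are only used by fitting and validation; for
    scoring a new patient they may be left at their defaults.
    """

    age: float
    size_mm: float
    nodes: int
    grade: int
    screen: bool = False
    er: str = "pos"
    chemo: bool = False
    hormone: bool = False
    time_years: float = float("nan")
    event: str = "censored"

    def endpoint(self) -> str:
        return ER_POS if self.er == "pos" else ER_NEG

    def treatments(self) -> tuple[str, ...]:
        out = []
        if self.hormone:
            out.append("hormone")
        if self.chemo:
            out.append("chemotherapy")
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)], columns=COHORT_COLUMNS)


def cohort_from_records(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=COHORT_COLUMNS)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, PatientRecord):
        return data.to_frame()
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError("expected a PatientRecord or a cohort DataFrame")


def check_covariates(df: pd.DataFrame, endpoint: str | None = None) -> None:
    """Validate prognostic-factor columns, naming the offending field and row."""

    def _bad(mask, fieldname, why):
        if np.any(mask):
            idx = df.index[np.asarray(mask)][0]
            raise InvalidInputError(fieldname, f"{why} (first offending row: {idx})")

    needed = ("age",) if endpoint == OTHER else ("age", "size_mm", "nodes", "grade")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort is missing column(s): {', '.join(missing)}")
    age = df["age"].to_numpy(dtype=float)
    _bad(~np.isfinite(age) | (age <= 0), "age", "must be a positive number of years")
    if endpoint != OTHER:
        size = df["size_mm"].to_numpy(dtype=float)
        _bad(~np.isfinite(size) | (size < 1), "size_mm", "tumour size must be >= 1 mm")
        nodes = df["nodes"].to_numpy(dtype=float)
        _bad(
            ~np.isfinite(nodes) | (nodes < 0) | (nodes != np.round(nodes)),
            "nodes",
            "positive node count must be a non-negative integer",
        )
        grade = df["grade"].to_numpy(dtype=float)
        _bad(~np.isin(grade, (1, 2, 3)), "grade", "grade must be 1, 2 or 3")
        if "er" in df.columns and endpoint in (ER_NEG, ER_POS):
            er = df["er"].astype(str).to_numpy()
            want = "pos" if endpoint == ER_POS else "neg"
            _bad(er != want, "er", f"endpoint {endpoint} requires er == {want!r}")


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------


def fp_transform(data, endpoint: str, model: ModelCoefficients | None = None) -> pd.DataFrame:
    """Centered fractional-polynomial term values for one endpoint.

    Returns a DataFrame with one column per model term (in model order);
    evaluating a covariate at its centering point yields exactly 0 (grade,
    which Table 1 leaves uncentered, is returned raw).
    """
    model = model or default_model()
    endpoint = normalize_endpoint(endpoint)
    df = _as_frame(data)
    check_covariates(df, endpoint)
    terms = model.terms_for(endpoint)
    out = pd.DataFrame(index=df.index)
    for term in terms:
        if term.variable not in df.columns:
            raise SchemaError(f"cohort is missing column {term.variable!r}")
        values = df[term.variable]
        if term.variable in ("screen", "chemo", "hormone"):
            values = values.astype(float)
        out[term.name] = term.basis(values)
    return out


def prognostic_index(
    terms,
    endpoint: str,
    model: ModelCoefficients | None = None,
    treatments: Sequence[str] = (),
):
    """PI = sum(term * logHR) + sum of treatment log HRs.

    ``terms`` must be the output of :func:`fp_transform` for the same
    endpoint (a DataFrame or array with columns in model order).
    """
    model = model or default_model()
    endpoint = normalize_endpoint(endpoint)
    fpterms = model.terms_for(endpoint)
    values = np.asarray(terms, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != len(fpterms):
        raise ConfigurationError(
            f"expected {len(fpterms)} term values for {endpoint}, got {values.shape[1]}"
        )
    coefs = np.array([t.coefficient for t in fpterms])
    pi = values @ coefs
    pi = pi + treatment_log_hr_total(treatments, endpoint, model)
    return pi if isinstance(terms, (pd.DataFrame, np.ndarray)) and np.ndim(terms) > 1 else float(pi[0])


def treatment_log_hr_total(
    treatments: Sequence[str], endpoint: str, model: ModelCoefficients | None = None
) -> float:
    """Sum of configured treatment log HRs, validating applicability."""
    model = model or default_model()
    endpoint = normalize_endpoint(endpoint)
    total = 0.0
    for name in treatments:
        if name not in model.treatments:
            raise ConfigurationError(
                f"treatment {name!r} is not configured in the model file"
            )
        trt = model.treatments[name]
        if endpoint not in trt.applies_to:
            raise ConfigurationError(
                f"treatment {name!r} does not apply to endpoint {endpoint} "
                f"(hormone therapy is ER-positive only)"
            )
        total += trt.log_hr
    return total


def linear_predictor(
    data,
    endpoint: str,
    model: ModelCoefficients | None = None,
    treatments: Sequence[str] = (),
):
    """Convenience composition fp_transform -> prognostic_index."""
    model = model or default_model()
    terms = fp_transform(data, endpoint, model)
    pi = prognostic_index(terms, endpoint, model, treatments)
    if isinstance(data, PatientRecord):
        return float(np.asarray(pi).ravel()[0])
    return np.asarray(pi, dtype=float).ravel()


def mortality_index(age, model: ModelCoefficients | None = None):
    """Other-cause (non-breast) mortality index, a function of age alone."""
    model = model or default_model()
    age_arr = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(age_arr) | (age_arr <= 0)):
        raise InvalidInputError("age", "must be a positive number of years")
    mi = np.zeros(age_arr.shape, dtype=float)
    for term in model.other_mortality:
        mi = mi + term.coefficient * term.basis(age_arr)
    return float(mi) if np.isscalar(age) else mi


def _check_horizon(t) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < HORIZON[0]) | (t_arr > HORIZON[1]) | ~np.isfinite(t_arr)):
        raise HorizonError(
            f"prediction time must lie in [{HORIZON[0]:g}, {HORIZON[1]:g}] years"
        )
    return t_arr


def baseline_log_cumhaz(t, endpoint: str, model: ModelCoefficients | None = None):
    """Smoothed baseline log cumulative hazard B(t) on the supported horizon."""
    model = model or default_model()
    t_arr = _check_horizon(t)
    out = model.baseline_for(endpoint)(t_arr)
    return float(out) if np.isscalar(t) else out


def cumulative_baseline_hazard(t, endpoint: str, model: ModelCoefficients | None = None):
    """Lambda_0(t) = exp(B(t))."""
    return np.exp(baseline_log_cumhaz(t, endpoint, model))


@dataclass(frozen=True)
class RiskPrediction:
    """Cause-specific and competing-risks-adjusted cumulative risks at t."""

    pi: float
    mi: float
    t: float
    h_breast: float
    h_other: float
    risk_breast: float
    risk_other: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def absolute_mortality(
    pi,
    mi,
    t,
    endpoint: str,
    model: ModelCoefficients | None = None,
):
    """Competing-risks absolute mortality from indices and horizon.

    Returns a :class:`RiskPrediction` for scalar inputs, or a DataFrame with
    columns ``pi, mi, h_breast, h_other, risk_breast, risk_other`` for arrays.
    """
    model = model or default_model()
    endpoint = normalize_endpoint(endpoint)
    if endpoint == OTHER:
        raise ConfigurationError("endpoint must be a breast endpoint (ER +/-)")
    pi_arr = np.asarray(pi, dtype=float)
    mi_arr = np.asarray(mi, dtype=float)
    # -inf is a legal degenerate index (zero hazard); NaN and +inf are not.
    for name_, arr in (("pi", pi_arr), ("mi", mi_arr)):
        if np.any(np.isnan(arr)) or np.any(arr == np.inf):
            raise InvalidInputError(name_, "index must be finite (or -inf)")
    lam_b = np.exp(baseline_log_cumhaz(t, endpoint, model))
    lam_o = np.exp(baseline_log_cumhaz(t, OTHER, model))
    h_b = 1.0 - np.exp(-np.exp(pi_arr) * lam_b)
    h_o = 1.0 - np.exp(-np.exp(mi_arr) * lam_o)
    rb = h_b * (1.0 - h_o)
    ro = h_o * (1.0 - h_b)
    if np.isscalar(pi) and np.isscalar(mi) and np.isscalar(t):
        return RiskPrediction(
            pi=float(pi_arr), mi=float(mi_arr), t=float(t),
            h_breast=float(h_b), h_other=float(h_o),
            risk_breast=float(rb), risk_other=float(ro),
        )
    return pd.DataFrame(
        {"pi": pi_arr, "mi": mi_arr, "h_breast": h_b, "h_other": h_o,
         "risk_breast": rb, "risk_other": ro}
    )


def score_patient(
    patient: PatientRecord,
    t: float = 10.0,
    model: ModelCoefficients | None = None,
    use_treatment_flags: bool = True,
) -> RiskPrediction:
    """Score one patient at horizon ``t`` (treatments from the record's flags)."""
    model = model or default_model()
    endpoint = patient.endpoint()
    treatments = patient.treatments() if use_treatment_flags else ()
    pi = linear_predictor(patient, endpoint, model, treatments)
    mi = mortality_index(float(patient.age), model)
    return absolute_mortality(pi, mi, float(t), endpoint, model)


def score_cohort(
    cohort: pd.DataFrame,
    t: float = 10.0,
    model: ModelCoefficients | None = None,
    use_treatment_flags: bool = True,
) -> pd.DataFrame:
    """Vectorised scoring of a cohort table (ER strata handled internally).

    The hormone flag contributes only for ER-positive rows (the configured
    effect is adjuvant endocrine therapy, which has no counterpart in the
    ER-negative model); the chemotherapy flag contributes for all rows.
    """
    model = model or default_model()
    out = pd.DataFrame(index=cohort.index, columns=["pi", "mi", "h_breast", "h_other", "risk_breast", "risk_other"], dtype=float)
    mi = mortality_index(cohort["age"].to_numpy(dtype=float), model)
    er = cohort["er"].astype(str).to_numpy()
    unknown = ~np.isin(er, ("pos", "neg"))
    if unknown.any():
        raise InvalidInputError("er", "must be 'pos' or 'neg'")
    for endpoint, mask in ((ER_POS, er == "pos"), (ER_NEG, er == "neg")):
        if not mask.any():
            continue
        sub = cohort.loc[mask]
        pi = linear_predictor(sub, endpoint, model)
        if use_treatment_flags:
            if "chemo" in sub.columns:
                pi = pi + sub["chemo"].to_numpy(dtype=float) * treatment_log_hr_total(
                    ("chemotherapy",), endpoint, model
                )
            if endpoint == ER_POS and "hormone" in sub.columns:
                pi = pi + sub["hormone"].to_numpy(dtype=float) * treatment_log_hr_total(
                    ("hormone",), endpoint, model
                )
        res = absolute_mortality(pi, mi[mask], float(t), endpoint, model)
        out.loc[mask, ["pi", "mi", "h_breast", "h_other", "risk_breast", "risk_other"]] = res.to_numpy()
    return out


@dataclass(frozen=True)
class TreatmentBenefit:
    """One step of the cumulative treatment-benefit decomposition."""

    treatment: str
    log_hr: float
    risk_breast_treated: float
    benefit_over_previous: float
    benefit_over_untreated: float


def treatment_benefit(
    patient: PatientRecord,
    regimens: Sequence[str],
    t: float = 10.0,
    model: ModelCoefficients | None = None,
) -> list[TreatmentBenefit]:
    """Absolute breast-cancer mortality reduction for cumulative regimens.

    Treatments are applied in the documented display order (hormone, then
    chemotherapy); each entry reports the configured log HR, the treated Rb,
    the incremental benefit over the previous regimen set and the benefit over
    no adjuvant treatment.  All benefits are on the competing-risks scale, so
    the decomposition order affects only the split, not the combined Rb.
    """
    model = model or default_model()
    endpoint = patient.endpoint()
    regimens = list(regimens)
    for name in regimens:
        treatment_log_hr_total((name,), endpoint, model)  # validates
    ordered = [name for name in TREATMENT_ORDER if name in regimens]
    ordered += [name for name in regimens if name not in TREATMENT_ORDER]
    pi0 = linear_predictor(patient, endpoint, model, treatments=())
    mi = mortality_index(float(patient.age), model)
    rb_untreated = absolute_mortality(pi0, mi, t, endpoint, model).risk_breast
    out: list[TreatmentBenefit] = []
    prev_rb = rb_untreated
    applied: list[str] = []
    for name in ordered:
        applied.append(name)
        pi = pi0 + treatment_log_hr_total(applied, endpoint, model)
        rb = absolute_mortality(pi, mi, t, endpoint, model).risk_breast
        out.append(
            TreatmentBenefit(
                treatment=name,
                log_hr=model.treatments[name].log_hr,
                risk_breast_treated=rb,
                benefit_over_previous=prev_rb - rb,
                benefit_over_untreated=rb_untreated - rb,
            )
        )
        prev_rb = rb
    return out
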