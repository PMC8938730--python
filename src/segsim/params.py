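"""Parameter registry for the hypertension microsimulation.

Every quantity the simulation consumes lives in a :class:`ParameterSet`:
the two 5-year blood-pressure risk equations, clinical transition
probabilities (behavioral modification, prescription, adherence, control),
cause-specific mortality rates, behavior dynamics (smoking, activity, BMI
drift), an employment multinomial, baseline distributions at age 25,
psychosocial-work-environment (PWE) score distributions by occupational
class, and the race-by-gender occupational allocation table.  Each
parameter carries a provenance string so synthetic fixture values are
never mistaken for published estimates.

The registry also owns the probability algebra used throughout the model:
the DEALE (declining exponential approximation to life expectancy)
conversion between 5-year and annual probabilities, hazard-ratio
application on the rate scale, and the ±25% one-way perturbation used in
sensitivity analysis.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# categorical vocabularies
# ---------------------------------------------------------------------------

RACES = ("black", "white")
GENDERS = ("male", "female")
#: occupational classes ordered from highest to lowest status
CLASSES = ("health_diagnosing", "health_treating", "technician", "aide")
ADHERENCE_LEVELS = ("high", "medium", "low")
SMOKING_STATES = ("never", "current", "former")
BP_STATES = ("normotensive", "prehypertensive", "hypertensive")
EMPLOYMENT_STATES = ("full_time", "part_time", "unemployed")
AGE_BANDS = ("18-29", "30-44", "45+")
#: 5-year attained-age bands used for mortality rates and reporting
REPORT_BANDS = ("25-29", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60-64")

#: the eleven covariates of both risk equations, in canonical order
RISK_COVARIATES = (
    "LogBMI",
    "CurrentSmoker",
    "CurrentlyPrehypertensive",
    "FamilyHistory",
    "WorkFullTime",
    "WorkPartTime",
    "JobDemand",
    "JobControl",
    "Support",
    "Age",
    "Women",
)

RISK_EQUATION_NAMES = ("hypertension_5yr", "prehypertension_5yr")

_SIMPLEX_TOL = 1e-9


class ParameterError(ValueError):
    """A parameter value violates its contract (range, simplex, ordering)."""


class SchemaError(ValueError):
    """A parameter file is missing a required block or is malformed."""


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise ParameterError(f"{name} = {p!r} is not a probability in [0, 1]")


def _check_simplex(name: str, values: Iterable[float], tol: float = _SIMPLEX_TOL) -> None:
    vals = list(values)
    for v in vals:
        _check_prob(name, v)
    if abs(sum(vals) - 1.0) > tol:
        raise ParameterError(f"{name} sums to {sum(vals)!r}, expected 1 ± {tol}")


# ---------------------------------------------------------------------------
# probability algebra
# ---------------------------------------------------------------------------

def deale_5yr_to_annual(p5):
    """Convert a 5-year probability to an annual one at constant hazard.

    Uses the constant-rate exponential form ``r = -ln(1 - p5) / 5`` and
    ``p1 = 1 - exp(-r)``, algebraically identical to the root form
    ``p1 = 1 - (1 - p5)**(1/5)``.  Accepts scalars or arrays.
    """
    arr = np.asarray(p5, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ParameterError("5-year probability must lie in [0, 1)")
    out = 1.0 - np.power(1.0 - arr, 0.2)
    return float(out) if np.isscalar(p5) or arr.ndim == 0 else out


def annual_to_5yr(p1):
    """Compound an annual probability over five cycles (inverse of DEALE)."""
    arr = np.asarray(p1, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ParameterError("annual probability must lie in [0, 1]")
    out = 1.0 - np.power(1.0 - arr, 5.0)
    return float(out) if np.isscalar(p1) or arr.ndim == 0 else out


def rate_to_annual_probability(rate):
    """Convert an annual event rate to an annual probability, ``1 - e^-rate``."""
    arr = np.asarray(rate, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("rate must be non-negative")
    out = 1.0 - np.exp(-arr)
    return float(out) if np.isscalar(rate) or arr.ndim == 0 else out


def apply_hazard_ratio(rate, hr):
    """Annual death probability from a rate scaled by a hazard ratio.

    The hazard ratio acts multiplicatively on the rate scale before the
    exponential rate-to-probability conversion: ``1 - exp(-hr * rate)``.
    """
    rate_arr = np.asarray(rate, dtype=float)
    hr_arr = np.asarray(hr, dtype=float)
    if np.any(rate_arr < 0) or np.any(hr_arr < 0):
        raise ParameterError("rate and hazard ratio must be non-negative")
    out = 1.0 - np.exp(-hr_arr * rate_arr)
    if np.isscalar(rate) and np.isscalar(hr):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RiskEquation:
    """A logistic 5-year onset equation: ``logit(p5) = intercept + x·coef``."""

    name: str
    intercept: float
    coefficients: dict[str, float]

    def validate(self) -> None:
        if self.name not in RISK_EQUATION_NAMES:
            raise ParameterError(f"unknown risk equation name {self.name!r}")
        got = set(self.coefficients)
        want = set(RISK_COVARIATES)
        if got != want:
            raise ParameterError(
                f"risk equation {self.name}: covariates {sorted(got ^ want)} "
                "missing or unexpected"
            )

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "RiskEquation":
        return cls(name=name, intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()})


@dataclass
class TransitionTable:
    """Named clinical transition probabilities (all per year).

    ``crude`` holds state-only transition probabilities (no covariates) used
    by the engine's homogeneous fallback mode and by validation oracles.
    """

    prehyp_to_controlled: float
    control_by_adherence: dict[str, float]
    prescription: dict[str, float]
    adherence_distribution: dict[str, float]
    crude: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        _check_prob("prehyp_to_controlled", self.prehyp_to_controlled)
        for lvl in ADHERENCE_LEVELS:
            _check_prob(f"control_by_adherence[{lvl}]", self.control_by_adherence[lvl])
        for race in RACES:
            _check_prob(f"prescription[{race}]", self.prescription[race])
        _check_simplex("adherence_distribution",
                       [self.adherence_distribution[l] for l in ADHERENCE_LEVELS])
        if self.prescription["black"] < self.prescription["white"]:
            raise ParameterError(
                "prescription probability for black workers must be >= white "
                "(structural constraint of the parameter set)"
            )
        for k, v in self.crude.items():
            _check_prob(f"crude[{k}]", v)

    def to_dict(self) -> dict:
        return {
            "prehyp_to_controlled": self.prehyp_to_controlled,
            "control_by_adherence": dict(self.control_by_adherence),
            "prescription": dict(self.prescription),
            "adherence_distribution": dict(self.adherence_distribution),
            "crude": dict(self.crude),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionTable":
        return cls(
            prehyp_to_controlled=float(d["prehyp_to_controlled"]),
            control_by_adherence={k: float(v) for k, v in d["control_by_adherence"].items()},
            prescription={k: float(v) for k, v in d["prescription"].items()},
            adherence_distribution={k: float(v) for k, v in d["adherence_distribution"].items()},
            crude={k: float(v) for k, v in d.get("crude", {}).items()},
        )


@dataclass
class MortalityModel:
    """Annual cause-specific mortality rates on 5-year attained-age bands.

    Rates are indexed race → gender → 8-vector over :data:`REPORT_BANDS`.
    Pregnancy-related rates apply to women only and are indexed race →
    8-vector.  Hypertensives' CVD rate is scaled by a gender-specific
    hazard ratio (≥ 1).
    """

    cvd_rate: dict[str, dict[str, list[float]]]
    non_cvd_rate: dict[str, dict[str, list[float]]]
    pregnancy_rate: dict[str, list[float]]
    cvd_hazard_ratio_hypertensive: dict[str, float]

    def validate(self) -> None:
        for table, label in ((self.cvd_rate, "cvd_rate"), (self.non_cvd_rate, "non_cvd_rate")):
            for race in RACES:
                for gender in GENDERS:
                    rates = table[race][gender]
                    if len(rates) != len(REPORT_BANDS):
                        raise ParameterError(f"{label}[{race}][{gender}] must have 8 bands")
                    if any(r < 0 for r in rates):
                        raise ParameterError(f"{label}[{race}][{gender}] has a negative rate")
                    if any(b > a for a, b in zip(rates[1:], rates)):
                        raise ParameterError(
                            f"{label}[{race}][{gender}] must be non-decreasing in age")
        for race in RACES:
            rates = self.pregnancy_rate[race]
            if len(rates) != len(REPORT_BANDS) or any(r < 0 for r in rates):
                raise ParameterError(f"pregnancy_rate[{race}] invalid")
        for gender in GENDERS:
            if self.cvd_hazard_ratio_hypertensive[gender] < 1.0:
                raise ParameterError("CVD hazard ratio for hypertensives must be >= 1")

    def to_dict(self) -> dict:
        return {
            "cvd_rate": {r: {g: list(map(float, v)) for g, v in d.items()}
                         for r, d in self.cvd_rate.items()},
            "non_cvd_rate": {r: {g: list(map(float, v)) for g, v in d.items()}
                             for r, d in self.non_cvd_rate.items()},
            "pregnancy_rate": {r: list(map(float, v)) for r, v in self.pregnancy_rate.items()},
            "cvd_hazard_ratio_hypertensive": dict(self.cvd_hazard_ratio_hypertensive),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MortalityModel":
        return cls(
            cvd_rate={r: {g: [float(x) for x in v] for g, v in dd.items()}
                      for r, dd in d["cvd_rate"].items()},
            non_cvd_rate={r: {g: [float(x) for x in v] for g, v in dd.items()}
                          for r, dd in d["non_cvd_rate"].items()},
            pregnancy_rate={r: [float(x) for x in v] for r, v in d["pregnancy_rate"].items()},
            cvd_hazard_ratio_hypertensive={k: float(v) for k, v in
                                           d["cvd_hazard_ratio_hypertensive"].items()},
        )


@dataclass
class BehaviorModel:
    """Annual behavior dynamics: smoking, physical activity, BMI drift."""

    smoking_transitions: dict[str, dict[str, float]]
    activity_transitions: dict[str, float]
    bmi_drift: dict[str, float]

    def validate(self) -> None:
        for band in AGE_BANDS:
            for key in ("never_to_current", "current_to_quit", "quit_to_current"):
                _check_prob(f"smoking_transitions[{band}][{key}]",
                            self.smoking_transitions[band][key])
        for key in ("inactive_to_active", "active_to_inactive"):
            _check_prob(f"activity_transitions[{key}]", self.activity_transitions[key])
        if self.bmi_drift["noise_sd"] < 0:
            raise ParameterError("bmi_drift noise_sd must be >= 0")
        for key in ("active", "inactive", "noise_sd"):
            if key not in self.bmi_drift:
                raise ParameterError(f"bmi_drift missing {key!r}")

    def to_dict(self) -> dict:
        return {
            "smoking_transitions": {b: dict(v) for b, v in self.smoking_transitions.items()},
            "activity_transitions": dict(self.activity_transitions),
            "bmi_drift": dict(self.bmi_drift),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BehaviorModel":
        return cls(
            smoking_transitions={b: {k: float(x) for k, x in v.items()}
                                 for b, v in d["smoking_transitions"].items()},
            activity_transitions={k: float(v) for k, v in d["activity_transitions"].items()},
            bmi_drift={k: float(v) for k, v in d["bmi_drift"].items()},
        )


#: covariate order of the employment multinomial linear predictors
EMPLOYMENT_COVARIATES = ("intercept", "age", "female", "black", "ever_unemployed",
                         "class_health_treating", "class_technician", "class_aide")


@dataclass
class EmploymentModel:
    """Three-outcome multinomial logit for annual employment status.

    Linear predictors for ``full_time`` and ``part_time`` are measured
    against the ``unemployed`` baseline (score 0).  Age enters centered at
    25.  ``frozen=True`` turns the step into the identity (toy fixtures).
    """

    coefficients: dict[str, dict[str, float]]
    frozen: bool = False

    def validate(self) -> None:
        for outcome in ("full_time", "part_time"):
            coefs = self.coefficients[outcome]
            missing = set(EMPLOYMENT_COVARIATES) - set(coefs)
            if missing:
                raise ParameterError(f"employment[{outcome}] missing {sorted(missing)}")
        un = self.implied_unemployment_by_class()
        probs = [un[c] for c in CLASSES]
        if any(b < a - 1e-12 for a, b in zip(probs, probs[1:])):
            raise ParameterError(
                "implied class unemployment must be non-decreasing from "
                "health_diagnosing to aide"
            )

    def linear_predictors(self, age, female, black, ever_unemployed, occ_class_index):
        """Vectorized (score_ft, score_pt) against the unemployed baseline."""
        age = np.asarray(age, dtype=float) - 25.0
        female = np.asarray(female, dtype=float)
        black = np.asarray(black, dtype=float)
        ever = np.asarray(ever_unemployed, dtype=float)
        cls_idx = np.asarray(occ_class_index)
        scores = []
        for outcome in ("full_time", "part_time"):
            c = self.coefficients[outcome]
            cls_eff = np.array([0.0, c["class_health_treating"],
                                c["class_technician"], c["class_aide"]])
            scores.append(c["intercept"] + c["age"] * age + c["female"] * female
                          + c["black"] * black + c["ever_unemployed"] * ever
                          + cls_eff[cls_idx])
        return scores[0], scores[1]

    def probabilities(self, age, female, black, ever_unemployed, occ_class_index):
        """Per-worker (p_ft, p_pt, p_un) via softmax over the three outcomes."""
        s_ft, s_pt = self.linear_predictors(age, female, black, ever_unemployed,
                                            occ_class_index)
        s_ft = np.atleast_1d(np.asarray(s_ft, dtype=float))
        s_pt = np.atleast_1d(np.asarray(s_pt, dtype=float))
        scores = np.stack([s_ft, s_pt, np.zeros_like(s_ft)], axis=-1)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=-1, keepdims=True)

    def implied_unemployment_by_class(self, age: float = 25.0, female: bool = False,
                                      black: bool = False,
                                      ever_unemployed: bool = False) -> dict[str, float]:
        """Class-level unemployment probability at reference covariates."""
        probs = self.probabilities(np.full(4, age), np.full(4, female),
                                   np.full(4, black), np.full(4, ever_unemployed),
                                   np.arange(4))
        return {c: float(probs[i, 2]) for i, c in enumerate(CLASSES)}

    def to_dict(self) -> dict:
        return {"coefficients": {o: dict(c) for o, c in self.coefficients.items()},
                "frozen": bool(self.frozen)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EmploymentModel":
        return cls(coefficients={o: {k: float(v) for k, v in c.items()}
                                 for o, c in d["coefficients"].items()},
                   frozen=bool(d.get("frozen", False)))


@dataclass
class BaselineDistributions:
    """Age-25 baseline sampling distributions by race (and gender)."""

    female_share: dict[str, float]
    family_history: dict[str, float]
    smoking: dict[str, dict[str, dict[str, float]]]
    log_bmi: dict[str, dict[str, dict[str, float]]]
    active: dict[str, dict[str, float]]
    bp_state: dict[str, dict[str, dict[str, float]]]
    employment: dict[str, dict[str, dict[str, dict[str, float]]]]

    def validate(self) -> None:
        for race in RACES:
            _check_prob(f"female_share[{race}]", self.female_share[race])
            _check_prob(f"family_history[{race}]", self.family_history[race])
            for gender in GENDERS:
                _check_simplex(f"smoking[{race}][{gender}]",
                               [self.smoking[race][gender][s] for s in SMOKING_STATES])
                _check_simplex(f"bp_state[{race}][{gender}]",
                               [self.bp_state[race][gender][s] for s in BP_STATES])
                _check_prob(f"active[{race}][{gender}]", self.active[race][gender])
                if self.log_bmi[race][gender]["sigma"] < 0:
                    raise ParameterError(f"log_bmi[{race}][{gender}] sigma must be >= 0")
                for cls in CLASSES:
                    _check_simplex(
                        f"employment[{race}][{gender}][{cls}]",
                        [self.employment[race][gender][cls][e] for e in EMPLOYMENT_STATES])

    def to_dict(self) -> dict:
        return {
            "female_share": dict(self.female_share),
            "family_history": dict(self.family_history),
            "smoking": copy.deepcopy(self.smoking),
            "log_bmi": copy.deepcopy(self.log_bmi),
            "active": copy.deepcopy(self.active),
            "bp_state": copy.deepcopy(self.bp_state),
            "employment": copy.deepcopy(self.employment),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaselineDistributions":
        return cls(**{k: copy.deepcopy(d[k]) for k in
                      ("female_share", "family_history", "smoking", "log_bmi",
                       "active", "bp_state", "employment")})


@dataclass
class AllocationTable:
    """Race × gender → probability 4-vector over occupational classes.

    The quantitative embodiment of occupational segregation: the status-quo
    table holds the predicted probabilities for 25-year-old workers, and the
    counterfactual scenarios are rewrites of its rows.
    """

    rows: dict[tuple[str, str], np.ndarray]

    def __post_init__(self):
        self.rows = {k: np.asarray(v, dtype=float) for k, v in self.rows.items()}

    def row(self, race: str, gender: str) -> np.ndarray:
        try:
            return self.rows[(race, gender)]
        except KeyError:
            raise KeyError(f"allocation table has no row for ({race}, {gender})") from None

    def validate(self, tol: float = 0.005) -> None:
        for (race, gender), row in self.rows.items():
            if race not in RACES or gender not in GENDERS:
                raise ParameterError(f"unknown allocation row key ({race}, {gender})")
            if row.shape != (4,):
                raise ParameterError(f"allocation row ({race}, {gender}) must have 4 entries")
            if np.any(row < 0) or np.any(row > 1):
                raise ParameterError(f"allocation row ({race}, {gender}) out of [0, 1]")
            if abs(row.sum() - 1.0) > tol:
                raise ParameterError(
                    f"allocation row ({race}, {gender}) sums to {row.sum():.6f}, "
                    f"expected 1 ± {tol}")

    def copy(self) -> "AllocationTable":
        return AllocationTable(rows={k: v.copy() for k, v in self.rows.items()})

    def __eq__(self, other) -> bool:
        if not isinstance(other, AllocationTable):
            return NotImplemented
        return (set(self.rows) == set(other.rows)
                and all(np.array_equal(self.rows[k], other.rows[k]) for k in self.rows))

    def to_dict(self) -> dict:
        return {race: {gender: [float(x) for x in self.rows[(race, gender)]]
                       for r2, gender in self.rows if r2 == race}
                for race, _ in self.rows}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AllocationTable":
        rows = {}
        for race, genders in d.items():
            for gender, vec in genders.items():
                rows[(race, gender)] = np.asarray(vec, dtype=float)
        return cls(rows=rows)


@dataclass
class PWEDistribution:
    """Per-class normal location/scale for demand, control and support."""

    by_class: dict[str, dict[str, dict[str, float]]]

    def validate(self) -> None:
        for cls in CLASSES:
            for dim in ("demand", "control", "support"):
                spec = self.by_class[cls][dim]
                if spec["sd"] < 0:
                    raise ParameterError(f"pwe[{cls}][{dim}] sd must be >= 0")
        # structural gradients: control and support decrease, demand
        # (iso-strain driver) does not decrease, from diagnosing to aides
        for dim, direction in (("control", -1), ("support", -1), ("demand", +1)):
            means = [self.by_class[c][dim]["mean"] for c in CLASSES]
            diffs = np.diff(means) * direction
            if np.any(diffs < -1e-9):
                raise ParameterError(f"pwe {dim} means violate the class gradient")

    def to_dict(self) -> dict:
        return copy.deepcopy(self.by_class)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PWEDistribution":
        return cls(by_class=copy.deepcopy(dict(d)))


@dataclass
class ParameterSet:
    """The complete provenance-tagged parameter bundle driving a simulation."""

    risk_equations: dict[str, RiskEquation]
    transitions: TransitionTable
    mortality: MortalityModel
    behavior: BehaviorModel
    employment: EmploymentModel
    baselines: BaselineDistributions
    pwe: PWEDistribution
    allocation: AllocationTable
    composition: dict
    provenance: dict[str, str] = field(default_factory=dict)

    REQUIRED_BLOCKS = ("risk_equations", "transitions", "allocation")
    OPTIONAL_BLOCKS = ("mortality", "behavior", "employment", "baselines",
                       "pwe", "composition")

    def validate(self) -> None:
        for name in RISK_EQUATION_NAMES:
            if name not in self.risk_equations:
                raise SchemaError(f"risk_equations missing {name!r}")
            self.risk_equations[name].validate()
        self.transitions.validate()
        self.mortality.validate()
        self.behavior.validate()
        self.employment.validate()
        self.baselines.validate()
        self.pwe.validate()
        self.allocation.validate()
        comp = self.composition
        _check_prob("composition.male_share", comp["male_share"])
        for g in GENDERS:
            _check_prob(f"composition.white_share[{g}]", comp["white_share"][g])
        missing = [k for k in ("risk_equations", "transitions", "mortality", "behavior",
                               "employment", "baselines", "pwe", "allocation",
                               "composition")
                   if k not in self.provenance]
        if missing:
            raise SchemaError(f"provenance entries missing for blocks: {missing}")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def to_dict(self) -> dict:
        return _to_builtin({
            "risk_equations": {n: eq.to_dict() for n, eq in self.risk_equations.items()},
            "transitions": self.transitions.to_dict(),
            "mortality": self.mortality.to_dict(),
            "behavior": self.behavior.to_dict(),
            "employment": self.employment.to_dict(),
            "baselines": self.baselines.to_dict(),
            "pwe": self.pwe.to_dict(),
            "allocation": self.allocation.to_dict(),
            "composition": copy.deepcopy(self.composition),
            "provenance": dict(self.provenance),
        })

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(
            risk_equations={n: RiskEquation.from_dict(n, v)
                            for n, v in d["risk_equations"].items()},
            transitions=TransitionTable.from_dict(d["transitions"]),
            mortality=MortalityModel.from_dict(d["mortality"]),
            behavior=BehaviorModel.from_dict(d["behavior"]),
            employment=EmploymentModel.from_dict(d["employment"]),
            baselines=BaselineDistributions.from_dict(d["baselines"]),
            pwe=PWEDistribution.from_dict(d["pwe"]),
            allocation=AllocationTable.from_dict(d["allocation"]),
            composition=copy.deepcopy(d["composition"]),
            provenance=dict(d.get("provenance", {})),
        )

    def digest(self) -> str:
        """Stable sha256 digest of the canonical JSON form (for manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# file I/O and perturbation
# ---------------------------------------------------------------------------

def _to_builtin(obj):
    """Recursively coerce numpy scalars/arrays to plain Python types."""
    if isinstance(obj, Mapping):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_builtin(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_parameters(params: ParameterSet, path) -> None:
    """Write a ParameterSet to a YAML file (round-trips with load_parameters)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_builtin(params.to_dict()), fh, sort_keys=True)


def load_parameters(path) -> ParameterSet:
    """Load, complete and validate a parameter file.

    Required blocks (risk_equations, transitions, allocation) must be
    present; optional blocks missing from the file are substituted from the
    default fixture with a logged warning.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"parameter file {path} did not parse to a mapping")
    for block in ParameterSet.REQUIRED_BLOCKS:
        if block not in raw:
            raise SchemaError(f"parameter file missing required block {block!r}")
    missing = [b for b in ParameterSet.OPTIONAL_BLOCKS if b not in raw]
    if missing:
        from .fixtures import default_parameter_fixture  # lazy: avoids cycle

        defaults = default_parameter_fixture().to_dict()
        raw = dict(raw)
        prov = dict(raw.get("provenance", {}))
        for block in missing:
            logger.warning("parameter file missing optional block %r; "
                           "using default fixture values", block)
            raw[block] = defaults[block]
            prov.setdefault(block, "fixture (substituted default)")
        for block in ("risk_equations", "transitions", "allocation"):
            prov.setdefault(block, "parameter file")
        raw["provenance"] = prov
    params = ParameterSet.from_dict(raw)
    params.validate()
    return params


#: sensitivity-analysis blocks eligible for one-way perturbation
SENSITIVITY_BLOCKS = ("prescription", "control_by_adherence")


def perturb_parameters(params: ParameterSet, block: str, factor: float) -> ParameterSet:
    """Return a deep copy with one sensitivity block scaled by ``1 + factor``.

    Every probability in the chosen block is multiplied by ``1 + factor``
    and clamped to [0, 1]; all other parameters are untouched.  The input
    is never mutated.
    """
    if block not in SENSITIVITY_BLOCKS:
        raise ParameterError(
            f"unknown sensitivity block {block!r}; expected one of {SENSITIVITY_BLOCKS}")
    if factor < -1.0:
        raise ParameterError("perturbation factor must be >= -1")
    out = params.copy()
    table = getattr(out.transitions, block)
    for key in table:
        table[key] = min(1.0, max(0.0, table[key] * (1.0 + factor)))
    return out
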