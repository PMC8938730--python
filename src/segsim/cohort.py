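"""Cohort initialization: baseline sampling and occupational allocation.

A cohort is a struct-of-arrays container holding one simulated single-race
cohort of 25-year-old healthcare workers.  All baseline attributes are
drawn by inverse-CDF categorical sampling from the configured baseline
distributions, which keeps random-number streams synchronized across
counterfactual scenarios (common random numbers): two runs that share a
seed consume identical uniforms draw-for-draw, so scenarios that leave a
row of the allocation table unchanged produce bit-identical output for the
workers governed by that row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    BP_STATES,
    CLASSES,
    EMPLOYMENT_STATES,
    GENDERS,
    RACES,
    SMOKING_STATES,
    AllocationTable,
    ParameterSet,
)

# integer encodings used by the engine
STATE_NORMO, STATE_PREHYP, STATE_HYPER, STATE_CONTROLLED, STATE_DEAD = range(5)
HEALTH_STATES = ("normotensive", "prehypertensive", "hypertensive", "controlled", "dead")
SMOKE_NEVER, SMOKE_CURRENT, SMOKE_FORMER = range(3)
EMP_FT, EMP_PT, EMP_UN = range(3)
ADH_NONE, ADH_HIGH, ADH_MEDIUM, ADH_LOW = -1, 0, 1, 2

#: minimum admissible BMI (kg/m²); guards the log transform
BMI_FLOOR = 12.0


def categorical_from_uniform(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Inverse-CDF categorical draw.

    ``u`` is an array of uniforms; ``probs`` is either a 1-D probability
    vector shared by all draws or a per-draw matrix of shape ``(n, k)``.
    Returns integer category indices.  Using explicit uniforms (instead of
    ``Generator.choice``) is what makes common-random-number pairing exact.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 1:
        edges = np.cumsum(probs)
        edges[-1] = max(edges[-1], 1.0)
        return np.searchsorted(edges, u, side="right").astype(np.int8)
    edges = np.cumsum(probs, axis=1)
    edges[:, -1] = np.maximum(edges[:, -1], 1.0)
    return (u[:, None] >= edges).sum(axis=1).astype(np.int8)


@dataclass
class PWEProfile:
    """Standardized psychosocial work environment scores for one worker.

    Assigned once at age 25 from the class-specific distribution and never
    redrawn; when the worker is unemployed the *effective* covariates
    entering the risk equations are zero for that cycle, but the stored
    profile is unchanged.
    """

    demand: float
    control: float
    support: float


@dataclass
class Worker:
    """One simulated individual's attributes at a cycle (scalar view)."""

    id: int
    race: str
    gender: str
    age: int
    family_history: bool
    bmi: float
    smoking: str
    physically_active: bool
    occupational_class: str
    employment: str
    ever_unemployed: bool
    pwe: PWEProfile
    health_state: str
    on_medication: bool = False
    adherence: str = "none"

    def validate(self) -> None:
        if (self.adherence != "none") != self.on_medication:
            raise ValueError("adherence level set iff on medication")
        if self.on_medication and self.health_state not in ("hypertensive", "controlled"):
            raise ValueError("medication implies hypertensive or controlled state")
        if self.bmi <= 0:
            raise ValueError("BMI must be positive")


_ADH_NAMES = {ADH_NONE: "none", ADH_HIGH: "high", ADH_MEDIUM: "medium", ADH_LOW: "low"}
_ADH_CODES = {v: k for k, v in _ADH_NAMES.items()}


@dataclass
class Cohort:
    """Struct-of-arrays container for one single-race cohort."""

    race: str
    female: np.ndarray
    age: np.ndarray
    family_history: np.ndarray
    bmi: np.ndarray
    smoking: np.ndarray
    active: np.ndarray
    occ_class: np.ndarray
    employment: np.ndarray
    ever_unemployed: np.ndarray
    demand: np.ndarray
    control: np.ndarray
    support: np.ndarray
    state: np.ndarray
    on_medication: np.ndarray
    adherence: np.ndarray

    @property
    def n(self) -> int:
        return self.state.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return self.state != STATE_DEAD

    def worker(self, i: int) -> Worker:
        """Scalar Worker view of individual ``i`` (copy, not a live view)."""
        return Worker(
            id=i,
            race=self.race,
            gender="female" if self.female[i] else "male",
            age=int(self.age[i]),
            family_history=bool(self.family_history[i]),
            bmi=float(self.bmi[i]),
            smoking=SMOKING_STATES[self.smoking[i]],
            physically_active=bool(self.active[i]),
            occupational_class=CLASSES[self.occ_class[i]],
            employment=EMPLOYMENT_STATES[self.employment[i]],
            ever_unemployed=bool(self.ever_unemployed[i]),
            pwe=PWEProfile(float(self.demand[i]), float(self.control[i]),
                           float(self.support[i])),
            health_state=HEALTH_STATES[self.state[i]],
            on_medication=bool(self.on_medication[i]),
            adherence=_ADH_NAMES[int(self.adherence[i])],
        )

    @classmethod
    def from_workers(cls, workers: list[Worker]) -> "Cohort":
        """Build a cohort from scalar Worker records (single race)."""
        races = {w.race for w in workers}
        if len(races) != 1:
            raise ValueError("a Cohort holds workers of a single race")
        for w in workers:
            w.validate()
        return cls(
            race=workers[0].race,
            female=np.array([w.gender == "female" for w in workers]),
            age=np.array([w.age for w in workers], dtype=np.int64),
            family_history=np.array([w.family_history for w in workers]),
            bmi=np.array([w.bmi for w in workers], dtype=float),
            smoking=np.array([SMOKING_STATES.index(w.smoking) for w in workers],
                             dtype=np.int8),
            active=np.array([w.physically_active for w in workers]),
            occ_class=np.array([CLASSES.index(w.occupational_class) for w in workers],
                               dtype=np.int8),
            employment=np.array([EMPLOYMENT_STATES.index(w.employment) for w in workers],
                                dtype=np.int8),
            ever_unemployed=np.array([w.ever_unemployed for w in workers]),
            demand=np.array([w.pwe.demand for w in workers], dtype=float),
            control=np.array([w.pwe.control for w in workers], dtype=float),
            support=np.array([w.pwe.support for w in workers], dtype=float),
            state=np.array([HEALTH_STATES.index(w.health_state) for w in workers],
                           dtype=np.int8),
            on_medication=np.array([w.on_medication for w in workers]),
            adherence=np.array([_ADH_CODES[w.adherence] for w in workers], dtype=np.int8),
        )

    def copy(self) -> "Cohort":
        import copy as _copy
        return _copy.deepcopy(self)


def allocate_occupation(race: str, gender: str, table: AllocationTable,
                        rng: np.random.Generator, size: int | None = None):
    """Draw occupational class(es) from the allocation row for (race, gender)."""
    row = table.row(race, gender)
    total = row.sum()
    if abs(total - 1.0) > 0.005:
        raise ValueError(f"allocation row ({race}, {gender}) sums to {total:.4f}")
    u = rng.random(size if size is not None else 1)
    draws = categorical_from_uniform(u, row / total)
    if size is None:
        return CLASSES[int(draws[0])]
    return draws


def assign_pwe(occ_class: str | np.ndarray, params: ParameterSet,
               rng: np.random.Generator):
    """Draw PWE profile(s) from the class-specific normal distributions.

    Scalar class name → a single :class:`PWEProfile`; an integer array of
    class indices → three aligned arrays (demand, control, support).
    """
    by_class = params.pwe.by_class
    if isinstance(occ_class, str):
        spec = by_class[occ_class]
        vals = [rng.normal(spec[d]["mean"], spec[d]["sd"])
                for d in ("demand", "control", "support")]
        return PWEProfile(*map(float, vals))
    idx = np.asarray(occ_class)
    out = []
    for dim in ("demand", "control", "support"):
        means = np.array([by_class[c][dim]["mean"] for c in CLASSES])[idx]
        sds = np.array([by_class[c][dim]["sd"] for c in CLASSES])[idx]
        out.append(rng.normal(0.0, 1.0, size=idx.shape[0]) * sds + means)
    return tuple(out)


def init_cohort(n: int, race: str, params: ParameterSet,
                allocation: AllocationTable | None = None,
                rng: np.random.Generator | int | None = None) -> Cohort:
    """Create a baseline cohort of ``n`` alive 25-year-old workers.

    Gender, family history, smoking, BMI, activity, blood-pressure state
    and employment come from the baseline distributions; occupational class
    from the (scenario-specific) allocation row; PWE from the class
    distributions.  Fully reproducible from the RNG state.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if race not in RACES:
        raise ValueError(f"unknown race {race!r}")
    if allocation is None:
        allocation = params.allocation
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    b = params.baselines

    female = rng.random(n) < b.female_share[race]
    family_history = rng.random(n) < b.family_history[race]

    def _by_gender_categorical(table, categories):
        probs = np.empty((n, len(categories)))
        for gi, gender in enumerate(GENDERS):
            mask = female if gender == "female" else ~female
            probs[mask] = [table[race][gender][c] for c in categories]
        return categorical_from_uniform(rng.random(n), probs)

    smoking = _by_gender_categorical(b.smoking, SMOKING_STATES)

    mu = np.where(female, b.log_bmi[race]["female"]["mu"], b.log_bmi[race]["male"]["mu"])
    sigma = np.where(female, b.log_bmi[race]["female"]["sigma"],
                     b.log_bmi[race]["male"]["sigma"])
    bmi = np.maximum(np.exp(rng.normal(0.0, 1.0, n) * sigma + mu), BMI_FLOOR)

    p_active = np.where(female, b.active[race]["female"], b.active[race]["male"])
    active = rng.random(n) < p_active

    state = _by_gender_categorical(b.bp_state, BP_STATES).astype(np.int8)

    # occupational class: one uniform per worker against the gender row
    class_probs = np.empty((n, 4))
    for gender in GENDERS:
        mask = female if gender == "female" else ~female
        class_probs[mask] = allocation.row(race, gender)
    row_sums = class_probs.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 0.005):
        raise ValueError("allocation row does not sum to ~1")
    occ_class = categorical_from_uniform(rng.random(n), class_probs / row_sums[:, None])

    demand, control, support = assign_pwe(occ_class, params, rng)

    emp_probs = np.empty((n, 3))
    for gi, gender in enumerate(GENDERS):
        mask = female if gender == "female" else ~female
        for ci, cls in enumerate(CLASSES):
            m = mask & (occ_class == ci)
            emp_probs[m] = [b.employment[race][gender][cls][e] for e in EMPLOYMENT_STATES]
    employment = categorical_from_uniform(rng.random(n), emp_probs)

    return Cohort(
        race=race,
        female=female,
        age=np.full(n, 25, dtype=np.int64),
        family_history=family_history,
        bmi=bmi,
        smoking=smoking,
        active=active,
        occ_class=occ_class,
        employment=employment,
        ever_unemployed=employment == EMP_UN,
        demand=demand,
        control=control,
        support=support,
        state=state,
        on_medication=np.zeros(n, dtype=bool),
        adherence=np.full(n, ADH_NONE, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# allocation table CSV I/O
# ---------------------------------------------------------------------------

def allocation_to_frame(tables: dict[str, AllocationTable]) -> pd.DataFrame:
    """Long-format frame (scenario, race, gender, class, probability)."""
    records = []
    for scenario, table in tables.items():
        for (race, gender), row in table.rows.items():
            for cls, p in zip(CLASSES, row):
                records.append({"scenario": scenario, "race": race, "gender": gender,
                                "class": cls, "probability": float(p)})
    return pd.DataFrame.from_records(records)


def frame_to_allocation(frame: pd.DataFrame) -> dict[str, AllocationTable]:
    """Inverse of :func:`allocation_to_frame`."""
    tables: dict[str, AllocationTable] = {}
    for scenario, group in frame.groupby("scenario", sort=False):
        rows = {}
        for (race, gender), sub in group.groupby(["race", "gender"], sort=False):
            vec = sub.set_index("class")["probability"].reindex(list(CLASSES))
            rows[(race, gender)] = vec.to_numpy(dtype=float)
        tables[str(scenario)] = AllocationTable(rows=rows)
    return tables


def write_allocation_csv(tables: dict[str, AllocationTable], path) -> None:
    allocation_to_frame(tables).to_csv(path, index=False)


def read_allocation_csv(path) -> dict[str, AllocationTable]:
    return frame_to_allocation(pd.read_csv(path))
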