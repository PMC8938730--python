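"""Counterfactual scenario construction and multi-cohort experiments.

The status-quo allocation table encodes occupational segregation: each
race × gender group has its own probability row over the four occupational
classes.  Four desegregation counterfactuals rewrite those rows:

* **A** — race-blind within gender: each gender's row is the composition-
  weighted average of its two race rows (gender inequity remains).
* **B** — race-and-gender-blind: every row is the overall composition-
  weighted average of all four rows.
* **C** — Black workers receive the white rows of their own gender; white
  rows are untouched.
* **D** — every group receives the status-quo white-male row.

Because the original multinomial allocation regressions are not published,
scenarios A and B are reconstructed by mixture-weight marginalization of
the status-quo rows using workforce composition weights; the published
scenario rows are shipped alongside as a reference
(:data:`segsim.fixtures.PRINTED_SCENARIO_ROWS`), and the two constructions
agree within 0.005 per entry.

Experiments run ``n_cohorts`` independent cohorts per scenario × race and
average per-cycle prevalence unweighted across cohorts.  Cohort random
streams are keyed by (race, cohort index) only — not by scenario — so
scenario contrasts are paired by common random numbers: a scenario that
leaves a group's allocation row unchanged reproduces that group's output
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import N_CYCLES, run_cohort
from .params import (
    GENDERS,
    RACES,
    SENSITIVITY_BLOCKS,
    AllocationTable,
    ParameterSet,
    perturb_parameters,
)

SCENARIOS = ("status_quo", "A", "B", "C", "D")

SCENARIO_DESCRIPTIONS = {
    "status_quo": "occupationally segregated workforce (observed allocation)",
    "A": "race-blind allocation within gender (gender inequity remains)",
    "B": "race-and-gender-blind allocation",
    "C": "Black workers allocated like white workers of the same gender",
    "D": "all workers allocated like white men in the status quo",
}


@dataclass
class ScenarioSpec:
    """A named counterfactual with its constructed allocation table."""

    name: str
    allocation: AllocationTable
    description: str = ""

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not self.description:
            self.description = SCENARIO_DESCRIPTIONS[self.name]
        self.allocation.validate(tol=0.005)


def build_scenario_allocation(name: str, status_quo: AllocationTable,
                              weights: dict | None = None) -> AllocationTable:
    """Construct a scenario's allocation table from the status-quo table.

    ``weights`` supplies the workforce composition needed by the mixture
    scenarios: ``{"male_share": m, "white_share": {"male": p, "female": q}}``.
    Scenario C/D and status_quo need no weights.
    """
    if name == "status_quo":
        return status_quo.copy()
    rows = {}
    if name in ("A", "B"):
        if weights is None:
            raise ValueError(f"scenario {name} requires composition weights")
        white_share = weights["white_share"]
        gender_rows = {}
        for gender in GENDERS:
            w = white_share[gender]
            gender_rows[gender] = (w * status_quo.row("white", gender)
                                   + (1.0 - w) * status_quo.row("black", gender))
        if name == "A":
            for race in RACES:
                for gender in GENDERS:
                    rows[(race, gender)] = gender_rows[gender].copy()
        else:
            m = weights["male_share"]
            overall = m * gender_rows["male"] + (1.0 - m) * gender_rows["female"]
            rows = {(race, gender): overall.copy()
                    for race in RACES for gender in GENDERS}
    elif name == "C":
        for gender in GENDERS:
            white_row = status_quo.row("white", gender)
            rows[("white", gender)] = white_row.copy()
            rows[("black", gender)] = white_row.copy()
    elif name == "D":
        white_male = status_quo.row("white", "male")
        rows = {(race, gender): white_male.copy()
                for race in RACES for gender in GENDERS}
    else:
        raise ValueError(f"unknown scenario {name!r}")
    table = AllocationTable(rows=rows)
    table.validate(tol=0.005)
    return table


def make_scenario_specs(params: ParameterSet,
                        names: tuple[str, ...] = SCENARIOS) -> list[ScenarioSpec]:
    """Build ScenarioSpecs for the requested scenario names."""
    return [ScenarioSpec(name, build_scenario_allocation(
        name, params.allocation, weights=params.composition)) for name in names]


@dataclass
class ExperimentConfig:
    """Cohort counts, sizes, seed and scenario list for an experiment."""

    n_cohorts: int = 500
    cohort_size: int = 100_000
    seed: int = 0
    scenarios: tuple[str, ...] = SCENARIOS
    races: tuple[str, ...] = RACES
    n_cycles: int = N_CYCLES
    mode: str = "risk"

    def __post_init__(self):
        if self.n_cohorts < 1 or self.cohort_size < 1:
            raise ValueError("n_cohorts and cohort_size must be >= 1")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")


_RACE_CODE = {race: i for i, race in enumerate(RACES)}


def _cohort_seed(master_seed: int, race: str, cohort_index: int) -> np.random.SeedSequence:
    """Scenario-independent substream key: common random numbers across scenarios."""
    return np.random.SeedSequence([int(master_seed), _RACE_CODE[race], int(cohort_index)])


@dataclass
class ExperimentResult:
    """Per-cohort prevalence series for each scenario × race.

    ``prevalence[(scenario, race)]`` is an ``(n_cohorts, n_cycles)`` array
    of per-cycle hypertension prevalence (hypertensive / alive).  Means
    across cohorts are unweighted.
    """

    prevalence: dict[tuple[str, str], np.ndarray]
    config: ExperimentConfig
    parameter_digest: str
    alive: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def mean_prevalence(self, scenario: str, race: str) -> np.ndarray:
        return self.prevalence[(scenario, race)].mean(axis=0)

    def career_average(self, scenario: str, race: str) -> float:
        """Unweighted mean over cohorts and all cycles (ages 25–64)."""
        return float(self.prevalence[(scenario, race)].mean())

    def cohort_career_averages(self, scenario: str, race: str) -> np.ndarray:
        return self.prevalence[(scenario, race)].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long frame: scenario, race, cycle, age, mean_prevalence."""
        records = []
        for (scenario, race), arr in self.prevalence.items():
            mean = arr.mean(axis=0)
            for cycle, p in enumerate(mean):
                records.append({"scenario": scenario, "race": race, "cycle": cycle,
                                "age": 25 + cycle, "mean_prevalence": float(p)})
        return pd.DataFrame.from_records(records)


def run_experiment(cfg: ExperimentConfig, params: ParameterSet) -> ExperimentResult:
    """Run every scenario × race × cohort combination and collect prevalence.

    Identical (race, cohort) seeds are reused across scenarios, so scenario
    contrasts are common-random-number paired.
    """
    params.validate()
    specs = make_scenario_specs(params, tuple(cfg.scenarios))
    prevalence: dict[tuple[str, str], np.ndarray] = {}
    alive: dict[tuple[str, str], np.ndarray] = {}
    for spec in specs:
        for race in cfg.races:
            prev = np.empty((cfg.n_cohorts, cfg.n_cycles))
            alv = np.empty((cfg.n_cohorts, cfg.n_cycles))
            for j in range(cfg.n_cohorts):
                counts = run_cohort(cfg.cohort_size, race, spec.allocation, params,
                                    seed=_cohort_seed(cfg.seed, race, j),
                                    n_cycles=cfg.n_cycles, mode=cfg.mode)
                alive_counts = counts.frame["alive"].to_numpy(dtype=float)
                if np.any(alive_counts == 0):
                    raise ZeroDivisionError("no workers alive in a cycle")
                prev[j] = counts.frame["hypertensive"].to_numpy() / alive_counts
                alv[j] = alive_counts
            prevalence[(spec.name, race)] = prev
            alive[(spec.name, race)] = alv
    return ExperimentResult(prevalence=prevalence, config=cfg,
                            parameter_digest=params.digest(), alive=alive)


@dataclass
class SensitivityResult:
    """One-way ±25% sensitivity intervals around base career prevalence.

    ``arms[(block, factor)]`` holds the full ExperimentResult of each
    perturbed run; ``interval(scenario, race, block)`` returns
    ``(base, low, high)`` where low/high are the min/max career-average
    prevalence across the base and the two perturbed runs.
    """

    base: ExperimentResult
    arms: dict[tuple[str, float], ExperimentResult]

    def interval(self, scenario: str, race: str, block: str) -> tuple[float, float, float]:
        base = self.base.career_average(scenario, race)
        values = [base] + [res.career_average(scenario, race)
                           for (b, _), res in self.arms.items() if b == block]
        return base, min(values), max(values)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (scenario, race) in self.base.prevalence:
            for block in dict.fromkeys(b for b, _ in self.arms):
                base, low, high = self.interval(scenario, race, block)
                records.append({"scenario": scenario, "race": race, "block": block,
                                "base": base, "low": low, "high": high})
        return pd.DataFrame.from_records(records)


def run_sensitivity(cfg: ExperimentConfig, params: ParameterSet,
                    factor: float = 0.25,
                    blocks: tuple[str, ...] = SENSITIVITY_BLOCKS) -> SensitivityResult:
    """Rerun the full experiment with each block at ±``factor`` (separate runs)."""
    base = run_experiment(cfg, params)
    arms = {}
    for block in blocks:
        for f in (-factor, +factor):
            if f == 0.0:
                continue
            arms[(block, f)] = run_experiment(cfg, perturb_parameters(params, block, f))
    return SensitivityResult(base=base, arms=arms)
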