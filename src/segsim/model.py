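"""Model/Results facade over the microsimulation experiment.

`HypertensionMicrosim` bundles a parameter set with an experiment
configuration the way a statistical model bundles data with a design;
``fit()`` executes the multi-cohort simulation and returns a
:class:`MicrosimResults` carrying prevalence trajectories, racial gaps,
sensitivity intervals, a ``summary()`` table and plotting helpers.  All
parameters are exogenous inputs — nothing is estimated from data — so
``fit`` here means "run the stochastic model to convergence over cohorts",
and the dispersion across cohorts plays the role of Monte-Carlo
uncertainty (classical standard errors are not meaningful for simulated
individuals).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fixtures import default_parameter_fixture
from .outcomes import age_group_means, racial_gap, summary_table, write_report
from .params import ParameterSet, load_parameters
from .scenarios import (
    SCENARIOS,
    ExperimentConfig,
    ExperimentResult,
    SensitivityResult,
    run_experiment,
    run_sensitivity,
)


class HypertensionMicrosim:
    """State-transition microsimulation of hypertension in a segregated workforce."""

    def __init__(self, params: ParameterSet | None = None, n_cohorts: int = 500,
                 cohort_size: int = 100_000, scenarios: tuple[str, ...] = SCENARIOS,
                 seed: int = 0):
        self.params = params if params is not None else default_parameter_fixture()
        self.config = ExperimentConfig(n_cohorts=n_cohorts, cohort_size=cohort_size,
                                       seed=seed, scenarios=tuple(scenarios))

    @classmethod
    def from_config(cls, params_path, **kwargs) -> "HypertensionMicrosim":
        """Build from a YAML parameter file."""
        return cls(params=load_parameters(params_path), **kwargs)

    def fit(self, seed: int | None = None, sensitivity: bool = False,
            sensitivity_factor: float = 0.25) -> "MicrosimResults":
        """Run the experiment (and optionally the ±25% sensitivity arms)."""
        cfg = self.config
        if seed is not None:
            cfg = ExperimentConfig(n_cohorts=cfg.n_cohorts, cohort_size=cfg.cohort_size,
                                   seed=seed, scenarios=cfg.scenarios, races=cfg.races,
                                   n_cycles=cfg.n_cycles, mode=cfg.mode)
        if sensitivity:
            sens = run_sensitivity(cfg, self.params, factor=sensitivity_factor)
            return MicrosimResults(self, sens.base, sens)
        return MicrosimResults(self, run_experiment(cfg, self.params), None)

    run = fit  # simulation-native alias


class MicrosimResults:
    """Fitted-model view of an experiment: estimates, dispersion, summaries."""

    def __init__(self, model: HypertensionMicrosim, result: ExperimentResult,
                 sensitivity: SensitivityResult | None):
        self.model = model
        self.result = result
        self.sensitivity = sensitivity

    # -- point estimates -------------------------------------------------
    def career_prevalence(self, scenario: str, race: str) -> float:
        """Career-average (ages 25–64) prevalence, per 100."""
        return self.result.career_average(scenario, race) * 100.0

    def career_prevalence_se(self, scenario: str, race: str) -> float:
        """Monte-Carlo standard error of the career average across cohorts."""
        per_cohort = self.result.cohort_career_averages(scenario, race) * 100.0
        if per_cohort.size < 2:
            return float("nan")
        return float(per_cohort.std(ddof=1) / np.sqrt(per_cohort.size))

    def racial_gap(self, scenario: str) -> dict[str, float]:
        """Black − white prevalence per 100, by age band and career."""
        black = age_group_means(self.result.mean_prevalence(scenario, "black"),
                                race="black", scenario=scenario)
        white = age_group_means(self.result.mean_prevalence(scenario, "white"),
                                race="white", scenario=scenario)
        return racial_gap(black, white)

    # -- tables ----------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        return summary_table(self.result)

    def sensitivity_frame(self) -> pd.DataFrame | None:
        return None if self.sensitivity is None else self.sensitivity.to_frame()

    def summary(self) -> str:
        """Human-readable run summary with career prevalences and gaps."""
        cfg = self.result.config
        lines = [
            "Hypertension microsimulation results",
            "====================================",
            f"cohorts: {cfg.n_cohorts} x {cfg.cohort_size:,} workers per race, "
            f"{cfg.n_cycles} annual cycles (ages 25-64)",
            f"seed: {cfg.seed}   parameter digest: {self.result.parameter_digest[:12]}",
            "",
            "career-average hypertension prevalence (cases per 100, "
            "Monte-Carlo SE in parentheses):",
        ]
        scenarios = list(dict.fromkeys(s for s, _ in self.result.prevalence))
        for scenario in scenarios:
            parts = []
            for race in ("white", "black"):
                if (scenario, race) in self.result.prevalence:
                    val = self.career_prevalence(scenario, race)
                    se = self.career_prevalence_se(scenario, race)
                    parts.append(f"{race} {val:5.2f} ({se:.3f})")
            gap = self.racial_gap(scenario)["25-64"]
            lines.append(f"  {scenario:<11} {'  '.join(parts)}   gap {gap:+.2f}")
        if self.sensitivity is not None:
            lines += ["", "one-way sensitivity intervals (career prevalence per 100):"]
            for _, row in self.sensitivity.to_frame().iterrows():
                lines.append(
                    f"  {row['scenario']:<11}{row['race']:<7}{row['block']:<22}"
                    f"{row['base'] * 100:5.2f} ({row['low'] * 100:.2f}, "
                    f"{row['high'] * 100:.2f})")
        return "\n".join(lines)

    # -- output ----------------------------------------------------------
    def save_report(self, out_dir):
        return write_report(self.result, self.sensitivity, out_dir)

    def plot_prevalence(self, ax=None):
        """Per-cycle mean prevalence trajectories, one panel per scenario."""
        import matplotlib.pyplot as plt

        scenarios = list(dict.fromkeys(s for s, _ in self.result.prevalence))
        if ax is None:
            fig, axes = plt.subplots(1, len(scenarios), figsize=(3 * len(scenarios), 3),
                                     sharey=True)
            axes = np.atleast_1d(axes)
        else:
            axes = np.atleast_1d(ax)
        ages = np.arange(25, 25 + self.result.config.n_cycles)
        for axis, scenario in zip(axes, scenarios):
            for race, color in (("white", "tab:blue"), ("black", "tab:red")):
                if (scenario, race) in self.result.prevalence:
                    axis.plot(ages, self.result.mean_prevalence(scenario, race) * 100,
                              label=race, color=color)
            axis.set_title(scenario)
            axis.set_xlabel("age")
        axes[0].set_ylabel("hypertension prevalence (per 100)")
        axes[0].legend()
        return axes
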