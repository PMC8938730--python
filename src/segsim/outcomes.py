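"""Outcome aggregation: prevalence series, age-band summaries, gaps, reports.

Prevalence in a cycle is the number of hypertensive workers divided by the
number of alive workers.  Workers in the controlled state are excluded
from the numerator by default — controlled means normotensive in the
current cycle under treatment or behavior modification; the alternative
convention (counting controlled as treated hypertension) is available via
``include_controlled=True``.  Prevalences are stored as fractions;
reporting per 100 is display-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import StateCounts
from .params import REPORT_BANDS

BAND_WIDTH = 5


@dataclass
class PrevalenceSeries:
    """Per-cycle prevalence with supporting counts for one scenario × race."""

    frame: pd.DataFrame  # columns: cycle, age, prevalence, alive, hypertensive
    race: str
    scenario: str | None = None


def prevalence_by_cycle(counts: StateCounts,
                        include_controlled: bool = False) -> PrevalenceSeries:
    """Hypertensive / alive at each cycle; zero alive is an explicit error."""
    alive = counts.frame["alive"].to_numpy(dtype=float)
    if np.any(alive == 0):
        cycle = int(np.argmax(alive == 0))
        raise ZeroDivisionError(f"no alive workers at cycle {cycle}")
    numer = counts.frame["hypertensive"].to_numpy(dtype=float)
    if include_controlled:
        numer = numer + counts.frame["controlled"].to_numpy(dtype=float)
    frame = pd.DataFrame({
        "cycle": counts.frame.index,
        "age": counts.frame["age"].to_numpy(),
        "prevalence": numer / alive,
        "alive": alive.astype(int),
        "hypertensive": counts.frame["hypertensive"].to_numpy(),
    })
    return PrevalenceSeries(frame=frame, race=counts.race, scenario=counts.scenario)


@dataclass
class AgeGroupSummary:
    """Mean prevalence per 100 by 5-year age band plus the 25–64 career mean."""

    bands: dict[str, float]
    career: float
    race: str
    scenario: str | None = None


def age_group_means(series: PrevalenceSeries | np.ndarray, race: str = "",
                    scenario: str | None = None) -> AgeGroupSummary:
    """Unweighted band means of a 40-cycle prevalence trajectory, per 100.

    Accepts a :class:`PrevalenceSeries` or a bare 40-vector of fractions.
    Cycle ``c`` (0-based) maps to attained age ``25 + c``; bands are the
    inclusive 5-year blocks 25–29 … 60–64.
    """
    if isinstance(series, PrevalenceSeries):
        values = series.frame["prevalence"].to_numpy(dtype=float)
        race = race or series.race
        scenario = scenario if scenario is not None else series.scenario
    else:
        values = np.asarray(series, dtype=float)
    if values.shape != (len(REPORT_BANDS) * BAND_WIDTH,):
        raise ValueError(f"expected a complete 40-cycle series, got {values.shape}")
    bands = {band: float(values[i * BAND_WIDTH:(i + 1) * BAND_WIDTH].mean()) * 100.0
             for i, band in enumerate(REPORT_BANDS)}
    return AgeGroupSummary(bands=bands, career=float(values.mean()) * 100.0,
                           race=race, scenario=scenario)


def racial_gap(black: AgeGroupSummary, white: AgeGroupSummary) -> dict[str, float]:
    """Black minus white prevalence (per 100) per band and over the career."""
    if black.scenario != white.scenario:
        raise ValueError(f"scenario mismatch: {black.scenario!r} vs {white.scenario!r}")
    gap = {band: black.bands[band] - white.bands[band] for band in REPORT_BANDS}
    gap["25-64"] = black.career - white.career
    return gap


def savings_estimate(workforce_size: float, excess_cost: float,
                     prevalence_drop: float) -> float:
    """Annual societal savings in USD from a prevalence reduction.

    ``workforce_size`` workers × ``excess_cost`` USD/person/year excess
    spending by hypertensive patients × ``prevalence_drop`` (percentage
    points expressed as a fraction).
    """
    if workforce_size < 0 or excess_cost < 0 or prevalence_drop < 0:
        raise ValueError("savings inputs must be non-negative")
    return float(workforce_size) * float(excess_cost) * float(prevalence_drop)


def summary_table(result) -> pd.DataFrame:
    """Age-band prevalence table (per 100): scenario × race rows, band columns."""
    records = []
    for (scenario, race) in result.prevalence:
        summ = age_group_means(result.mean_prevalence(scenario, race),
                               race=race, scenario=scenario)
        row = {"scenario": scenario, "race": race}
        row.update({band: round(v, 4) for band, v in summ.bands.items()})
        row["25-64"] = round(summ.career, 4)
        records.append(row)
    return pd.DataFrame.from_records(records)


def write_report(result, sensitivity, out_dir, seed: int | None = None) -> dict[str, Path]:
    """Emit the standard report files into ``out_dir``.

    * ``age_band_prevalence.csv`` — scenario × race × age-band means (per 100)
    * ``sensitivity.csv`` — base/low/high career prevalence per block (per 100)
    * ``prevalence_by_cycle.csv`` — per-cycle mean prevalence trajectories
    * ``manifest.json`` — seed, parameter digest, package version
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table3 = summary_table(result)
    paths["age_bands"] = out_dir / "age_band_prevalence.csv"
    table3.to_csv(paths["age_bands"], index=False)

    paths["by_cycle"] = out_dir / "prevalence_by_cycle.csv"
    result.to_frame().to_csv(paths["by_cycle"], index=False)

    if sensitivity is not None:
        sens = sensitivity.to_frame().copy()
        for col in ("base", "low", "high"):
            sens[col] = sens[col] * 100.0
        bad = sens[(sens["low"] > sens["base"]) | (sens["base"] > sens["high"])]
        if len(bad):
            raise ValueError("sensitivity interval does not contain the base value")
        paths["sensitivity"] = out_dir / "sensitivity.csv"
        sens.to_csv(paths["sensitivity"], index=False)

    from . import __version__

    manifest = {
        "seed": int(seed if seed is not None else result.config.seed),
        "parameter_digest": result.parameter_digest,
        "n_cohorts": result.config.n_cohorts,
        "cohort_size": result.config.cohort_size,
        "scenarios": list(result.config.scenarios),
        "version": __version__,
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
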