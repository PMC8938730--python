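"""Annual-cycle transition engine.

Advances a cohort one year at a time through the five-state hypertension
natural-history model: behaviors (smoking, activity, BMI drift), employment
(three-outcome multinomial), blood-pressure transitions driven by the two
5-year risk equations converted to annual probabilities by the DEALE
constant-hazard method, treatment dynamics (race-specific prescription,
adherence drawn once at initiation, adherence-specific control), and
competing-cause mortality.

Within-cycle event order is fixed: mortality draw first; survivors then
update behaviors, employment, and health state; age increments last.  The
number of random draws per cycle is a fixed function of cohort size, so
paired runs under common random numbers stay synchronized draw-for-draw
regardless of which transitions fire.

Allowed transitions (death reachable from every living state):

    normotensive   → prehypertensive | hypertensive
    prehypertensive→ hypertensive | controlled (behavioral modification)
    hypertensive   → controlled (medicated only)
    controlled     → prehypertensive | hypertensive (like normotensive)

Prehypertensive workers never return to normotensive, and unmedicated
hypertensives never become controlled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (
    ADH_NONE,
    BMI_FLOOR,
    EMP_FT,
    EMP_PT,
    EMP_UN,
    HEALTH_STATES,
    SMOKE_CURRENT,
    SMOKE_FORMER,
    SMOKE_NEVER,
    STATE_CONTROLLED,
    STATE_DEAD,
    STATE_HYPER,
    STATE_NORMO,
    STATE_PREHYP,
    Cohort,
    Worker,
    categorical_from_uniform,
    init_cohort,
)
from .params import (
    ADHERENCE_LEVELS,
    AllocationTable,
    ParameterSet,
    RiskEquation,
    deale_5yr_to_annual,
)

N_CYCLES = 40  # ages 25 → 64, one cycle per year


class StateCounts:
    """Per-cycle tallies of workers by health state.

    Wraps a DataFrame with one row per completed cycle (0-based; cycle ``c``
    is reported at attained age ``25 + c``), columns for the five health
    states plus ``alive``, and the pre-simulation baseline tallies in
    ``baseline``.
    """

    COLUMNS = list(HEALTH_STATES) + ["alive"]

    def __init__(self, frame: pd.DataFrame, baseline: pd.Series, race: str,
                 scenario: str | None = None):
        self.frame = frame
        self.baseline = baseline
        self.race = race
        self.scenario = scenario

    @property
    def n(self) -> int:
        return int(self.baseline[list(HEALTH_STATES)].sum())

    def validate(self) -> None:
        totals = self.frame[list(HEALTH_STATES)].sum(axis=1)
        if not (totals == self.n).all():
            raise ValueError("state counts do not sum to cohort size at every cycle")
        dead = self.frame["dead"].to_numpy()
        if np.any(np.diff(dead) < 0):
            raise ValueError("dead count must be non-decreasing (absorbing state)")
        if not (self.frame["alive"] == self.n - self.frame["dead"]).all():
            raise ValueError("alive count inconsistent with dead count")

    @staticmethod
    def _tally(cohort: Cohort) -> dict[str, int]:
        counts = np.bincount(cohort.state, minlength=5)
        row = {name: int(counts[i]) for i, name in enumerate(HEALTH_STATES)}
        row["alive"] = int(cohort.n - counts[STATE_DEAD])
        return row


def _require_alive(worker: Worker) -> None:
    if worker.health_state == "dead":
        raise ValueError("operation requires a living worker")


def _as_cohort(worker: Worker) -> Cohort:
    return Cohort.from_workers([worker])


# ---------------------------------------------------------------------------
# risk equations
# ---------------------------------------------------------------------------

def _risk_logit(eq: RiskEquation, cohort: Cohort,
                currently_prehypertensive: np.ndarray | None = None) -> np.ndarray:
    """Vectorized linear predictor of a 5-year risk equation.

    Effective work covariates (full/part-time indicators and the three PWE
    scores) are zero for unemployed workers.  ``currently_prehypertensive``
    overrides the state-derived indicator where the equation is evaluated
    under a counterfactual state (it is forced to 0 for normotensive and
    controlled workers).
    """
    if np.any(cohort.bmi[cohort.alive] <= 0):
        raise ValueError("BMI must be positive for risk-equation evaluation")
    employed = cohort.employment != EMP_UN
    if currently_prehypertensive is None:
        currently_prehypertensive = cohort.state == STATE_PREHYP
    c = eq.coefficients
    logit = (
        eq.intercept
        + c["LogBMI"] * np.log(cohort.bmi)
        + c["CurrentSmoker"] * (cohort.smoking == SMOKE_CURRENT)
        + c["CurrentlyPrehypertensive"] * np.asarray(currently_prehypertensive, float)
        + c["FamilyHistory"] * cohort.family_history
        + c["WorkFullTime"] * (cohort.employment == EMP_FT)
        + c["WorkPartTime"] * (cohort.employment == EMP_PT)
        + c["JobDemand"] * np.where(employed, cohort.demand, 0.0)
        + c["JobControl"] * np.where(employed, cohort.control, 0.0)
        + c["Support"] * np.where(employed, cohort.support, 0.0)
        + c["Age"] * cohort.age
        + c["Women"] * cohort.female
    )
    return logit


def eval_risk_equation(eq: RiskEquation, worker: Worker | Cohort) -> float | np.ndarray:
    """5-year onset probability for a worker (or a whole cohort)."""
    if isinstance(worker, Worker):
        _require_alive(worker)
        if worker.bmi <= 0:
            raise ValueError("BMI must be positive")
        return float(expit(_risk_logit(eq, _as_cohort(worker)))[0])
    return expit(_risk_logit(eq, worker))


def _onset_annual(cohort: Cohort, params: ParameterSet,
                  mode: str = "risk") -> tuple[np.ndarray, np.ndarray]:
    """Annual (to-prehypertensive, to-hypertensive) probabilities, full cohort.

    In ``risk`` mode, the hypertension equation carries the worker's actual
    prehypertension indicator while the prehypertension equation is always
    evaluated with it forced to 0 (it only applies to normotensive and
    controlled workers).  In ``crude`` mode the state-only fallback
    probabilities are used.
    """
    n = cohort.n
    if mode == "crude":
        crude = params.transitions.crude
        is_pre = cohort.state == STATE_PREHYP
        p_hyp = np.where(is_pre, crude["prehyp_to_hyper"], crude["normo_to_hyper"])
        p_pre = np.where(is_pre, 0.0, crude["normo_to_prehyp"])
        return p_pre.astype(float), p_hyp.astype(float)
    eq1 = params.risk_equations["hypertension_5yr"]
    eq2 = params.risk_equations["prehypertension_5yr"]
    p5_hyp = expit(_risk_logit(eq1, cohort))
    p5_pre = expit(_risk_logit(eq2, cohort, currently_prehypertensive=np.zeros(n)))
    p_hyp = deale_5yr_to_annual(np.minimum(p5_hyp, 1 - 1e-12))
    p_pre = deale_5yr_to_annual(np.minimum(p5_pre, 1 - 1e-12))
    p_pre = np.where(cohort.state == STATE_PREHYP, 0.0, p_pre)
    return p_pre, p_hyp


def annual_onset_probabilities(worker: Worker, params: ParameterSet,
                               mode: str = "risk") -> tuple[float, float]:
    """Annual onset probabilities for one living, non-hypertensive worker.

    Returns ``(p_to_prehypertensive, p_to_hypertensive)``; for workers
    already prehypertensive the first component is zero.  Controlled
    workers are treated like normotensive ones.
    """
    _require_alive(worker)
    if worker.health_state == "hypertensive":
        raise ValueError("onset probabilities are undefined for hypertensive workers")
    cohort = _as_cohort(worker)
    p_pre, p_hyp = _onset_annual(cohort, params, mode=mode)
    return float(p_pre[0]), float(p_hyp[0])


# ---------------------------------------------------------------------------
# per-cycle steps (vectorized internals + scalar per-worker surface)
# ---------------------------------------------------------------------------

def _smoking_band_index(age: np.ndarray) -> np.ndarray:
    return np.where(age < 30, 0, np.where(age < 45, 1, 2)).astype(np.int8)


def _step_behaviors(cohort: Cohort, params: ParameterSet, rng: np.random.Generator,
                    active_mask: np.ndarray) -> None:
    b = params.behavior
    n = cohort.n
    u_smoke = rng.random(n)
    u_act = rng.random(n)
    z_bmi = rng.standard_normal(n)

    band_names = ("18-29", "30-44", "45+")
    bands = _smoking_band_index(cohort.age)
    p_nc = np.array([b.smoking_transitions[bn]["never_to_current"] for bn in band_names])[bands]
    p_cq = np.array([b.smoking_transitions[bn]["current_to_quit"] for bn in band_names])[bands]
    p_qc = np.array([b.smoking_transitions[bn]["quit_to_current"] for bn in band_names])[bands]
    smoking = cohort.smoking
    start_current = active_mask & (smoking == SMOKE_NEVER) & (u_smoke < p_nc)
    quit = active_mask & (smoking == SMOKE_CURRENT) & (u_smoke < p_cq)
    relapse = active_mask & (smoking == SMOKE_FORMER) & (u_smoke < p_qc)
    smoking[start_current | relapse] = SMOKE_CURRENT
    smoking[quit] = SMOKE_FORMER

    a = b.activity_transitions
    to_inactive = active_mask & cohort.active & (u_act < a["active_to_inactive"])
    to_active = active_mask & ~cohort.active & (u_act < a["inactive_to_active"])
    cohort.active[to_inactive] = False
    cohort.active[to_active] = True

    drift = np.where(cohort.active, b.bmi_drift["active"], b.bmi_drift["inactive"])
    delta = drift + b.bmi_drift["noise_sd"] * z_bmi
    cohort.bmi[active_mask] = np.maximum(cohort.bmi[active_mask] + delta[active_mask],
                                         BMI_FLOOR)


def _step_employment(cohort: Cohort, params: ParameterSet, rng: np.random.Generator,
                     active_mask: np.ndarray) -> None:
    u_emp = rng.random(cohort.n)  # always drawn: keeps CRN streams aligned
    if params.employment.frozen:
        return
    black = cohort.race == "black"
    probs = params.employment.probabilities(
        cohort.age, cohort.female, np.full(cohort.n, black), cohort.ever_unemployed,
        cohort.occ_class)
    new_emp = categorical_from_uniform(u_emp, probs)
    cohort.employment[active_mask] = new_emp[active_mask]
    cohort.ever_unemployed |= cohort.employment == EMP_UN


def _step_health(cohort: Cohort, params: ParameterSet, rng: np.random.Generator,
                 active_mask: np.ndarray, mode: str = "risk") -> None:
    n = cohort.n
    u_onset = rng.random(n)
    u_presc = rng.random(n)
    u_adh = rng.random(n)
    u_ctrl = rng.random(n)

    state_before = cohort.state.copy()
    p_pre, p_hyp = _onset_annual(cohort, params, mode=mode)
    t = params.transitions

    # normotensive / controlled: onset transitions
    nc = active_mask & np.isin(state_before, (STATE_NORMO, STATE_CONTROLLED))
    to_hyper = nc & (u_onset < p_hyp)
    to_pre = nc & ~to_hyper & (u_onset < p_hyp + p_pre)
    cohort.state[to_hyper] = STATE_HYPER
    cohort.state[to_pre] = STATE_PREHYP
    # a controlled worker whose blood pressure rises only to the
    # prehypertensive range leaves the medicated pathway
    cohort.on_medication[to_pre] = False
    cohort.adherence[to_pre] = ADH_NONE

    # prehypertensive: onset to hypertension or behavioral-modification control
    pre = active_mask & (state_before == STATE_PREHYP)
    pre_to_hyper = pre & (u_onset < p_hyp)
    pre_to_ctrl = pre & ~pre_to_hyper & (u_onset < p_hyp + t.prehyp_to_controlled)
    cohort.state[pre_to_hyper] = STATE_HYPER
    cohort.state[pre_to_ctrl] = STATE_CONTROLLED

    # hypertensive at the start of this step: medication and control
    hyper = active_mask & (state_before == STATE_HYPER)
    presc_p = t.prescription[cohort.race]
    newly_prescribed = hyper & ~cohort.on_medication & (u_presc < presc_p)
    cohort.on_medication[newly_prescribed] = True
    if newly_prescribed.any():
        dist = np.array([t.adherence_distribution[l] for l in ADHERENCE_LEVELS])
        cohort.adherence[newly_prescribed] = categorical_from_uniform(
            u_adh[newly_prescribed], dist / dist.sum())
    ctrl_probs = np.array([t.control_by_adherence[l] for l in ADHERENCE_LEVELS])
    medicated = hyper & cohort.on_medication
    adh = np.where(cohort.adherence >= 0, cohort.adherence, 0)
    to_controlled = medicated & (u_ctrl < ctrl_probs[adh])
    cohort.state[to_controlled] = STATE_CONTROLLED


def _step_mortality(cohort: Cohort, params: ParameterSet,
                    rng: np.random.Generator) -> None:
    u = rng.random(cohort.n)
    m = params.mortality
    band = np.clip((cohort.age - 25) // 5, 0, 7)
    race = cohort.race
    cvd = np.where(cohort.female,
                   np.asarray(m.cvd_rate[race]["female"])[band],
                   np.asarray(m.cvd_rate[race]["male"])[band])
    hr = np.where(cohort.female,
                  m.cvd_hazard_ratio_hypertensive["female"],
                  m.cvd_hazard_ratio_hypertensive["male"])
    cvd = cvd * np.where(cohort.state == STATE_HYPER, hr, 1.0)
    non_cvd = np.where(cohort.female,
                       np.asarray(m.non_cvd_rate[race]["female"])[band],
                       np.asarray(m.non_cvd_rate[race]["male"])[band])
    preg = np.where(cohort.female, np.asarray(m.pregnancy_rate[race])[band], 0.0)
    # competing causes combined additively on the rate scale, single draw
    p_death = 1.0 - np.exp(-(cvd + non_cvd + preg))
    dies = cohort.alive & (u < p_death)
    cohort.state[dies] = STATE_DEAD


def _worker_step(step, worker: Worker, params: ParameterSet,
                 rng: np.random.Generator, **kw) -> Worker:
    _require_alive(worker)
    cohort = _as_cohort(worker)
    step(cohort, params, rng, np.array([True]), **kw)
    return cohort.worker(0)


def step_behaviors(worker: Worker, params: ParameterSet,
                   rng: np.random.Generator) -> Worker:
    """Update one worker's smoking, activity, and BMI for a cycle."""
    return _worker_step(_step_behaviors, worker, params, rng)


def step_employment(worker: Worker, params: ParameterSet,
                    rng: np.random.Generator) -> Worker:
    """Draw one worker's employment status for a cycle."""
    return _worker_step(_step_employment, worker, params, rng)


def step_medication_and_control(worker: Worker, params: ParameterSet,
                                rng: np.random.Generator) -> Worker:
    """Prescription / adherence / control step for one hypertensive worker."""
    _require_alive(worker)
    if worker.health_state != "hypertensive":
        raise ValueError("medication step applies to hypertensive workers only")
    return _worker_step(_step_health, worker, params, rng)


def step_mortality(worker: Worker, params: ParameterSet,
                   rng: np.random.Generator) -> Worker:
    """Single combined-cause death draw for one worker."""
    _require_alive(worker)
    cohort = _as_cohort(worker)
    _step_mortality(cohort, params, rng)
    return cohort.worker(0)


# ---------------------------------------------------------------------------
# cycle and cohort drivers
# ---------------------------------------------------------------------------

def advance_cycle(cohort: Cohort, params: ParameterSet, rng: np.random.Generator,
                  mode: str = "risk") -> tuple[Cohort, dict[str, int]]:
    """Advance the cohort one annual cycle in place.

    Order: mortality → behaviors → employment → health state → age.  Dead
    workers are skipped by every step but the per-cycle draw count stays
    fixed, so common-random-number pairing is exact.  Returns the cohort
    and the post-cycle state tallies.
    """
    _step_mortality(cohort, params, rng)
    survivors = cohort.alive
    _step_behaviors(cohort, params, rng, survivors)
    _step_employment(cohort, params, rng, survivors)
    _step_health(cohort, params, rng, survivors, mode=mode)
    cohort.age[survivors] += 1
    return cohort, StateCounts._tally(cohort)


def run_cohort(n: int, race: str, allocation: AllocationTable | None,
               params: ParameterSet, seed, n_cycles: int = N_CYCLES,
               mode: str = "risk",
               return_trajectories: bool = False) -> StateCounts | tuple:
    """Initialize and run one cohort for ``n_cycles`` annual cycles.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence`, or a
    Generator; results are bit-reproducible given the same seed.  With
    ``return_trajectories`` the per-worker state matrix
    (``n_cycles + 1`` × ``n``, baseline first) is returned alongside.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort = init_cohort(n, race, params, allocation=allocation, rng=rng)
    baseline = pd.Series(StateCounts._tally(cohort))
    rows = []
    trajectories = [cohort.state.copy()] if return_trajectories else None
    for _ in range(n_cycles):
        _, tally = advance_cycle(cohort, params, rng, mode=mode)
        rows.append(tally)
        if return_trajectories:
            trajectories.append(cohort.state.copy())
    frame = pd.DataFrame(rows)
    frame.index.name = "cycle"
    frame.insert(0, "age", 25 + frame.index)
    counts = StateCounts(frame=frame, baseline=baseline, race=race)
    counts.validate()
    if return_trajectories:
        return counts, np.array(trajectories)
    return counts


def markov_transition_matrix(params: ParameterSet) -> np.ndarray:
    """5×5 one-cycle transition matrix of the homogeneous (crude-mode) chain.

    Valid as an exact cohort-level description only under degenerate
    parameters: crude mode, zero mortality, frozen behaviors/employment,
    and either certain prescription with a point-mass adherence level or
    zero prescription.  Used as the independent matrix-power oracle.
    """
    t = params.transitions
    crude = t.crude
    presc = t.prescription["black"]
    if t.prescription["white"] != presc:
        raise ValueError("homogeneous chain requires race-invariant prescription")
    if presc not in (0.0, 1.0):
        raise ValueError("homogeneous chain requires prescription probability 0 or 1")
    levels = [l for l in ADHERENCE_LEVELS if t.adherence_distribution[l] == 1.0]
    if presc == 1.0 and not levels:
        raise ValueError("homogeneous chain requires a point-mass adherence level")
    p_ctrl = t.control_by_adherence[levels[0]] if presc == 1.0 else 0.0
    a, b_ = crude["normo_to_prehyp"], crude["normo_to_hyper"]
    c = crude["prehyp_to_hyper"]
    d = t.prehyp_to_controlled
    M = np.zeros((5, 5))
    M[STATE_NORMO] = [1 - a - b_, a, b_, 0, 0]
    M[STATE_PREHYP] = [0, 1 - c - d, c, d, 0]
    M[STATE_HYPER] = [0, 0, 1 - p_ctrl, p_ctrl, 0]
    M[STATE_CONTROLLED] = [0, a, b_, 1 - a - b_, 0]
    M[STATE_DEAD] = [0, 0, 0, 0, 1]
    return M
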