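"""Transition engine: risk equations, cycle steps, trajectory invariants."""

import math

import numpy as np
import pytest
from conftest import make_worker

import segsim as ss
from segsim.cohort import (
    EMP_UN,
    STATE_CONTROLLED,
    STATE_DEAD,
    STATE_HYPER,
    STATE_NORMO,
    STATE_PREHYP,
)
from segsim.engine import _step_employment, markov_transition_matrix
from segsim.fixtures import FixtureOptions
from segsim.params import BP_STATES


class TestRiskEquation:
    def test_intercept_only(self, default_params):
        """All covariates zero: probability is the inverse-logit intercept."""
        w = make_worker(age=0, gender="male", family_history=False, bmi=1.0,
                        health_state="normotensive", employment="unemployed",
                        ever_unemployed=True)
        eq = default_params.risk_equations["hypertension_5yr"]
        p = ss.eval_risk_equation(eq, w)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(12.07)), rel=1e-9)
        assert p == pytest.approx(5.7e-6, rel=0.01)

    def test_hand_evaluated_reference_worker(self, default_params):
        """Prehypertensive 40-year-old woman, BMI 27, family history,
        full-time, neutral PWE, non-smoker: logit -0.3763, p = 0.40702."""
        w = make_worker()
        eq = default_params.risk_equations["hypertension_5yr"]
        p = ss.eval_risk_equation(eq, w)
        logit = math.log(p / (1 - p))
        assert logit == pytest.approx(-0.3763, abs=5e-5)
        assert p == pytest.approx(0.4070207245, abs=1e-6)

    def test_job_control_marginal_effect_is_exact(self, default_params):
        eq = default_params.risk_equations["hypertension_5yr"]
        w0 = make_worker()
        w1 = make_worker(pwe=ss.PWEProfile(0.0, 1.0, 0.0))
        p0, p1 = ss.eval_risk_equation(eq, w0), ss.eval_risk_equation(eq, w1)
        diff = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
        assert diff == pytest.approx(-0.347, abs=1e-12)

    def test_unemployment_zeroes_effective_work_covariates(self, default_params):
        eq = default_params.risk_equations["hypertension_5yr"]
        rich_pwe = make_worker(employment="unemployed", ever_unemployed=True,
                               pwe=ss.PWEProfile(2.0, 2.0, 2.0))
        zero_pwe = make_worker(employment="unemployed", ever_unemployed=True)
        assert ss.eval_risk_equation(eq, rich_pwe) == ss.eval_risk_equation(eq, zero_pwe)
        employed = make_worker(pwe=ss.PWEProfile(2.0, 2.0, 2.0))
        assert ss.eval_risk_equation(eq, employed) != ss.eval_risk_equation(eq, rich_pwe)

    def test_dead_worker_rejected(self, default_params):
        eq = default_params.risk_equations["hypertension_5yr"]
        with pytest.raises(ValueError, match="living"):
            ss.eval_risk_equation(eq, make_worker(health_state="dead"))


class TestAnnualOnset:
    def test_deale_applied_to_risk_equations(self, default_params):
        """Annual probabilities equal the constant-hazard conversion of the
        5-year equation outputs (independent closed-form oracle)."""
        w = make_worker(health_state="normotensive")
        p_pre, p_hyp = ss.annual_onset_probabilities(w, default_params)
        p5_hyp = ss.eval_risk_equation(
            default_params.risk_equations["hypertension_5yr"], w)
        p5_pre = ss.eval_risk_equation(
            default_params.risk_equations["prehypertension_5yr"], w)
        assert p_hyp == pytest.approx(1.0 - (1.0 - p5_hyp) ** 0.2, abs=1e-12)
        assert p_pre == pytest.approx(1.0 - (1.0 - p5_pre) ** 0.2, abs=1e-12)

    def test_prehypertension_raises_onset(self, default_params):
        _, p_normo = ss.annual_onset_probabilities(
            make_worker(health_state="normotensive"), default_params)
        p_pre_component, p_hyper = ss.annual_onset_probabilities(
            make_worker(health_state="prehypertensive"), default_params)
        assert p_hyper > p_normo
        assert p_pre_component == 0.0

    def test_controlled_matches_normotensive_twin(self, default_params):
        normo = ss.annual_onset_probabilities(
            make_worker(health_state="normotensive"), default_params)
        controlled = ss.annual_onset_probabilities(
            make_worker(health_state="controlled", on_medication=True,
                        adherence="high"), default_params)
        assert normo == controlled

    def test_hypertensive_rejected(self, default_params):
        with pytest.raises(ValueError, match="hypertensive"):
            ss.annual_onset_probabilities(
                make_worker(health_state="hypertensive"), default_params)


class TestBehaviorStep:
    def test_frozen_toy_leaves_worker_unchanged(self, frozen_toy):
        w = make_worker()
        out = ss.step_behaviors(w, frozen_toy, np.random.default_rng(0))
        assert (out.smoking, out.physically_active, out.bmi) == \
               (w.smoking, w.physically_active, w.bmi)

    def test_certain_smoking_initiation(self, default_params):
        params = default_params.copy()
        params.behavior.smoking_transitions["30-44"]["never_to_current"] = 1.0
        w = make_worker(smoking="never", age=40)
        out = ss.step_behaviors(w, params, np.random.default_rng(0))
        assert out.smoking == "current"

    def test_deterministic_bmi_drift(self, default_params):
        params = default_params.copy()
        params.behavior.bmi_drift = {"active": 0.10, "inactive": 0.25, "noise_sd": 0.0}
        for band in params.behavior.smoking_transitions.values():
            band.update({k: 0.0 for k in band})
        params.behavior.activity_transitions = {"inactive_to_active": 0.0,
                                                "active_to_inactive": 0.0}
        w = make_worker(physically_active=False, bmi=30.0)
        out = ss.step_behaviors(w, params, np.random.default_rng(0))
        assert out.bmi == pytest.approx(30.25)


class TestEmploymentStep:
    def test_frozen_toy_keeps_status(self, frozen_toy):
        w = make_worker(employment="part_time")
        out = ss.step_employment(w, frozen_toy, np.random.default_rng(0))
        assert out.employment == "part_time"

    def test_class_unemployment_gradient_in_simulation(self, default_params):
        """Aides accumulate more unemployment than diagnosing professionals
        over many simulated worker-cycles (10^5 per class)."""
        shares = []
        for cls_idx in (0, 3):
            cohort = ss.init_cohort(10_000, "white", default_params, rng=13)
            cohort.occ_class[:] = cls_idx
            rng = np.random.default_rng(17)
            unemployed_cycles = 0
            for _ in range(10):
                _step_employment(cohort, default_params, rng,
                                 np.ones(cohort.n, bool))
                unemployed_cycles += int((cohort.employment == EMP_UN).sum())
            shares.append(unemployed_cycles / (10 * cohort.n))
        assert shares[1] > shares[0]

    def test_unemployment_is_sticky_history(self, default_params):
        cohort = ss.init_cohort(5_000, "white", default_params, rng=19)
        ever_before = cohort.ever_unemployed.copy()
        _step_employment(cohort, default_params, np.random.default_rng(2),
                         np.ones(cohort.n, bool))
        assert (cohort.ever_unemployed | ~ever_before).all()  # never unset


class TestMedicationStep:
    def test_zero_prescription_means_hypertensive_forever(self, frozen_toy):
        params = frozen_toy.copy()
        params.transitions.prescription = {"black": 0.0, "white": 0.0}
        counts, traj = ss.run_cohort(2_000, "black", None, params, seed=23,
                                     return_trajectories=True)
        hyper_then_controlled = ((traj[:-1] == STATE_HYPER)
                                 & (traj[1:] == STATE_CONTROLLED))
        assert not hyper_then_controlled.any()

    def test_certain_control_with_high_adherence(self, default_params):
        params = default_params.copy()
        params.transitions.prescription = {"black": 1.0, "white": 1.0}
        params.transitions.adherence_distribution = {"high": 1.0, "medium": 0.0,
                                                     "low": 0.0}
        params.transitions.control_by_adherence["high"] = 1.0
        w = make_worker(health_state="hypertensive")
        out = ss.step_medication_and_control(w, params, np.random.default_rng(0))
        assert out.health_state == "controlled"
        assert out.on_medication and out.adherence == "high"

    def test_relapsed_controlled_worker_keeps_medication(self, default_params):
        """A medicated worker who relapses to hypertension keeps the original
        prescription and adherence level (no new initiation draw)."""
        params = default_params.copy()
        params.transitions.control_by_adherence = {"high": 0.0, "medium": 0.0,
                                                   "low": 0.0}
        w = make_worker(health_state="hypertensive", on_medication=True,
                        adherence="low")
        out = ss.step_medication_and_control(w, params, np.random.default_rng(0))
        assert out.on_medication and out.adherence == "low"
        assert out.health_state == "hypertensive"

    def test_non_hypertensive_rejected(self, default_params):
        with pytest.raises(ValueError, match="hypertensive"):
            ss.step_medication_and_control(make_worker(), default_params,
                                           np.random.default_rng(0))


class TestMortalityStep:
    @pytest.fixture()
    def high_mortality_params(self, frozen_toy):
        params = frozen_toy.copy()
        for race in ("black", "white"):
            for g in ("male", "female"):
                params.mortality.cvd_rate[race][g] = [0.2] * 8
                params.mortality.non_cvd_rate[race][g] = [0.0] * 8
            params.mortality.pregnancy_rate[race] = [0.0] * 8
        return params

    def test_zero_mortality_toy_never_dies(self, frozen_toy):
        counts = ss.run_cohort(1_000, "white", None, frozen_toy, seed=29)
        assert (counts.frame["dead"] == 0).all()

    def test_hypertension_raises_death_probability(self, high_mortality_params):
        n = 40_000
        deaths = {}
        for state in (STATE_NORMO, STATE_HYPER):
            cohort = ss.init_cohort(n, "white", high_mortality_params, rng=31)
            cohort.state[:] = state
            from segsim.engine import _step_mortality

            _step_mortality(cohort, high_mortality_params, np.random.default_rng(37))
            deaths[state] = int((cohort.state == STATE_DEAD).sum())
        # HR 1.8 (men) / 2.0 (women) on the CVD rate: clear separation
        assert deaths[STATE_HYPER] > deaths[STATE_NORMO] * 1.2

    def test_pregnancy_rate_raises_female_mortality(self, high_mortality_params):
        params = high_mortality_params.copy()
        for race in ("black", "white"):
            params.mortality.pregnancy_rate[race] = [0.3] * 8
            for g in ("male", "female"):
                params.mortality.cvd_rate[race][g] = [0.05] * 8
        cohort = ss.init_cohort(40_000, "white", params, rng=41)
        cohort.state[:] = STATE_NORMO
        from segsim.engine import _step_mortality

        _step_mortality(cohort, params, np.random.default_rng(43))
        female_death = (cohort.state[cohort.female] == STATE_DEAD).mean()
        male_death = (cohort.state[~cohort.female] == STATE_DEAD).mean()
        assert female_death > male_death * 2


class TestTrajectoryInvariants:
    def test_conservation_and_absorbing_death(self, trajectories):
        counts, traj = trajectories
        counts.validate()  # counts sum to n, dead non-decreasing
        dead = traj == STATE_DEAD
        assert not (dead[:-1] & ~dead[1:]).any()  # death is absorbing

    def test_forbidden_transitions_never_occur(self, trajectories):
        _, traj = trajectories
        prev, nxt = traj[:-1], traj[1:]
        assert not ((prev == STATE_PREHYP) & (nxt == STATE_NORMO)).any()
        assert not ((prev == STATE_HYPER) & (nxt == STATE_NORMO)).any()
        assert not ((prev == STATE_HYPER) & (nxt == STATE_PREHYP)).any()
        assert not ((prev == STATE_CONTROLLED) & (nxt == STATE_NORMO)).any()

    def test_static_toy_counts_constant(self, static_toy):
        counts = ss.run_cohort(1_500, "white", None, static_toy, seed=47)
        for col in ("normotensive", "prehypertensive", "hypertensive",
                    "controlled", "dead"):
            assert counts.frame[col].nunique() == 1
        baseline_hyper = counts.baseline["hypertensive"]
        assert (counts.frame["hypertensive"] == baseline_hyper).all()

    def test_run_cohort_bit_determinism(self, default_params):
        a = ss.run_cohort(2_000, "black", None, default_params, seed=53)
        b = ss.run_cohort(2_000, "black", None, default_params, seed=53)
        assert a.frame.equals(b.frame)


def _homogeneous_toy(a, b, c, d, p_ctrl, prescribed):
    """Degenerate parameters under which the cohort is an exact 5-state chain."""
    params = ss.toy_parameter_fixture(FixtureOptions(
        zero_mortality=True, frozen_behaviors=True, frozen_employment=True))
    t = params.transitions
    t.crude = {"normo_to_prehyp": a, "normo_to_hyper": b, "prehyp_to_hyper": c}
    t.prehyp_to_controlled = d
    t.prescription = {"black": 1.0 if prescribed else 0.0,
                      "white": 1.0 if prescribed else 0.0}
    t.adherence_distribution = {"high": 1.0, "medium": 0.0, "low": 0.0}
    t.control_by_adherence["high"] = p_ctrl
    params.validate()
    return params


class TestMarkovCohortOracle:
    """Empirical state fractions must match the matrix-power solution of the
    equivalent homogeneous Markov cohort within 3 binomial SEs."""

    CASES = [
        dict(a=0.03, b=0.008, c=0.035, d=0.05, p_ctrl=0.43, prescribed=True),
        dict(a=0.10, b=0.020, c=0.080, d=0.10, p_ctrl=0.30, prescribed=True),
        dict(a=0.06, b=0.015, c=0.050, d=0.00, p_ctrl=0.00, prescribed=False),
    ]

    @staticmethod
    def _oracle_matrix(a, b, c, d, p_ctrl, prescribed):
        # written out independently of the engine's helper
        p = p_ctrl if prescribed else 0.0
        return np.array([
            [1 - a - b, a, b, 0, 0],
            [0, 1 - c - d, c, d, 0],
            [0, 0, 1 - p, p, 0],
            [0, a, b, 1 - a - b, 0],
            [0, 0, 0, 0, 1],
        ])

    @staticmethod
    def _baseline_vector(params, race):
        bl = params.baselines
        f = bl.female_share[race]
        v = np.zeros(5)
        for i, s in enumerate(BP_STATES):
            v[i] = f * bl.bp_state[race]["female"][s] \
                + (1 - f) * bl.bp_state[race]["male"][s]
        return v

    @pytest.mark.parametrize("case", CASES)
    def test_matrix_power_agreement(self, case):
        params = _homogeneous_toy(**case)
        n = 6_000
        counts = ss.run_cohort(n, "black", None, params, seed=59, mode="crude")
        M = self._oracle_matrix(**case)
        v0 = self._baseline_vector(params, "black")
        cols = ["normotensive", "prehypertensive", "hypertensive", "controlled",
                "dead"]
        for cycle in (5, 20, 40):
            expected = v0 @ np.linalg.matrix_power(M, cycle)
            observed = counts.frame.loc[cycle - 1, cols].to_numpy(float) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert (np.abs(observed - expected) <= 3 * se + 1e-12).all()

    @pytest.mark.parametrize("case", CASES[:1])
    def test_engine_helper_matches_hand_matrix(self, case):
        params = _homogeneous_toy(**case)
        assert np.allclose(markov_transition_matrix(params),
                           self._oracle_matrix(**case))


class TestMonotoneRiskEffects:
    """Shifting the PWE distributions in the protective direction weakly
    lowers simulated hypertension prevalence (signs of the onset equation)."""

    @pytest.mark.parametrize("dim, shift, direction", [
        ("control", +1.0, -1),
        ("support", +1.0, -1),
        ("demand", +1.0, +1),
    ])
    def test_twin_cohort_contrast(self, default_params, dim, shift, direction):
        shifted = default_params.copy()
        for cls in shifted.pwe.by_class.values():
            cls[dim]["mean"] += shift
        base = ss.run_cohort(20_000, "black", None, default_params, seed=61)
        twin = ss.run_cohort(20_000, "black", None, shifted, seed=61)
        prev_base = (base.frame["hypertensive"] / base.frame["alive"]).mean()
        prev_twin = (twin.frame["hypertensive"] / twin.frame["alive"]).mean()
        assert np.sign(prev_twin - prev_base) == direction
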