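"""Cohort initialization: baseline sampling, allocation, reproducibility."""

import numpy as np
import pytest

import segsim as ss
from segsim.cohort import STATE_HYPER, allocation_to_frame, frame_to_allocation
from segsim.params import CLASSES, AllocationTable


def _class_shares(cohort, mask=None):
    mask = np.ones(cohort.n, bool) if mask is None else mask
    return np.bincount(cohort.occ_class[mask], minlength=4) / mask.sum()


class TestInitCohort:
    def test_determinism_field_by_field(self, default_params):
        a = ss.init_cohort(2000, "black", default_params, rng=42)
        b = ss.init_cohort(2000, "black", default_params, rng=42)
        for name in ("female", "bmi", "smoking", "occ_class", "employment",
                     "state", "demand", "control", "support"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_all_start_alive_at_25(self, default_params):
        cohort = ss.init_cohort(500, "white", default_params, rng=0)
        assert (cohort.age == 25).all()
        assert cohort.alive.all()
        assert not cohort.on_medication.any()

    def test_class_shares_match_allocation_row(self, default_params):
        """Empirical class shares of Black women match the status-quo row
        within 3 Monte-Carlo standard errors."""
        n = 100_000
        cohort = ss.init_cohort(n, "black", default_params, rng=7)
        women = cohort.female
        shares = _class_shares(cohort, women)
        expected = np.array([0.015, 0.205, 0.223, 0.557])
        se = np.sqrt(expected * (1 - expected) / women.sum())
        assert (np.abs(shares - expected) < 3 * se).all()

    def test_degenerate_allocation_is_point_mass(self, default_params):
        table = AllocationTable(rows={(r, g): np.array([0.0, 0.0, 0.0, 1.0])
                                      for r in ("black", "white")
                                      for g in ("male", "female")})
        cohort = ss.init_cohort(300, "white", default_params, allocation=table, rng=1)
        assert (cohort.occ_class == 3).all()  # everyone an aide

    def test_missing_allocation_row_raises(self, default_params):
        table = AllocationTable(rows={("white", "male"): np.array([1.0, 0, 0, 0])})
        with pytest.raises(KeyError, match="female"):
            ss.init_cohort(100, "white", default_params, allocation=table, rng=0)

    def test_baseline_prevalence_matches_configuration(self, default_params):
        n = 50_000
        cohort = ss.init_cohort(n, "white", default_params, rng=3)
        bp = default_params.baselines.bp_state["white"]
        f = default_params.baselines.female_share["white"]
        expected = (f * bp["female"]["hypertensive"]
                    + (1 - f) * bp["male"]["hypertensive"])
        observed = (cohort.state == STATE_HYPER).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_class_shares_stable_across_cohort_size(self, default_params):
        small = _class_shares(ss.init_cohort(5_000, "white", default_params, rng=9))
        large = _class_shares(ss.init_cohort(50_000, "white", default_params, rng=10))
        assert np.abs(small - large).max() < 0.03


class TestAllocateOccupation:
    def test_status_quo_white_man_frequencies(self, default_params):
        rng = np.random.default_rng(0)
        draws = ss.allocate_occupation("white", "male", default_params.allocation,
                                       rng, size=200_000)
        freq = np.bincount(draws, minlength=4) / draws.size
        expected = np.array([0.312, 0.235, 0.291, 0.162])
        se = np.sqrt(expected * (1 - expected) / draws.size)
        assert (np.abs(freq - expected) < 3 * se).all()

    def test_point_mass_row(self, default_params):
        table = AllocationTable(rows={("white", "male"): np.array([1.0, 0, 0, 0])})
        rng = np.random.default_rng(0)
        assert ss.allocate_occupation("white", "male", table, rng) == "health_diagnosing"

    def test_scenario_d_white_woman_gets_white_male_row(self, default_params):
        table = ss.build_scenario_allocation("D", default_params.allocation)
        rng = np.random.default_rng(1)
        draws = ss.allocate_occupation("white", "female", table, rng, size=200_000)
        freq = np.bincount(draws, minlength=4) / draws.size
        expected = np.array([0.312, 0.235, 0.291, 0.162])
        se = np.sqrt(expected * (1 - expected) / draws.size)
        assert (np.abs(freq - expected) < 3 * se).all()

    def test_invalid_row_sum_rejected(self):
        table = AllocationTable(rows={("white", "male"): np.array([0.5, 0.2, 0.1, 0.1])})
        with pytest.raises(ValueError, match="sums to"):
            ss.allocate_occupation("white", "male", table, np.random.default_rng(0))


class TestAssignPWE:
    def test_zero_variance_gives_class_mean(self, default_params):
        params = default_params.copy()
        for cls in params.pwe.by_class.values():
            for dim in cls.values():
                dim["sd"] = 0.0
        profile = ss.assign_pwe("aide", params, np.random.default_rng(0))
        assert profile.control == pytest.approx(
            params.pwe.by_class["aide"]["control"]["mean"])

    def test_control_gradient_in_large_sample(self, default_params):
        rng = np.random.default_rng(4)
        idx = np.repeat(np.array([0, 3]), 20_000)
        _, control, _ = ss.assign_pwe(idx, default_params, rng)
        assert control[:20_000].mean() > control[20_000:].mean()

    def test_seed_determinism(self, default_params):
        a = ss.assign_pwe("technician", default_params, np.random.default_rng(5))
        b = ss.assign_pwe("technician", default_params, np.random.default_rng(5))
        assert (a.demand, a.control, a.support) == (b.demand, b.control, b.support)


class TestWorkerInvariants:
    def test_adherence_medication_coupling(self):
        from conftest import make_worker

        with pytest.raises(ValueError, match="adherence"):
            make_worker(on_medication=True, adherence="none").validate()
        with pytest.raises(ValueError, match="medication"):
            make_worker(health_state="normotensive", on_medication=True,
                        adherence="high").validate()
        make_worker(health_state="hypertensive", on_medication=True,
                    adherence="high").validate()


def test_worker_round_trip(default_params):
    cohort = ss.init_cohort(50, "black", default_params, rng=11)
    workers = [cohort.worker(i) for i in range(cohort.n)]
    rebuilt = ss.Cohort.from_workers(workers)
    assert np.array_equal(rebuilt.state, cohort.state)
    assert np.allclose(rebuilt.bmi, cohort.bmi)
    assert np.array_equal(rebuilt.occ_class, cohort.occ_class)


def test_allocation_csv_round_trip(default_params, tmp_path):
    tables = {"status_quo": default_params.allocation,
              "D": ss.build_scenario_allocation("D", default_params.allocation)}
    path = tmp_path / "alloc.csv"
    ss.write_allocation_csv(tables, path)
    loaded = ss.read_allocation_csv(path)
    assert set(loaded) == {"status_quo", "D"}
    for name, table in tables.items():
        for key, row in table.rows.items():
            assert loaded[name].rows[key] == pytest.approx(row)


def test_allocation_frame_shape(default_params):
    frame = allocation_to_frame({"status_quo": default_params.allocation})
    assert len(frame) == 16  # 4 groups x 4 classes
    back = frame_to_allocation(frame)
    assert back["status_quo"] == default_params.allocation
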