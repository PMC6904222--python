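"""Drive/resist classification, transitions, kinetics and derived curves."""

import numpy as np
import pandas as pd
import pytest

from forceglide import states as st
from forceglide.synthetic import (
    ROLE_DRIVE,
    ROLE_RESIST,
    AssayConfig,
    EventCalibration,
    generate_event_traces,
    simulate_gliding,
)
from forceglide.tether import TetherModel, ewlc_force

RNG = np.random.default_rng(42)
DT = 0.2


def _trace(segments, noise_sd=20.0, seed=0):
    """Build a displacement trace from (n_frames, level) segments."""
    rng = np.random.default_rng(seed)
    parts = [np.full(n, level) for n, level in segments]
    x = np.concatenate(parts)
    return x + rng.normal(0, noise_sd, x.size)


class TestFindEquilibrium:
    def test_pure_noise_baseline(self):
        x = RNG.normal(0.0, 20.0, 2000)
        eq = st.find_equilibrium(x)
        assert abs(eq.position) < 3.0
        assert eq.noise_sd == pytest.approx(20.0, rel=0.15)
        assert not eq.fallback

    def test_plateau_does_not_shift_the_peak(self):
        # 30% of frames sit on a -300 nm excursion plateau
        x = _trace([(700, 0.0), (300, -300.0)], seed=1)
        eq = st.find_equilibrium(x)
        assert abs(eq.position) < 10.0

    def test_constant_series_degenerate(self):
        eq = st.find_equilibrium(np.full(100, 123.0))
        assert eq.position == 123.0
        assert eq.degenerate

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            st.find_equilibrium(np.zeros(10))


class TestClassificationCriteria:
    def test_two_points_beyond_hundred_nanometres_make_an_event(self):
        x = _trace([(100, 0.0), (4, 150.0), (100, 0.0)], noise_sd=20.0, seed=2)
        eq = st.EquilibriumEstimate(0.0, 20.0)
        events = st.classify_events(x, eq, np.full(x.size, 830.0), DT)
        assert len(events) == 1
        assert events[0].role == "resist"

    def test_two_sd_branch_qualifies_below_hundred(self):
        # peak 90 nm with sd 30: under the 100 nm rule but over 2 SD = 60
        x = _trace([(100, 0.0), (5, 90.0), (100, 0.0)], noise_sd=10.0, seed=3)
        eq = st.EquilibriumEstimate(0.0, 30.0)
        events = st.classify_events(x, eq, np.full(x.size, 830.0), DT)
        assert len(events) == 1
        assert events[0].role == "resist"

    def test_single_point_spike_is_not_an_event(self):
        x = np.zeros(200)
        x[100] = 400.0
        eq = st.EquilibriumEstimate(0.0, 20.0)
        assert st.classify_events(x, eq, np.full(x.size, 830.0), DT) == []

    def test_long_gap_removes_track(self):
        x = _trace([(100, 0.0), (5, 200.0), (100, 0.0)], seed=4)
        x[40:71] = np.nan  # 6.2 s of missing frames
        eq = st.EquilibriumEstimate(0.0, 20.0)
        assert st.classify_events(x, eq, np.full(x.size, 830.0), DT) == []

    def test_short_gap_tolerated(self):
        x = _trace([(100, 0.0), (10, 250.0), (100, 0.0)], seed=5)
        x[20:35] = np.nan  # 3 s gap: below the 5 s rule
        eq = st.EquilibriumEstimate(0.0, 20.0)
        assert len(st.classify_events(x, eq, np.full(x.size, 830.0), DT)) == 1

    def test_unknown_frame_interval_rejected(self):
        eq = st.EquilibriumEstimate(0.0, 20.0)
        with pytest.raises(ValueError):
            st.classify_events(np.zeros(100), eq, np.zeros(100), 0.0)

    def test_drive_sign_negative(self):
        x = _trace([(50, 0.0), (20, -300.0), (50, 0.0)], seed=6)
        eq = st.EquilibriumEstimate(0.0, 20.0)
        events = st.classify_events(x, eq, np.full(x.size, 830.0), DT)
        assert len(events) == 1
        assert events[0].role == "drive"
        assert events[0].peak_displacement < 0


class TestClassificationAccuracy:
    def test_frame_level_role_accuracy(self, events_sim):
        disp = events_sim.displacements()
        total = correct = 0
        for k in range(events_sim.n_motors):
            evs, _ = st.analyze_track(disp[k], events_sim.mt_velocity, DT,
                                      kinesin=k)
            rec = st.events_to_role_matrix(evs, events_sim.n_motors,
                                           events_sim.time.size, DT)[k]
            truth = events_sim.roles[k]
            engaged = truth != 0
            total += engaged.sum()
            correct += (rec[engaged] == truth[engaged]).sum()
        assert correct / total >= 0.95

    def test_event_count_within_five_percent(self, events_sim):
        disp = events_sim.displacements()
        n_rec = 0
        for k in range(events_sim.n_motors):
            evs, _ = st.analyze_track(disp[k], events_sim.mt_velocity, DT,
                                      kinesin=k)
            n_rec += len(evs)
        n_true = len(events_sim.events)
        assert abs(n_rec - n_true) / n_true <= 0.05

    def test_role_signs_never_contradict_displacements(self, events_sim):
        disp = events_sim.displacements()
        for k in range(events_sim.n_motors):
            evs, _ = st.analyze_track(disp[k], events_sim.mt_velocity, DT,
                                      kinesin=k)
            for e in evs:
                mean_plateau = np.mean(e.displacement)
                if e.role == "drive":
                    assert mean_plateau < 0
                else:
                    assert mean_plateau > 0


class TestTransitions:
    @staticmethod
    def _event(kinesin, role, start, end):
        n = max(int((end - start) / DT), 2)
        sign = -1 if role == "drive" else 1
        return st.MotorEvent(
            kinesin=kinesin, role=role, start=start, end=end,
            times=start + DT * np.arange(n),
            displacement=sign * np.full(n, 200.0),
            force=np.zeros(n), run_length=1.0,
            peak_displacement=sign * 200.0)

    def test_counted_pairs_and_rate(self):
        evs = [self._event(0, "drive", 0.0, 3.0),
               self._event(0, "drive", 5.0, 8.0),
               self._event(0, "resist", 9.0, 10.0)]
        rate, mix, recs = st.count_transitions({0: evs}, observation_minutes=1.0)
        assert rate == 2.0
        assert mix["DD"] == 0.5 and mix["DR"] == 0.5
        assert len(recs) == 2

    def test_single_event_no_transition(self):
        rate, mix, recs = st.count_transitions(
            {0: [self._event(0, "drive", 0.0, 3.0)]}, observation_minutes=1.0)
        assert rate == 0.0 and recs == [] and mix == {}

    def test_mix_sums_to_one(self):
        evs = [self._event(0, r, 3.0 * i, 3.0 * i + 2.0)
               for i, r in enumerate(["drive", "resist", "resist", "drive"])]
        _, mix, _ = st.count_transitions({0: evs}, observation_minutes=1.0)
        assert sum(mix.values()) == pytest.approx(1.0)

    def test_max_gap_drops_distant_pairs(self):
        evs = [self._event(0, "drive", 0.0, 3.0),
               self._event(0, "drive", 30.0, 33.0)]
        rate, _, _ = st.count_transitions({0: evs}, 1.0, max_gap=10.0)
        assert rate == 0.0


class TestKinetics:
    def test_stationary_kinesin_run_length(self):
        # one event, cargo at 830 nm/s, kinesin stationary, 2 s -> 1.66 µm
        n = 10
        e = st.MotorEvent(0, "resist", 0.0, 2.0, DT * np.arange(n),
                          np.full(n, 200.0), np.zeros(n),
                          run_length=830.0 * 2.0 / 1000.0,
                          peak_displacement=200.0)
        out = st.event_kinetics([e])
        assert out.loc[0, "mean_run_length_um"] == pytest.approx(1.66)

    def test_duration_from_boundaries(self):
        e = TestTransitions._event(0, "drive", 1.2, 4.2)
        assert e.duration == pytest.approx(3.0)

    def test_exponential_sample_mean_within_two_sem(self):
        rng = np.random.default_rng(8)
        events = []
        for i, tau in enumerate(rng.exponential(3.0, 1000)):
            events.append(TestTransitions._event(0, "drive", 10.0 * i,
                                                 10.0 * i + max(tau, 0.41)))
        out = st.event_kinetics(events)
        mean, sem = out.loc[0, "mean_duration_s"], out.loc[0, "sem_duration_s"]
        assert abs(mean - 3.0) < 2 * sem + 0.05

    def test_empty_role_omitted(self):
        out = st.event_kinetics([TestTransitions._event(0, "drive", 0.0, 2.0)])
        assert list(out.role) == ["drive"]


class TestForceVsTime:
    def test_ramp_average_below_point_four_before_point_eight_seconds(self):
        # displacement ramps at 800 nm/s until the tether is taut (~450 nm);
        # the DNA stretches near its contour within ~0.7 s, so the average
        # tension over the first 0.8 s stays in the sub-0.4 pN regime
        n = 25
        tvec = DT * np.arange(n)
        d = np.minimum(800.0 * tvec, 450.0)
        e = st.MotorEvent(0, "resist", 0.0, DT * n, tvec, d,
                          np.zeros(n), 1.0, 450.0)
        out = st.force_vs_time([e], TetherModel())
        early = out[(out.time_s < 0.8)]
        assert early.mean_force_pN.mean() < 0.4

    def test_zero_displacement_zero_force(self):
        n = 10
        e = st.MotorEvent(0, "resist", 0.0, 2.0, DT * np.arange(n),
                          np.zeros(n), np.zeros(n), 1.0, 0.0)
        out = st.force_vs_time([e], TetherModel())
        assert (out.mean_force_pN == 0.0).all()

    def test_plateau_force_matches_tether_model(self):
        n = 30
        e = st.MotorEvent(0, "resist", 0.0, DT * n, DT * np.arange(n),
                          np.full(n, 520.0), np.zeros(n), 1.0, 520.0)
        out = st.force_vs_time([e], TetherModel())
        expected = ewlc_force(500.0)  # 520 nm displacement minus 20 nm offset
        late = out[out.time_s > 1.0]
        assert late.mean_force_pN.iloc[-1] == pytest.approx(expected, rel=0.05)


class TestFractionDriving:
    def test_single_frame_contribution(self):
        roles = np.array([[ROLE_DRIVE], [ROLE_DRIVE], [ROLE_RESIST]])
        out = st.fraction_driving([roles])
        row = out[out.n_attached == 3].iloc[0]
        assert row.fraction_driving == pytest.approx(2 / 3)

    def test_all_drive_gives_one(self):
        roles = np.full((4, 100), ROLE_DRIVE, dtype=np.int8)
        out = st.fraction_driving([roles])
        assert (out.fraction_driving == 1.0).all()

    def test_low_confidence_flag(self):
        roles = np.array([[ROLE_DRIVE] * 10])
        out = st.fraction_driving([roles])
        assert out.iloc[0].low_confidence

    def test_recovers_generator_prior_across_bins(self, events_sim):
        disp = events_sim.displacements()
        events = []
        for k in range(events_sim.n_motors):
            evs, _ = st.analyze_track(disp[k], events_sim.mt_velocity, DT,
                                      kinesin=k)
            events += evs
        roles = st.events_to_role_matrix(events, events_sim.n_motors,
                                         events_sim.time.size, DT)
        out = st.fraction_driving([roles])
        good = out[~out.low_confidence]
        p = EventCalibration().p_drive
        assert ((good.ci_low - 0.08 < p) & (p < good.ci_high + 0.08)).all()


class TestRelativeVelocity:
    def test_stationary_kinesin_sees_cargo_speed(self):
        n = 40
        e = st.MotorEvent(0, "resist", 0.0, DT * n, DT * np.arange(n),
                          np.full(n, 300.0), np.zeros(n), 1.0, 300.0)
        out = st.relative_velocity_curves([e], np.full(n, 830.0), DT)
        assert np.allclose(out.mean_v_rel_nm_s, 830.0, atol=1.0)

    def test_ramp_exceeds_then_matches_cargo_speed(self):
        sim = generate_event_traces(EventCalibration(), n_kinesins=20,
                                    duration=300.0, seed=17)
        disp = sim.displacements()
        events = []
        for k in range(sim.n_motors):
            evs, _ = st.analyze_track(disp[k], sim.mt_velocity, DT, kinesin=k)
            events += evs
        out = st.relative_velocity_curves(events, sim.mt_velocity, DT)
        v_mt = sim.mt_velocity.mean()
        drive = out[out.role == "drive"].sort_values("time_s")
        # early driving relative velocity exceeds the cargo speed
        assert drive.mean_v_rel_nm_s.iloc[0] > v_mt * 1.2
        # late curves of the two roles converge to within 10% of cargo speed
        late = out[(out.time_s > 2.0) & (out.time_s < 5.0) & (out.n >= 8)]
        piv = late.pivot_table(index="time_s", columns="role",
                               values="mean_v_rel_nm_s").dropna()
        assert len(piv) >= 3
        gap = (piv["drive"] - piv["resist"]).abs().mean()
        assert gap < 0.10 * v_mt


@pytest.fixture(scope="module")
def sweep():
    # endpoints of the published density range; anchors in reach scale
    # with surface concentration
    datasets = {}
    for dens, n in ((0.03, 2), (0.46, 10)):
        events, mats = [], []
        for seed in range(3):
            sim = simulate_gliding(
                AssayConfig(motor_count=n, duration=60.0),
                seed=seed, record_interval=0.2)
            disp = sim.displacements()
            for k in range(sim.n_motors):
                evs, _ = st.analyze_track(disp[k], sim.mt_velocity, 0.2,
                                          kinesin=k)
                events += evs
            mats.append(sim.roles)
        datasets[dens] = {"events": events, "roles": mats}
    return datasets


class TestDensitySweep:

    def test_run_length_decreases_with_density(self, sweep):
        out = st.density_sweep(sweep)
        drive = out[out.role == "drive"].sort_values("surface_density")
        assert (drive.mean_run_length_um.iloc[-1]
                < drive.mean_run_length_um.iloc[0])

    def test_engaged_count_non_decreasing(self, sweep):
        out = st.density_sweep(sweep)
        eng = out.groupby("surface_density").mean_engaged_motors.first()
        assert eng.iloc[-1] >= eng.iloc[0]

    def test_single_density_single_condition(self, sweep):
        one = {0.03: sweep[0.03]}
        out = st.density_sweep(one)
        assert (out.surface_density == 0.03).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            st.density_sweep({})
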