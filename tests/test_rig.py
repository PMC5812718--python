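"""Virtual rig: protocol safety, reset semantics, stochastic calibration."""

import numpy as np
import pytest

from multipatch import (
    CalibrationError,
    PipetteSpec,
    ProtocolError,
    TissueModel,
    VirtualRig,
    calibrate_from_counts,
)
from multipatch.rig import (
    CONTACT_CONTACTING,
    CONTACT_NONE,
    GIGASEAL_THRESHOLD_MOHM,
)
from multipatch.states import PressureState


def make_rig(n=1, seed=0, spec=None, **tissue_kwargs):
    return VirtualRig(
        n, pipette_spec=spec or PipetteSpec(), tissue=TissueModel(**tissue_kwargs), seed=seed
    )


class TestDescent:
    def test_elapsed_time_from_descent_speed(self):
        rig = make_rig()
        rig.set_pressure(0, PressureState.HIGH_POSITIVE)
        assert rig.descend_to_depth(0, 400.0) == pytest.approx(2.0)

    def test_descent_without_high_pressure_is_protocol_violation(self):
        rig = make_rig()
        with pytest.raises(ProtocolError):
            rig.descend_to_depth(0, 400.0)

    def test_no_clogs_when_probability_zero(self):
        rig = make_rig(n=1000, spec=PipetteSpec(clog_on_descent_prob=0.0))
        for i in range(1000):
            rig.set_pressure(i, PressureState.HIGH_POSITIVE)
            rig.descend_to_depth(i, 400.0)
        assert not any(p.clogged for p in rig.pipettes)

    def test_clog_fraction_matches_binomial(self):
        p = 31 / 164
        n = 10_000
        rig = make_rig(n=n, seed=5)
        for i in range(n):
            rig.set_pressure(i, PressureState.HIGH_POSITIVE)
            rig.descend_to_depth(i, 400.0)
        frac = sum(q.clogged for q in rig.pipettes) / n
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_clog_raises_measured_resistance_above_threshold(self):
        rig = make_rig(spec=PipetteSpec(clog_on_descent_prob=1.0),
                       measurement_noise_mohm=0.0)
        base = rig.true_resistance(0)
        rig.set_pressure(0, PressureState.HIGH_POSITIVE)
        rig.descend_to_depth(0, 400.0)
        assert rig.true_resistance(0) - base > 0.35


class TestHunting:
    def test_baseline_flat_without_encounters(self):
        rig = make_rig(encounter_hazard_per_step=0.0, measurement_noise_mohm=0.0)
        base = rig.true_resistance(0)
        for _ in range(500):
            rig.hunt_step(0)
        assert rig.true_resistance(0) == pytest.approx(base)
        assert rig.pipettes[0].depth_um == pytest.approx(1000.0)

    def test_contact_ramp_monotone_rise_above_quarter_megohm(self):
        rig = make_rig(encounter_hazard_per_step=0.0,
                       encounter_script=((0, 5),), measurement_noise_mohm=0.0)
        readings = []
        for _ in range(8):
            rig.hunt_step(0)
            readings.append(rig.true_resistance(0))
        post = readings[4:7]  # encounter fires at step 5 -> readings 5,6,7
        assert all(b > a for a, b in zip(post, post[1:]))
        assert post[-1] - readings[3] >= 0.25

    def test_steps_to_encounter_is_geometric(self):
        h, n = 0.05, 10_000
        rig = make_rig(seed=11, encounter_hazard_per_step=h)
        waits = []
        p = rig.pipettes[0]
        for _ in range(n):
            p.contact, p.ramp_progress, p.steps_taken = CONTACT_NONE, 0, 0
            steps = 0
            while p.contact == CONTACT_NONE:
                rig.hunt_step(0)
                steps += 1
            waits.append(steps)
        se = np.sqrt((1 - h) / h**2 / n)
        assert abs(np.mean(waits) - 1 / h) < 3 * se

    def test_motion_forbidden_when_phase_forbids(self):
        rig = make_rig(spec=PipetteSpec(clog_on_descent_prob=1.0))
        rig.set_pressure(0, PressureState.HIGH_POSITIVE)
        rig.descend_to_depth(0, 400.0)
        with pytest.raises(ProtocolError):
            rig.hunt_step(0)  # clogged
        rig2 = make_rig()
        rig2.deactivate(0)
        with pytest.raises(ProtocolError):
            rig2.hunt_step(0)


class TestDislodgement:
    def _rig_with_contact(self, dislodge_prob, seed=0):
        rig = make_rig(n=2, seed=seed,
                       dislodge_prob_per_foreign_move=dislodge_prob,
                       measurement_noise_mohm=0.0)
        p = rig.pipettes[1]
        p.contact = CONTACT_CONTACTING
        p.ramp_progress = 4
        return rig

    def test_zero_probability_retains_all_contacts(self):
        rig = self._rig_with_contact(0.0)
        for _ in range(100):
            assert rig.foreign_movement_perturbation(moving=0) == []

    def test_dislodged_fraction_matches_binomial(self):
        p, n = 10 / 49, 10_000
        rig = self._rig_with_contact(p, seed=3)
        lost = 0
        for _ in range(n):
            rig.pipettes[1].contact = CONTACT_CONTACTING
            lost += len(rig.foreign_movement_perturbation(moving=0))
        assert abs(lost / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_dislodge_resets_measured_resistance_to_baseline(self):
        rig = self._rig_with_contact(1.0)
        baseline = rig.pipettes[1].bare_resistance_mohm
        assert rig.true_resistance(1) > baseline
        rig.foreign_movement_perturbation(moving=0)
        assert rig.true_resistance(1) == pytest.approx(baseline)


def run_schedule_against_rig(rig, i, duration_s=60.0):
    """Drive the published 60-s pressure/voltage program directly."""
    from multipatch import GigasealSchedule

    sched = GigasealSchedule()
    t = 0.0
    while t < duration_s - 1e-9:
        rig.gigaseal_step(i, 1.0, sched.pressure_at(t), sched.voltage_at(t))
        t += 1.0
    return rig.pipettes[i].seal_resistance_mohm


class TestGigaseal:
    def _contacting_rig(self, seed=0, **kw):
        rig = make_rig(seed=seed, measurement_noise_mohm=0.0, **kw)
        p = rig.pipettes[0]
        p.contact = CONTACT_CONTACTING
        p.ramp_progress = 4
        return rig

    def test_success_fated_attempt_crosses_gigaohm_within_60s(self):
        rig = self._contacting_rig(seal_success_base=1.0)
        rig.begin_gigaseal(0, waiting_min=0.0)
        final = run_schedule_against_rig(rig, 0)
        assert final >= GIGASEAL_THRESHOLD_MOHM
        assert rig.end_gigaseal(0)

    def test_failure_fated_attempt_stays_below_100_mohm_rise_at_35s(self):
        rig = self._contacting_rig(seal_success_base=0.0)
        rig.begin_gigaseal(0, waiting_min=0.0)
        r0 = rig.pipettes[0].seal_resistance_mohm
        run_schedule_against_rig(rig, 0, duration_s=35.0)
        assert rig.pipettes[0].seal_resistance_mohm - r0 < 100.0

    def test_success_fraction_matches_binomial_at_zero_wait(self):
        base, n = 77 / 133, 10_000
        rig = self._contacting_rig(seed=9, seal_success_base=base)
        wins = 0
        for _ in range(n):
            rig.begin_gigaseal(0, waiting_min=0.0)
            wins += rig.pipettes[0]._seal_fate
            rig.pipettes[0].sealing = False
            rig.pipettes[0].contact = CONTACT_CONTACTING
        assert abs(wins / n - base) < 3 * np.sqrt(base * (1 - base) / n)

    def test_waiting_monotonically_harms_seal_success(self):
        rig = self._contacting_rig(seed=2, seal_success_base=0.8,
                                   seal_success_decay_per_min_waiting=0.7)
        fracs = []
        for wait in (0.0, 2.0, 5.0):
            wins = 0
            for _ in range(3000):
                rig.begin_gigaseal(0, waiting_min=wait)
                wins += rig.pipettes[0]._seal_fate
                rig.pipettes[0].sealing = False
                rig.pipettes[0].contact = CONTACT_CONTACTING
            fracs.append(wins / 3000)
        assert fracs[0] > fracs[1] > fracs[2]

    def test_gigaseal_on_clogged_pipette_is_protocol_violation(self):
        rig = self._contacting_rig()
        rig.pipettes[0].clogged = True
        with pytest.raises(ProtocolError):
            rig.begin_gigaseal(0)

    def test_dislodged_contact_is_fated_to_fail(self):
        rig = self._contacting_rig(seal_success_base=1.0,
                                   dislodge_prob_per_foreign_move=1.0)
        rig2_contact = rig.pipettes[0]
        rig2_contact.contact = CONTACT_CONTACTING
        rig.foreign_movement_perturbation(moving=None)
        rig.begin_gigaseal(0, waiting_min=0.0)
        final = run_schedule_against_rig(rig, 0)
        assert final < GIGASEAL_THRESHOLD_MOHM


class TestBreakin:
    def _sealed_rig(self, seed=0, **kw):
        rig = make_rig(seed=seed, **kw)
        p = rig.pipettes[0]
        p.gigasealed = True
        p._seal_fate = True
        p.seal_resistance_mohm = 1500.0
        return rig

    def test_certain_pulse_succeeds_first_time(self):
        rig = self._sealed_rig(breakin_success_prob_per_pulse=1.0)
        assert rig.attempt_breakin(0)
        assert rig.last_breakin_pulses == 1
        assert rig.pipettes[0].broken_in

    def test_eventual_success_matches_closed_form(self):
        p_pulse, n_pulses, n = 0.2, 5, 10_000
        expected = 1 - (1 - p_pulse) ** n_pulses
        rig = self._sealed_rig(seed=21, breakin_success_prob_per_pulse=p_pulse)
        wins = 0
        for _ in range(n):
            rig.pipettes[0].broken_in = False
            rig.pipettes[0].membrane = None
            wins += rig.attempt_breakin(0, max_pulses=n_pulses)
        assert abs(wins / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_breakin_without_gigaseal_is_protocol_violation(self):
        rig = make_rig()
        with pytest.raises(ProtocolError):
            rig.attempt_breakin(0)

    def test_default_per_pulse_probability_gives_printed_attempt_rate(self):
        tissue = TissueModel()
        attempt = 1 - (1 - tissue.breakin_success_prob_per_pulse) ** tissue.breakin_max_pulses
        assert attempt == pytest.approx(52 / 77)


class TestCalibration:
    def test_ml_proportions_from_counts(self):
        res = calibrate_from_counts({"clog": (31, 164), "seal": (77, 133),
                                     "breakin": (52, 77)})
        assert res.proportions["seal"].estimate == pytest.approx(77 / 133)
        assert res.tissue.seal_success_base == pytest.approx(77 / 133)
        attempt = 1 - (1 - res.tissue.breakin_success_prob_per_pulse) ** 10
        assert attempt == pytest.approx(52 / 77)
        lo, hi = res.proportions["clog"].ci_low, res.proportions["clog"].ci_high
        assert lo < 31 / 164 < hi

    def test_certain_stage(self):
        res = calibrate_from_counts({"seal": (20, 20)})
        assert res.proportions["seal"].estimate == 1.0

    def test_zero_attempts_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_from_counts({"seal": (0, 0)})
        with pytest.raises(CalibrationError):
            calibrate_from_counts({"seal": (5, 4)})

    def test_binomial_draw_recovery_coverage(self, rng):
        """Wilson CIs cover the generating probabilities >=93% of the time."""
        truth = {"clog": 31 / 164, "seal": 77 / 133, "breakin": 52 / 77}
        ns = {"clog": 164, "seal": 133, "breakin": 77}
        hits = {k: 0 for k in truth}
        reps = 200
        for _ in range(reps):
            counts = {k: (int(rng.binomial(ns[k], truth[k])), ns[k]) for k in truth}
            res = calibrate_from_counts(counts)
            for k in truth:
                p = res.proportions[k]
                hits[k] += p.ci_low <= truth[k] <= p.ci_high
        for k, n_hit in hits.items():
            assert n_hit / reps >= 0.93, k
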