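"""The multipatcher control algorithm.

A trial drives up to four pipettes through a common prologue — bath
quality control (3–9 MΩ acceptance window), concurrent descent to target
depth under high positive pressure, and regional localization (a >0.35 MΩ
rise versus the bath reading deactivates a clogged tip) — and then one of
three coordination strategies for the hunting/gigasealing stages:

``SYNC_ALL``
    Pipettes hunt independently; each detection deactivates that motor
    while the rest keep hunting; when all have contacts, gigasealing runs
    simultaneously in every pipette, then synchronous break-in.  Held
    contacts are exposed to dislodgement by the others' movement and to
    the deleterious effect of waiting.

``RETRACT_REPLAY``
    As above, but each detecting pipette retracts 30 µm and parks; when
    all are parked, every pipette advances 30 µm simultaneously (the
    "replay"), then synchronous gigasealing and break-in.  Recontact on
    the replay is stochastic.

``INTERLEAVED``
    All pipettes hunt in lock-step 2-µm steps; on any detection every
    motor halts, the single detecting pipette runs its 60-s gigaseal
    schedule, and the rest then resume.  Gigasealed pipettes are held at
    −70 mV (immune to later motion) until a final simultaneous break-in.

The gigasealing attempt follows a fixed 60-s pressure/voltage program;
see :class:`GigasealSchedule`.
"""

from __future__ import annotations

import enum
import json
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ProtocolError
from .rig import GIGASEAL_THRESHOLD_MOHM, VirtualRig
from .states import ALLOWED_TRANSITIONS, PipettePhase, PressureState, check_transition

__all__ = [
    "AlgorithmVariant",
    "GigasealSchedule",
    "ControllerEvent",
    "TrialParams",
    "qc_check",
    "regional_localization",
    "detect_neuron",
    "run_trial",
]


class AlgorithmVariant(enum.Enum):
    SYNC_ALL = "sync_all"
    RETRACT_REPLAY = "retract_replay"
    INTERLEAVED = "interleaved"


@dataclass(frozen=True)
class GigasealSchedule:
    """The timed pressure/voltage program of one gigasealing attempt.

    Steps: (1) hold low positive pressure 10 s to confirm contact,
    (2) atmospheric 5 s, (3) low suction 10 s to form the seal,
    (4) back to atmospheric with an instantaneous switch of the holding
    potential to −35 mV, (5) linear ramp to −70 mV over 30 s,
    (6) hold 5 s.  Total 60 s; the holding voltage is non-increasing
    from step 4 onward.
    """

    confirm_s: float = 10.0
    atmospheric_s: float = 5.0
    suction_s: float = 10.0
    ramp_s: float = 30.0
    final_hold_s: float = 5.0
    ramp_start_mv: float = -35.0
    ramp_end_mv: float = -70.0

    @property
    def total_s(self) -> float:
        return (
            self.confirm_s
            + self.atmospheric_s
            + self.suction_s
            + self.ramp_s
            + self.final_hold_s
        )

    @property
    def ramp_onset_s(self) -> float:
        return self.confirm_s + self.atmospheric_s + self.suction_s

    def pressure_at(self, t_s: float) -> PressureState:
        if t_s < self.confirm_s:
            return PressureState.LOW_POSITIVE
        if t_s < self.confirm_s + self.atmospheric_s:
            return PressureState.ATMOSPHERIC
        if t_s < self.ramp_onset_s:
            return PressureState.LOW_SUCTION
        return PressureState.ATMOSPHERIC

    def voltage_at(self, t_s: float) -> float:
        """Holding potential (mV) at schedule time ``t_s``."""
        if t_s < self.ramp_onset_s:
            return 0.0
        u = t_s - self.ramp_onset_s
        if u >= self.ramp_s:
            return self.ramp_end_mv
        return self.ramp_start_mv + (u / self.ramp_s) * (self.ramp_end_mv - self.ramp_start_mv)


class EventType(enum.Enum):
    QC_PASS = "QC_PASS"
    QC_FAIL = "QC_FAIL"
    CLOG_DEACTIVATED = "CLOG_DEACTIVATED"
    STEP = "STEP"
    DETECT = "DETECT"
    HALT_ALL = "HALT_ALL"
    SEAL_START = "SEAL_START"
    SEAL_OK = "SEAL_OK"
    SEAL_FAIL = "SEAL_FAIL"
    SEAL_ABORTED = "SEAL_ABORTED"
    RESUME = "RESUME"
    BREAKIN_START = "BREAKIN_START"
    BREAKIN_OK = "BREAKIN_OK"
    BREAKIN_FAIL = "BREAKIN_FAIL"


@dataclass(frozen=True)
class ControllerEvent:
    """One audit-log entry; serialized as a JSON line with fixed field order."""

    t: float
    pipette: int
    event: EventType
    detail: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {"t": round(self.t, 6), "pipette": self.pipette,
             "event": self.event.value, "detail": self.detail}
        )

    @classmethod
    def from_json(cls, line: str) -> "ControllerEvent":
        d = json.loads(line)
        return cls(d["t"], d["pipette"], EventType(d["event"]), d.get("detail", ""))


@dataclass(frozen=True)
class TrialParams:
    """Controller-side tunables (schedule, thresholds, cadence)."""

    schedule: GigasealSchedule = field(default_factory=GigasealSchedule)
    qc_range_mohm: tuple[float, float] = (3.0, 9.0)
    localization_threshold_mohm: float = 0.35
    detect_rise_mohm: float = 0.25
    detect_monotonic_tol_mohm: float = 0.01
    step_um: float = 2.0
    step_measure_s: float = 0.5
    localization_s: float = 1.0
    max_hunt_um: float = 600.0
    retract_um: float = 30.0
    abort_policy: bool = False
    abort_check_s: float = 35.0
    abort_delta_mohm: float = 100.0
    breakin_delay_s: float = 0.0
    breakin_pulse_s: float = 0.1
    seal_dt_s: float = 1.0
    record_steps: bool = True


# -- pure decision rules -------------------------------------------------------


def qc_check(measured_r_mohm: float, qc_range: tuple[float, float] = (3.0, 9.0)) -> bool:
    """Bath QC: accept iff resistance lies in the inclusive 3–9 MΩ window."""
    lo, hi = qc_range
    return lo <= measured_r_mohm <= hi


def regional_localization(
    surface_r_mohm: float, depth_r_mohm: float, threshold_mohm: float = 0.35
) -> bool:
    """True = keep hunting; False = tip blocked or fouled (strict > threshold)."""
    return not (depth_r_mohm - surface_r_mohm > threshold_mohm)


def detect_neuron(
    history: Sequence[float],
    rise_mohm: float = 0.25,
    monotonic_tol_mohm: float = 0.01,
) -> bool:
    """Contact detector on the last four averaged resistance readings.

    Fires iff the three consecutive step-to-step changes are each above
    ``-monotonic_tol_mohm`` (monotone up to measurement noise) and the
    cumulative rise over the three steps strictly exceeds ``rise_mohm``.
    Returns False (not an error) on insufficient history.
    """
    if len(history) < 4:
        return False
    h = list(history)[-4:]
    diffs = [h[k + 1] - h[k] for k in range(3)]
    if any(d <= -monotonic_tol_mohm for d in diffs):
        return False
    return (h[3] - h[0]) > rise_mohm


# -- trial runner ---------------------------------------------------------------


class _Pipette:
    """Controller-visible bookkeeping for one pipette."""

    def __init__(self, idx: int):
        self.idx = idx
        self.phase = PipettePhase.INSTALLED
        self.baseline_mohm: float | None = None
        self.history: deque[float] = deque(maxlen=4)
        self.detect_time_s: float | None = None
        self.seal_start_s: float | None = None
        self.seal_elapsed_s: float = 0.0
        self.lost_while_waiting = False
        self.dislodge_pending = False

    def set_phase(self, new: PipettePhase) -> None:
        check_transition(self.phase, new)
        self.phase = new


class TrialController:
    """Runs one multipatching trial of a given variant against a rig."""

    def __init__(
        self,
        variant: AlgorithmVariant,
        rig: VirtualRig,
        depths_um: Sequence[float],
        params: TrialParams | None = None,
    ):
        if not isinstance(variant, AlgorithmVariant):
            raise ValueError(f"unknown algorithm variant: {variant!r}")
        if len(depths_um) != len(rig.pipettes):
            raise ValueError("one target depth per pipette required")
        self.variant = variant
        self.rig = rig
        self.depths = list(depths_um)
        self.p = params or TrialParams()
        self.events: list[ControllerEvent] = []
        self.pipettes = [_Pipette(i) for i in range(len(rig.pipettes))]
        self.timings = {"descent_s": 0.0, "hunt_s": 0.0, "seal_s_total": 0.0, "total_s": 0.0}

    # -- logging helpers --

    def log(self, pipette: int, ev: EventType, detail: str = "") -> None:
        self.events.append(ControllerEvent(self.rig.t, pipette, ev, detail))

    # -- stages --

    def _qc_and_descend(self) -> None:
        rig, p = self.rig, self.p
        for pip in self.pipettes:
            r = rig.measure(pip.idx)
            pip.baseline_mohm = r
            if qc_check(r, p.qc_range_mohm):
                pip.set_phase(PipettePhase.LOCALIZING)
                self.log(pip.idx, EventType.QC_PASS, f"R={r:.2f}MΩ")
            else:
                pip.set_phase(PipettePhase.QC_FAILED)
                rig.deactivate(pip.idx)
                self.log(pip.idx, EventType.QC_FAIL, f"R={r:.2f}MΩ")
        elapsed = 0.0
        for pip in self.pipettes:
            if pip.phase is PipettePhase.LOCALIZING:
                rig.set_pressure(pip.idx, PressureState.HIGH_POSITIVE)
                elapsed = max(elapsed, rig.descend_to_depth(pip.idx, self.depths[pip.idx]))
        rig.advance(elapsed)
        self.timings["descent_s"] = elapsed

    def _localize(self) -> None:
        rig, p = self.rig, self.p
        rig.advance(p.localization_s)
        for pip in self.pipettes:
            if pip.phase is not PipettePhase.LOCALIZING:
                continue
            rig.set_pressure(pip.idx, PressureState.LOW_POSITIVE)
            depth_r = rig.measure(pip.idx)
            if regional_localization(pip.baseline_mohm, depth_r, p.localization_threshold_mohm):
                pip.set_phase(PipettePhase.HUNTING)
                pip.history.append(depth_r)
            else:
                rig.set_pressure(pip.idx, PressureState.ATMOSPHERIC)
                rig.deactivate(pip.idx)
                pip.set_phase(PipettePhase.DEACTIVATED_CLOGGED)
                self.log(
                    pip.idx, EventType.CLOG_DEACTIVATED,
                    f"ΔR={depth_r - pip.baseline_mohm:.2f}MΩ",
                )

    def _hunting_pipettes(self) -> list[_Pipette]:
        return [q for q in self.pipettes if q.phase is PipettePhase.HUNTING]

    def _held_contacts(self) -> list[_Pipette]:
        """Pipettes holding an unsealed contact, exposed to foreign motion."""
        return [
            q
            for q in self.pipettes
            if q.phase is PipettePhase.HALTED and q.detect_time_s is not None
        ]

    def _apply_movement_episode(self) -> None:
        """Close one movement episode: dislodgement risk for held contacts."""
        holders = self._held_contacts()
        if not holders:
            return
        lost = self.rig.foreign_movement_perturbation()
        for j in lost:
            self.pipettes[j].lost_while_waiting = True

    def _hunt_cycle(self) -> list[_Pipette]:
        """One synchronized step+measure cycle; returns pipettes that detected."""
        rig, p = self.rig, self.p
        hunters = self._hunting_pipettes()
        rig.advance(p.step_measure_s)
        self.timings["hunt_s"] += p.step_measure_s
        detections = []
        max_steps = int(p.max_hunt_um / p.step_um)
        for pip in hunters:
            rig.hunt_step(pip.idx, p.step_um)
            if p.record_steps:
                self.log(pip.idx, EventType.STEP, f"depth={rig.pipettes[pip.idx].depth_um:.0f}µm")
            pip.history.append(rig.measure(pip.idx))
            if detect_neuron(list(pip.history), p.detect_rise_mohm, p.detect_monotonic_tol_mohm):
                detections.append(pip)
            elif rig.pipettes[pip.idx].steps_taken >= max_steps:
                pip.set_phase(PipettePhase.LOST)
                rig.deactivate(pip.idx)
                self.log(pip.idx, EventType.SEAL_FAIL, "max hunting depth, no neuron")
        return detections

    # -- gigasealing --

    def _run_schedules(self, pips: list[_Pipette]) -> None:
        """Execute the 60-s schedule on ``pips`` with shared timestamps."""
        rig, p = self.rig, self.p
        sched = p.schedule
        now = rig.t
        r0: dict[int, float] = {}
        for pip in pips:
            waiting_min = 0.0
            if pip.detect_time_s is not None:
                waiting_min = max(0.0, (now - pip.detect_time_s) / 60.0)
            rig.begin_gigaseal(pip.idx, waiting_min)
            pip.set_phase(PipettePhase.GIGASEALING)
            pip.seal_start_s = now
            r0[pip.idx] = rig.pipettes[pip.idx].seal_resistance_mohm
            self.log(pip.idx, EventType.SEAL_START, f"wait={waiting_min:.2f}min")
        active = list(pips)
        t_local = 0.0
        current_pressure: PressureState | None = None
        while t_local < sched.total_s - 1e-9 and active:
            pressure = sched.pressure_at(t_local)
            if pressure is not current_pressure:
                for pip in active:
                    rig.set_pressure(pip.idx, pressure)
                current_pressure = pressure
            voltage = sched.voltage_at(t_local)
            dt = min(p.seal_dt_s, sched.total_s - t_local)
            for pip in active:
                rig.gigaseal_step(pip.idx, dt, pressure, voltage)
            rig.advance(dt)
            t_local += dt
            if p.abort_policy and abs(t_local - p.abort_check_s) < 1e-9:
                for pip in list(active):
                    delta = rig.pipettes[pip.idx].seal_resistance_mohm - r0[pip.idx]
                    if delta < p.abort_delta_mohm:
                        rig.set_pressure(pip.idx, PressureState.ATMOSPHERIC)
                        rig.end_gigaseal(pip.idx)
                        rig.deactivate(pip.idx)
                        pip.seal_elapsed_s = t_local
                        pip.set_phase(PipettePhase.SEAL_FAILED)
                        self.log(pip.idx, EventType.SEAL_ABORTED, f"ΔR={delta:.0f}MΩ at {t_local:.0f}s")
                        active.remove(pip)
        for pip in active:
            ok = rig.end_gigaseal(pip.idx)
            rig.deactivate(pip.idx)  # motor off for the rest of the trial
            pip.seal_elapsed_s = sched.total_s
            if ok:
                pip.set_phase(PipettePhase.GIGASEALED_HELD)
                self.log(pip.idx, EventType.SEAL_OK,
                         f"R={rig.pipettes[pip.idx].seal_resistance_mohm:.0f}MΩ")
            else:
                pip.set_phase(PipettePhase.SEAL_FAILED)
                self.log(pip.idx, EventType.SEAL_FAIL,
                         f"R={rig.pipettes[pip.idx].seal_resistance_mohm:.0f}MΩ")
        self.timings["seal_s_total"] += sum(q.seal_elapsed_s for q in pips)

    def _breakin_all(self) -> None:
        rig, p = self.rig, self.p
        sealed = [q for q in self.pipettes if q.phase is PipettePhase.GIGASEALED_HELD]
        if not sealed:
            return
        if p.breakin_delay_s > 0:
            rig.advance(p.breakin_delay_s)
        max_pulses_used = 0
        for pip in sealed:
            pip.set_phase(PipettePhase.BREAKING_IN)
            self.log(pip.idx, EventType.BREAKIN_START)
            ok = rig.attempt_breakin(pip.idx, p.breakin_pulse_s)
            max_pulses_used = max(max_pulses_used, rig.last_breakin_pulses)
            if ok:
                pip.set_phase(PipettePhase.WHOLE_CELL)
                self.log(pip.idx, EventType.BREAKIN_OK,
                         f"pulses={rig.last_breakin_pulses}")
            else:
                pip.set_phase(PipettePhase.GIGASEALED_HELD)
                self.log(pip.idx, EventType.BREAKIN_FAIL,
                         f"pulses={rig.last_breakin_pulses}")
        rig.advance(max_pulses_used * p.breakin_pulse_s)

    # -- variant main loops --

    def _run_interleaved(self) -> None:
        rig = self.rig
        while self._hunting_pipettes():
            detections = self._hunt_cycle()
            if not detections:
                continue
            # Halt everything; seal detectors one at a time, lowest index first.
            self.log(detections[0].idx, EventType.HALT_ALL,
                     f"detected by pipette {detections[0].idx}")
            self._apply_movement_episode()
            for pip in self.pipettes:
                if pip.phase is PipettePhase.HUNTING:
                    pip.set_phase(PipettePhase.HALTED)
            for pip in sorted(detections, key=lambda q: q.idx):
                pip.detect_time_s = rig.t
                rig.hold_contact(pip.idx)
                self.log(pip.idx, EventType.DETECT,
                         f"R={pip.history[-1]:.2f}MΩ" if pip.history else "")
                self._run_schedules([pip])
            for pip in self.pipettes:
                if pip.phase is PipettePhase.HALTED:
                    pip.set_phase(PipettePhase.HUNTING)
                    self.log(pip.idx, EventType.RESUME)
        self._breakin_all()

    def _run_sync_all(self) -> None:
        rig = self.rig
        bout_open = False  # movement occurred since the last episode close
        while self._hunting_pipettes():
            detections = self._hunt_cycle()
            if bout_open and detections:
                # the bout that just ended exposed previously held contacts
                self._apply_movement_episode()
                bout_open = False
            for pip in detections:
                pip.detect_time_s = rig.t
                rig.hold_contact(pip.idx)
                rig.deactivate(pip.idx)
                pip.set_phase(PipettePhase.HALTED)
                self.log(pip.idx, EventType.DETECT, f"R={pip.history[-1]:.2f}MΩ")
            if self._hunting_pipettes() and self._held_contacts():
                bout_open = True
        if bout_open:
            self._apply_movement_episode()
        holders = self._held_contacts()
        if holders:
            self._run_schedules(holders)
        self._breakin_all()

    def _run_retract_replay(self) -> None:
        rig, p = self.rig, self.p
        parked: list[_Pipette] = []
        while self._hunting_pipettes():
            detections = self._hunt_cycle()
            for pip in detections:
                pip.detect_time_s = rig.t
                rig.retract(pip.idx, p.retract_um)
                pip.set_phase(PipettePhase.HALTED)
                parked.append(pip)
                self.log(pip.idx, EventType.DETECT,
                         f"retract {p.retract_um:.0f}µm")
        if parked:
            # simultaneous replay advance of all parked pipettes
            rig.advance(p.step_measure_s)
            recontacted = 0
            for pip in parked:
                if rig.replay_advance(pip.idx, p.retract_um):
                    recontacted += 1
            self.log(parked[0].idx, EventType.HALT_ALL,
                     f"replay advance, {recontacted}/{len(parked)} recontacted")
            self._run_schedules(parked)
        self._breakin_all()

    # -- entry point --

    def run(self):
        from .campaign import PipetteOutcome, TrialRecord  # local import, no cycle at module load

        self._qc_and_descend()
        self._localize()
        if self.variant is AlgorithmVariant.INTERLEAVED:
            self._run_interleaved()
        elif self.variant is AlgorithmVariant.SYNC_ALL:
            self._run_sync_all()
        else:
            self._run_retract_replay()
        self.timings["total_s"] = self.rig.t
        outcomes = []
        for pip in self.pipettes:
            rp = self.rig.pipettes[pip.idx]
            outcomes.append(
                PipetteOutcome(
                    qc=pip.phase is not PipettePhase.QC_FAILED,
                    clogged=pip.phase is PipettePhase.DEACTIVATED_CLOGGED,
                    hunted=pip.phase
                    not in (PipettePhase.QC_FAILED, PipettePhase.DEACTIVATED_CLOGGED),
                    detected=pip.detect_time_s is not None,
                    sealed=rp.gigasealed or rp.broken_in,
                    whole_cell=rp.broken_in,
                    seal_wait_min=(
                        (pip.seal_start_s - pip.detect_time_s) / 60.0
                        if pip.seal_start_s is not None and pip.detect_time_s is not None
                        else 0.0
                    ),
                    lost_while_waiting=pip.lost_while_waiting,
                    quality=rp.membrane,
                )
            )
        return TrialRecord(
            trial_id=0,
            variant=self.variant.value,
            pipettes=outcomes,
            timings=dict(self.timings),
            events=[e for e in self.events],
        )


def run_trial(
    variant: AlgorithmVariant | str,
    rig: VirtualRig,
    depths_um: Sequence[float] | None = None,
    params: TrialParams | None = None,
):
    """Run one multipatching trial; returns a ``TrialRecord``.

    ``depths_um`` defaults to 400 µm for every pipette (cortical layer 4
    territory for the craniotomy geometry the rig emulates).
    """
    if isinstance(variant, str):
        try:
            variant = AlgorithmVariant(variant)
        except ValueError as exc:
            raise ValueError(f"unknown algorithm variant: {variant!r}") from exc
    depths = list(depths_um) if depths_um is not None else [400.0] * len(rig.pipettes)
    return TrialController(variant, rig, depths, params).run()
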