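"""Virtual rig: ground-truth stochastic model of pipettes in brain tissue.

This is the synthetic substrate every controller test runs against.  It
models the statistical structure the robot has to cope with in vivo:

* tip clogging during the high-pressure descent to depth;
* geometric waiting (per 2-µm step) for a neuron encounter during
  hunting, followed by a monotone resistance ramp on approach;
* dislodgement of held (not yet sealed) contacts when *other* pipettes
  move in the tissue;
* degradation of gigaseal success probability with waiting time, as the
  neuron is continuously exposed to ejected intracellular solution;
* saturating gigaseal resistance growth to >1 GΩ under suction and
  hyperpolarization, and suction-pulse break-in.

The rig owns the simulated clock and a single seeded random generator;
all stochastic draws consume it in the order the controller invokes
them, so a trial is bit-reproducible for a fixed seed.  The controller
never reads ground truth directly — only noisy averaged resistance
measurements via :meth:`VirtualRig.measure`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import CalibrationError, ProtocolError
from .states import PressureState

__all__ = [
    "PipetteSpec",
    "TissueModel",
    "RigState",
    "VirtualRig",
    "StageProportion",
    "CalibrationResult",
    "calibrate_from_counts",
]

#: Published stage counts used for the default calibration.
DEFAULT_STAGE_COUNTS: dict[str, tuple[int, int]] = {
    "clog": (31, 164),
    "seal": (77, 133),
    "breakin": (52, 77),
    "dislodge": (10, 49),
    "recontact": (27, 59),
}

GIGASEAL_THRESHOLD_MOHM = 1000.0
DESCENT_SPEED_UM_PER_S = 200.0


@dataclass(frozen=True)
class PipetteSpec:
    """Fabrication and failure characteristics of the pipettes.

    Bare tip resistances are drawn uniformly from ``bare_resistance_range``
    (fabrication range 5–9 MΩ; the controller's QC acceptance window is
    the wider 3–9 MΩ).  A clog acquired on descent raises the measured
    resistance by ``clog_resistance_increment_mohm`` — above the 0.35 MΩ
    detection threshold so the localization check can fire.
    """

    bare_resistance_range: tuple[float, float] = (5.0, 9.0)
    clog_on_descent_prob: float = 31 / 164
    clog_resistance_increment_mohm: float = 0.6

    def __post_init__(self) -> None:
        lo, hi = self.bare_resistance_range
        if not (0 < lo <= hi):
            raise ValueError("invalid bare resistance range")
        if not 0 <= self.clog_on_descent_prob <= 1:
            raise ValueError("clog probability outside [0, 1]")
        if self.clog_resistance_increment_mohm <= 0.35:
            raise ValueError("clog increment must exceed the 0.35 MΩ detection threshold")


@dataclass(frozen=True)
class TissueModel:
    """Stochastic tissue parameters.

    Defaults are the package's calibration to the published stage counts
    (probabilities as maximum-likelihood proportions) plus choices for
    quantities the counts do not pin down (hazard, ramp shape, growth
    timescale); see the methods note.
    """

    encounter_hazard_per_step: float = 1.0 / 150.0
    contact_ramp_mohm_per_step: float = 0.15
    contact_ramp_steps: int = 4
    dislodge_prob_per_foreign_move: float = 10 / 49
    seal_success_base: float = 77 / 133
    seal_success_decay_per_min_waiting: float = 0.66
    replay_recontact_prob: float = 27 / 59
    breakin_success_prob_per_pulse: float = 1.0 - (1.0 - 52 / 77) ** (1.0 / 10.0)
    breakin_max_pulses: int = 10
    seal_growth_timescale_s: float = 12.0
    seal_target_mohm: float = 1500.0
    failed_seal_delta_mohm: float = 80.0
    failed_seal_timescale_s: float = 30.0
    measurement_noise_mohm: float = 0.045
    #: Deterministic encounter script for tests: pipette index -> step number
    #: (1-based) at which contact begins. Overrides the hazard when set.
    encounter_script: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        for name in (
            "encounter_hazard_per_step",
            "dislodge_prob_per_foreign_move",
            "seal_success_base",
            "replay_recontact_prob",
            "breakin_success_prob_per_pulse",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= self.seal_success_decay_per_min_waiting <= 1.0:
            raise ValueError("waiting decay must be a multiplicative factor in [0, 1]")
        if self.contact_ramp_mohm_per_step * 3 < 0.25:
            raise ValueError("contact ramp too shallow to trip the 0.25 MΩ / 3-step detector")

    def scripted_step(self, pipette: int) -> int | None:
        if self.encounter_script is None:
            return None
        for pid, step in self.encounter_script:
            if pid == pipette:
                return step
        return None


# Contact life cycle of a pipette tip in tissue.
CONTACT_NONE = "none"
CONTACT_APPROACHING = "approaching"
CONTACT_CONTACTING = "contacting"
CONTACT_DISLODGED = "dislodged"
CONTACT_RETRACTED = "retracted"  # neuron position remembered, tip pulled back


@dataclass
class RigState:
    """Ground truth for one pipette (invisible to the controller)."""

    bare_resistance_mohm: float
    depth_um: float = 0.0
    pressure: PressureState = PressureState.ATMOSPHERIC
    contact: str = CONTACT_NONE
    seal_resistance_mohm: float = 0.0
    clogged: bool = False
    broken_in: bool = False
    gigasealed: bool = False
    motor_active: bool = True
    steps_taken: int = 0
    ramp_progress: int = 0
    contact_time_s: float | None = None
    sealing: bool = False
    _seal_fate: bool | None = None
    membrane: dict | None = None

    def baseline_mohm(self, spec: PipetteSpec) -> float:
        r = self.bare_resistance_mohm
        if self.clogged:
            r += spec.clog_resistance_increment_mohm
        return r


class VirtualRig:
    """Simulated four-pipette rig with a shared clock and seeded RNG."""

    def __init__(
        self,
        n_pipettes: int = 4,
        pipette_spec: PipetteSpec | None = None,
        tissue: TissueModel | None = None,
        seed: int | np.random.Generator | None = None,
    ):
        if n_pipettes < 1:
            raise ValueError("need at least one pipette")
        self.spec = pipette_spec or PipetteSpec()
        self.tissue = tissue or TissueModel()
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.t = 0.0
        self.last_breakin_pulses = 0
        lo, hi = self.spec.bare_resistance_range
        self.pipettes = [
            RigState(bare_resistance_mohm=float(self.rng.uniform(lo, hi)))
            for _ in range(n_pipettes)
        ]
        for p in self.pipettes:
            p.seal_resistance_mohm = p.bare_resistance_mohm

    # -- clock ---------------------------------------------------------------

    def advance(self, dt_s: float) -> None:
        """Advance the clock; held gigaseals keep maturing at −70 mV hold."""
        if dt_s < 0:
            raise ValueError("cannot advance the clock backwards")
        self.t += dt_s
        for p in self.pipettes:
            if p.gigasealed and not p.broken_in:
                self._grow_seal(p, dt_s, active=True)

    # -- measurement ---------------------------------------------------------

    def true_resistance(self, i: int) -> float:
        """Noise-free resistance the seal test would report for pipette ``i``."""
        p = self.pipettes[i]
        if p.sealing or p.gigasealed:
            return p.seal_resistance_mohm
        r = p.baseline_mohm(self.spec)
        if p.contact in (CONTACT_APPROACHING, CONTACT_CONTACTING):
            steps = min(p.ramp_progress, self.tissue.contact_ramp_steps)
            r += steps * self.tissue.contact_ramp_mohm_per_step
        return r

    def measure(self, i: int, n_avg: int = 5) -> float:
        """Averaged resistance reading (MΩ): truth plus averaged seal-test noise."""
        sigma = self.tissue.measurement_noise_mohm / math.sqrt(n_avg)
        return self.true_resistance(i) + float(self.rng.normal(0.0, sigma))

    def set_pressure(self, i: int, state: PressureState) -> None:
        self.pipettes[i].pressure = state

    # -- descent & localization ----------------------------------------------

    def descend_to_depth(self, i: int, target_depth_um: float) -> float:
        """Lower pipette ``i`` to depth at ~200 µm/s under high positive pressure.

        Returns the elapsed time (s); the caller advances the shared clock
        (descents of several pipettes run concurrently).  With probability
        ``clog_on_descent_prob`` the tip clogs, raising its measured
        resistance by the clog increment.
        """
        p = self.pipettes[i]
        if p.pressure is not PressureState.HIGH_POSITIVE:
            raise ProtocolError("descent requires HIGH_POSITIVE pressure")
        if target_depth_um <= 0:
            raise ValueError("target depth must be > 0")
        p.depth_um = target_depth_um
        if self.rng.random() < self.spec.clog_on_descent_prob:
            p.clogged = True
        p.seal_resistance_mohm = p.baseline_mohm(self.spec)
        return target_depth_um / DESCENT_SPEED_UM_PER_S

    def deactivate(self, i: int) -> None:
        p = self.pipettes[i]
        p.motor_active = False

    # -- neuron hunting --------------------------------------------------------

    def hunt_step(self, i: int, step_um: float = 2.0) -> None:
        """Advance one hunting step; may start a neuron encounter.

        An encounter fires as a Bernoulli trial per step (or at the
        scripted step in deterministic tests); once approaching, the
        measured resistance ramps up monotonically over the next
        ``contact_ramp_steps`` steps.  A contact that ramps out without
        the controller halting is stepped past and lost.
        """
        p = self.pipettes[i]
        if not p.motor_active:
            raise ProtocolError("hunt step on a deactivated motor")
        if p.clogged:
            raise ProtocolError("hunt step on a clogged pipette")
        if p.sealing or p.gigasealed:
            raise ProtocolError("hunt step during a gigaseal")
        p.depth_um += step_um
        p.steps_taken += 1
        if p.contact == CONTACT_NONE:
            scripted = self.tissue.scripted_step(i)
            if scripted is not None:
                fire = p.steps_taken == scripted
            else:
                fire = self.rng.random() < self.tissue.encounter_hazard_per_step
            if fire:
                p.contact = CONTACT_APPROACHING
                p.ramp_progress = 1
                p.contact_time_s = self.t
        elif p.contact == CONTACT_APPROACHING:
            p.ramp_progress += 1
            if p.ramp_progress >= self.tissue.contact_ramp_steps:
                p.contact = CONTACT_CONTACTING
        elif p.contact == CONTACT_CONTACTING:
            p.ramp_progress += 1
            if p.ramp_progress > self.tissue.contact_ramp_steps + 2:
                # stepped past the neuron without halting
                p.contact = CONTACT_NONE
                p.ramp_progress = 0
                p.contact_time_s = None

    def hold_contact(self, i: int) -> None:
        """Freeze the approach ramp when the controller halts on detection."""
        p = self.pipettes[i]
        if p.contact in (CONTACT_APPROACHING, CONTACT_CONTACTING):
            p.contact = CONTACT_CONTACTING

    # -- inter-pipette mechanical coupling -------------------------------------

    def foreign_movement_perturbation(self, moving: int | None = None) -> list[int]:
        """Apply one movement episode's dislodgement risk to held contacts.

        Every held, not-yet-sealing contact (other than the moving
        pipette's own) is lost with ``dislodge_prob_per_foreign_move``;
        on loss the measured resistance returns exactly to the
        pre-contact baseline.  Returns the dislodged pipette indices.
        """
        lost = []
        for j, p in enumerate(self.pipettes):
            if j == moving:
                continue
            if p.contact == CONTACT_CONTACTING and not (p.sealing or p.gigasealed):
                if self.rng.random() < self.tissue.dislodge_prob_per_foreign_move:
                    p.contact = CONTACT_DISLODGED
                    p.ramp_progress = 0
                    lost.append(j)
        return lost

    # -- retract / replay (iteration-2 mechanics) -------------------------------

    def retract(self, i: int, distance_um: float = 30.0) -> None:
        p = self.pipettes[i]
        if p.contact not in (CONTACT_APPROACHING, CONTACT_CONTACTING):
            raise ProtocolError("retract without a contact to remember")
        p.depth_um -= distance_um
        p.contact = CONTACT_RETRACTED
        p.ramp_progress = 0

    def replay_advance(self, i: int, distance_um: float = 30.0) -> bool:
        """Advance back onto a remembered neuron; recontact is stochastic."""
        p = self.pipettes[i]
        if p.contact != CONTACT_RETRACTED:
            raise ProtocolError("replay advance without a remembered contact")
        p.depth_um += distance_um
        if self.rng.random() < self.tissue.replay_recontact_prob:
            p.contact = CONTACT_CONTACTING
            p.ramp_progress = self.tissue.contact_ramp_steps
            return True
        p.contact = CONTACT_NONE
        return False

    # -- gigasealing ------------------------------------------------------------

    def begin_gigaseal(self, i: int, waiting_min: float = 0.0) -> None:
        """Start a gigasealing attempt; the attempt's fate is drawn once here.

        Success probability is ``seal_success_base * decay**waiting_min``;
        a dislodged or absent contact is fated to fail outright.  Seal
        success is therefore non-increasing in waiting time for any
        decay factor <= 1.
        """
        p = self.pipettes[i]
        if p.clogged:
            raise ProtocolError("gigaseal attempt on a clogged pipette")
        if p.sealing or p.gigasealed:
            raise ProtocolError("gigaseal attempt already active")
        if waiting_min < 0:
            raise ValueError("waiting time must be >= 0")
        if p.contact == CONTACT_CONTACTING:
            prob = self.tissue.seal_success_base * (
                self.tissue.seal_success_decay_per_min_waiting ** waiting_min
            )
            p._seal_fate = bool(self.rng.random() < prob)
        else:
            p._seal_fate = False
        p.sealing = True
        p.seal_resistance_mohm = self.true_resistance_pre_seal(i)

    def true_resistance_pre_seal(self, i: int) -> float:
        p = self.pipettes[i]
        r = p.baseline_mohm(self.spec)
        if p.contact in (CONTACT_APPROACHING, CONTACT_CONTACTING):
            r += min(p.ramp_progress, self.tissue.contact_ramp_steps) * (
                self.tissue.contact_ramp_mohm_per_step
            )
        return r

    def _grow_seal(self, p: RigState, dt_s: float, active: bool) -> None:
        if p._seal_fate:
            target = self.tissue.seal_target_mohm
            k = 1.0 / self.tissue.seal_growth_timescale_s
            if not active:
                k *= 0.2
        else:
            target = p.baseline_mohm(self.spec) + self.tissue.failed_seal_delta_mohm
            k = 1.0 / self.tissue.failed_seal_timescale_s
        p.seal_resistance_mohm = target - (target - p.seal_resistance_mohm) * math.exp(-k * dt_s)

    def gigaseal_step(self, i: int, dt_s: float, pressure: PressureState, holding_mv: float) -> float:
        """Integrate the seal trajectory over ``dt_s`` under the given drive.

        Growth toward the gigaseal asymptote runs at full rate while
        suction or a hyperpolarizing holding potential is applied and at
        a fifth of that rate otherwise; a failure-fated attempt creeps
        toward a sub-100-MΩ increase.  Returns the current seal
        resistance (MΩ).
        """
        p = self.pipettes[i]
        if p.clogged:
            raise ProtocolError("gigaseal step on a clogged pipette")
        if not p.sealing:
            raise ProtocolError("gigaseal step outside an attempt")
        active = pressure is PressureState.LOW_SUCTION or holding_mv < 0
        self._grow_seal(p, dt_s, active=active)
        return p.seal_resistance_mohm

    def end_gigaseal(self, i: int) -> bool:
        """Close the attempt; True iff the seal crossed 1 GΩ (held thereafter)."""
        p = self.pipettes[i]
        if not p.sealing:
            raise ProtocolError("no gigaseal attempt to end")
        p.sealing = False
        p.gigasealed = p.seal_resistance_mohm >= GIGASEAL_THRESHOLD_MOHM
        if not p.gigasealed:
            p._seal_fate = None
        return p.gigasealed

    # -- break-in ----------------------------------------------------------------

    def attempt_breakin(self, i: int, pulse_duration_s: float = 0.1, max_pulses: int | None = None) -> bool:
        """Apply suction pulses until break-in or ``max_pulses`` failures.

        Each pulse ruptures the patch with ``breakin_success_prob_per_pulse``;
        on success the pipette enters whole-cell mode and acquires lumped
        membrane properties.  Returns True on success (the failed attempt
        leaves the pipette gigasealed — recorded as gigaseal-only).  The
        number of pulses used is left in ``last_breakin_pulses`` so the
        controller can advance the shared clock for concurrent attempts.
        """
        p = self.pipettes[i]
        if not p.gigasealed or p.seal_resistance_mohm < GIGASEAL_THRESHOLD_MOHM:
            raise ProtocolError("break-in requires a held gigaseal (>= 1 GΩ)")
        n = max_pulses if max_pulses is not None else self.tissue.breakin_max_pulses
        for pulse in range(n):
            self.last_breakin_pulses = pulse + 1
            if self.rng.random() < self.tissue.breakin_success_prob_per_pulse:
                p.broken_in = True
                p.membrane = {
                    "capacitance_pf": float(max(5.0, self.rng.normal(66.1, 34.8))),
                    "membrane_resistance_mohm": float(max(10.0, self.rng.normal(99.3, 44.4))),
                    "series_resistance_mohm": float(max(5.0, self.rng.normal(31.5, 16.5))),
                }
                return True
        return False


# -- calibration ------------------------------------------------------------------


@dataclass(frozen=True)
class StageProportion:
    successes: int
    attempts: int
    estimate: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CalibrationResult:
    tissue: TissueModel
    proportions: dict[str, StageProportion]


def calibrate_from_counts(
    stage_counts: dict[str, tuple[int, int]],
    base: TissueModel | None = None,
    ci_alpha: float = 0.05,
) -> CalibrationResult:
    """Maximum-likelihood tissue model from per-stage success counts.

    ``stage_counts`` maps stage names to ``(successes, attempts)``:
    ``clog`` (clogged / installed), ``seal`` (gigasealed / active),
    ``breakin`` (whole-cell / gigasealed, attempt level — converted to a
    per-pulse probability), ``dislodge`` (contacts lost / waiting
    episodes) and ``recontact`` (re-engaged / replayed).  Each proportion
    carries a Wilson 95% binomial CI.
    """
    base = base or TissueModel()
    props: dict[str, StageProportion] = {}
    updates: dict[str, float] = {}
    field_map = {
        "clog": None,  # lives on PipetteSpec; reported, not set on TissueModel
        "seal": "seal_success_base",
        "dislodge": "dislodge_prob_per_foreign_move",
        "recontact": "replay_recontact_prob",
    }
    for stage, (succ, att) in stage_counts.items():
        if att <= 0:
            raise CalibrationError(f"stage {stage!r} has zero attempts")
        if not 0 <= succ <= att:
            raise CalibrationError(f"stage {stage!r} has successes > attempts")
        p = succ / att
        lo, hi = proportion_confint(succ, att, alpha=ci_alpha, method="wilson")
        props[stage] = StageProportion(succ, att, p, float(lo), float(hi))
        if stage == "breakin":
            updates["breakin_success_prob_per_pulse"] = (
                1.0 - (1.0 - p) ** (1.0 / base.breakin_max_pulses)
            )
        elif field_map.get(stage):
            updates[field_map[stage]] = p
    tissue = replace(base, **updates)
    return CalibrationResult(tissue=tissue, proportions=props)
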