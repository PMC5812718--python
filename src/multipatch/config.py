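"""Run configuration: flat key/value YAML with units embedded in key names.

Defaults reproduce the robot's published operating parameters (pressure
set points, detection and localization thresholds, the 60-s gigaseal
schedule) so a config file is auditable line by line; every effective
parameter is echoed into the output header of a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .controller import AlgorithmVariant, GigasealSchedule, TrialParams
from .errors import ConfigError
from .rig import PipetteSpec, TissueModel


@dataclass
class RunConfig:
    variant: str = "interleaved"
    n_pipettes: int = 4
    n_trials: int = 100
    seed: int = 0
    target_depth_um: float = 400.0

    # pressure set points (mBar) — fixed hardware states, echoed for audit
    high_positive_mbar: int = 800
    low_positive_mbar: int = 25
    atmospheric_mbar: int = 0
    low_suction_mbar: int = -15
    high_suction_mbar: int = -300

    # controller thresholds and cadence
    qc_min_mohm: float = 3.0
    qc_max_mohm: float = 9.0
    localization_threshold_mohm: float = 0.35
    detect_rise_mohm: float = 0.25
    detect_monotonic_tol_mohm: float = 0.01
    step_um: float = 2.0
    step_measure_s: float = 0.5
    max_hunt_um: float = 600.0
    retract_um: float = 30.0
    abort_policy: bool = False

    # gigaseal schedule (s / mV)
    seal_confirm_s: float = 10.0
    seal_atmospheric_s: float = 5.0
    seal_suction_s: float = 10.0
    seal_ramp_s: float = 30.0
    seal_final_hold_s: float = 5.0
    seal_ramp_start_mv: float = -35.0
    seal_ramp_end_mv: float = -70.0

    # rig: pipettes
    bare_resistance_min_mohm: float = 5.0
    bare_resistance_max_mohm: float = 9.0
    clog_on_descent_prob: float = 31 / 164
    clog_resistance_increment_mohm: float = 0.6

    # rig: tissue
    encounter_hazard_per_step: float = 1.0 / 150.0
    contact_ramp_mohm_per_step: float = 0.15
    dislodge_prob_per_foreign_move: float = 10 / 49
    seal_success_base: float = 77 / 133
    seal_success_decay_per_min_waiting: float = 0.66
    replay_recontact_prob: float = 27 / 59
    breakin_success_prob_per_pulse: float = 1.0 - (1.0 - 52 / 77) ** 0.1
    measurement_noise_mohm: float = 0.045

    def __post_init__(self) -> None:
        try:
            AlgorithmVariant(self.variant)
        except ValueError:
            raise ConfigError(
                f"unknown variant {self.variant!r}; choose from "
                f"{[v.value for v in AlgorithmVariant]}"
            )
        if self.n_pipettes < 1:
            raise ConfigError("n_pipettes must be >= 1")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.target_depth_um <= 0:
            raise ConfigError("target_depth_um must be > 0")

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # -- conversions to runtime objects ---------------------------------------

    def pipette_spec(self) -> PipetteSpec:
        return PipetteSpec(
            bare_resistance_range=(self.bare_resistance_min_mohm, self.bare_resistance_max_mohm),
            clog_on_descent_prob=self.clog_on_descent_prob,
            clog_resistance_increment_mohm=self.clog_resistance_increment_mohm,
        )

    def tissue_model(self) -> TissueModel:
        return TissueModel(
            encounter_hazard_per_step=self.encounter_hazard_per_step,
            contact_ramp_mohm_per_step=self.contact_ramp_mohm_per_step,
            dislodge_prob_per_foreign_move=self.dislodge_prob_per_foreign_move,
            seal_success_base=self.seal_success_base,
            seal_success_decay_per_min_waiting=self.seal_success_decay_per_min_waiting,
            replay_recontact_prob=self.replay_recontact_prob,
            breakin_success_prob_per_pulse=self.breakin_success_prob_per_pulse,
            measurement_noise_mohm=self.measurement_noise_mohm,
        )

    def schedule(self) -> GigasealSchedule:
        return GigasealSchedule(
            confirm_s=self.seal_confirm_s,
            atmospheric_s=self.seal_atmospheric_s,
            suction_s=self.seal_suction_s,
            ramp_s=self.seal_ramp_s,
            final_hold_s=self.seal_final_hold_s,
            ramp_start_mv=self.seal_ramp_start_mv,
            ramp_end_mv=self.seal_ramp_end_mv,
        )

    def trial_params(self, record_steps: bool = False) -> TrialParams:
        return TrialParams(
            schedule=self.schedule(),
            qc_range_mohm=(self.qc_min_mohm, self.qc_max_mohm),
            localization_threshold_mohm=self.localization_threshold_mohm,
            detect_rise_mohm=self.detect_rise_mohm,
            detect_monotonic_tol_mohm=self.detect_monotonic_tol_mohm,
            step_um=self.step_um,
            step_measure_s=self.step_measure_s,
            max_hunt_um=self.max_hunt_um,
            retract_um=self.retract_um,
            abort_policy=self.abort_policy,
            record_steps=record_steps,
        )
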