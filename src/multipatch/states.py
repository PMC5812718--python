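"""Discrete pneumatic and phase states of the patching robot.

The pressure controller exposes five discrete set points applied to the
pipette interior; the robot's per-pipette life cycle is a finite state
machine whose legal transitions are declared here and enforced everywhere
a phase is mutated.
"""

from __future__ import annotations

import enum

from .errors import ProtocolError


class PressureState(enum.Enum):
    """Pneumatic set points (mBar) selectable per pipette."""

    HIGH_POSITIVE = 800
    LOW_POSITIVE = 25
    ATMOSPHERIC = 0
    LOW_SUCTION = -15
    HIGH_SUCTION = -300

    @property
    def set_point_mbar(self) -> int:
        return self.value


class PipettePhase(enum.Enum):
    INSTALLED = "INSTALLED"
    QC_FAILED = "QC_FAILED"
    LOCALIZING = "LOCALIZING"
    DEACTIVATED_CLOGGED = "DEACTIVATED_CLOGGED"
    HUNTING = "HUNTING"
    HALTED = "HALTED"
    GIGASEALING = "GIGASEALING"
    GIGASEALED_HELD = "GIGASEALED_HELD"
    SEAL_FAILED = "SEAL_FAILED"
    BREAKING_IN = "BREAKING_IN"
    WHOLE_CELL = "WHOLE_CELL"
    LOST = "LOST"


#: Legal phase transitions. GIGASEALING is reachable only from a halted or
#: hunting pipette that detected a neuron; WHOLE_CELL only through break-in
#: from a held gigaseal.
ALLOWED_TRANSITIONS: dict[PipettePhase, frozenset[PipettePhase]] = {
    PipettePhase.INSTALLED: frozenset(
        {PipettePhase.QC_FAILED, PipettePhase.LOCALIZING}
    ),
    PipettePhase.QC_FAILED: frozenset(),
    PipettePhase.LOCALIZING: frozenset(
        {PipettePhase.DEACTIVATED_CLOGGED, PipettePhase.HUNTING}
    ),
    PipettePhase.DEACTIVATED_CLOGGED: frozenset(),
    PipettePhase.HUNTING: frozenset(
        {PipettePhase.HALTED, PipettePhase.GIGASEALING, PipettePhase.LOST}
    ),
    PipettePhase.HALTED: frozenset(
        {PipettePhase.HUNTING, PipettePhase.GIGASEALING}
    ),
    PipettePhase.GIGASEALING: frozenset(
        {PipettePhase.GIGASEALED_HELD, PipettePhase.SEAL_FAILED}
    ),
    PipettePhase.GIGASEALED_HELD: frozenset({PipettePhase.BREAKING_IN}),
    PipettePhase.SEAL_FAILED: frozenset(),
    PipettePhase.BREAKING_IN: frozenset(
        {PipettePhase.WHOLE_CELL, PipettePhase.GIGASEALED_HELD}
    ),
    PipettePhase.WHOLE_CELL: frozenset(),
    PipettePhase.LOST: frozenset(),
}


def check_transition(old: PipettePhase, new: PipettePhase) -> None:
    """Raise :class:`ProtocolError` if ``old -> new`` is not a legal move."""
    if new not in ALLOWED_TRANSITIONS[old]:
        raise ProtocolError(f"illegal phase transition {old.name} -> {new.name}")
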