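"""Seal-test signal chain: stimulus, electrode forward model, filters, estimator.

The robot measures pipette resistance with a small square-wave voltage
command in voltage clamp (10 mV peak-to-peak at 10 Hz by default) and
computes resistance on line as applied voltage over the peak-to-peak
amplitude of the measured current.  This module provides a forward model
(:func:`synthesize_current`) that turns a lumped electrode circuit into a
sampled current trace, the two digital filters applied to the raw signal
(a 13-tap triangular moving average and a first-order exponential
smoother), and the estimator itself.

Units are fixed package-wide: voltages in mV, currents in pA (nA where
noted), resistances in MΩ, capacitances in pF, times in s.  With those
units Ohm's law reads ``I_pA = 1000 * V_mV / R_MΩ``.

Conventions (documented, not inferable from the estimator alone):

* the stated command amplitude is *peak-to-peak*, so ``R = V_pp / I_pp``
  holds without a factor of two;
* the "decay rate = 0.001 s" exponential filter is read as a first-order
  causal smoother with time constant 1 ms;
* per-cycle peak-to-peak current is measured as the difference of plateau
  levels, each plateau taken as the mean of the last 25% of a half-cycle
  (after capacitive settling), with the median across cycles used as the
  robust summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import InsufficientHistoryError, InvalidCircuitError, MeasurementError

__all__ = [
    "SquareWaveStimulus",
    "ElectrodeCircuit",
    "CurrentTrace",
    "ResistanceEstimate",
    "synthesize_current",
    "triangular_moving_average",
    "exponential_settle_filter",
    "estimate_resistance",
    "averaged_resistance",
    "measure_resistance",
]


@dataclass(frozen=True)
class SquareWaveStimulus:
    """Square-wave voltage command applied in voltage clamp.

    Parameters
    ----------
    peak_to_peak_mv
        Command amplitude, peak to peak (mV).  The wave alternates between
        ``dc_offset + pp/2`` and ``dc_offset - pp/2``, starting high.
    frequency_hz
        Square-wave frequency (Hz).
    dc_offset_mv
        DC offset of the command (mV); 0 during hunting, stepped down to
        −35 .. −70 mV during gigasealing.
    sample_rate_hz
        Digitization rate (Hz).
    duration_s
        Length of the synthesized / analyzed window (s).
    """

    peak_to_peak_mv: float = 10.0
    frequency_hz: float = 10.0
    dc_offset_mv: float = 0.0
    sample_rate_hz: float = 15000.0
    duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.peak_to_peak_mv <= 0:
            raise ValueError("peak_to_peak_mv must be > 0")
        if self.sample_rate_hz < 2 * self.frequency_hz:
            raise ValueError("sample_rate_hz must be >= 2 * frequency_hz")
        if self.duration_s <= 1.0 / self.frequency_hz:
            raise ValueError("duration_s must exceed one stimulus period")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def voltage(self) -> np.ndarray:
        """Command voltage at each sample (mV), high during the first half-period."""
        t = self.times()
        phase = (t * self.frequency_hz) % 1.0
        half = np.where(phase < 0.5, 0.5, -0.5)
        return self.dc_offset_mv + self.peak_to_peak_mv * half

    def edges(self) -> list[tuple[float, float]]:
        """Voltage steps of the command as ``(time_s, delta_mv)`` pairs.

        The command is taken to rest at ``dc_offset`` before t=0, so the
        first edge is a half-amplitude step; every later half-period
        boundary is a full peak-to-peak swing of alternating sign.
        """
        half_period = 0.5 / self.frequency_hz
        n_edges = int(np.ceil(self.duration_s / half_period))
        out = [(0.0, self.peak_to_peak_mv / 2.0)]
        sign = -1.0
        for k in range(1, n_edges):
            out.append((k * half_period, sign * self.peak_to_peak_mv))
            sign = -sign
        return out


@dataclass(frozen=True)
class ElectrodeCircuit:
    """Lumped electrical model of a pipette and (optionally) its seal.

    ``mode`` selects which resistance the seal test sees: in the bath the
    pipette tip resistance alone; once a membrane is engaged
    (cell-attached or whole-cell) the measured resistance is dominated by
    the seal pathway, carried in ``seal_resistance_mohm``.
    ``stray_capacitance_pf`` produces first-order transients at each
    command edge with time constant R·C.
    """

    pipette_resistance_mohm: float
    stray_capacitance_pf: float = 0.0
    seal_resistance_mohm: float = float("inf")
    mode: str = "bath"  # bath | cell_attached | whole_cell

    def __post_init__(self) -> None:
        if self.pipette_resistance_mohm <= 0:
            raise InvalidCircuitError("pipette resistance must be > 0 MΩ")
        if self.stray_capacitance_pf < 0:
            raise InvalidCircuitError("stray capacitance must be >= 0 pF")
        if self.mode not in ("bath", "cell_attached", "whole_cell"):
            raise InvalidCircuitError(f"unknown mode {self.mode!r}")
        if self.mode != "bath" and self.seal_resistance_mohm < self.pipette_resistance_mohm:
            raise InvalidCircuitError("seal resistance below pipette resistance")

    @property
    def effective_resistance_mohm(self) -> float:
        """Resistance governing the seal-test current in the current mode."""
        if self.mode == "bath":
            return self.pipette_resistance_mohm
        return self.seal_resistance_mohm


@dataclass
class CurrentTrace:
    """Uniformly sampled current trace (pA)."""

    samples_pa: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples_pa = np.asarray(self.samples_pa, dtype=float)
        if not np.all(np.isfinite(self.samples_pa)):
            raise ValueError("current trace contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples_pa)

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz

    def to_csv(self, path) -> None:
        """Write ``time_s,current_pA`` rows, 6 significant digits."""
        with open(path, "w") as fh:
            fh.write("time_s,current_pA\n")
            for t, i in zip(self.times(), self.samples_pa):
                fh.write(f"{t:.6g},{i:.6g}\n")


@dataclass(frozen=True)
class ResistanceEstimate:
    value_mohm: float
    timestamp_s: float
    n_cycles_used: int

    def __post_init__(self) -> None:
        if self.value_mohm <= 0:
            raise ValueError("resistance estimate must be > 0")


def synthesize_current(
    stim: SquareWaveStimulus,
    circuit: ElectrodeCircuit,
    noise_rms_pa: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> CurrentTrace:
    """Forward-model the seal-test current response of ``circuit``.

    The response is the resistive plateau ``1000 * V / R`` plus, at each
    command edge of size ΔV, a first-order capacitive transient
    ``(1000 * ΔV / R) * exp(-t / τ)`` with ``τ = R·C`` (µs for MΩ·pF),
    i.e. a transient carrying total charge C·ΔV, plus white Gaussian
    noise of the requested RMS.  Deterministic for a fixed seed.
    """
    r = circuit.effective_resistance_mohm
    if r <= 0:
        raise InvalidCircuitError("effective resistance must be > 0 MΩ")
    t = stim.times()
    current = 1000.0 * stim.voltage() / r
    tau_s = r * circuit.stray_capacitance_pf * 1e-6  # MΩ·pF -> µs -> s
    if tau_s > 0:
        for t_edge, dv in stim.edges():
            mask = t >= t_edge
            current[mask] += (1000.0 * dv / r) * np.exp(-(t[mask] - t_edge) / tau_s)
    if noise_rms_pa > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_rms_pa, size=current.shape)
    return CurrentTrace(current, stim.sample_rate_hz)


def triangular_kernel(half_width: int) -> np.ndarray:
    """Symmetric triangular kernel of ``2*half_width + 1`` taps, summing to 1."""
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    ramp = np.arange(1, half_width + 2, dtype=float)
    kernel = np.concatenate([ramp, ramp[-2::-1]])
    return kernel / kernel.sum()


def triangular_moving_average(trace: CurrentTrace, half_width: int = 6) -> CurrentTrace:
    """Smooth with a triangular moving average (default 13 taps, half-width 6).

    Edges are handled by reflect padding so the output has the input's
    length and a constant input is preserved exactly (unit DC gain).
    """
    kernel = triangular_kernel(half_width)
    x = trace.samples_pa
    if len(x) <= len(kernel):
        raise ValueError("trace shorter than filter kernel")
    padded = np.pad(x, half_width, mode="reflect")
    y = np.convolve(padded, kernel, mode="valid")
    return CurrentTrace(y, trace.sample_rate_hz, trace.t0_s)


def exponential_settle_filter(trace: CurrentTrace, tau_s: float = 0.001) -> CurrentTrace:
    """First-order causal exponential smoother with time constant ``tau_s``.

    Suppresses residual capacitive spikes from uncompensated pipette
    capacitance so that the plateau-based peak-to-peak measurement
    reflects the resistive current.  Initialized at the first sample, so
    DC gain is exactly 1.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    x = trace.samples_pa
    dt = 1.0 / trace.sample_rate_hz
    a = 1.0 - np.exp(-dt / tau_s)
    # y[n] = a*x[n] + (1-a)*y[n-1], y[-1] = x[0]
    y, _ = lfilter([a], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * x[0]])
    return CurrentTrace(y, trace.sample_rate_hz, trace.t0_s)


def _plateau_levels(stim: SquareWaveStimulus, trace: CurrentTrace) -> np.ndarray:
    """Mean of the last 25% of each half-cycle (post-settling plateau)."""
    sr = trace.sample_rate_hz
    half_period_samples = sr / (2.0 * stim.frequency_hz)
    n_half = int(len(trace) / half_period_samples)
    levels = []
    for k in range(n_half):
        lo = int(round(k * half_period_samples))
        hi = int(round((k + 1) * half_period_samples))
        hi = min(hi, len(trace))
        start = lo + int(0.75 * (hi - lo))
        if hi - start < 1:
            continue
        levels.append(float(np.mean(trace.samples_pa[start:hi])))
    return np.asarray(levels)


def estimate_resistance(stim: SquareWaveStimulus, trace: CurrentTrace) -> ResistanceEstimate:
    """Resistance as applied voltage over peak-to-peak measured current.

    Peak-to-peak current is measured per cycle as the difference between
    adjacent half-cycle plateaus; the median across cycles divides the
    peak-to-peak command voltage (mV / nA -> MΩ).

    Raises
    ------
    MeasurementError
        If the measured peak-to-peak current is zero — the signature of a
        broken measurement (amplifier or valve fault), not a resistance.
    """
    levels = _plateau_levels(stim, trace)
    if len(levels) < 2:
        raise ValueError("trace spans less than one full stimulus cycle")
    pp_per_cycle = np.abs(np.diff(levels))
    i_pp_pa = float(np.median(pp_per_cycle))
    if i_pp_pa <= 0.0:
        raise MeasurementError("zero peak-to-peak current in seal test")
    value = 1000.0 * stim.peak_to_peak_mv / i_pp_pa  # mV / nA = MΩ
    t_end = trace.t0_s + len(trace) / trace.sample_rate_hz
    return ResistanceEstimate(value, t_end, n_cycles_used=len(pp_per_cycle))


def averaged_resistance(history: Sequence) -> float:
    """Arithmetic mean of exactly five consecutive resistance estimates.

    Accepts :class:`ResistanceEstimate` objects or plain MΩ values.
    """
    if len(history) != 5:
        raise InsufficientHistoryError(
            f"averaging window needs exactly 5 estimates, got {len(history)}"
        )
    values = [h.value_mohm if isinstance(h, ResistanceEstimate) else float(h) for h in history]
    return float(np.mean(values))


def measure_resistance(
    circuit: ElectrodeCircuit,
    stim: SquareWaveStimulus | None = None,
    noise_rms_pa: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ResistanceEstimate:
    """Full measurement chain: synthesize -> triangular MA -> exponential -> estimate."""
    stim = stim or SquareWaveStimulus()
    trace = synthesize_current(stim, circuit, noise_rms_pa=noise_rms_pa, seed=seed)
    trace = triangular_moving_average(trace)
    trace = exponential_settle_filter(trace)
    return estimate_resistance(stim, trace)
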