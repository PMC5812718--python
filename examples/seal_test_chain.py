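"""Seal-test measurement chain on a synthetic electrode.

Synthesizes the current response of a 6.5 MΩ pipette with 8 pF of
uncompensated stray capacitance to the standard 10 mV / 10 Hz square
wave, applies the robot's two digital filters, and estimates resistance
the way the robot does (peak-to-peak voltage over peak-to-peak current).
"""

from multipatch import (
    ElectrodeCircuit,
    SquareWaveStimulus,
    estimate_resistance,
    exponential_settle_filter,
    synthesize_current,
    triangular_moving_average,
)

stim = SquareWaveStimulus()  # 10 mV pp, 10 Hz, 15 kHz sampling, 0.5 s
circuit = ElectrodeCircuit(pipette_resistance_mohm=6.5, stray_capacitance_pf=8.0)

raw = synthesize_current(stim, circuit, noise_rms_pa=5.0, seed=42)
smoothed = exponential_settle_filter(triangular_moving_average(raw))
est = estimate_resistance(stim, smoothed)

print(f"true pipette resistance : 6.50 MΩ")
print(f"raw trace peak-to-peak  : {raw.samples_pa.max() - raw.samples_pa.min():7.1f} pA "
      "(inflated by capacitive edge transients)")
print(f"estimated resistance    : {est.value_mohm:.2f} MΩ "
      f"(median over {est.n_cycles_used} cycles)")
# The estimate lands within ~1% of truth: the filters suppress the edge
# transients so the plateau difference reflects the resistive current only.
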