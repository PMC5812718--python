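# multipatch

A discrete-event simulator of a multi-pipette *in vivo* autopatching robot.
It re-creates, entirely in software, the control logic that coordinates four
interacting whole-cell patch-clamp pipettes in the living brain — quality
control, descent, blind neuron hunting, gigasealing and break-in — together
with the seal-test measurement chain and a stochastic "virtual rig" standing
in for the tissue, so coordination policies, detection rules, pressure/voltage
schedules and yield accounting can be exercised and tested with no hardware.

It is aimed at instrument-control and lab-automation developers who want to
test patching policy logic at their desk, and at methods researchers who want
to ask *what-if* questions about multi-electrode coordination (how much yield
does waiting cost? how bad does mechanical coupling have to be before
synchronous strategies collapse?).

## The problem and the model

Blind *in vivo* patching finds neurons by resistance: a pipette advancing in
2 µm steps under low positive pressure shows a monotone rise in its seal-test
resistance R when its tip presses onto a cell.  Resistance is measured by
applying a square-wave command (10 mV peak-to-peak, 10 Hz, sampled at 15 kHz)
in voltage clamp and computing

    R = V_pp / I_pp

from the peak-to-peak current, after a 13-tap triangular moving average and a
first-order exponential smoother (τ = 1 ms) suppress capacitive edge
transients; each resistance value used by the controller is the mean of five
consecutive estimates.

One pipette's algorithm is a finite state machine: QC (accept 3–9 MΩ) →
descent at ~200 µm/s under +800 mBar → regional localization (a rise
> 0.35 MΩ versus the bath reading means a clogged tip: depressurize and
deactivate) → neuron hunting (detect when three consecutive steps rise
monotonically by > 0.25 MΩ total) → a fixed 60-s gigasealing program
(10 s at +25 mBar, 5 s atmospheric, 10 s at −15 mBar suction, then holding
potential stepped to −35 mV and ramped linearly to −70 mV over 30 s, 5 s
hold; success = R ≥ 1 GΩ) → suction-pulse break-in to whole-cell mode.

With four pipettes the interesting physics is *interaction*: a moving pipette
displaces tissue and can dislodge another pipette's held contact, and a neuron
held for minutes under ejected pipette solution seals less well.  The package
implements the three coordination strategies that were iterated in hardware:

1. **sync_all** — hunt independently, hold each contact until all four have
   one, then gigaseal all simultaneously (held contacts suffer dislodgement
   and waiting decay);
2. **retract_replay** — on each detection retract 30 µm and park, then
   advance all 30 µm together and gigaseal synchronously (recontact on the
   replay is unreliable);
3. **interleaved** — on any detection halt *all* motors, gigaseal that one
   pipette immediately, then resume the rest; gigasealed pipettes held at
   −70 mV are immune to later motion.  Gigasealing is serialized, giving a
   scaling floor of 70 s per pipette (60 s schedule + 10 s assessment).

The virtual rig models clogging as a Bernoulli draw per descent, encounters
as geometric waiting per step, dislodgement as a Bernoulli draw per foreign
movement episode, and gigaseal success as `p_base · decay^minutes_waiting`,
with all stage probabilities calibrated from published campaign counts.

## Worked example

```
$ python examples/compare_strategies.py
strategy          gigaseal/active   whole-cell/pipette
sync_all                    27.8%                15.5%
retract_replay              18.0%                10.5%
interleaved                 49.8%                27.3%
```

500 seeded trials per strategy at the default calibration.  The gigaseal
column is the fraction of active (unclogged) pipettes that reached a ≥ 1 GΩ
seal; interleaving roughly doubles it because contacts never wait and never
feel other pipettes' motion.  `examples/single_trial.py` prints one trial's
event log (detections, halts, serialized 60-s seal attempts, simultaneous
break-in), and `examples/published_funnel.py` recomputes the published
campaign funnel from the packaged count fixtures, e.g. gigaseals in 57.9%
(77/133) of active pipettes and break-in for 67.5% (52/77) of gigaseals.

A thin CLI wraps the same library code:

```
multipatch simulate --variant interleaved --trials 100 --seed 7 --out run/
multipatch stats run/trials.jsonl
multipatch fixture anesthetized
```

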