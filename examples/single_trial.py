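"""One interleaved multipatching trial, event by event.

Runs a four-pipette trial of the halt-and-gigaseal strategy against the
default virtual rig and prints the key coordination events: detections
halt every motor, gigasealing attempts are strictly serialized, and
break-in happens simultaneously at the end.
"""

from multipatch import TrialParams, VirtualRig, run_trial
from multipatch.controller import EventType

rig = VirtualRig(n_pipettes=4, seed=7)
record = run_trial("interleaved", rig, params=TrialParams(record_steps=False))

for e in record.events:
    print(f"t={e.t:7.1f}s  pipette {e.pipette}  {e.event.value:<16} {e.detail}")

n_wc = record.n_whole_cell()
print(f"\ntrial duration {record.timings['total_s'] / 60:.1f} min, "
      f"{sum(p.sealed for p in record.pipettes)} gigaseals, "
      f"{n_wc} whole-cell recordings")
# A typical trial yields 1-3 whole-cell recordings in ~5 simulated minutes;
# SEAL_START/SEAL_OK pairs never overlap across pipettes.
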