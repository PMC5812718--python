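"""Recompute the published campaign funnel from the packaged fixtures.

The deterministic fixtures encode the raw published stage counts; every
percentage below is recomputed from those counts by yield_stats, not
stored anywhere.
"""

from multipatch import make_anesthetized_fixture, make_awake_fixtures, yield_stats

s = yield_stats(make_anesthetized_fixture())
print("anesthetized campaign (41 trials, 164 pipettes):")
print(f"  clogged on descent      {100 * s.clog_rate:5.1f}%  ({s.n_clogged}/{s.n_pipettes})")
print(f"  gigaseal among active   {100 * s.gigaseal_rate_active:5.1f}%  ({s.n_sealed}/{s.n_active})")
print(f"  break-in among sealed   {100 * s.breakin_rate_sealed:5.1f}%  ({s.n_whole_cell}/{s.n_sealed})")
print(f"  whole-cell per pipette  {100 * s.whole_cell_rate_per_pipette:5.1f}%  ({s.n_whole_cell}/{s.n_pipettes})")
print(f"  trials with >=1         {100 * s.trials_ge1_rate:5.1f}%  ({s.n_trials_ge1}/{s.n_trials})")

fx = make_awake_fixtures()
pip = yield_stats(fx["pipette_level"])
tri = yield_stats(fx["trial_level"])
print("\nawake campaign (97 trials, 388 pipettes):")
print(f"  whole-cell per pipette  {100 * pip.whole_cell_rate_per_pipette:5.1f}%  "
      f"({pip.n_whole_cell}/{pip.n_pipettes})")
print(f"  trials with >=1         {100 * tri.trials_ge1_rate:5.1f}%  "
      f"({tri.n_trials_ge1}/{tri.n_trials})")
print(f"  trials with >=2         {100 * tri.trials_multi_rate:5.1f}%  "
      f"({tri.n_trials_multi}/{tri.n_trials})")
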