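"""Simulate BOLD from a known bottom-up model.

Draws one run of the face-encoding design, simulates the six-region
network, and prints per-region signal amplitudes: the visual drive
enters IOG and propagates forward through the backbone.
"""

import numpy as np

import emodcm as e
from emodcm.model_space import REGIONS

spec = e.enumerate_bottom_up()[0]          # valence modulates IOG->OFC
params = e.default_group_parameters(spec)

events = e.sample_design(seed=0, n_runs=1, scans_per_run=155, n_faces=37,
                         valence_split=(13, 12, 12))
print(f"design: {len(events)} faces, "
      f"first onset {events.onset.iloc[0]:.1f} s, "
      f"last offset {events.onset.iloc[-1] + 3.5:.1f} s "
      f"(window {155 * 2.4:.0f} s)")

inputs = e.events_to_inputs(events, dt=2.4 / 16, n_runs=1, scans_per_run=155)
ts = e.simulate_bold(params, inputs, spec)

print(f"simulated {ts.n_scans} scans at TR {ts.tr} s")
for r, label in enumerate(REGIONS):
    sd = ts.data[:, r].std()
    print(f"  {label}: signal SD {sd * 100:.3f} (percent x100 scale)")
print("IOG carries the largest response (it receives the drive); "
      "downstream regions inherit attenuated copies through A.")
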