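#!/usr/bin/env python
"""Resting neuron vs contact-release speed.

Sweeps the speed grid for all four morphologies with no injected
current: every excitation comes from the moving device.  Writes
results/resting_sweep.tsv and prints the speed threshold and the
subthreshold resting-potential elevation.
"""

from pathlib import Path

import numpy as np

from teng_neuron import SweepConfig, pattern_sweep
from teng_neuron.cli_io import write_sweep_table

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

result = pattern_sweep(SweepConfig(protocol="resting"))
write_sweep_table(result.table, OUT / "resting_sweep.tsv")

flat = result.table[result.table["pattern"] == "flat"].sort_values("speed_cm_s")
silent = flat[flat["n_spikes"] == 0]
firing = flat[flat["n_spikes"] > 0]
print(flat.to_string(index=False, float_format=lambda x: f"{x:.6g}"))
print(f"\nfinding: no spikes up to {silent['speed_cm_s'].max()} cm/s; "
      f"firing from {firing['speed_cm_s'].min()} cm/s on, "
      f"rate rising to {firing['firing_rate_Hz'].max():.0f} Hz at "
      f"{firing['speed_cm_s'].max()} cm/s.")
print("         subthreshold runs show a small positive resting-potential shift "
      f"(up to {silent['baseline_shift_mV'].max()*1e3:.3f} uV) that grows with speed.")
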