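#!/usr/bin/env python
"""Tabulate the TENG output characteristics V_oc(x) and C(x).

Builds the flat-device curve twice (closed form and 2D Poisson solver)
to demonstrate the oracle agreement, then one Poisson curve per surface
morphology.  Writes results/curves/<shape>.tsv and prints the ordering
of the morphologies.
"""

from pathlib import Path

import numpy as np

from teng_neuron import (
    MicropatternSpec,
    TENGConfig,
    build_curve,
    closed_form_voc,
    default_gap_grid,
)
from teng_neuron.cli_io import write_curve

OUT = Path(__file__).resolve().parent.parent / "results" / "curves"
OUT.mkdir(parents=True, exist_ok=True)

gaps = default_gap_grid()

flat_cfg = TENGConfig()
cf = build_curve(flat_cfg, gaps, method="closed_form")
write_curve(cf, OUT / "flat_closed_form.tsv", flat_cfg)

curves = {}
for shape in ("flat", "cube", "pyramid", "sphere"):
    cfg = TENGConfig(pattern=MicropatternSpec(shape=shape))
    curve = build_curve(cfg, gaps, method="poisson_2d", cells_per_layer=16)
    write_curve(curve, OUT / f"{shape}.tsv", cfg)
    curves[shape] = curve

sel = gaps > 0
err = np.max(np.abs(curves["flat"].voc[sel] - cf.voc[sel]) / cf.voc[sel])
print(f"flat device: Poisson vs closed-form V_oc max deviation {err:.2%}")
print(f"V_oc at the largest gap ({gaps[-1]*1e6:.0f} um):")
for shape, curve in sorted(curves.items(), key=lambda kv: -kv[1].voc[-1]):
    print(f"  {shape:8s} {curve.voc[-1]:8.1f} V   C = {curve.cap_total[-1]*1e12:.3f} pF")
print("finding: micropatterns raise V_oc and lower C; the cube pattern is highest,")
print(f"         {curves['cube'].voc[-1]/curves['flat'].voc[-1]:.2f}x the flat output.")
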