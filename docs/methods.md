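# Methods

## Device electrostatics

The device is a vertical contact–separation stack: bottom Au electrode,
Kapton film (7×10⁻⁷ m, ε_r = 3.4), air gap x, silk film (7×10⁻⁷ m,
ε_r = 2.6), top Au electrode; plate area A = 15×10⁻⁵ m², tribo surface
charge density σ = 5×10⁻⁵ C m⁻² (positive on silk, negative on Kapton).
With zero net free charge on the floating electrodes, Gauss's law pins
the displacement field to zero in both dielectrics and to −σ in the gap,
giving the flat-device closed forms used as oracles:

* V_oc(x) = σx/ε₀ (independent of the dielectric thicknesses),
* C(x) = ε₀A/(d_eff + x), d_eff = d_silk/ε_silk + d_kapton/ε_kapton ≈ 0.475 µm.

**2D solver.** Micropatterned surfaces are handled on a 2D
cross-section: one pattern pitch wide (20 µm default), finite-volume
discretization with a tensor grid (`cells_per_layer` cells per material
band), distance-weighted harmonic-mean permittivity at faces, zero
normal field on the lateral sides. Electrodes are floating
equipotential Dirichlet surfaces: the problem is solved by superposition
of a grounded-electrode charge problem and a charge-free unit (1 V)
problem, with the top-electrode potential fixed by zero induced charge.
Both right-hand sides are solved with one sparse direct factorization
(`scipy.sparse.linalg.spsolve`), which is exact — the originally
envisaged SOR/CG iteration with a 10⁻⁸ residual tolerance is replaced by
a direct solve because the systems are small (≤ ~10⁵ unknowns) and a
factorization removes the iteration-tolerance knob entirely.

**Surface charge.** The tribo charge follows the patterned contour
(cube → rectangle, pyramid → triangle, sphere → semi-ellipse cross
sections; default feature 10 µm wide × 10 µm high on a 20 µm pitch,
chosen as typical micropatterning scales — the real feature sizes are
configurable). Charge is deposited in the first *air* cell outward of
each surface segment, σ per unit contour length, with the flat silk face
carrying the balancing countercharge. Because the effective charge
plane then sits half a gap cell away from the true surface, the flat
V_oc carries a clean first-order error ≈ 1/cells_per_layer, which is
what the mesh-convergence checks measure (0.195% at 512 cells/layer;
the convergence estimate reported on a `FieldSolution` is the relative
V_oc change under one refinement). The patterned contour carries more
charge per footprint than flat (contour/pitch ≈ 2.0 cube, 1.6 pyramid,
1.3 sphere), which is why cube > pyramid/sphere > flat in V_oc.

**Capacitance.** Two notions coexist and both are exposed:

* the physical electrode-to-electrode capacitance, read from the unit
  field problem (equals the series-stack closed form for flat geometry);
  `build_curve(method="poisson_2d")` tabulates this one;
* the quotient C = Q/V_oc with Q = σA (`extract_voc_capacitance`), which
  for the flat device equals ε₀A/x — it ignores the dielectric drop and
  so deviates from the stack value below x ≈ 25 µm (≈ d_eff/0.02).

The distinction matters: with the quotient capacitance C·V_oc ≡ σA is
constant, so the two motion-drive terms cancel identically and the
device could never stimulate. The curves fed to the neuron stage
therefore use the physical capacitance.

## Membrane and cable model

Classical squid-axon Hodgkin–Huxley kinetics in absolute potential with
V_rest = −60 mV: E_Na = +52.4, E_K = −72.1, E_L = −49.2 mV (the printed
magnitudes of the potassium/leak/resting values are interpreted with
their physiological negative signs), ḡ_Na = 120, ḡ_K = 36, g_L = 0.3
mS cm⁻², C_m = 1 µF cm⁻². The α/β rate functions are the standard 1952
forms shifted by V_rest, no temperature scaling; their removable
singularities are filled by series limits. The axon: radius 0.001 cm,
length 1 cm, 100 compartments (dz = 0.01 cm), R_i = 35 Ω cm and
R_e = 20 Ω cm both converted to per-length resistances over the axial
cross-section πa² (R_e is configurable to 0 for an ideal bath); sealed
ends. The model's true resting state (the zero-current root, −60.003 mV
here) initializes every run and is reported alongside the nominal
−60 mV.

**Time stepping.** Operator-split explicit scheme: forward-Euler voltage
update, then exact exponential-Euler gating at the pre-step voltage
(gating can never leave [0,1]). Δt = 0.001 ms, checked at run start
against the diffusion bound Δt ≤ C_m dz²(2πa)(r_i+r_e)/2000 ≈ 0.0055 ms.
Output is decimated to 0.025 ms. The kernel is numba-jitted with an
identical pure-Python fallback; plain and coupled runs share one code
path, so the zero-speed coupled run is bit-identical to the plain run by
construction. Halving Δt moves coupled-run spike times by < 1%.

## Device–neuron coupling

The moving device enters the membrane balance (per membrane area; the
device capacitance is divided by the plate area, the only reading that
makes every term dimensionally consistent) as

    (C_m − C(x)) dV/dt = axial − I_ion − dC/dx·ẋ·(V_oc − V) − C·dV_oc/dx·ẋ.

The ionic currents enter with the standard sign (−I_ion); a sign-flipped
variant (+I_ion) would destabilize the resting state.
C(x) ≪ C_m everywhere here (≤ 2×10⁻³ µF cm⁻² at 1 µm gap), and the
denominator is guarded against C(x) ≥ C_m. A motionless device (v = 0)
exchanges no charge, so the update degenerates to the plain one — the
C_m − C(x) denominator applies only while the device moves.

**Gap derivatives.** dC/dx and dV_oc/dx are the *forward difference
quotients of the tabulated curve*, i.e. exactly the slopes of its
piecewise-linear interpolant, held constant per segment. This is
self-consistent (the derivative of the interpolated value) and
sign-correct: central differences on the nodes overestimate |dC/dx| on
the convex C(x) enough to flip the sign of the small far-field drive
combination dC/dx·V_oc + C·dV_oc/dx ( = σ·d_eff/(d_eff+x)² in the
continuum), which would invert the subthreshold resting-potential
shift.

**The tabulation is part of the model.** Integrating the drive over one
approach gives a path-independent depolarizing charge
σ[d_eff/(d_eff+x_min) − d_eff/(d_eff+x_max)] < σ = 5 nC cm⁻², i.e. at
most ~5 mV — a continuum-resolved device at these material parameters
cannot reach threshold at any speed. Excitation arises because the
finite gap grid (default 21 uniform nodes over 0–500 µm) smears the
sharp capacitance rise near contact across the first 25 µm segment,
concentrating the drive into ≈ ±50 µA cm⁻² pulses (at 0.5 cm/s) around
each contact event. The discrete difference-quotient model, not its
continuum limit, is the excitable system under study, and the 21-node
default is kept as the study condition.

**Motion.** Triangular wave between x_min = 1 µm (avoiding the
degenerate gap-0 corner) and x_max = 0.05 cm at constant |ẋ| = v,
starting separated at t = 0; turning points use the incoming one-sided
velocity. Speeds follow the study grid 0.025–1 cm/s. The coupling is
applied uniformly along the axon by default (the drive has no axial
structure), with an optional compartment sub-range for a localized
device.

## Protocols and metrics

* resting protocol: no injected current, 200 ms horizon;
* firing protocol: 10 µA cm⁻² uniformly injected during 0–100 ms (an
  amplitude that produces sustained ~70 Hz firing in this model).

Spikes are peaks above 0 mV separated by ≥ 2 ms
(`scipy.signal.find_peaks`). Firing rate is counted over the full
record for both protocols: the post-stimulus device-evoked spikes are
what make the firing-state rate speed-dependent at all. FWHM is
measured per spike against the run's pre-stimulus resting value with
linearly interpolated half crossings; truncated spikes are excluded.
The inter-pulse delay trend is evaluated on the device-evoked (resting
protocol) train. The subthreshold baseline shift is the mean of the
trace's second half minus the resting value.

## Synthetic generators

`synthetic_trace` builds template spike trains (Gaussian / triangular /
rectangular pulses on a flat baseline, optional seeded white noise) with
known ground truth, giving closed-form oracles for the detector, FWHM,
rate and delay code. It emulates clean, uniformly sampled,
single-compartment recordings only — no drift, no bursting, no
subthreshold oscillations — so passing metric tests certify the
extraction arithmetic, not robustness to messy electrophysiology.
`fixture_curve` provides solver-free device curves (constant, linear,
zero-V_oc, and a saturating monotone shape) used to hand-verify the
coupling algebra and the capacitance-rescaling equivalence.

## Non-monotone behavior at the window edge and the highest speed

Under the default study conditions two of the speed trends are not
uniformly monotone, and both trace to the motion-profile defaults:

1. at 0.5 cm/s the stroke time (x_max − x_min)/v = 99.8 ms nearly
   coincides with the end of the 100 ms stimulated window, so the
   contact event adds one spike inside the window that the device-free
   run lacks;
2. at 1 cm/s the release half of the triangular turning point follows
   the approach pulse within ~2.5 ms, clipping the evoked spike's peak
   (46.6 vs 49.8 mV at 0.5 cm/s); since FWHM is measured at half of a
   *lower* peak, the width grows (1.69 vs 1.65 ms) — in this model
   amplitude and FWHM move oppositely at the highest speed rather than
   both shrinking.

Both are properties of the triangular motion defaults, not of the
coupling scheme; a dwell-at-contact waveform would decouple them.

## Problem sizes

Default runs use 100 compartments × 2×10⁵ steps (200 ms at 1 µs);
sweeps cover 7 speeds × 4 morphologies × 2 protocols with one 21-node
Poisson curve per morphology at 16 cells/layer; oracle-grade flat solves
use 512 cells/layer. The full sweep pair runs in ~3 minutes on one CPU
with the numba kernel.

## Known limitations

* 2D cross-section surrogate for the 3D device; fringe fields at the
  plate perimeter and pattern corners are approximate.
* Single motion waveform (triangular); no dwell, no load circuit, no
  charge decay.
* Uniform coupling along the axon ignores the device's spatial
  footprint.
* The charge-quotient capacitance C = σA/V_oc is exposed but
  deliberately not used for the neuron drive (see above).
* No temperature dependence or stochastic channel gating.
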