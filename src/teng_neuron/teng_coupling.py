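"""Coupling of a moving contact-separation TENG to the cable-model axon.

As the device gap x(t) changes at contact-release speed dx/dt, the
gap-dependent open-circuit voltage V_oc(x) and capacitance C(x) enter the
membrane balance as an extra drive current and a modified effective
capacitance.  Per membrane area (C here is the TENG capacitance divided by
the plate area):

    (C_m - C(x)) dV_m/dt = axial - I_ion
                           - dC/dx * dx/dt * (V_oc(x) - V_m)
                           - C(x) * dV_oc/dx * dx/dt

The drive is affine in V_m, I_drive = A(t) + B(t) V_m with
A = -dC/dx*dxdt*V_oc - C*dVoc/dx*dxdt and B = +dC/dx*dxdt, so the whole
time dependence can be precomputed from the motion profile and the
tabulated TENGCurve before entering the stepping kernel.

A motionless device (speed 0) exchanges no charge with the membrane: the
coupled update then degenerates exactly to the plain cable update
(denominator C_m), and the zero-speed run is bit-identical to the plain
run by construction.

Units at the interface: motion in cm and cm/s (converted internally to
the solver's cm/ms), curve queries in SI (m, V, F/cm^2), membrane terms
in mV / ms / uA/cm^2 / uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cable_core import (
    NO_STIMULUS,
    AxonConfig,
    AxonState,
    SimResult,
    StimulusProtocol,
    _advance,
    check_stability,
    resting_state,
)
from .hh_membrane import MembraneParams
from .teng_model import TENGCurve, query_curve

CM_PER_M = 100.0


class ModelValidityError(RuntimeError):
    """Raised when C(x) >= C_m: the update denominator C_m - C(x) of the
    discretized scheme would vanish or change sign."""


@dataclass(frozen=True)
class MotionProfile:
    """Triangular contact-release motion of the top plate.

    The plate starts separated at ``x_max`` and, from ``t_start`` on,
    oscillates between ``x_min`` and ``x_max`` at constant speed ``v``
    (|dx/dt| = v except at the turning points, where the incoming
    one-sided velocity is used).
    """

    v: float = 0.5            # cm/s
    x_min: float = 1e-4       # cm (1 um: avoids the gap-0 V_oc=0 corner)
    x_max: float = 0.05       # cm
    t_start: float = 0.0      # ms
    waveform: str = "triangular"

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("speed must be >= 0")
        if not (0 <= self.x_min < self.x_max):
            raise ValueError("need 0 <= x_min < x_max")
        if self.waveform != "triangular":
            raise ValueError("only the triangular waveform is implemented")

    @property
    def period_ms(self) -> float:
        """Full contact-release period 2(x_max - x_min)/v in ms."""
        if self.v == 0:
            return np.inf
        return 2.0 * (self.x_max - self.x_min) / self.v * 1e3


def gap_trajectory(t, profile: MotionProfile):
    """Gap x (cm) and velocity dx/dt (cm/s) at time(s) ``t`` (ms).

    Vectorized over ``t``.  Before ``t_start`` the plate rests at x_max
    with zero velocity; at the exact turning samples the incoming
    segment's one-sided velocity is reported.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = np.isscalar(t) or t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    x = np.full_like(t_arr, profile.x_max)
    dxdt = np.zeros_like(t_arr)
    if profile.v > 0:
        stroke_ms = (profile.x_max - profile.x_min) / profile.v * 1e3
        active = t_arr >= profile.t_start
        tau = np.mod(t_arr[active] - profile.t_start, 2.0 * stroke_ms)
        down = tau <= stroke_ms
        v_cm_ms = profile.v * 1e-3
        xa = np.empty_like(tau)
        va = np.empty_like(tau)
        xa[down] = profile.x_max - v_cm_ms * tau[down]
        va[down] = -profile.v
        xa[~down] = profile.x_min + v_cm_ms * (tau[~down] - stroke_ms)
        va[~down] = profile.v
        # turning samples: keep the incoming side's velocity
        at_top = (tau == 0.0) & (t_arr[active] > profile.t_start)
        va[at_top] = profile.v
        xa[at_top] = profile.x_max
        x[active] = xa
        dxdt[active] = va
    if scalar:
        return float(x[0]), float(dxdt[0])
    return x, dxdt


@dataclass
class CouplingTerms:
    """Instantaneous TENG drive at one gap position."""

    I_drive: float   # uA/cm^2
    C_x: float       # TENG capacitance per area, uF/cm^2
    x: float         # cm
    dxdt: float      # cm/s


def _per_area_terms(x_cm, curve: TENGCurve):
    """Query the curve at gap(s) in cm; return (voc_mV, c_uF, dvoc_mV_per_cm,
    dcap_uF_per_cm2_per_cm) in solver units."""
    voc, cpa, dvoc, dcap = query_curve(curve, np.asarray(x_cm) / CM_PER_M)
    voc_mV = np.asarray(voc) * 1e3
    c_uF = np.asarray(cpa) * 1e6
    dvoc_mV_cm = np.asarray(dvoc) * 1e3 / CM_PER_M
    dcap_uF_cm = np.asarray(dcap) * 1e6 / CM_PER_M
    return voc_mV, c_uF, dvoc_mV_cm, dcap_uF_cm


def coupling_terms(
    x: float, dxdt: float, V_m: float, curve: TENGCurve, C_m: float = 1.0
) -> CouplingTerms:
    """Evaluate the TENG drive current at gap ``x`` (cm), speed ``dxdt``
    (cm/s) and membrane potential ``V_m`` (mV):

    I_drive = -dC/dx * dxdt * (V_oc - V_m) - C * dV_oc/dx * dxdt
    """
    voc, c, dvoc, dcap = _per_area_terms(x, curve)
    if c >= C_m:
        raise ModelValidityError(
            f"TENG capacitance per area {c:.3g} uF/cm^2 >= C_m {C_m:g}: "
            "the update denominator C_m - C(x) would vanish or flip sign"
        )
    dxdt_ms = dxdt * 1e-3
    i_drive = -dcap * dxdt_ms * (voc - V_m) - c * dvoc * dxdt_ms
    return CouplingTerms(I_drive=float(i_drive), C_x=float(c), x=x, dxdt=dxdt)


def _drive_arrays(
    profile: MotionProfile,
    curve: TENGCurve,
    nsteps: int,
    dt: float,
    t0: float,
    C_m: float,
):
    """Precompute (A, B, Cx) per step: I_drive = A + B*V, denominator C_m - Cx."""
    t = t0 + np.arange(nsteps) * dt
    x, dxdt = gap_trajectory(t, profile)
    voc, c, dvoc, dcap = _per_area_terms(x, curve)
    if np.any(c >= C_m):
        raise ModelValidityError(
            f"TENG capacitance per area reaches {float(np.max(c)):.3g} uF/cm^2 "
            f">= C_m {C_m:g} along the trajectory"
        )
    dxdt_ms = dxdt * 1e-3
    a = -dcap * dxdt_ms * voc - c * dvoc * dxdt_ms
    b = dcap * dxdt_ms
    return np.ascontiguousarray(a), np.ascontiguousarray(b), np.ascontiguousarray(c), x, dxdt


def step_coupled(
    state: AxonState,
    profile: MotionProfile,
    curve: TENGCurve,
    p: MembraneParams,
    cfg: AxonConfig,
    coupled_compartments: Optional[tuple[int, int]] = None,
    stim: StimulusProtocol = NO_STIMULUS,
) -> AxonState:
    """One explicit step of the TENG-coupled cable equation.

    On coupled compartments the voltage update divides by C_m - C(x) and
    adds the drive current; elsewhere it is the plain update.  With a
    zero-speed profile this is exactly ``step_plain``.
    """
    check_stability(cfg, p)
    new = state.copy()
    lo, hi = coupled_compartments or (0, cfg.n_compartments)
    if profile.v == 0:
        zeros = np.zeros(1)
        _advance(new, cfg, stim, p, 1, zeros, zeros, zeros, 0, 0, record_every=1)
        return new
    a, b, c, _, _ = _drive_arrays(profile, curve, 1, cfg.dt, state.t, p.C_m)
    _advance(new, cfg, stim, p, 1, a, b, c, lo, hi, record_every=1)
    return new


def run_coupled(
    cfg: AxonConfig,
    profile: MotionProfile,
    curve: TENGCurve,
    stim: Optional[StimulusProtocol] = None,
    p: MembraneParams = MembraneParams(),
    coupled_compartments: Optional[tuple[int, int]] = None,
) -> SimResult:
    """Full TENG-coupled simulation from the resting steady state.

    ``stim=None`` is the resting protocol; pass a suprathreshold
    StimulusProtocol for the firing protocol.  The recorded result carries
    the gap trajectory alongside the voltage trace.
    """
    check_stability(cfg, p)
    stim = stim or NO_STIMULUS
    state = resting_state(cfg, p)
    nsteps = round(cfg.t_end / cfg.dt)
    rec = cfg.record_every
    lo, hi = coupled_compartments or (0, cfg.n_compartments)
    if profile.v == 0:
        zeros = np.zeros(nsteps)
        a = b = c = zeros
        lo = hi = 0
    else:
        a, b, c, _, _ = _drive_arrays(profile, curve, nsteps, cfg.dt, 0.0, p.C_m)
    v_rows = _advance(state, cfg, stim, p, nsteps, a, b, c, lo, hi, rec)
    n_rec = v_rows.shape[0]
    times = np.concatenate([[0.0], (np.arange(1, n_rec + 1) * rec) * cfg.dt])
    v_trace = np.vstack([resting_state(cfg, p).V, v_rows])
    x_t, dxdt_t = gap_trajectory(times, profile)
    snapshot = {
        "axon": cfg.__dict__ | {},
        "stimulus": stim.__dict__ | {},
        "membrane": p.__dict__ | {},
        "motion": profile.__dict__ | {},
        "curve_provenance": curve.provenance,
        "coupled_compartments": [lo, hi],
        "mode": "coupled",
    }
    return SimResult(
        times=times,
        V_trace=v_trace,
        config=snapshot,
        log={"resting_potential_mV": float(v_trace[0, 0])},
        x_t=x_t,
        dxdt_t=dxdt_t,
    )
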