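"""Compartmental cable-equation solver for an unmyelinated axon.

The axon is a cylinder of radius a discretized into n compartments of
length dz.  Membrane dynamics per compartment follow the Hodgkin-Huxley
model; compartments couple through the axial term

    (1 / (2 pi a (r_i + r_e))) d2V/dz2

with r_i = R_i / (pi a^2) and, by the same cross-section convention,
r_e = R_e / (pi a^2) (set R_e = 0 for an ideal extracellular bath).
Boundaries are sealed (zero axial current).

Unit system: mV, ms, cm, uA/cm^2, uF/cm^2, mS/cm^2, Ohm*cm.  The axial
prefactor 1/((2 pi a)(r_i+r_e)) is in mA/cm^2 per mV/cm^2 and carries an
explicit factor 1000 to express it in uA/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .hh_membrane import (
    GatingState,
    MembraneParams,
    resting_potential,
    steady_state_gating,
)


class InstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class AxonConfig:
    """Axon geometry and numerical grid."""

    a: float = 0.001             # radius, cm
    length: float = 1.0          # cm
    n_compartments: int = 100
    R_i: float = 35.0            # intracellular resistivity, Ohm*cm
    R_e: float = 20.0            # extracellular resistivity, Ohm*cm
    dt: float = 0.001            # ms
    t_end: float = 200.0         # ms
    record_dt: float = 0.025     # output sampling, ms

    def __post_init__(self) -> None:
        if min(self.a, self.length, self.R_i, self.dt, self.t_end) <= 0:
            raise ValueError("a, length, R_i, dt, t_end must be > 0")
        if self.R_e < 0:
            raise ValueError("R_e must be >= 0")
        if self.n_compartments < 3:
            raise ValueError("need at least 3 compartments")
        if self.record_dt < self.dt:
            raise ValueError("record_dt must be >= dt")

    @property
    def dz(self) -> float:
        return self.length / self.n_compartments

    @property
    def record_every(self) -> int:
        return max(1, round(self.record_dt / self.dt))


@dataclass(frozen=True)
class StimulusProtocol:
    """Injected transmembrane current: ``amplitude`` uA/cm^2 during
    [t_on, t_off) on ``target_compartments`` (half-open index range;
    None = all compartments)."""

    amplitude: float = 0.0
    t_on: float = 0.0
    t_off: float = 0.0
    target_compartments: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.amplitude != 0.0 and not (self.t_on < self.t_off):
            raise ValueError("need t_on < t_off for a non-zero stimulus")

    def target_range(self, n_compartments: int) -> tuple[int, int]:
        if self.target_compartments is None:
            return 0, n_compartments
        lo, hi = self.target_compartments
        if not (0 <= lo < hi <= n_compartments):
            raise ValueError(
                f"target_compartments {self.target_compartments} invalid for "
                f"{n_compartments} compartments"
            )
        return lo, hi


NO_STIMULUS = StimulusProtocol()


@dataclass
class AxonState:
    """Membrane potential and gating per compartment at time ``t`` (ms)."""

    V: np.ndarray
    gating: GatingState
    t: float = 0.0

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        ncomp = len(self.V)
        for name in ("n", "m", "h"):
            arr = np.asarray(getattr(self.gating, name), dtype=float)
            if arr.shape != (ncomp,):
                raise ValueError("gating arrays must match n_compartments")

    def copy(self) -> "AxonState":
        return AxonState(
            V=self.V.copy(),
            gating=GatingState(
                n=np.asarray(self.gating.n).copy(),
                m=np.asarray(self.gating.m).copy(),
                h=np.asarray(self.gating.h).copy(),
            ),
            t=self.t,
        )


@dataclass
class SimResult:
    """Recorded trace of one simulation run."""

    times: np.ndarray            # ms, strictly increasing
    V_trace: np.ndarray          # (n_times, n_compartments) mV
    config: dict                 # snapshot of every input
    log: dict = field(default_factory=dict)
    x_t: Optional[np.ndarray] = None      # TENG gap (cm) at recorded times
    dxdt_t: Optional[np.ndarray] = None   # cm/s at recorded times

    def __post_init__(self) -> None:
        if self.V_trace.shape[0] != len(self.times):
            raise ValueError("V_trace rows must match times")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def compartment_trace(self, index: int | None = None):
        """(times, V) of one compartment; default: the middle one."""
        if index is None:
            index = self.V_trace.shape[1] // 2
        return self.times, self.V_trace[:, index]


def per_length_resistances(cfg: AxonConfig) -> tuple[float, float]:
    """Axial resistances per unit length (Ohm/cm): r = R / (pi a^2)."""
    area = math.pi * cfg.a ** 2
    return cfg.R_i / area, cfg.R_e / area


def axial_coefficient(cfg: AxonConfig) -> float:
    """k such that the axial current density is k * (discrete Laplacian of
    V in mV), in uA/cm^2: k = 1000 / ((2 pi a)(r_i + r_e) dz^2)."""
    r_i, r_e = per_length_resistances(cfg)
    return 1e3 / ((2.0 * math.pi * cfg.a) * (r_i + r_e) * cfg.dz ** 2)


def stability_limit(cfg: AxonConfig, p: MembraneParams) -> float:
    """Largest explicit dt (ms) for the axial diffusion term:
    dt <= C_m / (2 k) with k the axial coefficient per dz^2."""
    return 0.5 * p.C_m / axial_coefficient(cfg)


def check_stability(cfg: AxonConfig, p: MembraneParams) -> None:
    lim = stability_limit(cfg, p)
    if cfg.dt > lim:
        raise InstabilityError(
            f"dt={cfg.dt} ms exceeds the explicit stability bound "
            f"{lim:.3g} ms for dz={cfg.dz} cm"
        )


def laplacian_term(V: np.ndarray, dz: float, cfg: AxonConfig) -> np.ndarray:
    """Axial (cable) current density in uA/cm^2 for a voltage profile.

    Second central difference with sealed ends, scaled by
    1000/((2 pi a)(r_i+r_e) dz^2).
    """
    V = np.asarray(V, dtype=float)
    if len(V) < 3:
        raise ValueError("need >= 3 compartments")
    r_i, r_e = per_length_resistances(cfg)
    k = 1e3 / ((2.0 * math.pi * cfg.a) * (r_i + r_e) * dz ** 2)
    out = np.empty_like(V)
    out[1:-1] = k * (V[:-2] - 2.0 * V[1:-1] + V[2:])
    out[0] = k * (V[1] - V[0])
    out[-1] = k * (V[-2] - V[-1])
    return out


def resting_state(cfg: AxonConfig, p: MembraneParams) -> AxonState:
    """Uniform steady state: V at the zero-current root, gating at x_inf."""
    v0 = resting_potential(p)
    g = steady_state_gating(v0, p.V_rest)
    ncomp = cfg.n_compartments
    return AxonState(
        V=np.full(ncomp, v0),
        gating=GatingState(
            n=np.full(ncomp, g.n), m=np.full(ncomp, g.m), h=np.full(ncomp, g.h)
        ),
        t=0.0,
    )


def _kernel_args(cfg: AxonConfig, stim: StimulusProtocol, p: MembraneParams):
    lo, hi = stim.target_range(cfg.n_compartments)
    on = round(stim.t_on / cfg.dt)
    off = round(stim.t_off / cfg.dt)
    if stim.amplitude == 0.0:
        on = off = 0
    return dict(
        k_lap=axial_coefficient(cfg),
        e_na=p.E_Na, e_k=p.E_K, e_l=p.E_L,
        gbar_na=p.gbar_Na, gbar_k=p.gbar_K, g_l=p.g_L,
        c_m=p.C_m, v_rest=p.V_rest,
        stim_amp=stim.amplitude, stim_lo=lo, stim_hi=hi,
        stim_on=on, stim_off=off,
    )


def _advance(
    state: AxonState,
    cfg: AxonConfig,
    stim: StimulusProtocol,
    p: MembraneParams,
    nsteps: int,
    drive_a: np.ndarray,
    drive_b: np.ndarray,
    cap_x: np.ndarray,
    coup_lo: int,
    coup_hi: int,
    record_every: int,
) -> np.ndarray:
    """Advance ``state`` in place by ``nsteps``; returns the recorded rows."""
    n_rec = nsteps // record_every
    v_out = np.empty((n_rec, cfg.n_compartments))
    step0 = round(state.t / cfg.dt)
    args = _kernel_args(cfg, stim, p)
    bad = _kernel.run_steps(
        state.V,
        np.asarray(state.gating.n), np.asarray(state.gating.m),
        np.asarray(state.gating.h),
        nsteps, step0, cfg.dt,
        args["k_lap"],
        args["e_na"], args["e_k"], args["e_l"],
        args["gbar_na"], args["gbar_k"], args["g_l"],
        args["c_m"], args["v_rest"],
        args["stim_amp"], args["stim_lo"], args["stim_hi"],
        args["stim_on"], args["stim_off"],
        drive_a, drive_b, cap_x,
        coup_lo, coup_hi,
        record_every, v_out,
    )
    if bad >= 0:
        raise InstabilityError(
            f"non-finite membrane potential at step {bad} "
            f"(t={bad * cfg.dt:.4g} ms); dt={cfg.dt} ms, dz={cfg.dz} cm"
        )
    state.t = (step0 + nsteps) * cfg.dt
    return v_out


def step_plain(
    state: AxonState,
    stim: StimulusProtocol,
    p: MembraneParams,
    cfg: AxonConfig,
) -> AxonState:
    """One forward-Euler + exponential-Euler step of the plain cable run."""
    check_stability(cfg, p)
    new = state.copy()
    zeros = np.zeros(1)
    _advance(new, cfg, stim, p, 1, zeros, zeros, zeros, 0, 0, record_every=1)
    return new


def run_plain(
    cfg: AxonConfig,
    stim: StimulusProtocol = NO_STIMULUS,
    p: MembraneParams = MembraneParams(),
) -> SimResult:
    """Full plain-cable simulation from the resting steady state."""
    check_stability(cfg, p)
    state = resting_state(cfg, p)
    nsteps = round(cfg.t_end / cfg.dt)
    rec = cfg.record_every
    zeros = np.zeros(nsteps)
    v_rows = _advance(state, cfg, stim, p, nsteps, zeros, zeros, zeros, 0, 0, rec)
    n_rec = v_rows.shape[0]
    times = np.concatenate([[0.0], (np.arange(1, n_rec + 1) * rec) * cfg.dt])
    v0 = resting_state(cfg, p).V
    v_trace = np.vstack([v0, v_rows])
    snapshot = {
        "axon": cfg.__dict__ | {},
        "stimulus": stim.__dict__ | {},
        "membrane": p.__dict__ | {},
        "mode": "plain",
    }
    return SimResult(
        times=times,
        V_trace=v_trace,
        config=snapshot,
        log={"resting_potential_mV": float(v0[0]), "kernel_numba": _kernel.HAVE_NUMBA},
    )
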