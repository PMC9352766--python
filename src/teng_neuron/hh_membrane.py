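"""Hodgkin-Huxley membrane kinetics for the squid giant axon.

Classical conductance-based model: potassium (gated by n^4), sodium
(m^3 h) and a fixed leak.  Rate functions are the standard 1952
squid-axon forms written in absolute membrane potential with a resting
potential of -60 mV (the classical expressions with V replaced by
V - V_rest); no temperature scaling is applied.

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2.  All functions accept scalars
or numpy arrays of membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class MembraneParams:
    """Membrane constants (defaults: squid-axon values used throughout)."""

    E_Na: float = 52.4     # mV
    E_K: float = -72.1     # mV
    E_L: float = -49.2     # mV
    gbar_Na: float = 120.0  # mS/cm^2
    gbar_K: float = 36.0    # mS/cm^2
    g_L: float = 0.3        # mS/cm^2
    C_m: float = 1.0        # uF/cm^2
    V_rest: float = -60.0   # mV

    def __post_init__(self) -> None:
        if min(self.gbar_Na, self.gbar_K, self.g_L, self.C_m) <= 0:
            raise ValueError("conductances and C_m must be strictly positive")
        if not (self.E_Na > self.V_rest > self.E_K):
            raise ValueError("need E_Na > V_rest > E_K")


@dataclass
class GatingState:
    """Channel gating probabilities (each in [0, 1]; scalar or array)."""

    n: np.ndarray | float
    m: np.ndarray | float
    h: np.ndarray | float

    def __post_init__(self) -> None:
        for name in ("n", "m", "h"):
            v = np.asarray(getattr(self, name))
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"gating variable {name} outside [0, 1]")


def _safe_exprel_inv(u):
    """u / (exp(u) - 1), continuous through u = 0."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-7
    out[small] = 1.0 - u[small] / 2.0
    us = u[~small]
    out[~small] = us / np.expm1(us)
    return out


def rate_constants(V, V_rest: float = -60.0):
    """Opening/closing rates (alpha_n, beta_n, alpha_m, beta_m, alpha_h,
    beta_h) in 1/ms at membrane potential ``V`` (mV).

    The removable singularities of alpha_n (at V_rest+10) and alpha_m
    (at V_rest+25) are filled with their limits.
    """
    v = np.asarray(V, dtype=float) - V_rest
    a_n = 0.1 * _safe_exprel_inv((10.0 - v) / 10.0)
    b_n = 0.125 * np.exp(-v / 80.0)
    a_m = 1.0 * _safe_exprel_inv((25.0 - v) / 10.0)
    b_m = 4.0 * np.exp(-v / 18.0)
    a_h = 0.07 * np.exp(-v / 20.0)
    b_h = 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)
    if np.isscalar(V):
        return tuple(float(x) for x in (a_n, b_n, a_m, b_m, a_h, b_h))
    return a_n, b_n, a_m, b_m, a_h, b_h


def steady_state_gating(V, V_rest: float = -60.0) -> GatingState:
    """Gating fixed point x_inf = alpha / (alpha + beta) at clamped ``V``."""
    a_n, b_n, a_m, b_m, a_h, b_h = rate_constants(V, V_rest)
    return GatingState(
        n=a_n / (a_n + b_n), m=a_m / (a_m + b_m), h=a_h / (a_h + b_h)
    )


def advance_gating(
    state: GatingState, V, dt: float, V_rest: float = -60.0
) -> GatingState:
    """One exponential-Euler step of the gating ODEs dx/dt = a(1-x) - b x.

    Each variable relaxes exactly toward its voltage-dependent fixed point
    with time constant 1/(alpha+beta); the update cannot leave [0, 1] for
    any dt > 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a_n, b_n, a_m, b_m, a_h, b_h = rate_constants(V, V_rest)

    def step(x, a, b):
        inf = a / (a + b)
        return inf + (x - inf) * np.exp(-dt * (a + b))

    return GatingState(
        n=step(state.n, a_n, b_n),
        m=step(state.m, a_m, b_m),
        h=step(state.h, a_h, b_h),
    )


def conductances(state: GatingState, p: MembraneParams):
    """(g_K, g_Na) in mS/cm^2: g_K = gbar_K n^4, g_Na = gbar_Na m^3 h."""
    g_K = p.gbar_K * np.asarray(state.n) ** 4
    g_Na = p.gbar_Na * np.asarray(state.m) ** 3 * np.asarray(state.h)
    return g_K, g_Na


def ionic_current(V, state: GatingState, p: MembraneParams):
    """Total ionic membrane current (uA/cm^2), outward positive:

    I_ion = g_K (V - E_K) + g_Na (V - E_Na) + g_L (V - E_L)
    """
    g_K, g_Na = conductances(state, p)
    return (
        g_K * (np.asarray(V) - p.E_K)
        + g_Na * (np.asarray(V) - p.E_Na)
        + p.g_L * (np.asarray(V) - p.E_L)
    )


def resting_potential(p: MembraneParams) -> float:
    """True resting potential: the root of I_ion(V, x_inf(V)) = 0.

    With the default constants this sits within a fraction of a millivolt
    of the nominal V_rest = -60 mV (E_L is chosen so the currents balance
    there), but the solver steady state is what the simulations use as
    their initial condition.
    """

    def f(v):
        return float(ionic_current(v, steady_state_gating(v, p.V_rest), p))

    return brentq(f, p.V_rest - 15.0, p.V_rest + 15.0, xtol=1e-12)
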