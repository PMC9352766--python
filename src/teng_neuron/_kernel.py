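"""Explicit time-stepping kernel shared by the plain and TENG-coupled runs.

One code path serves both simulators: the coupled run supplies per-step
drive coefficients (A, B, with I_drive = A + B*V in uA/cm^2) and the
instantaneous TENG capacitance per area Cx (uF/cm^2, entering the update
denominator C_m - Cx); the plain run passes zeros.  This guarantees the
zero-speed coupled run reproduces the plain run bit for bit.

Scheme: forward-Euler voltage update (operator split), then exact
exponential-Euler gating update evaluated at the pre-step voltage.
Sealed (zero axial flux) ends.

The kernel is numba-jitted when numba imports cleanly and falls back to
the identical pure-Python function otherwise.
"""

from __future__ import annotations

import math

import numpy as np


def _run_steps(
    V, n, m, h,
    nsteps, step0, dt,
    k_lap,                      # uA/cm^2 per mV of discrete Laplacian
    e_na, e_k, e_l, gbar_na, gbar_k, g_l, c_m, v_rest,
    stim_amp, stim_lo, stim_hi, stim_on, stim_off,   # step indices
    drive_a, drive_b, cap_x,    # arrays of length nsteps (zeros when plain)
    coup_lo, coup_hi,
    record_every, v_out,        # v_out: (n_records, ncomp), filled in order
):
    ncomp = V.shape[0]
    vnew = np.empty(ncomp)
    rec = 0
    for i in range(nsteps):
        step = step0 + i
        stim_on_now = stim_on <= step < stim_off
        a_t = drive_a[i]
        b_t = drive_b[i]
        cx_t = cap_x[i]
        for j in range(ncomp):
            vj = V[j]
            # sealed-end discrete Laplacian
            if j == 0:
                lap = k_lap * (V[1] - vj)
            elif j == ncomp - 1:
                lap = k_lap * (V[ncomp - 2] - vj)
            else:
                lap = k_lap * (V[j - 1] - 2.0 * vj + V[j + 1])
            gk = gbar_k * n[j] ** 4
            gna = gbar_na * m[j] ** 3 * h[j]
            i_ion = gk * (vj - e_k) + gna * (vj - e_na) + g_l * (vj - e_l)
            i_s = stim_amp if (stim_on_now and stim_lo <= j < stim_hi) else 0.0
            if coup_lo <= j < coup_hi:
                denom = c_m - cx_t
                drive = a_t + b_t * vj
            else:
                denom = c_m
                drive = 0.0
            vnew[j] = vj + (dt / denom) * (lap + i_s - i_ion + drive)
        # gating: exponential Euler at the pre-step voltage
        for j in range(ncomp):
            v = V[j] - v_rest
            u = (10.0 - v) / 10.0
            if abs(u) < 1e-7:
                a_n = 0.1 * (1.0 - u / 2.0)
            else:
                a_n = 0.1 * u / (math.exp(u) - 1.0)
            b_n = 0.125 * math.exp(-v / 80.0)
            u = (25.0 - v) / 10.0
            if abs(u) < 1e-7:
                a_m = 1.0 * (1.0 - u / 2.0)
            else:
                a_m = 1.0 * u / (math.exp(u) - 1.0)
            b_m = 4.0 * math.exp(-v / 18.0)
            a_h = 0.07 * math.exp(-v / 20.0)
            b_h = 1.0 / (math.exp((30.0 - v) / 10.0) + 1.0)

            inf = a_n / (a_n + b_n)
            n[j] = inf + (n[j] - inf) * math.exp(-dt * (a_n + b_n))
            inf = a_m / (a_m + b_m)
            m[j] = inf + (m[j] - inf) * math.exp(-dt * (a_m + b_m))
            inf = a_h / (a_h + b_h)
            h[j] = inf + (h[j] - inf) * math.exp(-dt * (a_h + b_h))
        for j in range(ncomp):
            V[j] = vnew[j]
        if (i + 1) % record_every == 0:
            ok = True
            for j in range(ncomp):
                v_out[rec, j] = V[j]
                if not math.isfinite(V[j]):
                    ok = False
            rec += 1
            if not ok:
                return step + 1
    return -1  # all finite


try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    run_steps = njit(cache=True, fastmath=False)(_run_steps)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    run_steps = _run_steps
    HAVE_NUMBA = False
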