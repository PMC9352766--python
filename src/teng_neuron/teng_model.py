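"""Electrostatics of a vertical contact-separation TENG.

A triboelectric nanogenerator (TENG) in contact-separation mode is a
parallel-plate stack: bottom Au electrode / Kapton film / air gap x /
silk film / top Au electrode.  Contact electrification deposits a fixed
surface charge density +sigma on the silk face and -sigma on the Kapton
face; as the plates separate the induced electrode potential difference
(the open-circuit voltage V_oc) grows with the gap while the inter-electrode
capacitance C falls.

This module provides

* closed-form flat-plate expressions for V_oc(x) and C(x),
* a 2D cross-section finite-volume Poisson solver that handles
  micropatterned (cube / pyramid / sphere bump) dielectric surfaces, and
* :class:`TENGCurve`, the tabulated (gap, V_oc, C) record consumed by the
  neuron-coupling stage.

All geometry is in SI metres; voltages in volts; capacitance in farads
(total) and F/cm^2 (per plate area).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

PatternShape = Literal["flat", "cube", "pyramid", "sphere"]
CurveMethod = Literal["closed_form", "poisson_2d"]


@dataclass(frozen=True)
class MicropatternSpec:
    """Surface micropattern carved into the Kapton face.

    ``feature_width``/``feature_height``/``pitch`` describe one periodic
    feature of the given cross-section shape; they are ignored for
    ``shape="flat"``.
    """

    shape: PatternShape = "flat"
    feature_width: float = 10e-6
    feature_height: float = 10e-6
    pitch: float = 20e-6

    def __post_init__(self) -> None:
        if self.shape not in ("flat", "cube", "pyramid", "sphere"):
            raise ValueError(f"unknown pattern shape {self.shape!r}")
        if self.shape != "flat":
            if not (0 < self.feature_width <= self.pitch):
                raise ValueError("need 0 < feature_width <= pitch")
            if self.feature_height <= 0:
                raise ValueError("feature_height must be positive")

    def height_profile(self, xi: np.ndarray) -> np.ndarray:
        """Feature height above the nominal Kapton surface at lateral
        offset ``xi`` from the feature centre (metres)."""
        xi = np.asarray(xi, dtype=float)
        if self.shape == "flat":
            return np.zeros_like(xi)
        half = self.feature_width / 2.0
        inside = np.abs(xi) <= half
        h = np.zeros_like(xi)
        if self.shape == "cube":
            h[inside] = self.feature_height
        elif self.shape == "pyramid":
            h[inside] = self.feature_height * (1.0 - np.abs(xi[inside]) / half)
        else:  # sphere -> semi-elliptical cross-section
            h[inside] = self.feature_height * np.sqrt(
                np.clip(1.0 - (xi[inside] / half) ** 2, 0.0, None)
            )
        return h


@dataclass(frozen=True)
class TENGConfig:
    """Device geometry and materials (defaults: the silk/Kapton device)."""

    plate_area: float = 15e-5          # m^2
    d_silk: float = 7e-7               # m
    d_kapton: float = 7e-7             # m
    electrode_thickness: float = 5e-7  # m
    sigma: float = 5e-5                # tribo surface charge density, C/m^2
    eps_silk: float = 2.6
    eps_kapton: float = 3.4
    pattern: MicropatternSpec = field(default_factory=MicropatternSpec)

    def __post_init__(self) -> None:
        for name in ("plate_area", "d_silk", "d_kapton", "electrode_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.eps_silk < 1 or self.eps_kapton < 1:
            raise ValueError("relative permittivities must be >= 1")

    @property
    def d_eff(self) -> float:
        """Effective dielectric thickness d_silk/eps_silk + d_kapton/eps_kapton (m)."""
        return self.d_silk / self.eps_silk + self.d_kapton / self.eps_kapton

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "plate_area": self.plate_area,
                "d_silk": self.d_silk,
                "d_kapton": self.d_kapton,
                "electrode_thickness": self.electrode_thickness,
                "sigma": self.sigma,
                "eps_silk": self.eps_silk,
                "eps_kapton": self.eps_kapton,
                "pattern": [
                    self.pattern.shape,
                    self.pattern.feature_width,
                    self.pattern.feature_height,
                    self.pattern.pitch,
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def closed_form_voc(gap: float, cfg: TENGConfig) -> float:
    """Open-circuit voltage of the flat parallel-plate device, sigma*x/eps0.

    With equal and opposite tribo charge on the facing dielectric surfaces
    and zero net free charge on the floating electrodes, the displacement
    field vanishes everywhere except in the air gap where D = -sigma, so
    V_oc grows linearly with the gap and is independent of the dielectric
    thicknesses.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    return cfg.sigma * gap / EPS0


def closed_form_capacitance(gap: float, cfg: TENGConfig) -> float:
    """Series dielectric-stack capacitance eps0*A/(d_silk/eps_s + d_kapton/eps_k + x)."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if cfg.plate_area <= 0:  # pragma: no cover - guarded by TENGConfig
        raise ValueError("plate_area must be positive")
    return EPS0 * cfg.plate_area / (cfg.d_eff + gap)


@dataclass
class FieldSolution:
    """Potential on the 2D cross-section grid plus the electrode potentials."""

    grid_potential: np.ndarray        # (ny, nx) volts, cell-centred
    cell_size: float                  # representative (gap-layer) cell height, m
    gap: float                        # m
    electrode_potentials: tuple[float, float]  # (V_bottom, V_top)
    convergence_estimate: float       # relative V_oc change under one refinement
    capacitance: float = 0.0          # electrode-to-electrode C (F) for the
                                      # full plate area, from the charge-free
                                      # unit (1 V) field problem

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid_potential)):
            raise ValueError("grid potential contains non-finite values")
        if self.convergence_estimate < 0:
            raise ValueError("convergence_estimate must be >= 0")

    @property
    def voc(self) -> float:
        return self.electrode_potentials[1] - self.electrode_potentials[0]


class SolverError(RuntimeError):
    pass


def _band_edges(cfg: TENGConfig, gap: float) -> dict[str, tuple[float, float]]:
    """Vertical extents of the dielectric stack between the electrode faces.

    ``gap`` is the air distance between the pattern tips and the silk face
    (x=0 means contact).  The electrodes themselves are not discretized:
    they are the Dirichlet boundaries at the bottom and top of the stack.
    """
    h = cfg.pattern.feature_height if cfg.pattern.shape != "flat" else 0.0
    y0 = 0.0
    bands = {}
    bands["kapton"] = (y0, y0 + cfg.d_kapton)
    y0 += cfg.d_kapton
    if h > 0:
        bands["pattern"] = (y0, y0 + h)
        y0 += h
    bands["gap"] = (y0, y0 + gap)
    y0 += gap
    bands["silk"] = (y0, y0 + cfg.d_silk)
    return bands


def _solve_once(cfg: TENGConfig, gap: float, cells_per_layer: int):
    """Assemble and solve one finite-volume Poisson problem.

    The electrodes are floating equipotential Dirichlet surfaces: the
    bottom electrode is the 0 V gauge and the top-electrode potential V_t
    is fixed by requiring zero net induced charge on it.  By superposition
    phi = phi_q + V_t * phi_u, where phi_q has both electrodes grounded
    with the tribo charges as sources and phi_u is the charge-free unit
    problem (bottom 0, top 1);  V_t = -Q_top(phi_q) / Q_top(phi_u).

    Returns (phi grid, y cell edges, x cell width, V_bottom, V_top,
    gap cell height).
    """
    n = int(cells_per_layer)
    pat = cfg.pattern
    flat = pat.shape == "flat" or pat.feature_height == 0.0

    bands = _band_edges(cfg, gap)
    # lateral domain: one pattern pitch (patterned) or a token width (flat)
    if flat:
        width = 4e-6
        nx = 4
    else:
        width = pat.pitch
        nx = max(16, 2 * n)
    dx = width / nx
    xc = (np.arange(nx) + 0.5) * dx - width / 2.0  # centred on the feature

    # vertical edges, band by band
    y_edges = [0.0]
    band_rows: dict[str, tuple[int, int]] = {}
    for name, (lo, hi) in bands.items():
        if hi - lo <= 0:
            band_rows[name] = (len(y_edges) - 1, len(y_edges) - 1)
            continue
        start = len(y_edges) - 1
        y_edges.extend(np.linspace(lo, hi, n + 1)[1:])
        band_rows[name] = (start, start + n)
    y_edges = np.asarray(y_edges)
    ny = len(y_edges) - 1
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    dy = np.diff(y_edges)

    # permittivity map
    eps = np.ones((ny, nx))
    r0, r1 = band_rows["kapton"]
    eps[r0:r1, :] = cfg.eps_kapton
    r0, r1 = band_rows["silk"]
    eps[r0:r1, :] = cfg.eps_silk
    if not flat:
        r0, r1 = band_rows["pattern"]
        h_col = pat.height_profile(xc)
        y_pat0 = bands["pattern"][0]
        for j in range(r0, r1):
            inside = yc[j] - y_pat0 <= h_col
            eps[j, inside] = cfg.eps_kapton

    # --- tribo surface charge -------------------------------------------
    # charge per cell (C per metre of depth); deposited in the first air
    # cell on the outward side of each charged dielectric surface
    q = np.zeros((ny, nx))
    gap_r0, gap_r1 = band_rows["gap"]
    dy_gap = dy[gap_r0] if gap_r1 > gap_r0 else 0.0

    # Kapton surface (negative charge), following the pattern contour
    if flat:
        q_kapton_total = -cfg.sigma * width
        q[gap_r0, :] += q_kapton_total / nx
    else:
        y_surface_base = bands["kapton"][1]
        nsub = 8
        xs = np.linspace(-width / 2.0, width / 2.0, nx * nsub + 1)
        hs = pat.height_profile(xs)
        q_kapton_total = 0.0
        for k in range(len(xs) - 1):
            seg_len = math.hypot(xs[k + 1] - xs[k], hs[k + 1] - hs[k])
            dq = -cfg.sigma * seg_len
            q_kapton_total += dq
            xm = 0.5 * (xs[k] + xs[k + 1])
            ym = y_surface_base + 0.5 * (hs[k] + hs[k + 1])
            # outward normal of the surface (pointing into the air)
            tx, ty = xs[k + 1] - xs[k], hs[k + 1] - hs[k]
            norm = math.hypot(tx, ty) or 1.0
            nxv, nyv = -ty / norm, tx / norm  # rotate tangent by +90 deg
            if nyv < 0:
                nxv, nyv = -nxv, -nyv
            # step outward until the containing cell is air
            ci = min(nx - 1, max(0, int((xm + width / 2.0) / dx)))
            cj = int(np.searchsorted(y_edges, ym, side="right") - 1)
            cj = min(ny - 1, max(0, cj))
            step = 0
            while eps[cj, ci] != 1.0 and step < ny:
                px = xm + nxv * (step + 1) * 0.6 * min(dx, dy_gap or dx)
                py = ym + nyv * (step + 1) * 0.6 * min(dx, dy_gap or dx)
                ci = min(nx - 1, max(0, int((px + width / 2.0) / dx)))
                cj = min(ny - 1, max(0, int(np.searchsorted(y_edges, py, side="right") - 1)))
                step += 1
            q[cj, ci] += dq

    # silk surface (positive, balances the Kapton total): first air cell
    # below the silk face
    if gap_r1 > gap_r0:
        q[gap_r1 - 1, :] += -q_kapton_total / nx

    # --- finite-volume assembly -----------------------------------------
    # unknowns phi[j, i]; zero normal D on the lateral box sides; Dirichlet
    # electrode faces at y=0 (phi=0) and y=y_top (phi=V_t); face flux
    # coefficient = eps_face * face_len / dist, distance-weighted harmonic
    # mean eps across material interfaces.
    idx = np.arange(ny * nx).reshape(ny, nx)
    rows_l, cols_l, vals_l = [], [], []
    b_q = np.zeros(ny * nx)   # tribo-charge problem, both electrodes 0 V
    b_u = np.zeros(ny * nx)   # unit problem, top electrode at 1 V, no charge

    def add(r, c, v):
        rows_l.append(r)
        cols_l.append(c)
        vals_l.append(v)

    bot_coef = np.empty(nx)
    top_coef = np.empty(nx)
    for j in range(ny):
        for i in range(nx):
            p = idx[j, i]
            diag = 0.0
            # horizontal neighbours (uniform dx, face length dy[j])
            for ii in (i - 1, i + 1):
                if 0 <= ii < nx:
                    e1, e2 = eps[j, i], eps[j, ii]
                    eface = 2.0 * e1 * e2 / (e1 + e2)
                    coef = eface * EPS0 * dy[j] / dx
                    add(p, idx[j, ii], coef)
                    diag -= coef
            # vertical neighbours / electrode faces
            for jj in (j - 1, j + 1):
                if 0 <= jj < ny:
                    d1, d2 = dy[j] / 2.0, dy[jj] / 2.0
                    e1, e2 = eps[j, i], eps[jj, i]
                    eface = (d1 + d2) / (d1 / e1 + d2 / e2)
                    coef = eface * EPS0 * dx / (d1 + d2)
                    add(p, idx[jj, i], coef)
                    diag -= coef
                else:
                    # Dirichlet electrode face at half-cell distance
                    coef = eps[j, i] * EPS0 * dx / (dy[j] / 2.0)
                    diag -= coef
                    if jj == ny:  # top electrode, potential V_t
                        top_coef[i] = coef
                        b_u[p] -= coef * 1.0
                    else:
                        bot_coef[i] = coef
            add(p, p, diag)
            b_q[p] += -q[j, i]

    A = csr_matrix((vals_l, (rows_l, cols_l)), shape=(ny * nx, ny * nx))
    sol2 = spsolve(A, np.column_stack([b_q, b_u]))
    phi_q = sol2[:, 0].reshape(ny, nx)
    phi_u = sol2[:, 1].reshape(ny, nx)
    if not (np.all(np.isfinite(phi_q)) and np.all(np.isfinite(phi_u))):
        raise SolverError(
            f"Poisson solve failed (non-finite potential) at gap={gap:g} m"
        )

    def q_top(phi: np.ndarray, v_t: float) -> float:
        # induced charge on the top electrode = -(outward D flux from it)
        return float(np.sum(top_coef * (phi[ny - 1, :] - v_t)))

    qq = q_top(phi_q, 0.0)
    qu = q_top(phi_u, 1.0)
    if qu == 0.0:
        raise SolverError("degenerate unit problem (zero electrode coupling)")
    v_t = -qq / qu
    phi = phi_q + v_t * phi_u
    if not np.all(np.isfinite(phi)):
        raise SolverError(
            f"Poisson solve failed (non-finite potential) at gap={gap:g} m"
        )
    # electrode-to-electrode capacitance: |charge per volt| in the unit
    # problem (per metre depth, width `width`), scaled to the plate area
    cap_device = abs(qu) * cfg.plate_area / width
    return phi, y_edges, dx, 0.0, v_t, dy_gap, cap_device


def solve_poisson_2d(
    cfg: TENGConfig,
    gap: float,
    cells_per_layer: int = 32,
    compute_convergence: bool = True,
) -> FieldSolution:
    """Solve the 2D cross-section electrostatics of the stack at one gap.

    The bottom electrode / Kapton / air gap / silk / top electrode stack is
    discretized on a rectilinear tensor grid (``cells_per_layer`` cells per
    material band), with the micropattern cross-section carved into the
    Kapton face.  Tribo charge (-sigma per unit surface length on the
    Kapton contour, balancing +charge on the silk face) enters as free
    charge in the adjacent air cells; the electrodes are floating
    equipotential regions (emulated by a very large permittivity) carrying
    zero net free charge; the outer box is zero-normal-field.

    ``convergence_estimate`` is the relative change of V_oc under one mesh
    refinement (cells_per_layer doubled); it is 0 when
    ``compute_convergence=False`` is requested together with sigma == 0.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if cells_per_layer < 4:
        raise ValueError("cells_per_layer must be >= 4")
    if gap == 0.0:
        raise SolverError("gap=0 leaves no air band to discretize; use the closed forms")

    phi, y_edges, dx, v_bot, v_top, dy_gap, cap = _solve_once(cfg, gap, cells_per_layer)
    voc = v_top - v_bot
    conv = 0.0
    if compute_convergence and cfg.sigma > 0:
        _, _, _, vb2, vt2, _, _ = _solve_once(cfg, gap, 2 * cells_per_layer)
        voc2 = vt2 - vb2
        conv = abs(voc - voc2) / max(abs(voc2), 1e-300)
    return FieldSolution(
        grid_potential=phi,
        cell_size=dy_gap,
        gap=gap,
        electrode_potentials=(v_bot, v_top),
        convergence_estimate=conv,
        capacitance=cap,
    )


def extract_voc_capacitance(sol: FieldSolution, cfg: TENGConfig) -> tuple[float, float]:
    """V_oc and C from a field solution, with C = Q/V_oc and Q = sigma*A.

    The tribo charge Q is sigma times the nominal plate area.  When V_oc is
    zero (gap 0, or sigma 0) the quotient is indeterminate and the
    series-stack closed form is returned for C instead.
    """
    voc = sol.voc
    q_tribo = cfg.sigma * cfg.plate_area
    if voc == 0.0 or q_tribo == 0.0:
        return voc, closed_form_capacitance(sol.gap, cfg)
    return voc, q_tribo / voc


@dataclass
class TENGCurve:
    """Tabulated (gap, V_oc, C) characteristic of one device build.

    ``gaps`` in metres (strictly increasing), ``voc`` in volts
    (non-decreasing), ``cap_total`` in farads (non-increasing),
    ``cap_per_area`` in F/cm^2.  Queries interpolate piecewise-linearly;
    derivatives are the forward difference quotients
    (f(x_{k+1}) - f(x_k)) / (x_{k+1} - x_k), i.e. exactly the slopes of
    the piecewise-linear interpolant, held constant on each segment
    (backward quotient on the final node).  The tabulated curve and its
    difference quotients ARE the device model seen by the neuron stage.
    """

    gaps: np.ndarray
    voc: np.ndarray
    cap_total: np.ndarray
    plate_area: float                      # m^2
    provenance: Literal["closed_form", "poisson_2d", "fixture_table"]

    def __post_init__(self) -> None:
        self.gaps = np.asarray(self.gaps, dtype=float)
        self.voc = np.asarray(self.voc, dtype=float)
        self.cap_total = np.asarray(self.cap_total, dtype=float)
        if not (len(self.gaps) == len(self.voc) == len(self.cap_total)):
            raise ValueError("gaps, voc, cap_total must have equal length")
        if len(self.gaps) < 2:
            raise ValueError("need at least 2 gap nodes")
        if np.any(self.gaps < 0) or np.any(np.diff(self.gaps) <= 0):
            raise ValueError("gaps must be strictly increasing and >= 0")
        if np.any(np.diff(self.voc) < 0):
            raise ValueError("voc must be non-decreasing in gap")
        if np.any(np.diff(self.cap_total) > 0):
            raise ValueError("cap_total must be non-increasing in gap")
        if self.plate_area <= 0:
            raise ValueError("plate_area must be positive")
        # per-segment forward difference quotients (= interpolant slopes)
        dg = np.diff(self.gaps)
        self._dvoc_seg = np.diff(self.voc) / dg
        self._dcap_seg = np.diff(self.cap_total) / dg

    @property
    def cap_per_area(self) -> np.ndarray:
        """Capacitance per plate area in F/cm^2."""
        return self.cap_total / (self.plate_area * 1e4)

    def query(self, x: float | np.ndarray):
        return query_curve(self, x)


def build_curve(
    cfg: TENGConfig,
    gaps,
    method: CurveMethod = "closed_form",
    cells_per_layer: int = 24,
) -> TENGCurve:
    """Tabulate V_oc(x) and C(x) over ``gaps`` (metres, strictly increasing).

    With ``method="poisson_2d"`` each positive gap is solved with the 2D
    finite-volume solver; V_oc is the electrode potential difference and C
    the electrode-to-electrode capacitance of the charge-free unit field
    problem (which for flat geometry reproduces the series-stack closed
    form).  A gap node at exactly 0 falls back to the closed forms.
    """
    gaps = np.asarray(gaps, dtype=float)
    if gaps.ndim != 1 or len(gaps) < 2:
        raise ValueError("need >= 2 gap nodes")
    if np.any(gaps < 0) or np.any(np.diff(gaps) <= 0):
        raise ValueError("gaps must be strictly increasing and >= 0")
    if method not in ("closed_form", "poisson_2d"):
        raise ValueError(f"unknown method {method!r}")

    voc = np.empty_like(gaps)
    cap = np.empty_like(gaps)
    for k, g in enumerate(gaps):
        if method == "closed_form" or g == 0.0:
            voc[k] = closed_form_voc(g, cfg)
            cap[k] = closed_form_capacitance(g, cfg)
        else:
            try:
                sol = solve_poisson_2d(
                    cfg, g, cells_per_layer=cells_per_layer, compute_convergence=False
                )
            except SolverError as exc:
                raise SolverError(f"Poisson solve failed at gap={g:g} m: {exc}") from exc
            voc[k] = sol.voc
            cap[k] = sol.capacitance
    return TENGCurve(
        gaps=gaps,
        voc=voc,
        cap_total=cap,
        plate_area=cfg.plate_area,
        provenance=method,
    )


def query_curve(curve: TENGCurve, x):
    """Interpolate (voc [V], cap_per_area [F/cm^2], dvoc_dx [V/m],
    dcap_dx [F/cm^2/m]) at gap ``x`` (metres; scalar or array).

    Values are piecewise-linear in the nodes; the derivatives are the
    difference quotients of the segment containing ``x`` (the forward
    quotient at a node, the backward one at the final node).  No
    extrapolation: ``x`` outside the tabulated range raises.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < curve.gaps[0]) or np.any(x_arr > curve.gaps[-1]):
        raise ValueError(
            f"gap query outside tabulated range "
            f"[{curve.gaps[0]:g}, {curve.gaps[-1]:g}] m"
        )
    area_cm2 = curve.plate_area * 1e4
    voc = np.interp(x_arr, curve.gaps, curve.voc)
    cpa = np.interp(x_arr, curve.gaps, curve.cap_total) / area_cm2
    seg = np.clip(
        np.searchsorted(curve.gaps, x_arr, side="right") - 1,
        0,
        len(curve.gaps) - 2,
    )
    dvoc = curve._dvoc_seg[seg]
    dcap = curve._dcap_seg[seg] / area_cm2
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(voc), float(cpa), float(dvoc), float(dcap)
    return voc, cpa, dvoc, dcap


def default_gap_grid(x_max: float = 5e-4, n: int = 21) -> np.ndarray:
    """Default gap sampling: ``n`` nodes from 0 to ``x_max`` metres."""
    return np.linspace(0.0, x_max, n)
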