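"""Reproducible computational experiments: speed and morphology sweeps.

Two protocols are swept over the contact-release speed grid and the four
electrode morphologies:

* resting — no injected current; every excitation comes from the TENG.
* firing — a sustained suprathreshold current (default 10 uA/cm^2)
  injected during 0-100 ms, the TENG superposed throughout.

The module also hosts the synthetic generators that make the metrics
stage testable without running the PDE solver: template-based voltage
traces with known spike content, and solver-free fixture TENG curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cable_core import AxonConfig, SimResult, StimulusProtocol
from .hh_membrane import MembraneParams
from .spike_metrics import APMetrics, SpikeTrain, summarize_trace
from .teng_coupling import MotionProfile, run_coupled
from .teng_model import (
    TENGConfig,
    TENGCurve,
    build_curve,
    default_gap_grid,
)

SPEED_GRID = (0.025, 0.05, 0.075, 0.1, 0.25, 0.5, 1.0)  # cm/s
PATTERNS = ("flat", "cube", "pyramid", "sphere")


@dataclass
class SweepConfig:
    """Grid and base configuration of one sweep."""

    speeds: tuple = SPEED_GRID
    patterns: tuple = PATTERNS
    protocol: str = "resting"            # "resting" | "firing"
    teng: TENGConfig = field(default_factory=TENGConfig)
    axon: AxonConfig = field(default_factory=AxonConfig)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    motion_x_min: float = 1e-4           # cm
    motion_x_max: float = 0.05           # cm
    firing_amplitude: float = 10.0       # uA/cm^2
    firing_window: tuple = (0.0, 100.0)  # ms
    curve_method: str = "poisson_2d"
    cells_per_layer: int = 16
    n_gap_nodes: int = 21

    def __post_init__(self) -> None:
        if len(self.speeds) == 0 or any(s < 0 for s in self.speeds):
            raise ValueError("speeds must be >= 0 (0 is the static control)")
        if list(self.speeds) != sorted(self.speeds):
            raise ValueError("speeds must be sorted ascending")
        if len(self.patterns) == 0:
            raise ValueError("need at least one pattern")
        if self.protocol not in ("resting", "firing"):
            raise ValueError("protocol must be 'resting' or 'firing'")

    def stimulus(self) -> Optional[StimulusProtocol]:
        if self.protocol == "resting":
            return None
        return StimulusProtocol(
            amplitude=self.firing_amplitude,
            t_on=self.firing_window[0],
            t_off=self.firing_window[1],
        )

    def gap_grid(self) -> np.ndarray:
        return default_gap_grid(self.motion_x_max / 100.0, self.n_gap_nodes)


@dataclass
class SweepResult:
    """Long-format metric table (one row per grid point) plus the raw
    metric objects and traces keyed by (speed, pattern)."""

    table: pd.DataFrame
    metrics: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)


def _metric_row(
    speed: float, pattern: str, protocol: str, m: APMetrics
) -> dict:
    return {
        "speed_cm_s": speed,
        "pattern": pattern,
        "protocol": protocol,
        "n_spikes": m.n_spikes,
        "firing_rate_Hz": m.firing_rate,
        "mean_fwhm_ms": float(np.mean(m.fwhm)) if len(m.fwhm) else np.nan,
        "mean_delay_ms": (
            float(np.mean(m.interspike_delays))
            if len(m.interspike_delays)
            else np.nan
        ),
        "mean_peak_mV": m.mean_peak,
        "baseline_mV": m.baseline,
        "baseline_shift_mV": m.baseline_shift,
    }


def run_protocol(
    cfg: SweepConfig, curve: TENGCurve, speed: float
) -> tuple[SimResult, APMetrics]:
    """One grid point: a coupled run plus its metric summary."""
    profile = MotionProfile(v=speed, x_min=cfg.motion_x_min, x_max=cfg.motion_x_max)
    res = run_coupled(
        cfg.axon, profile, curve, stim=cfg.stimulus(), p=cfg.membrane
    )
    t, v = res.compartment_trace()
    m = summarize_trace(t, v)
    return res, m


def curve_for_pattern(cfg: SweepConfig, pattern: str) -> TENGCurve:
    teng = replace(
        cfg.teng,
        pattern=replace(cfg.teng.pattern, shape=pattern),
    )
    return build_curve(
        teng,
        cfg.gap_grid(),
        method=cfg.curve_method,
        cells_per_layer=cfg.cells_per_layer,
    )


def speed_sweep(cfg: SweepConfig, curve: Optional[TENGCurve] = None) -> SweepResult:
    """Sweep the contact-release speed at one morphology (default: the
    first pattern of the config).  Deterministic; any failed run aborts
    naming its grid point."""
    pattern = cfg.patterns[0]
    if curve is None:
        curve = curve_for_pattern(cfg, pattern)
    rows, metrics, results = [], {}, {}
    for speed in cfg.speeds:
        try:
            res, m = run_protocol(cfg, curve, speed)
        except Exception as exc:
            raise RuntimeError(
                f"sweep failed at speed={speed} cm/s, pattern={pattern}, "
                f"protocol={cfg.protocol}: {exc}"
            ) from exc
        rows.append(_metric_row(speed, pattern, cfg.protocol, m))
        metrics[(speed, pattern)] = m
        results[(speed, pattern)] = res
    return SweepResult(
        table=pd.DataFrame(rows),
        metrics=metrics,
        results=results,
        curves={pattern: curve},
    )


def pattern_sweep(cfg: SweepConfig) -> SweepResult:
    """Build one TENG curve per morphology, then speed-sweep each."""
    tables, metrics, results, curves = [], {}, {}, {}
    for pattern in cfg.patterns:
        curve = curve_for_pattern(cfg, pattern)
        out = speed_sweep(replace(cfg, patterns=(pattern,)), curve)
        tables.append(out.table)
        metrics.update(out.metrics)
        results.update(out.results)
        curves[pattern] = curve
    return SweepResult(
        table=pd.concat(tables, ignore_index=True),
        metrics=metrics,
        results=results,
        curves=curves,
    )


# ---------------------------------------------------------------------------
# synthetic generators


def synthetic_trace(
    spike_times,
    t_end: float = 200.0,
    dt: float = 0.025,
    baseline: float = -60.0,
    amplitude: float = 100.0,
    template: str = "gaussian",
    width: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Voltage trace with known spike content, for metric-oracle tests.

    ``spike_times`` (ms) place templates of the given ``template`` kind
    ("gaussian": sd = width; "triangular"/"rectangular": half-width =
    width) and ``amplitude`` (mV above baseline) on a flat baseline with
    optional white noise.  Returns (times, V, ground_truth SpikeTrain).
    Overlapping templates (closer than 6*width) are rejected.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if len(spike_times) > 1 and np.min(np.diff(spike_times)) < 6.0 * width:
        raise ValueError("templates overlap: spikes closer than 6*width")
    times = np.arange(0.0, t_end + dt / 2, dt)
    V = np.full_like(times, baseline)
    for t0 in spike_times:
        if template == "gaussian":
            V += amplitude * np.exp(-0.5 * ((times - t0) / width) ** 2)
        elif template == "triangular":
            V += amplitude * np.clip(1.0 - np.abs(times - t0) / width, 0.0, None)
        elif template == "rectangular":
            V += amplitude * (np.abs(times - t0) <= width / 2.0)
        else:
            raise ValueError(f"unknown template {template!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, noise_sd, size=V.shape)
    # ground truth: peak sample nearest each template centre
    idx = np.clip(np.round(spike_times / dt).astype(int), 0, len(times) - 1)
    truth = SpikeTrain(
        spike_times=times[idx],
        peak_values=V[idx],
        detection_threshold=0.0,
        min_separation=2.0,
    )
    return times, V, truth


def fixture_curve(
    kind: str,
    x_max: float = 5e-4,
    n: int = 21,
    voc_scale: float = 100.0,
    voc_slope: float = 2e5,
    cap0: float = 3e-9,
    cap_decay: float = 5e-4,
    plate_area: float = 15e-5,
) -> TENGCurve:
    """Solver-free TENG curves for coupling and metric tests.

    kinds:
      * ``constant`` — V_oc and C constant (zero drive at any speed);
      * ``linear_voc_const_C`` — V_oc = voc_slope * x, C = cap0;
      * ``zero_voc_const_C`` — V_oc = 0, C = cap0 (capacitance-rescaling
        equivalence tests);
      * ``paperlike`` — saturating V_oc = voc_scale*(1 - exp(-x/x_max*3)),
        slowly decreasing C = cap0 / (1 + x/cap_decay).
    """
    gaps = np.linspace(0.0, x_max, n)
    if kind == "constant":
        voc = np.full(n, voc_scale)
        cap = np.full(n, cap0)
    elif kind == "linear_voc_const_C":
        voc = voc_slope * gaps
        cap = np.full(n, cap0)
    elif kind == "zero_voc_const_C":
        voc = np.zeros(n)
        cap = np.full(n, cap0)
    elif kind == "paperlike":
        voc = voc_scale * (1.0 - np.exp(-3.0 * gaps / x_max))
        cap = cap0 / (1.0 + gaps / cap_decay)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return TENGCurve(
        gaps=gaps,
        voc=voc,
        cap_total=cap,
        plate_area=plate_area,
        provenance="fixture_table",
    )
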