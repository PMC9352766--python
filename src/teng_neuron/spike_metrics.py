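"""Spike-train metrics for membrane-voltage traces.

Extracts the quantities reported for the stimulated axon: spike (action
potential) times and peaks, firing rate over a window, full width at half
maximum (FWHM) per spike, inter-spike delays, and the shift of the
resting baseline.  Detection is an upward threshold crossing grouped by a
refractory separation (scipy.signal.find_peaks with ``height`` and
``distance``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks


class TraceError(ValueError):
    pass


@dataclass
class SpikeTrain:
    """Detected spikes of one trace."""

    spike_times: np.ndarray      # ms, peak times, strictly increasing
    peak_values: np.ndarray      # mV
    detection_threshold: float   # mV
    min_separation: float        # ms

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if len(self.spike_times) != len(self.peak_values):
            raise ValueError("spike_times and peak_values must match")
        if len(self.spike_times) > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class APMetrics:
    """Summary metrics of one run's trace."""

    firing_rate: float                 # Hz
    fwhm: np.ndarray                   # ms, one entry per (untruncated) spike
    interspike_delays: np.ndarray      # ms
    baseline: float                    # mV
    baseline_shift: float              # mV
    n_spikes: int = 0
    mean_peak: float = float("nan")    # mV
    truncated_spikes: int = 0

    def __post_init__(self) -> None:
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        self.interspike_delays = np.asarray(self.interspike_delays, dtype=float)
        if self.firing_rate < 0:
            raise ValueError("firing_rate must be >= 0")
        if np.any(self.fwhm <= 0):
            raise ValueError("each FWHM must be > 0")


def _check_uniform(times: np.ndarray) -> float:
    dt = np.diff(times)
    if len(dt) == 0 or np.any(dt <= 0):
        raise TraceError("trace must have >= 2 strictly increasing samples")
    if np.max(dt) - np.min(dt) > 1e-9 * np.max(dt) + 1e-12:
        raise TraceError("trace must be uniformly sampled")
    return float(np.mean(dt))


def detect_spikes(
    times: np.ndarray,
    V: np.ndarray,
    threshold: float = 0.0,
    min_separation: float = 2.0,
) -> SpikeTrain:
    """Detect spikes: peaks above ``threshold`` (mV) separated by at least
    ``min_separation`` (ms).  Requires uniform sampling."""
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    if min_separation <= 0:
        raise ValueError("min_separation must be > 0")
    dt = _check_uniform(times)
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(V, height=threshold, distance=distance)
    return SpikeTrain(
        spike_times=times[idx],
        peak_values=V[idx],
        detection_threshold=threshold,
        min_separation=min_separation,
    )


def firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count inside [t0, t1) divided by the window length, in Hz."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive duration")
    n = int(np.sum((train.spike_times >= t0) & (train.spike_times < t1)))
    return n / (t1 - t0) * 1e3


def fwhm(
    times: np.ndarray,
    V: np.ndarray,
    train: SpikeTrain,
    baseline: float,
) -> np.ndarray:
    """Full width at half maximum (ms) of each detected spike.

    The half level is baseline + (peak - baseline)/2; the two crossings
    around the peak are located by linear interpolation.  Spikes whose
    half-level crossings fall outside the trace are excluded.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    _check_uniform(times)
    widths = []
    for t_pk, v_pk in zip(train.spike_times, train.peak_values):
        if v_pk <= baseline:
            continue
        half = baseline + 0.5 * (v_pk - baseline)
        i_pk = int(np.argmin(np.abs(times - t_pk)))
        # walk left
        i = i_pk
        while i > 0 and V[i] >= half:
            i -= 1
        if V[i] >= half:  # ran off the left edge
            continue
        t_left = np.interp(half, [V[i], V[i + 1]], [times[i], times[i + 1]])
        # walk right
        i = i_pk
        n = len(V)
        while i < n - 1 and V[i] >= half:
            i += 1
        if V[i] >= half:  # truncated at the right edge
            continue
        t_right = np.interp(half, [V[i], V[i - 1]], [times[i], times[i - 1]])
        widths.append(t_right - t_left)
    return np.asarray(widths)


def interspike_delays(train: SpikeTrain) -> np.ndarray:
    """Successive differences of the spike times (ms)."""
    return np.diff(train.spike_times)


def baseline_shift(
    times: np.ndarray,
    V: np.ndarray,
    reference: float,
    window: tuple[float, float],
    threshold: float = 0.0,
    min_separation: float = 2.0,
) -> float:
    """Time-averaged V over a spike-free ``window`` minus ``reference`` (mV).

    Raises if the window contains detected spikes.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    t0, t1 = window
    sel = (times >= t0) & (times <= t1)
    if not np.any(sel):
        raise TraceError("empty baseline window")
    train = detect_spikes(times[sel], V[sel], threshold, min_separation)
    if len(train) > 0:
        raise TraceError(
            f"baseline window [{t0}, {t1}] ms contains {len(train)} spike(s)"
        )
    return float(np.mean(V[sel]) - reference)


def summarize_trace(
    times: np.ndarray,
    V: np.ndarray,
    reference_baseline: Optional[float] = None,
    rate_window: Optional[tuple[float, float]] = None,
    threshold: float = 0.0,
    min_separation: float = 2.0,
) -> APMetrics:
    """One-stop metric extraction for a simulation trace.

    ``reference_baseline`` defaults to the first sample (pre-stimulus
    resting value); ``rate_window`` defaults to the full trace.  The
    baseline shift is computed over the longest available spike-free tail
    of the trace and is NaN when the trace spikes throughout.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    if reference_baseline is None:
        reference_baseline = float(V[0])
    if rate_window is None:
        rate_window = (float(times[0]), float(times[-1]) + 1e-9)
    train = detect_spikes(times, V, threshold, min_separation)
    widths = fwhm(times, V, train, reference_baseline)
    delays = interspike_delays(train)
    rate = firing_rate(train, rate_window)

    shift = float("nan")
    if len(train) == 0:
        sel = times >= times[0] + 0.5 * (times[-1] - times[0])
        shift = float(np.mean(V[sel]) - reference_baseline)
    else:
        # longest spike-free stretch after the last spike
        t_last = train.spike_times[-1] + 5.0 * min_separation
        sel = times >= t_last
        if np.sum(sel) > 10:
            shift = float(np.mean(V[sel]) - reference_baseline)

    return APMetrics(
        firing_rate=rate,
        fwhm=widths,
        interspike_delays=delays,
        baseline=reference_baseline,
        baseline_shift=shift,
        n_spikes=len(train),
        mean_peak=float(np.mean(train.peak_values)) if len(train) else float("nan"),
        truncated_spikes=len(train) - len(widths),
    )
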