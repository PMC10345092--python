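"""Action-potential rise-speed extraction from current-clamp sweeps.

An AP is registered at each upward crossing of a dV/dt threshold (default
10 V/s) that is followed by a voltage peak above a floor (default -10 mV)
within a short search window; crossings within a refractory merge window
collapse to one event.  The rise speed of an AP is the maximum of the central
finite-difference derivative over its rising segment (threshold crossing to
voltage peak), in V/s (1 mV/ms == 1 V/s).  The per-cell summary is the mean
rise speed of the FIRST AP of every suprathreshold current step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Sweep", "APFeatures", "detect_aps", "ap_rise_speed", "sweep_features", "cell_rise_speed"]


@dataclass
class Sweep:
    """One current-clamp sweep: uniformly sampled voltage vs time.

    ``time`` in seconds, ``voltage`` in millivolts, ``sampling_rate`` in Hz,
    ``step_current`` in picoamperes (NaN when unknown).
    """

    time: np.ndarray
    voltage: np.ndarray
    sampling_rate: float
    step_current: float = float("nan")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValueError("time and voltage must be 1-D arrays of equal length")
        if len(self.time) < 3:
            raise ValueError("sweep too short")
        dt = np.diff(self.time)
        expected = 1.0 / self.sampling_rate
        if not np.allclose(dt, expected, rtol=1e-9, atol=1e-12):
            raise ValueError("non-uniform sampling: time step deviates from 1/sampling_rate")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class APFeatures:
    """AP detections and rise speeds for one sweep."""

    ap_times: np.ndarray
    rise_speeds: np.ndarray  # V/s, one per AP
    is_suprathreshold: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_suprathreshold = len(self.ap_times) > 0

    @property
    def first_ap_rise_speed(self) -> float:
        if not self.is_suprathreshold:
            raise ValueError("sweep has no detected APs")
        return float(self.rise_speeds[0])


def _dvdt(sweep: Sweep) -> np.ndarray:
    """Central-difference derivative in V/s (one-sided at the ends)."""
    return np.gradient(sweep.voltage, sweep.dt) / 1000.0  # mV/s -> V/s


def detect_aps(
    sweep: Sweep,
    dvdt_threshold: float = 10.0,
    min_peak: float = -10.0,
    merge_window: float = 1e-3,
    peak_search: float = 5e-3,
) -> np.ndarray:
    """Times of detected APs (at the dV/dt threshold crossing).

    A candidate is an upward crossing of ``dvdt_threshold`` (V/s) whose voltage
    reaches at least ``min_peak`` (mV) within ``peak_search`` seconds;
    candidates within ``merge_window`` seconds of the previous accepted one are
    merged.  The derivative criterion is one-sided, so a time-reversed spike
    (fast fall, slow rise) is not detected.
    """
    dvdt = _dvdt(sweep)
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    n_search = max(1, int(round(peak_search * sweep.sampling_rate)))
    ap_times = []
    last = -np.inf
    for idx in crossings:
        t = sweep.time[idx]
        if t - last < merge_window:
            continue
        window = sweep.voltage[idx:idx + n_search + 1]
        if window.size and window.max() >= min_peak:
            ap_times.append(t)
            last = t
    return np.asarray(ap_times)


def ap_rise_speed(
    sweep: Sweep,
    ap_time: float,
    peak_search: float = 5e-3,
) -> float:
    """Peak dV/dt (V/s) over the rising segment of the AP at ``ap_time``.

    The rising segment runs from the threshold crossing to the voltage peak
    within the search window; the derivative is the central finite difference.
    """
    idx = int(np.searchsorted(sweep.time, ap_time - 1e-12))
    if idx >= len(sweep.time):
        raise ValueError(f"ap_time {ap_time} outside sweep")
    n_search = max(1, int(round(peak_search * sweep.sampling_rate)))
    window = sweep.voltage[idx:idx + n_search + 1]
    if window.size < 2:
        raise ValueError("rising-phase window is empty")
    peak_idx = idx + int(np.argmax(window))
    if peak_idx <= idx:
        peak_idx = idx + 1
    dvdt = _dvdt(sweep)
    return float(dvdt[idx:peak_idx + 1].max())


def sweep_features(sweep: Sweep, **detect_kwargs) -> APFeatures:
    """Detect APs and compute each one's rise speed."""
    times = detect_aps(sweep, **detect_kwargs)
    speeds = np.array([ap_rise_speed(sweep, t) for t in times])
    return APFeatures(ap_times=times, rise_speeds=speeds)


def cell_rise_speed(sweeps: list[Sweep], **detect_kwargs) -> float:
    """Mean first-AP rise speed over the suprathreshold sweeps of one cell.

    Subthreshold sweeps (no detected AP) are ignored; a cell with none is an
    error.
    """
    firsts = []
    for sweep in sweeps:
        feats = sweep_features(sweep, **detect_kwargs)
        if feats.is_suprathreshold:
            firsts.append(feats.first_ap_rise_speed)
    if not firsts:
        raise ValueError("no suprathreshold sweeps")
    return float(np.mean(firsts))
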