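"""Heel-raise event and phase detection from the foot-pitch signal.

Events are found with a hysteresis threshold on foot pitch: an event opens
when pitch exceeds ``pitch_threshold_deg`` and closes when it falls below
``threshold − hysteresis``; short blips are discarded, near-contiguous
events merged, and the boundaries extended outward to the nearest local
pitch minimum so the full rise onset and drop completion are included.

Within each event the pitch gradient (central differences of a zero-phase
moving-average-smoothed pitch, deg/s) splits the repetition into the rise
(sustained positive gradient), hold (plateau) and drop (sustained negative
gradient) phases, matching the concentric/isometric/eccentric muscle states.

When no reference orientation stream is available, pitch is estimated from
the insole accelerometer as ``asin(ay/‖a‖)`` — during the quasi-static hold
the along-foot axis reading is the gravity projection of the pitch angle —
low-pass filtered at 3 Hz (2nd-order Butterworth, zero-phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DataError
from .streams import SyncedSession

PHASE_NAMES = ("rise", "hold", "drop")


class Trace(NamedTuple):
    """A uniformly sampled scalar signal on the master clock."""

    time: np.ndarray
    values: np.ndarray
    rate_hz: float


@dataclass
class SegmentationConfig:
    """Tunables of event/phase detection.

    All thresholds are artifact defaults sitting far below a typical ~25°
    heel-raise excursion; every one is exposed here.
    """

    pitch_threshold_deg: float = 5.0
    hysteresis_deg: float = 2.0
    min_event_s: float = 1.0
    min_gap_s: float = 1.0
    gradient_smooth_window_s: float = 0.3
    gradient_threshold_deg_per_s: float = 3.0
    pitch_source: str = "auto"  # auto | orientation | accel_surrogate

    def __post_init__(self) -> None:
        if not self.pitch_threshold_deg > self.hysteresis_deg >= 0:
            raise DataError("require threshold > hysteresis >= 0")
        if self.min_event_s <= 0 or self.gradient_smooth_window_s <= 0:
            raise DataError("windows must be positive")
        if self.pitch_source not in ("auto", "orientation", "accel_surrogate"):
            raise ConfigurationError(f"unknown pitch_source '{self.pitch_source}'")


@dataclass
class HeelRaiseEvent:
    """One detected repetition with phase boundaries on the master clock."""

    event_index: int
    t_start: float
    t_rise_end: float
    t_drop_start: float
    t_end: float
    preceding_idle_s: float = float("nan")
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (
            self.t_start < self.t_rise_end <= self.t_drop_start < self.t_end
        ):
            raise DataError("phase boundaries out of order")

    @property
    def phase_durations_s(self) -> tuple[float, float, float]:
        """(rise, hold, drop) durations in seconds."""
        return (
            self.t_rise_end - self.t_start,
            self.t_drop_start - self.t_rise_end,
            self.t_end - self.t_drop_start,
        )

    def phase_interval(self, phase: str) -> tuple[float, float]:
        if phase == "rise":
            return (self.t_start, self.t_rise_end)
        if phase == "hold":
            return (self.t_rise_end, self.t_drop_start)
        if phase == "drop":
            return (self.t_drop_start, self.t_end)
        raise KeyError(phase)


def pitch_trace(session: SyncedSession, source: str = "auto") -> Trace:
    """Foot pitch in degrees on the insole master clock.

    ``orientation`` passes the reference pitch channel through (interpolated
    onto the insole clock); ``accel_surrogate`` derives pitch from the
    accelerometer; ``auto`` prefers the orientation stream when present.
    """
    if source == "auto":
        source = "orientation" if session.orientation is not None else "accel_surrogate"
    ins = session.insole
    if source == "orientation":
        if session.orientation is None:
            raise ConfigurationError("no orientation stream in session")
        ori = session.orientation
        pitch = np.interp(ins.time, ori.time, ori.pitch)
        return Trace(ins.time, pitch, ins.rate_hz)
    if source != "accel_surrogate":
        raise ConfigurationError(f"unknown pitch source '{source}'")
    return Trace(ins.time, accel_tilt_deg(ins.ax, ins.ay, ins.az, ins.rate_hz)[0],
                 ins.rate_hz)


def accel_tilt_deg(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(pitch, roll) in degrees from the gravity direction of a 3-axis accel.

    pitch = asin(ay/‖a‖), roll = asin(ax/‖a‖), each clamped to ±1 before the
    arcsine and low-pass filtered (2nd-order Butterworth, zero-phase) to
    suppress motion transients.  Valid as an attitude estimate only for
    quasi-static movement.
    """
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    norm = np.where(norm > 0, norm, 1.0)
    pitch = np.degrees(np.arcsin(np.clip(ay / norm, -1.0, 1.0)))
    roll = np.degrees(np.arcsin(np.clip(ax / norm, -1.0, 1.0)))
    if cutoff_hz and cutoff_hz < rate_hz / 2 and len(pitch) > 12:
        b, a = sps.butter(2, cutoff_hz / (rate_hz / 2.0))
        pitch = sps.filtfilt(b, a, pitch)
        roll = sps.filtfilt(b, a, roll)
    return pitch, roll


def _smooth(values: np.ndarray, rate_hz: float, window_s: float) -> np.ndarray:
    """Centered (zero-phase) moving average with an odd window."""
    n = max(int(round(window_s * rate_hz)), 1)
    if n % 2 == 0:
        n += 1
    if n <= 1 or n >= len(values):
        return values.copy()
    pad = n // 2
    padded = np.concatenate([np.full(pad, values[0]), values, np.full(pad, values[-1])])
    kernel = np.ones(n) / n
    return np.convolve(padded, kernel, mode="valid")


def _gradient(values: np.ndarray, rate_hz: float) -> np.ndarray:
    """Central-difference derivative, units per second."""
    return np.gradient(values) * rate_hz


def detect_events(
    pitch: Trace, cfg: SegmentationConfig | None = None
) -> list[tuple[float, float]]:
    """Find heel-raise events as (t_start, t_end) intervals.

    Hysteresis thresholding on pitch, minimum-duration filtering, merging of
    near-contiguous events, then outward extension of each boundary to the
    nearest local minimum of the smoothed pitch.
    """
    cfg = cfg or SegmentationConfig()
    t, p, fs = pitch.time, pitch.values, pitch.rate_hz
    if len(t) < 2 or (t[-1] - t[0]) < cfg.min_event_s:
        warnings.warn("trace shorter than min_event_s; no events", stacklevel=2)
        return []
    open_thr = cfg.pitch_threshold_deg
    close_thr = cfg.pitch_threshold_deg - cfg.hysteresis_deg

    raw: list[tuple[int, int]] = []
    inside = False
    i_open = 0
    for i, v in enumerate(p):
        if not inside and v > open_thr:
            inside, i_open = True, i
        elif inside and v < close_thr:
            raw.append((i_open, i))
            inside = False
    if inside:
        raw.append((i_open, len(p) - 1))

    raw = [(a, b) for a, b in raw if (t[b] - t[a]) >= cfg.min_event_s]

    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and (t[a] - t[merged[-1][1]]) < cfg.min_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    smoothed = _smooth(p, fs, cfg.gradient_smooth_window_s)
    floor = close_thr  # keep walking while still clearly elevated
    out: list[tuple[float, float]] = []
    for a, b in merged:
        while a > 0 and (smoothed[a - 1] < smoothed[a] or smoothed[a - 1] > floor):
            a -= 1
        while b < len(p) - 1 and (smoothed[b + 1] < smoothed[b] or smoothed[b + 1] > floor):
            b += 1
        out.append((float(t[a]), float(t[b])))
    return out


def detect_phases(
    pitch: Trace,
    event: tuple[float, float],
    cfg: SegmentationConfig | None = None,
    event_index: int = 0,
) -> HeelRaiseEvent:
    """Split one event into rise/hold/drop via the pitch gradient.

    The rise is the supra-threshold positive-gradient run containing the
    event's gradient maximum, the drop the sub-threshold negative run
    containing its minimum; the hold lies between.  Each boundary is placed
    at the half-peak gradient crossing of its run: for the zero-phase
    smoothing used here the smearing of a corner is symmetric, so the
    half-peak crossing localizes the underlying corner without bias (a
    plain "gradient falls below threshold" rule would shift every boundary
    outward by about half the smoothing width).
    """
    cfg = cfg or SegmentationConfig()
    t, p, fs = pitch.time, pitch.values, pitch.rate_hz
    t_start, t_end = event
    sel = np.nonzero((t >= t_start - 0.5 / fs) & (t <= t_end + 0.5 / fs))[0]
    if sel.size < 3:
        raise DataError("event interval contains fewer than 3 samples")
    i0, i1 = int(sel[0]), int(sel[-1])
    g = _gradient(_smooth(p, fs, cfg.gradient_smooth_window_s), fs)[i0 : i1 + 1]
    gthr = cfg.gradient_threshold_deg_per_s

    def run_bounds(mask: np.ndarray, anchor: int) -> tuple[int, int]:
        a = b = anchor
        while a > 0 and mask[a - 1]:
            a -= 1
        while b < len(mask) - 1 and mask[b + 1]:
            b += 1
        return a, b

    def half_peak_bounds(a: int, b: int, signed: np.ndarray) -> tuple[float, float]:
        """Sub-sample half-peak crossing times (in samples) of one run."""
        half = 0.5 * signed[a : b + 1].max()
        idx = np.nonzero(signed[a : b + 1] >= half)[0]
        left, right = a + int(idx[0]), a + int(idx[-1])
        if left > 0 and signed[left] > signed[left - 1]:
            left = left - (signed[left] - half) / (signed[left] - signed[left - 1])
        if right < len(signed) - 1 and signed[right] > signed[right + 1]:
            right = right + (signed[right] - half) / (signed[right] - signed[right + 1])
        return float(left), float(right)

    pos_mask = g > gthr
    if not pos_mask.any():
        warnings.warn(
            f"event {event_index}: no supra-threshold rise gradient; "
            "phases marked invalid",
            stacklevel=2,
        )
        return HeelRaiseEvent(
            event_index=event_index,
            t_start=t_start,
            t_rise_end=float("nan"),
            t_drop_start=float("nan"),
            t_end=t_end,
            valid=False,
        )
    ra, rb = run_bounds(pos_mask, int(np.argmax(g)))
    i_start, i_rise_end = half_peak_bounds(ra, rb, g)

    neg_mask = g < -gthr
    if neg_mask.any():
        da, db = run_bounds(neg_mask, int(np.argmin(g)))
        i_drop_start, i_end = half_peak_bounds(da, db, -g)
    else:  # monotone ramp with no descent: degenerate one-sample drop
        i_drop_start, i_end = float(len(g) - 2), float(len(g) - 1)

    one = 1.0  # at least one sample between boundaries
    i_rise_end = max(i_rise_end, i_start + one)
    i_drop_start = float(np.clip(i_drop_start, i_rise_end, len(g) - 2))
    i_end = float(np.clip(i_end, i_drop_start + one, len(g) - 1))

    t0 = float(t[i0])
    dt = 1.0 / fs
    return HeelRaiseEvent(
        event_index=event_index,
        t_start=t0 + i_start * dt,
        t_rise_end=t0 + i_rise_end * dt,
        t_drop_start=t0 + i_drop_start * dt,
        t_end=t0 + i_end * dt,
    )


def segment_session(
    session: SyncedSession, cfg: SegmentationConfig | None = None
) -> list[HeelRaiseEvent]:
    """Detect all heel-raise events of a session and split them into phases.

    ``preceding_idle_s`` of each event is the gap back to the previous
    event's end (or to the start of the recording for the first event).
    """
    cfg = cfg or SegmentationConfig()
    trace = pitch_trace(session, cfg.pitch_source)
    intervals = detect_events(trace, cfg)
    events: list[HeelRaiseEvent] = []
    prev_end = float(trace.time[0]) if len(trace.time) else 0.0
    for k, iv in enumerate(intervals):
        ev = detect_phases(trace, iv, cfg, event_index=k)
        ev.preceding_idle_s = ev.t_start - prev_end
        prev_end = ev.t_end
        events.append(ev)
    return events
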