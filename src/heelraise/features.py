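"""Waveform-length, partial-pressure and centre-of-pressure features.

Three quantities summarize a heel raise:

* **Waveform length (WL)** — the sliding-window sum of absolute successive
  differences of the raw EMG, ``WL(t) = Σ_{n=t−N+2}^{t} |x(n) − x(n−1)|``,
  a standard activation envelope.
* **Medial partial pressure (MPP)** — the medial share of the forefoot
  load, ``100·F2/(F2+F3)`` %, from the sensors under the 1st (medial) and
  4th (lateral) metatarsal heads.  Undefined when the forefoot is unloaded.
* **Medio-lateral COP (ML COP)** — ``100·(W − COP_x)/W`` %, the relative
  medial centre-of-pressure position within a grid insole of width ``W``.

``phase_features`` reduces each detected repetition to per-phase means of
these quantities (plus pitch and roll), the representation used for
eversion/inversion classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .segmentation import (
    PHASE_NAMES,
    HeelRaiseEvent,
    accel_tilt_deg,
)
from .streams import SyncedSession


def waveform_length(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Sliding-window waveform length of a raw EMG trace.

    Window-end aligned: output sample ``t`` sums the ``N−1`` absolute
    first differences ending at ``t``; the first ``N−1`` outputs are NaN
    (undefined).  Output has the same length as the input.
    """
    n = int(window_samples)
    if n < 2:
        raise ParameterError("window_samples must be >= 2")
    x = np.asarray(x, dtype=float)
    if len(x) < n:
        raise DataError(f"trace shorter than window ({len(x)} < {n})")
    d = np.abs(np.diff(x))
    csum = np.concatenate([[0.0], np.cumsum(d)])
    out = np.full(len(x), np.nan)
    # sum of d[t-N+1 .. t-1] = csum[t] - csum[t-N+1]
    out[n - 1 :] = csum[n - 1 :] - csum[: len(x) - n + 1]
    return out


def default_wl_window(rate_hz: float, window_s: float = 0.25) -> int:
    """Default WL window: 0.25 s of samples at the EMG rate (minimum 2)."""
    return max(int(round(window_s * rate_hz)), 2)


def mpp(f2, f3, load_floor: float = 0.0):
    """Medial partial pressure ``100·F2/(F2+F3)`` in percent.

    Samples whose forefoot load ``F2+F3`` does not exceed ``load_floor``
    are undefined (NaN) rather than a division error.  Accepts scalars or
    arrays; negative forces are a data error.
    """
    f2 = np.asarray(f2, dtype=float)
    f3 = np.asarray(f3, dtype=float)
    if np.any(f2 < 0) or np.any(f3 < 0):
        raise DataError("forces must be non-negative")
    denom = f2 + f3
    defined = denom > max(load_floor, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(defined, 100.0 * f2 / np.where(defined, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def session_load_floor(session: SyncedSession, fraction: float = 0.01) -> float:
    """MPP validity floor: ``fraction`` of the 95th-percentile forefoot load."""
    load = session.insole.f2 + session.insole.f3
    return fraction * float(np.percentile(load, 95))


def ml_cop(cop_x, width_mm: float):
    """Relative medial COP position, ``100·(W − COP_x)/W`` percent."""
    cop_x = np.asarray(cop_x, dtype=float)
    if width_mm <= 0:
        raise ParameterError("width_mm must be positive")
    if np.any((cop_x < 0) | (cop_x > width_mm)):
        raise DataError("cop_x outside [0, width_mm]")
    out = 100.0 * (width_mm - cop_x) / width_mm
    if out.ndim == 0:
        return float(out)
    return out


def cop_from_grid(sensor_positions_mm, forces):
    """Force-weighted mean sensor coordinate; NaN when nothing is loaded."""
    pos = np.asarray(sensor_positions_mm, dtype=float)
    f = np.asarray(forces, dtype=float)
    if pos.shape != f.shape:
        raise ParameterError("positions and forces must have equal shape")
    if np.any(f < 0):
        raise DataError("forces must be non-negative")
    total = f.sum()
    if total <= 0:
        return float("nan")
    return float((pos * f).sum() / total)


def _orientation_traces(session: SyncedSession) -> tuple[np.ndarray, np.ndarray]:
    """(pitch, roll) in degrees on the insole clock, surrogate if needed."""
    ins = session.insole
    if session.orientation is not None:
        ori = session.orientation
        return (
            np.interp(ins.time, ori.time, ori.pitch),
            np.interp(ins.time, ori.time, ori.roll),
        )
    return accel_tilt_deg(ins.ax, ins.ay, ins.az, ins.rate_hz)


def _phase_mask(time: np.ndarray, a: float, b: float, last: bool) -> np.ndarray:
    if last:
        return (time >= a) & (time <= b)
    return (time >= a) & (time < b)


def _nanmean_or_nan(values: np.ndarray) -> float:
    vals = values[~np.isnan(values)]
    return float(vals.mean()) if vals.size else float("nan")


def phase_features(
    session: SyncedSession,
    events: list[HeelRaiseEvent],
    wl_window_samples: int | None = None,
    load_floor: float | None = None,
) -> pd.DataFrame:
    """Per event × phase means of MPP, roll, pitch, per-muscle WL, ML COP.

    One row per (event, phase) with columns ``event_index``, ``phase``,
    ``mean_mpp_pct``, ``mean_roll_deg``, ``mean_pitch_deg``, one
    ``mean_wl_<muscle>`` column per EMG channel and ``mean_ml_cop_pct``
    when a grid-COP stream is present.  Undefined MPP samples are excluded
    from their phase mean; an all-undefined phase yields NaN.
    """
    ins = session.insole
    if load_floor is None:
        load_floor = session_load_floor(session)
    mpp_trace = mpp(ins.f2, ins.f3, load_floor=load_floor)
    pitch, roll = _orientation_traces(session)

    wl_traces: dict[str, np.ndarray] = {}
    emg = session.emg
    if emg is not None:
        n = wl_window_samples or default_wl_window(emg.rate_hz)
        for name, x in emg.channels.items():
            wl_traces[name] = waveform_length(x, n)

    cop_trace = None
    if session.grid_cop is not None:
        cop_trace = ml_cop(session.grid_cop.cop_x, session.grid_cop.width_mm)

    rows = []
    for ev in events:
        if not ev.valid:
            continue
        for phase in PHASE_NAMES:
            a, b = ev.phase_interval(phase)
            mask = _phase_mask(ins.time, a, b, last=(phase == "drop"))
            if not mask.any():  # degenerate phase: use nearest sample
                mask = np.zeros_like(mask)
                mask[int(np.argmin(np.abs(ins.time - 0.5 * (a + b))))] = True
            row = {
                "event_index": ev.event_index,
                "phase": phase,
                "mean_mpp_pct": _nanmean_or_nan(mpp_trace[mask]),
                "mean_roll_deg": float(roll[mask].mean()),
                "mean_pitch_deg": float(pitch[mask].mean()),
            }
            if emg is not None:
                emask = _phase_mask(emg.time, a, b, last=(phase == "drop"))
                for name, trace in wl_traces.items():
                    row[f"mean_wl_{name}"] = _nanmean_or_nan(trace[emask])
            if cop_trace is not None:
                gmask = _phase_mask(
                    session.grid_cop.time, a, b, last=(phase == "drop")
                )
                row["mean_ml_cop_pct"] = _nanmean_or_nan(cop_trace[gmask])
            rows.append(row)
    return pd.DataFrame(rows)
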