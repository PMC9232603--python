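"""Phase-percent time normalization and event-ensemble statistics.

Even under cueing, repetition phases vary in duration, so traces from
different events cannot be averaged sample-by-sample.  Each detected phase
is therefore resampled onto a fixed grid of ``points_per_phase`` equally
spaced phase fractions (a "percent of phase" axis); the rise/hold/drop
segments are concatenated and the event ensemble is summarized by its
pointwise mean and sample standard deviation.

Because raw EMG amplitudes are not comparable across subjects (electrode
placement, tissue), per-phase waveform-length features are expressed
relative to each subject's mean rise-phase WL per muscle
(:func:`normalize_emg_to_rise`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .segmentation import PHASE_NAMES, HeelRaiseEvent


def normalize_phase_time(
    time: np.ndarray,
    values: np.ndarray,
    event: HeelRaiseEvent,
    points_per_phase: int = 100,
) -> np.ndarray:
    """Resample one event of a trace onto the phase-percent grid.

    Each phase is linearly interpolated at ``points_per_phase`` equally
    spaced fractions of its duration; rise, hold and drop are concatenated
    (length ``3 × points_per_phase``).
    """
    if points_per_phase < 2:
        raise ParameterError("points_per_phase must be >= 2")
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    out = []
    for phase in PHASE_NAMES:
        a, b = event.phase_interval(phase)
        n_inside = int(((time >= a) & (time <= b)).sum())
        if n_inside < 2:
            warnings.warn(
                f"phase '{phase}' covers {n_inside} samples; nearest-sample fill",
                stacklevel=2,
            )
        frac = np.linspace(0.0, 1.0, points_per_phase)
        out.append(np.interp(a + frac * (b - a), time, values))
    return np.concatenate(out)


def aggregate(event_traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise ensemble mean and sample SD over events (rows).

    A single event yields zero SD.
    """
    m = np.atleast_2d(np.asarray(event_traces, dtype=float))
    if m.shape[0] < 1:
        raise ParameterError("need at least one event trace")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(m.shape[1])
    return mean, sd


@dataclass
class PhaseNormalizedTrace:
    """One channel resampled to the phase-percent grid across all events."""

    channel: str
    points_per_phase: int
    event_matrix: np.ndarray  # (n_events, 3 * points_per_phase)
    mean: np.ndarray
    sd: np.ndarray

    @property
    def phase_percent(self) -> np.ndarray:
        """0–100 % axis within each phase, concatenated rise→hold→drop."""
        one = np.linspace(0.0, 100.0, self.points_per_phase)
        return np.concatenate([one, one, one])

    @property
    def phase_labels(self) -> np.ndarray:
        return np.repeat(np.array(PHASE_NAMES), self.points_per_phase)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "phase": self.phase_labels,
                "phase_pct": self.phase_percent,
                "mean": self.mean,
                "sd": self.sd,
            }
        )


def phase_normalized_trace(
    time: np.ndarray,
    values: np.ndarray,
    events: list[HeelRaiseEvent],
    channel: str = "",
    points_per_phase: int = 100,
) -> PhaseNormalizedTrace:
    """Resample every valid event and aggregate into mean ± SD."""
    rows = [
        normalize_phase_time(time, values, ev, points_per_phase)
        for ev in events
        if ev.valid
    ]
    if not rows:
        raise ParameterError("no valid events to aggregate")
    matrix = np.vstack(rows)
    mean, sd = aggregate(matrix)
    return PhaseNormalizedTrace(
        channel=channel,
        points_per_phase=points_per_phase,
        event_matrix=matrix,
        mean=mean,
        sd=sd,
    )


def normalize_emg_to_rise(
    features: pd.DataFrame,
    subject_col: str = "subject",
    mode: str = "pooled",
    ev_variants: tuple[str, ...] = ("DL-EV", "SL-EV"),
) -> pd.DataFrame:
    """Express per-phase WL features relative to the subject's rise-phase mean.

    For every subject and muscle, each ``mean_wl_<muscle>`` value is divided
    by that subject's mean rise-phase WL for the muscle.  ``mode='pooled'``
    pools the rise means over all conditions present for the subject;
    ``mode='ev_only'`` uses only eversion trials (``variant`` column in
    ``ev_variants``) as the denominator.  The chosen mode and denominators
    are recorded in ``result.attrs['normalization']``.
    """
    if mode not in ("pooled", "ev_only"):
        raise ParameterError("mode must be 'pooled' or 'ev_only'")
    if subject_col not in features.columns:
        raise ParameterError(f"missing '{subject_col}' column")
    wl_cols = [c for c in features.columns if c.startswith("mean_wl_")]
    if not wl_cols:
        raise ParameterError("no mean_wl_* columns to normalize")

    out = features.copy()
    denominators: dict = {}
    for subj, grp in features.groupby(subject_col):
        rise = grp[grp["phase"] == "rise"]
        if mode == "ev_only":
            rise = rise[rise["variant"].isin(ev_variants)]
        for col in wl_cols:
            denom = float(rise[col].mean())
            denominators[(subj, col)] = denom
            sel = out[subject_col] == subj
            if not np.isfinite(denom) or denom == 0.0:
                warnings.warn(
                    f"subject {subj}: zero/undefined rise-phase mean for {col}",
                    stacklevel=2,
                )
                out.loc[sel, f"rel_{col[5:]}"] = np.nan
            else:
                out.loc[sel, f"rel_{col[5:]}"] = out.loc[sel, col] / denom
    out.attrs["normalization"] = {
        "mode": mode,
        "denominator": "per-subject mean rise-phase WL",
        "denominators": {f"{s}/{c}": d for (s, c), d in denominators.items()},
    }
    return out
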