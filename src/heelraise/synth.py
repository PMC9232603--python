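"""Synthetic heel-raise session generator with ground-truth labels.

Emulates the cued exercise protocol — idle, rise, hold and drop phases of
5, 1, 3 and 1 s, five repetitions — for the four heel-raise variants
(double/single leg × ankle eversion/inversion).  Every generated quantity is
derived from a programmed foot-orientation profile:

* **pitch** follows a smoothed trapezoid per repetition (0° → ``pitch_max``
  over the rise, plateau over the hold, back to 0° over the drop), with
  per-event phase-duration jitter;
* **roll** ramps by ``roll_delta_deg`` in proportion to pitch — positive
  (medial/eversion) for EV variants, negative for IV;
* **forefoot forces** F2 (1st metatarsal, medial) and F3 (4th metatarsal,
  lateral) are scaled so the instantaneous medial partial pressure
  ``100·F2/(F2+F3)`` interpolates the programmed baseline→raised profile;
  the heel channel F4 unloads once pitch leaves the ground;
* **acceleration** is the gravity projection of the orientation
  (``ay = sin pitch``, ``ax = sin roll``, ``az = cos pitch · cos roll``, in
  g) plus band-limited motion bursts during rise/drop and white noise;
* **EMG** is amplitude-modulated Gaussian noise: per-muscle, per-phase
  envelope gains, with the Peroneus Longus strongly recruited during the
  eversion rise and weak + delayed during the inversion rise, and the
  plantar flexors (GM/GL/SL) boosted under single-leg load.

All randomness flows from a single seed, so sessions are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError
from .streams import (
    EmgStream,
    GridCopStream,
    InsoleStream,
    OrientationStream,
    SyncedSession,
)

VARIANTS = ("DL-EV", "DL-IV", "SL-EV", "SL-IV")
PHASES = ("idle", "rise", "hold", "drop")
MUSCLES = ("PL", "GM", "GL", "SL")

#: smoothing half-support of the pitch trapezoid corners (cosine taper)
CORNER_TAPER_S = 0.2


def _variant_defaults(variant: str) -> dict:
    ev = variant.endswith("EV")
    single = variant.startswith("SL")
    leg_factor = 1.6 if single else 1.0
    gains = {
        # envelope SD (mV) per phase: idle, rise, hold, drop
        "PL": {"idle": 0.05, "rise": 1.0 if ev else 0.3,
               "hold": 0.4 if ev else 0.25, "drop": 0.3 if ev else 0.2},
        "GM": {"idle": 0.05, "rise": 0.8 * leg_factor, "hold": 0.5 * leg_factor,
               "drop": 0.4 * leg_factor},
        "GL": {"idle": 0.05, "rise": 0.8 * leg_factor, "hold": 0.5 * leg_factor,
               "drop": 0.4 * leg_factor},
        "SL": {"idle": 0.05, "rise": (0.96 if ev else 0.8) * leg_factor,
               "hold": (0.6 if ev else 0.5) * leg_factor,
               "drop": (0.48 if ev else 0.4) * leg_factor},
    }
    return {
        "roll_delta_deg": 5.0 if ev else -10.0,
        "mpp_baseline_pct": 55.0 if ev else 45.0,
        "mpp_raised_pct": 75.0 if ev else 25.0,
        "emg_gain": gains,
        "pl_delay_s": 0.0 if ev else 0.3,
    }


@dataclass
class SynthesisParams:
    """Parameters of one synthetic heel-raise session.

    Defaults reproduce the cued protocol: idle/rise/hold/drop of 5/1/3/1 s,
    five repetitions.  ``None`` fields are filled from the variant
    (EV: roll +5°, MPP 55→75 %; IV: roll −10°, MPP 45→25 %).
    """

    variant: str = "DL-EV"
    n_events: int = 5
    phase_durations_s: tuple[float, float, float, float] = (5.0, 1.0, 3.0, 1.0)
    pitch_max_deg: float = 25.0
    roll_delta_deg: float | None = None
    mpp_baseline_pct: float | None = None
    mpp_raised_pct: float | None = None
    duration_jitter_cv: float = 0.08
    noise_sd: float = 0.02          # accelerometer white noise, g
    force_noise: float = 1.0        # FSR white noise, device units
    angle_noise_deg: float = 0.3    # orientation stream white noise, degrees
    motion_burst_g: float = 0.05    # band-limited accel transients in rise/drop
    emg_gain: dict | None = None    # per muscle per phase envelope SD, mV
    pl_delay_s: float | None = None  # PL recruitment onset delay in the rise
    rate_hz: float = 30.0
    emg_rate_hz: float = 2000.0
    grid_rate_hz: float = 50.0
    grid_width_mm: float = 100.0
    include_emg: bool = True
    include_grid_cop: bool = True
    tail_idle_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}")
        if self.n_events < 1:
            raise ParameterError("n_events must be >= 1")
        if any(d <= 0 for d in self.phase_durations_s):
            raise ParameterError("phase durations must be positive")
        defaults = _variant_defaults(self.variant)
        for name in ("roll_delta_deg", "mpp_baseline_pct", "mpp_raised_pct",
                     "emg_gain", "pl_delay_s"):
            if getattr(self, name) is None:
                setattr(self, name, defaults[name])
        for v in (self.mpp_baseline_pct, self.mpp_raised_pct):
            if not 0.0 <= v <= 100.0:
                raise ParameterError("MPP percentages must lie in [0, 100]")


@dataclass
class EventTruth:
    """True boundaries and per-phase programmed levels of one repetition."""

    t_rise_start: float
    t_hold_start: float
    t_drop_start: float
    t_drop_end: float
    mpp_mean_pct: dict[str, float] = field(default_factory=dict)
    roll_mean_deg: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Per-event truth for a generated session."""

    variant: str
    events: list[EventTruth]

    def __post_init__(self) -> None:
        for ev in self.events:
            b = (ev.t_rise_start, ev.t_hold_start, ev.t_drop_start, ev.t_drop_end)
            if not all(x < y for x, y in zip(b, b[1:])):
                raise ParameterError("event boundaries must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def boundary_array(self) -> np.ndarray:
        """(n_events, 4) array of rise-start/hold-start/drop-start/drop-end."""
        return np.array(
            [[e.t_rise_start, e.t_hold_start, e.t_drop_start, e.t_drop_end]
             for e in self.events]
        )

    def to_json(self) -> str:
        return json.dumps(
            {"variant": self.variant, "events": [asdict(e) for e in self.events]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            variant=obj["variant"],
            events=[EventTruth(**e) for e in obj["events"]],
        )


def _draw_durations(rng: np.random.Generator, params: SynthesisParams) -> np.ndarray:
    """(n_events, 4) jittered idle/rise/hold/drop durations, strictly positive."""
    base = np.asarray(params.phase_durations_s)
    cv = params.duration_jitter_cv
    out = np.empty((params.n_events, 4))
    floor = 2.0 / params.rate_hz
    for i in range(params.n_events):
        for j in range(4):
            d = base[j] * (1.0 + cv * rng.standard_normal()) if cv > 0 else base[j]
            while d <= floor:
                warnings.warn(
                    "jittered phase duration non-positive; redrawing", stacklevel=2
                )
                d = base[j] * (1.0 + cv * rng.standard_normal())
            out[i, j] = d
    return out


def _trapezoid(t: np.ndarray, truths: list[EventTruth], top: float) -> np.ndarray:
    """Piecewise-linear pitch trapezoid (before corner smoothing)."""
    y = np.zeros_like(t)
    for ev in truths:
        rise = (t >= ev.t_rise_start) & (t < ev.t_hold_start)
        hold = (t >= ev.t_hold_start) & (t < ev.t_drop_start)
        drop = (t >= ev.t_drop_start) & (t < ev.t_drop_end)
        y[rise] = top * (t[rise] - ev.t_rise_start) / (ev.t_hold_start - ev.t_rise_start)
        y[hold] = top
        y[drop] = top * (ev.t_drop_end - t[drop]) / (ev.t_drop_end - ev.t_drop_start)
    return y


def _smooth_corners(y: np.ndarray, rate_hz: float) -> np.ndarray:
    """Convolve with a normalized cosine (Hann) kernel of CORNER_TAPER_S."""
    m = max(int(round(CORNER_TAPER_S * rate_hz)), 1)
    k = np.hanning(m + 2)[1:-1]
    k /= k.sum()
    return np.convolve(y, k, mode="same")


def _burst_window(t: np.ndarray, truths: list[EventTruth]) -> np.ndarray:
    w = np.zeros_like(t)
    for ev in truths:
        w[(t >= ev.t_rise_start) & (t < ev.t_hold_start)] = 1.0
        w[(t >= ev.t_drop_start) & (t < ev.t_drop_end)] = 1.0
    return w


def _bandlimited_noise(rng: np.random.Generator, n: int, rate_hz: float) -> np.ndarray:
    """Unit-variance noise band-limited to roughly 2–6 Hz."""
    from scipy import signal as sps

    x = rng.standard_normal(n)
    nyq = rate_hz / 2.0
    b, a = sps.butter(2, [2.0 / nyq, min(6.0 / nyq, 0.99)], btype="band")
    y = sps.lfilter(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def programmed_profiles(
    params: SynthesisParams, truths: list[EventTruth], t: np.ndarray
) -> dict[str, np.ndarray]:
    """Noise-free pitch/roll/MPP profiles on grid ``t`` for given boundaries."""
    pitch = _smooth_corners(
        _trapezoid(t, truths, params.pitch_max_deg), 1.0 / float(np.median(np.diff(t)))
    )
    frac = pitch / params.pitch_max_deg
    roll = params.roll_delta_deg * frac
    mpp = params.mpp_baseline_pct + (params.mpp_raised_pct - params.mpp_baseline_pct) * frac
    return {"pitch": pitch, "roll": roll, "mpp": mpp, "frac": frac}


def _phase_masks(t: np.ndarray, ev: EventTruth) -> dict[str, np.ndarray]:
    return {
        "rise": (t >= ev.t_rise_start) & (t < ev.t_hold_start),
        "hold": (t >= ev.t_hold_start) & (t < ev.t_drop_start),
        "drop": (t >= ev.t_drop_start) & (t <= ev.t_drop_end),
    }


def generate_session(params: SynthesisParams) -> tuple[SyncedSession, GroundTruth]:
    """Generate one labeled synthetic session.

    Returns the session (insole + orientation, optionally EMG and grid-COP
    streams, all sharing the insole master clock) and its ground truth.
    """
    rng = np.random.default_rng(params.seed)
    durations = _draw_durations(rng, params)

    truths: list[EventTruth] = []
    tcur = 0.0
    for i in range(params.n_events):
        idle, rise, hold, drop = durations[i]
        t_rise = tcur + idle
        truths.append(
            EventTruth(
                t_rise_start=t_rise,
                t_hold_start=t_rise + rise,
                t_drop_start=t_rise + rise + hold,
                t_drop_end=t_rise + rise + hold + drop,
            )
        )
        tcur = truths[-1].t_drop_end
    total = tcur + params.tail_idle_s

    fs = params.rate_hz
    t = np.arange(int(round(total * fs)) + 1) / fs
    prof = programmed_profiles(params, truths, t)
    pitch, roll, mpp, frac = prof["pitch"], prof["roll"], prof["mpp"], prof["frac"]

    # record per-phase programmed means in the ground truth
    for ev in truths:
        for phase, mask in _phase_masks(t, ev).items():
            ev.mpp_mean_pct[phase] = float(mpp[mask].mean())
            ev.roll_mean_deg[phase] = float(roll[mask].mean())

    # forces: forefoot load grows as weight shifts forward; MPP splits it
    forefoot = 50.0 + 50.0 * frac
    f2 = forefoot * mpp / 100.0
    f3 = forefoot * (1.0 - mpp / 100.0)
    f4 = 40.0 * np.clip(1.0 - pitch / 5.0, 0.0, 1.0)   # heel unloads past ~5°
    f1 = 10.0 + 10.0 * frac

    pr, rr = np.deg2rad(pitch), np.deg2rad(roll)
    ax = np.sin(rr)
    ay = np.sin(pr)
    az = np.cos(pr) * np.cos(rr)
    if params.motion_burst_g > 0:
        w = _burst_window(t, truths)
        for arr, scale in ((ax, 0.6), (ay, 1.0), (az, 1.0)):
            arr += params.motion_burst_g * scale * w * _bandlimited_noise(rng, len(t), fs)
    if params.noise_sd > 0:
        ax = ax + rng.normal(0.0, params.noise_sd, len(t))
        ay = ay + rng.normal(0.0, params.noise_sd, len(t))
        az = az + rng.normal(0.0, params.noise_sd, len(t))
    if params.force_noise > 0:
        for arr in (f1, f2, f3, f4):
            arr += rng.normal(0.0, params.force_noise, len(t))
    insole = InsoleStream(
        time=t,
        f1=np.clip(f1, 0.0, None), f2=np.clip(f2, 0.0, None),
        f3=np.clip(f3, 0.0, None), f4=np.clip(f4, 0.0, None),
        ax=ax, ay=ay, az=az, rate_hz=fs,
    )

    noise = params.angle_noise_deg
    orientation = OrientationStream(
        time=t.copy(),
        pitch=np.clip(pitch + rng.normal(0.0, noise, len(t)) if noise > 0 else pitch,
                      -90.0, 90.0),
        roll=np.clip(roll + rng.normal(0.0, noise, len(t)) if noise > 0 else roll,
                     -90.0, 90.0),
        rate_hz=fs,
    )

    emg = None
    if params.include_emg:
        emg = _generate_emg(params, truths, total, rng)

    grid = None
    if params.include_grid_cop:
        # the grid insole sees a milder medial shift than the two-sensor MPP
        tg = np.arange(int(round(total * params.grid_rate_hz)) + 1) / params.grid_rate_hz
        mpp_g = np.interp(tg, t, mpp)
        pct = 50.0 + 0.5 * (mpp_g - 50.0)
        cop_x = params.grid_width_mm * (1.0 - pct / 100.0)
        if params.force_noise > 0:
            cop_x = cop_x + rng.normal(0.0, 0.5, len(tg))
        grid = GridCopStream(
            time=tg,
            cop_x=np.clip(cop_x, 0.0, params.grid_width_mm),
            width_mm=params.grid_width_mm,
            rate_hz=params.grid_rate_hz,
        )

    session = SyncedSession(
        insole=insole,
        orientation=orientation,
        emg=emg,
        grid_cop=grid,
        metadata={"variant": params.variant, "seed": params.seed, "synthetic": True},
    )
    return session, GroundTruth(variant=params.variant, events=truths)


def _generate_emg(
    params: SynthesisParams,
    truths: list[EventTruth],
    total_s: float,
    rng: np.random.Generator,
) -> EmgStream:
    fs = params.emg_rate_hz
    t = np.arange(int(round(total_s * fs)) + 1) / fs
    channels: dict[str, np.ndarray] = {}
    smooth_n = max(int(round(0.1 * fs)), 1)
    k = np.hanning(smooth_n + 2)[1:-1]
    k /= k.sum()
    for muscle in MUSCLES:
        gains = params.emg_gain[muscle]
        g = np.full_like(t, gains["idle"])
        for ev in truths:
            rise_on = ev.t_rise_start
            if muscle == "PL":
                rise_on = min(ev.t_rise_start + params.pl_delay_s, ev.t_hold_start)
            g[(t >= rise_on) & (t < ev.t_hold_start)] = gains["rise"]
            g[(t >= ev.t_hold_start) & (t < ev.t_drop_start)] = gains["hold"]
            g[(t >= ev.t_drop_start) & (t <= ev.t_drop_end)] = gains["drop"]
        g = np.convolve(g, k, mode="same")
        channels[muscle] = g * rng.standard_normal(len(t))
    return EmgStream(time=t, channels=channels, rate_hz=fs)


@dataclass
class CohortOffsets:
    """Inter-subject random offsets applied on top of the variant profiles.

    Subjects differ in habitual medial loading and foot-roll style, so each
    subject gets one MPP offset (added to both the baseline and raised
    levels, for every variant) and one roll offset (added to the rise roll
    excursion).  Within-subject EV/IV contrast is preserved; pooled
    single-threshold separation on MPP alone can fail.
    """

    mpp_offset_sd_pct: float = 12.0
    roll_offset_sd_deg: float = 1.5


def generate_cohort(
    n_subjects: int,
    per_subject_offsets: CohortOffsets | None = None,
    seed: int = 0,
    variants: tuple[str, ...] = VARIANTS,
    base_params: SynthesisParams | None = None,
) -> list[tuple[SyncedSession, GroundTruth]]:
    """Generate one session per subject × variant with subject-level offsets.

    Each returned session's metadata carries ``subject`` and ``variant``.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    offsets = per_subject_offsets or CohortOffsets()
    root = np.random.default_rng(seed)
    sessions: list[tuple[SyncedSession, GroundTruth]] = []
    for subj in range(n_subjects):
        d_mpp = offsets.mpp_offset_sd_pct * root.standard_normal()
        d_roll = offsets.roll_offset_sd_deg * root.standard_normal()
        for variant in variants:
            sub_seed = int(root.integers(0, 2**31 - 1))
            defaults = _variant_defaults(variant)
            kwargs = {}
            if base_params is not None:
                kwargs = {
                    k: v for k, v in asdict(base_params).items()
                    if k not in ("variant", "seed", "roll_delta_deg",
                                 "mpp_baseline_pct", "mpp_raised_pct", "emg_gain",
                                 "pl_delay_s")
                }
            params = SynthesisParams(
                variant=variant,
                seed=sub_seed,
                roll_delta_deg=defaults["roll_delta_deg"] + d_roll,
                mpp_baseline_pct=float(
                    np.clip(defaults["mpp_baseline_pct"] + d_mpp, 2.0, 98.0)
                ),
                mpp_raised_pct=float(
                    np.clip(defaults["mpp_raised_pct"] + d_mpp, 2.0, 98.0)
                ),
                **kwargs,
            )
            session, truth = generate_session(params)
            session.metadata["subject"] = subj
            sessions.append((session, truth))
    return sessions
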