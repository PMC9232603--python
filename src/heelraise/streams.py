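"""Sensor stream containers, delimited-text I/O, resampling and synchronization.

The toolkit revolves around four stream kinds recorded during a heel-raise
session:

* :class:`InsoleStream` — 4 force-sensing-resistor (FSR) channels plus a
  3-axis accelerometer sampled at a nominal 30 Hz.  Channel anatomy:
  ``F1`` toe, ``F2`` 1st metatarsal head (medial forefoot), ``F3`` 4th
  metatarsal head (lateral forefoot), ``F4`` heel.  Accelerometer axes:
  ``ax`` medio-lateral, ``ay`` along-foot (anterior), ``az`` vertical, in g.
* :class:`OrientationStream` — foot pitch/roll in degrees from a reference
  IMU.  Pitch 0 = flat foot, positive = heel up; roll positive = eversion.
* :class:`EmgStream` — raw multi-channel EMG (mV) at its own, higher rate.
* :class:`GridCopStream` — medio-lateral centre-of-pressure coordinate (mm)
  from a grid-type pressure insole, with the insole width as metadata.

Files are comma-delimited text with one header row; lines starting with
``#`` carry ``key=value`` sidecar metadata (used for the grid insole width).
The insole stream is the master clock: other streams are trimmed/aligned to
it but keep their native sampling rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import AlignmentError, DataError, FormatError, ParameterError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


class StreamKind(str, Enum):
    INSOLE = "insole"
    ORIENTATION = "orientation"
    EMG = "emg"
    GRID_COP = "grid_cop"


def _check_time(time: np.ndarray) -> None:
    if time.ndim != 1:
        raise DataError("time must be one-dimensional")
    if len(time) > 1:
        bad = np.nonzero(np.diff(time) <= 0)[0]
        if bad.size:
            raise DataError(f"time not strictly increasing at index {bad[0] + 1}")


def _check_rate(time: np.ndarray, rate_hz: float) -> None:
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be positive")
    if len(time) > 1:
        dt = float(np.median(np.diff(time)))
        if abs(dt - 1.0 / rate_hz) > 0.1 / rate_hz:
            raise DataError(
                f"median sampling interval {dt:.6g}s deviates >10% from "
                f"nominal 1/{rate_hz:g}s"
            )


@dataclass
class InsoleStream:
    """Force (4 FSR channels) + 3-axis acceleration at a nominal 30 Hz."""

    time: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    f4: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate_hz: float = 30.0

    _channels = ("f1", "f2", "f3", "f4", "ax", "ay", "az")
    _header = ("time", "F1", "F2", "F3", "F4", "ax", "ay", "az")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in self._channels:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.time.shape:
                raise DataError(f"channel {name} length differs from time")
        _check_time(self.time)
        _check_rate(self.time, self.rate_hz)
        for name in ("f1", "f2", "f3", "f4"):
            if np.any(getattr(self, name) < 0):
                raise DataError(f"negative force in channel {name}")

    def __len__(self) -> int:
        return len(self.time)

    def channel_arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._channels}


@dataclass
class OrientationStream:
    """Foot pitch/roll angle time series in degrees."""

    time: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    rate_hz: float = 30.0

    _channels = ("pitch", "roll")
    _header = ("time", "pitch", "roll")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        for name in self._channels:
            if getattr(self, name).shape != self.time.shape:
                raise DataError(f"channel {name} length differs from time")
        _check_time(self.time)
        _check_rate(self.time, self.rate_hz)
        if np.any(np.abs(self.pitch) > 90) or np.any(np.abs(self.roll) > 90):
            raise DataError("pitch/roll outside [-90, 90] degrees")

    def __len__(self) -> int:
        return len(self.time)

    def channel_arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._channels}


@dataclass
class EmgStream:
    """Raw multi-channel EMG in mV; channel names are muscle labels."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    rate_hz: float = 2000.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.shape != self.time.shape:
                raise DataError(f"channel {name} length differs from time")
        _check_time(self.time)
        _check_rate(self.time, self.rate_hz)

    def __len__(self) -> int:
        return len(self.time)

    def channel_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.channels)


@dataclass
class GridCopStream:
    """Medio-lateral COP coordinate (mm) from a grid pressure insole."""

    time: np.ndarray
    cop_x: np.ndarray
    width_mm: float
    rate_hz: float = 50.0

    _channels = ("cop_x",)
    _header = ("time", "cop_x")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cop_x = np.asarray(self.cop_x, dtype=float)
        if self.cop_x.shape != self.time.shape:
            raise DataError("cop_x length differs from time")
        _check_time(self.time)
        _check_rate(self.time, self.rate_hz)
        if self.width_mm <= 0:
            raise ParameterError("width_mm must be positive")
        if np.any((self.cop_x < 0) | (self.cop_x > self.width_mm)):
            raise DataError("cop_x outside [0, width_mm]")

    def __len__(self) -> int:
        return len(self.time)

    def channel_arrays(self) -> dict[str, np.ndarray]:
        return {"cop_x": self.cop_x}


Stream = InsoleStream | OrientationStream | EmgStream | GridCopStream


@dataclass
class SyncedSession:
    """All streams of one session placed on the insole master clock.

    Member streams cover the same time interval to within one master-clock
    sample; the insole stream defines that clock.  Metadata carries subject
    id, variant label, applied synchronization lags and source files.
    """

    insole: InsoleStream
    orientation: OrientationStream | None = None
    emg: EmgStream | None = None
    grid_cop: GridCopStream | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def t0(self) -> float:
        return float(self.insole.time[0])

    @property
    def t1(self) -> float:
        return float(self.insole.time[-1])

    def streams(self) -> dict[str, Stream]:
        out: dict[str, Stream] = {"insole": self.insole}
        for name in ("orientation", "emg", "grid_cop"):
            if getattr(self, name) is not None:
                out[name] = getattr(self, name)
        return out


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _validated_frame(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    time = df["time"].to_numpy(dtype=float)
    if len(time) > 1:
        bad = np.nonzero(np.diff(time) <= 0)[0]
        if bad.size:
            raise DataError(
                f"{path}: time not strictly increasing at row index {bad[0] + 1}"
            )
    return df


def _drop_out_of_range(df: pd.DataFrame, mask: np.ndarray, path, what: str) -> pd.DataFrame:
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("%s: rejected %d out-of-range rows (%s)", path, n_bad, what)
        df = df.loc[mask].reset_index(drop=True)
    return df


def read_stream(path, kind: StreamKind | str, rate_hz: float | None = None) -> Stream:
    """Read one delimited-text stream file and validate it.

    Parameters
    ----------
    path : path-like
        CSV file with a header row; ``#``-prefixed leading lines hold
        ``key=value`` sidecar metadata.
    kind : StreamKind or str
        Which of the four stream kinds the file contains.
    rate_hz : float, optional
        Nominal sampling rate; if omitted it is taken from the sidecar
        ``rate_hz`` entry or estimated from the median sampling interval.
    """
    kind = StreamKind(kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stream file not found: {path}")
    sidecar = _read_sidecar(path)
    df = pd.read_csv(path, comment="#")
    if rate_hz is None:
        if "rate_hz" in sidecar:
            rate_hz = float(sidecar["rate_hz"])
        elif len(df) > 1:
            rate_hz = 1.0 / float(np.median(np.diff(df["time"].to_numpy(dtype=float))))
        else:
            rate_hz = {StreamKind.EMG: 2000.0, StreamKind.GRID_COP: 50.0}.get(kind, 30.0)

    if kind is StreamKind.INSOLE:
        df = _validated_frame(df, list(InsoleStream._header), path)
        forces = df[["F1", "F2", "F3", "F4"]].to_numpy(dtype=float)
        df = _drop_out_of_range(df, (forces >= 0).all(axis=1), path, "negative force")
        return InsoleStream(
            time=df["time"].to_numpy(dtype=float),
            f1=df["F1"].to_numpy(dtype=float),
            f2=df["F2"].to_numpy(dtype=float),
            f3=df["F3"].to_numpy(dtype=float),
            f4=df["F4"].to_numpy(dtype=float),
            ax=df["ax"].to_numpy(dtype=float),
            ay=df["ay"].to_numpy(dtype=float),
            az=df["az"].to_numpy(dtype=float),
            rate_hz=rate_hz,
        )
    if kind is StreamKind.ORIENTATION:
        df = _validated_frame(df, list(OrientationStream._header), path)
        angles = df[["pitch", "roll"]].to_numpy(dtype=float)
        df = _drop_out_of_range(
            df, (np.abs(angles) <= 90).all(axis=1), path, "angle outside ±90°"
        )
        return OrientationStream(
            time=df["time"].to_numpy(dtype=float),
            pitch=df["pitch"].to_numpy(dtype=float),
            roll=df["roll"].to_numpy(dtype=float),
            rate_hz=rate_hz,
        )
    if kind is StreamKind.EMG:
        df = _validated_frame(df, ["time"], path)
        names = [c for c in df.columns if c != "time"]
        if not names:
            raise FormatError(f"{path}: EMG file has no channel columns")
        return EmgStream(
            time=df["time"].to_numpy(dtype=float),
            channels={c: df[c].to_numpy(dtype=float) for c in names},
            rate_hz=rate_hz,
        )
    # grid COP
    df = _validated_frame(df, ["time", "cop_x"], path)
    if "width_mm" not in sidecar:
        raise FormatError(f"{path}: missing required column 'width_mm' (sidecar)")
    width = float(sidecar["width_mm"])
    cop = df["cop_x"].to_numpy(dtype=float)
    df = _drop_out_of_range(df, (cop >= 0) & (cop <= width), path, "cop_x outside insole")
    return GridCopStream(
        time=df["time"].to_numpy(dtype=float),
        cop_x=df["cop_x"].to_numpy(dtype=float),
        width_mm=width,
        rate_hz=rate_hz,
    )


def write_stream(stream: Stream, path) -> Path:
    """Write a stream as delimited text; inverse of :func:`read_stream`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sidecar = [f"# rate_hz={stream.rate_hz:g}"]
    if isinstance(stream, GridCopStream):
        sidecar.append(f"# width_mm={stream.width_mm:g}")
    if isinstance(stream, EmgStream):
        cols = {"time": stream.time, **stream.channels}
    else:
        header = stream._header
        arrays = [stream.time] + [
            getattr(stream, name) for name in stream._channels
        ]
        cols = dict(zip(header, arrays))
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for line in sidecar:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


_KIND_OF_TYPE = {
    InsoleStream: StreamKind.INSOLE,
    OrientationStream: StreamKind.ORIENTATION,
    EmgStream: StreamKind.EMG,
    GridCopStream: StreamKind.GRID_COP,
}


def kind_of(stream: Stream) -> StreamKind:
    return _KIND_OF_TYPE[type(stream)]


# ---------------------------------------------------------------------------
# Resampling and synchronization
# ---------------------------------------------------------------------------

def resample(stream: Stream, target_rate_hz: float):
    """Linearly interpolate a stream onto a uniform grid at ``target_rate_hz``.

    The grid spans the original time range; the first sample coincides with
    the original start time and the grid step is exactly ``1/target_rate_hz``.
    """
    if target_rate_hz <= 0:
        raise ParameterError("target_rate_hz must be positive")
    if len(stream) < 2:
        raise DataError("resample requires at least 2 samples")
    t0, t1 = float(stream.time[0]), float(stream.time[-1])
    n = int(np.floor((t1 - t0) * target_rate_hz + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate_hz

    def interp(y: np.ndarray) -> np.ndarray:
        return np.interp(grid, stream.time, y)

    if isinstance(stream, EmgStream):
        return EmgStream(
            time=grid,
            channels={k: interp(v) for k, v in stream.channels.items()},
            rate_hz=target_rate_hz,
        )
    kwargs = {name: interp(getattr(stream, name)) for name in stream._channels}
    if isinstance(stream, GridCopStream):
        kwargs["width_mm"] = stream.width_mm
    return type(stream)(time=grid, rate_hz=target_rate_hz, **kwargs)


def _trim(stream: Stream, t0: float, t1: float, tol: float):
    mask = (stream.time >= t0 - tol) & (stream.time <= t1 + tol)
    if not mask.any():
        raise AlignmentError("stream has no samples in the common interval")
    if isinstance(stream, EmgStream):
        return EmgStream(
            time=stream.time[mask],
            channels={k: v[mask] for k, v in stream.channels.items()},
            rate_hz=stream.rate_hz,
        )
    kwargs = {name: getattr(stream, name)[mask] for name in stream._channels}
    if isinstance(stream, GridCopStream):
        kwargs["width_mm"] = stream.width_mm
    return type(stream)(time=stream.time[mask], rate_hz=stream.rate_hz, **kwargs)


def _xcorr_lag_s(insole: InsoleStream, orientation: OrientationStream) -> float | None:
    """Lag (s) to subtract from the orientation clock; None if degenerate.

    Uses the along-foot acceleration ``ay`` as a pitch surrogate: during a
    heel raise both quantities peak together, so their normalized
    cross-correlation peaks at the true clock offset.
    """
    fs = insole.rate_hz
    x = insole.ay
    ori = resample(orientation, fs)
    y = ori.pitch
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return None
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    c = sps.correlate(xs, ys, mode="full")
    lags = sps.correlation_lags(len(xs), len(ys), mode="full")
    s = int(lags[int(np.argmax(c))])
    # orientation sample j aligns with insole sample j + s
    return float(orientation.time[0] - insole.time[0] - s / fs)


def synchronize(
    insole: InsoleStream,
    orientation: OrientationStream | None = None,
    emg: EmgStream | None = None,
    grid_cop: GridCopStream | None = None,
    method: str = "shared-clock",
    metadata: dict | None = None,
    min_overlap_s: float = 1.0,
) -> SyncedSession:
    """Place all streams on the insole master clock.

    ``shared-clock`` trusts the timestamps and trims every stream to the
    common interval.  ``cross-correlation`` first estimates the clock offset
    of the orientation stream against the insole pitch surrogate (``ay``)
    and removes it; flat signals fall back to shared-clock with a warning.
    The applied lag per stream is recorded in the session metadata.
    """
    if method not in ("shared-clock", "cross-correlation"):
        raise ParameterError(f"unknown synchronization method '{method}'")
    others = {"orientation": orientation, "emg": emg, "grid_cop": grid_cop}
    meta = dict(metadata or {})
    lags = {name: 0.0 for name, s in others.items() if s is not None}

    if method == "cross-correlation" and orientation is not None:
        lag = _xcorr_lag_s(insole, orientation)
        if lag is None:
            warnings.warn(
                "zero-variance signal under cross-correlation; "
                "falling back to shared-clock",
                stacklevel=2,
            )
        else:
            orientation = replace(orientation, time=orientation.time - lag)
            others["orientation"] = orientation
            lags["orientation"] = lag

    t0, t1 = float(insole.time[0]), float(insole.time[-1])
    for name, s in others.items():
        if s is None:
            continue
        overlap = min(t1, float(s.time[-1])) - max(t0, float(s.time[0]))
        if overlap < min_overlap_s:
            raise AlignmentError(
                f"{name} stream overlaps insole by {max(overlap, 0):.3f}s "
                f"(< {min_overlap_s:g}s required)"
            )
        t0 = max(t0, float(s.time[0]))
        t1 = min(t1, float(s.time[-1]))

    tol = 0.5 / insole.rate_hz
    insole = _trim(insole, t0, t1, tol)
    trimmed = {
        name: (_trim(s, t0, t1, tol) if s is not None else None)
        for name, s in others.items()
    }
    meta["sync_method"] = method
    meta["applied_lag_s"] = lags
    return SyncedSession(insole=insole, metadata=meta, **trimmed)


# ---------------------------------------------------------------------------
# Session directories
# ---------------------------------------------------------------------------

_SESSION_FILES = {
    "insole": ("insole.csv", StreamKind.INSOLE),
    "orientation": ("orientation.csv", StreamKind.ORIENTATION),
    "emg": ("emg.csv", StreamKind.EMG),
    "grid_cop": ("grid_cop.csv", StreamKind.GRID_COP),
}


def write_session(session: SyncedSession, directory) -> Path:
    """Write all session streams plus a ``meta.json`` into a directory."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, (fname, _) in _SESSION_FILES.items():
        stream = getattr(session, name)
        if stream is not None:
            write_stream(stream, directory / fname)
    with open(directory / "meta.json", "w") as fh:
        json.dump(session.metadata, fh, indent=2)
    return directory


def load_session(directory, method: str = "shared-clock") -> SyncedSession:
    """Read a session directory written by :func:`write_session`."""
    import json

    directory = Path(directory)
    streams: dict[str, Stream | None] = {}
    for name, (fname, kind) in _SESSION_FILES.items():
        path = directory / fname
        streams[name] = read_stream(path, kind) if path.exists() else None
    if streams["insole"] is None:
        raise FileNotFoundError(f"no insole.csv in {directory}")
    meta = {}
    meta_path = directory / "meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return synchronize(
        streams["insole"],
        orientation=streams["orientation"],
        emg=streams["emg"],
        grid_cop=streams["grid_cop"],
        method=method,
        metadata=meta,
    )
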