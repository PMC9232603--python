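"""Stream I/O, resampling and synchronization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heelraise import (
    EmgStream,
    GridCopStream,
    InsoleStream,
    OrientationStream,
    StreamKind,
    read_stream,
    resample,
    synchronize,
    write_stream,
)
from heelraise.errors import AlignmentError, DataError, FormatError
from heelraise.streams import kind_of


def _grid(n, rate=30.0, t0=0.0):
    return t0 + np.arange(n) / rate


def make_insole(n=90, rate=30.0, rng=None):
    rng = rng or np.random.default_rng(0)
    t = _grid(n, rate)
    forces = rng.uniform(0, 50, (4, n))
    acc = rng.normal(0, 0.1, (3, n))
    return InsoleStream(t, *forces, *acc, rate_hz=rate)


@st.composite
def stream_strategy(draw):
    n = draw(st.integers(min_value=3, max_value=40))
    kind = draw(st.sampled_from(list(StreamKind)))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    rate = {StreamKind.EMG: 2000.0, StreamKind.GRID_COP: 50.0}.get(kind, 30.0)
    t = _grid(n, rate)
    if kind is StreamKind.INSOLE:
        return make_insole(n, rng=rng)
    if kind is StreamKind.ORIENTATION:
        return OrientationStream(t, rng.uniform(-80, 80, n), rng.uniform(-80, 80, n))
    if kind is StreamKind.EMG:
        return EmgStream(t, {"PL": rng.normal(0, 1, n), "GM": rng.normal(0, 1, n)})
    return GridCopStream(t, rng.uniform(0, 100, n), width_mm=100.0)


class TestReadWrite:
    def test_minimal_insole_file(self, tmp_path):
        path = tmp_path / "insole.csv"
        path.write_text(
            "time,F1,F2,F3,F4,ax,ay,az\n"
            "0,1,2,3,4,0,0,1\n"
            "0.033333,1,2,3,4,0,0,1\n"
            "0.066667,1,2,3,4,0,0,1\n"
        )
        s = read_stream(path, "insole")
        assert len(s) == 3
        assert s.rate_hz == pytest.approx(30.0, rel=0.01)

    def test_nonmonotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,pitch,roll\n0,0,0\n0.033,1,0\n0.033,2,0\n")
        with pytest.raises(DataError, match="index 2"):
            read_stream(path, "orientation")

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,F1,F2,F3,ax,ay,az\n0,1,1,1,0,0,1\n")
        with pytest.raises(FormatError, match="F4"):
            read_stream(path, "insole")

    def test_literal_values_written(self, tmp_path):
        s = InsoleStream(
            _grid(3), [1, 1, 1], [30, 30, 30], [10, 10, 10], [4, 4, 4],
            [0, 0, 0], [0, 0, 0], [1, 1, 1],
        )
        path = write_stream(s, tmp_path / "s.csv")
        text = path.read_text()
        assert ",30," in text and ",10," in text

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_stream(tmp_path / "nope.csv", "insole")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(stream=stream_strategy())
    def test_round_trip_identity(self, stream, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "s.csv"
        write_stream(stream, path)
        back = read_stream(path, kind_of(stream))
        assert type(back) is type(stream)
        np.testing.assert_allclose(back.time, stream.time, atol=1e-9)
        for name, arr in stream.channel_arrays().items():
            np.testing.assert_allclose(
                back.channel_arrays()[name], arr, atol=1e-9, err_msg=name
            )


class TestResample:
    def test_constant_stays_constant(self):
        t = _grid(60)
        s = OrientationStream(t, np.full(60, 7.0), np.zeros(60))
        r = resample(s, 45.0)
        assert np.allclose(r.pitch, 7.0)
        assert r.rate_hz == 45.0

    def test_linear_ramp_exact(self):
        t = _grid(60)
        s = OrientationStream(t, 10 * t, np.zeros(60))
        r = resample(s, 60.0)
        np.testing.assert_allclose(r.pitch, 10 * r.time, atol=1e-9)

    @pytest.mark.parametrize("freq", [1.0, 2.0, 3.0])
    def test_sine_within_interpolation_bound(self, freq):
        # max linear-interp error for a sine: A*(2*pi*f/fs)^2 / 8
        fs, amp = 30.0, 10.0
        t = _grid(300, fs)
        s = OrientationStream(t, amp * np.sin(2 * np.pi * freq * t), np.zeros(300))
        r = resample(s, 90.0)
        rms = np.sqrt(np.mean((r.pitch - amp * np.sin(2 * np.pi * freq * r.time)) ** 2))
        assert rms < amp * (2 * np.pi * freq / fs) ** 2 / 8

    def test_identity_at_original_rate(self):
        s = make_insole(90)
        r = resample(s, s.rate_hz)
        np.testing.assert_allclose(r.time, s.time, atol=1e-9)
        np.testing.assert_allclose(r.f2, s.f2, atol=1e-9)

    def test_too_short(self):
        s = OrientationStream(np.array([0.0]), np.array([1.0]), np.array([0.0]))
        with pytest.raises(DataError):
            resample(s, 30.0)


class TestSynchronize:
    def _pair(self, seed=3):
        from heelraise import SynthesisParams, generate_session

        session, _ = generate_session(
            SynthesisParams(seed=seed, include_emg=False, include_grid_cop=False)
        )
        return session.insole, session.orientation

    def test_aligned_streams_zero_lag(self):
        ins, ori = self._pair()
        sess = synchronize(ins, orientation=ori, method="cross-correlation")
        assert abs(sess.metadata["applied_lag_s"]["orientation"]) <= 1.0 / ins.rate_hz

    def test_shift_recovered(self):
        ins, ori = self._pair()
        shifted = replace(ori, time=ori.time + 0.5)
        sess = synchronize(ins, orientation=shifted, method="cross-correlation")
        lag = sess.metadata["applied_lag_s"]["orientation"]
        assert lag == pytest.approx(0.5, abs=1.0 / ins.rate_hz)

    def test_disjoint_ranges_error(self):
        ins, ori = self._pair()
        far = replace(ori, time=ori.time + 1000.0)
        with pytest.raises(AlignmentError):
            synchronize(ins, orientation=far)

    def test_flat_signal_falls_back(self):
        ins, ori = self._pair()
        flat = replace(ori, pitch=np.zeros_like(ori.pitch))
        ins_flat = replace(ins, ay=np.zeros_like(ins.ay))
        with pytest.warns(UserWarning, match="shared-clock"):
            sess = synchronize(ins_flat, orientation=flat, method="cross-correlation")
        assert sess.metadata["applied_lag_s"]["orientation"] == 0.0

    def test_idempotent(self):
        ins, ori = self._pair()
        shifted = replace(ori, time=ori.time + 0.2)
        first = synchronize(ins, orientation=shifted, method="cross-correlation")
        second = synchronize(
            first.insole, orientation=first.orientation, method="cross-correlation"
        )
        np.testing.assert_allclose(second.insole.time, first.insole.time, atol=1e-9)
        np.testing.assert_allclose(
            second.orientation.pitch, first.orientation.pitch, atol=1e-9
        )
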