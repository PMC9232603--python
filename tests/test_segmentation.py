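"""Event detection and rise/hold/drop phase splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heelraise import (
    SegmentationConfig,
    SynthesisParams,
    Trace,
    detect_events,
    detect_phases,
    generate_session,
    pitch_trace,
    segment_session,
)
from heelraise.errors import ConfigurationError

from conftest import noiseless_params

FS = 30.0
SAMPLE = 1.0 / FS


def trapezoid_trace(rise, hold, drop, lead=3.0, tail=3.0, top=25.0, fs=FS):
    """Sharp-cornered pitch trapezoid with analytic corner times."""
    total = lead + rise + hold + drop + tail
    t = np.arange(int(round(total * fs)) + 1) / fs
    corners = np.array([lead, lead + rise, lead + rise + hold, lead + rise + hold + drop])
    p = np.interp(t, [0, *corners, t[-1]], [0, 0, top, top, 0, 0])
    return Trace(t, p, fs), corners


class TestPitchTrace:
    def test_static_flat_foot_zero_pitch(self):
        from heelraise import InsoleStream, SyncedSession

        n = 90
        t = np.arange(n) / FS
        ins = InsoleStream(t, *[np.ones(n)] * 4, np.zeros(n), np.zeros(n), np.ones(n))
        tr = pitch_trace(SyncedSession(insole=ins), "accel_surrogate")
        np.testing.assert_allclose(tr.values, 0.0, atol=1e-9)

    def test_static_tilt_thirty_degrees(self):
        from heelraise import InsoleStream, SyncedSession

        n = 90
        t = np.arange(n) / FS
        ins = InsoleStream(
            t, *[np.ones(n)] * 4,
            np.zeros(n), np.full(n, 0.5), np.full(n, np.sqrt(3) / 2),
        )
        tr = pitch_trace(SyncedSession(insole=ins), "accel_surrogate")
        np.testing.assert_allclose(tr.values, 30.0, atol=1e-6)

    def test_surrogate_plateau_matches_programmed_peak(self):
        session, _ = generate_session(noiseless_params(include_emg=False))
        tr = pitch_trace(session, "accel_surrogate")
        # hold-phase plateau of the first event
        mask = (tr.time >= 6.5) & (tr.time <= 8.5)
        assert abs(tr.values[mask].mean() - 25.0) < 0.5

    def test_missing_orientation_stream(self):
        from heelraise import SyncedSession

        session, _ = generate_session(noiseless_params(include_emg=False))
        bare = SyncedSession(insole=session.insole)
        with pytest.raises(ConfigurationError):
            pitch_trace(bare, "orientation")


class TestDetectEvents:
    def test_all_zero_pitch_no_events(self):
        t = np.arange(300) / FS
        assert detect_events(Trace(t, np.zeros(300), FS)) == []

    def test_short_blip_discarded(self):
        t = np.arange(300) / FS
        p = np.where((t > 5.0) & (t < 5.2), 10.0, 0.0)
        assert detect_events(Trace(t, p, FS)) == []

    def test_short_trace_warns_empty(self):
        t = np.arange(10) / FS
        with pytest.warns(UserWarning):
            assert detect_events(Trace(t, np.full(10, 20.0), FS)) == []

    def test_noiseless_session_five_events(self):
        session, truth = generate_session(noiseless_params(include_emg=False))
        tr = pitch_trace(session, "orientation")
        events = detect_events(tr)
        assert len(events) == 5
        for (a, b), ev in zip(events, truth.events):
            assert a <= ev.t_rise_start + SAMPLE
            assert b >= ev.t_drop_end - SAMPLE


class TestDetectPhases:
    def test_noiseless_trapezoid_durations(self):
        tr, corners = trapezoid_trace(1.0, 3.0, 1.0)
        (iv,) = detect_events(tr)
        ev = detect_phases(tr, iv)
        assert np.allclose(ev.phase_durations_s, (1.0, 3.0, 1.0), atol=SAMPLE + 1e-9)

    def test_monotone_ramp_degenerate_hold(self):
        t = np.arange(200) / FS
        p = np.minimum(5.0 * t, 30.0)  # rises for 6 s then stays up
        tr = Trace(t, p, FS)
        (iv,) = detect_events(tr)
        ev = detect_phases(tr, iv)
        assert ev.valid
        assert ev.phase_durations_s[1] >= 0.0

    def test_flat_event_marked_invalid(self):
        t = np.arange(300) / FS
        p = np.where((t > 3) & (t < 7), 10.0, 0.0)
        with pytest.warns(UserWarning, match="invalid"):
            ev = detect_phases(Trace(t, p, FS), (3.5, 6.5))
        assert not ev.valid

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rise=st.floats(0.5, 2.0),
        hold=st.floats(1.0, 4.0),
        drop=st.floats(0.5, 2.0),
    )
    def test_boundaries_match_analytic_corners(self, rise, hold, drop):
        tr, corners = trapezoid_trace(rise, hold, drop)
        (iv,) = detect_events(tr)
        ev = detect_phases(tr, iv)
        detected = [ev.t_start, ev.t_rise_end, ev.t_drop_start, ev.t_end]
        assert np.abs(np.array(detected) - corners).max() <= SAMPLE + 1e-9


class TestSegmentSession:
    def test_noiseless_recovery_within_one_sample(self):
        session, truth = generate_session(noiseless_params(include_emg=False))
        events = segment_session(session)
        assert len(events) == 5
        detected = np.array(
            [[e.t_start, e.t_rise_end, e.t_drop_start, e.t_end] for e in events]
        )
        assert np.abs(detected - truth.boundary_array()).max() <= SAMPLE + 1e-9

    def test_phases_partition_each_event(self, default_session):
        session, _ = default_session
        for ev in segment_session(session):
            rise, hold, drop = ev.phase_durations_s
            assert rise > 0 and hold >= 0 and drop > 0
            assert ev.t_start + rise + hold + drop == pytest.approx(ev.t_end)

    def test_idle_only_session_empty(self):
        from heelraise import InsoleStream, SyncedSession

        n = 600
        t = np.arange(n) / FS
        rng = np.random.default_rng(0)
        ins = InsoleStream(
            t, *[np.full(n, 10.0)] * 4,
            rng.normal(0, 0.02, n), rng.normal(0, 0.02, n), 1 + rng.normal(0, 0.02, n),
        )
        assert segment_session(SyncedSession(insole=ins)) == []

    def test_event_count_stable_under_noise(self):
        # zero-mean pitch noise (SD <= 0.5 deg) never changes the event count
        base, _ = generate_session(noiseless_params(include_emg=False,
                                                    include_grid_cop=False))
        tr = pitch_trace(base, "orientation")
        rng = np.random.default_rng(42)
        for _ in range(100):
            noisy = Trace(tr.time, tr.values + rng.normal(0, 0.5, len(tr.time)), FS)
            assert len(detect_events(noisy)) == 5

    def test_accel_surrogate_segments_default_session(self, default_session):
        session, truth = default_session
        cfg = SegmentationConfig(pitch_source="accel_surrogate")
        events = segment_session(session, cfg)
        assert len(events) == truth.n_events
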