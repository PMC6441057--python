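"""Ripple-triggered cortical average and normalized spindle power."""

import numpy as np
import pytest

from sleepcouple.coupling import (
    interripple_baseline_power,
    ripple_triggered_average,
    ripple_triggered_spindle_power,
    select_events,
)
from sleepcouple.errors import InputError
from sleepcouple.io import ChannelInfo, EventTable, Recording

FS = 1000.0


def _events(times, state="NREM"):
    return EventTable.from_records(
        [
            {"start_s": t - 0.03, "peak_s": t, "end_s": t + 0.03,
             "channel": "CA1", "kind": "ripple", "state": state}
            for t in times
        ]
    )


def _recording(mfc, fs=FS):
    return Recording(
        np.atleast_2d(mfc), fs, [ChannelInfo("mFC", region="mFC", kind="wire")]
    )


class TestSelectEvents:
    def test_cap_chronological(self, rng):
        times = np.sort(rng.uniform(2, 598, 100))
        rec = _recording(np.zeros(int(600 * FS)))
        peaks = select_events(_events(times), rec, cap=40)
        np.testing.assert_allclose(peaks, times[:40])

    def test_non_nrem_excluded(self):
        rec = _recording(np.zeros(int(60 * FS)))
        ev = _events([10.0, 20.0], state="WI")
        assert len(select_events(ev, rec)) == 0

    def test_out_of_bounds_windows_dropped(self):
        rec = _recording(np.zeros(int(60 * FS)))
        peaks = select_events(_events([0.5, 30.0, 59.8]), rec, window_s=1.0)
        np.testing.assert_allclose(peaks, [30.0])


class TestTriggeredAverage:
    def test_identical_transients_recovered(self, rng):
        """Events aligned to identical injected cortical transients: the mean
        trace converges to the transient, noise suppressed ~ 1/sqrt(n)."""
        n = int(300 * FS)
        x = rng.standard_normal(n)
        times = np.arange(5.0, 295.0, 3.0)
        t_w = np.arange(int(-0.2 * FS), int(0.2 * FS)) / FS
        transient = 20 * np.exp(-(t_w**2) / (2 * 0.05**2)) * np.cos(2 * np.pi * 4 * t_w)
        for ts in times:
            c = int(ts * FS)
            x[c + int(-0.2 * FS) : c + int(0.2 * FS)] += transient
        rec = _recording(x)
        ta = ripple_triggered_average(rec, "mFC", _events(times), cap=1000)
        # expected trace = the transient as seen through the same 1-50 Hz
        # band-pass (computed on a clean signal, independent of averaging)
        from sleepcouple._filters import bandpass

        clean = np.zeros(int(10 * FS))
        c = int(5 * FS)
        clean[c + int(-0.2 * FS) : c + int(0.2 * FS)] += transient
        ref = bandpass(clean, FS, 1.0, 50.0)
        mid = np.abs(ta.lags_s) < 0.15
        offsets = np.round(ta.lags_s[mid] * FS).astype(int)
        expect = ref[c + offsets]
        assert np.corrcoef(ta.mean_trace[mid], expect)[0, 1] > 0.99
        # residual noise suppressed ~ 1/sqrt(n): sem = 1/sqrt(96) ~ 0.1
        assert np.max(np.abs(ta.mean_trace[mid] - expect)) < 0.5

    def test_random_events_average_to_zero(self, rng):
        """On stationary noise the triggered average shrinks ~ 1/sqrt(n)."""
        x = rng.standard_normal(int(600 * FS)) * 10
        rec = _recording(x)
        times = np.sort(rng.uniform(2, 598, 200))
        few = ripple_triggered_average(rec, "mFC", _events(times[:12]), cap=12)
        many = ripple_triggered_average(rec, "mFC", _events(times), cap=200)
        ratio = np.std(few.mean_trace) / np.std(many.mean_trace)
        assert ratio == pytest.approx(np.sqrt(200 / 12), rel=0.5)

    def test_cap_applied(self, rng):
        x = rng.standard_normal(int(120 * FS))
        times = np.sort(rng.uniform(2, 118, 50))
        ta = ripple_triggered_average(_recording(x), "mFC", _events(times), cap=30)
        assert ta.n_events == 30

    def test_no_events_rejected(self):
        rec = _recording(np.zeros(int(10 * FS)))
        with pytest.raises(InputError):
            ripple_triggered_average(rec, "mFC", EventTable())


class TestTriggeredSpindlePower:
    def test_stationary_power_normalizes_to_one(self, rng):
        """Random events on a stationary spindle-band field: normalized power
        ~ 1 at every lag (tolerance widened for the small n used here)."""
        from sleepcouple._filters import bandpass

        x = bandpass(rng.standard_normal(int(600 * FS)), FS, 10, 18) * 30
        x += rng.standard_normal(int(600 * FS))
        times = np.sort(rng.uniform(3, 597, 250))
        tp = ripple_triggered_spindle_power(_recording(x), "mFC", _events(times), cap=250)
        assert np.abs(tp.norm_power - 1).max() < 0.15

    def test_coupled_peak_near_lag_zero(self, coupled_rec):
        ev = coupled_rec.ground_truth.events.select(kind="ripple")
        tp = ripple_triggered_spindle_power(coupled_rec, events=ev, cap=60)
        assert tp.peak_norm_power > 1.5
        peak_lag = tp.lags_s[np.argmax(tp.norm_power)]
        assert abs(peak_lag) <= 0.1

    def test_uncoupled_flat(self, uncoupled_rec):
        ev = uncoupled_rec.ground_truth.events.select(kind="ripple")
        tp = ripple_triggered_spindle_power(uncoupled_rec, events=ev, cap=60)
        assert np.abs(tp.norm_power - 1).max() < 0.35
        assert tp.peak_norm_power < 1.35

    def test_lagged_coupling_shifts_peak(self):
        """Coupling injected at +150 ms moves the normalized-power peak to
        +150 ms within one smoothing window."""
        from sleepcouple.synth import CouplingParams, RippleParams, SynthParams, generate_recording

        p = SynthParams(
            seed=41, fs=1000.0,
            bout_schedule=[("WI", 10.0), ("NREM", 300.0), ("WI", 10.0)],
            ripples=RippleParams(rate_per_min=15.0),
            coupling=CouplingParams(gain=2.0, lag_ms=150.0),
        )
        rec = generate_recording(p)
        ev = rec.ground_truth.events.select(kind="ripple")
        tp = ripple_triggered_spindle_power(rec, events=ev, cap=60)
        peak_lag = tp.lags_s[np.argmax(tp.norm_power)]
        assert peak_lag == pytest.approx(0.15, abs=0.1)

    def test_self_consistency_baseline_as_events(self, rng):
        """Using the midpoint epochs themselves as trigger events yields
        normalized power ~ 1 everywhere."""
        from sleepcouple._filters import bandpass

        x = bandpass(rng.standard_normal(int(600 * FS)), FS, 10, 18) * 30
        rec = _recording(x)
        times = np.sort(rng.uniform(3, 597, 200))
        mids = (times[:-1] + times[1:]) / 2
        tp = ripple_triggered_spindle_power(rec, "mFC", _events(mids), cap=200)
        assert np.abs(tp.norm_power - 1).max() < 0.2

    def test_needs_two_events(self):
        rec = _recording(np.zeros(int(10 * FS)))
        with pytest.raises(InputError):
            ripple_triggered_spindle_power(rec, "mFC", _events([5.0]))


class TestBaselinePower:
    def test_constant_power_signal(self):
        """A pure spindle-band tone has constant envelope power: the baseline
        equals that power within 2%."""
        t = np.arange(int(120 * FS)) / FS
        x = 10 * np.sin(2 * np.pi * 14.0 * t)
        times = np.arange(3.0, 117.0, 3.0)
        base = interripple_baseline_power(_recording(x), "mFC", _events(times), cap=500)
        # power convention: squared analytic envelope, i.e. A^2 for a tone
        assert base == pytest.approx(100.0, rel=0.02)

    def test_identical_recordings_identical_baselines(self, rng):
        x = rng.standard_normal(int(120 * FS)) * 20
        times = np.sort(rng.uniform(3, 117, 40))
        b1 = interripple_baseline_power(_recording(x), "mFC", _events(times))
        b2 = interripple_baseline_power(_recording(x.copy()), "mFC", _events(times))
        assert b1 == b2
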