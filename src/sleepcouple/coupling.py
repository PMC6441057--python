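"""Ripple-triggered cortical analyses.

Two peri-event measures on the medial frontal cortex (mFC) channel, aligned
to hippocampal ripple peaks (NREM ripples only):

* the mean low-frequency (1-50 Hz) trace — the classic ripple-triggered
  average, dominated by the cortical down-state;
* spindle-band (10-18 Hz) instantaneous power (squared analytic envelope,
  100-ms smoothed), averaged across events per lag and normalized by the
  mean spindle power in 2-s epochs centered at the midpoints between
  consecutive used ripples. For uncoupled data the normalized power is ~1 at
  every lag; coupling shows as a peak near lag 0.

To equate event counts across animals the number of ripples is capped
(default 585, taken chronologically; random subsampling with a seed is
available). The same midpoint epochs give the per-animal inter-ripple
baseline power used for the between-genotype null comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import amplitude_envelope, bandpass, moving_average
from .errors import InputError
from .io import EventTable, Recording

DEFAULT_CAP = 585  # per-animal ripple count equalizer


@dataclass
class TriggeredAverage:
    lags_s: np.ndarray
    mean_trace: np.ndarray  # µV, band-limited
    n_events: int
    channel: str = "mFC"


@dataclass
class TriggeredPower:
    lags_s: np.ndarray
    norm_power: np.ndarray  # unitless, ~1 far from lag 0 when uncoupled
    peak_norm_power: float
    baseline_power: float  # µV², per animal
    n_events: int
    channel: str = "mFC"


def select_events(
    events: EventTable,
    rec: Recording,
    cap: int = DEFAULT_CAP,
    window_s: float = 1.0,
    state: str = "NREM",
    selection: str = "first",
    seed: int | None = None,
) -> np.ndarray:
    """Peak times of usable events: given state, window inside the recording,
    at most ``cap`` of them (chronological ``"first"`` or ``"random"``)."""
    frame = events.frame
    if "state" in frame.columns and state is not None:
        frame = frame[frame["state"] == state]
    peaks = frame["peak_s"].to_numpy(dtype=float)
    ok = (peaks - window_s >= 0) & (peaks + window_s <= rec.duration_s)
    peaks = peaks[ok]
    if len(peaks) > cap:
        if selection == "random":
            rng = np.random.default_rng(seed)
            peaks = np.sort(rng.choice(peaks, size=cap, replace=False))
        else:
            peaks = peaks[:cap]
    return peaks


def _stack_windows(trace: np.ndarray, fs: float, peaks_s: np.ndarray, window_s: float) -> np.ndarray:
    half = int(round(window_s * fs))
    rows = []
    for t in peaks_s:
        c = int(round(t * fs))
        rows.append(trace[c - half : c + half + 1])
    return np.asarray(rows)


def ripple_triggered_average(
    rec: Recording,
    mfc_channel: str | None = None,
    events: EventTable | None = None,
    cap: int = DEFAULT_CAP,
    window_s: float = 1.0,
    band: tuple[float, float] = (1.0, 50.0),
    selection: str = "first",
    seed: int | None = None,
) -> TriggeredAverage:
    """Mean band-limited mFC trace around NREM ripple peaks."""
    mfc_channel = mfc_channel or rec.find_channel(region="mFC")
    if events is None or len(events) == 0:
        raise InputError("no ripple events supplied")
    peaks = select_events(events, rec, cap=cap, window_s=window_s, selection=selection, seed=seed)
    if len(peaks) == 0:
        raise InputError("no usable events (state/window constraints)")
    filtered = bandpass(rec.channel(mfc_channel), rec.fs, band[0], band[1])
    windows = _stack_windows(filtered, rec.fs, peaks, window_s)
    half = int(round(window_s * rec.fs))
    lags = np.arange(-half, half + 1) / rec.fs
    return TriggeredAverage(lags_s=lags, mean_trace=windows.mean(axis=0), n_events=len(peaks), channel=mfc_channel)


def _spindle_power_trace(
    rec: Recording, channel: str, band: tuple[float, float], smooth_ms: float
) -> np.ndarray:
    filtered = bandpass(rec.channel(channel), rec.fs, band[0], band[1])
    power = amplitude_envelope(filtered) ** 2
    return moving_average(power, int(round(smooth_ms * 1e-3 * rec.fs)))


def _midpoint_baseline(
    power: np.ndarray, fs: float, peaks_s: np.ndarray, epoch_s: float = 2.0
) -> float:
    """Mean power over 2-s epochs centered at midpoints between consecutive
    used ripples; epochs clipped out of bounds are dropped."""
    if len(peaks_s) < 2:
        raise InputError("need >= 2 events to form inter-ripple midpoints")
    mids = (peaks_s[:-1] + peaks_s[1:]) / 2.0
    half = int(round(epoch_s / 2 * fs))
    vals = []
    for m in mids:
        c = int(round(m * fs))
        if c - half < 0 or c + half > len(power):
            continue
        vals.append(power[c - half : c + half].mean())
    if not vals:
        raise InputError("no in-bounds midpoint epochs")
    return float(np.mean(vals))


def ripple_triggered_spindle_power(
    rec: Recording,
    mfc_channel: str | None = None,
    events: EventTable | None = None,
    cap: int = DEFAULT_CAP,
    window_s: float = 1.0,
    band: tuple[float, float] = (10.0, 18.0),
    smooth_ms: float = 100.0,
    peak_window_s: float = 0.5,
    selection: str = "first",
    seed: int | None = None,
) -> TriggeredPower:
    """Normalized peri-ripple spindle power; see module docstring."""
    mfc_channel = mfc_channel or rec.find_channel(region="mFC")
    if events is None or len(events) == 0:
        raise InputError("no ripple events supplied")
    peaks = select_events(events, rec, cap=cap, window_s=window_s, selection=selection, seed=seed)
    if len(peaks) < 2:
        raise InputError("need >= 2 usable events")
    power = _spindle_power_trace(rec, mfc_channel, band, smooth_ms)
    windows = _stack_windows(power, rec.fs, peaks, window_s)
    mean_power = windows.mean(axis=0)
    baseline = _midpoint_baseline(power, rec.fs, peaks)
    norm = mean_power / baseline
    half = int(round(window_s * rec.fs))
    lags = np.arange(-half, half + 1) / rec.fs
    peak_region = np.abs(lags) <= peak_window_s
    return TriggeredPower(
        lags_s=lags,
        norm_power=norm,
        peak_norm_power=float(norm[peak_region].max()),
        baseline_power=baseline,
        n_events=len(peaks),
        channel=mfc_channel,
    )


def interripple_baseline_power(
    rec: Recording,
    mfc_channel: str | None = None,
    events: EventTable | None = None,
    cap: int = DEFAULT_CAP,
    band: tuple[float, float] = (10.0, 18.0),
    smooth_ms: float = 100.0,
    window_s: float = 1.0,
) -> float:
    """Per-animal mean spindle power over inter-ripple midpoint epochs (µV²)."""
    mfc_channel = mfc_channel or rec.find_channel(region="mFC")
    if events is None or len(events) == 0:
        raise InputError("no ripple events supplied")
    peaks = select_events(events, rec, cap=cap, window_s=window_s)
    if len(peaks) < 2:
        raise InputError("need >= 2 usable events")
    power = _spindle_power_trace(rec, mfc_channel, band, smooth_ms)
    return _midpoint_baseline(power, rec.fs, peaks)
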