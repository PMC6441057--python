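"""CA1 sharp-wave ripple detection and per-animal ripple statistics.

Pipeline: zero-phase band-pass 150-250 Hz; squared signal smoothed with a
10-ms boxcar (a power envelope); z-scored against a baseline of all NREM+WI
samples (movement is excluded because EMG contaminates the ripple band);
candidate events are contiguous runs above the 2-SD boundary threshold,
merged across gaps shorter than 20 ms, then filtered on duration (50-100 ms)
and peak amplitude.

Amplitude criterion modes:
* ``"band"`` (default) — peak z must lie *within* [2, 5] SD, reading
  "an amplitude from 2 to 5 SD above the baseline" as an acceptance band;
  large-amplitude artifacts are thereby rejected.
* ``"fma"`` — FMAToolbox convention: boundaries at 2 SD, peak must exceed
  5 SD.

An automatic spike-artifact veto replaces the original manual screening:
events whose 500-1000 Hz power z exceeds their ripple-band z are rejected
(skipped when the veto band exceeds Nyquist).

Intraripple frequency is the median instantaneous frequency (analytic-signal
phase derivative of the band-passed trace) within the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._filters import bandpass, instantaneous_frequency, moving_average
from .errors import ConfigurationError, InputError
from .io import EventTable, Hypnogram, Recording


@dataclass
class RippleConfig:
    band: tuple[float, float] = (150.0, 250.0)
    smooth_ms: float = 10.0
    boundary_sd: float = 2.0
    peak_sd_lo: float = 2.0
    peak_sd_hi: float = 5.0
    min_dur_ms: float = 50.0
    max_dur_ms: float = 100.0
    merge_gap_ms: float = 20.0
    mode: str = "band"  # "band" | "fma"
    spike_veto: bool = True
    veto_band: tuple[float, float] = (500.0, 1000.0)

    def __post_init__(self) -> None:
        if self.mode not in ("band", "fma"):
            raise ConfigurationError(f"unknown ripple mode {self.mode!r}")


def power_envelope(x: np.ndarray, fs: float, band: tuple[float, float], smooth_ms: float) -> np.ndarray:
    """Band-pass, square, boxcar-smooth: the detector's power envelope."""
    filtered = bandpass(x, fs, band[0], band[1])
    return moving_average(filtered**2, int(round(smooth_ms * 1e-3 * fs)))


def _state_mask(h: Hypnogram, fs: float, n_samples: int, states: tuple[str, ...]) -> np.ndarray:
    samples_per_bin = int(round(h.bin_s * fs))
    per_bin = np.isin(h.labels, states)
    mask = np.repeat(per_bin, samples_per_bin)
    if len(mask) < n_samples:  # trailing partial bin: extend last label
        mask = np.concatenate([mask, np.full(n_samples - len(mask), per_bin[-1] if len(per_bin) else False)])
    return mask[:n_samples]


def _contiguous_regions(above: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def detect_ripples(
    rec: Recording,
    ca1_channel: str | None = None,
    hypnogram: Hypnogram | None = None,
    cfg: RippleConfig | None = None,
) -> EventTable:
    """Detect sharp-wave ripples on the CA1 channel; see module docstring."""
    cfg = cfg or RippleConfig()
    ca1_channel = ca1_channel or rec.find_channel(region="CA1")
    if hypnogram is None:
        if rec.ground_truth is not None:
            hypnogram = rec.ground_truth.hypnogram
        else:
            raise ConfigurationError("a hypnogram is required for the ripple baseline")
    x = rec.channel(ca1_channel)
    fs = rec.fs

    filtered = bandpass(x, fs, cfg.band[0], cfg.band[1])
    env = moving_average(filtered**2, int(round(cfg.smooth_ms * 1e-3 * fs)))
    baseline = _state_mask(hypnogram, fs, rec.n_samples, ("NREM", "WI"))
    if not baseline.any():
        raise InputError("no NREM/WI samples available for the ripple baseline")
    mu = float(env[baseline].mean())
    sd = float(env[baseline].std())
    if sd == 0:
        raise InputError("degenerate (constant) ripple-band envelope")
    z = (env - mu) / sd

    regions = _contiguous_regions(z >= cfg.boundary_sd)
    # merge events separated by less than the merge gap, before the duration test
    merge_gap = cfg.merge_gap_ms * 1e-3 * fs
    merged: list[tuple[int, int]] = []
    for a, b in regions:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    veto_z = None
    if cfg.spike_veto and cfg.veto_band[1] < fs / 2:
        veto_env = power_envelope(x, fs, cfg.veto_band, cfg.smooth_ms)
        v_mu = float(veto_env[baseline].mean())
        v_sd = float(veto_env[baseline].std())
        if v_sd > 0:
            veto_z = (veto_env - v_mu) / v_sd

    inst_freq = None  # computed lazily on first accepted candidate
    records = []
    for a, b in merged:
        dur_ms = (b - a) / fs * 1e3
        if not cfg.min_dur_ms <= dur_ms <= cfg.max_dur_ms:
            continue
        peak_i = a + int(np.argmax(z[a:b]))
        peak_z = float(z[peak_i])
        if cfg.mode == "band":
            if not cfg.peak_sd_lo <= peak_z <= cfg.peak_sd_hi:
                continue
        else:  # fma
            if peak_z < cfg.peak_sd_hi:
                continue
        state = str(hypnogram.labels[min(int(peak_i / fs / hypnogram.bin_s), hypnogram.n_bins - 1)])
        if state not in ("NREM", "WI"):
            continue
        if veto_z is not None and float(veto_z[a:b].max()) > peak_z:
            continue
        if inst_freq is None:
            inst_freq = instantaneous_frequency(filtered, fs)
        records.append(
            {
                "start_s": a / fs,
                "peak_s": peak_i / fs,
                "end_s": b / fs,
                "channel": ca1_channel,
                "kind": "ripple",
                "peak_z": peak_z,
                "intra_freq_hz": float(np.median(inst_freq[a:b])),
                "state": state,
            }
        )
    return EventTable.from_records(records)


def ripple_stats(events: EventTable, hypnogram: Hypnogram) -> pd.DataFrame:
    """Per-state rate (events/min), mean intraripple frequency and duration.

    States with zero duration in the hypnogram are omitted (rate undefined).
    """
    rows = []
    for state in ("NREM", "WI"):
        minutes = hypnogram.state_seconds(state) / 60.0
        if minutes == 0:
            continue
        sub = events.select(state=state).frame if len(events) else events.frame
        n = len(sub)
        rows.append(
            {
                "state": state,
                "n_events": n,
                "rate_per_min": n / minutes,
                "mean_intra_freq_hz": float(sub["intra_freq_hz"].mean()) if n else np.nan,
                "mean_duration_ms": float(((sub["end_s"] - sub["start_s"]) * 1e3).mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def match_events(
    detected: EventTable,
    truth: EventTable,
    tol_s: float = 0.025,
) -> tuple[float, float, int]:
    """(recall, precision, n_matched) by greedy peak-time matching within tol."""
    det = detected.frame["peak_s"].to_numpy() if len(detected) else np.array([])
    tru = truth.frame["peak_s"].to_numpy() if len(truth) else np.array([])
    used = np.zeros(len(det), dtype=bool)
    matched = 0
    for t in tru:
        if len(det) == 0:
            break
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            matched += 1
    recall = matched / len(tru) if len(tru) else float("nan")
    precision = matched / len(det) if len(det) else float("nan")
    return recall, precision, matched
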