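"""Phase-amplitude coupling: Kullback-Leibler modulation index and comodulogram.

The modulation index (MI) follows the KL-divergence construction: band-pass
the slow band and take its analytic phase; band-pass the fast band and take
its amplitude envelope; average the envelope in ``n_bins`` phase bins,
normalize the bin means to a distribution P; MI = KL(P || uniform) / log(n).
MI is 0 for a phase-independent envelope and bounded by 1, and is invariant
to overall signal amplitude.

Multiple segments (e.g. the REM epochs of one animal) are supported by
filtering each segment separately and pooling the phase-binned envelope
histograms, which avoids edge artifacts at concatenation joins.

The comodulogram evaluates MI on a grid of band centers — by default phase
2-12 Hz (2-Hz bandwidth) by amplitude 20-120 Hz (10-Hz bandwidth) — and the
scalar summary is the mean MI over the high-coupling region, phase 7-8 Hz by
amplitude 60-90 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import amplitude_envelope, bandpass, instantaneous_phase
from .errors import InputError

#: High-coupling summary region (phase Hz, amplitude Hz).
SUMMARY_PHASE_RANGE = (7.0, 8.0)
SUMMARY_AMP_RANGE = (60.0, 90.0)


def _as_segments(x) -> list[np.ndarray]:
    if isinstance(x, (list, tuple)):
        return [np.asarray(s, dtype=float) for s in x]
    return [np.asarray(x, dtype=float)]


def _binned_amplitude(
    segments: list[np.ndarray],
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (sum, count) of envelope per phase bin across segments."""
    lo = phase_band[0]
    min_len = int(10 * fs / lo)  # >= 10 cycles of the slow band's low edge
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    usable = 0
    for seg in segments:
        if len(seg) < min_len:
            continue
        usable += 1
        phase = instantaneous_phase(
            bandpass(seg, fs, *phase_band, transition_hz=(phase_band[1] - phase_band[0]) / 2)
        )
        amp = amplitude_envelope(
            bandpass(seg, fs, *amp_band, transition_hz=(amp_band[1] - amp_band[0]) / 2)
        )
        idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
        sums += np.bincount(idx, weights=amp, minlength=n_bins)
        counts += np.bincount(idx, minlength=n_bins)
    if usable == 0:
        raise InputError(
            f"no segment reaches 10 cycles of {lo} Hz ({min_len} samples)"
        )
    return sums, counts


def modulation_index(
    x,
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    n_bins: int = 18,
) -> float:
    """KL modulation index in [0, 1]; ``x`` may be one array or a list of
    segments whose phase-bin histograms are pooled."""
    sums, counts = _binned_amplitude(_as_segments(x), fs, phase_band, amp_band, n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return 0.0
    prob = means / total
    nz = prob > 0
    kl = float(np.sum(prob[nz] * np.log(prob[nz] * n_bins)))
    return kl / np.log(n_bins)


@dataclass
class Comodulogram:
    phase_freqs: np.ndarray  # band centers, Hz
    amp_freqs: np.ndarray
    mi: np.ndarray  # (n_phase, n_amp)
    channel: str = ""
    state: str = ""

    def argmax_centers(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


def comodulogram(
    x,
    fs: float,
    phase_freqs: np.ndarray | None = None,
    amp_freqs: np.ndarray | None = None,
    phase_bw: float = 2.0,
    amp_bw: float = 10.0,
    n_bins: int = 18,
    channel: str = "",
    state: str = "",
) -> Comodulogram:
    """MI over a grid of (phase, amplitude) band centers.

    Phase series and amplitude envelopes are each computed once per band and
    reused across the grid. Bands exceeding Nyquist raise an error.
    """
    segments = _as_segments(x)
    if phase_freqs is None:
        phase_freqs = np.arange(2.0, 13.0, 1.0)
    if amp_freqs is None:
        amp_freqs = np.arange(20.0, 125.0, 5.0)
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    for c in phase_freqs:
        if c + phase_bw / 2 >= fs / 2 or c - phase_bw / 2 <= 0:
            raise InputError(f"phase band at {c} Hz outside (0, Nyquist)")
    for c in amp_freqs:
        if c + amp_bw / 2 >= fs / 2 or c - amp_bw / 2 <= 0:
            raise InputError(f"amplitude band at {c} Hz outside (0, Nyquist)")

    min_len = int(10 * fs / (phase_freqs.min() - phase_bw / 2))
    usable = [s for s in segments if len(s) >= min_len]
    if not usable:
        raise InputError("no segment long enough for the lowest phase band")

    phases = {}
    for c in phase_freqs:
        phases[c] = [
            instantaneous_phase(
                bandpass(s, fs, c - phase_bw / 2, c + phase_bw / 2, transition_hz=phase_bw / 2)
            )
            for s in usable
        ]
    amps = {}
    for c in amp_freqs:
        amps[c] = [
            amplitude_envelope(
                bandpass(s, fs, c - amp_bw / 2, c + amp_bw / 2, transition_hz=amp_bw / 2)
            )
            for s in usable
        ]

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    mi = np.zeros((len(phase_freqs), len(amp_freqs)))
    for i, cp in enumerate(phase_freqs):
        idx_list = [np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1) for ph in phases[cp]]
        for j, ca in enumerate(amp_freqs):
            sums = np.zeros(n_bins)
            counts = np.zeros(n_bins, dtype=np.int64)
            for idx, amp in zip(idx_list, amps[ca]):
                sums += np.bincount(idx, weights=amp, minlength=n_bins)
                counts += np.bincount(idx, minlength=n_bins)
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            total = means.sum()
            if total > 0:
                prob = means / total
                nz = prob > 0
                mi[i, j] = float(np.sum(prob[nz] * np.log(prob[nz] * n_bins))) / np.log(n_bins)
    return Comodulogram(phase_freqs, amp_freqs, mi, channel=channel, state=state)


def pac_summary(
    c: Comodulogram,
    phase_range: tuple[float, float] = SUMMARY_PHASE_RANGE,
    amp_range: tuple[float, float] = SUMMARY_AMP_RANGE,
) -> float:
    """Mean MI over grid cells whose centers fall in the summary region."""
    pi = (c.phase_freqs >= phase_range[0]) & (c.phase_freqs <= phase_range[1])
    ai = (c.amp_freqs >= amp_range[0]) & (c.amp_freqs <= amp_range[1])
    if not pi.any() or not ai.any():
        raise InputError("summary region contains no grid cells")
    return float(c.mi[np.ix_(pi, ai)].mean())


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """FFT phase-randomized surrogate (preserves the amplitude spectrum,
    destroys cross-frequency coupling). Used for PAC null levels."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, len(spec))
    phases[0] = 0.0
    if len(x) % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=len(x))
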