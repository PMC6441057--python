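"""Welch power spectral density, whitening, band power, and line-noise masks.

PSDs are density-normalized (µV²/Hz): the integral over frequency recovers
the signal variance (Parseval). "Whitening" multiplies the PSD by frequency,
the usual flattening of the 1/f background for display. Line noise (50 Hz)
is handled as a bin *mask* — masked bins are excluded from band averages and
group statistics — rather than as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import InputError, IntegrityError


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise InputError(f"invalid band {self.name}: ({self.lo_hz}, {self.hi_hz})")


#: The four analysis bands: delta, theta, spindle, high beta.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 5.0, 9.0),
    BandDefinition("spindle", 10.0, 18.0),
    BandDefinition("high_beta", 19.0, 30.0),
)


@dataclass
class Spectrum:
    """A PSD on a frequency grid, with an inclusion mask for line bins."""

    freqs: np.ndarray
    psd: np.ndarray
    n_epochs: int = 1
    channel: str = ""
    state: str = ""
    mask: np.ndarray = field(default=None)  # True = bin included

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise IntegrityError("freqs and psd must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise IntegrityError("frequency grid must be strictly increasing")
        if self.mask is None:
            self.mask = np.ones_like(self.freqs, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    fmin: float = 0.0,
    fmax: float | None = None,
    channel: str = "",
    state: str = "",
) -> Spectrum:
    """Welch PSD with Hamming windows of ``window_s`` seconds.

    Defaults (2-s windows, 50% overlap) give 0.5 Hz resolution and 19
    averaging segments on a 20-s epoch.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if len(x) < nperseg:
        raise InputError(f"segment ({len(x)} samples) shorter than window ({nperseg})")
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)),
        detrend="constant",
        scaling="density",
    )
    if fmax is None:
        fmax = fs / 2
    keep = (freqs >= fmin) & (freqs <= fmax)
    return Spectrum(freqs[keep], psd[keep], channel=channel, state=state)


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Mean PSD across epochs on a common grid (per-animal averaging)."""
    if not spectra:
        raise InputError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.freqs, first.freqs):
            raise IntegrityError("spectra are on different frequency grids")
    psd = np.mean([s.psd for s in spectra], axis=0)
    mask = np.logical_and.reduce([s.mask for s in spectra])
    return Spectrum(
        first.freqs.copy(),
        psd,
        n_epochs=sum(s.n_epochs for s in spectra),
        channel=first.channel,
        state=first.state,
        mask=mask,
    )


def whiten(s: Spectrum) -> Spectrum:
    """Multiply the PSD by frequency (1/f flattening for display)."""
    return replace(s, freqs=s.freqs.copy(), psd=s.freqs * s.psd, mask=s.mask.copy())


def band_power(s: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over the band (µV²), masked bins excluded."""
    inband = (s.freqs >= band.lo_hz) & (s.freqs <= band.hi_hz)
    if not inband.any():
        raise InputError(f"band {band.name} outside spectrum range")
    keep = inband & s.mask
    if keep.sum() < 2:
        raise InputError(f"band {band.name} has fewer than 2 usable bins")
    return float(np.trapezoid(s.psd[keep], s.freqs[keep]))


def notch_mask(s: Spectrum, line_hz: float = 50.0, half_width_hz: float = 1.0) -> Spectrum:
    """Exclude bins within ``line_hz ± half_width_hz`` (nearest bin if width 0)."""
    mask = s.mask.copy()
    if half_width_hz <= 0:
        mask[int(np.argmin(np.abs(s.freqs - line_hz)))] = False
    else:
        mask &= ~(np.abs(s.freqs - line_hz) <= half_width_hz)
    return replace(s, freqs=s.freqs.copy(), psd=s.psd.copy(), mask=mask)
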