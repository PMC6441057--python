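"""Interregional synchronization via magnitude-squared coherence (MSC).

MSC is the Welch cross-spectrum magnitude squared, normalized by the two
auto-spectra:

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))

which is bounded in [0, 1]. The estimator needs at least two averaging
segments (a single segment gives identically 1), and its expected value on
independent signals is the well-known 1/K bias floor for K independent
segments. Band connectivity is the unweighted mean of C_xy over the in-band
frequency bins (line-masked bins excluded), for the four analysis bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InputError
from .io import Hypnogram, Recording
from .spectral import BandDefinition, DEFAULT_BANDS
from .staging import select_epoch_pairs, stage

#: Region pairs examined for long-range and intrahippocampal synchrony.
DEFAULT_PAIRS = (("mFC", "CA1"), ("mFC", "RS"), ("CA1", "DG"))


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    cxy: np.ndarray
    pxy: np.ndarray  # components retained for audit
    pxx: np.ndarray
    pyy: np.ndarray
    pair: tuple[str, str] = ("x", "y")
    state: str = ""
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones_like(self.freqs, dtype=bool)


@dataclass(frozen=True)
class BandConnectivity:
    pair: tuple[str, str]
    band: str
    value: float
    state: str = ""
    animal: str = ""
    genotype: str = ""


def _n_segments(n: int, nperseg: int, noverlap: int) -> int:
    if n < nperseg:
        return 0
    return 1 + (n - nperseg) // (nperseg - noverlap)


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    fmin: float = 0.0,
    fmax: float | None = None,
    pair: tuple[str, str] = ("x", "y"),
    state: str = "",
) -> CoherenceSpectrum:
    """Magnitude-squared coherence with Welch-averaged spectra.

    Defaults (2-s Hamming windows, 50% overlap) give 19 segments on a 20-s
    epoch, hence a ~1/19 independent-noise bias floor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(nperseg * overlap_frac))
    if _n_segments(len(x), nperseg, noverlap) < 2:
        raise InputError("coherence needs >= 2 averaging segments (single-segment MSC is identically 1)")
    kwargs = dict(
        fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    # canonical argument order makes msc(x, y) and msc(y, x) the *same*
    # floating-point computation, so symmetry holds exactly
    if x.tobytes() <= y.tobytes():
        freqs, pxy = sps.csd(x, y, **kwargs)
    else:
        freqs, pyx = sps.csd(y, x, **kwargs)
        pxy = np.conjugate(pyx)
    _, pxx = sps.welch(x, **kwargs)
    _, pyy = sps.welch(y, **kwargs)
    denom = pxx * pyy
    cxy = np.zeros_like(freqs)
    ok = denom > 0
    cxy[ok] = np.abs(pxy[ok]) ** 2 / denom[ok]
    cxy = np.clip(cxy, 0.0, 1.0)
    if fmax is None:
        fmax = fs / 2
    keep = (freqs >= fmin) & (freqs <= fmax)
    return CoherenceSpectrum(
        freqs=freqs[keep], cxy=cxy[keep], pxy=pxy[keep], pxx=pxx[keep], pyy=pyy[keep],
        pair=pair, state=state,
    )


def band_connectivity(
    c: CoherenceSpectrum,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    animal: str = "",
    genotype: str = "",
) -> list[BandConnectivity]:
    """Unweighted mean coherence over in-band, unmasked frequency bins."""
    out = []
    for band in bands:
        keep = (c.freqs >= band.lo_hz) & (c.freqs <= band.hi_hz) & c.mask
        if not keep.any():
            raise InputError(f"band {band.name} empty after masking")
        out.append(
            BandConnectivity(
                pair=c.pair, band=band.name, value=float(c.cxy[keep].mean()),
                state=c.state, animal=animal, genotype=genotype,
            )
        )
    return out


def connectivity_table(
    recordings: list[Recording],
    hypnograms: list[Hypnogram] | None = None,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Per animal x state x pair x band mean coherence over 20-s epochs.

    Coherence spectra are averaged across epochs within each state per animal
    (the animal is the experimental unit), then band-averaged. Animals with
    no valid NREM/REM epoch pair are dropped with a warning.
    """
    rows = []
    for i, rec in enumerate(recordings):
        hyp = hypnograms[i] if hypnograms is not None else stage(rec)
        epoch_pairs = select_epoch_pairs(hyp)
        if not epoch_pairs:
            warnings.warn(f"animal {rec.meta.get('animal', i)}: no valid epoch pairs; dropped")
            continue
        animal = str(rec.meta.get("animal", i))
        genotype = str(rec.meta.get("genotype", ""))
        for state in ("NREM", "REM"):
            for pair in pairs:
                spectra = []
                for ep in epoch_pairs:
                    seg = ep.nrem_segment(rec) if state == "NREM" else ep.rem_segment(rec)
                    spectra.append(
                        msc(
                            seg.channel(pair[0]), seg.channel(pair[1]), rec.fs,
                            window_s=window_s, overlap_frac=overlap_frac,
                            pair=pair, state=state,
                        )
                    )
                mean_c = spectra[0]
                mean_c.cxy = np.mean([s.cxy for s in spectra], axis=0)
                for bc in band_connectivity(mean_c, bands, animal=animal, genotype=genotype):
                    rows.append(
                        {
                            "animal": animal, "genotype": genotype, "state": state,
                            "pair": f"{pair[0]}-{pair[1]}", "band": bc.band,
                            "coherence": bc.value,
                        }
                    )
    return pd.DataFrame(rows, columns=["animal", "genotype", "state", "pair", "band", "coherence"])
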