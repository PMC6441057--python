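"""Rule-based sleep staging from a cortical screw channel and EMG.

The recording is cut into 2-s bins. Per bin, the EMG is rectified and its
maximum taken, and the screw-channel short-time spectrum gives delta, theta,
alpha and gamma power. Rules, in precedence order:

* MOVE — rectified EMG maximum above a threshold (default 2 x the SD of the
  bin-wise EMG maxima over the whole recording; a fixed µV override stands in
  for the per-animal video adjustment).
* REM  — theta/delta power ratio above twice its recording-level mean.
* NREM — alpha/gamma power ratio above its recording-level mean.
* WI   — everything else (waking immobility).

Two merge passes then relabel single-bin gaps: a non-moving bin flanked by
REM keeps REM if its theta/delta ratio still exceeds the mean; a non-moving
bin flanked by NREM keeps NREM if its alpha/gamma ratio is not below half the
mean. Each pass runs to a fixed point, so merging is idempotent.

Epoch selection for the spectral/connectivity analyses takes, for every REM
bout of at least 10 bins, the first 20 s of REM and the 20 s of NREM that
precede a 20-s excluded pre-REM transition gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, IntegrityError
from .io import Hypnogram, Recording, STATES

#: Staging band edges (Hz). Delta/theta match the connectivity bands; alpha
#: and gamma edges are package choices (gamma stops below the 50 Hz line).
STAGING_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 9.0),
    "alpha": (10.0, 15.0),
    "gamma": (30.0, 48.0),
}


@dataclass
class BinFeatures:
    """Per-bin features: rectified-EMG maximum and screw-channel band powers."""

    emg_max: np.ndarray
    band_powers: dict[str, np.ndarray]
    bin_s: float = 2.0

    @property
    def n_bins(self) -> int:
        return len(self.emg_max)

    @property
    def r_ag(self) -> np.ndarray:
        """Alpha/gamma power ratio (NREM discriminator)."""
        return _safe_ratio(self.band_powers["alpha"], self.band_powers["gamma"])

    @property
    def r_td(self) -> np.ndarray:
        """Theta/delta power ratio (REM discriminator)."""
        return _safe_ratio(self.band_powers["theta"], self.band_powers["delta"])


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~ok & (num > 0)] = np.inf
    return out


@dataclass
class StagingThresholds:
    emg_k: float = 2.0  # movement threshold, in SDs of bin-wise EMG maxima
    rem_factor: float = 2.0  # REM: r_td > rem_factor * mean(r_td)
    rem_merge_factor: float = 1.0
    nrem_merge_factor: float = 0.5
    emg_threshold_uv: float | None = None  # fixed override (video-adjusted)

    def __post_init__(self) -> None:
        for name in ("emg_k", "rem_factor", "rem_merge_factor", "nrem_merge_factor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def compute_bin_features(
    rec: Recording,
    bin_s: float = 2.0,
    screw_channel: str | None = None,
    emg_channel: str | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BinFeatures:
    """Per-bin EMG maxima and screw-channel band powers.

    The short-time spectrum inside each bin uses 1-s Hamming windows with 50%
    overlap; band power is the mean spectral power over in-band bins.
    An incomplete trailing bin is dropped.
    """
    bands = dict(bands or STAGING_BANDS)
    screw_channel = screw_channel or rec.find_channel(kind="screw")
    emg_channel = emg_channel or rec.find_channel(kind="emg")
    eeg = rec.channel(screw_channel)
    emg = np.abs(rec.channel(emg_channel))  # rectified

    samples_per_bin = int(round(bin_s * rec.fs))
    n_bins = rec.n_samples // samples_per_bin
    if n_bins < 1:
        raise ConfigurationError("recording shorter than one bin")
    eeg = eeg[: n_bins * samples_per_bin].reshape(n_bins, samples_per_bin)
    emg = emg[: n_bins * samples_per_bin].reshape(n_bins, samples_per_bin)

    nperseg = min(int(round(rec.fs)), samples_per_bin)
    freqs, psd = sps.welch(
        eeg,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    powers = {}
    for name, (lo, hi) in bands.items():
        inband = (freqs >= lo) & (freqs <= hi)
        powers[name] = psd[:, inband].mean(axis=1)
    return BinFeatures(emg_max=emg.max(axis=1), band_powers=powers, bin_s=bin_s)


def _merge_pass(
    labels: np.ndarray,
    ratio: np.ndarray,
    threshold: float,
    state: str,
) -> bool:
    """One left-to-right gap-relabelling sweep; returns True if anything changed."""
    changed = False
    for i in range(1, len(labels) - 1):
        if (
            labels[i - 1] == state
            and labels[i + 1] == state
            and labels[i] not in (state, "MOVE")
            and ratio[i] >= threshold
        ):
            labels[i] = state
            changed = True
    return changed


def classify_bins(features: BinFeatures, thresholds: StagingThresholds | None = None) -> Hypnogram:
    """Apply the staging rules and merge passes; returns a Hypnogram."""
    th = thresholds or StagingThresholds()
    f = features
    emg_thr = (
        th.emg_threshold_uv
        if th.emg_threshold_uv is not None
        else th.emg_k * float(np.std(f.emg_max))
    )
    r_ag, r_td = f.r_ag, f.r_td
    finite_ag = r_ag[np.isfinite(r_ag)]
    finite_td = r_td[np.isfinite(r_td)]
    mean_ag = float(finite_ag.mean()) if len(finite_ag) else 0.0
    mean_td = float(finite_td.mean()) if len(finite_td) else 0.0

    labels = np.full(f.n_bins, "WI", dtype="U4")
    labels[r_ag > mean_ag] = "NREM"
    labels[r_td > th.rem_factor * mean_td] = "REM"  # REM wins NREM ties
    labels[f.emg_max > emg_thr] = "MOVE"  # EMG rule wins everything

    # merge passes, each to a fixed point (idempotent overall)
    while _merge_pass(labels, r_td, th.rem_merge_factor * mean_td, "REM"):
        pass
    while _merge_pass(labels, r_ag, th.nrem_merge_factor * mean_ag, "NREM"):
        pass
    return Hypnogram(labels, bin_s=f.bin_s)


def stage(rec: Recording, thresholds: StagingThresholds | None = None, **feature_kwargs) -> Hypnogram:
    """Convenience: compute_bin_features then classify_bins."""
    return classify_bins(compute_bin_features(rec, **feature_kwargs), thresholds)


@dataclass(frozen=True)
class EpochPair:
    """Matched 20-s NREM and REM segments around one REM-bout onset.

    Bin indices are starts of 10-bin runs; the 10 bins between NREM segment
    end and REM onset form the excluded pre-REM transition gap.
    """

    nrem_start_bin: int
    rem_start_bin: int
    bin_s: float = 2.0
    n_bins: int = 10

    @property
    def nrem_interval_s(self) -> tuple[float, float]:
        return (self.nrem_start_bin * self.bin_s, (self.nrem_start_bin + self.n_bins) * self.bin_s)

    @property
    def rem_interval_s(self) -> tuple[float, float]:
        return (self.rem_start_bin * self.bin_s, (self.rem_start_bin + self.n_bins) * self.bin_s)

    def nrem_segment(self, rec: Recording, channels: list[str] | None = None) -> Recording:
        return rec.slice(*self.nrem_interval_s, channels=channels)

    def rem_segment(self, rec: Recording, channels: list[str] | None = None) -> Recording:
        return rec.slice(*self.rem_interval_s, channels=channels)


def select_epoch_pairs(h: Hypnogram, n_bins: int = 10) -> list[EpochPair]:
    """One EpochPair per REM bout of >= ``n_bins`` bins.

    The REM segment is the bout's first ``n_bins`` bins; the ``n_bins`` bins
    immediately before REM onset are excluded (transition); the ``n_bins``
    bins before that gap must all be NREM. Gap content is unconstrained.
    Bouts failing any condition are dropped.
    """
    pairs = []
    for start, end in h.bouts("REM"):
        if end - start < n_bins:
            continue
        nrem_start = start - 2 * n_bins
        if nrem_start < 0:
            continue
        if not np.all(h.labels[nrem_start : nrem_start + n_bins] == "NREM"):
            continue
        pairs.append(EpochPair(nrem_start_bin=nrem_start, rem_start_bin=start, bin_s=h.bin_s, n_bins=n_bins))
    return pairs


@dataclass
class StagingAccuracy:
    confusion: pd.DataFrame  # rows = true state, columns = predicted
    overall: float
    per_state: dict[str, float]


def staging_accuracy(predicted: Hypnogram, truth: Hypnogram) -> StagingAccuracy:
    """Confusion matrix (rows = truth) and per-state/overall accuracy."""
    if predicted.n_bins != truth.n_bins or predicted.bin_s != truth.bin_s:
        raise IntegrityError("hypnograms differ in length or bin size")
    conf = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    for t, p in zip(truth.labels, predicted.labels):
        conf.loc[t, p] += 1
    overall = float(np.trace(conf.to_numpy())) / truth.n_bins
    per_state = {}
    for s in STATES:
        n_true = int(conf.loc[s].sum())
        if n_true:
            per_state[s] = float(conf.loc[s, s]) / n_true
    return StagingAccuracy(confusion=conf, overall=overall, per_state=per_state)


def rem_bout_recall(
    predicted: Hypnogram,
    truth: Hypnogram,
    min_bins: int = 10,
    min_fraction: float = 0.5,
) -> float:
    """Fraction of true REM bouts (>= min_bins) with >= min_fraction of their
    bins predicted REM. Returns NaN if there are no qualifying true bouts."""
    bouts = [b for b in truth.bouts("REM") if b[1] - b[0] >= min_bins]
    if not bouts:
        return float("nan")
    hits = sum(
        1
        for (a, b) in bouts
        if np.mean(predicted.labels[a:b] == "REM") >= min_fraction
    )
    return hits / len(bouts)
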