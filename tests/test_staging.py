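"""Sleep staging: bin features, classification rules, merges, epoch pairs."""

import numpy as np
import pytest

from sleepcouple.errors import ConfigurationError, IntegrityError
from sleepcouple.io import ChannelInfo, Hypnogram, Recording
from sleepcouple.staging import (
    BinFeatures,
    StagingThresholds,
    _merge_pass,
    classify_bins,
    compute_bin_features,
    rem_bout_recall,
    select_epoch_pairs,
    stage,
    staging_accuracy,
)


def _recording(eeg, emg, fs=2000.0):
    data = np.vstack([eeg, emg])
    channels = [
        ChannelInfo("sFC", region="sFC", kind="screw"),
        ChannelInfo("EMG", region="EMG", kind="emg"),
    ]
    return Recording(data, fs, channels)


def _features(n, emg=0.0, r_ag=1.0, r_td=1.0):
    """Hand-built BinFeatures with chosen ratios (delta=gamma=1)."""
    ones = np.ones(n)
    return BinFeatures(
        emg_max=np.full(n, emg, dtype=float),
        band_powers={
            "delta": ones.copy(),
            "theta": np.full(n, r_td, dtype=float),
            "alpha": np.full(n, r_ag, dtype=float),
            "gamma": ones.copy(),
        },
    )


class TestBinFeatures:
    def test_bin_count_floor(self):
        fs = 2000.0
        n = int(61 * fs)  # 61 s -> 30 complete 2-s bins
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal(n), rng.standard_normal(n), fs)
        f = compute_bin_features(rec)
        assert f.n_bins == 30

    def test_theta_sinusoid_dominates(self):
        fs = 2000.0
        t = np.arange(int(20 * fs)) / fs
        rec = _recording(50 * np.sin(2 * np.pi * 7.5 * t), np.zeros_like(t), fs)
        f = compute_bin_features(rec)
        assert np.all(f.band_powers["theta"] > 50 * f.band_powers["delta"])

    def test_zero_emg(self):
        fs = 2000.0
        n = int(10 * fs)
        rec = _recording(np.random.default_rng(0).standard_normal(n), np.zeros(n), fs)
        f = compute_bin_features(rec)
        assert np.all(f.emg_max == 0)

    def test_missing_channel(self):
        rec = Recording(
            np.zeros((1, 4000)), 2000.0, [ChannelInfo("sFC", region="sFC", kind="screw")]
        )
        with pytest.raises(ConfigurationError):
            compute_bin_features(rec)


class TestClassifyBins:
    def test_movement_rule_wins(self):
        """A bin with huge EMG is MOVE even when its theta/delta ratio
        satisfies the REM criterion."""
        f = _features(10, emg=1.0, r_td=1.0)
        f.emg_max[5] = 100.0  # ~3 x SD of emg_max
        f.band_powers["theta"][5] = 30.0  # r_td well above 2 x mean
        h = classify_bins(f)
        assert h.labels[5] == "MOVE"

    def test_rem_gap_merge(self):
        """A non-moving gap bin between REM bins whose theta/delta ratio is
        still above the mean is relabelled REM."""
        f = _features(9, r_td=1.0)
        f.band_powers["theta"][[3, 5]] = 30.0  # clear REM bins
        f.band_powers["theta"][4] = 1.5 * np.mean([1, 1, 1, 30, 1.5, 30, 1, 1, 1])
        h = classify_bins(f)
        assert h.labels[4] == "REM"
        assert h.labels[3] == h.labels[5] == "REM"

    def test_nrem_gap_merge_relaxed_threshold(self):
        f = _features(9, r_ag=1.0)
        f.band_powers["alpha"][[3, 5]] = 30.0  # clear NREM bins
        mean_ag = np.mean([1, 1, 1, 30, 0.6 * 4.0, 30, 1, 1, 1])
        f.band_powers["alpha"][4] = 0.6 * mean_ag  # above half the mean, below it
        h = classify_bins(f)
        assert h.labels[4] == "NREM"

    def test_degenerate_all_wi(self):
        """Identical features below thresholds give all-WI."""
        h = classify_bins(_features(8))
        assert set(h.labels) == {"WI"}

    def test_rem_precedence_over_nrem(self):
        f = _features(10)
        f.band_powers["theta"][2] = 50.0
        f.band_powers["alpha"][2] = 50.0  # satisfies both criteria
        h = classify_bins(f)
        assert h.labels[2] == "REM"

    def test_merge_pass_idempotent(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["NREM", "WI", "REM", "MOVE"], size=200).astype("U4")
        ratio = rng.uniform(0, 2, 200)
        while _merge_pass(labels, ratio, 1.0, "REM"):
            pass
        snapshot = labels.copy()
        assert not _merge_pass(labels, ratio, 1.0, "REM")
        assert np.array_equal(labels, snapshot)

    def test_gain_invariance(self, rec600, hyp600):
        """Doubling every signal leaves the hypnogram unchanged (thresholds
        are relative: EMG x SD, ratios of powers)."""
        doubled = Recording(
            rec600.data * 2.0, rec600.fs, list(rec600.channels), dict(rec600.meta)
        )
        h2 = stage(doubled)
        assert np.array_equal(h2.labels, hyp600.labels)


class TestEpochPairs:
    def _hyp(self, labels):
        return Hypnogram(np.array(labels, dtype="U4"))

    def test_standard_selection(self):
        labels = ["NREM"] * 20 + ["WI"] * 10 + ["REM"] * 12
        pairs = select_epoch_pairs(self._hyp(labels))
        assert len(pairs) == 1
        ep = pairs[0]
        assert ep.rem_start_bin == 30
        assert ep.nrem_start_bin == 10  # the 10 NREM bins before the excluded gap
        assert ep.nrem_interval_s == (20.0, 40.0)
        assert ep.rem_interval_s == (60.0, 80.0)

    def test_short_rem_bout_dropped(self):
        labels = ["NREM"] * 30 + ["REM"] * 8 + ["WI"] * 4
        assert select_epoch_pairs(self._hyp(labels)) == []

    def test_gap_content_unconstrained(self):
        """A MOVE bin inside the excluded pre-REM gap does not disqualify the
        pair; only the 10 bins before the gap must be NREM."""
        labels = ["NREM"] * 10 + ["NREM"] * 9 + ["MOVE"] + ["REM"] * 10
        pairs = select_epoch_pairs(self._hyp(labels))
        assert len(pairs) == 1
        assert pairs[0].nrem_start_bin == 0

    def test_non_nrem_before_gap_disqualifies(self):
        labels = ["WI"] * 10 + ["NREM"] * 5 + ["WI"] * 5 + ["REM"] * 10
        assert select_epoch_pairs(self._hyp(labels)) == []


class TestAccuracy:
    def test_identity(self):
        h = Hypnogram(np.array(["NREM"] * 5 + ["REM"] * 5))
        acc = staging_accuracy(h, h)
        assert acc.overall == 1.0
        assert acc.per_state == {"NREM": 1.0, "REM": 1.0}

    def test_all_wi_against_half_wi(self):
        truth = Hypnogram(np.array(["WI"] * 10 + ["NREM"] * 10))
        pred = Hypnogram(np.array(["WI"] * 20))
        acc = staging_accuracy(pred, truth)
        assert acc.overall == 0.5

    def test_random_labels_quarter_accuracy(self):
        """Uniform random labels over 4 states vs uniform truth: accuracy
        ~ 1/4 (multinomial expectation)."""
        rng = np.random.default_rng(0)
        states = ["MOVE", "WI", "NREM", "REM"]
        truth = Hypnogram(rng.choice(states, 4000).astype("U4"))
        pred = Hypnogram(rng.choice(states, 4000).astype("U4"))
        assert staging_accuracy(pred, truth).overall == pytest.approx(0.25, abs=0.03)

    def test_length_mismatch(self):
        with pytest.raises(IntegrityError):
            staging_accuracy(
                Hypnogram(np.array(["WI"] * 3)), Hypnogram(np.array(["WI"] * 4))
            )

    def test_rem_bout_recall(self):
        truth = Hypnogram(np.array(["NREM"] * 10 + ["REM"] * 12 + ["NREM"] * 10))
        hit = Hypnogram(np.array(["NREM"] * 10 + ["REM"] * 12 + ["NREM"] * 10))
        miss = Hypnogram(np.array(["NREM"] * 32))
        assert rem_bout_recall(hit, truth) == 1.0
        assert rem_bout_recall(miss, truth) == 0.0


def test_thresholds_validation():
    with pytest.raises(ConfigurationError):
        StagingThresholds(emg_k=-1.0)
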