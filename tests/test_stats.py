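"""Group statistics: t-tests, permutation tests, BH-FDR, spectra comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepcouple.errors import InputError, IntegrityError
from sleepcouple.spectral import Spectrum
from sleepcouple.stats import (
    bh_fdr,
    compare_spectra,
    permutation_test,
    two_sample_ttest,
)


def brute_force_bh(p, alpha=0.05):
    """Independent step-up oracle, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # q_i = min over j >= i of m * p_(j) / j
    q_sorted = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    passing = np.flatnonzero(sorted_p <= np.arange(1, m + 1) * alpha / m)
    reject = np.zeros(m, dtype=bool)
    if len(passing):
        reject[order[: passing[-1] + 1]] = True
    return q, reject


class TestTtest:
    def test_identical_groups(self):
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift(self):
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 1e-6

    def test_constant_equal_groups_convention(self):
        assert two_sample_ttest([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            two_sample_ttest([1.0], [1.0, 2.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            two_sample_ttest([1.0, np.nan], [1.0, 2.0])


class TestPermutation:
    def test_exhaustive_small_case(self):
        """a={1,2}, b={3,4}: 2 of the C(4,2)=6 assignments reach |mean diff|
        >= 2, so p = 2/6 (full-enumeration oracle)."""
        assert permutation_test([1.0, 2.0], [3.0, 4.0]) == pytest.approx(2 / 6)

    def test_constant_data(self):
        assert permutation_test([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_exhaustive_seed_independent(self):
        a, b = [1.0, 2.0, 5.0], [3.0, 4.0, 9.0]
        assert permutation_test(a, b, seed=1) == permutation_test(a, b, seed=999)

    def test_monte_carlo_reproducible(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 0.5
        p1 = permutation_test(a, b, n_perm=2000, seed=3)
        p2 = permutation_test(a, b, n_perm=2000, seed=3)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_preconditions(self):
        with pytest.raises(InputError):
            permutation_test([1.0], [2.0, 3.0])
        with pytest.raises(InputError):
            permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=10)


class TestBhFdr:
    def test_hand_worked_example(self):
        """Thresholds at alpha=0.05 for m=4 are 0.0125/0.025/0.0375/0.05:
        only the first two p-values survive the step-up."""
        q, reject = bh_fdr([0.01, 0.02, 0.04, 0.5], alpha=0.05)
        assert list(reject) == [True, True, False, False]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.0533333, 0.5], rtol=1e-5)

    def test_flat_family(self):
        q, reject = bh_fdr([0.5] * 6)
        assert not reject.any()
        np.testing.assert_allclose(q, 0.5)

    def test_single_p(self):
        q, reject = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)
        assert reject[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_brute_force(self, pvals, alpha):
        q, reject = bh_fdr(pvals, alpha=alpha)
        q_ref, reject_ref = brute_force_bh(pvals, alpha=alpha)
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        assert np.array_equal(reject, reject_ref)

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCompareSpectra:
    def _spectra(self, psds, mask=None):
        freqs = np.arange(1.0, 101.0, 0.5)
        return [Spectrum(freqs, psd, mask=mask) for psd in psds]

    def test_identical_groups_no_rejections(self, rng):
        base = rng.uniform(1, 2, 200)
        a = self._spectra([base] * 4)
        b = self._spectra([base] * 4)
        res = compare_spectra(a, b)
        assert not res.significant.any()

    def test_grid_mismatch(self, rng):
        a = self._spectra([rng.uniform(size=200)] * 2)
        b = [Spectrum(np.arange(1.0, 51.0, 0.5), rng.uniform(size=100))] * 2
        with pytest.raises(IntegrityError):
            compare_spectra(a, b)

    def test_masked_bins_excluded(self, rng):
        mask = np.ones(200, dtype=bool)
        mask[97:101] = False  # around 50 Hz
        a = self._spectra([rng.uniform(1, 2, 200) for _ in range(3)], mask=mask)
        b = self._spectra([rng.uniform(1, 2, 200) for _ in range(3)], mask=mask)
        res = compare_spectra(a, b)
        assert len(res) == mask.sum()
        assert not np.isin(res.freq_hz, [49.5, 50.0, 50.5]).any()

    def test_band_limited_elevation_detected(self, rng):
        """A 15-50 Hz power elevation in one group is recovered as a near-
        contiguous block of rejections there, while rejections among the null
        bins below 10 Hz stay at the FDR level (BH controls the false
        *discovery* rate, not family-wise error, so occasional single null
        rejections are expected)."""
        freqs = np.arange(1.0, 101.0, 0.5)
        bump = 1.0 + 0.8 * ((freqs >= 15) & (freqs <= 50))
        hits = 0
        low_fraction = []
        n_runs = 20
        for _ in range(n_runs):
            ga = self._spectra([np.exp(rng.normal(0, 0.1, len(freqs))) * bump for _ in range(8)])
            gb = self._spectra([np.exp(rng.normal(0, 0.1, len(freqs))) for _ in range(6)])
            res = compare_spectra(ga, gb)
            inband = res[(res.freq_hz >= 15) & (res.freq_hz <= 50)]
            low = res[res.freq_hz <= 10]
            hits += inband.significant.mean() > 0.9
            low_fraction.append(low.significant.mean())
        assert hits >= 0.9 * n_runs
        assert np.mean(low_fraction) <= 0.05

    def test_single_effect_bin_among_nulls(self, rng):
        """One huge-effect bin among 200 nulls is rejected; false rejections
        stay at the FDR level on average."""
        freqs = np.arange(1.0, 101.0, 0.5)
        false = 0
        detected = 0
        n_runs = 30
        for _ in range(n_runs):
            pa = rng.normal(10, 1, (5, len(freqs)))
            pb = rng.normal(10, 1, (5, len(freqs)))
            pa[:, 40] += 20.0
            res = compare_spectra(
                [Spectrum(freqs, r) for r in pa], [Spectrum(freqs, r) for r in pb]
            )
            detected += bool(res.significant.iloc[40])
            false += int(res.significant.sum()) - int(res.significant.iloc[40])
        assert detected == n_runs
        assert false / n_runs <= 0.05 * 200
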