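"""Group-comparison machinery: t-tests, permutation tests, BH-FDR.

Conventions: two-sided tests throughout; the classic pooled-variance
two-sample t-test by default (Welch via ``equal_var=False``); permutation
tests permute group labels, enumerate exhaustively when the number of
assignments fits the permutation budget, and otherwise use the add-one Monte
Carlo estimate p = (1 + #{|T*| >= |T|}) / (1 + n_perm); multiple comparisons
are corrected per family with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, IntegrityError
from .spectral import Spectrum


def two_sample_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test; (t, p). Degenerate zero-variance input
    with equal means returns (0, 1) by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("groups must contain finite values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sstats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def permutation_test(
    a,
    b,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic=None,
) -> float:
    """Two-sided label-permutation p-value for a difference statistic
    (default: difference of group means).

    Exhaustive over all C(n, n_a) assignments when that count is within
    ``n_perm`` (then deterministic and seed-independent); Monte Carlo with
    the add-one correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) + len(b) < 4:
        raise InputError("combined n must be >= 4")
    if n_perm < 1000:
        raise InputError("n_perm must be >= 1000")
    if statistic is None:
        statistic = lambda u, v: u.mean() - v.mean()
    pooled = np.concatenate([a, b])
    na = len(a)
    t_obs = abs(statistic(a, b))
    total = comb(len(pooled), na)
    if total <= n_perm:
        count = 0
        for idx in combinations(range(len(pooled)), na):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            t = abs(statistic(pooled[mask], pooled[~mask]))
            if t >= t_obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[:na], perm[na:])) >= t_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejection mask at ``alpha``)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def compare_spectra(
    group_a: list[Spectrum],
    group_b: list[Spectrum],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-frequency-bin group t-tests with BH-FDR over the panel's bins.

    Each group is a list of per-animal spectra on a common grid; masked
    (line-frequency) bins are excluded from the family. Returns a tidy frame
    ``freq_hz, t, p, q, significant`` for the unmasked bins.
    """
    grids = [s.freqs for s in group_a + group_b]
    for gfreqs in grids[1:]:
        if not np.array_equal(gfreqs, grids[0]):
            raise IntegrityError("spectra are on different frequency grids")
    mask = np.logical_and.reduce([s.mask for s in group_a + group_b])
    pa = np.array([s.psd for s in group_a])
    pb = np.array([s.psd for s in group_b])
    t, p = sstats.ttest_ind(pa[:, mask], pb[:, mask], axis=0, equal_var=equal_var)
    # constant identical bins: scipy returns nan; identical groups are a null
    nan = ~np.isfinite(p)
    p = np.where(nan, 1.0, p)
    t = np.where(nan, 0.0, t)
    q, reject = bh_fdr(p, alpha=alpha)
    return pd.DataFrame(
        {
            "freq_hz": grids[0][mask],
            "t": t,
            "p": p,
            "q": q,
            "significant": reject,
        }
    )
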