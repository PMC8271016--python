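"""Nonparametric statistics used by the experiment orchestration.

Thin, contract-enforcing wrappers: Mann–Whitney U with an exact
(permutation-enumerated) p-value for small pooled samples, the Friedman
rank test with tie correction, and pairwise Wilcoxon signed-rank
post-hoc comparisons with Holm step-down adjustment.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import ValidationError

EXACT_POOLED_N = 20


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact permutation p for pooled n ≤ 20 (full enumeration); normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if x.size + y.size <= EXACT_POOLED_N:
        from math import comb

        method = sps.PermutationMethod(n_resamples=comb(x.size + y.size, x.size) + 1, rng=0)
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def friedman_test(blocks) -> tuple[float, float]:
    """Friedman rank test over a (k treatments × m subjects) table.

    ``blocks`` is array-like of shape (k, m); each subject (column) is
    ranked across treatments.  Fully tied data return statistic 0,
    p = 1.
    """
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("blocks must be a 2-D (k, m) table")
    k, m = arr.shape
    if k < 2 or m < 2:
        raise ValidationError("need at least 2 treatments and 2 subjects")
    if np.all(arr == arr[0:1, :]):  # every subject fully tied across treatments
        return 0.0, 1.0
    if k >= 3:
        res = sps.friedmanchisquare(*arr)
        return float(res.statistic), float(res.pvalue)
    # k = 2: scipy requires three treatments; use the tie-corrected rank
    # formula directly (chi-square with k - 1 = 1 degree of freedom)
    ranks = sps.rankdata(arr, axis=0)
    row_sums = ranks.sum(axis=1)
    num = (k - 1) * float(np.sum((row_sums - m * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranks**2)) - m * k * (k + 1) ** 2 / 4.0
    if den == 0.0:
        return 0.0, 1.0
    chi2 = num / den
    return chi2, float(sps.chi2.sf(chi2, k - 1))


def posthoc_pairwise(blocks, method: str = "wilcoxon_holm"):
    """All pairwise post-hoc comparisons after a Friedman test.

    Wilcoxon signed-rank per treatment pair, Holm step-down adjustment.
    Returns a list of ((i, j), raw_p, adjusted_p) tuples.
    """
    if method != "wilcoxon_holm":
        raise ValidationError(f"unknown post-hoc method {method!r}")
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("need a (k >= 2, m) table")
    k = arr.shape[0]
    pairs, raw = [], []
    for i in range(k):
        for j in range(i + 1, k):
            d = arr[i] - arr[j]
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(arr[i], arr[j], zero_method="wilcox").pvalue)
            pairs.append((i, j))
            raw.append(p)
    adj = multipletests(raw, method="holm")[1] if raw else []
    return [(pair, float(p), float(a)) for pair, p, a in zip(pairs, raw, adj)]
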