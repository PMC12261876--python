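"""Independent brute-force oracles used by the tests.

Each oracle recomputes a statistic from first principles (full enumeration,
explicit counting, or the textbook ANOVA decomposition) so the package's
implementations can be checked against an independent path.
"""

import itertools

import numpy as np
from scipy import stats


def wilcoxon_enumeration_p(d, two_sided=True):
    """Two-sided signed-rank p by literally enumerating all 2^n sign flips."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((0, 1), repeat=n)
        ]
    )
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    if two_sided:
        return min(1.0, 2.0 * min(p_le, p_ge))
    return p_ge


def icc21_anova(x1, x2):
    """ICC(2,1) via an explicit two-way ANOVA decomposition (loops, no vectorization)."""
    data = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    n, k = data.shape
    grand = data.mean()
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (data[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (data[:, j].mean() - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            resid = data[i, j] - data[i].mean() - data[:, j].mean() + grand
            ss_err += resid**2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def overlap_counting(vv1, vv2, mask):
    """Spatial overlap % by explicit per-voxel counting."""
    n_vv = n_dd = n_v1 = n_v2 = n_d1 = n_d2 = 0
    for a, b, m in zip(np.ravel(vv1), np.ravel(vv2), np.ravel(mask)):
        if not m:
            continue
        if a and b:
            n_vv += 1
        if (not a) and (not b):
            n_dd += 1
        n_v1 += bool(a)
        n_v2 += bool(b)
        n_d1 += not a
        n_d2 += not b
    return 2.0 * (n_vv + n_dd) / (n_v1 + n_v2 + n_d1 + n_d2) * 100.0


def min_total_age_difference(ages_a, ages_b):
    """Exhaustive-search minimum total |age difference| over all matchings."""
    a = list(ages_a)
    b = list(ages_b)
    if len(a) > len(b):
        a, b = b, a
    best = np.inf
    for perm in itertools.permutations(range(len(b)), len(a)):
        total = sum(abs(a[i] - b[j]) for i, j in enumerate(perm))
        best = min(best, total)
    return best
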