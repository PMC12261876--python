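"""Agreement and consistency statistics for paired ventilation measurements.

Implements the statistical toolbox used to assess repeatability (measurement
1 vs 2), intercenter consistency (age-matched independent cohorts), and
field-strength differences (1.5 T vs 3 T in the same subjects):

* paired two-sided Wilcoxon signed-rank test (exact null for small n);
* Bland-Altman bias and 95% limits of agreement;
* per-subject coefficient of variation between the two values, summarized
  as the cohort median;
* ICC(2,1) — two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation — with the Viera-Garrett interpretation scale;
* paired Cohen's d (mean difference / sd of differences) with the
  Sawilowsky effect-size scale;
* voxel-wise spatial overlap of binary ventilated-volume maps;
* age matching of independent cohorts by optimal assignment;
* percent change of a Bland-Altman bias relative to the reference cohort.

No multiple-testing correction is applied by default (exploratory design);
``holm_adjust`` is available for callers who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

__all__ = [
    "PairedSample",
    "BlandAltmanResult",
    "MatchResult",
    "StatsError",
    "bland_altman",
    "pairwise_cov",
    "icc_absolute_agreement",
    "interpret_icc",
    "cohens_d_paired",
    "interpret_effect_size",
    "wilcoxon_signed_rank",
    "spatial_overlap",
    "age_match",
    "percent_change",
    "holm_adjust",
    "PARAMETER_LABELS",
]

# Scalar ventilation parameters of a report row, in table order.
PARAMETER_LABELS: dict[str, str] = {
    "mean_rvent": "Mean RVent (mL/mL)",
    "cov_rvent": "CoV RVent (%)",
    "mean_fvlcm": "Mean FVL-CM (-)",
    "vvp_rvent": "VVP RVent (%)",
    "vvp_fvlcm": "VVP FVL-CM (%)",
    "tidal_volume": "Tidal volume (mL)",
    "breathing_frequency": "Breathing frequency (breaths/min)",
}


class StatsError(ValueError):
    """Raised for degenerate statistical input."""


@dataclass(frozen=True)
class PairedSample:
    """Per-subject values of one parameter under two paired conditions.

    Condition A/B may be measurement 1/2, 1.5 T/3 T, or Center 1/Center 2
    (after age matching). Differences are always condition A − condition B.
    """

    ids: tuple[str, ...]
    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        if x1.ndim != 1 or x1.shape != x2.shape or len(self.ids) != x1.size:
            raise StatsError("paired sample requires equal-length ids, x1, x2")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n(self) -> int:
        return int(self.x1.size)

    @property
    def differences(self) -> np.ndarray:
        return self.x1 - self.x2

    def swapped(self) -> "PairedSample":
        return PairedSample(self.ids, self.x2.copy(), self.x1.copy())


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one-to-one age matching across two cohorts."""

    pairs: tuple[tuple[str, str, float], ...]  # (id_A, id_B, |delta age|)
    excluded: tuple[str, ...]
    median_age_difference: float


def bland_altman(p: PairedSample) -> BlandAltmanResult:
    """Bias = mean(x1 − x2); limits of agreement = bias ± 1.96 sample sd."""
    if p.n < 2:
        raise StatsError("Bland-Altman needs at least 2 pairs")
    d = p.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


def pairwise_cov(p: PairedSample) -> tuple[np.ndarray, float]:
    """Per-subject between-measurement CoV (%) and its cohort median.

    For two values the sample standard deviation is |x1 − x2|/√2, so
    CoV = 100·|x1 − x2| / (√2 · mean). Subjects with zero mean are excluded
    from the median and returned as NaN.
    """
    means = (p.x1 + p.x2) / 2.0
    sd = np.abs(p.x1 - p.x2) / np.sqrt(2.0)
    cov = np.full(p.n, np.nan)
    ok = means != 0
    cov[ok] = 100.0 * sd[ok] / means[ok]
    if not ok.any():
        raise StatsError("all per-subject means are zero; CoV undefined")
    return cov, float(np.median(cov[ok]))


def icc_absolute_agreement(p: PairedSample) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares with n subjects (rows) and k = 2
    conditions (columns):

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))
    """
    if p.n < 3:
        raise StatsError("ICC needs at least 3 subjects")
    data = np.column_stack([p.x1, p.x2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((data - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise StatsError("ICC undefined: no variance in the data")
    return float((msr - mse) / denom)


def interpret_icc(icc: float) -> str:
    """Viera-Garrett agreement label for an ICC value (must be <= 1)."""
    if icc > 1 + 1e-9:
        raise StatsError("ICC cannot exceed 1")
    icc = min(icc, 1.0)
    if icc <= 0:
        return "less than chance"
    if icc <= 0.20:
        return "slight"
    if icc <= 0.40:
        return "fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "substantial"
    return "almost perfect"


def cohens_d_paired(p: PairedSample) -> float:
    """Paired Cohen's d: mean(x1 − x2) / sample sd of the differences."""
    d = p.differences
    if d.size < 2:
        raise StatsError("Cohen's d needs at least 2 pairs")
    if np.all(d == 0):
        return 0.0
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise StatsError("Cohen's d undefined: constant nonzero differences")
    return float(d.mean()) / sd


# Sawilowsky thresholds, largest first; label applies to the largest
# threshold not exceeding |d|.
_SAWILOWSKY = (
    (2.0, "huge"),
    (1.2, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.01, "very small"),
)


def interpret_effect_size(d: float) -> str:
    """Sawilowsky effect-size label by magnitude; |d| < 0.01 is negligible."""
    mag = abs(d)
    for threshold, label in _SAWILOWSKY:
        if mag >= threshold:
            return label
    return "negligible"


def _exact_signed_rank_p(d: np.ndarray, two_sided: bool) -> float:
    """Exact signed-rank p by enumerating the 2^n sign-flip null.

    The null distribution of W+ (sum of ranks of positive differences) is
    built by subset-sum convolution over the (possibly tied, midrank)
    ranks — equivalent to full 2^n enumeration but polynomial time. Ranks
    are doubled so midranks become integers.
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.round(2.0 * ranks).astype(int)
    w_obs = int(round(float(2.0 * ranks[d > 0].sum())))
    pmf = np.array([1.0])
    for r in r2:
        nxt = np.zeros(pmf.size + r)
        nxt[: pmf.size] += pmf
        nxt[r:] += pmf
        pmf = nxt
    pmf /= pmf.sum()
    cdf = float(pmf[: w_obs + 1].sum())
    sf = float(pmf[w_obs:].sum())
    if two_sided:
        return min(1.0, 2.0 * min(cdf, sf))
    return sf


def wilcoxon_signed_rank(p: PairedSample, two_sided: bool = True) -> float:
    """Paired Wilcoxon signed-rank p-value (two-sided by default).

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment); if all differences are zero the p-value is 1. The exact
    sign-flip null distribution is used for n <= 25 (midranks for ties);
    above that, the normal approximation with continuity correction.
    """
    d = p.differences
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size <= 25:
        return _exact_signed_rank_p(d, two_sided)
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True,
        alternative="two-sided" if two_sided else "greater", method="approx",
    )
    return float(res.pvalue)


def spatial_overlap(vv1: np.ndarray, vv2: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of in-mask voxels with matching ventilated/defect labels.

    Overlap = 2(n_vv + n_dd) / (n_v1 + n_v2 + n_d1 + n_d2) x 100, where
    n_vv / n_dd count voxels labeled ventilated / defect in both maps and
    n_vi / n_di the per-map label counts.
    """
    mask = np.asarray(mask, dtype=bool)
    if vv1.shape != vv2.shape or vv1.shape != mask.shape:
        raise StatsError("maps and mask must share the grid")
    if not mask.any():
        raise StatsError("empty mask")
    a = np.asarray(vv1, dtype=bool)[mask]
    b = np.asarray(vv2, dtype=bool)[mask]
    n_vv = int(np.sum(a & b))
    n_dd = int(np.sum(~a & ~b))
    denom = int(a.sum()) + int(b.sum()) + int((~a).sum()) + int((~b).sum())
    return 2.0 * (n_vv + n_dd) / denom * 100.0


def age_match(
    ages_a: dict[str, float], ages_b: dict[str, float]
) -> MatchResult:
    """One-to-one matching minimizing total |age difference|.

    Solved as an optimal assignment; the min(n_A, n_B) matched pairs are
    returned with the unmatched subjects of the larger cohort listed as
    excluded.
    """
    if not ages_a or not ages_b:
        raise StatsError("both cohorts must be nonempty")
    ids_a, ids_b = list(ages_a), list(ages_b)
    cost = np.abs(
        np.subtract.outer(
            np.array([ages_a[i] for i in ids_a], dtype=float),
            np.array([ages_b[i] for i in ids_b], dtype=float),
        )
    )
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (ids_a[r], ids_b[c], float(cost[r, c])) for r, c in zip(rows, cols)
    )
    used = {p[0] for p in pairs} | {p[1] for p in pairs}
    excluded = tuple(i for i in ids_a + ids_b if i not in used)
    median_d = float(np.median([p[2] for p in pairs]))
    return MatchResult(pairs=pairs, excluded=excluded, median_age_difference=median_d)


def percent_change(bias: float, reference_level: float) -> float:
    """Bland-Altman bias as percent change relative to the reference mean.

    With bias = reference − comparison, the percent change of the comparison
    condition relative to the reference is 100 x (comparison − reference) /
    reference = −100 x bias / reference; positive values mean the comparison
    condition reads higher.
    """
    if reference_level == 0:
        raise StatsError("percent change undefined for zero reference level")
    return -100.0 * bias / reference_level


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
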