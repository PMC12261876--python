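"""Tests of the agreement/consistency statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    icc21_anova,
    min_total_age_difference,
    overlap_counting,
    wilcoxon_enumeration_p,
)
from preful3d import repstats
from preful3d.repstats import (
    PairedSample,
    StatsError,
    age_match,
    bland_altman,
    cohens_d_paired,
    icc_absolute_agreement,
    interpret_effect_size,
    interpret_icc,
    pairwise_cov,
    percent_change,
    spatial_overlap,
    wilcoxon_signed_rank,
)


def _sample(x1, x2):
    x1 = np.asarray(x1, float)
    return PairedSample(tuple(f"s{i}" for i in range(x1.size)), x1, np.asarray(x2, float))


class TestBlandAltman:
    def test_identical_conditions(self):
        r = bland_altman(_sample([1, 2, 3], [1, 2, 3]))
        assert r.bias == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_constant_difference(self):
        r = bland_altman(_sample([2, 3, 4], [1, 2, 3]))
        assert (r.bias, r.loa_low, r.loa_high) == (1.0, 1.0, 1.0)

    def test_arithmetic_example(self):
        r = bland_altman(_sample([0, 2, 4], [0, 0, 0]))
        assert r.bias == pytest.approx(2.0)
        assert r.sd_diff == pytest.approx(2.0)
        assert r.loa_low == pytest.approx(-1.92)
        assert r.loa_high == pytest.approx(5.92)

    def test_antisymmetry_under_condition_swap(self, rng):
        p = _sample(rng.normal(5, 1, 12), rng.normal(5, 1, 12))
        a, b = bland_altman(p), bland_altman(p.swapped())
        assert b.bias == pytest.approx(-a.bias)
        assert b.loa_low == pytest.approx(-a.loa_high)
        assert b.loa_high == pytest.approx(-a.loa_low)


class TestPairwiseCov:
    def test_examples(self):
        cov, med = pairwise_cov(_sample([10, 9], [10, 11]))
        assert cov[0] == 0.0
        assert cov[1] == pytest.approx(100 * np.sqrt(2) / 10)
        cov, med = pairwise_cov(_sample([7, 7, 7], [7, 7, 7]))
        assert med == 0.0

    def test_zero_mean_subject_excluded(self):
        cov, med = pairwise_cov(_sample([1, -1], [1, 1]))
        assert np.isnan(cov[1])
        assert med == 0.0


class TestICC:
    def test_perfect_agreement(self):
        assert icc_absolute_agreement(_sample([1, 2, 3, 4], [1, 2, 3, 4])) == pytest.approx(1.0)

    def test_matches_anova_oracle_on_fuzz(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x1 = rng.normal(0, rng.uniform(0.5, 3), n)
            x2 = x1 * rng.uniform(0.2, 1.5) + rng.normal(0, 1, n) + rng.uniform(-1, 1)
            p = _sample(x1, x2)
            assert icc_absolute_agreement(p) == pytest.approx(
                icc21_anova(x1, x2), abs=1e-10
            )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 15
            x1 = r.normal(10, 3, n)
            x2 = x1 + r.normal(0, 1, n)
            df = pd.DataFrame(
                {
                    "subject": np.tile(np.arange(n), 2),
                    "rater": np.repeat(["a", "b"], n),
                    "y": np.concatenate([x1, x2]),
                }
            )
            # ICC(A,1): two-way, absolute agreement, single measurement
            icc2 = pingouin.intraclass_corr(
                df, targets="subject", raters="rater", ratings="y"
            ).set_index("Type").loc["ICC(A,1)", "ICC"]
            assert icc_absolute_agreement(_sample(x1, x2)) == pytest.approx(
                float(icc2), abs=1e-8
            )

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(42)
        p = _sample(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))
        assert icc_absolute_agreement(p) == pytest.approx(0.0, abs=0.05)

    def test_known_reliability_recovered(self):
        rng = np.random.default_rng(7)
        n = 10_000
        subject = rng.normal(0, 3.0, n)  # variance 9
        x1 = subject + rng.normal(0, 1.0, n)
        x2 = subject + rng.normal(0, 1.0, n)
        assert icc_absolute_agreement(_sample(x1, x2)) == pytest.approx(0.9, abs=0.02)

    def test_degenerate_data_rejected(self):
        with pytest.raises(StatsError):
            icc_absolute_agreement(_sample([1, 1, 1], [1, 1, 1]))


class TestInterpretations:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (-0.2, "less than chance"), (0.1, "slight"), (0.35, "fair"),
            (0.5, "moderate"), (0.70, "substantial"), (0.95, "almost perfect"),
            (0.40, "fair"), (0.60, "moderate"), (0.80, "substantial"), (1.0, "almost perfect"),
        ],
    )
    def test_viera_garrett_bands(self, icc, label):
        assert interpret_icc(icc) == label

    @pytest.mark.parametrize(
        "d,label",
        [
            (0.5, "medium"), (-1.3, "very large"), (0.1, "very small"),
            (0.005, "negligible"), (0.25, "small"), (0.9, "large"),
            (2.5, "huge"), (-0.8, "large"),
        ],
    )
    def test_sawilowsky_labels(self, d, label):
        assert interpret_effect_size(d) == label


class TestCohensD:
    def test_no_difference(self):
        assert cohens_d_paired(_sample([1, 2, 3], [1, 2, 3])) == 0.0

    def test_sign_flips_on_swap(self, rng):
        p = _sample(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        assert cohens_d_paired(p.swapped()) == pytest.approx(-cohens_d_paired(p))

    def test_known_standardized_shift_recovered(self):
        rng = np.random.default_rng(11)
        n = 10_000
        x2 = rng.normal(0, 1, n)
        x1 = x2 + rng.normal(0.5, 1.0, n)
        assert cohens_d_paired(_sample(x1, x2)) == pytest.approx(0.5, abs=0.05)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(StatsError):
            cohens_d_paired(_sample([2, 3, 4], [1, 2, 3]))


class TestWilcoxon:
    def test_enumeration_examples(self):
        assert wilcoxon_signed_rank(_sample([1, 2, 3], [0, 0, 0])) == pytest.approx(0.25)
        assert wilcoxon_signed_rank(_sample([-1, 1], [0, 0])) == pytest.approx(1.0)
        assert wilcoxon_signed_rank(_sample([5, 5, 5], [5, 5, 5])) == 1.0

    def test_matches_full_enumeration_all_small_n(self, rng):
        for n in range(1, 9):
            for _ in range(25):
                d = rng.normal(0.3, 1.0, n)
                if rng.random() < 0.3:  # inject ties and zeros sometimes
                    d = np.round(d, 0)
                p = wilcoxon_signed_rank(_sample(d, np.zeros(n)))
                assert p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.5, 1.0, 60)
        p = wilcoxon_signed_rank(_sample(d, np.zeros(60)))
        from scipy import stats

        expected = float(
            stats.wilcoxon(d, correction=True, method="approx").pvalue
        )
        assert p == pytest.approx(expected)


class TestSpatialOverlap:
    def test_identical_and_complement(self, rng):
        vv = rng.random((6, 6, 6)) > 0.5
        mask = np.ones_like(vv)
        assert spatial_overlap(vv, vv, mask) == 100.0
        assert spatial_overlap(vv, ~vv, mask) == 0.0

    def test_printed_formula_small_case(self):
        vv1 = np.array([1, 1, 0, 0], bool).reshape(4, 1, 1)
        vv2 = np.array([1, 0, 0, 0], bool).reshape(4, 1, 1)
        mask = np.ones_like(vv1)
        assert spatial_overlap(vv1, vv2, mask) == pytest.approx(75.0)

    def test_matches_counting_oracle_on_fuzz(self, rng):
        for _ in range(30):
            shape = (5, 4, 3)
            vv1 = rng.random(shape) > rng.random()
            vv2 = rng.random(shape) > rng.random()
            mask = rng.random(shape) > 0.3
            if not mask.any():
                continue
            assert spatial_overlap(vv1, vv2, mask) == pytest.approx(
                overlap_counting(vv1, vv2, mask)
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        vv1 = r.random((4, 4, 4)) > 0.5
        vv2 = r.random((4, 4, 4)) > 0.5
        mask = np.ones((4, 4, 4), bool)
        o = spatial_overlap(vv1, vv2, mask)
        assert 0.0 <= o <= 100.0
        assert o == spatial_overlap(vv2, vv1, mask)


class TestAgeMatch:
    def test_small_example(self):
        m = age_match({"a": 25}, {"b": 24, "c": 60})
        assert m.pairs == (("a", "b", 1.0),)
        assert m.excluded == ("c",)
        assert m.median_age_difference == 1.0

    def test_identical_lists_fully_matched(self):
        ages = {f"s{i}": 20 + i for i in range(5)}
        other = {f"t{i}": 20 + i for i in range(5)}
        m = age_match(ages, other)
        assert len(m.pairs) == 5
        assert m.excluded == ()
        assert m.median_age_difference == 0.0

    def test_cohort_sizes_mirror_study(self, rng):
        a = {f"a{i}": float(v) for i, v in enumerate(rng.integers(19, 45, 24))}
        b = {f"b{i}": float(v) for i, v in enumerate(rng.integers(19, 65, 26))}
        m = age_match(a, b)
        assert len(m.pairs) == 24
        assert len(m.excluded) == 2

    def test_optimality_vs_exhaustive_search(self, rng):
        for _ in range(10):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 8))
            a = {f"a{i}": float(v) for i, v in enumerate(rng.uniform(18, 70, na))}
            b = {f"b{i}": float(v) for i, v in enumerate(rng.uniform(18, 70, nb))}
            m = age_match(a, b)
            total = sum(d for _, _, d in m.pairs)
            assert total == pytest.approx(
                min_total_age_difference(list(a.values()), list(b.values()))
            )


class TestPercentChange:
    @pytest.mark.parametrize(
        "bias,ref,expected",
        [(-18.0, 100.0, 18.0), (0.0, 5.0, 0.0), (1.0, 2.0, -50.0)],
    )
    def test_examples(self, bias, ref, expected):
        assert percent_change(bias, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(StatsError):
            percent_change(1.0, 0.0)


class TestHolm:
    def test_adjusted_values_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = repstats.holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.04)
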