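from itertools import product

import numpy as np
import pytest
from scipy import stats

from eegagree.agreement import (
    PairedMeasures, anova_sums_of_squares, bland_altman, cohens_d_paired,
    effect_size_label, paired_tests, partial_eta_sq, rm_anova_2x2,
    wilcoxon_signed_rank,
)


def _pm(wet, dry, name="m"):
    return PairedMeasures(subject_id=list(range(len(wet))),
                          value_wet=np.asarray(wet, float),
                          value_dry=np.asarray(dry, float),
                          measure_name=name)


class TestBlandAltman:
    def test_three_point_worked_example(self):
        # diffs (wet - dry): -1, 0, -2 -> bias -1, sd 1
        r = bland_altman(_pm([1, 2, 3], [2, 2, 5]))
        t975 = stats.t.ppf(0.975, 2)
        assert r.bias == pytest.approx(-1.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(-1 - 1.96)
        assert r.loa_high == pytest.approx(-1 + 1.96)
        assert r.bias_ci == pytest.approx((-1 - t975 / np.sqrt(3),
                                           -1 + t975 / np.sqrt(3)))
        half = t975 * 1.0 * np.sqrt(3 / 3)
        assert r.loa_low_ci == pytest.approx((-2.96 - half, -2.96 + half))

    def test_perfect_agreement(self):
        r = bland_altman(_pm([1, 2, 3], [1, 2, 3]))
        assert r.bias == 0.0
        assert r.loa_low == r.loa_high == 0.0
        assert not r.bias_significant

    def test_constant_offset(self):
        r = bland_altman(_pm([2, 3, 4], [1, 2, 3]))
        assert r.bias == pytest.approx(1.0)
        assert r.sd_diff == 0.0
        assert r.bias_significant  # zero-width CI excludes 0

    def test_shift_equivariance(self, rng):
        wet = rng.normal(size=10)
        dry = rng.normal(size=10)
        base = bland_altman(_pm(wet, dry))
        shifted_both = bland_altman(_pm(wet + 5, dry + 5))
        assert shifted_both.bias == pytest.approx(base.bias)
        shifted_wet = bland_altman(_pm(wet + 2, dry))
        assert shifted_wet.bias == pytest.approx(base.bias + 2)

    def test_sign_convention(self, rng):
        wet = rng.normal(size=8)
        dry = wet - 3.0  # dry underestimates
        r = bland_altman(_pm(wet, dry))
        assert r.bias == pytest.approx(3.0)
        assert r.sign_convention == "wet - dry"
        r2 = bland_altman(_pm(wet, dry), reference_first=False)
        assert r2.bias == pytest.approx(-3.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(_pm([1, 2], [1, 2]))

    def test_incomplete_pairs_dropped(self):
        pm = _pm([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert pm.n == 3
        assert pm.n_dropped == 1


def brute_force_rm_anova(y):
    """Sums of squares by explicit cell-mean loops (independent oracle)."""
    n = y.shape[0]
    grand = y.mean()
    out = {}
    for eff, axes in [("a", (0, 2)), ("b", (0, 1))]:
        means = y.mean(axis=axes)
        out[f"ss_{eff}"] = 2 * n * sum((m - grand) ** 2 for m in means)
    cell = y.mean(axis=0)
    am, bm = y.mean(axis=(0, 2)), y.mean(axis=(0, 1))
    out["ss_ab"] = n * sum(
        (cell[i, j] - am[i] - bm[j] + grand) ** 2
        for i, j in product(range(2), range(2)))
    subj = y.mean(axis=(1, 2))
    ia, ib = y.mean(axis=2), y.mean(axis=1)
    out["ss_a_err"] = 2 * sum(
        (ia[s, i] - subj[s] - am[i] + grand) ** 2
        for s, i in product(range(n), range(2)))
    out["ss_b_err"] = 2 * sum(
        (ib[s, j] - subj[s] - bm[j] + grand) ** 2
        for s, j in product(range(n), range(2)))
    out["ss_ab_err"] = sum(
        (y[s, i, j] - ia[s, i] - ib[s, j] - cell[i, j]
         + subj[s] + am[i] + bm[j] - grand) ** 2
        for s, i, j in product(range(n), range(2), range(2)))
    return out


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        y = np.ones((5, 2, 2)) * 3.3
        for t in rm_anova_2x2(y):
            assert t.statistic == 0.0
            assert t.p == 1.0

    def test_matches_brute_force_oracle(self, rng):
        y = rng.normal(size=(4, 2, 2))
        ref = brute_force_rm_anova(y)
        res = rm_anova_2x2(y)
        n = 4
        for t, (ss_e, ss_err) in zip(res, [("ss_a", "ss_a_err"),
                                           ("ss_b", "ss_b_err"),
                                           ("ss_ab", "ss_ab_err")]):
            f_ref = (ref[ss_e] / 1.0) / (ref[ss_err] / (n - 1))
            assert t.statistic == pytest.approx(f_ref, rel=1e-10)
            assert t.df == n - 1
            eta_ref = ref[ss_e] / (ref[ss_e] + ref[ss_err])
            assert t.effect_size[1] == pytest.approx(eta_ref, rel=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.normal(size=(6, 2, 2))
        rows = [
            dict(subject=s, a=f"a{i}", b=f"b{j}", y=y[s, i, j])
            for s, i, j in product(range(6), range(2), range(2))
        ]
        df = pd.DataFrame(rows)
        ref = pingouin.rm_anova(data=df, dv="y", within=["a", "b"],
                                subject="subject", detailed=True)
        res = rm_anova_2x2(y, factor_names=("a", "b"))
        for t, name in zip(res, ["a", "b", "a * b"]):
            row = ref[ref.Source == name].iloc[0]
            assert t.statistic == pytest.approx(row.F, rel=1e-6)
            assert t.p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_sum_of_squares_decomposition_is_exact(self, rng):
        y = rng.normal(size=(7, 2, 2))
        ss = anova_sums_of_squares(y)
        parts = (ss["subjects"] + ss["a"] + ss["b"] + ss["ab"]
                 + ss["a_err"] + ss["b_err"] + ss["ab_err"])
        assert parts == pytest.approx(ss["total"], rel=1e-10)

    def test_incomplete_cells_rejected(self):
        y = np.ones((4, 2, 2))
        y[0, 1, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(y)


class TestPairedTests:
    def test_identical_pairs(self):
        with pytest.raises(ZeroDivisionError):
            paired_tests(_pm([1, 2, 3], [1, 2, 3]))

    def test_worked_example(self):
        # diffs -1, -2, -3: mean -2, sd 1, t = -2 / (1/sqrt(3)) = -2*sqrt(3)
        t = paired_tests(_pm([0, 0, 0], [1, 2, 3]))
        assert t.statistic == pytest.approx(-2 * np.sqrt(3))
        assert t.df == 2
        ref = stats.ttest_rel([0, 0, 0], [1, 2, 3])
        assert t.p == pytest.approx(ref.pvalue)

    def test_bonferroni_doubles_and_caps(self, rng):
        wet = rng.normal(size=6)
        dry = rng.normal(size=6)
        p1 = paired_tests(_pm(wet, dry), bonferroni_m=1).p
        p2 = paired_tests(_pm(wet, dry), bonferroni_m=2).p
        assert p2 == pytest.approx(min(1.0, 2 * p1))

    def test_one_sided_direction(self):
        pm = _pm([0, 0, 0, 0], [1, 2, 3, 2])  # wet < dry
        less = paired_tests(pm, sided="one", direction="less")
        greater = paired_tests(pm, sided="one", direction="greater")
        assert less.p < 0.05 < greater.p


def exact_wilcoxon_p(diffs, alternative="two-sided"):
    """Sign-enumeration oracle for the signed-rank test (no zeros)."""
    diffs = np.asarray(diffs, float)
    n = diffs.size
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    if alternative == "greater":
        return (ws >= w_obs).mean()
    if alternative == "less":
        return (ws <= w_obs).mean()
    return min(1.0, 2 * min((ws >= w_obs).mean(), (ws <= w_obs).mean()))


class TestWilcoxon:
    def test_all_positive_n6_one_sided(self):
        pm = _pm([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        t = wilcoxon_signed_rank(pm, sided="one", direction="greater")
        assert t.p == pytest.approx(1 / 64)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 11))
            diffs = rng.normal(size=n)
            diffs[diffs == 0] = 0.5
            pm = _pm(diffs, np.zeros(n))
            for sided, alt in [("two", "two-sided"), ("one", "greater")]:
                t = wilcoxon_signed_rank(pm, sided=sided, direction="greater")
                ref = exact_wilcoxon_p(diffs, alt)
                if sided == "two":
                    # scipy's two-sided doubling convention matches ours
                    ref = stats.wilcoxon(diffs, method="exact").pvalue
                assert t.p == pytest.approx(ref)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(_pm([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))

    def test_agrees_in_direction_with_t_test(self, rng):
        wet = np.arange(8.0)
        dry = wet - np.linspace(0.5, 1.5, 8)
        t = paired_tests(_pm(wet, dry))
        w = wilcoxon_signed_rank(_pm(wet, dry), sided="one",
                                 direction="greater")
        assert t.statistic > 0
        assert w.p < 0.05


class TestEffectSizes:
    def test_cohens_d_definitions(self):
        assert cohens_d_paired(np.array([0.0, 1.0, -1.0])) == 0.0
        d = np.array([1.0, 3.0])  # mean 2, sd sqrt(2)
        assert cohens_d_paired(d) == pytest.approx(2 / np.sqrt(2))
        with pytest.raises(ZeroDivisionError):
            cohens_d_paired(np.array([1.0, 1.0]))

    def test_labels(self):
        assert effect_size_label(-0.55) == "moderate"
        assert effect_size_label(-0.83) == "large"
        assert effect_size_label(-0.03) == "negligible"
        assert effect_size_label(0.3) == "small"

    def test_partial_eta_sq(self):
        assert partial_eta_sq(3.0, 1.0) == pytest.approx(0.75)
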