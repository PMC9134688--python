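"""Statistical tests against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from myelinquant import (
    bky_fdr,
    fisher_exact_2x2,
    pearson_correlation,
    regional_means,
    student_t,
    two_way_anova_tukey,
    welch_t,
)
from myelinquant.dti import ScalarMapSet
from myelinquant.stats import _bh_rejections


def fisher_bruteforce(table):
    """Independent oracle: enumerate all tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestRegionalMeans:
    @staticmethod
    def _maps(fa):
        shape = fa.shape
        ones = np.ones(shape)
        return ScalarMapSet(FA=fa, MD=ones, AD=ones, RD=ones,
                            mask=np.ones(shape, dtype=bool))

    def test_uniform_region(self):
        fa = np.full((4, 4, 2), 0.5)
        labels = np.ones((4, 4, 2), dtype=int)
        table = regional_means(self._maps(fa), labels, {1: "ic"})
        assert table[table.metric == "FA"].value.iloc[0] == pytest.approx(0.5)

    def test_bilateral_pooling(self):
        # one label split across hemispheres with equal voxel counts
        fa = np.zeros((4, 2, 1))
        fa[:2] = 0.4
        fa[2:] = 0.6
        labels = np.ones((4, 2, 1), dtype=int)
        table = regional_means(self._maps(fa), labels, {1: "cc"})
        assert table[table.metric == "FA"].value.iloc[0] == pytest.approx(0.5)

    def test_missing_label_raises(self):
        fa = np.zeros((2, 2, 1))
        with pytest.raises(ValueError, match="opt"):
            regional_means(self._maps(fa), np.zeros((2, 2, 1), dtype=int), {3: "opt"})


class TestTTests:
    def test_identical_groups(self):
        res = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_student_equals_welch_for_balanced_equal_variance(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        assert student_t(a, b).t == pytest.approx(welch_t(a, b).t)

    def test_welch_satterthwaite_df(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([10.0, 30.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df_expected = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert welch_t(a, b).df == pytest.approx(df_expected)

    def test_degenerate_equal_constant_groups(self):
        res = student_t([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p == 1.0

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 10_000
        for _ in range(reps):
            if student_t(rng.normal(size=6), rng.normal(size=6)).p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.01)

    def test_label_order_symmetry(self):
        a = [1.0, 2.0, 5.0]
        b = [2.0, 4.0, 9.0]
        assert welch_t(a, b).p == pytest.approx(welch_t(b, a).p)
        assert welch_t(a, b).t == pytest.approx(-welch_t(b, a).t)


class TestBkyFdr:
    def test_all_ones_no_discoveries(self):
        qvals, flags = bky_fdr(np.ones(10), q=0.1)
        assert not flags.any()

    def test_single_strong_signal(self):
        p = np.array([1e-6, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9])
        _, flags = bky_fdr(p, q=0.1)
        assert flags[0] and flags[1:].sum() == 0

    def test_matches_reference_implementation(self):
        # statsmodels' two-stage BKY step-up as the independent cross-check
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=12)
            p[: rng.integers(0, 4)] *= 1e-4
            _, ours = bky_fdr(p, q=0.1)
            theirs = multipletests(p, alpha=0.1, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(ours, theirs)

    def test_qvalue_is_smallest_rejecting_level(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.5])
        qvals, flags = bky_fdr(p, q=0.1)
        from myelinquant.stats import _tsbky_rejections

        for i, qv in enumerate(qvals):
            if qv < 1.0:
                assert _tsbky_rejections(p, min(qv * 1.01, 1 - 1e-9))[i]
                if qv > 1e-6:
                    assert not _tsbky_rejections(p, qv * 0.99)[i]

    def test_never_less_powerful_than_plain_bh(self):
        rng = np.random.default_rng(9)
        q = 0.1
        for _ in range(100):
            p = rng.uniform(size=10) ** rng.uniform(0.5, 3)
            _, two_stage = bky_fdr(p, q=q)
            bh = _bh_rejections(np.asarray(p), q / (1 + q))
            assert two_stage.sum() >= bh.sum()

    def test_fdr_controlled_under_global_null(self):
        rng = np.random.default_rng(2024)
        fdp = []
        for _ in range(2000):
            p = rng.uniform(size=10)
            _, flags = bky_fdr(p, q=0.1)
            fdp.append(flags.any())  # all discoveries are false under the null
        assert np.mean(fdp) <= 0.12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bky_fdr([], q=0.1)


class TestFisherExact:
    def test_eruption_table(self):
        # 9/11 treated vs 1/11 vehicle pups with erupted teeth
        assert fisher_exact_2x2([[9, 2], [1, 10]]) == pytest.approx(0.0019, abs=5e-5)

    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            table = rng.integers(0, 15, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_bruteforce(table), abs=1e-10
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestTwoWayAnova:
    @staticmethod
    def _balanced(seed=0, trt_effect=0.0, age_effect=1.0, noise=1.0):
        rng = np.random.default_rng(seed)
        rows = []
        for trt in ("T4", "vehicle"):
            for age in (3, 5, 7):
                for _ in range(4):
                    y = (
                        age_effect * age
                        + (trt_effect if trt == "T4" else 0.0)
                        + noise * rng.normal()
                    )
                    rows.append({"value": y, "group": trt, "pnd": age})
        return pd.DataFrame(rows)

    def test_no_treatment_effect_deterministic_zero_f(self):
        # identical within-cell patterns in both groups: SS_treatment is
        # exactly 0 while age signal and residual spread are nonzero
        rows = []
        for trt in ("T4", "vehicle"):
            for age in (3, 5, 7):
                for delta in (-1.0, -0.5, 0.5, 1.0):
                    rows.append({"value": 10.0 * age + delta, "group": trt, "pnd": age})
        res = two_way_anova_tukey(pd.DataFrame(rows))
        assert res.effects["treatment"][0] == pytest.approx(0.0, abs=1e-20)
        assert res.effects["age"][0] > 1e3

    def test_matches_balanced_closed_form(self):
        # independent oracle: balanced two-way sums of squares from cell means
        data = self._balanced(seed=5, trt_effect=2.0)
        y = data.value.to_numpy()
        cells = data.groupby(["group", "pnd"]).value.mean().unstack()
        n_rep = 4
        grand = y.mean()
        row_means = cells.mean(axis=1)
        col_means = cells.mean(axis=0)
        ss_a = n_rep * cells.shape[1] * ((row_means - grand) ** 2).sum()
        ss_b = n_rep * cells.shape[0] * ((col_means - grand) ** 2).sum()
        interaction = (
            cells.values
            - row_means.values[:, None]
            - col_means.values[None, :]
            + grand
        )
        ss_ab = n_rep * (interaction**2).sum()
        fitted = data.groupby(["group", "pnd"]).value.transform("mean")
        ss_e = ((y - fitted) ** 2).sum()
        df_a, df_b = 1, 2
        df_ab = 2
        df_e = len(y) - 6
        res = two_way_anova_tukey(data)
        assert res.effects["treatment"][0] == pytest.approx(
            (ss_a / df_a) / (ss_e / df_e), rel=1e-8
        )
        assert res.effects["age"][0] == pytest.approx((ss_b / df_b) / (ss_e / df_e), rel=1e-8)
        assert res.effects["interaction"][0] == pytest.approx(
            (ss_ab / df_ab) / (ss_e / df_e), rel=1e-8
        )
        assert res.effects["treatment"][1:3] == (df_a, df_e)

    def test_tukey_identical_cells_near_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=4)
        rows = []
        for trt in ("a", "b"):
            for age in (1, 2):
                for v in base:
                    rows.append({"value": v, "group": trt, "pnd": age})
        res = two_way_anova_tukey(pd.DataFrame(rows))
        assert (res.tukey["p-adj"].astype(float) > 0.95).all()

    def test_within_age_comparisons_flagged(self):
        res = two_way_anova_tukey(self._balanced())
        flagged = res.tukey[res.tukey.within_age]
        assert len(flagged) == 3  # one treatment contrast per age

    def test_empty_cell_rejected(self):
        data = self._balanced()
        data = data[~((data.group == "T4") & (data.pnd == 3))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova_tukey(data)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_sampling_distribution(self):
        rng = np.random.default_rng(0)
        rho = 0.6
        rs = []
        for _ in range(2000):
            x = rng.normal(size=12)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=12)
            rs.append(pearson_correlation(x, y).r)
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation(np.ones(5), np.arange(5.0))
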