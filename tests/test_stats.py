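"""Tests of the ANOVA/Tukey, ANCOVA slope-equality and t-test battery."""

import numpy as np
import pandas as pd
import pytest

from retinad import stats
from retinad.exceptions import InvalidParameterError

from conftest import hand_anova, hand_ttest, hand_tukey_p


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        g = {3: [1.0, 2.0, 3.0], 6: [1.0, 2.0, 3.0], 9: [1.0, 2.0, 3.0]}
        res = stats.anova_tukey(g)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        groups = {3: [1, 2, 3], 6: [2, 3, 4], 9: [3, 4, 5]}
        res = stats.anova_tukey(groups)
        f_hand, p_hand = hand_anova(list(groups.values()))
        assert res.f_stat == pytest.approx(f_hand, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)
        assert res.df_between == 2 and res.df_within == 6

    def test_tukey_matches_studentized_range(self, rng):
        groups = {a: rng.normal(10 + a, 2, 12) for a in (3, 6, 9, 12)}
        res = stats.anova_tukey(groups)
        glist = list(groups.values())
        keys = list(groups)
        for i in range(4):
            for j in range(i + 1, 4):
                want = hand_tukey_p(glist, i, j)
                assert res.tukey_p(str(keys[i]), str(keys[j])) == pytest.approx(
                    want, abs=1e-6
                )

    def test_tukey_p_not_below_unadjusted(self, rng):
        for _ in range(10):
            groups = {a: rng.normal(0, 1, 8) for a in (3, 6, 9)}
            res = stats.anova_tukey(groups)
            keys = list(groups)
            for i in range(3):
                for j in range(i + 1, 3):
                    _, p_raw = hand_ttest(groups[keys[i]], groups[keys[j]])
                    # Tukey adjusts for 3 comparisons: adjusted >= unadjusted
                    assert (
                        res.tukey_p(str(keys[i]), str(keys[j])) >= p_raw - 1e-9
                    )

    def test_small_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.anova_tukey({3: [1.0], 6: [1.0, 2.0]})

    def test_anova_f_equals_t_squared_for_two_groups(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 12)
        res = stats.anova_tukey({0: x, 1: y})
        t = stats.ttest_by_age(x, y)
        assert res.f_stat == pytest.approx(t.t_stat**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.p_value, rel=1e-10)


class TestTTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = stats.ttest_by_age(x, x)
        assert res.t_stat == 0.0 and res.p_value == pytest.approx(1.0)

    def test_textbook_pair(self):
        res = stats.ttest_by_age([1, 2, 3], [4, 5, 6])
        t_hand, p_hand = hand_ttest([1, 2, 3], [4, 5, 6])
        assert res.t_stat == pytest.approx(-3.6742346, abs=1e-6)
        assert res.t_stat == pytest.approx(t_hand, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)
        assert res.df == 4

    def test_welch_option(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 5, 40)
        classic = stats.ttest_by_age(x, y, equal_var=True)
        welch = stats.ttest_by_age(x, y, equal_var=False)
        assert welch.df != classic.df

    def test_insufficient_n(self):
        with pytest.raises(InvalidParameterError):
            stats.ttest_by_age([1.0], [1.0, 2.0])


class TestAncova:
    def test_noise_free_lines_recover_slopes_exactly(self):
        ages = np.tile([3, 6, 9, 12], 4)
        g1 = 10.0 + 1.0 * ages
        g2 = 5.0 + 2.0 * ages
        values = np.concatenate([g1, g2])
        groups = np.array(["A"] * 16 + ["B"] * 16)
        res = stats.ancova_slopes(values, np.tile(ages, 2), groups)
        assert res.slopes["A"] == pytest.approx(1.0, abs=1e-10)
        assert res.slopes["B"] == pytest.approx(2.0, abs=1e-10)
        assert res.p_value < 1e-12

    def test_matches_closed_form_per_group_ols(self, rng):
        # interaction slope difference equals the difference of per-group
        # ordinary least-squares slopes
        ages = np.tile([3.0, 6.0, 9.0, 12.0], 5)
        v1 = 3.0 - 0.3 * ages + rng.normal(0, 1, ages.size)
        v2 = 3.1 - 0.1 * ages + rng.normal(0, 1, ages.size)
        res = stats.ancova_slopes(
            np.concatenate([v1, v2]),
            np.tile(ages, 2),
            np.array(["A"] * ages.size + ["B"] * ages.size),
        )
        s1 = np.polyfit(ages, v1, 1)[0]
        s2 = np.polyfit(ages, v2, 1)[0]
        assert res.slopes["A"] == pytest.approx(s1, rel=1e-8)
        assert res.slopes["B"] == pytest.approx(s2, rel=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.ancova_slopes(
                np.arange(8.0), np.tile([3.0, 6.0], 4), np.array(["A"] * 8)
            )

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the slope test ~ alpha under equal slopes."""
        rng = np.random.default_rng(77)
        ages = np.repeat([3.0, 6.0, 9.0, 12.0], 15)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            v1 = 30.0 - 0.2 * ages + rng.normal(0, 1.0, ages.size)
            v2 = 30.0 - 0.2 * ages + rng.normal(0, 1.0, ages.size)
            res = stats.ancova_slopes(
                np.concatenate([v1, v2]),
                np.tile(ages, 2),
                np.array(["A"] * ages.size + ["B"] * ages.size),
            )
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestReferenceAgreement:
    def test_twenty_random_datasets_match_hand_formulas(self, rng):
        """ANOVA F/p and t/p agree with first-principles oracles to 1e-8."""
        for _ in range(20):
            k = rng.integers(2, 5)
            groups = {
                i: rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), rng.integers(5, 15))
                for i in range(k)
            }
            res = stats.anova_tukey(groups)
            f_hand, p_hand = hand_anova(list(groups.values()))
            assert res.f_stat == pytest.approx(f_hand, abs=1e-8, rel=1e-8)
            assert res.p_value == pytest.approx(p_hand, abs=1e-8, rel=1e-8)
            x, y = groups[0], groups[1]
            t = stats.ttest_by_age(x, y)
            t_hand, p_t = hand_ttest(x, y)
            assert t.t_stat == pytest.approx(t_hand, abs=1e-8, rel=1e-8)
            assert t.p_value == pytest.approx(p_t, abs=1e-8, rel=1e-8)


class TestBuildSummary:
    @staticmethod
    def make_cohort(rng, n=8):
        rows = []
        for g, offset in (("APP/PS1", 0.0), ("WT", 1.0)):
            for age in (3, 6, 9, 12):
                for k in range(n):
                    rows.append(
                        (f"{g}-{age}-{k}", g, age, "inner_um",
                         31.0 + offset - 0.2 * age + rng.normal(0, 0.8))
                    )
        return pd.DataFrame(
            rows, columns=["animal_id", "genotype", "age_months", "parameter", "value"]
        )

    def test_report_structure_complete(self, rng):
        report = stats.build_summary(self.make_cohort(rng))
        assert len(report.cell_summary) == 8
        assert len(report.anova) == 2
        assert len(report.ancova) == 1
        assert len(report.ttests) == 4
        assert set(report.cell_summary.genotype) == {"APP/PS1", "WT"}
        assert ((report.ttests.p >= 0) & (report.ttests.p <= 1)).all()

    def test_single_age_skips_anova_with_note(self, rng):
        cohort = self.make_cohort(rng)
        cohort = cohort[cohort.age_months == 3]
        report = stats.build_summary(cohort)
        assert report.anova.empty
        assert any("ANOVA skipped" in n for n in report.notes)

    def test_permuted_labels_kill_slope_difference(self, rng):
        """Shuffling genotype labels makes the ANCOVA p roughly uniform."""
        pvals = []
        for _ in range(50):
            cohort = self.make_cohort(rng, n=6)
            cohort = cohort.assign(
                genotype=rng.permutation(cohort.genotype.to_numpy())
            )
            report = stats.build_summary(cohort)
            if not report.ancova.empty:
                pvals.append(report.ancova.p.iloc[0])
        assert np.mean(np.array(pvals) < 0.05) < 0.2
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.2)

    def test_significance_letters_shared_on_extreme_pairs(self, rng):
        rows = []
        for age, mean in ((3, 0.0), (6, 0.1), (9, 0.2), (12, 10.0)):
            for k in range(10):
                rows.append(
                    (f"a{age}-{k}", "WT", age, "x", mean + rng.normal(0, 0.3))
                )
        report = stats.build_summary(
            pd.DataFrame(rows, columns=["animal_id", "genotype", "age_months",
                                        "parameter", "value"])
        )
        cells = report.cell_summary.set_index("age_months")
        # 12 months differs from everything at the strongest tier
        assert "d" in cells.loc[12, "letters"]
        assert "d" in cells.loc[3, "letters"]
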