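import itertools

import numpy as np
import pandas as pd
import pytest

import oispec as o
from oispec.errors import ValidationError


def _long_table(data):
    """data: {group: {subject: [magnitudes per level]}}"""
    rows = []
    for g, subjects in data.items():
        for s, mags in subjects.items():
            for li, m in enumerate(mags):
                rows.append((s, g, f"L{li + 1}", m))
    return pd.DataFrame(rows, columns=["subject", "group", "level",
                                       "magnitude"])


def brute_force_anova_ss(df):
    """Independent sums-of-squares oracle: plain nested loops over the
    split-plot decomposition definitions."""
    groups = sorted(df["group"].unique())
    levels = sorted(df["level"].unique())
    subjects = sorted(df["subject"].unique())
    y = {(r.subject, r.level): r.magnitude for r in df.itertuples()}
    g_of = {r.subject: r.group for r in df.itertuples()}
    b = len(levels)
    gm = np.mean(list(y.values()))

    def mean(vals):
        return sum(vals) / len(vals)

    subj_mean = {s: mean([y[s, l] for l in levels]) for s in subjects}
    grp_mean = {g: mean([subj_mean[s] for s in subjects if g_of[s] == g])
                for g in groups}
    lvl_mean = {l: mean([y[s, l] for s in subjects]) for l in levels}
    cell_mean = {(g, l): mean([y[s, l] for s in subjects if g_of[s] == g])
                 for g, l in itertools.product(groups, levels)}

    ss_total = sum((y[s, l] - gm) ** 2 for s in subjects for l in levels)
    ss_group = b * sum(
        len([s for s in subjects if g_of[s] == g]) * (grp_mean[g] - gm) ** 2
        for g in groups)
    ss_subj = b * sum((subj_mean[s] - grp_mean[g_of[s]]) ** 2
                      for s in subjects)
    ss_level = len(subjects) * sum((lvl_mean[l] - gm) ** 2 for l in levels)
    ss_inter = sum(
        len([s for s in subjects if g_of[s] == g])
        * (cell_mean[g, l] - grp_mean[g] - lvl_mean[l] + gm) ** 2
        for g, l in itertools.product(groups, levels))
    ss_resid = ss_total - ss_group - ss_subj - ss_level - ss_inter
    return dict(total=ss_total, group=ss_group, subject=ss_subj,
                level=ss_level, interaction=ss_inter, residual=ss_resid)


class TestRmAnova:
    def test_all_equal_magnitudes_give_zero_F(self):
        table = _long_table({
            "WT-like": {"w1": [1, 1, 1], "w2": [1, 1, 1]},
            "AD-like": {"a1": [1, 1, 1], "a2": [1, 1, 1]},
        })
        res = o.rm_anova_two_way(table)
        assert res.group.F == 0.0 and res.within.F == 0.0
        assert res.interaction.F == 0.0

    def test_matches_brute_force_ss_oracle(self):
        rng = np.random.default_rng(0)
        table = _long_table({
            "WT-like": {f"w{i}": list(rng.normal(0.05, 0.01, 3))
                        for i in range(4)},
            "AD-like": {f"a{i}": list(rng.normal(0.03, 0.01, 3))
                        for i in range(4)},
        })
        res = o.rm_anova_two_way(table)
        ss = brute_force_anova_ss(table)
        a, b_, n = 2, 3, 4
        F_group = (ss["group"] / (a - 1)) / (ss["subject"] / (2 * (n - 1)))
        F_level = (ss["level"] / (b_ - 1)) / (
            ss["residual"] / (2 * (n - 1) * (b_ - 1)))
        F_inter = (ss["interaction"] / ((a - 1) * (b_ - 1))) / (
            ss["residual"] / (2 * (n - 1) * (b_ - 1)))
        assert res.group.F == pytest.approx(F_group, rel=1e-8)
        assert res.within.F == pytest.approx(F_level, rel=1e-8)
        assert res.interaction.F == pytest.approx(F_inter, rel=1e-8)

    def test_ss_decomposition_exhaustive(self):
        rng = np.random.default_rng(5)
        table = _long_table({
            "WT-like": {f"w{i}": list(rng.normal(0, 1, 5)) for i in range(5)},
            "AD-like": {f"a{i}": list(rng.normal(0, 1, 5)) for i in range(5)},
        })
        res = o.rm_anova_two_way(table)
        parts = (res.group.ss + res.ss_subject + res.within.ss
                 + res.interaction.ss + res.ss_residual)
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        table = _long_table({
            "WT-like": {f"w{i}": list(rng.normal(0.05, 0.02, 4))
                        for i in range(5)},
            "AD-like": {f"a{i}": list(rng.normal(0.02, 0.02, 4))
                        for i in range(5)},
        })
        res = o.rm_anova_two_way(table)
        aov = pg.mixed_anova(data=table, dv="magnitude", within="level",
                             subject="subject", between="group")
        aov = aov.set_index("Source")
        assert res.group.F == pytest.approx(aov.loc["group", "F"], rel=1e-8)
        assert res.within.F == pytest.approx(aov.loc["level", "F"], rel=1e-8)
        assert res.interaction.F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-8)
        assert res.group.p == pytest.approx(aov.loc["group", "p_unc"],
                                            rel=1e-8)

    def test_incomplete_table_lists_missing_cells(self):
        table = _long_table({
            "WT-like": {"w1": [1, 2, 3], "w2": [1, 2, 3]},
            "AD-like": {"a1": [1, 2, 3], "a2": [1, 2, 3]},
        })
        table = table[~((table.subject == "a1") & (table.level == "L2"))]
        with pytest.raises(ValidationError, match="a1"):
            o.rm_anova_two_way(table)

    def test_species_slice(self):
        rng = np.random.default_rng(1)
        table = o.simulate_cohort_magnitudes(3, seed=4)
        res = o.rm_anova_two_way(table, species="Hbt")
        assert res.group.df_num == 1
        with pytest.raises(ValidationError):
            o.rm_anova_two_way(table, species="nonsense")


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expect", [
        (0.05, 1, 0.05),
        (0.05, 5, 0.01),
        (0.05, 15, 0.05 / 15),  # the working level quoted as 0.003
    ])
    def test_adjusted_level(self, alpha, m, expect):
        assert o.bonferroni_threshold(alpha, m) == pytest.approx(expect,
                                                                 rel=1e-12)

    def test_fifteen_comparisons_round_to_printed_level(self):
        assert round(o.bonferroni_threshold(0.05, 15), 3) == 0.003

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            o.bonferroni_threshold(0.0, 3)
        with pytest.raises(ValidationError):
            o.bonferroni_threshold(0.05, 0)


class TestTTest:
    def test_identical_samples(self):
        t, p = o.ttest_two_sample_equal_var([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_pooled_formula_on_random_samples(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        for _ in range(100):
            na, nb = rng.integers(2, 8, 2)
            a = rng.normal(0, 1, na)
            b = rng.normal(0.3, 1.2, nb)
            t, p = o.ttest_two_sample_equal_var(a, b)
            # textbook pooled-variance formula
            sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                   / (na + nb - 2))
            t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_hand = 2 * sps.t.sf(abs(t_hand), na + nb - 2)
            assert t == pytest.approx(t_hand, abs=1e-10)
            assert p == pytest.approx(p_hand, abs=1e-10)

    def test_zero_variance_unequal_means_reported_infinite(self):
        t, p = o.ttest_two_sample_equal_var([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            o.ttest_two_sample_equal_var([1.0], [1.0, 2.0])


class TestHypercapniaMagnitude:
    def test_unit_series_gives_zero(self):
        assert o.hypercapnia_magnitude(np.ones(8 * 600), 8.0) == 0.0

    def test_constant_excursion(self):
        s = np.ones(8 * 600)
        s[8 * 250:8 * 500] = 1.2
        assert o.hypercapnia_magnitude(s, 8.0) == pytest.approx(0.2,
                                                                abs=1e-12)

    def test_short_record_rejected(self):
        with pytest.raises(ValidationError):
            o.hypercapnia_magnitude(np.ones(8 * 400), 8.0)

    def test_phantom_injected_gain_recovered(self, chronic_result,
                                             chronic_recording,
                                             reduced_proto):
        """Recovered challenge-window magnitude matches the injected
        hypercapnia excursion."""
        exp = reduced_proto["exp8"]
        window = (exp.gas_switch_s, exp.gas_switch_s + exp.gas_duration_s)
        rec_series = chronic_result.experiments["exp8"].roi_series["Hbt"]
        got = o.hypercapnia_magnitude(rec_series, 8.0, window_s=window)
        truth = chronic_recording.truth["exp8"]
        hbo_t, hbr_t = truth.concentration_movie()
        frac_true = truth.fractional_hbt_movie(
            chronic_result.experiments["exp8"].baseline_used, 8.0)
        roi = chronic_result.roi.pixels
        true_series = np.nanmean(frac_true[:, roi], axis=1)
        expect = o.hypercapnia_magnitude(true_series, 8.0, window_s=window)
        assert got == pytest.approx(expect, rel=0.03)


class TestCohortGenerator:
    def test_balanced_complete_long_table(self):
        table = o.simulate_cohort_magnitudes(4, seed=1)
        assert len(table) == 8 * 5 * 3  # subjects x levels x species
        counts = table.groupby(["subject", "level", "species"]).size()
        assert (counts == 1).all()

    def test_chronic_null_has_equal_group_means_in_expectation(self):
        t = o.simulate_cohort_magnitudes(50, seed=2, session_kind="chronic")
        hbt = t[t.species == "Hbt"]
        means = hbt.groupby("group")["magnitude"].mean()
        assert abs(means["WT-like"] - means["AD-like"]) < 0.01

    def test_acute_ad_deficit(self):
        t = o.simulate_cohort_magnitudes(20, seed=3, session_kind="acute")
        hbt = t[t.species == "Hbt"]
        means = hbt.groupby("group")["magnitude"].mean()
        assert means["AD-like"] < means["WT-like"]


class TestTTestProperties:
    from hypothesis import given, settings, strategies as st

    sample = st.lists(st.floats(-10, 10, allow_nan=False), min_size=2,
                      max_size=10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(a=sample, b=sample)
    def test_antisymmetric_and_p_in_unit_interval(self, a, b):
        import numpy as np

        va = np.var(a, ddof=1) if len(a) > 1 else 0.0
        vb = np.var(b, ddof=1) if len(b) > 1 else 0.0
        t_ab, p_ab = o.ttest_two_sample_equal_var(a, b)
        t_ba, p_ba = o.ttest_two_sample_equal_var(b, a)
        assert t_ab == pytest.approx(-t_ba, abs=1e-10) or (
            np.isinf(t_ab) and np.isinf(t_ba))
        assert 0.0 <= p_ab <= 1.0
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
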