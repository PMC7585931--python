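"""Group statistics: mixed repeated-measures ANOVA, Bonferroni, t-tests,
and the hypercapnia-window response magnitude.

The design is a two-way mixed (split-plot) ANOVA: a between-subject
factor ``group`` (WT-like vs AD-like) and a within-subject factor
``level`` (imaging session, or stimulation experiment), applied
separately to each hemoglobin species' mean response magnitudes.  On
complete data the sums of squares decompose exhaustively:

    SS_total = SS_group + SS_subject(group) + SS_level
               + SS_interaction + SS_residual

with the group effect tested against the subject(group) stratum and the
within effects against the residual stratum.  No sphericity correction
is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

LONG_TABLE_COLUMNS = ("subject", "group", "level", "magnitude")


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed two-way ANOVA decomposition."""

    group: EffectResult
    within: EffectResult
    interaction: EffectResult
    ss_subject: float
    ss_residual: float
    ss_total: float

    def as_frame(self) -> pd.DataFrame:
        rows = [("group", self.group), ("within", self.within),
                ("interaction", self.interaction)]
        return pd.DataFrame(
            [(n, e.ss, e.df_num, e.df_den, e.F, e.p) for n, e in rows],
            columns=["effect", "SS", "df_num", "df_den", "F", "p"])


def validate_long_table(table: pd.DataFrame,
                        species: str | None = None) -> pd.DataFrame:
    """Check completeness of a long magnitude table; returns the slice.

    Requires one row per (subject, level) [and species if given], every
    subject measured at every level, and each subject in exactly one
    group.  Raises listing the missing cells otherwise.
    """
    missing_cols = set(LONG_TABLE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValidationError(f"long table missing columns {sorted(missing_cols)}")
    df = table
    if species is not None:
        if "species" not in df.columns:
            raise ValidationError("table has no 'species' column")
        df = df[df["species"] == species]
        if df.empty:
            raise ValidationError(f"no rows for species {species!r}")
    if df.groupby("subject")["group"].nunique().max() > 1:
        raise ValidationError("a subject appears in more than one group")
    levels = sorted(df["level"].unique())
    counts = df.groupby(["subject", "level"]).size()
    if (counts > 1).any():
        dup = counts[counts > 1].index.tolist()
        raise ValidationError(f"duplicate (subject, level) rows: {dup}")
    missing = [(s, l) for s in df["subject"].unique() for l in levels
               if (s, l) not in counts.index]
    if missing:
        raise ValidationError(f"incomplete design, missing cells: {missing}")
    return df.copy()


def rm_anova_two_way(table: pd.DataFrame,
                     species: str | None = None) -> AnovaResult:
    """Two-way mixed ANOVA of response magnitudes.

    Parameters
    ----------
    table
        Long table with columns subject, group, level, magnitude (and
        optionally species); complete cases only.
    species
        Optional species slice ('Hbt' / 'Hbo' / 'Hbr') when the table
        carries all three.
    """
    df = validate_long_table(table, species)
    groups = sorted(df["group"].unique())
    levels = sorted(df["level"].unique())
    a, b = len(groups), len(levels)
    if a < 2:
        raise ValidationError("need >= 2 groups")
    if b < 2:
        raise ValidationError("need >= 2 within-factor levels")
    n_per = df.groupby("group")["subject"].nunique()
    if (n_per < 2).any():
        raise ValidationError("need >= 2 subjects per group")

    wide = df.pivot_table(index=["group", "subject"], columns="level",
                          values="magnitude", sort=True)
    y = wide.to_numpy()  # (N_subjects, b)
    grp = wide.index.get_level_values("group").to_numpy()
    N = y.shape[0]
    gm = y.mean()

    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)
    group_means = np.array([subj_means[grp == g].mean() for g in groups])
    n_g = np.array([(grp == g).sum() for g in groups])

    ss_total = float(((y - gm) ** 2).sum())
    ss_group = float(b * (n_g * (group_means - gm) ** 2).sum())
    ss_subject = float(b * sum(
        ((subj_means[grp == g] - group_means[i]) ** 2).sum()
        for i, g in enumerate(groups)))
    ss_level = float(N * ((level_means - gm) ** 2).sum())
    cell_means = np.stack([y[grp == g].mean(axis=0) for g in groups])
    ss_inter = float(sum(
        n_g[i] * ((cell_means[i] - group_means[i] - level_means + gm) ** 2).sum()
        for i in range(a)))
    ss_resid = ss_total - ss_group - ss_subject - ss_level - ss_inter
    ss_resid = max(ss_resid, 0.0)

    df_group, df_subj = a - 1, N - a
    df_level = b - 1
    df_inter = (a - 1) * (b - 1)
    df_resid = (N - a) * (b - 1)

    def effect(ss, df_num, ss_err, df_den):
        if ss <= 0.0:
            return EffectResult(0.0, df_num, df_den, 1.0, float(ss))
        ms = ss / df_num
        ms_err = ss_err / df_den
        if ms_err <= 0.0:
            return EffectResult(float("inf"), df_num, df_den, 0.0, float(ss))
        F = ms / ms_err
        return EffectResult(float(F), df_num, df_den,
                            float(sps.f.sf(F, df_num, df_den)), float(ss))

    return AnovaResult(
        group=effect(ss_group, df_group, ss_subject, df_subj),
        within=effect(ss_level, df_level, ss_resid, df_resid),
        interaction=effect(ss_inter, df_inter, ss_resid, df_resid),
        ss_subject=ss_subject,
        ss_residual=ss_resid,
        ss_total=ss_total,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted working significance level alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("number of comparisons must be >= 1")
    return alpha / m


def ttest_two_sample_equal_var(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-tailed.

    Returns (t, p) with df = n_a + n_b - 2.  A zero pooled variance with
    unequal means is reported as an infinite t (p = 0) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def hypercapnia_magnitude(fractional_series: np.ndarray, rate_hz: float,
                          window_s: tuple[float, float] = (250.0, 500.0)
                          ) -> float:
    """Mean fractional deviation from baseline over the challenge window.

    The default window [250, 500) s spans the CO2 challenge of the
    hypercapnia record; the series must cover it.
    """
    series = np.asarray(fractional_series, dtype=float)
    i0 = int(round(window_s[0] * rate_hz))
    i1 = int(round(window_s[1] * rate_hz))
    if not (0 <= i0 < i1 <= series.shape[0]):
        raise ValidationError(
            f"window {window_s} s outside record of "
            f"{series.shape[0] / rate_hz:g} s"
        )
    return float(np.nanmean(series[i0:i1]) - 1.0)
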