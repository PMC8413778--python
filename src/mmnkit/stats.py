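"""Group-level inferential statistics for the 2 x 2 mixed design.

The design has one within-subject factor with two levels (e.g. condition:
simple vs pattern oddball, or stimulus type: deviant vs standard) and one
between-subject factor with two levels (gender). With two within levels the
analysis reduces exactly to two univariate strata:

* difference scores d_i = y_i1 - y_i2 carry the within main effect
  (does the unweighted mean of the group difference-score means differ
  from zero?) and the interaction (do the group difference-score means
  differ?), both tested against the subject x within residual;
* subject means m_i carry the between main effect, tested against the
  subjects-within-groups error.

With unequal group sizes the within-effect tests use unweighted marginal
means (the SPSS Type III convention), so the denominator df is N - 2 for
all three effects. Sphericity is not an issue: every within factor has two
levels. Effect size is partial eta squared,
eta_p^2 = SS_effect / (SS_effect + SS_error-for-that-effect).

t-tests are classical: paired (d = mean difference / SD of differences) and
pooled-variance independent (d = mean difference / pooled SD), plus a
summary-statistics version that reconstructs group SDs from SEMs, which
lets printed group tables be re-analysed without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    d: float
    kind: str  # paired | independent | from_summary
    note: str = ""

    def summary(self) -> str:
        return f"t({self.df}) = {self.t:.2f}, p = {self.p:.3g}, d = {self.d:.2f} [{self.kind}]"


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df_num: int
    df_den: int
    F: float
    p: float
    eta_p2: float


@dataclass
class AnovaTable:
    effects: dict[str, AnovaEffect]
    ss_error_between: float
    ss_error_within: float
    df_error: int
    n_subjects: int
    flags: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append({"effect": e.name, "SS": e.ss, "df1": e.df_num,
                         "df2": e.df_den, "F": e.F, "p": e.p,
                         "eta_p2": e.eta_p2})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Mixed 2x2 ANOVA ({self.n_subjects} subjects)"]
        for e in self.effects.values():
            lines.append(
                f"  {e.name:<12s} F({e.df_num},{e.df_den}) = {e.F:.2f}, "
                f"p = {e.p:.3g}, eta_p2 = {e.eta_p2:.3f}"
            )
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


@dataclass
class SummaryGroup:
    """Printed group summary: mean, standard error of the mean, group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n < 2:
            raise ValueError("group size must be at least 2")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


def _f_p(F: float, df1: int, df2: int) -> float:
    return float(sps.f.sf(F, df1, df2))


def mixed_anova_core(y1: np.ndarray, y2: np.ndarray, group: np.ndarray,
                     within_name: str = "within",
                     between_name: str = "between") -> AnovaTable:
    """Mixed 2x2 ANOVA on paired arrays.

    ``y1``/``y2`` hold each subject's value at the two within levels and
    ``group`` the between-factor level per subject (two levels).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"between factor must have 2 levels, found {len(levels)}")
    in1 = group == levels[0]
    n1, n2 = int(in1.sum()), int((~in1).sum())
    if min(n1, n2) < 2:
        raise ValueError("each between-group needs at least 2 subjects")
    n = n1 + n2
    df_err = n - 2

    d = y1 - y2
    m = 0.5 * (y1 + y2)
    d1, d2 = d[in1].mean(), d[~in1].mean()
    m1, m2 = m[in1].mean(), m[~in1].mean()
    inv = 1.0 / n1 + 1.0 / n2

    # subject x within residual (within-stratum error), in the ANOVA metric
    ss_err_w = 0.5 * (((d[in1] - d1) ** 2).sum() + ((d[~in1] - d2) ** 2).sum())
    # subjects-within-groups (between-stratum error)
    ss_err_b = 2.0 * (((m[in1] - m1) ** 2).sum() + ((m[~in1] - m2) ** 2).sum())

    ss_within = (0.5 * (d1 + d2)) ** 2 * 2.0 / inv
    ss_inter = (d1 - d2) ** 2 / (2.0 * inv)
    ss_between = (m1 - m2) ** 2 * 2.0 / inv

    flags: list[str] = []

    def effect(name: str, ss: float, ss_err: float) -> AnovaEffect:
        if ss_err == 0.0:
            if ss == 0.0:
                flags.append(f"zero_variance[{name}]")
                return AnovaEffect(name, 0.0, 1, df_err, 0.0, 1.0, 0.0)
            flags.append(f"zero_error[{name}]")
            return AnovaEffect(name, ss, 1, df_err, np.inf, 0.0, 1.0)
        F = ss / (ss_err / df_err)
        return AnovaEffect(name, ss, 1, df_err, F, _f_p(F, 1, df_err),
                           ss / (ss + ss_err))

    effects = {
        between_name: effect(between_name, ss_between, ss_err_b),
        within_name: effect(within_name, ss_within, ss_err_w),
        "interaction": effect("interaction", ss_inter, ss_err_w),
    }
    return AnovaTable(effects, ss_err_b, ss_err_w, df_err, n, tuple(flags))


def mixed_anova_2x2(table: pd.DataFrame, dv: str,
                    within: str = "condition", between: str = "gender",
                    subject: str = "subject_id") -> AnovaTable:
    """Mixed 2x2 ANOVA from a tidy long-format table.

    Each subject must contribute exactly one value per within level and
    belong to exactly one between level.
    """
    piv = table.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="first")
    w_levels = sorted(table[within].unique())
    if len(w_levels) != 2:
        raise ValueError(f"within factor must have 2 levels, found {len(w_levels)}")
    counts = table.groupby(subject)[within].nunique()
    incomplete = counts[counts < 2]
    if len(incomplete):
        raise ValueError(
            "incomplete design: subject(s) missing a within level: "
            f"{list(incomplete.index)}"
        )
    gmap = table.groupby(subject)[between].agg(lambda s: s.unique())
    multi = [s for s, g in gmap.items() if len(g) > 1]
    if multi:
        raise ValueError(f"subject(s) assigned to multiple {between} levels: {multi}")
    group = np.array([gmap[s][0] for s in piv.index])
    return mixed_anova_core(
        piv[w_levels[0]].to_numpy(), piv[w_levels[1]].to_numpy(), group,
        within_name=within, between_name=between,
    )


def paired_t(x, y, kind_note: str = "") -> TestResult:
    """Paired t-test with d = mean(x - y) / SD(x - y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two matched 1-d samples of length >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    n = len(diff)
    if sd == 0:
        if diff.mean() == 0:
            return TestResult(0.0, n - 1, 1.0, 0.0, "paired", kind_note)
        raise ValueError(
            "differences have zero variance but nonzero mean (t undefined)"
        )
    res = sps.ttest_rel(x, y)
    return TestResult(float(res.statistic), n - 1, float(res.pvalue),
                      float(diff.mean() / sd), "paired", kind_note)


def independent_t(x, y, kind_note: str = "") -> TestResult:
    """Pooled-variance (Student) independent t-test with
    d = (mean(x) - mean(y)) / pooled SD and df = n1 + n2 - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(len(x), len(y)) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, n1 + n2 - 2, 1.0, 0.0, "independent", kind_note)
        raise ValueError("zero pooled variance with unequal means (t undefined)")
    res = sps.ttest_ind(x, y, equal_var=True)
    d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    return TestResult(float(res.statistic), n1 + n2 - 2, float(res.pvalue),
                      d, "independent", kind_note)


def t_from_summary(g1: SummaryGroup, g2: SummaryGroup,
                   kind_note: str = "") -> TestResult:
    """Pooled-variance t-test from printed summaries (mean, SEM, n).

    Group SDs are reconstructed as SEM * sqrt(n). Cohen's d is reported as
    |mean difference| / pooled SD; agreement with published d values is
    limited by the rounding of the printed summaries (about +/- 0.02).
    """
    sd1, sd2 = g1.sd, g2.sd
    if sd1 == 0 and sd2 == 0:
        if g1.mean == g2.mean:
            return TestResult(0.0, g1.n + g2.n - 2, 1.0, 0.0,
                              "from_summary", kind_note)
        raise ValueError("both SEMs are zero with unequal means (t undefined)")
    res = sps.ttest_ind_from_stats(
        g1.mean, sd1, g1.n, g2.mean, sd2, g2.n, equal_var=True
    )
    sp = np.sqrt(((g1.n - 1) * sd1 ** 2 + (g2.n - 1) * sd2 ** 2)
                 / (g1.n + g2.n - 2))
    return TestResult(float(res.statistic), g1.n + g2.n - 2,
                      float(res.pvalue), float(abs(g1.mean - g2.mean) / sp),
                      "from_summary", kind_note)
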