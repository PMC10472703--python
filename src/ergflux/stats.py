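"""Group-comparison statistics for the db/db vs db/+ study design.

Two-sample t-tests are computed either from raw samples or directly
from printed summary statistics (mean, SEM, n): the two routes agree
exactly because the t-statistic is a function of the summaries alone.
The orientation convention is fixed throughout: statistics are reported
as (group 2 minus group 1), i.e. (db/db - db/+) when the control group
is passed first, which matches the sign of every reported comparison in
the reference table bundled with the package.

Longitudinal designs use the two-way split-plot ("mixed-model") ANOVA
with one between-subjects factor (group) and one within-subjects factor
(time), with the Greenhouse-Geisser epsilon correcting the
within-subject degrees of freedom for sphericity violation. Simple main
effects compare the groups at a single timepoint.

All p-values are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: tolerance on |recomputed t - reported t| for the reference table
REFERENCE_T_TOL = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: mean +/- SEM with sample size."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary needs n >= 2")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @classmethod
    def from_sample(cls, x: np.ndarray, label: str = "") -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need n >= 2 to form a summary")
        return cls(
            label=label,
            mean=float(x.mean()),
            sem=float(x.std(ddof=1) / math.sqrt(x.size)),
            n=int(x.size),
        )


@dataclass
class TTestResult:
    """Two-sample t-test outcome, oriented as (group2 - group1)."""

    t: float
    df: float
    p: float
    pooled: bool
    mean_diff: float
    flags: set[str] = field(default_factory=set)


@dataclass
class FResult:
    """A single F-test (e.g. a simple main effect)."""

    f: float
    df1: float
    df2: float
    p: float


@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA: group (between), time (within), interaction.

    ``df_*`` are (numerator, denominator) pairs; the ``_gg`` variants
    are Greenhouse-Geisser corrected for the within-subject effects.
    """

    f_group: float
    f_time: float
    f_interaction: float
    df_group: tuple[float, float]
    df_time: tuple[float, float]
    df_interaction: tuple[float, float]
    epsilon_gg: float
    df_time_gg: tuple[float, float]
    df_interaction_gg: tuple[float, float]
    p_group: float
    p_time: float
    p_interaction: float
    p_time_gg: float
    p_interaction_gg: float
    ss: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Normality gate
# --------------------------------------------------------------------------

def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, two-sided p), 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk limited to n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; W is undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Two-sample t-tests
# --------------------------------------------------------------------------

def _finish_t(
    t_num: float, se: float, df: float, pooled: bool, mean_diff: float
) -> TTestResult:
    flags: set[str] = set()
    if se == 0.0:
        if mean_diff == 0.0:
            t = 0.0
            p = 1.0
        else:
            t = math.copysign(math.inf, mean_diff)
            p = 0.0
            flags.add("infinite-t")
    else:
        t = t_num / se
        p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(
        t=t, df=df, p=float(p), pooled=pooled, mean_diff=mean_diff, flags=flags
    )


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Student's pooled-variance t from two printed summaries.

    t = (mean2 - mean1) / (sp * sqrt(1/n1 + 1/n2)) with the pooled
    variance sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2) and
    df = n1 + n2 - 2.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = math.sqrt(sp2) * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
    diff = g2.mean - g1.mean
    return _finish_t(diff, se, float(df), pooled=True, mean_diff=diff)


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Welch's unequal-variance t with Welch-Satterthwaite df."""
    v1, v2 = g1.sem**2, g2.sem**2
    se = math.sqrt(v1 + v2)
    diff = g2.mean - g1.mean
    if se == 0.0:
        return _finish_t(diff, se, float(g1.n + g2.n - 2), False, diff)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return _finish_t(diff, se, float(df), pooled=False, mean_diff=diff)


def t_test_raw(
    x: np.ndarray, y: np.ndarray, welch: bool = False
) -> TTestResult:
    """Independent two-sample t-test on raw samples.

    Routed through the summary-statistic formulas, so it agrees exactly
    with the corresponding ``*_from_summary`` call on (mean, SEM, n).
    """
    g1 = GroupSummary.from_sample(np.asarray(x, dtype=float), "x")
    g2 = GroupSummary.from_sample(np.asarray(y, dtype=float), "y")
    return welch_t_from_summary(g1, g2) if welch else pooled_t_from_summary(g1, g2)


# --------------------------------------------------------------------------
# Split-plot mixed ANOVA with Greenhouse-Geisser correction
# --------------------------------------------------------------------------

def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-time covariance.

    The covariance is double-centered (C S C with C = I - J/k) and
    epsilon = (sum lambda)^2 / ((k-1) * sum lambda^2) over its
    eigenvalues; equivalently trace-based. Bounded in [1/(k-1), 1].
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.shape != (k, k) or k < 2:
        raise ValueError("covariance must be square with k >= 2")
    c = np.eye(k) - np.ones((k, k)) / k
    s = c @ cov @ c
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def mixed_anova(
    table: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    time: str = "time",
    value: str = "value",
) -> MixedAnovaResult:
    """Two-way split-plot ANOVA on a balanced complete long table.

    Every subject must appear exactly once at every timepoint; group
    sizes may differ. Between-subjects: group against
    subject-within-group error. Within-subjects: time and time x group
    against the time x subject-within-group error. The
    Greenhouse-Geisser epsilon comes from the pooled within-group
    covariance of the time measures and rescales the within-subject
    degrees of freedom; missing cells raise (no imputation).
    """
    df = table[[subject, group, time, value]].copy()
    wide = df.pivot_table(
        index=[group, subject], columns=time, values=value, aggfunc="first"
    )
    if wide.isna().any().any():
        raise ValueError("design has missing cells (every subject at every time)")
    counts = df.groupby([subject, time], observed=True).size()
    if (counts != 1).any():
        raise ValueError("duplicated subject x time cells")
    times = list(wide.columns)
    k = len(times)
    if k < 2:
        raise ValueError("need >= 2 timepoints for within-subject effects")
    groups = wide.index.get_level_values(0)
    group_labels = list(pd.unique(groups))
    a = len(group_labels)
    if a < 2:
        raise ValueError("need >= 2 groups")
    n_per_group = {g: int((groups == g).sum()) for g in group_labels}
    if min(n_per_group.values()) < 2:
        raise ValueError("need >= 2 subjects per group")
    n_subjects = wide.shape[0]

    y = wide.to_numpy(dtype=float)          # subjects x times
    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    group_means = np.array([y[groups == g].mean() for g in group_labels])
    cell_means = np.vstack([y[groups == g].mean(axis=0) for g in group_labels])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        k * sum(n_per_group[g] * (gm - grand) ** 2
                for g, gm in zip(group_labels, group_means))
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(n_subjects * ((time_means - grand) ** 2).sum())
    ss_inter = float(
        sum(
            n_per_group[g]
            * ((cell_means[i] - group_means[i] - time_means + grand) ** 2).sum()
            for i, g in enumerate(group_labels)
        )
    )
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_time - ss_inter

    df_group = (a - 1, n_subjects - a)
    df_time = (k - 1, (n_subjects - a) * (k - 1))
    df_inter = ((a - 1) * (k - 1), (n_subjects - a) * (k - 1))

    ms_group = ss_group / df_group[0]
    ms_subj = ss_subj_within / df_group[1]
    ms_time = ss_time / df_time[0]
    ms_inter = ss_inter / df_inter[0]
    ms_err = ss_err_within / df_time[1]

    f_group = ms_group / ms_subj if ms_subj > 0 else 0.0
    f_time = ms_time / ms_err if ms_err > 0 else 0.0
    f_inter = ms_inter / ms_err if ms_err > 0 else 0.0

    # pooled within-group covariance of the k time measures
    pooled = np.zeros((k, k))
    dof = 0
    for g in group_labels:
        yg = y[groups == g]
        pooled += (yg - yg.mean(axis=0)).T @ (yg - yg.mean(axis=0))
        dof += yg.shape[0] - 1
    eps = greenhouse_geisser_epsilon(pooled / dof)

    df_time_gg = (df_time[0] * eps, df_time[1] * eps)
    df_inter_gg = (df_inter[0] * eps, df_inter[1] * eps)

    def pval(f: float, d: tuple[float, float]) -> float:
        return float(sps.f.sf(f, d[0], d[1])) if f > 0 else 1.0

    return MixedAnovaResult(
        f_group=f_group,
        f_time=f_time,
        f_interaction=f_inter,
        df_group=tuple(map(float, df_group)),
        df_time=tuple(map(float, df_time)),
        df_interaction=tuple(map(float, df_inter)),
        epsilon_gg=eps,
        df_time_gg=df_time_gg,
        df_interaction_gg=df_inter_gg,
        p_group=pval(f_group, df_group),
        p_time=pval(f_time, df_time),
        p_interaction=pval(f_inter, df_inter),
        p_time_gg=pval(f_time, df_time_gg),
        p_interaction_gg=pval(f_inter, df_inter_gg),
        ss={
            "total": ss_total,
            "group": ss_group,
            "subject_within_group": ss_subj_within,
            "between_subjects": ss_between_subj,
            "time": ss_time,
            "interaction": ss_inter,
            "error_within": ss_err_within,
        },
    )


def simple_main_effects(
    table: pd.DataFrame,
    at,
    error: str = "per-timepoint",
    subject: str = "subject",
    group: str = "group",
    time: str = "time",
    value: str = "value",
) -> FResult:
    """Between-group F at one timepoint.

    ``error="per-timepoint"`` (default) is the one-way ANOVA at that
    time — for two groups F equals the square of the pooled t.
    ``error="omnibus"`` keeps the same numerator but tests it against
    the omnibus between-subjects error mean square and its df.
    """
    if error not in ("per-timepoint", "omnibus"):
        raise ValueError("error must be 'per-timepoint' or 'omnibus'")
    sub = table[table[time] == at]
    if sub.empty:
        raise ValueError(f"no rows at timepoint {at!r}")
    vals = [g[value].to_numpy(dtype=float) for _, g in sub.groupby(group, observed=True)]
    a = len(vals)
    if a < 2:
        raise ValueError("need >= 2 groups at the timepoint")
    grand = np.concatenate(vals).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    df1 = a - 1
    ms_between = ss_between / df1

    if error == "per-timepoint":
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
        df2 = sum(v.size for v in vals) - a
        ms_error = ss_within / df2
    else:
        omni = mixed_anova(table, subject=subject, group=group, time=time, value=value)
        df2 = omni.df_group[1]
        ms_error = omni.ss["subject_within_group"] / df2
    f = ms_between / ms_error if ms_error > 0 else 0.0
    p = float(sps.f.sf(f, df1, df2)) if f > 0 else 1.0
    return FResult(f=float(f), df1=float(df1), df2=float(df2), p=p)


# --------------------------------------------------------------------------
# Reference-table reproduction
# --------------------------------------------------------------------------

def load_reference_comparisons() -> pd.DataFrame:
    """The bundled table of reported db/+ vs db/db group comparisons.

    Twelve comparisons (OP amplitudes, retinal-layer morphometry, and
    respiration parameters), each as printed mean, SEM and n per group
    with the reported t-statistic and degrees of freedom.
    """
    ref = importlib.resources.files("ergflux.data") / "reference_comparisons.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def reproduce_reference_tests(
    table: pd.DataFrame | None = None, t_tol: float = REFERENCE_T_TOL
) -> pd.DataFrame:
    """Recompute every reference pooled t-test and compare to the report.

    Returns one row per comparison with the recomputed t and df, the
    absolute deviation ``delta_t`` from the reported t, and a ``passed``
    flag (|delta_t| <= ``t_tol`` and exact df match).
    """
    if table is None:
        table = load_reference_comparisons()
    rows = []
    for _, r in table.iterrows():
        g1 = GroupSummary(r["group1"], r["mean1"], r["sem1"], int(r["n1"]))
        g2 = GroupSummary(r["group2"], r["mean2"], r["sem2"], int(r["n2"]))
        res = pooled_t_from_summary(g1, g2)
        delta = abs(res.t - r["t_reported"])
        rows.append(
            {
                "label": r["label"],
                "t_recomputed": res.t,
                "t_reported": r["t_reported"],
                "delta_t": delta,
                "df_recomputed": int(res.df),
                "df_reported": int(r["df_reported"]),
                "p": res.p,
                "passed": bool(delta <= t_tol and int(res.df) == int(r["df_reported"])),
            }
        )
    return pd.DataFrame(rows)
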