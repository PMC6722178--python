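"""Group-level statistics for the posturographic outcome measures.

The analysis mirrors a conventional two-group posturography workflow:
Shapiro-Wilk normality gating with a log-transform fallback, a 2x2
mixed-design ANOVA (between factor: group, within factor: vision) with
partial eta-squared, independent t-tests (pooled, or Welch when the
equality-of-variances check fails) with Cohen's d, Mann-Whitney tests with
a tie-corrected normal-approximation z and eta-squared = z^2/N, chi-square
tests on baseline proportions, and a formatted baseline-characteristics
table.  Levene and Box M homogeneity diagnostics are computed and reported
but never gate the analysis automatically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GateDecision",
    "normality_gate",
    "mixed_anova_2x2",
    "two_group_test",
    "mann_whitney",
    "levene_test",
    "box_m_test",
    "baseline_table",
    "format_count",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    effect_size: float = float("nan")
    effect_label: str = ""
    transform_applied: bool = False
    group_summaries: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class GateDecision:
    route: str  # "parametric" | "log_transform" | "nonparametric"
    shapiro_p: dict
    reason: str = ""


def normality_gate(cells: dict[str, np.ndarray], alpha: float = 0.05) -> GateDecision:
    """Choose the analysis route from per-cell Shapiro-Wilk tests.

    All cells normal at ``alpha`` -> parametric.  Otherwise the data are
    log-transformed and re-tested; if the transform restores normality the
    log route is taken, else the nonparametric route.  Cells containing
    non-positive values cannot be log-transformed and fall through to the
    nonparametric route directly.
    """
    pvals = {}
    for label, v in cells.items():
        v = np.asarray(v, dtype=float)
        if len(v) < 3:
            raise ValueError(f"cell {label!r} has fewer than 3 values")
        pvals[label] = float(sps.shapiro(v).pvalue)
    if all(p >= alpha for p in pvals.values()):
        return GateDecision("parametric", pvals)
    if any(np.any(np.asarray(v, float) <= 0) for v in cells.values()):
        return GateDecision("nonparametric", pvals,
                            "non-normal cell and non-positive values "
                            "block the log transform")
    log_p = {lab: float(sps.shapiro(np.log(np.asarray(v, float))).pvalue)
             for lab, v in cells.items()}
    if all(p >= alpha for p in log_p.values()):
        return GateDecision("log_transform", log_p,
                            "normality restored by log transform")
    return GateDecision("nonparametric", log_p,
                        "non-normal after log transform")


def _partial_eta_sq(f: float, df1: float, df2: float) -> float:
    return f * df1 / (f * df1 + df2)


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    between: str = "group",
    within: str = "vision",
) -> dict[str, TestResult]:
    """2x2 mixed-design (split-plot) ANOVA by direct sums of squares.

    One between-subject factor and one within-subject factor, two levels
    each; every subject must provide both within-level values (incomplete
    subjects are dropped and noted).  Returns F, degrees of freedom, p and
    partial eta-squared (SS_effect / (SS_effect + SS_error of the effect's
    stratum)) for the between main effect, within main effect and their
    interaction.
    """
    df = data[[subject, between, within, dv]].dropna()
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    w_levels = sorted(df[within].unique())
    if len(w_levels) != 2:
        raise ValueError(f"within factor must have 2 levels, got {w_levels}")
    complete = wide.dropna()
    dropped = sorted(set(wide.index.get_level_values(0))
                     - set(complete.index.get_level_values(0)))
    groups = sorted(complete.index.get_level_values(1).unique())
    if len(groups) != 2:
        raise ValueError(f"between factor must have 2 levels, got {groups}")
    y = complete.to_numpy()  # (n_subjects, 2)
    g = complete.index.get_level_values(1).to_numpy()
    n_total = len(y)
    k = 2
    grand = y.mean()
    subj_means = y.mean(axis=1)

    ss_subj_tot = k * np.sum((subj_means - grand) ** 2)
    ss_group = k * sum(np.sum(g == gr) * (subj_means[g == gr].mean() - grand) ** 2
                       for gr in groups)
    ss_err_between = ss_subj_tot - ss_group
    ss_within_factor = n_total * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_cells = sum(np.sum(g == gr) * (y[g == gr, j].mean() - grand) ** 2
                   for gr in groups for j in range(k))
    ss_inter = ss_cells - ss_group - ss_within_factor
    ss_total = np.sum((y - grand) ** 2)
    ss_err_within = ss_total - ss_subj_tot - ss_within_factor - ss_inter

    df_err = n_total - 2
    note = (f"dropped incomplete subjects: {dropped}" if dropped else "")

    def result(name: str, ss_eff: float, ss_err: float) -> TestResult:
        if ss_err <= 1e-12 or df_err <= 0:
            # zero error variance: F is 0/0 (no effect) or unbounded
            if ss_eff <= 1e-12:
                return TestResult(name, 0.0, (1.0, float(df_err)), 1.0, 0.0,
                                  "partial_eta_sq",
                                  notes=note + " degenerate: zero error variance")
            return TestResult(name, float("inf"), (1.0, float(df_err)), 0.0,
                              1.0, "partial_eta_sq",
                              notes=note + " degenerate: zero error variance")
        f = (ss_eff / 1.0) / (ss_err / df_err)
        p = float(sps.f.sf(f, 1, df_err))
        return TestResult(name, float(f), (1.0, float(df_err)), p,
                          float(ss_eff / (ss_eff + ss_err)), "partial_eta_sq",
                          notes=note)

    return {
        between: result(f"mixed ANOVA: {between}", ss_group, ss_err_between),
        within: result(f"mixed ANOVA: {within}", ss_within_factor, ss_err_within),
        "interaction": result("mixed ANOVA: interaction", ss_inter, ss_err_within),
    }


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD; sign convention is group1 - group2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                   / (n1 + n2 - 2))
    if sp == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / sp)


def levene_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Levene's test (mean-centred) for equality of variances."""
    stat, p = sps.levene(x, y, center="mean")
    return TestResult("Levene", float(stat), (1.0, float(len(x) + len(y) - 2)),
                      float(p))


def box_m_test(y1: np.ndarray, y2: np.ndarray) -> TestResult:
    """Box's M test for equality of covariance matrices across two groups.

    ``y1``/``y2`` are (n_i, p) within-subject response matrices.  Uses the
    standard chi-square approximation.
    """
    mats = [np.asarray(y1, float), np.asarray(y2, float)]
    ns = [len(m) for m in mats]
    p = mats[0].shape[1]
    covs = [np.cov(m, rowvar=False, ddof=1) for m in mats]
    n_tot = sum(ns)
    g = len(mats)
    pooled = sum((n - 1) * c for n, c in zip(ns, covs)) / (n_tot - g)
    sign, logdet_p = np.linalg.slogdet(pooled)
    if sign <= 0:
        return TestResult("Box M", float("nan"), None, float("nan"),
                          notes="degenerate pooled covariance")
    m_stat = (n_tot - g) * logdet_p - sum(
        (n - 1) * np.linalg.slogdet(c)[0] for n, c in zip(ns, covs))
    c1 = ((2 * p**2 + 3 * p - 1) / (6 * (p + 1) * (g - 1))
          * (sum(1 / (n - 1) for n in ns) - 1 / (n_tot - g)))
    chi2 = m_stat * (1 - c1)
    df = p * (p + 1) * (g - 1) / 2
    return TestResult("Box M", float(chi2), float(df),
                      float(sps.chi2.sf(chi2, df)))


def _exact_u_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group labels."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        less = np.sum(a[:, None] < b[None, :])
        ties = np.sum(a[:, None] == b[None, :])
        return float(less + 0.5 * ties)

    count = total = 0
    d_obs = abs(u_obs - mu)
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= d_obs - 1e-12:
            count += 1
    return count / total


def mann_whitney(x: np.ndarray, y: np.ndarray,
                 exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney test with tie-corrected normal-approximation z.

    The reported U counts pairs in which the group-1 value is the smaller
    (plus half-ties), so U + U' = n1*n2 and identical groups give
    U = n1*n2/2 with z = 0.  The p-value is exact (full enumeration) for
    pooled n <= ``exact_max_n``, otherwise from the normal approximation.
    Effect size: eta-squared = z^2 / N.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    less = np.sum(x[:, None] < y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    u = float(less + 0.5 * ties)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = 0.0 if var == 0 else float((u - mu) / math.sqrt(var))
    if n <= exact_max_n:
        p = _exact_u_p(x, y, u)
        method = "exact enumeration"
    else:
        p = float(2 * sps.norm.sf(abs(z))) if var > 0 else 1.0
        method = "normal approximation, tie-corrected"
    return TestResult(
        "Mann-Whitney", u, None, min(1.0, p),
        effect_size=z**2 / n, effect_label="eta_sq",
        group_summaries={"median_1": float(np.median(x)),
                         "median_2": float(np.median(y)), "z": z},
        notes=method,
    )


def two_group_test(x: np.ndarray, y: np.ndarray, route: str = "auto",
                   alpha: float = 0.05) -> TestResult:
    """Independent two-group comparison along the gated route.

    ``route``: "parametric" (t-test; pooled df, switching to Welch when
    Levene rejects equality of variances), "log_transform" (t-test on
    log-values), "nonparametric" (Mann-Whitney), or "auto" to run
    :func:`normality_gate` first.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult("degenerate", float("nan"), None, float("nan"),
                          notes="constant data in both groups")
    gate_note = ""
    if route == "auto":
        if min(len(x), len(y)) < 3:
            route = "parametric"
            gate_note = "cells too small for normality gating; "
        else:
            route = normality_gate({"g1": x, "g2": y}, alpha).route
    if route == "nonparametric":
        return mann_whitney(x, y)
    transform = route == "log_transform"
    if transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log transform requires positive values")
        x, y = np.log(x), np.log(y)
    lev = levene_test(x, y)
    welch = bool(lev.p_value < alpha)
    res = sps.ttest_ind(x, y, equal_var=not welch)
    d = cohens_d(x, y)
    summaries = {
        "mean_1": float(x.mean()), "se_1": float(sps.sem(x)),
        "mean_2": float(y.mean()), "se_2": float(sps.sem(y)),
        "levene_p": lev.p_value,
    }
    name = "Welch t" if welch else "independent t"
    return TestResult(name, float(res.statistic), float(res.df),
                      float(res.pvalue), d, "cohens_d",
                      transform_applied=transform, group_summaries=summaries,
                      notes=gate_note + ("Welch correction applied "
                                         "(Levene p < alpha)" if welch else ""))


def format_count(k: int, n: int) -> str:
    """Format a proportion as ``"k (pct%)"`` with the percent rounded to int."""
    if n <= 0:
        raise ValueError("n must be positive")
    pct = int(math.floor(100.0 * k / n + 0.5))
    return f"{k} ({pct}%)"


def baseline_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table with between-group tests.

    Continuous fields (age, height, weight) are summarised as mean (SE) per
    group with a normality-gated t / Mann-Whitney p-value; sex is counted as
    women (percent) with a chi-square test (2x2, continuity-corrected).
    """
    required = {"group", "sex", "age", "height", "mass"}
    missing = required - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table lacks fields {sorted(missing)}")
    groups = sorted(subjects["group"].unique())
    if len(groups) != 2:
        raise ValueError("baseline table requires exactly two groups")
    g1 = subjects[subjects["group"] == groups[0]]
    g2 = subjects[subjects["group"] == groups[1]]
    rows = []
    rows.append({"characteristic": "Sample size", groups[0]: str(len(g1)),
                 groups[1]: str(len(g2)), "p_value": ""})
    labels = {"age": "Age (years)", "height": "Height (cm)",
              "mass": "Weight (kg)"}
    scale = {"age": 1.0, "height": 100.0, "mass": 1.0}
    for fieldname, label in labels.items():
        a = g1[fieldname].to_numpy(float) * scale[fieldname]
        b = g2[fieldname].to_numpy(float) * scale[fieldname]
        res = two_group_test(a, b)
        rows.append({
            "characteristic": label,
            groups[0]: f"{a.mean():.1f} ({sps.sem(a):.1f})",
            groups[1]: f"{b.mean():.1f} ({sps.sem(b):.1f})",
            "p_value": f"{res.p_value:.3f}",
        })
    w1 = int((g1["sex"] == "F").sum())
    w2 = int((g2["sex"] == "F").sum())
    table = np.array([[w1, len(g1) - w1], [w2, len(g2) - w2]])
    if table.min() >= 0 and table.sum(axis=1).min() > 0 and \
            0 < table[:, 0].sum() < table.sum():
        chi2 = sps.chi2_contingency(table, correction=True)
        p_sex = f"{chi2.pvalue:.3f}"
    else:
        p_sex = ""
    rows.append({"characteristic": "Number of women (%)",
                 groups[0]: format_count(w1, len(g1)),
                 groups[1]: format_count(w2, len(g2)),
                 "p_value": p_sex})
    return pd.DataFrame(rows)
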