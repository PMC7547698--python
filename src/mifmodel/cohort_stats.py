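"""Cohort-level statistical battery.

Mirrors the analyses applied to the 27-subject study: a bivariate
correlation screen between metabolites and outcomes, normality-gated
two-group comparisons, multiple (rank) regression of model parameters on
the Gln/Glu ratio and social context, a two-way interaction ANOVA on a
below/above-average Gln/Glu split, and a PCA dimensionality check of the
12 performance measures.

Normality is assessed with the Kolmogorov-Smirnov test in its
Lilliefors form (estimated mean/SD) at alpha = 0.05; non-normal
variables are routed to rank-based procedures (Spearman correlation,
Mann-Whitney U, rank regression, rank ANOVA).  No multiple-testing
correction is applied by default, mirroring the original reporting; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import kstest_normal
from statsmodels.stats.multitest import multipletests

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class StatReport:
    """One test result in a uniform shape."""

    analysis: str
    term: str
    statistic: float
    p: float
    n: int
    method: str
    rank_based: bool = False
    two_sided: bool = True
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "analysis": self.analysis,
            "term": self.term,
            "statistic": self.statistic,
            "p": self.p,
            "n": self.n,
            "method": self.method,
        }


def reports_frame(reports: Sequence[StatReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def is_normal(x, alpha: float = NORMALITY_ALPHA) -> bool:
    """Lilliefors-corrected KS normality check."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return False
    _, p = kstest_normal(x, dist="norm")
    return p > alpha


def correlation_screen(
    table: pd.DataFrame,
    x_vars: Sequence[str],
    y_vars: Sequence[str],
    adjust: bool = False,
) -> list:
    """All-pairs correlations between metabolite and outcome columns.

    Pearson by default; Spearman when either variable fails normality.
    Constant columns are flagged (NaN statistic) rather than crashed on.
    ``adjust=True`` applies Benjamini-Hochberg across the screen.
    """
    reports = []
    for xv in x_vars:
        for yv in y_vars:
            sub = table[[xv, yv]].dropna()
            n = len(sub)
            if n < 3:
                raise ValueError(f"need n >= 3 for {xv} vs {yv}")
            x, y = sub[xv].to_numpy(), sub[yv].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                reports.append(
                    StatReport("correlation", f"{xv}~{yv}", np.nan, np.nan, n,
                               "constant-column")
                )
                continue
            if is_normal(x) and is_normal(y):
                r, p = stats.pearsonr(x, y)
                method, rank = "pearson", False
            else:
                r, p = stats.spearmanr(x, y)
                method, rank = "spearman", True
            reports.append(
                StatReport("correlation", f"{xv}~{yv}", float(r), float(p), n,
                           method, rank_based=rank)
            )
    if adjust:
        ps = [r.p for r in reports if np.isfinite(r.p)]
        adj = iter(multipletests([p for p in ps], method="fdr_bh")[1])
        out = []
        for r in reports:
            if np.isfinite(r.p):
                out.append(StatReport(r.analysis, r.term, r.statistic,
                                      float(next(adj)), r.n, r.method + "+bh",
                                      r.rank_based))
            else:
                out.append(r)
        reports = out
    return reports


def two_sample_t_summary(m1, sd1, n1, m2, sd2, n2):
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, p) with df = n1 + n2 - 2; used to check group contrasts
    against published mean/SD tables.
    """
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def group_compare(values, groups, analysis: str = "group_compare") -> StatReport:
    """Two-group contrast with a normality gate.

    Pooled-variance Student t when the pooled sample passes the KS
    (Lilliefors) normality check, Mann-Whitney U otherwise; for the
    rank test the statistic reported is the rank sum of the first group,
    alongside U in ``extra``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    n = len(values)
    if is_normal(values):
        res = stats.ttest_ind(a, b, equal_var=True)
        extra = {
            "mean_sd": {
                str(labels[0]): (float(a.mean()), float(a.std(ddof=1))),
                str(labels[1]): (float(b.mean()), float(b.std(ddof=1))),
            }
        }
        return StatReport(analysis, f"{labels[0]} vs {labels[1]}",
                          float(res.statistic), float(res.pvalue), n,
                          "student_t_pooled", extra=extra)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    ranksum = float(res.statistic + len(a) * (len(a) + 1) / 2)
    extra = {
        "U": float(res.statistic),
        "median_iqr": {
            str(labels[0]): (float(np.median(a)), float(np.subtract(*np.percentile(a, [75, 25])))),
            str(labels[1]): (float(np.median(b)), float(np.subtract(*np.percentile(b, [75, 25])))),
        },
    }
    return StatReport(analysis, f"{labels[0]} vs {labels[1]}", ranksum,
                      float(res.pvalue), n, "mann_whitney_u", rank_based=True,
                      extra=extra)


def _code_group(groups) -> np.ndarray:
    """Social context coded -1 (isolation) / +1 (competition)."""
    groups = np.asarray(groups)
    return np.where(groups == "competition", 1.0, -1.0)


def ratio_regressions(
    table: pd.DataFrame,
    ratio: str,
    outcome: str,
    group: str = "group",
    interaction: bool = False,
) -> list:
    """OLS of a model parameter on (ratio, group[, ratio x group]).

    The group is coded -1/+1; the outcome is rank-transformed (rank
    regression) when it fails the normality gate.  Returns one
    StatReport per coefficient, with signed coefficients in ``extra``.
    """
    sub = table[[ratio, outcome, group]].dropna()
    if len(sub) < 5:
        raise ValueError("need n >= 5 for regression")
    x = sub[ratio].to_numpy(dtype=float)
    g = _code_group(sub[group])
    if np.ptp(x) == 0:
        raise ValueError("ratio column is constant")
    y = sub[outcome].to_numpy(dtype=float)
    rank = not is_normal(y)
    if rank:
        y = stats.rankdata(y)
    cols = {"const": np.ones_like(x), ratio: x, group: g}
    if interaction:
        cols[f"{ratio}:{group}"] = x * g
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    method = ("rank_" if rank else "") + "ols"
    reports = []
    for term in X.columns:
        if term == "const":
            continue
        reports.append(
            StatReport(f"regression[{outcome}]", term,
                       float(fit.tvalues[term]), float(fit.pvalues[term]),
                       len(sub), method, rank_based=rank,
                       extra={"coef": float(fit.params[term])})
        )
    return reports


def interaction_anova(
    table: pd.DataFrame,
    outcome: str,
    group: str = "group",
    ratio: str = "gln_glu",
    rank_flag: bool = False,
) -> list:
    """Two-way ANOVA with interaction on a 2x2 group x ratio-split design.

    Subjects are split at the cohort-mean Gln/Glu ratio; Type-II sums of
    squares accommodate the unbalanced cells.  When ``rank_flag`` the
    outcome is rank-transformed first.  Follow-up pooled t tests of the
    group contrast within each ratio stratum are appended.
    """
    sub = table[[outcome, group, ratio]].dropna().copy()
    sub["ratio_split"] = np.where(
        sub[ratio] >= sub[ratio].mean(), "high", "low"
    )
    cells = sub.groupby([group, "ratio_split"]).size()
    if len(cells) < 4 or cells.min() < 2:
        raise ValueError("each of the 4 design cells needs n >= 2")
    y = sub[outcome].to_numpy(dtype=float)
    if rank_flag:
        y = stats.rankdata(y)
    d = pd.DataFrame(
        {"y": y, "g": sub[group].to_numpy(), "r": sub["ratio_split"].to_numpy()}
    )
    if np.ptp(y) == 0:
        terms = ["g", "r", "g:r"]
        reports = [
            StatReport(f"anova[{outcome}]", t, 0.0, 1.0, len(d),
                       "anova2_typeII", rank_based=rank_flag)
            for t in terms
        ]
        return reports
    fit = smf.ols("y ~ C(g) * C(r)", data=d).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    mapping = {"C(g)": group, "C(r)": "ratio_split", "C(g):C(r)": f"{group}:ratio_split"}
    reports = [
        StatReport(f"anova[{outcome}]", mapping[idx], float(row["F"]),
                   float(row["PR(>F)"]), len(d), "anova2_typeII",
                   rank_based=rank_flag)
        for idx, row in tab.iterrows()
        if idx in mapping
    ]
    for stratum in ("low", "high"):
        s = d[d.r == stratum]
        a = s[s.g == s.g.unique()[0]].y.to_numpy()
        b = s[s.g == s.g.unique()[1]].y.to_numpy() if s.g.nunique() == 2 else None
        if b is None or len(a) < 2 or len(b) < 2:
            continue
        res = stats.ttest_ind(a, b, equal_var=True)
        reports.append(
            StatReport(f"anova[{outcome}]", f"{group}@{stratum}",
                       float(res.statistic), float(res.pvalue), len(s),
                       "followup_t", rank_based=rank_flag)
        )
    return reports


def pm_pca(pms, correlation: bool = False):
    """Variance explained by the principal components of the 12 PMs.

    Eigen-decomposition of the column-centered covariance matrix of the
    n x 12 PM matrix (or the correlation matrix when ``correlation``).
    Returns (explained, cumulative): each length 12, eigenvalue shares in
    descending order (zero eigenvalues retained for rank-deficient
    input).
    """
    mat = np.stack(
        [
            p.flat() if callable(getattr(p, "flat", None))
            else np.asarray(p, dtype=float).ravel()
            for p in pms
        ]
    )
    if mat.shape[0] < 6:
        raise ValueError("need at least 6 subjects for the PCA check")
    x = mat - mat.mean(axis=0)
    if correlation:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    cov = (x.T @ x) / (mat.shape[0] - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    explained = eig / total if total > 0 else np.zeros_like(eig)
    return explained, np.cumsum(explained)
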