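"""Group-comparison statistics for per-kidney metric tables.

The battery mirrors standard practice for small-n developmental
morphometry: Shapiro–Wilk normality and Brown–Forsythe
(median-centered Levene) equality-of-variance checks pick between the
classical and the heteroscedasticity-robust path; one-way ANOVA or
Welch's ANOVA compares >= 3 groups, pooled or Welch t-tests compare two;
Bonferroni or Tamhane T2 (pairwise Welch t with a Šidák-type
familywise adjustment) handle the pairwise comparisons.  Significance
tiers use the conventional 4-star thresholds
(*: p<0.0332, **: p<0.0021, ***: p<0.0002, ****: p<0.0001).

The F/W/t statistics are computed from the sum-of-squares formulas
directly; tests cross-check them against scipy/pingouin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetricTable",
    "AssumptionReport",
    "GroupComparisonResult",
    "significance_tier",
    "check_assumptions",
    "one_way_anova",
    "welch_anova",
    "posthoc",
    "two_sample_t",
    "fold_change",
    "load_metric_table",
]

#: column schema of the per-kidney metric table
TABLE_COLUMNS = ("kidney_id", "group", "metric", "value")

#: the 4-tier significance convention used in the figure legends
TIER_THRESHOLDS = ((0.0001, "****"), (0.0002, "***"), (0.0021, "**"), (0.0332, "*"))


def significance_tier(p: float) -> str:
    for threshold, stars in TIER_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


class MetricTable:
    """Per-kidney long-format table: one row per (kidney, metric)."""

    def __init__(self, df: pd.DataFrame):
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"metric table missing columns {sorted(missing)}")
        values = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("metric table contains non-finite values")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[Tuple]) -> "MetricTable":
        return cls(pd.DataFrame(records, columns=list(TABLE_COLUMNS)))

    def groups(self, metric: str) -> Dict[str, np.ndarray]:
        sub = self.df[self.df["metric"] == metric]
        if sub.empty:
            raise KeyError(f"no rows for metric {metric!r}")
        return {
            str(g): grp["value"].to_numpy(dtype=float)
            for g, grp in sub.groupby("group", sort=False)
        }

    def metrics(self) -> List[str]:
        return list(dict.fromkeys(self.df["metric"]))


def load_metric_table(path, column_map: Optional[Dict[str, str]] = None) -> MetricTable:
    """Read a metric table from CSV or spreadsheet (.xlsx/.xls).

    ``column_map`` maps source column names onto the canonical schema
    ``(kidney_id, group, metric, value)``, which lets deposited
    source-data spreadsheets be ingested once their layout is known.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return MetricTable(df[list(TABLE_COLUMNS)])


# ---------------------------------------------------------------------------
# assumption checks


@dataclass
class AssumptionReport:
    shapiro: Dict[str, Tuple[Optional[float], Optional[float]]]  # group -> (W, p)
    brown_forsythe: Tuple[float, float]  # (statistic, p)
    recommend_welch: bool
    warnings: List[str] = field(default_factory=list)


def check_assumptions(table: MetricTable, metric: str, alpha: float = 0.05) -> AssumptionReport:
    """Shapiro–Wilk per group plus Brown–Forsythe across groups.

    Groups with n < 3 skip Shapiro–Wilk with a warning.  The Welch path
    is recommended when Brown–Forsythe rejects equality of variances.
    """
    groups = table.groups(metric)
    shapiro: Dict[str, Tuple[Optional[float], Optional[float]]] = {}
    warnings: List[str] = []
    for name, values in groups.items():
        if len(values) < 3:
            warnings.append(f"group {name!r} has n={len(values)} < 3: Shapiro–Wilk skipped")
            shapiro[name] = (None, None)
        else:
            w, p = sps.shapiro(values)
            shapiro[name] = (float(w), float(p))
    bf_stat, bf_p = sps.levene(*groups.values(), center="median")
    return AssumptionReport(
        shapiro=shapiro,
        brown_forsythe=(float(bf_stat), float(bf_p)),
        recommend_welch=bool(bf_p < alpha),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# omnibus tests


@dataclass
class GroupComparisonResult:
    statistic_name: str  # "F", "W", "t", "t_welch"
    statistic: float
    df: Tuple[float, float]
    p_value: float
    assumption_report: Optional[AssumptionReport] = None
    posthoc: Optional[pd.DataFrame] = None

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)


def _group_arrays(table: MetricTable, metric: str, min_n: int = 2) -> Dict[str, np.ndarray]:
    groups = table.groups(metric)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if len(v) < min_n:
            raise ValueError(f"group {name!r} has n={len(v)} < {min_n}")
    return groups


def one_way_anova(table: MetricTable, metric: str) -> GroupComparisonResult:
    """Classical one-way ANOVA from the sum-of-squares decomposition."""
    groups = _group_arrays(table, metric)
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(values)
    n_total = sum(len(v) for v in values)
    grand = np.concatenate(values).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    df1, df2 = k - 1, n_total - k
    if df2 <= 0 or ssw == 0 and ssb == 0:
        raise ValueError("degenerate groups for ANOVA")
    f = (ssb / df1) / (ssw / df2) if ssw > 0 else np.inf
    p = float(sps.f.sf(f, df1, df2))
    return GroupComparisonResult("F", float(f), (float(df1), float(df2)), p)


def welch_anova(table: MetricTable, metric: str) -> GroupComparisonResult:
    """Welch's heteroscedasticity-robust one-way ANOVA (W statistic)."""
    groups = _group_arrays(table, metric)
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(values)
    n = np.array([len(v) for v in values], dtype=float)
    m = np.array([v.mean() for v in values])
    s2 = np.array([v.var(ddof=1) for v in values])
    if np.any(s2 == 0):
        raise ValueError("Welch ANOVA undefined for a zero-variance group")
    w = n / s2
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    numerator = ((w * (m - m_w) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / w_sum) ** 2 / (n - 1)).sum() / (k ** 2 - 1)
    statistic = numerator / (1 + 2 * lam * (k - 2) / 3)
    df1 = k - 1
    df2 = 1.0 / lam if lam > 0 else np.inf
    p = float(sps.f.sf(statistic, df1, df2))
    return GroupComparisonResult("W", float(statistic), (float(df1), float(df2)), p)


def _welch_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def _pooled_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, float]:
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def two_sample_t(table: MetricTable, metric: str, welch: bool = False) -> GroupComparisonResult:
    """Unpaired two-group t-test, pooled-variance or Welch-corrected."""
    groups = _group_arrays(table, metric)
    if len(groups) != 2:
        raise ValueError(f"t-test needs exactly two groups, got {len(groups)}")
    a, b = (np.asarray(v, dtype=float) for v in groups.values())
    if welch:
        t, df, p = _welch_t(a, b)
        name = "t_welch"
    else:
        t, df, p = _pooled_t(a, b)
        name = "t"
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    return GroupComparisonResult(name, t, (1.0, float(df)), p)


# ---------------------------------------------------------------------------
# post-hoc pairwise comparisons


def posthoc(
    table: MetricTable,
    metric: str,
    method: str = "bonferroni",
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Pairwise comparisons with familywise adjustment.

    ``bonferroni``: pairwise pooled t with adjusted p = min(1, p·m).
    ``tamhane_t2``: pairwise Welch t with the conservative Šidák-type
    adjustment 1 − (1 − p)^m; the matching post hoc for the Welch path.
    The family is all pairs unless ``pairs`` restricts it; the family
    size m is always reported.
    """
    if method not in {"bonferroni", "tamhane_t2"}:
        raise ValueError(f"unknown post-hoc method {method!r}")
    groups = _group_arrays(table, metric)
    if pairs is None:
        pairs = list(itertools.combinations(groups.keys(), 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        a, b = np.asarray(groups[ga], float), np.asarray(groups[gb], float)
        if method == "bonferroni":
            t, df, p = _pooled_t(a, b)
            p_adj = min(1.0, p * m)
        else:
            t, df, p = _welch_t(a, b)
            p_adj = 1.0 - (1.0 - p) ** m
        p_adj = max(p_adj, p)  # an adjustment never helps
        rows.append((ga, gb, t, df, p, p_adj, significance_tier(p_adj), m))
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "statistic", "df", "p_raw", "p_adj", "tier", "m"],
    )


def fold_change(
    table: MetricTable, metric: str, baseline_group: str, target_group: str
) -> float:
    """Ratio of group means, target over baseline."""
    groups = table.groups(metric)
    baseline = np.asarray(groups[baseline_group], float).mean()
    if baseline == 0:
        raise ValueError("baseline group mean is zero")
    return float(np.asarray(groups[target_group], float).mean() / baseline)


def compare_groups(
    table: MetricTable, metric: str, alpha: float = 0.05,
    force_welch: Optional[bool] = None,
) -> GroupComparisonResult:
    """Assumption-guided comparison for one metric.

    Two groups get a t-test (Welch when Brown–Forsythe rejects equal
    variances), three or more get classical or Welch's ANOVA with the
    matching post hoc (Bonferroni / Tamhane T2).  ``force_welch``
    overrides the automatic path selection.
    """
    report = check_assumptions(table, metric, alpha)
    welch = report.recommend_welch if force_welch is None else force_welch
    groups = table.groups(metric)
    if len(groups) == 2:
        result = two_sample_t(table, metric, welch=welch)
    elif welch:
        result = welch_anova(table, metric)
        result.posthoc = posthoc(table, metric, "tamhane_t2")
    else:
        result = one_way_anova(table, metric)
        result.posthoc = posthoc(table, metric, "bonferroni")
    result.assumption_report = report
    return result
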