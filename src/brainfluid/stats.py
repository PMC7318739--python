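"""Group statistics layer.

Mirrors the conventional small-cohort analysis stack of a two-strain animal
study:

* each measurement is gated per group through Shapiro–Wilk normality; both
  groups normal -> unpaired Student's t test, otherwise Mann–Whitney U;
* gross outliers in the region-wise capillary AQP4 tables are screened with
  an iterative two-sided Grubbs test at alpha = 0.05;
* region-resolved measurements are analysed with a two-way ANOVA
  (strain x region, Type-II sums of squares for the mildly unbalanced 11 vs
  10 design) followed by strain-within-region comparisons on the pooled
  residual variance, Bonferroni-corrected over the number of regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StatsResult",
    "TwoWayAnovaResult",
    "normality_gate",
    "compare_groups",
    "grubbs_critical_value",
    "grubbs_filter",
    "two_way_anova_bonferroni",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class StatsResult:
    """Outcome of a gated two-group comparison (mean ± SEM convention)."""

    test: str  # "student-t" or "mann-whitney"
    statistic: float
    p_value: float
    groups: Mapping[str, GroupSummary]
    normality_p: Mapping[str, float]
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        object.__setattr__(self, "significant", bool(self.p_value < ALPHA))


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    return groups


def normality_gate(values_by_group: Mapping[str, Sequence[float]], alpha: float = ALPHA) -> str:
    """Choose the test route: ``"parametric"`` iff both groups pass Shapiro–Wilk."""
    groups = _as_groups(values_by_group)
    for name, x in groups.items():
        if x.size < 3:
            raise ValueError(f"group {name!r} has n={x.size} < 3; Shapiro–Wilk needs n >= 3")
    ps = {name: _shapiro_p(x) for name, x in groups.items()}
    return "parametric" if all(p > alpha for p in ps.values()) else "nonparametric"


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is treated as failing normality
    return float(sps.shapiro(x).pvalue)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    route: str | None = None,
) -> StatsResult:
    """Two-sided two-group comparison on the gated route.

    ``route`` is normally decided by :func:`normality_gate`; passing it
    explicitly pins the test (useful when reproducing a published choice).
    """
    groups = _as_groups(values_by_group)
    if route is None:
        route = normality_gate(values_by_group)
    if route not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown route {route!r}")
    (na, xa), (nb, xb) = groups.items()

    if route == "parametric":
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] != xb[0]:
            raise ValueError("degenerate zero-variance input on the parametric route")
        if np.array_equal(np.sort(xa), np.sort(xb)):
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(xa, xb, equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "student-t"
    else:
        if np.array_equal(np.sort(xa), np.sort(xb)):
            stat, p = float(xa.size * xb.size / 2.0), 1.0
        else:
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney"

    summaries = {
        name: GroupSummary(n=int(x.size), mean=float(x.mean()), sem=float(sps.sem(x)))
        for name, x in groups.items()
    }
    normality = {name: _shapiro_p(x) for name, x in groups.items()}
    return StatsResult(test=test, statistic=stat, p_value=p, groups=summaries, normality_p=normality)


def grubbs_critical_value(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value for ``G = max|x - mean| / sd`` at level alpha."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Sequence[float], alpha: float = ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier screen.

    One point — the largest absolute deviation from the mean — is tested per
    pass and removed if ``G`` exceeds the critical value; passes repeat until
    no rejection or fewer than three points remain.

    Returns ``(kept, removed)`` as float arrays (kept preserves input order).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Grubbs test undefined for zero-variance data")
    keep = np.ones(x.size, dtype=bool)
    removed: list[float] = []
    while keep.sum() >= 3:
        cur = x[keep]
        sd = cur.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(cur - cur.mean())
        i_rel = int(np.argmax(dev))
        g = dev[i_rel] / sd
        if g <= grubbs_critical_value(cur.size, alpha):
            break
        i_abs = np.flatnonzero(keep)[i_rel]
        keep[i_abs] = False
        removed.append(float(x[i_abs]))
    return x[keep], np.asarray(removed)


@dataclass
class TwoWayAnovaResult:
    """ANOVA table plus Bonferroni-corrected strain-within-region post hocs."""

    anova: pd.DataFrame  # index: factor terms; columns: sum_sq, df, F, PR(>F)
    posthoc: pd.DataFrame  # one row per region
    residual_df: float
    mse: float


def two_way_anova_bonferroni(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "strain",
    cell: str = "region",
) -> TwoWayAnovaResult:
    """Two-way ANOVA (group x cell) with Bonferroni post hoc group comparisons.

    Post hoc comparisons are unpaired two-sample t tests within each cell,
    with p-values multiplied by the number of cells (regions). Using the
    within-cell variance rather than the model's pooled residual keeps the
    comparisons correctly sized when cells are heteroscedastic (perivascular
    AUC spread scales with the cell mean).

    With a single cell the model degenerates to a one-way ANOVA on ``group``,
    whose F equals the squared two-sample t statistic.
    """
    df = table[[group, cell, value]].dropna().copy()
    df.columns = ["g", "c", "y"]
    counts = df.groupby(["g", "c"], observed=True).size().unstack()
    if counts.isna().any().any() or (counts < 2).any().any():
        raise ValueError("every (group, cell) combination needs at least two observations")
    cells = list(counts.columns)

    if len(cells) > 1:
        model = smf.ols("y ~ C(g) * C(c)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    else:
        model = smf.ols("y ~ C(g)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    resid_df = float(model.df_resid)
    mse = float(model.ssr / model.df_resid)

    g_names = sorted(df["g"].unique())
    rows = []
    for c in cells:
        sub = df[df["c"] == c]
        x1 = sub.loc[sub["g"] == g_names[0], "y"].to_numpy()
        x2 = sub.loc[sub["g"] == g_names[1], "y"].to_numpy()
        diff = x1.mean() - x2.mean()
        res = sps.ttest_ind(x1, x2, equal_var=True)
        t, p_raw = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, p_raw * len(cells))
        rows.append(
            {
                cell: c,
                f"mean_{g_names[0]}": x1.mean(),
                f"mean_{g_names[1]}": x2.mean(),
                "diff": diff,
                "t": t,
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "significant": p_adj < ALPHA,
            }
        )
    posthoc = pd.DataFrame(rows)
    return TwoWayAnovaResult(anova=anova, posthoc=posthoc, residual_df=resid_df, mse=mse)
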