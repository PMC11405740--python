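"""Two-cluster comparison machinery: normality-gated tests and effect sizes.

For each variable and segment the two cluster samples are routed through a
Shapiro-Wilk gate: if both pass at ``alpha_normality`` the comparison is a
two-sided Student's t-test (pooled variance) reported with Cohen's d, its
confidence interval and the point-biserial correlation r; otherwise a
two-sided Mann-Whitney U reported with the rank-biserial correlation (RBC)
and the common-language effect size (CLES).

Orientation convention, stated on every output row: effects describe group
1 relative to group 0 — CLES is the probability that a random group-1
value exceeds a random group-0 value (ties counted half), RBC = 2*CLES - 1,
d = (mean1 - mean0) / pooled SD.  The normative definition of CLES is the
pairwise enumeration; the U-statistic identity is used for speed and is
checked against enumeration in the test suite.

Headline p-values are uncorrected (one test per variable x segment, as is
conventional for these level-wise report tables); Benjamini-Hochberg
adjusted columns are appended alongside, never substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sst

from pupilclust.schedule import TaskSchedule

logger = logging.getLogger(__name__)

DIRECTION_NOTE = "group 1 relative to group 0"


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    segment: tuple
    n0: int
    n1: int
    test: str                 # student_t | mann_whitney | chi_square
    statistic: float
    p_value: float
    d: float = np.nan
    d_ci_low: float = np.nan
    d_ci_high: float = np.nan
    r: float = np.nan
    r_ci_low: float = np.nan
    r_ci_high: float = np.nan
    rbc: float = np.nan
    cles: float = np.nan
    mean0: float = np.nan
    sd0: float = np.nan
    mean1: float = np.nan
    sd1: float = np.nan
    direction: str = DIRECTION_NOTE

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if np.isfinite(self.cles) and not 0.0 <= self.cles <= 1.0:
            raise ValueError("CLES outside [0, 1]")
        if np.isfinite(self.rbc) and not -1.0 <= self.rbc <= 1.0:
            raise ValueError("RBC outside [-1, 1]")


def cohens_d(x0, x1, ci_level: float = 0.95,
             noncentral: bool = False) -> tuple[float, tuple[float, float]]:
    """Cohen's d of group 1 relative to group 0, with a confidence interval.

    Pooled SD uses the n0 + n1 - 2 denominator.  The default CI comes from
    the large-sample normal approximation of the sampling variance of d,
    var(d) = (n0+n1)/(n0*n1) + d^2 / (2*(n0+n1-2)); a noncentral-t interval
    is available behind the flag.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n0, n1 = len(x0), len(x1)
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 observations per group")
    dof = n0 + n1 - 2
    pooled_var = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / dof
    if pooled_var == 0:
        raise ValueError("zero pooled SD: d undefined")
    d = (x1.mean() - x0.mean()) / np.sqrt(pooled_var)
    if noncentral:
        nc = d * np.sqrt(n0 * n1 / (n0 + n1))
        alpha = 1 - ci_level
        lo_nc = sst.nct.ppf(alpha / 2, dof, nc)
        hi_nc = sst.nct.ppf(1 - alpha / 2, dof, nc)
        scale = np.sqrt((n0 + n1) / (n0 * n1))
        ci = (lo_nc * scale, hi_nc * scale)
    else:
        se = np.sqrt((n0 + n1) / (n0 * n1) + d**2 / (2 * dof))
        z = sst.norm.ppf(0.5 + ci_level / 2)
        ci = (d - z * se, d + z * se)
    return float(d), (float(ci[0]), float(ci[1]))


def rank_effects(x0, x1) -> tuple[float, float, float]:
    """(U statistic, RBC, CLES) for group 1 relative to group 0.

    CLES = [#(x1 > x0 pairs) + 0.5 * #ties] / (n0 * n1), computed through
    the rank-sum identity U1 = R1 - n1*(n1+1)/2 with midranks, which equals
    the pairwise enumeration exactly (including ties).  RBC = 2*CLES - 1.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n0, n1 = len(x0), len(x1)
    if n0 < 1 or n1 < 1:
        raise ValueError("both groups must be non-empty")
    ranks = sst.rankdata(np.concatenate([x0, x1]))
    r1 = ranks[n0:].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0        # number of (x1 > x0) wins + half-ties
    cles = u1 / (n0 * n1)
    rbc = 2.0 * cles - 1.0
    return float(u1), float(rbc), float(cles)


def _point_biserial_ci(r: float, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    # Fisher z-transform interval
    r = np.clip(r, -0.999999, 0.999999)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sst.norm.ppf(0.5 + ci_level / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def compare_groups(x0, x1, variable: str = "", segment: tuple = (),
                   alpha_normality: float = 0.05,
                   welch: bool = False) -> ComparisonResult:
    """Normality-gated two-group comparison with effect sizes.

    Both groups normal by Shapiro-Wilk -> Student's t (pooled variance;
    Welch behind the flag) with d, d CI and point-biserial r; otherwise a
    two-sided Mann-Whitney U.  Rank effects (RBC, CLES) are reported for
    both branches; d is reported whenever the pooled SD is positive.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x0 = x0[np.isfinite(x0)]
    x1 = x1[np.isfinite(x1)]
    n0, n1 = len(x0), len(x1)
    if n0 < 3 or n1 < 3:
        raise ValueError("need at least 3 observations per group")

    degenerate = np.ptp(x0) == 0 or np.ptp(x1) == 0
    if degenerate:
        logger.info("%s %s: constant group values, forcing nonparametric branch", variable, segment)
        normal = False
    else:
        normal = (sst.shapiro(x0).pvalue > alpha_normality
                  and sst.shapiro(x1).pvalue > alpha_normality)

    u_stat, rbc, cles = rank_effects(x0, x1)
    try:
        d, (d_lo, d_hi) = cohens_d(x0, x1)
    except ValueError:
        d = d_lo = d_hi = np.nan

    if normal:
        res = sst.ttest_ind(x1, x0, equal_var=not welch)
        t = float(res.statistic)
        dof = n0 + n1 - 2
        r = t / np.sqrt(t**2 + dof) if np.isfinite(t) else np.nan
        r_lo, r_hi = _point_biserial_ci(r, n0 + n1) if np.isfinite(r) else (np.nan, np.nan)
        test, statistic, p = "student_t", t, float(res.pvalue)
    else:
        res = sst.mannwhitneyu(x1, x0, alternative="two-sided")
        test, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)
        r = r_lo = r_hi = np.nan

    return ComparisonResult(
        variable=variable, segment=segment, n0=n0, n1=n1,
        test=test, statistic=statistic, p_value=p,
        d=d, d_ci_low=d_lo, d_ci_high=d_hi,
        r=float(r) if np.isfinite(r) else np.nan, r_ci_low=r_lo, r_ci_high=r_hi,
        rbc=rbc, cles=cles,
        mean0=float(x0.mean()), sd0=float(x0.std(ddof=1)),
        mean1=float(x1.mean()), sd1=float(x1.std(ddof=1)),
    )


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df = 1) on a 2x2 count table.

    Continuity correction off by default; enable with ``yates``.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, dof, expected = sst.chi2_contingency(table, correction=yates)
    if (expected <= 0).any():
        raise ValueError("expected counts must all be positive")
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def _results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results])
    if len(df):
        # BH-adjusted p-values appended per metric family; headline p stays raw
        df["p_bh"] = np.nan
        for var, idx in df.groupby("variable").groups.items():
            p = df.loc[idx, "p_value"].to_numpy()
            order = np.argsort(p)
            m = len(p)
            adj = np.empty(m)
            prev = 1.0
            for rank_i, j in enumerate(order[::-1]):
                k = m - rank_i
                prev = min(prev, p[j] * m / k)
                adj[j] = prev
            df.loc[idx, "p_bh"] = adj
    return df


def _iter_comparisons(metrics: pd.DataFrame, labels: pd.DataFrame, by: list[str],
                      min_fraction: float = 0.5) -> list[ComparisonResult]:
    merged = metrics.merge(labels, on="participant", how="inner")
    n_by_cluster = labels["cluster"].value_counts()
    results = []
    for (metric, *seg), sub in merged.groupby(["metric"] + by, sort=True):
        x0 = sub.loc[sub["cluster"] == 0, "value"].to_numpy(dtype=float)
        x1 = sub.loc[sub["cluster"] == 1, "value"].to_numpy(dtype=float)
        x0, x1 = x0[np.isfinite(x0)], x1[np.isfinite(x1)]
        if (len(x0) < max(3, min_fraction * n_by_cluster.get(0, 0))
                or len(x1) < max(3, min_fraction * n_by_cluster.get(1, 0))):
            logger.info("skipping %s %s: insufficient data (%d, %d)", metric, seg, len(x0), len(x1))
            continue
        results.append(compare_groups(x0, x1, variable=metric, segment=tuple(int(s) for s in seg)))
    return results


def report_levels(metrics: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """One comparison row per metric x (block, level).

    ``metrics`` is long-format (participant, block, level, metric, value);
    ``labels`` maps participant -> aligned cluster (0/1).  Rows where more
    than half of a cluster is missing the metric are skipped and logged.
    """
    return _results_frame(_iter_comparisons(metrics, labels, by=["block", "level"]))


def report_blocks(metrics: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """One comparison row per metric x block.

    A participant's block value is the mean of their level values within
    the block; the cluster comparison then runs on those participant-level
    block values.
    """
    block_vals = (metrics.groupby(["participant", "block", "metric"], sort=True)["value"]
                  .mean().reset_index())
    return _results_frame(_iter_comparisons(block_vals, labels, by=["block"]))


def peak_reactions(metrics: pd.DataFrame, labels: pd.DataFrame,
                   schedule: TaskSchedule) -> pd.DataFrame:
    """Extreme segments of each cluster's mean metric profile.

    For every cluster and metric: the (block, level) of the maximum and
    minimum cluster mean, flagged when the extremum falls in a deceptive
    cell; exact ties resolve to the earliest segment and set ``tie``.
    """
    merged = metrics.merge(labels, on="participant", how="inner")
    cell_means = (merged.groupby(["cluster", "metric", "block", "level"], sort=True)["value"]
                  .mean().reset_index())
    rows = []
    for (cluster, metric), sub in cell_means.groupby(["cluster", "metric"], sort=True):
        sub = sub.sort_values(["block", "level"]).reset_index(drop=True)
        vals = sub["value"].to_numpy()
        if not np.isfinite(vals).any():
            continue
        for kind, pick in (("max", np.nanargmax), ("min", np.nanargmin)):
            i = int(pick(vals))
            extremum = vals[i]
            tie = bool((np.isclose(vals, extremum)).sum() > 1)
            block, level = int(sub.loc[i, "block"]), int(sub.loc[i, "level"])
            rows.append({
                "cluster": int(cluster), "metric": metric, "kind": kind,
                "block": block, "level": level, "value": float(extremum),
                "deceptive": (block, level) in schedule.deceptive_cells,
                "tie": tie,
            })
    return pd.DataFrame(rows)
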