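"""Group comparisons for chip experiments: one-way ANOVA with Tukey HSD,
plus dose–response summaries.

The replicate unit is the chip: each chip contributes one observation per
metric per day, and groups are (cell line, day, dose) combinations with at
least three replicate chips.  Stars follow the convention
``* p<0.01, ** p<0.001, *** p<0.0001``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TukeyPair",
    "ComparisonResult",
    "one_way_anova",
    "tukey_hsd",
    "compare_groups",
    "dose_response_summary",
    "significance_stars",
    "validate_experiment_table",
]

EXPERIMENT_COLUMNS = [
    "cell_line",
    "day",
    "dose_uM",
    "chip_id",
    "metric_name",
    "value",
]

METRIC_NAMES = ("n_ipts_crossed", "max_distance_um")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class TukeyPair:
    pair: tuple[int, int]
    mean_diff: float
    q: float
    p_adj: float


@dataclass(frozen=True)
class ComparisonResult:
    anova: AnovaResult
    tukey: tuple[TukeyPair, ...]
    group_labels: tuple[str, ...]


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} observations; need >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA over ``k >= 2`` samples.

    ``F = MS_between / MS_within`` on ``(k - 1, N - k)`` degrees of
    freedom; the p-value is the upper tail of the F distribution.

    Degenerate cases: identical values everywhere raise a validation
    error (F is 0/0); zero within-group variance with unequal means
    returns ``F = inf, p = 0`` with a warning.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n = np.array([g.size for g in arrays])
    total_n = int(n.sum())
    means = np.array([g.mean() for g in arrays])
    grand = np.concatenate(arrays).mean()

    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(arrays, means)))
    df_between = k - 1
    df_within = total_n - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    sds = tuple(float(g.std(ddof=1)) for g in arrays)
    if ms_within == 0:
        if ss_between == 0:
            raise ValueError(
                "all observations identical: F statistic is undefined (0/0)"
            )
        warnings.warn(
            "zero within-group variance with unequal means: F = inf, p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))

    return AnovaResult(
        F=float(f_stat),
        p=p,
        df_between=df_between,
        df_within=df_within,
        ms_within=ms_within,
        group_means=tuple(map(float, means)),
        group_sds=sds,
        group_sizes=tuple(map(int, n)),
    )


def tukey_hsd(groups, alpha: float = 0.05) -> list[TukeyPair]:
    """Tukey honestly-significant-difference pairwise comparisons.

    For each unordered pair (i, j):
    ``q = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j))``,
    with the adjusted p-value from the studentized range distribution on
    ``(k, N - k)``.  Uses the Tukey–Kramer form for unequal group sizes.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    arrays = _check_groups(groups)
    anova = one_way_anova(arrays)
    k = len(arrays)
    results: list[TukeyPair] = []
    for i, j in itertools.combinations(range(k), 2):
        diff = anova.group_means[i] - anova.group_means[j]
        se = np.sqrt(
            anova.ms_within
            / 2.0
            * (1.0 / anova.group_sizes[i] + 1.0 / anova.group_sizes[j])
        )
        if se == 0:
            q = float("inf") if diff else 0.0
        else:
            q = abs(diff) / se
        if np.isinf(q):
            p_adj = 0.0
        else:
            p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
        results.append(
            TukeyPair(pair=(i, j), mean_diff=float(diff), q=float(q), p_adj=p_adj)
        )
    return results


def compare_groups(
    table: pd.DataFrame,
    metric_name: str,
    group_by: list[str] | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """ANOVA + Tukey over one metric of a long-format experiment table."""
    if group_by is None:
        group_by = ["cell_line"]
    sub = table[table["metric_name"] == metric_name]
    if sub.empty:
        raise ValueError(f"no rows with metric_name == {metric_name!r}")
    labels, groups = [], []
    for key, grp in sub.groupby(group_by, sort=True):
        labels.append("/".join(str(k) for k in (key if isinstance(key, tuple) else (key,))))
        groups.append(grp["value"].to_numpy())
    anova = one_way_anova(groups)
    pairs = tukey_hsd(groups, alpha=alpha)
    return ComparisonResult(anova=anova, tukey=tuple(pairs), group_labels=tuple(labels))


def dose_response_summary(table: pd.DataFrame, metric_name: str) -> pd.DataFrame:
    """Per-dose mean ± SD of one metric, with a monotone-trend flag.

    Returns a DataFrame indexed by increasing dose with columns
    ``mean``, ``sd``, ``n``; the attribute ``attrs['non_increasing']`` is
    True iff dose-level means are non-increasing with dose (flat counts
    as non-increasing).
    """
    sub = table[table["metric_name"] == metric_name]
    doses = np.sort(sub["dose_uM"].unique())
    if doses.size < 2:
        raise ValueError(f"need >= 2 dose levels, got {doses.size}")
    rows = []
    for dose in doses:
        vals = sub.loc[sub["dose_uM"] == dose, "value"].to_numpy(dtype=float)
        rows.append(
            {
                "dose_uM": float(dose),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    out = pd.DataFrame(rows).set_index("dose_uM")
    means = out["mean"].to_numpy()
    out.attrs["non_increasing"] = bool(np.all(np.diff(means) <= 0))
    return out


def significance_stars(p: float) -> str:
    """Star annotation: ``*`` p<0.01, ``**`` p<0.001, ``***`` p<0.0001."""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


def validate_experiment_table(table: pd.DataFrame, min_replicates: int = 3) -> None:
    """Check schema and replication of a long-format experiment table.

    Requires the standard columns, non-negative values, IPT counts <= 17,
    and at least ``min_replicates`` chips per (cell_line, day, dose) group.
    """
    missing = [c for c in EXPERIMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"experiment table missing columns: {missing}")
    bad_metric = set(table["metric_name"]) - set(METRIC_NAMES)
    if bad_metric:
        raise ValueError(f"unknown metric names: {sorted(bad_metric)}")
    if (table["value"] < 0).any():
        raise ValueError("metric values must be non-negative")
    ipts = table.loc[table["metric_name"] == "n_ipts_crossed", "value"]
    if (ipts > 17).any():
        raise ValueError("n_ipts_crossed values exceed 17")
    counts = (
        table[table["metric_name"] == METRIC_NAMES[0]]
        .groupby(["cell_line", "day", "dose_uM"])["chip_id"]
        .nunique()
    )
    under = counts[counts < min_replicates]
    if not under.empty:
        raise ValueError(
            f"groups with fewer than {min_replicates} replicate chips:\n{under}"
        )
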