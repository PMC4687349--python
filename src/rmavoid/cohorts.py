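"""Cohort statistics: fraction tables, matched thresholds, Y(f) curves.

The central comparison device is threshold matching on a control cohort:
palindromic and non-palindromic sites have different null Kr distributions,
so a single cutoff is not comparable across the two strata.  Instead a
false-positive fraction f is fixed and each stratum receives the Kr threshold
at which exactly f of its *control* pairs fall below — the empirical
f-quantile with a lower tie-break.  The excess-avoidance curve
Y(f) = (fraction of actual pairs below the matched threshold) − f
then estimates the fraction of pairs underrepresented *because of* R-M
systems, net of the compositional false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrast import ThresholdConfig, classify_representation

__all__ = [
    "CohortSummary",
    "fraction_table",
    "matched_threshold",
    "excess_avoidance_curve",
    "compare_distributions",
    "compare_fractions",
    "kr_histogram",
]


@dataclass
class CohortSummary:
    """Per-stratum under/normal/over fractions with counts retained."""

    table: pd.DataFrame
    thresholds: ThresholdConfig

    def __str__(self) -> str:  # pragma: no cover - display sugar
        return self.table.to_string(index=False)


def fraction_table(
    records: pd.DataFrame,
    group_by: list[str] | str,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> CohortSummary:
    """Fractions of under/normal/over-represented pairs per stratum.

    Only records passing the min-expected filter enter the denominators.
    Strata emptied by the filter are reported with n=0 and NaN fractions,
    never dropped.  Numerators are retained alongside the fractions.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    rows = []
    for key, sub in records.groupby(group_by, dropna=False, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        passing = sub[sub["passes_min_expected"] & sub["kr"].notna()]
        n = len(passing)
        reps = [classify_representation(k, cfg) for k in passing["kr"]]
        n_under = reps.count("under")
        n_over = reps.count("over")
        n_normal = n - n_under - n_over
        row = dict(zip(group_by, key))
        row.update(
            n_pairs=n,
            n_under=n_under,
            n_normal=n_normal,
            n_over=n_over,
            fraction_under=n_under / n if n else float("nan"),
            fraction_normal=n_normal / n if n else float("nan"),
            fraction_over=n_over / n if n else float("nan"),
        )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(group_by).reset_index(drop=True)
    return CohortSummary(table=table, thresholds=cfg)


def matched_threshold(control_kr_values, f: float) -> float:
    """Largest threshold t with fraction(control Kr <= t) <= f.

    Empirical quantile with a lower tie-break: the realised control
    false-positive rate never exceeds f.  When f is below 1/n the returned
    threshold sits just below the control minimum (zero pairs qualify).
    """
    values = np.sort(np.asarray(list(control_kr_values), dtype=float))
    if values.size == 0:
        raise ValueError("control Kr multiset must be non-empty")
    if not 0 < f < 1:
        raise ValueError(f"false-positive fraction must lie in (0, 1), got {f}")
    n = values.size
    k = int(np.floor(f * n + 1e-12))  # max number of control pairs allowed below t
    if k == 0:
        return float(np.nextafter(values[0], -np.inf))
    # step down through ties: t = k-th smallest value only if distinct from the next
    while k > 0 and k < n and values[k - 1] == values[k]:
        k -= 1
    if k == 0:
        return float(np.nextafter(values[0], -np.inf))
    return float(values[k - 1])


def excess_avoidance_curve(
    actual_kr, control_kr, f_grid
) -> pd.DataFrame:
    """Y(f) = fraction(actual Kr <= matched threshold) − f over a grid of f.

    Actual and control must come from the same site stratum (palindromic or
    non-palindromic) for the matching to be meaningful.
    """
    actual = np.asarray(list(actual_kr), dtype=float)
    if actual.size == 0:
        raise ValueError("actual Kr set must be non-empty")
    rows = []
    for f in f_grid:
        t = matched_threshold(control_kr, f)
        frac = float(np.mean(actual <= t))
        rows.append({"f": f, "threshold": t, "actual_fraction": frac, "y": frac - f})
    return pd.DataFrame(rows)


def compare_distributions(kr_a, kr_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on Kr values -> (statistic, p)."""
    a = np.asarray(list(kr_a), dtype=float)
    b = np.asarray(list(kr_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values for the KS test")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FractionComparison:
    statistic: float
    pvalue: float
    method: str  # 'chi2' | 'fisher'


def compare_fractions(k1: int, n1: int, k2: int, n2: int) -> FractionComparison:
    """Compare two underrepresentation fractions k1/n1 vs k2/n2.

    Chi-square on the 2x2 table, falling back to Fisher's exact test when any
    expected cell is below 5.
    """
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot compare fractions with a zero denominator")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("numerators must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        res = stats.fisher_exact(table)
        return FractionComparison(float(res[0]), float(res[1]), "fisher")
    res = stats.chi2_contingency(table, correction=False)
    return FractionComparison(float(res.statistic), float(res.pvalue), "chi2")


def kr_histogram(kr_values, bins: int = 41, upper: float = 2.0) -> pd.DataFrame:
    """Percentages of pairs per Kr bin over [0, upper), plus an overflow bin.

    Bin percentages are relative to all pairs, so the in-range bins sum to the
    percentage of pairs with Kr < upper and the overflow row holds the rest.
    """
    values = np.asarray(list(kr_values), dtype=float)
    n = values.size
    edges = np.linspace(0.0, upper, bins + 1)
    counts, _ = np.histogram(values[values < upper], bins=edges)
    pct = 100.0 * counts / n if n else np.full(bins, np.nan)
    df = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "percent": pct,
        }
    )
    overflow = int(np.sum(values >= upper))
    df.loc[len(df)] = {
        "bin_left": upper,
        "bin_right": np.inf,
        "count": overflow,
        "percent": 100.0 * overflow / n if n else np.nan,
    }
    return df
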