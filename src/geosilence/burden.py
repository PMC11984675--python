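"""Per-cell burden of geographical silencing events.

A cell's burden is the number of runs of at least L (default 10)
consecutive silenced genes it carries across the somatic chromosomes.
Cells are classified into extremes by strict thresholds: high burden means
strictly more than 150 events, the low extreme strictly fewer than 25;
cells on or between the boundaries are intermediate. Condition differences
in the fraction of high-burden cells are assessed with a Pearson chi-square
test on the high / not-high contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "per_cell_burden",
    "classify_burden",
    "class_frequencies",
    "high_burden_test",
    "BurdenTestResult",
]


def per_cell_burden(
    run_events: pd.DataFrame,
    cell_meta: pd.DataFrame,
    min_length: int = 10,
) -> pd.DataFrame:
    """Count qualifying (length ≥ L) run events per cell.

    Every cell in ``cell_meta`` gets a record; cells without any qualifying
    event get 0. Returns a DataFrame indexed by cell id with columns
    condition, cluster and n_events.
    """
    qualifying = run_events[run_events["length"] >= min_length]
    counts = qualifying.groupby("cell_id", observed=True).size()
    table = cell_meta[["condition", "cluster"]].copy()
    table["n_events"] = counts.reindex(table.index).fillna(0).astype(int)
    return table


def classify_burden(
    records: pd.DataFrame,
    high_threshold: int = 150,
    low_threshold: int = 25,
) -> pd.DataFrame:
    """Label each cell high (> high), low (< low) or intermediate.

    Both inequalities are strict, so a cell at exactly either threshold is
    intermediate.
    """
    if low_threshold >= high_threshold:
        raise ValueError("low_threshold must be < high_threshold")
    records = records.copy()
    n = records["n_events"].to_numpy()
    labels = np.where(
        n > high_threshold, "high", np.where(n < low_threshold, "low", "intermediate")
    )
    records["burden_class"] = labels
    return records


def class_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Per-condition fractions of cells in each burden class (rows sum to 1)."""
    counts = (
        records.groupby(["condition", "burden_class"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["low", "intermediate", "high"], fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass
class BurdenTestResult:
    """Chi-square comparison of high-burden frequency between two conditions."""

    condition: str
    control: str
    statistic: float
    p_value: float
    dof: int
    observed: pd.DataFrame
    expected: np.ndarray
    low_expected_warning: bool


def high_burden_test(
    records: pd.DataFrame,
    condition_pairs: list[tuple[str, str]],
    contrast: str = "high_vs_rest",
    correction: bool = False,
) -> list[BurdenTestResult]:
    """Pearson chi-square of high-burden cell frequency per condition pair.

    Each pair ``(condition, control)`` yields a 2×2 table of
    {high, not-high} × {condition, control}; with ``contrast='high_vs_low'``
    intermediate cells are excluded and the table is {high, low} × arms.
    Yates continuity correction is off by default. When any expected cell
    count falls below 1 the result is flagged, recommending an exact test.
    """
    if contrast not in ("high_vs_rest", "high_vs_low"):
        raise ValueError("contrast must be 'high_vs_rest' or 'high_vs_low'")
    if "burden_class" not in records.columns:
        raise ValueError("records must be classified first (classify_burden)")
    results = []
    for condition, control in condition_pairs:
        sub = records[records["condition"].isin([condition, control])]
        if contrast == "high_vs_low":
            sub = sub[sub["burden_class"].isin(["high", "low"])]
        is_high = (sub["burden_class"] == "high").map({True: "high", False: "not_high"})
        observed = (
            pd.crosstab(is_high, sub["condition"])
            .reindex(index=["high", "not_high"], fill_value=0)
            .reindex(columns=[condition, control], fill_value=0)
        )
        table = observed.to_numpy()
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            # A zero margin (e.g., no high-burden cell in either arm) makes
            # the chi-square undefined; report no evidence of a difference.
            statistic, p_value, dof = 0.0, 1.0, 1
            expected = table.astype(float)
        else:
            result = scipy.stats.chi2_contingency(table, correction=correction)
            statistic = float(result.statistic)
            p_value = float(result.pvalue)
            dof = int(result.dof)
            expected = np.asarray(result.expected_freq)
        results.append(
            BurdenTestResult(
                condition=condition,
                control=control,
                statistic=statistic,
                p_value=p_value,
                dof=dof,
                observed=observed,
                expected=expected,
                low_expected_warning=bool(np.any(expected < 1)),
            )
        )
    return results
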