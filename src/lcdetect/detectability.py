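"""Detectability estimation and paired algorithm comparisons.

Detectability is the fraction of 2AFC trials in which the signal-present
image was correctly selected, assessed separately per dose level and
reconstruction algorithm (and optionally per lesion type, reader or reader
group).  Algorithms are compared per dose with a paired Student's t-test,
the reader being the pairing unit: each reader contributes one
detectability score per cell, and with R readers the test has R - 1
degrees of freedom.  Differences are reported in percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiffResult",
    "clean_responses",
    "aggregate",
    "reader_scores",
    "paired_t_test",
    "compare_all",
    "subgroup",
]


@dataclass
class DiffResult:
    """Paired-t comparison of two algorithms' per-reader detectability."""

    mean_diff: float  # percentage points
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_value: float
    algorithm: str | None = None
    reference: str | None = None
    dose_mGy: float | None = None
    degenerate: bool = False


def clean_responses(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop invalid responses; return retained records and an exclusion log."""
    valid = records["valid"].astype(bool)
    kept = records[valid].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no valid records remain after cleaning")
    log = {"n_input": int(len(records)), "n_excluded": int((~valid).sum()),
           "n_retained": int(len(kept))}
    return kept, log


def aggregate(records: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Detectability per stratum.

    Returns one row per observed combination of `by` keys with columns
    n_trials, n_correct and detectability = n_correct / n_trials.  The
    strata partition the records, so totals are conserved at any
    granularity.
    """
    by = list(by)
    g = records.groupby(by, observed=True)["correct"]
    out = g.agg(n_trials="count", n_correct="sum").reset_index()
    out["n_correct"] = out["n_correct"].astype(int)
    out["detectability"] = out["n_correct"] / out["n_trials"]
    return out


def reader_scores(
    records: pd.DataFrame, by: Sequence[str] = ("algorithm", "dose_mGy")
) -> pd.DataFrame:
    """Per-reader detectability within each stratum (the t-test pairing unit)."""
    return aggregate(records, ["reader_id", *by])


def paired_t_test(
    scores_a: Sequence[float], scores_b: Sequence[float], **labels
) -> DiffResult:
    """Paired Student's t-test on matched per-reader scores (A minus B).

    t = mean(diff) / (sd(diff)/sqrt(n)) with df = n - 1; two-sided p; the
    95% CI is mean +/- t_{0.975,df} * sd/sqrt(n).  Scores are proportions;
    results are reported in percentage points.  A zero-variance nonzero-mean
    sample is degenerate: infinite t, p = 0, with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = (a - b) * 100.0  # percentage points
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return DiffResult(0.0, 0.0, 0.0, 0.0, df, 1.0, **labels)
        warnings.warn(
            "zero-variance differences with nonzero mean: degenerate t-test",
            stacklevel=2,
        )
        t = np.inf if mean > 0 else -np.inf
        return DiffResult(mean, mean, mean, t, df, 0.0, degenerate=True, **labels)
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    tq = float(stats.t.ppf(0.975, df))
    return DiffResult(mean, mean - tq * se, mean + tq * se, float(t), df, p, **labels)


def compare_all(
    records: pd.DataFrame,
    reference: str,
    algorithms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-dose paired comparison of every algorithm against `reference`.

    The pairing unit is the reader: each reader's detectability in the
    (algorithm, dose) cell, pooled over lesion types, scans and slices.
    """
    present = list(pd.unique(records["algorithm"]))
    if reference not in present:
        raise ValueError(f"reference algorithm {reference!r} not in records")
    if algorithms is None:
        algorithms = [a for a in present if a != reference]
    scores = reader_scores(records)
    wide = scores.pivot_table(
        index=["reader_id", "dose_mGy"], columns="algorithm", values="detectability"
    )
    rows = []
    for dose in sorted(records["dose_mGy"].unique()):
        cell = wide.xs(dose, level="dose_mGy")
        for algo in algorithms:
            res = paired_t_test(
                cell[algo], cell[reference],
                algorithm=algo, reference=reference, dose_mGy=float(dose),
            )
            rows.append(
                {
                    "reference": reference,
                    "algorithm": algo,
                    "dose_mGy": float(dose),
                    "mean_diff_pp": res.mean_diff,
                    "ci_low_pp": res.ci_low,
                    "ci_high_pp": res.ci_high,
                    "t_stat": res.t_stat,
                    "df": res.df,
                    "p_value": res.p_value,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


def subgroup(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Restrict to one reader group (e.g. radiologist vs non-radiologist)."""
    known = set(records["reader_group"].unique())
    if group not in known:
        raise ValueError(f"unknown reader group {group!r}; present: {sorted(known)}")
    return records[records["reader_group"] == group].reset_index(drop=True)
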