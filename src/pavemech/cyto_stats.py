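"""Severing-rate and crossover statistics, plus group comparisons.

Severing rates are reported per cell as events per square micrometre
per minute and summarized as mean +/- SD across cells (the reporting
convention for severing); anisotropy-style summaries use mean +/- SE.
Group comparisons use the Mann-Whitney U test (exact for small
samples) or Student's t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SeveringRecord:
    """Observed severing events and per-cell observation windows."""

    events: pd.DataFrame  # columns: cell, x, y, t
    cell_areas: dict  # cell id -> um^2
    durations: dict  # cell id -> minutes

    def __post_init__(self) -> None:
        if not self.cell_areas:
            raise ValueError("at least one cell required")
        for cid, a in self.cell_areas.items():
            if a <= 0:
                raise ValueError(f"cell {cid}: area must be positive")
            if self.durations.get(cid, 0) <= 0:
                raise ValueError(f"cell {cid}: duration must be positive")
        if len(self.events):
            tmax = self.events.groupby("cell")["t"].max()
            for cid, t in tmax.items():
                if t > self.durations[cid] + 1e-9:
                    raise ValueError(f"cell {cid}: event time beyond duration")


@dataclass
class RateSummary:
    """Per-cell severing rates and their group summary."""

    per_cell: pd.Series  # events / um^2 / min, indexed by cell
    mean: float
    sd: float  # across cells
    se: float
    n_cells: int


def severing_rate(record: SeveringRecord) -> RateSummary:
    """Per-cell rate = count / (area x duration); summary across cells."""
    cells = sorted(record.cell_areas)
    counts = (
        record.events.groupby("cell").size() if len(record.events) else pd.Series(dtype=int)
    )
    rates = pd.Series(
        {
            c: counts.get(c, 0) / (record.cell_areas[c] * record.durations[c])
            for c in cells
        },
        name="rate",
    )
    n = len(rates)
    sd = float(rates.std(ddof=1)) if n > 1 else 0.0
    return RateSummary(
        per_cell=rates,
        mean=float(rates.mean()),
        sd=sd,
        se=sd / np.sqrt(n) if n > 1 else 0.0,
        n_cells=n,
    )


@dataclass
class CrossoverSummary:
    density_t1: float  # per 10 um^2
    density_t2: float
    percent_change: int | None  # rounded to nearest integer; None if undefined


def crossover_density(
    counts_t1: np.ndarray,
    counts_t2: np.ndarray,
    window_area: float,
) -> CrossoverSummary:
    """Crossover densities per 10 um^2 and their percent change.

    ``counts_t1``/``counts_t2`` are per-window crossover counts in the
    same windows at the two timepoints; densities are group means
    normalized to 10 um^2, percent change = 100 (m2 - m1)/m1 rounded
    to the nearest integer (None when the baseline mean is zero).
    """
    if window_area <= 0:
        raise ValueError("window_area must be positive")
    c1 = np.asarray(counts_t1, float)
    c2 = np.asarray(counts_t2, float)
    d1 = float(np.mean(c1) / window_area * 10.0)
    d2 = float(np.mean(c2) / window_area * 10.0)
    if d1 == 0:
        return CrossoverSummary(d1, d2, None)
    change = int(round(100.0 * (d2 - d1) / d1))
    return CrossoverSummary(d1, d2, change)


def percent_change_of_means(mean_t1: float, mean_t2: float) -> int:
    """100 (m2 - m1)/m1 rounded to the nearest integer."""
    if mean_t1 == 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return int(round(100.0 * (mean_t2 - mean_t1) / mean_t1))


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    summary_a: dict = field(default_factory=dict)  # mean, se, sd, n
    summary_b: dict = field(default_factory=dict)


def _summary(x: np.ndarray) -> dict:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return {
        "mean": float(np.mean(x)),
        "sd": sd,
        "se": sd / np.sqrt(n) if n > 1 else 0.0,
        "n": n,
    }


def compare_groups(
    a: np.ndarray, b: np.ndarray, test: str = "mann_whitney"
) -> GroupComparison:
    """Two-sided Mann-Whitney U or Student's t comparison.

    Mann-Whitney is exact for combined n <= 20 without ties, and uses
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "t_test":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t test requires n >= 2 per group")
        res = stats.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("test must be 'mann_whitney' or 't_test'")
    return GroupComparison(
        test=test,
        statistic=stat,
        p_value=min(p, 1.0),
        summary_a=_summary(a),
        summary_b=_summary(b),
    )
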