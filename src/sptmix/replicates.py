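"""Replicate-level immobile-fraction summaries and group comparison.

Each biological replicate (an independently simulated or acquired movie
set) contributes one immobile percentage; conditions are compared with an
unpaired two-tailed t-test, pooled-variance (Student) by default with the
Welch form behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy import stats

__all__ = ["ReplicateSummary", "GroupComparison", "summarize_replicates", "compare_groups"]


@dataclass
class ReplicateSummary:
    condition: str
    replicate_fractions: List[float]
    mean: float
    sd: float
    n_replicates: int
    n_cells: int = 0
    n_tracks: int = 0


@dataclass
class GroupComparison:
    condition_a: str
    condition_b: str
    t_statistic: float
    p_value: float
    test: str


def summarize_replicates(
    fractions: Sequence[float],
    condition: str = "",
    n_cells: int = 0,
    n_tracks: int = 0,
) -> ReplicateSummary:
    """Mean and sample standard deviation (n-1 denominator) of per-replicate
    immobile percentages; a single replicate reports sd = 0."""
    fr = [float(v) for v in fractions]
    if len(fr) == 0:
        raise ValueError("need at least one replicate")
    if any(not (0 <= v <= 100) for v in fr):
        raise ValueError("fractions must be percentages in [0, 100]")
    arr = np.asarray(fr)
    return ReplicateSummary(
        condition=condition,
        replicate_fractions=fr,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(fr) > 1 else 0.0,
        n_replicates=len(fr),
        n_cells=n_cells,
        n_tracks=n_tracks,
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of replicate
    percentages (pooled variance unless ``welch``).

    Degenerate case: when both groups have zero variance and equal means the
    comparison reports t = 0, p = 1; zero variance with different means
    reports p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(a.mean() - b.mean()) * np.inf, 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        condition_a=label_a,
        condition_b=label_b,
        t_statistic=float(t),
        p_value=float(p),
        test="welch t test (two tailed, unpaired)" if welch else "t test (two tailed, unpaired)",
    )
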