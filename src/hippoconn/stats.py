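"""Nonparametric phase comparisons: two-sided Wilcoxon rank-sum test.

Every phase contrast in this package — behavioral durations and path lengths,
and per-band network Coef/Eff — is a two-sided rank-sum (Mann-Whitney)
comparison.  Small tie-free samples (n_a + n_b <= 12) use the exact null
distribution by enumeration over rank assignments; larger or tied samples use
the normal approximation with tie and continuity corrections.  Significance
marks follow the convention * p < 0.05, ** p < 0.01, *** p < 0.001 (strict
inequalities), "ns" otherwise.

No multiple-testing correction is applied by default; reports carry that as
explicit metadata, and Bonferroni / Benjamini-Hochberg adjustment of the
reported p-values is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


class StatsError(ValueError):
    pass


EXACT_LIMIT = 12  # largest pooled n for exact enumeration (tie-free only)


@dataclass
class GroupSummary:
    mean: float
    std: float  # sample std, n-1 denominator
    sem: float
    n: int


@dataclass
class PhaseComparison:
    metric: str
    band: str | None
    phase_a: str
    phase_b: str
    n_a: int
    n_b: int
    statistic: float  # rank sum of group a
    p_value: float
    mark: str


def _exact_ranksum_p(w: float, n_a: int, n_b: int) -> float:
    """Exact two-sided p for rank-sum w of group a, tie-free pooled ranks.

    Counts subsets of {1..N} of size n_a by rank sum via dynamic programming
    and doubles the smaller tail (capped at 1).
    """
    n = n_a + n_b
    max_sum = n_a * (2 * n - n_a + 1) // 2
    # counts[k][s] = number of k-subsets of the ranks seen so far summing to s
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n_a), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    dist = counts[n_a]
    total = dist.sum()  # C(N, n_a)
    w_int = int(round(w))
    lower = dist[: w_int + 1].sum() / total
    upper = dist[w_int:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def ranksum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of ``a``, p).

    Exact by enumeration when n_a + n_b <= 12 with no ties; otherwise a
    normal approximation with tie correction and continuity correction.
    Identical constant samples give p = 1 (no discriminating information).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:n_a].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if n <= EXACT_LIMIT and not has_ties:
        return w, _exact_ranksum_p(w, n_a, n_b)
    mu = n_a * (n + 1) / 2.0
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    diff = w - mu
    # continuity correction: shrink |diff| by 0.5 toward the mean
    z = (abs(diff) - 0.5) / math.sqrt(var) if diff != 0 else 0.0
    z = max(z, 0.0)
    return w, min(1.0, 2.0 * float(norm.sf(z)))


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean, sample std (n-1), and standard error of a group."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatsError("need at least 2 values to summarize")
    std = float(v.std(ddof=1))
    return GroupSummary(mean=float(v.mean()), std=std, sem=std / math.sqrt(v.size), n=int(v.size))


def significance_mark(p: float) -> str:
    """Star notation with strict thresholds: p = 0.05 is already 'ns'."""
    if not (0.0 <= p <= 1.0):
        raise StatsError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _adjust(pvals: list[float], method: str | None) -> list[float]:
    if method is None:
        return pvals
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0).tolist()
    if method == "fdr_bh":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        return adj.tolist()
    raise StatsError(f"unknown adjustment method {method!r}")


def phase_comparison_report(
    data: pd.DataFrame,
    metrics: Sequence[str],
    phase_col: str = "phase",
    band_col: str | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """All pairwise phase comparisons per metric (and per band, if given).

    ``data`` is a tidy table with one row per trial.  Trials are pooled across
    sessions; no multiple-testing correction is applied unless ``adjust`` is
    set — both facts are recorded in the result's ``attrs``.  Phases with
    fewer than 2 observations are skipped with a warning.
    """
    if phase_col not in data.columns:
        raise StatsError(f"missing phase column {phase_col!r}")
    phases = list(dict.fromkeys(data[phase_col]))
    if len(phases) < 2:
        raise StatsError("need at least 2 phases to compare")
    band_values: list[str | None]
    if band_col is None:
        band_values = [None]
    else:
        band_values = list(dict.fromkeys(data[band_col]))
    rows: list[PhaseComparison] = []
    for band in band_values:
        sub = data if band is None else data[data[band_col] == band]
        for metric in metrics:
            for pa, pb in combinations(phases, 2):
                va = sub.loc[sub[phase_col] == pa, metric].to_numpy(dtype=float)
                vb = sub.loc[sub[phase_col] == pb, metric].to_numpy(dtype=float)
                if va.size < 2 or vb.size < 2:
                    warnings.warn(
                        f"skipping {metric} {pa} vs {pb}"
                        + (f" ({band})" if band else "")
                        + ": a phase has fewer than 2 observations"
                    )
                    continue
                stat, p = ranksum(va, vb)
                rows.append(
                    PhaseComparison(
                        metric=metric,
                        band=band,
                        phase_a=pa,
                        phase_b=pb,
                        n_a=int(va.size),
                        n_b=int(vb.size),
                        statistic=stat,
                        p_value=p,
                        mark="",
                    )
                )
    pvals = _adjust([r.p_value for r in rows], adjust)
    for r, p in zip(rows, pvals):
        r.p_value = p
        r.mark = significance_mark(p)
    report = pd.DataFrame([vars(r) for r in rows])
    report.attrs["observation_unit"] = "trial, pooled across sessions"
    report.attrs["multiple_testing_correction"] = adjust or "none"
    return report
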