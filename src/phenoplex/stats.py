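"""Differential comparison of tile-level phenotype fractions between case
types: two-sided Mann-Whitney U tests with Bonferroni adjustment over an
explicit comparison family, and a table-style formatted report with
increase/decrease annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_CODES = {
    "tonsil": "T",
    "NLPHL-pA": "A",
    "NLPHL-pC": "C",
    "NLPHL-pE": "E",
    "THRLBCL": "H",
    "LRcHL": "L",
}


@dataclass
class DifferentialResult:
    phenotype: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    significant: bool
    direction: str  # change in group_b relative to group_a


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    *,
    exact_below_n: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Uses exact enumeration when both samples are smaller than
    ``exact_below_n`` and tie-free; otherwise the normal approximation with
    tie and continuity corrections. Fractions are compared as given;
    undefined (NaN) values must be dropped by the caller or are dropped
    here. An empty sample raises a ValueError naming the group.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0:
        raise ValueError("sample_a is empty after dropping undefined fractions")
    if b.size == 0:
        raise ValueError("sample_b is empty after dropping undefined fractions")
    pooled = np.concatenate((a, b))
    if np.all(pooled == pooled[0]):
        # full ties: U at its null mean, no evidence against the null
        return a.size * b.size / 2.0, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) < exact_below_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def bonferroni_adjust(p_values: Iterable[float], m: int) -> list[float]:
    """Bonferroni family-wise adjustment: p -> min(1, m*p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, m * float(p)) for p in p_values]


def build_comparison_plan(
    fractions: pd.DataFrame,
    phenotypes: Optional[Sequence[str]] = None,
    group_order: Optional[Sequence[str]] = None,
) -> list[tuple[str, str, str]]:
    """Default family: every phenotype x every unordered case-type pair
    present in the data, ordered deterministically."""
    if phenotypes is None:
        phenotypes = sorted(fractions["phenotype"].unique())
    groups = [g for g in (group_order or sorted(fractions["case_type"].unique()))]
    plan = []
    for ph in phenotypes:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                plan.append((ph, ga, gb))
    return plan


def differential_table(
    fractions: pd.DataFrame,
    plan: Optional[Sequence[tuple[str, str, str]]] = None,
    significance_level: float = 0.001,
    group_order: Optional[Sequence[str]] = None,
) -> list[DifferentialResult]:
    """Run the comparison plan on per-tile fraction records.

    ``fractions`` needs columns case_type, phenotype, fraction. ``plan`` is
    a sequence of (phenotype, group_a, group_b); the Bonferroni family size
    m is the number of tests in the plan. Undefined fractions (empty
    parent) are dropped per comparison. A group absent from the data raises
    an error naming it.
    """
    if not (0.0 < significance_level < 1.0):
        raise ValueError("significance_level must be in (0, 1)")
    if plan is None:
        plan = build_comparison_plan(fractions, group_order=group_order)
    m = len(plan)
    present = set(fractions["case_type"].unique())
    results = []
    for ph, ga, gb in plan:
        for g in (ga, gb):
            if g not in present:
                raise ValueError(f"case type {g!r} absent from fraction records")
        sel = fractions["phenotype"] == ph
        a = fractions.loc[sel & (fractions["case_type"] == ga), "fraction"].dropna()
        b = fractions.loc[sel & (fractions["case_type"] == gb), "fraction"].dropna()
        u, p = mann_whitney_u(a, b)
        p_adj = bonferroni_adjust([p], m)[0]
        med_a, med_b = float(a.median()), float(b.median())
        direction = (
            "increase" if med_b > med_a else "decrease" if med_b < med_a else "none"
        )
        results.append(
            DifferentialResult(
                phenotype=ph, group_a=ga, group_b=gb,
                n_a=int(a.size), n_b=int(b.size),
                median_a=med_a, median_b=med_b,
                u_statistic=u, p_raw=p, p_adjusted=p_adj,
                m_comparisons=m,
                significant=p_adj < significance_level,
                direction=direction,
            )
        )
    return results


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def format_report(
    results: Sequence[DifferentialResult],
    group_order: Optional[Sequence[str]] = None,
) -> str:
    """Human-readable report: one row per phenotype, one column per case
    type, medians as percentages annotated with significant increases (↑) or
    decreases (↓) versus the compared groups' code letters."""
    if not results:
        return "(no comparisons)"
    groups = list(
        group_order
        or dict.fromkeys(g for r in results for g in (r.group_a, r.group_b))
    )
    phenos = list(dict.fromkeys(r.phenotype for r in results))
    medians: dict[tuple[str, str], float] = {}
    notes: dict[tuple[str, str], list[str]] = {}
    for r in results:
        medians[(r.phenotype, r.group_a)] = r.median_a
        medians[(r.phenotype, r.group_b)] = r.median_b
        if r.significant and r.direction != "none":
            arrow = "↑" if r.direction == "increase" else "↓"
            code = GROUP_CODES.get(r.group_a, r.group_a)
            notes.setdefault((r.phenotype, r.group_b), []).append(arrow + code)
    width = 16
    lines = ["".ljust(width) + "".join(g.ljust(width) for g in groups)]
    for ph in phenos:
        row = [ph.ljust(width)]
        for g in groups:
            med = medians.get((ph, g))
            cell = "-" if med is None else f"{100 * med:.2g}%"
            ann = notes.get((ph, g))
            if ann:
                cell += " " + ",".join(ann)
            row.append(cell.ljust(width))
        lines.append("".join(row))
    return "\n".join(lines)
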