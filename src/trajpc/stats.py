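"""Pairwise statistical comparison of subtypes.

For each pair of retained subtypes, evolving continuous variables are
compared with a two-sided Mann-Whitney U test on the raw (untransformed,
undirected) values at the baseline and final timepoints; static continuous
demographics (age) with a single Mann-Whitney U test; binary demographics
(gender) with Fisher's exact test.  Significance is flagged against a
Bonferroni-adjusted level alpha / n_c with the comparison budget

    n_c = n_p * (V_d + 2 * V_e)

where ``n_p`` counts subtype pairs, ``V_d`` demographic variables and
``V_e`` evolving clinical variables assessed at the two timepoints.
Unadjusted p-values are reported; only the flag uses the adjusted level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import LongitudinalCohort
from .subtypes import SubtypePartition

EXACT_MWU_MAX_N = 20  # combined sample size at or below which the exact null is enumerated


@dataclass(frozen=True)
class ComparisonBudget:
    n_p: int
    V_d: int
    V_e: int
    n_c: int
    alpha: float
    alpha_adjusted: float


def bonferroni_budget(n_p: int, V_d: int, V_e: int, alpha: float = 0.05) -> ComparisonBudget:
    """Bonferroni comparison budget ``n_c = n_p (V_d + 2 V_e)``."""
    if n_p < 1:
        raise ValueError("need at least one subtype pair")
    if V_d < 0 or V_e < 0:
        raise ValueError("variable counts must be nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n_c = n_p * (V_d + 2 * V_e)
    if n_c == 0:
        raise ValueError("comparison budget is empty")
    return ComparisonBudget(n_p, V_d, V_e, n_c, alpha, alpha / n_c)


def pairwise_mwu(group_a, group_b) -> tuple[float, str]:
    """Two-sided Mann-Whitney U p-value and the method used.

    Small samples (combined n <= 20, no ties) use the exact permutation
    null; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_MWU_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return float(min(p, 1.0)), method


def fisher_gender(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


def _classify(cohort: LongitudinalCohort):
    evolving, demo_cont, demo_bin = [], [], []
    for v, spec in enumerate(cohort.variables):
        if spec.kind == "continuous" and not spec.static:
            evolving.append(v)
        elif spec.kind == "continuous" and spec.static:
            demo_cont.append(v)
        elif spec.kind == "binary":
            demo_bin.append(v)
        # genotype variables are not part of the clinical comparison table
    return evolving, demo_cont, demo_bin


def compare_subtypes(
    cohort: LongitudinalCohort,
    partition: SubtypePartition,
    baseline_t: int = 0,
    final_t: int = -1,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, ComparisonBudget]:
    """Pairwise subtype comparison table with Bonferroni-flagged significance.

    Returns one row per (subtype pair, variable, block): block ``baseline``
    and ``final`` for evolving clinical variables, block ``demographic``
    (tested once) for static continuous and binary variables.  Medians are
    computed from the raw data; the variable's severity direction is
    reported alongside.
    """
    retained = sorted(partition.retained)
    if len(retained) < 2:
        raise ValueError("need at least 2 retained subtypes")
    final_t = range(cohort.n_timepoints)[final_t]
    evolving, demo_cont, demo_bin = _classify(cohort)
    pairs = list(combinations(retained, 2))
    budget = bonferroni_budget(
        len(pairs), len(demo_cont) + len(demo_bin), len(evolving), alpha
    )
    pid_index = {p: i for i, p in enumerate(cohort.patient_ids)}
    members = {
        c: [pid_index[p] for p in partition.members(c) if p in pid_index]
        for c in retained
    }
    for c, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"subtype {c} has fewer than 2 members in the cohort")

    rows = []

    def mwu_row(block, v, t, ca, cb):
        spec = cohort.variables[v]
        a = cohort.values[members[ca], v, t]
        b = cohort.values[members[cb], v, t]
        p, method = pairwise_mwu(a, b)
        rows.append(
            {
                "block": block,
                "variable": spec.name,
                "direction": spec.direction,
                "subtype_a": ca,
                "subtype_b": cb,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "p_value": p,
                "test": f"mwu[{method}]",
                "significant": p < budget.alpha_adjusted,
            }
        )

    for ca, cb in pairs:
        for v in evolving:
            mwu_row("baseline", v, 0 if baseline_t is None else baseline_t, ca, cb)
        for v in evolving:
            mwu_row("final", v, final_t, ca, cb)
        for v in demo_cont:
            mwu_row("demographic", v, final_t, ca, cb)
        for v in demo_bin:
            spec = cohort.variables[v]
            a = cohort.values[members[ca], v, 0]
            b = cohort.values[members[cb], v, 0]
            table = [
                [int((a == 1).sum()), int((a == 0).sum())],
                [int((b == 1).sum()), int((b == 0).sum())],
            ]
            p = fisher_gender(table)
            rows.append(
                {
                    "block": "demographic",
                    "variable": spec.name,
                    "direction": None,
                    "subtype_a": ca,
                    "subtype_b": cb,
                    "median_a": float(np.mean(a)),
                    "median_b": float(np.mean(b)),
                    "p_value": p,
                    "test": "fisher",
                    "significant": p < budget.alpha_adjusted,
                }
            )
    df = pd.DataFrame(rows)
    if len(df) != budget.n_c:
        raise AssertionError("comparison table does not match the Bonferroni budget")
    return df, budget
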