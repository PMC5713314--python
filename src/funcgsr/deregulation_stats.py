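"""Case/control deregulation testing and ranking on the functionome.

Each gene set's GSR indices are compared between case and control samples
with a two-sided Mann-Whitney U test; p-values are corrected across the
collection by the Benjamini-Hochberg step-up procedure, and sets are ranked by
ascending p (ties broken by set name, for determinism).  The significance
level of the study is q < 0.01 by default; a config switch allows the raw-p
reading.  Top-fraction selection and Venn set operations support the
cross-disease overlap analyses.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsr_core import FunctionomeMatrix

logger = logging.getLogger("funcgsr")

#: significance level applied to BH-adjusted values (q)
SIGNIFICANCE_LEVEL = 0.01

#: Mann-Whitney switches from exact enumeration to the tie-corrected normal
#: approximation when n_case * n_control exceeds this product
EXACT_SWITCH_PRODUCT = 400


def mannwhitney_term(case_gsr, control_gsr) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for one gene set.

    Exact enumeration when ``n_case * n_control <= 400`` and the pooled values
    are tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)`` with U the statistic of the case group.
    """
    case = np.asarray(case_gsr, dtype=float)
    ctrl = np.asarray(control_gsr, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("empty group in Mann-Whitney test")
    pooled = np.concatenate([case, ctrl])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if case.size * ctrl.size <= EXACT_SWITCH_PRODUCT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j>=i} (m * p_(j) / j)`` capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def build_table(
    functionome: FunctionomeMatrix,
    disease: str,
    significance_on: str = "q",
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Full deregulation table for one disease versus its matched controls.

    Columns: U, p, q, rank (1-based by ascending p, ties by set name),
    mean/sd for both groups, the signed deregulation direction
    ``mean_case - mean_control``, and a ``significant`` flag at
    ``q < alpha`` (or raw ``p`` when ``significance_on="p"``).
    """
    if significance_on not in ("p", "q"):
        raise ValueError("significance_on must be 'p' or 'q'")
    case_mask = functionome.rows_for(group="case", disease=disease)
    ctrl_mask = functionome.rows_for(group="control", disease=disease)
    if not case_mask.any():
        raise ValueError(f"no case samples for disease {disease!r}")
    if not ctrl_mask.any():
        raise ValueError(f"no control samples for disease {disease!r}")

    X = functionome.gsr
    rows = []
    for k, name in enumerate(functionome.set_names):
        case_v, ctrl_v = X[case_mask, k], X[ctrl_mask, k]
        U, p = mannwhitney_term(case_v, ctrl_v)
        rows.append(
            {
                "set_name": name,
                "U": U,
                "p": p,
                "mean_case": case_v.mean(),
                "sd_case": case_v.std(ddof=1) if case_v.size > 1 else 0.0,
                "mean_control": ctrl_v.mean(),
                "sd_control": ctrl_v.std(ddof=1) if ctrl_v.size > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows).set_index("set_name")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = table["mean_case"] - table["mean_control"]
    order = table.sort_values(["p", "set_name"], kind="mergesort").index
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    table["significant"] = table[significance_on] < alpha
    table.attrs["disease"] = disease
    table.attrs["alpha"] = alpha
    table.attrs["significance_on"] = significance_on
    return table


def select_top_fraction(table: pd.DataFrame, fraction: float = 0.10,
                        top_k: int | None = None) -> set[str]:
    """The ``floor(fraction * m)`` lowest-p set names (ties by name), or an
    absolute ``top_k`` override."""
    if top_k is None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        top_k = math.floor(fraction * len(table))
    ordered = table.sort_values(["p", "set_name"], kind="mergesort")
    return set(ordered.index[:top_k])


def venn_partition(lists: dict[str, set]) -> dict[str, dict]:
    """Exclusive regions of a 2- or 3-way Venn diagram.

    Region keys join the member list names with ``&`` (sorted); values carry
    the count and the sorted names.  Counts sum to the union size.
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("venn_partition supports 2 or 3 sets")
    names = sorted(lists)
    out: dict[str, dict] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(lists[n]) for n in combo))
            outside = set.union(
                *(set(lists[n]) for n in names if n not in combo), set()
            )
            region = inside - outside
            out["&".join(combo)] = {
                "count": len(region),
                "members": sorted(region),
            }
    return out


def group_summary(functionome: FunctionomeMatrix) -> pd.DataFrame:
    """Per-disease summary of pooled GSR indices (study Table-1 shape).

    For each disease: sample counts, case and control mean (SD) over all
    entries of the functionome block, and a Mann-Whitney p on the pooled
    indices.
    """
    diseases = sorted(
        {
            functionome.sample_labels[s]["disease"]
            for s in functionome.sample_ids
            if functionome.sample_labels[s]["group"] == "case"
        }
    )
    rows = []
    for d in diseases:
        case = functionome.gsr[functionome.rows_for(group="case", disease=d), :].ravel()
        ctrl = functionome.gsr[functionome.rows_for(group="control", disease=d), :].ravel()
        n_case = int(functionome.rows_for(group="case", disease=d).sum())
        n_ctrl = int(functionome.rows_for(group="control", disease=d).sum())
        if case.size and ctrl.size:
            _, p = mannwhitney_term(case, ctrl)
        else:
            p = np.nan
        rows.append(
            {
                "disease": d,
                "n_case": n_case,
                "n_control": n_ctrl,
                "mean_case": case.mean() if case.size else np.nan,
                "sd_case": case.std(ddof=1) if case.size > 1 else np.nan,
                "mean_control": ctrl.mean() if ctrl.size else np.nan,
                "sd_control": ctrl.std(ddof=1) if ctrl.size > 1 else np.nan,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("disease")
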