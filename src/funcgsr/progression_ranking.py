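"""Progressive-deregulation extraction along the ES -> CCC/EC transition.

A term is *progressively deregulated* when it is significant in all three
diseases and its deregulation rank moves upward (toward 1) while its
case-group GSR drops from endometriosis to both carcinomas.  Five criteria
are applied (all inequalities strict):

1. significant in ES, CCC and EC (same significance scale as the
   deregulation tables, BH-q by default);
2. ``|rank_CCC - rank_EC| < 100``;
3. ``(rank_CCC + rank_EC) / 2 < 300``;
4. ``rank_ES - rank_CCC > 0`` and ``rank_ES - rank_EC > 0`` (the conjunctive
   reading; a disjunctive switch is provided);
5. ``mean_gsr_CCC < mean_gsr_ES`` and ``mean_gsr_EC < mean_gsr_ES`` on
   case-group means (the GSR-depression condition; on by default,
   toggleable).

Intersecting the passed terms with the factor elements coexisting among the
three diseases yields the core transformation functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("funcgsr")

RANK_DIFF_LIMIT = 100
RANK_MEAN_LIMIT = 300


@dataclass
class ProgressionRecord:
    set_name: str
    rank_ES: int
    rank_CCC: int
    rank_EC: int
    q_ES: float
    q_CCC: float
    q_EC: float
    mean_gsr_ES: float
    mean_gsr_CCC: float
    mean_gsr_EC: float
    pass_flags: dict[str, bool]
    passed: bool


def progressive_filter(
    table_es: pd.DataFrame,
    table_ccc: pd.DataFrame,
    table_ec: pd.DataFrame,
    rank_diff_limit: int = RANK_DIFF_LIMIT,
    rank_mean_limit: float = RANK_MEAN_LIMIT,
    cancer_rank_mode: str = "and",
    require_gsr_depression: bool = True,
) -> list[ProgressionRecord]:
    """Apply the five progression criteria over the shared term universe.

    The three deregulation tables (indexed by set name, with ``rank``, ``q``,
    ``significant`` and ``mean_case`` columns) are inner-joined; terms absent
    from any table are not considered.
    """
    if cancer_rank_mode not in ("and", "or"):
        raise ValueError("cancer_rank_mode must be 'and' or 'or'")
    common = table_es.index.intersection(table_ccc.index).intersection(table_ec.index)
    if common.empty:
        raise ValueError("no terms shared by the three deregulation tables")

    records = []
    for name in sorted(common):
        r_es = int(table_es.loc[name, "rank"])
        r_ccc = int(table_ccc.loc[name, "rank"])
        r_ec = int(table_ec.loc[name, "rank"])
        g_es = float(table_es.loc[name, "mean_case"])
        g_ccc = float(table_ccc.loc[name, "mean_case"])
        g_ec = float(table_ec.loc[name, "mean_case"])
        up_ccc = r_es - r_ccc > 0
        up_ec = r_es - r_ec > 0
        flags = {
            "significant_all": bool(
                table_es.loc[name, "significant"]
                and table_ccc.loc[name, "significant"]
                and table_ec.loc[name, "significant"]
            ),
            "cancer_rank_close": abs(r_ccc - r_ec) < rank_diff_limit,
            "cancer_rank_high": (r_ccc + r_ec) / 2 < rank_mean_limit,
            "rank_upward": (up_ccc and up_ec) if cancer_rank_mode == "and" else (up_ccc or up_ec),
        }
        if require_gsr_depression:
            flags["gsr_depressed"] = g_ccc < g_es and g_ec < g_es
        records.append(
            ProgressionRecord(
                set_name=name,
                rank_ES=r_es,
                rank_CCC=r_ccc,
                rank_EC=r_ec,
                q_ES=float(table_es.loc[name, "q"]),
                q_CCC=float(table_ccc.loc[name, "q"]),
                q_EC=float(table_ec.loc[name, "q"]),
                mean_gsr_ES=g_es,
                mean_gsr_CCC=g_ccc,
                mean_gsr_EC=g_ec,
                pass_flags=flags,
                passed=all(flags.values()),
            )
        )
    n_pass = sum(r.passed for r in records)
    logger.info("progression filter: %d/%d terms pass", n_pass, len(records))
    return records


def records_frame(records: list[ProgressionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "set_name": r.set_name,
            "rank_ES": r.rank_ES,
            "rank_CCC": r.rank_CCC,
            "rank_EC": r.rank_EC,
            "q_ES": r.q_ES,
            "q_CCC": r.q_CCC,
            "q_EC": r.q_EC,
            "mean_gsr_ES": r.mean_gsr_ES,
            "mean_gsr_CCC": r.mean_gsr_CCC,
            "mean_gsr_EC": r.mean_gsr_EC,
            "passed": r.passed,
        }
        row.update({f"pass_{k}": v for k, v in r.pass_flags.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("set_name")


def core_intersection(
    coexisting_terms, progressive_records: list[ProgressionRecord]
) -> list[str]:
    """Terms both coexisting (3-way factor-element overlap) and progressively
    deregulated, sorted by the mean of their three ranks ascending."""
    passed = {r.set_name: r for r in progressive_records if r.passed}
    coexisting = set(coexisting_terms)
    if not coexisting or not passed:
        raise ValueError("both coexisting and progressive term lists must be non-empty")
    hits = coexisting & set(passed)
    if not hits:
        logger.warning("core intersection is empty")
    return sorted(
        hits,
        key=lambda s: (
            (passed[s].rank_ES + passed[s].rank_CCC + passed[s].rank_EC) / 3,
            s,
        ),
    )


def ranking_paths(records: list[ProgressionRecord]) -> pd.DataFrame:
    """Long-format rank paths ES -> CCC and ES -> EC for passed records,
    plus an ``__average__`` row of per-disease mean ranks and mean GSR."""
    passed = [r for r in records if r.passed]
    if not passed:
        raise ValueError("no passed records to chart")
    rows = []
    for r in passed:
        rows.append(
            {
                "set_name": r.set_name,
                "rank_ES": r.rank_ES,
                "rank_CCC": r.rank_CCC,
                "rank_EC": r.rank_EC,
                "gsr_ES": r.mean_gsr_ES,
                "gsr_CCC": r.mean_gsr_CCC,
                "gsr_EC": r.mean_gsr_EC,
            }
        )
    frame = pd.DataFrame(rows)
    avg = {
        "set_name": "__average__",
        "rank_ES": frame["rank_ES"].mean(),
        "rank_CCC": frame["rank_CCC"].mean(),
        "rank_EC": frame["rank_EC"].mean(),
        "gsr_ES": frame["gsr_ES"].mean(),
        "gsr_CCC": frame["gsr_CCC"].mean(),
        "gsr_EC": frame["gsr_EC"].mean(),
    }
    frame = pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)
    return frame.set_index("set_name")
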