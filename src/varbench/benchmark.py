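"""Benchmark orchestration: per-dataset tool rankings and VUS prioritization.

Two ranking views are produced per labeled cohort: a fixed-threshold view
ranked by coverage-weighted normalized MCC (every tool included, silence
penalized through coverage) and a multi-threshold ROC view ranked by auROC
over rank-transformed scores (tools scoring fewer than half the variants are
excluded, as are tools whose numeric scale is an artificial recoding of
categorical labels).  Ranks are then averaged across cohorts — optionally
weighted by cohort size — to select the top tools, and variants of unknown
significance are triaged by how many of those top tools call them
pathogenic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortDataset
from .metrics import (
    confusion_at_threshold,
    rank_transform,
    roc_and_auroc,
)
from .registry import ScoreMatrix, ToolSpec

logger = logging.getLogger("varbench")


@dataclass
class RankingTable:
    """Tools of one dataset ordered by a single ranking metric."""

    dataset: str
    ranking_metric: str  # weighted_norm_mcc | auroc
    rows: pd.DataFrame  # one row per tool, includes 'tool' and 'rank'
    excluded: tuple = ()  # tools left out (e.g. low coverage), with reason

    def rank_of(self, tool: str) -> int:
        return int(self.rows.loc[self.rows["tool"] == tool, "rank"].iloc[0])


@dataclass
class PrioritizationReport:
    """Per-VUS ensemble agreement among top tools."""

    rows: pd.DataFrame  # variant, gene, n_tools_scored, n_tools_pathogenic, ...

    def tier_fractions(self) -> pd.Series:
        classified = self.rows[self.rows["tier"] != "unscored"]
        if len(classified) == 0:
            return pd.Series(dtype=float)
        return classified["tier"].value_counts(normalize=True)


def _labeled_subset(
    dataset: CohortDataset, matrix: ScoreMatrix
) -> tuple[list[str], np.ndarray]:
    keys = [r.key_str for r in dataset.records if r.label in ("pathogenic", "benign")]
    labels = np.array(
        [r.label == "pathogenic" for r in dataset.records
         if r.label in ("pathogenic", "benign")],
        dtype=bool,
    )
    missing = [k for k in keys if k not in matrix.data.index]
    if missing:
        raise ValueError(
            "score matrix lacks rows for labeled variants: "
            + ", ".join(missing[:5])
        )
    return keys, labels


def _sort_and_rank(rows: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Descending sort by metric (undefined last), ties by coverage then name."""
    df = rows.copy()
    df["_m"] = df[metric].fillna(-math.inf)
    cov = df["coverage"] if "coverage" in df.columns else 0.0
    df["_c"] = cov
    df = df.sort_values(
        by=["_m", "_c", "tool"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns=["_m", "_c"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def evaluate_fixed(
    dataset: CohortDataset,
    matrix: ScoreMatrix,
    registry: Sequence[ToolSpec],
    threshold_override: Mapping[str, float] | None = None,
) -> RankingTable:
    """Fixed-threshold evaluation ranked by coverage-weighted normalized MCC.

    Each tool is scored with its reference threshold, or with its entry in
    ``threshold_override`` (e.g. a calibrated threshold).  Tools whose
    ranking metric is undefined sort below all defined ones.
    """
    if threshold_override:
        known = {s.name for s in registry}
        unknown = set(threshold_override) - known
        if unknown:
            raise ValueError(f"override for unknown tool(s): {sorted(unknown)}")
    keys, labels = _labeled_subset(dataset, matrix)
    if labels.all() or not labels.any():
        raise ValueError("dataset must contain both pathogenic and benign variants")
    sub = matrix.subset(keys)
    rows = []
    for spec in registry:
        thr = (threshold_override or {}).get(spec.name, spec.reference_threshold)
        cs = confusion_at_threshold(sub.column(spec.name), labels, thr, spec.comparator)
        rows.append(
            {
                "tool": spec.name,
                "threshold": thr,
                "n_total": cs.n_total,
                "n_scored": cs.n_scored,
                "coverage": cs.coverage,
                "tp": cs.tp, "tn": cs.tn, "fp": cs.fp, "fn": cs.fn,
                "sensitivity": cs.sensitivity,
                "specificity": cs.specificity,
                "precision": cs.precision,
                "mcc": cs.mcc,
                "normalized_mcc": cs.normalized_mcc,
                "weighted_norm_mcc": cs.weighted_norm_mcc,
            }
        )
    table = _sort_and_rank(pd.DataFrame(rows), "weighted_norm_mcc")
    return RankingTable(dataset.name, "weighted_norm_mcc", table)


def evaluate_roc(
    dataset: CohortDataset,
    matrix: ScoreMatrix,
    registry: Sequence[ToolSpec],
    min_coverage: float = 0.5,
) -> RankingTable:
    """Multi-threshold (ROC) evaluation ranked by auROC.

    Scores are rank-transformed (direction-oriented) first; the curve is
    built from scored variants only.  Tools below ``min_coverage`` and tools
    flagged as categorical recodings are excluded and listed separately.
    """
    keys, labels = _labeled_subset(dataset, matrix)
    if labels.all() or not labels.any():
        raise ValueError("dataset must contain both pathogenic and benign variants")
    sub = matrix.subset(keys)
    rows, excluded = [], []
    for spec in registry:
        if spec.excluded_from_multithreshold:
            excluded.append((spec.name, "categorical"))
            continue
        col = sub.column(spec.name)
        cov = float(np.sum(~np.isnan(col))) / len(col)
        if cov < min_coverage:
            excluded.append((spec.name, f"coverage {cov:.3f} < {min_coverage}"))
            continue
        try:
            ranked = rank_transform(col, spec.direction)
            roc = roc_and_auroc(ranked, labels)
        except ValueError as err:
            excluded.append((spec.name, str(err)))
            continue
        rows.append(
            {
                "tool": spec.name,
                "n_total": len(col),
                "n_scored": roc.n_scored,
                "coverage": cov,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "auroc": roc.auroc,
            }
        )
    if not rows:
        raise ValueError("all tools were excluded from ROC evaluation")
    table = _sort_and_rank(pd.DataFrame(rows), "auroc")
    if excluded:
        logger.info(
            "evaluate_roc[%s]: excluded %s", dataset.name,
            "; ".join(f"{t} ({why})" for t, why in excluded),
        )
    return RankingTable(dataset.name, "auroc", table, excluded=tuple(excluded))


def average_rank_select(
    tables: Sequence[RankingTable],
    k: int,
    weights: Sequence[float] | None = None,
) -> list[str]:
    """Select the k tools with the lowest (weighted) mean rank across tables.

    A tool absent from a table (e.g. excluded by coverage) receives that
    table's worst rank + 1, so exclusion is penalized but not disqualifying.
    Ties in mean rank break lexicographically by tool name.
    """
    if not tables:
        raise ValueError("at least one ranking table is required")
    if weights is None:
        w = np.ones(len(tables))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(tables),) or (w <= 0).any():
            raise ValueError("weights must be positive, one per table")
    universe = sorted({t for tb in tables for t in tb.rows["tool"]})
    if k > len(universe):
        raise ValueError(f"k={k} exceeds the {len(universe)} ranked tools")
    ranks = np.empty((len(tables), len(universe)), dtype=float)
    for i, tb in enumerate(tables):
        worst = len(tb.rows)
        lookup = dict(zip(tb.rows["tool"], tb.rows["rank"]))
        for j, tool in enumerate(universe):
            if tool in lookup:
                ranks[i, j] = lookup[tool]
            else:
                ranks[i, j] = worst + 1
                logger.info(
                    "average_rank_select: %s missing from %s; assigned rank %d",
                    tool, tb.dataset, worst + 1,
                )
    mean_rank = (w[:, None] * ranks).sum(axis=0) / w.sum()
    order = sorted(zip(mean_rank, universe))
    return [tool for _, tool in order[:k]]


def prioritize_vus(
    vus_matrix: ScoreMatrix,
    top_tools: Sequence[ToolSpec],
    thresholds: Mapping[str, float] | None = None,
    majority: float = 0.5,
    genes: Mapping[str, str] | None = None,
) -> PrioritizationReport:
    """Triage unlabeled/VUS variants by top-tool agreement.

    For each variant, every top tool that scored it votes with its strict
    comparator at its (possibly calibrated) threshold.  The agreement
    fraction uses the tools that scored the variant as denominator.  Tiers:
    ``unanimous_pathogenic`` (all scoring tools vote pathogenic),
    ``majority_pathogenic`` (fraction strictly above ``majority``),
    ``majority_benign`` (otherwise), ``unscored`` (no tool scored it;
    excluded from percentage summaries).
    """
    if not top_tools:
        raise ValueError("top_tools must be non-empty")
    thresholds = thresholds or {}
    missing_thr = [
        s.name for s in top_tools
        if s.name not in thresholds and s.reference_threshold is None
    ]
    if missing_thr:
        raise ValueError(f"no threshold for tool(s): {missing_thr}")
    rows = []
    for key in vus_matrix.variants:
        n_scored = 0
        n_path = 0
        for spec in top_tools:
            val = vus_matrix.data.at[key, spec.name]
            if pd.isna(val):
                continue
            n_scored += 1
            thr = thresholds.get(spec.name, spec.reference_threshold)
            if spec.is_pathogenic_call(float(val), thr):
                n_path += 1
        if n_scored == 0:
            tier, frac = "unscored", math.nan
            logger.info("prioritize_vus: %s scored by zero tools", key)
        else:
            frac = n_path / n_scored
            if n_path == n_scored:
                tier = "unanimous_pathogenic"
            elif frac > majority:
                tier = "majority_pathogenic"
            else:
                tier = "majority_benign"
        rows.append(
            {
                "variant": key,
                "gene": (genes or {}).get(key, ""),
                "n_tools_scored": n_scored,
                "n_tools_pathogenic": n_path,
                "agreement_fraction": frac,
                "tier": tier,
            }
        )
    return PrioritizationReport(pd.DataFrame(rows))
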