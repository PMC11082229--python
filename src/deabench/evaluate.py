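"""Benchmark metrics, rank aggregation, performance levels, LODOCV, and
cross-setting comparison.

A workflow is scored on five metrics against spike-in ground truth: partial
AUC of the 1-q confidence ROC at FPR caps 0.01 / 0.05 / 0.1 (raw,
unstandardized areas), the normalized Matthews correlation (MCC+1)/2, and
the geometric mean of specificity and recall. Each metric is converted to a
rank over workflows (average-tie convention, larger metric = better) and
the final rank is the arithmetic mean of the five ranks. Workflows are then
binned into performance levels H / RH / RL / L at the top 5% / 25% / 50%
positions using a ceiling rule on the bin boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .core import GroundTruth, PROTEIN_GROUP_DELIMITER, WorkflowSpec
from .stats import DEAResult, LOGFC_THRESHOLD, Q_THRESHOLD, call_de

__all__ = [
    "ConfusionCounts", "MetricVector", "confusion_counts", "nmcc", "gmean",
    "f1_mcc", "pauc", "metric_vector", "aggregate_ranks", "label_levels",
    "spearman", "lodocv", "kruskal_wallis_ranks", "pairwise_option_compare",
    "cross_setting_compare",
]

METRIC_NAMES = ("pauc001", "pauc005", "pauc01", "nmcc", "gmean")
LEVELS = ("H", "RH", "RL", "L")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricVector:
    """The five benchmark metrics for one workflow on one contrast."""

    pauc001: float
    pauc005: float
    pauc01: float
    nmcc: float
    gmean: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pauc001, self.pauc005, self.pauc01, self.nmcc, self.gmean])


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

def confusion_counts(
    result: DEAResult,
    truth: GroundTruth,
    logfc_thresh: float = LOGFC_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
) -> ConfusionCounts:
    """TP/FP/TN/FN of the DE calls against ground truth."""
    proteins = list(result.table["protein"])
    missing = [p for p in proteins if p not in truth.is_de]
    if missing:
        raise KeyError(f"proteins absent from truth: {missing[:5]}")
    calls = call_de(result, logfc_thresh, q_thresh)
    tp = fp = tn = fn = 0
    for p in proteins:
        called = bool(calls[p])
        if truth.is_de[p]:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return ConfusionCounts(tp, fp, tn, fn)


def _mcc(c: ConfusionCounts) -> float:
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def nmcc(c: ConfusionCounts) -> float:
    """Normalized Matthews correlation (MCC + 1) / 2; zero denominator -> MCC 0."""
    return 0.5 * (_mcc(c) + 1.0)


def gmean(c: ConfusionCounts) -> float:
    """Geometric mean of specificity and recall; undefined terms count as 0."""
    spec = c.tn / (c.fp + c.tn) if (c.fp + c.tn) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return math.sqrt(spec * rec)


def f1_mcc(c: ConfusionCounts) -> tuple[float, float]:
    """(F1, MCC) of a confusion matrix (classifier-evaluation metrics)."""
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return f1, _mcc(c)


# ---------------------------------------------------------------------------
# Partial AUC
# ---------------------------------------------------------------------------

def pauc(
    confidences: Mapping[str, float] | pd.Series,
    truth: GroundTruth,
    fpr_max: float,
) -> float:
    """Raw trapezoidal ROC area over FPR in [0, fpr_max].

    Confidence = 1 - q per protein; tied confidences traverse the ROC
    diagonally (simultaneous step). Returns a value in [0, fpr_max].
    """
    if not 0 < fpr_max <= 1:
        raise ValueError("fpr_max must lie in (0, 1]")
    conf = pd.Series(confidences)
    y = np.array([truth.is_de[p] for p in conf.index], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("pAUC needs both positive and negative proteins in truth")
    fpr, tpr, _ = roc_curve(y, conf.to_numpy(), drop_intermediate=False)
    # clip the curve at fpr_max, interpolating the last segment
    area = 0.0
    for k in range(1, fpr.size):
        x0, x1 = fpr[k - 1], fpr[k]
        y0, y1 = tpr[k - 1], tpr[k]
        if x0 >= fpr_max:
            break
        if x1 > fpr_max:
            y1 = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            x1 = fpr_max
        area += (x1 - x0) * (y0 + y1) / 2.0
    return float(area)


def metric_vector(
    result: DEAResult,
    truth: GroundTruth,
    logfc_thresh: float = LOGFC_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
) -> MetricVector:
    """The five benchmark metrics for one DEA result."""
    conf = pd.Series(
        1.0 - result.table["qvalue"].to_numpy(), index=result.table["protein"].to_numpy()
    )
    c = confusion_counts(result, truth, logfc_thresh, q_thresh)
    return MetricVector(
        pauc001=pauc(conf, truth, 0.01),
        pauc005=pauc(conf, truth, 0.05),
        pauc01=pauc(conf, truth, 0.1),
        nmcc=nmcc(c),
        gmean=gmean(c),
    )


# ---------------------------------------------------------------------------
# Rank aggregation and performance levels
# ---------------------------------------------------------------------------

def label_levels(n_total: int, positions: Sequence[int]) -> list[str]:
    """Performance level per ranking position.

    H = top 5%, RH = 5-25%, RL = 25-50%, L = bottom half, with ceiling-rule
    bin boundaries: position <= ceil(0.05 N) is H, and so on.
    """
    h_cut = math.ceil(0.05 * n_total)
    rh_cut = math.ceil(0.25 * n_total)
    rl_cut = math.ceil(0.50 * n_total)
    out = []
    for pos in positions:
        if not 1 <= pos <= n_total:
            raise ValueError(f"position {pos} outside 1..{n_total}")
        if pos <= h_cut:
            out.append("H")
        elif pos <= rh_cut:
            out.append("RH")
        elif pos <= rl_cut:
            out.append("RL")
        else:
            out.append("L")
    return out


def aggregate_ranks(metrics: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-workflow mean metrics into the final ranking table.

    ``metrics``: one row per workflow (index = workflow key or WorkflowSpec
    string), columns = the five metric names. Per metric, workflows are
    ranked descending by performance (average-tie convention); the final
    rank is the mean of the five ranks; the table is ordered by final rank,
    ties broken lexicographically by workflow key. Adds positions 1..N,
    ranking_score = N - position, and the performance level.
    """
    if metrics.shape[0] < 2:
        raise ValueError("ranking needs >= 2 workflows")
    missing = set(METRIC_NAMES) - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    out = metrics.copy()
    out.index = out.index.map(str)
    for m in METRIC_NAMES:
        out[f"rank_{m}"] = sps.rankdata(-out[m].to_numpy(), method="average")
    out["rank_final"] = out[[f"rank_{m}" for m in METRIC_NAMES]].mean(axis=1)
    # stable sort: lexicographic by workflow key first, then by final rank,
    # so ties end up in lexicographic order
    out = out.sort_index(kind="mergesort").sort_values("rank_final", kind="mergesort")
    n = out.shape[0]
    out["position"] = np.arange(1, n + 1)
    out["ranking_score"] = n - out["position"]
    out["level"] = label_levels(n, out["position"].tolist())
    return out


def spearman(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Spearman rank correlation (average-tie ranks)."""
    a = np.asarray(ranks_a, float)
    b = np.asarray(ranks_b, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(sps.spearmanr(a, b).statistic)


def lodocv(per_dataset_metrics: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Leave-one-dataset-out validation of the workflow ranking.

    For each held-out dataset, workflows are ranked on the mean metrics of
    the remaining datasets and on the held-out dataset alone; the returned
    series holds the Spearman correlation of the two final-rank vectors.
    """
    names = list(per_dataset_metrics)
    if len(names) < 3:
        raise ValueError("LODOCV needs >= 3 datasets")
    wf_index = per_dataset_metrics[names[0]].index
    for name in names[1:]:
        if not per_dataset_metrics[name].index.equals(wf_index):
            raise ValueError("datasets must share one workflow index")
    correlations = {}
    for held_out in names:
        rest = [per_dataset_metrics[n] for n in names if n != held_out]
        mean_rest = sum(df[list(METRIC_NAMES)] for df in rest) / len(rest)
        train = aggregate_ranks(mean_rest)
        test = aggregate_ranks(per_dataset_metrics[held_out][list(METRIC_NAMES)])
        keys = train.index
        correlations[held_out] = spearman(
            train.loc[keys, "rank_final"], test.loc[keys, "rank_final"]
        )
    return pd.Series(correlations, name="spearman_r")


def kruskal_wallis_ranks(
    rank_groups: Mapping[str, Sequence[float]], min_n: int = 5
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test on grouped workflow ranks.

    Mirrors the instrument-sensitivity check: every group must have at
    least ``min_n`` members or the test is refused.
    """
    if len(rank_groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, vals in rank_groups.items():
        if len(vals) < min_n:
            raise ValueError(f"group {g!r} has {len(vals)} < {min_n} members")
    h, p = sps.kruskal(*rank_groups.values())
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Matched-pair option comparison
# ---------------------------------------------------------------------------

_STEP_FIELDS = {
    "matrix": "matrix_type",
    "normalization": "normalization",
    "imputation": "imputation",
    "dea": "dea",
}


def pairwise_option_compare(
    step: str,
    specs: Sequence[WorkflowSpec],
    metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Rank the options of one workflow step by matched-pair comparisons.

    For every option pair, workflows identical in every other step form
    matched pairs; an option wins a pair when its mean metric difference is
    positive. Per metric, options are ordered by win count (ties broken by
    the option's median metric over its workflows); the final option rank
    is the mean of the five per-metric ranks. ``metrics`` is indexed by
    str(spec). Option pairs without matched workflows are skipped and
    reported in the ``skipped_pairs`` DataFrame attribute.
    """
    if step not in _STEP_FIELDS:
        raise ValueError(f"unknown step {step!r}")
    field_name = _STEP_FIELDS[step]
    by_rest: dict[tuple, dict[str, str]] = {}
    for spec in specs:
        option = getattr(spec, field_name)
        rest = tuple(
            getattr(spec, f) for f in
            ("setting", "matrix_type", "normalization", "imputation", "dea")
            if f != field_name
        )
        by_rest.setdefault(rest, {})[option] = str(spec)
    options = sorted({getattr(s, field_name) for s in specs})
    skipped = []
    per_metric_rank = {}
    for m in METRIC_NAMES:
        wins = {o: 0 for o in options}
        for a, b in combinations(options, 2):
            diffs = []
            for members in by_rest.values():
                if a in members and b in members:
                    diffs.append(metrics.loc[members[a], m] - metrics.loc[members[b], m])
            if not diffs:
                skipped.append((m, a, b))
                continue
            mean_diff = float(np.mean(diffs))
            if mean_diff > 0:
                wins[a] += 1
            elif mean_diff < 0:
                wins[b] += 1
        medians = {
            o: float(
                metrics.loc[
                    [str(s) for s in specs if getattr(s, field_name) == o], m
                ].median()
            )
            for o in options
        }
        order = sorted(options, key=lambda o: (-wins[o], -medians[o], o))
        scores = [(-wins[o], -medians[o]) for o in order]
        ranks = {}
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and scores[j] == scores[i]:
                j += 1
            avg = (i + 1 + j) / 2.0
            for k in range(i, j):
                ranks[order[k]] = avg
            i = j
        per_metric_rank[m] = ranks
    table = pd.DataFrame(
        {m: {o: per_metric_rank[m][o] for o in options} for m in METRIC_NAMES}
    )
    table["rank_final"] = table[list(METRIC_NAMES)].mean(axis=1)
    table = table.sort_values(["rank_final"], kind="mergesort")
    table.attrs["skipped_pairs"] = skipped
    return table


# ---------------------------------------------------------------------------
# Cross-setting comparison
# ---------------------------------------------------------------------------

def cross_setting_compare(
    results: Mapping[str, DEAResult],
    truth: GroundTruth,
    logfc_thresh: float = LOGFC_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
    delimiter: str = PROTEIN_GROUP_DELIMITER,
) -> dict[str, ConfusionCounts]:
    """Compare settings over the merged protein list.

    Proteins from all settings are merged; multi-protein groups are
    removed; a protein absent from a setting is padded with log2fc = 0 and
    q = 1 (never called DE), so a truly-DE absentee counts as FN and a
    truly-null absentee as TN.
    """
    if len(results) < 2:
        raise ValueError("cross-setting comparison needs >= 2 settings")
    merged: set[str] = set()
    for res in results.values():
        merged |= set(res.table["protein"])
    merged = {p for p in merged if delimiter not in p}
    if not merged:
        raise ValueError("no single-protein groups shared across settings")
    proteins = sorted(merged)
    not_covered = [p for p in proteins if p not in truth.is_de]
    if not_covered:
        raise KeyError(f"truth does not cover {not_covered[:5]}")
    out = {}
    for setting, res in results.items():
        table = res.table.set_index("protein")
        padded = pd.DataFrame(
            {
                "protein": proteins,
                "log2fc": [
                    float(table.at[p, "log2fc"]) if p in table.index else 0.0
                    for p in proteins
                ],
                "pvalue": [
                    float(table.at[p, "pvalue"]) if p in table.index else 1.0
                    for p in proteins
                ],
                "qvalue": [
                    float(table.at[p, "qvalue"]) if p in table.index else 1.0
                    for p in proteins
                ],
            }
        )
        padded_res = DEAResult(padded, contrast=res.contrast, spec=res.spec)
        out[setting] = confusion_counts(padded_res, truth, logfc_thresh, q_thresh)
    return out
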