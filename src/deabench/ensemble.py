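"""Ensemble inference across DEA workflows.

Per protein, the member workflows' p-values are combined by one of five
combiners and the member log2 fold changes are integrated by taking the
one of largest magnitude; the combined p-values are then BH-adjusted over
the ensemble's protein list. Combiners:

- ``hurdle``: z_i = Phi^-1(1 - p_i), statistic sum z_i^2 ~ chi^2 with t
  degrees of freedom when t of the K members observed the protein; t = 1
  returns the single p unchanged; t = 0 gives p = 1.
- ``fisher``: -2 sum ln p_i ~ chi^2 with 2t degrees of freedom.
- ``min`` / ``max`` / ``median``: order-statistic voting (any / all /
  majority of members significant), median uses the midpoint rule for an
  even member count.

Two orchestrators mirror the two ensembling strategies: ``ens_multi_quant``
combines the best workflow per quantification view; ``ens_topk`` combines
the global top-k workflows of a ranking.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import DEAResult, bh_adjust

__all__ = [
    "combine_pvalues_hurdle", "combine_pvalues_fisher", "combine_pvalues_vote",
    "combine_logfc", "combine_results", "ens_multi_quant", "ens_topk",
    "ENSEMBLE_METHODS",
]

ENSEMBLE_METHODS = ("hurdle", "fisher", "min", "max", "median")

_P_FLOOR = 1e-300


def _clean(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray([v for v in pvalues if v is not None and not np.isnan(v)], float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clipped to 1e-300")
        p = np.maximum(p, _P_FLOOR)
    return p


def combine_pvalues_hurdle(pvalues: Sequence[float]) -> float:
    """Hurdle combination: sum of squared normal quantiles, chi^2 on t df."""
    p = _clean(pvalues)
    t = p.size
    if t == 0:
        return 1.0
    if t == 1:
        return float(p[0])
    z = sps.norm.ppf(1.0 - p)
    statistic = float(z @ z)
    return float(sps.chi2.sf(statistic, t))


def combine_pvalues_fisher(pvalues: Sequence[float]) -> float:
    """Fisher's method: -2 sum ln p, chi^2 on 2t df (t = members present)."""
    p = _clean(pvalues)
    t = p.size
    if t == 0:
        return 1.0
    statistic = float(-2.0 * np.log(p).sum())
    return float(sps.chi2.sf(statistic, 2 * t))


def combine_pvalues_vote(pvalues: Sequence[float], mode: str) -> float:
    """Order-statistic voting: min / max / median of the present p-values."""
    p = _clean(pvalues)
    if p.size == 0:
        return 1.0
    if mode == "min":
        return float(p.min())
    if mode == "max":
        return float(p.max())
    if mode == "median":
        return float(np.median(p))
    raise ValueError(f"unknown voting mode {mode!r}")


def combine_logfc(log2fcs: Sequence[float]) -> float:
    """The member log2FC of largest magnitude; ties go to the earlier member."""
    values = [v for v in log2fcs if v is not None and not np.isnan(v)]
    if not values:
        raise ValueError("no log2 fold changes to combine")
    best = values[0]
    for v in values[1:]:
        if abs(v) > abs(best):
            best = v
    return float(best)


def _combine_p(pvalues: Sequence[float], method: str) -> float:
    if method == "hurdle":
        return combine_pvalues_hurdle(pvalues)
    if method == "fisher":
        return combine_pvalues_fisher(pvalues)
    if method in {"min", "max", "median"}:
        return combine_pvalues_vote(pvalues, method)
    raise ValueError(f"unknown ensemble method {method!r}")


def combine_results(members: Sequence[DEAResult], method: str) -> DEAResult:
    """Combine >= 2 member DEA results into one ensembled result.

    Proteins present in at least one member are kept; each protein's
    combined p uses the members that observed it; q-values are recomputed
    by BH over the ensemble protein list.
    """
    if len(members) < 2:
        raise ValueError("ensemble needs >= 2 member results")
    contrasts = {m.contrast for m in members if m.contrast is not None}
    if len(contrasts) > 1:
        raise ValueError(f"members span different contrasts: {sorted(contrasts)}")
    tables = [m.table.set_index("protein") for m in members]
    proteins = sorted(set().union(*(t.index for t in tables)))
    combined_p = np.empty(len(proteins))
    combined_fc = np.empty(len(proteins))
    for i, prot in enumerate(proteins):
        ps = [float(t.at[prot, "pvalue"]) for t in tables if prot in t.index]
        fcs = [float(t.at[prot, "log2fc"]) for t in tables if prot in t.index]
        combined_p[i] = _combine_p(ps, method)
        combined_fc[i] = combine_logfc(fcs)
    table = pd.DataFrame(
        {
            "protein": proteins,
            "log2fc": combined_fc,
            "pvalue": combined_p,
            "qvalue": bh_adjust(combined_p),
            "flagged": False,
        }
    )
    contrast = next(iter(contrasts)) if contrasts else None
    return DEAResult(table, contrast=contrast)


def ens_multi_quant(
    per_view_results: Mapping[str, DEAResult], method: str = "hurdle"
) -> DEAResult:
    """Ensemble of the top workflow per quantification view (matrix type).

    ``per_view_results`` maps matrix type -> that view's best workflow
    result; at least two distinct views are required.
    """
    if len(per_view_results) < 2:
        raise ValueError("ens_multi_quant needs results from >= 2 matrix types")
    return combine_results(list(per_view_results.values()), method)


def ens_topk(
    ranking: pd.DataFrame,
    k: int,
    results: Mapping[str, DEAResult],
    method: str = "hurdle",
) -> DEAResult:
    """Ensemble of the global top-k workflows of an aggregate_ranks table.

    ``results`` maps str(spec) -> DEAResult for (at least) the top-k rows.
    """
    if k < 2:
        raise ValueError("ens_topk needs k >= 2")
    if k > ranking.shape[0]:
        raise ValueError(f"k={k} exceeds the {ranking.shape[0]} ranked workflows")
    top = ranking.sort_values("position").index[:k]
    missing = [w for w in top if w not in results]
    if missing:
        raise KeyError(f"no DEA result supplied for top workflows: {missing}")
    return combine_results([results[w] for w in top], method)
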