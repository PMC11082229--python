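"""Normalization and missing-value imputation for expression matrices.

Normalization removes cross-sample systematic bias and never touches the
missingness pattern; imputation fills missing cells and never alters an
observed value. Every operation returns the transformed matrix together
with a :class:`PreprocessRecord` that is sufficient to replay it.

Scaling-type corrections (div.*, total, max) act on the raw intensity
scale; centering and regression-based corrections (center.*, Rlr, lossf)
act on log2 intensities, matching how these methods are used in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from .core import ExpressionMatrix, MISSING

__all__ = ["PreprocessRecord", "normalize", "impute", "register_plugin", "PLUGINS"]


@dataclass
class PreprocessRecord:
    """Audit record of one preprocessing step."""

    method: str
    parameters: dict = field(default_factory=dict)
    per_sample: dict = field(default_factory=dict)
    seed: int | None = None
    fallbacks: list = field(default_factory=list)


#: User-registered plugin transforms: {"normalization"|"imputation": {name: fn}}.
#: A plugin takes and returns an ExpressionMatrix.
PLUGINS: dict[str, dict[str, Callable]] = {"normalization": {}, "imputation": {}, "dea": {}}


def register_plugin(step: str, name: str, fn: Callable) -> None:
    """Register an implementation for a plugin-slot option."""
    if step not in PLUGINS:
        raise ValueError(f"unknown plugin step {step!r}")
    PLUGINS[step][name] = fn


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

_RAW_SCALE_METHODS = {"div.mean", "div.median", "total", "sum", "max"}
_LOG_SCALE_METHODS = {"center.mean", "center.median", "Rlr", "lossf"}


def normalize(
    matrix: ExpressionMatrix, method: str
) -> tuple[ExpressionMatrix, PreprocessRecord]:
    """Apply a per-sample normalization. "sum"/"TIC" are aliases of "total"."""
    if method in {"sum", "TIC"}:
        method = "total"
    if method in _RAW_SCALE_METHODS and matrix.scale != "raw":
        raise ValueError(f"{method} operates on the raw scale")
    if method in _LOG_SCALE_METHODS and matrix.scale != "log2":
        raise ValueError(f"{method} operates on the log2 scale")

    record = PreprocessRecord(method=method)
    x = matrix.values.copy()
    mask = np.isnan(x)

    if method == "none":
        pass
    elif method in {"center.mean", "center.median"}:
        stat = np.nanmean if method == "center.mean" else np.nanmedian
        offsets = stat(x, axis=0)
        x = x - offsets
        record.per_sample["offset"] = dict(zip(matrix.sample_ids, offsets.tolist()))
    elif method in {"div.mean", "div.median"}:
        stat = np.nanmean if method == "div.mean" else np.nanmedian
        scales = stat(x, axis=0)
        x = x / scales
        record.per_sample["scale"] = dict(zip(matrix.sample_ids, scales.tolist()))
    elif method == "total":
        sums = np.nansum(x, axis=0)
        x = x / sums * sums.mean()
        record.per_sample["scale"] = dict(zip(matrix.sample_ids, (sums / sums.mean()).tolist()))
    elif method == "max":
        maxes = np.nanmax(x, axis=0)
        x = x / maxes
        record.per_sample["scale"] = dict(zip(matrix.sample_ids, maxes.tolist()))
    elif method in {"quantiles", "quantiles.robust"}:
        x = _quantile_normalize(x, robust=method.endswith("robust"))
    elif method == "MBQN":
        means = np.nanmean(x, axis=0)
        x = _quantile_normalize(x, robust=False)
        x = x - np.nanmean(x, axis=0) + means
        record.per_sample["restored_mean"] = dict(zip(matrix.sample_ids, means.tolist()))
    elif method == "Rlr":
        x = _regression_normalize(x, robust=True)
    elif method == "lossf":
        x = _regression_normalize(x, robust=False)
    elif method in PLUGINS["normalization"]:
        out = PLUGINS["normalization"][method](matrix)
        record.parameters["plugin"] = True
        return out, record
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    x[mask] = MISSING  # normalization must not create or destroy missingness
    return matrix.copy_with(values=x), record


def _quantile_normalize(x: np.ndarray, robust: bool) -> np.ndarray:
    """Quantile normalization tolerating missing values.

    Each column's observed empirical quantile function is interpolated onto
    a common grid; the reference is the per-quantile mean (or median for the
    robust variant). Observed values are replaced by the reference evaluated
    at their average-rank quantile, so columns with identical rank order
    become identical and complete columns share one multiset of values.
    """
    n_rows, n_cols = x.shape
    grid = np.linspace(0.0, 1.0, n_rows)
    curves = np.empty((n_rows, n_cols))
    for j in range(n_cols):
        obs = np.sort(x[~np.isnan(x[:, j]), j])
        if obs.size == 0:
            raise ValueError(f"column {j} has no observed values")
        q = np.linspace(0.0, 1.0, obs.size) if obs.size > 1 else np.array([0.5])
        curves[:, j] = np.interp(grid, q, obs)
    reference = np.median(curves, axis=1) if robust else curves.mean(axis=1)
    out = x.copy()
    for j in range(n_cols):
        idx = ~np.isnan(x[:, j])
        n_obs = int(idx.sum())
        ranks = rankdata(x[idx, j], method="average")
        q = (ranks - 1.0) / (n_obs - 1.0) if n_obs > 1 else np.full(1, 0.5)
        out[idx, j] = np.interp(q, grid, reference)
    return out


def _regression_normalize(x: np.ndarray, robust: bool) -> np.ndarray:
    """Remove each sample's systematic deviation from the row-median profile.

    The sample is regressed on the reference profile (Huber robust line for
    Rlr, lowess curve for lossf) and the fitted systematic deviation
    fit(ref) - ref is subtracted, so a sample already matching the reference
    is returned unchanged and per-protein group differences are preserved.
    """
    reference = np.nanmedian(x, axis=1)
    out = x.copy()
    for j in range(x.shape[1]):
        idx = ~np.isnan(x[:, j]) & ~np.isnan(reference)
        ref, y = reference[idx], x[idx, j]
        if ref.size < 3 or np.ptp(ref) == 0:
            continue
        if robust:
            import statsmodels.api as sm

            model = sm.RLM(y, sm.add_constant(ref), M=sm.robust.norms.HuberT())
            params = model.fit().params
            fitted = params[0] + params[1] * ref
        else:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            fitted = lowess(y, ref, frac=2.0 / 3.0, return_sorted=False)
        out[idx, j] = y - (fitted - ref)
    return out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

_K_NEIGHBORS = 10
_SD_FLOOR = 1e-6


def impute(
    matrix: ExpressionMatrix,
    method: str,
    seed: int = 0,
    q: float = 0.01,
    tune: float = 1.0,
) -> tuple[ExpressionMatrix, PreprocessRecord]:
    """Fill missing cells. Observed values are never altered.

    All methods except ``none``/``zero`` expect log2-scale input. Proteins
    with no observed value fall back to MinDet under knn/SeqKNN/Impseq and
    the fallback is noted in the record.
    """
    record = PreprocessRecord(method=method, seed=seed, parameters={"q": q, "tune": tune})
    if method == "none":
        return matrix.copy_with(), record
    if method not in {"zero"} and matrix.scale != "log2" and method not in PLUGINS["imputation"]:
        raise ValueError(f"imputation {method!r} expects a log2-scale matrix")

    x = matrix.values.copy()
    mask = np.isnan(x)

    if method == "zero":
        x[mask] = 0.0
    elif method == "min":
        x[mask] = np.nanmin(x)
    elif method == "MinDet":
        x = _min_det(x, q)
    elif method == "MinProb":
        rng = np.random.default_rng(seed)
        centers = np.nanquantile(x, q, axis=0)
        sds = _protein_sds(x)
        sd = max(tune * float(np.nanmedian(sds)), _SD_FLOOR)
        for j in range(x.shape[1]):
            rows = np.flatnonzero(mask[:, j])
            x[rows, j] = rng.normal(centers[j], sd, size=rows.size)
        record.parameters["draw_sd"] = sd
    elif method == "knn":
        x = _knn_impute(x, record, q)
    elif method == "SeqKNN":
        x = _seq_knn_impute(x, record, q)
    elif method == "Impseq":
        x = _impseq_impute(x, record, q)
    elif method in PLUGINS["imputation"]:
        out = PLUGINS["imputation"][method](matrix)
        record.parameters["plugin"] = True
        return out, record
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    x[~mask] = matrix.values[~mask]
    return matrix.copy_with(values=x), record


def _min_det(x: np.ndarray, q: float) -> np.ndarray:
    out = x.copy()
    lows = np.nanquantile(x, q, axis=0)
    for j in range(x.shape[1]):
        out[np.isnan(x[:, j]), j] = lows[j]
    return out


def _protein_sds(x: np.ndarray) -> np.ndarray:
    """Per-protein sd over observed entries (needs >= 2 observations)."""
    counts = (~np.isnan(x)).sum(axis=1)
    rows = x[counts >= 2]
    if rows.size == 0:
        return np.array([])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sds = np.nanstd(rows, axis=1, ddof=1)
    return sds[np.isfinite(sds)]


def _pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """RMS difference over jointly observed samples; inf if none shared."""
    shared = ~np.isnan(a) & ~np.isnan(b)
    n = int(shared.sum())
    if n == 0:
        return np.inf
    d = a[shared] - b[shared]
    return float(np.sqrt((d @ d) / n))


def _knn_impute(x: np.ndarray, record: PreprocessRecord, q: float) -> np.ndarray:
    """Non-sequential KNN: neighbors drawn from the original matrix.

    For each missing cell, the K nearest proteins (RMS distance over shared
    samples, smaller index wins ties) among those observed in that column
    donate their column mean.
    """
    out = x.copy()
    fallback = _min_det(x, q)
    n = x.shape[0]
    incomplete = np.flatnonzero(np.isnan(x).any(axis=1))
    for i in incomplete:
        if not np.any(~np.isnan(x[i])):
            out[i] = fallback[i]
            record.fallbacks.append(int(i))
            continue
        dists = np.array([_pairwise_distance(x[i], x[k]) if k != i else np.inf
                          for k in range(n)])
        for j in np.flatnonzero(np.isnan(x[i])):
            candidates = np.flatnonzero(~np.isnan(x[:, j]) & np.isfinite(dists))
            if candidates.size == 0:
                out[i, j] = fallback[i, j]
                record.fallbacks.append((int(i), int(j)))
                continue
            order = candidates[np.lexsort((candidates, dists[candidates]))]
            chosen = order[:_K_NEIGHBORS]
            out[i, j] = float(x[chosen, j].mean())
    return out


def _seq_knn_impute(x: np.ndarray, record: PreprocessRecord, q: float) -> np.ndarray:
    """Sequential KNN: proteins imputed in order of ascending missing rate;
    once imputed, a protein joins the pool of eligible (complete) neighbors."""
    out = x.copy()
    fallback = _min_det(x, q)
    miss = np.isnan(x)
    pool = list(np.flatnonzero(~miss.any(axis=1)))
    todo = np.flatnonzero(miss.any(axis=1))
    todo = todo[np.lexsort((todo, miss[todo].mean(axis=1)))]
    for i in todo:
        if not np.any(~np.isnan(x[i])) or not pool:
            out[i] = np.where(miss[i], fallback[i], out[i])
            record.fallbacks.append(int(i))
            pool.append(int(i))
            continue
        pool_arr = np.array(sorted(pool))
        dists = np.array([_pairwise_distance(x[i], out[k]) for k in pool_arr])
        finite = np.isfinite(dists)
        if not finite.any():
            out[i] = np.where(miss[i], fallback[i], out[i])
            record.fallbacks.append(int(i))
            pool.append(int(i))
            continue
        order = pool_arr[finite][np.lexsort((pool_arr[finite], dists[finite]))]
        chosen = order[:_K_NEIGHBORS]
        for j in np.flatnonzero(miss[i]):
            out[i, j] = float(out[chosen, j].mean())
        pool.append(int(i))
    return out


def _impseq_impute(x: np.ndarray, record: PreprocessRecord, q: float) -> np.ndarray:
    """Sequential regression imputation.

    Proteins are processed by ascending missing rate. A missing cell in
    sample j is predicted by an ordinary least-squares regression of sample
    j on the protein's observed samples, fitted over the proteins that are
    currently complete (previously imputed proteins included).
    """
    out = x.copy()
    fallback = _min_det(x, q)
    miss = np.isnan(x)
    complete = ~miss.any(axis=1)
    todo = np.flatnonzero(miss.any(axis=1))
    todo = todo[np.lexsort((todo, miss[todo].mean(axis=1)))]
    for i in todo:
        obs_cols = np.flatnonzero(~np.isnan(x[i]))
        donors = np.flatnonzero(complete)
        if obs_cols.size == 0 or donors.size < obs_cols.size + 2:
            out[i] = np.where(miss[i], fallback[i], out[i])
            record.fallbacks.append(int(i))
            complete[i] = True
            continue
        X = np.column_stack([np.ones(donors.size), out[np.ix_(donors, obs_cols)]])
        for j in np.flatnonzero(miss[i]):
            beta, *_ = np.linalg.lstsq(X, out[donors, j], rcond=None)
            out[i, j] = float(beta[0] + beta[1:] @ x[i, obs_cols])
        complete[i] = True
    return out
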