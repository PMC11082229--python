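"""Reference DEA statistics, FDR control, DE calling, and workflow execution.

The built-in statistics are the Welch t-test, a one-way F test, and an
empirical-Bayes moderated t in which per-protein residual variances are
shrunk toward a prior fitted by method of moments on log s^2. Third-party
DEA tools plug in through :func:`deabench.preprocess.register_plugin`
with the contract (matrix, design) -> per-protein (log2fc, p); the runner
BH-adjusts afterwards.

Conventions: log2fc = mean(group_a) - mean(group_b); proteins that cannot
be tested (fewer than two observations in a group) are kept with p = 1 and
flagged, so every protein of the input has a record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .core import (
    ContrastDesign,
    COUNT_BASED_DEA,
    COUNT_MATRIX_TYPES,
    ExpressionMatrix,
    WorkflowSpec,
    log_transform,
    validate_workflow,
)
from .preprocess import PLUGINS, PreprocessRecord, impute, normalize

__all__ = [
    "DEAResult", "ttest", "anova_f", "moderated_t", "bh_adjust", "call_de",
    "run_workflow", "LOGFC_THRESHOLD", "Q_THRESHOLD",
]

#: Default DE-call thresholds: |log2FC| >= log2(1.5) and q < 0.05.
LOGFC_THRESHOLD = math.log2(1.5)
Q_THRESHOLD = 0.05


@dataclass
class DEAResult:
    """Per-protein differential-expression statistics for one contrast."""

    table: pd.DataFrame  # columns: protein, log2fc, pvalue, qvalue, flagged
    contrast: tuple[str, str] | None = None
    spec: WorkflowSpec | None = None
    records: list[PreprocessRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"protein", "log2fc", "pvalue", "qvalue"}
        if not required <= set(self.table.columns):
            raise ValueError(f"result table needs columns {sorted(required)}")
        if self.table["protein"].duplicated().any():
            raise ValueError("duplicate protein records in DEA result")

    def write(self, path) -> None:
        self.table[["protein", "log2fc", "pvalue", "qvalue"]].to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def _group_arrays(matrix: ExpressionMatrix, design: ContrastDesign):
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    a, b = design.contrast
    ja = [col[s] for s in design.samples_of(a) if s in col]
    jb = [col[s] for s in design.samples_of(b) if s in col]
    if len(ja) < 2 or len(jb) < 2:
        raise ValueError("each contrast group needs >= 2 samples present in the matrix")
    return matrix.values[:, ja], matrix.values[:, jb]


def _finish(matrix, design, log2fc, pvalue, flagged, spec=None, records=None) -> DEAResult:
    qvalue = bh_adjust(pvalue)
    table = pd.DataFrame(
        {
            "protein": matrix.protein_ids,
            "log2fc": log2fc,
            "pvalue": np.where(np.isnan(pvalue), 1.0, pvalue),
            "qvalue": qvalue,
            "flagged": flagged,
        }
    )
    return DEAResult(table, contrast=tuple(design.contrast), spec=spec,
                     records=list(records or []))


def _mean_diff(xa_row: np.ndarray, xb_row: np.ndarray) -> float:
    ma = np.nanmean(xa_row) if np.any(~np.isnan(xa_row)) else np.nan
    mb = np.nanmean(xb_row) if np.any(~np.isnan(xb_row)) else np.nan
    if np.isnan(ma) and np.isnan(mb):
        return 0.0
    if np.isnan(ma) or np.isnan(mb):
        return 0.0  # one group entirely missing: no defensible fold change
    return float(ma - mb)


def ttest(matrix: ExpressionMatrix, design: ContrastDesign) -> DEAResult:
    """Two-sided Welch t-test per protein on observed log2 values."""
    if matrix.scale != "log2":
        raise ValueError("t-test expects log2-scale values")
    xa, xb = _group_arrays(matrix, design)
    n = matrix.n_proteins
    log2fc = np.zeros(n)
    pvalue = np.ones(n)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        a = xa[i][~np.isnan(xa[i])]
        b = xb[i][~np.isnan(xb[i])]
        log2fc[i] = _mean_diff(xa[i], xb[i])
        if a.size < 2 or b.size < 2:
            flagged[i] = True
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            pvalue[i] = 1.0 if a.mean() == b.mean() else 0.0
            continue
        res = sps.ttest_ind(a, b, equal_var=False)
        pvalue[i] = float(res.pvalue)
    return _finish(matrix, design, log2fc, pvalue, flagged)


def anova_f(matrix: ExpressionMatrix, design: ContrastDesign) -> DEAResult:
    """One-way F test per protein across all design groups.

    For two groups this reproduces the pooled (equal-variance) t-test
    p-value exactly. The reported log2fc is for the design's contrast pair.
    """
    if matrix.scale != "log2":
        raise ValueError("ANOVA expects log2-scale values")
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    group_cols = {}
    for s, g in design.group_of.items():
        if s in col:
            group_cols.setdefault(g, []).append(col[s])
    if len(group_cols) < 2:
        raise ValueError("need >= 2 groups")
    xa, xb = _group_arrays(matrix, design)
    n = matrix.n_proteins
    log2fc = np.zeros(n)
    pvalue = np.ones(n)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        log2fc[i] = _mean_diff(xa[i], xb[i])
        samples = []
        for g, cols in group_cols.items():
            vals = matrix.values[i, cols]
            vals = vals[~np.isnan(vals)]
            if vals.size < 2:
                samples = []
                break
            samples.append(vals)
        if not samples:
            flagged[i] = True
            continue
        if all(np.ptp(s) == 0 for s in samples):
            means = [s.mean() for s in samples]
            pvalue[i] = 1.0 if np.ptp(means) == 0 else 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.f_oneway(*samples)
        pvalue[i] = float(res.pvalue)
    return _finish(matrix, design, log2fc, pvalue, flagged)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior on log s^2.

    Given per-protein sample variances s^2 on df residual degrees of
    freedom, assumes s^2 ~ s0^2 * chi^2_df/df scaled by a chi^2_d0 prior and
    matches the mean and variance of log s^2.
    """
    keep = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[keep], df[keep]
    if s2.size < 2:
        raise ValueError("too few positive variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = math.exp(emean)
    return d0, s0_2


def moderated_t(
    matrix: ExpressionMatrix,
    design: ContrastDesign,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEAResult:
    """Empirical-Bayes moderated t-test.

    Per-protein pooled residual variance s^2 (d residual df) is shrunk to
    s2_post = (d0*s0^2 + d*s^2)/(d0 + d) with the prior (d0, s0^2) fitted by
    moments on log s^2; the moderated t = log2fc / sqrt(s2_post*(1/nA+1/nB))
    is referred to a t distribution on d + d0 df. ``prior_df``/``prior_var``
    override the fitted prior (d0 = 0 recovers the ordinary pooled t-test;
    d0 = inf uses the prior variance for every protein).
    """
    if matrix.scale != "log2":
        raise ValueError("moderated t expects log2-scale values")
    xa, xb = _group_arrays(matrix, design)
    n = matrix.n_proteins
    log2fc = np.zeros(n)
    s2 = np.full(n, np.nan)
    df = np.zeros(n)
    na = np.zeros(n)
    nb = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        a = xa[i][~np.isnan(xa[i])]
        b = xb[i][~np.isnan(xb[i])]
        log2fc[i] = _mean_diff(xa[i], xb[i])
        na[i], nb[i] = a.size, b.size
        if a.size < 2 or b.size < 2:
            flagged[i] = True
            continue
        d = a.size + b.size - 2
        ss = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
        s2[i] = ss / d
        df[i] = d

    testable = np.isfinite(s2)
    if prior_df is None or prior_var is None:
        if int((testable & (s2 > 0)).sum()) < 10:
            warnings.warn("fewer than 10 proteins with finite variance; "
                          "falling back to the Welch t-test")
            return ttest(matrix, design)
        d0, s0_2 = fit_variance_prior(s2[testable], df[testable])
        if prior_df is not None:
            d0 = prior_df
        if prior_var is not None:
            s0_2 = prior_var
    else:
        d0, s0_2 = prior_df, prior_var

    pvalue = np.ones(n)
    for i in np.flatnonzero(testable):
        d = df[i]
        if np.isinf(d0):
            s2_post = s0_2
            total_df = np.inf
        else:
            s2_post = (d0 * s0_2 + d * s2[i]) / (d0 + d)
            total_df = d + d0
        se = math.sqrt(s2_post * (1.0 / na[i] + 1.0 / nb[i]))
        if se == 0:
            pvalue[i] = 1.0 if log2fc[i] == 0 else 0.0
            continue
        t = log2fc[i] / se
        if np.isinf(total_df):
            pvalue[i] = 2.0 * sps.norm.sf(abs(t))
        else:
            pvalue[i] = 2.0 * sps.t.sf(abs(t), total_df)
    return _finish(matrix, design, log2fc, pvalue, flagged)


_DEA_FUNCTIONS = {"ttest": ttest, "anova": anova_f, "modt": moderated_t}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing p-values count as 1."""
    p = np.asarray(pvalues, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    result: DEAResult,
    logfc_thresh: float = LOGFC_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
) -> pd.Series:
    """DE call per protein: |log2fc| >= logfc_thresh AND q < q_thresh."""
    t = result.table
    calls = (t["log2fc"].abs() >= logfc_thresh) & (t["qvalue"] < q_thresh)
    return pd.Series(calls.to_numpy(), index=t["protein"].to_numpy(), name="is_de")


def run_workflow(
    views: dict[str, ExpressionMatrix],
    spec: WorkflowSpec,
    design: ContrastDesign,
    seed: int = 0,
) -> DEAResult:
    """Execute one workflow: select view, log-transform, normalize, impute, test, BH."""
    violations = validate_workflow(spec)
    if violations:
        raise ValueError(f"invalid workflow {spec}: " + "; ".join(violations))
    if spec.matrix_type not in views:
        raise KeyError(f"matrix type {spec.matrix_type!r} not among views "
                       f"{sorted(views)}")
    matrix = views[spec.matrix_type]
    records: list[PreprocessRecord] = []
    raw_scale_norms = {"div.mean", "div.median", "total", "sum", "max"}
    needs_log = (
        spec.dea not in COUNT_BASED_DEA and spec.matrix_type not in COUNT_MATRIX_TYPES
    ) or spec.dea in _DEA_FUNCTIONS
    try:
        # scaling corrections act on raw intensities, before the log transform
        if spec.normalization in raw_scale_norms:
            matrix, rec = normalize(matrix, spec.normalization)
            records.append(rec)
        if matrix.scale == "raw" and needs_log:
            matrix = log_transform(matrix)
        if spec.normalization != "none" and spec.normalization not in raw_scale_norms:
            matrix, rec = normalize(matrix, spec.normalization)
            records.append(rec)
    except Exception as err:
        raise RuntimeError(f"normalization stage failed for {spec}: {err}") from err
    try:
        matrix, rec = impute(matrix, spec.imputation, seed=seed)
        records.append(rec)
    except Exception as err:
        raise RuntimeError(f"imputation stage failed for {spec}: {err}") from err
    try:
        if spec.dea in PLUGINS["dea"]:
            table = PLUGINS["dea"][spec.dea](matrix, design)
            if "qvalue" not in table:
                table = table.assign(qvalue=bh_adjust(table["pvalue"]))
            if "flagged" not in table:
                table = table.assign(flagged=False)
            result = DEAResult(table, contrast=tuple(design.contrast))
        else:
            result = _DEA_FUNCTIONS[spec.dea](matrix, design)
    except Exception as err:
        raise RuntimeError(f"DEA stage failed for {spec}: {err}") from err
    result.spec = spec
    result.records = records
    return result
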