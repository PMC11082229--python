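"""Independent brute-force oracles used to verify the package's algorithms.

Each oracle is written from the mathematical definition, deliberately
avoiding the code paths (and where possible the libraries) used by the
implementation it checks.
"""

from itertools import combinations

import numpy as np
from scipy import special


def bh_stepup(pvalues):
    """Hand Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvalues, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def pauc_sweep(confidences, labels, fpr_max):
    """Brute-force partial ROC area via an explicit threshold sweep.

    Thresholds at every distinct confidence; tied confidences enter
    together (diagonal step). The last segment is linearly interpolated at
    fpr_max before trapezoidal integration.
    """
    conf = np.asarray(confidences, float)
    y = np.asarray(labels, int)
    pos, neg = y.sum(), (1 - y).sum()
    points = [(0.0, 0.0)]
    for threshold in sorted(set(conf), reverse=True):
        predicted = conf >= threshold
        tpr = (predicted & (y == 1)).sum() / pos
        fpr = (predicted & (y == 0)).sum() / neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        if x0 >= fpr_max:
            break
        if x1 > fpr_max:
            y1 = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            x1 = fpr_max
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def powerset_frequent(transactions, min_sr):
    """All frequent itemsets by exhaustive power-set enumeration (<= ~12 items)."""
    items = sorted(set().union(*transactions)) if transactions else []
    n = len(transactions)
    out = {}
    for size in range(1, len(items) + 1):
        for combo in combinations(items, size):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count / n >= min_sr - 1e-12:
                out[s] = count / n
    return out


def knn_oracle(x, k=10, q=0.01):
    """Direct re-computation of the non-sequential KNN imputation contract."""
    x = np.asarray(x, float)
    n, m = x.shape
    out = x.copy()
    col_lows = np.nanquantile(x, q, axis=0)
    for i in range(n):
        miss = np.isnan(x[i])
        if not miss.any():
            continue
        if np.isnan(x[i]).all():
            out[i, miss] = col_lows[miss]
            continue
        dists = np.full(n, np.inf)
        for other in range(n):
            if other == i:
                continue
            shared = ~np.isnan(x[i]) & ~np.isnan(x[other])
            if shared.sum() == 0:
                continue
            diff = x[i, shared] - x[other, shared]
            dists[other] = np.sqrt((diff ** 2).mean())
        for j in np.flatnonzero(miss):
            donors = [o for o in range(n)
                      if np.isfinite(dists[o]) and not np.isnan(x[o, j])]
            if not donors:
                out[i, j] = col_lows[j]
                continue
            donors.sort(key=lambda o: (dists[o], o))
            chosen = donors[:k]
            out[i, j] = np.mean([x[o, j] for o in chosen])
    return out


def moderated_t_oracle(xa, xb):
    """Step-by-step empirical-Bayes moderated t on two observed groups.

    Returns per-protein (log2fc, p). Written from the closed-form recipe:
    pooled variances, method-of-moments prior on log s^2, posterior
    variance shrinkage, t on d + d0 degrees of freedom.
    """
    from scipy import stats as sps

    n = xa.shape[0]
    lfc = np.empty(n)
    s2 = np.full(n, np.nan)
    dfs = np.zeros(n)
    counts = np.zeros((n, 2))
    for i in range(n):
        a = xa[i][~np.isnan(xa[i])]
        b = xb[i][~np.isnan(xb[i])]
        counts[i] = (a.size, b.size)
        if a.size and b.size:
            lfc[i] = a.mean() - b.mean()
        else:
            lfc[i] = 0.0
        if a.size >= 2 and b.size >= 2:
            dfs[i] = a.size + b.size - 2
            s2[i] = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / dfs[i]

    keep = np.isfinite(s2) & (s2 > 0) & (dfs > 0)
    z = np.log(s2[keep])
    d = dfs[keep]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2))
    if evar > 0:
        # invert trigamma by bisection (independent of the package's Newton)
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * np.sqrt(lo * hi)
        s0_2 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)

    p = np.ones(n)
    for i in range(n):
        if not np.isfinite(s2[i]):
            continue
        if np.isinf(d0):
            s2_post, total_df = s0_2, np.inf
        else:
            s2_post = (d0 * s0_2 + dfs[i] * s2[i]) / (d0 + dfs[i])
            total_df = d0 + dfs[i]
        se = np.sqrt(s2_post * (1 / counts[i, 0] + 1 / counts[i, 1]))
        if se == 0:
            p[i] = 1.0 if lfc[i] == 0 else 0.0
            continue
        t = lfc[i] / se
        if np.isinf(total_df):
            p[i] = 2 * sps.norm.sf(abs(t))
        else:
            p[i] = 2 * sps.t.sf(abs(t), total_df)
    return lfc, p
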