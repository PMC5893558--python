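"""Independent brute-force oracles for the counting-based statistics.

Everything here is written with explicit Python loops straight from the
definitions, deliberately sharing no code with the package, and is only
ever run on small inputs.
"""

from __future__ import annotations

import numpy as np


def oracle_conditional_cdf(p1, p2, t1, t2):
    num = den = 0
    for a, b in zip(p1, p2):
        if b <= t2:
            den += 1
            if a <= t1:
                num += 1
    return float("nan") if den == 0 else num / den


def oracle_cfdr(p1, p2, strata=(1.0, 0.1, 0.01, 0.001), min_stratum_size=100):
    """Per-SNP conditional FDR of trait 1 given trait 2, by direct counting:
    stratum = smallest usable threshold >= p2_i; raw = min(1, p1 / ecdf);
    then a running minimum scanning from p1 = 1 downward within stratum."""
    p1 = list(map(float, p1))
    p2 = list(map(float, p2))
    strata = sorted(strata, reverse=True)
    if 1.0 not in strata:
        strata = [1.0] + strata
    denom = {t: sum(1 for b in p2 if b <= t) for t in strata}
    usable = [t for t in strata if denom[t] >= min_stratum_size]

    assigned, raw = [], []
    for i in range(len(p1)):
        t = min(t for t in usable if t >= p2[i])
        assigned.append(t)
        num = sum(1 for j in range(len(p1)) if p1[j] <= p1[i] and p2[j] <= t)
        raw.append(min(1.0, p1[i] / (num / denom[t])))

    out = list(raw)
    for t in set(assigned):
        idx = [i for i in range(len(p1)) if assigned[i] == t]
        idx.sort(key=lambda i: -p1[i])
        best = 1.0
        for i in idx:
            best = min(best, raw[i])
            out[i] = best
    return np.array(out)


def oracle_fold_enrichment(pA, pB, strata_neglog, grid):
    """fold[s, g] per the proportion-ratio definition, NaN when undefined."""
    n = len(pA)
    fold = np.full((len(strata_neglog), len(grid)), np.nan)
    counts = np.zeros_like(fold, dtype=int)
    for s, sl in enumerate(strata_neglog):
        t2 = 10.0 ** (-sl)
        stratum = [i for i in range(n) if pB[i] <= t2]
        for g, gl in enumerate(grid):
            t1 = 10.0 ** (-gl)
            joint = sum(1 for i in stratum if pA[i] <= t1)
            base = sum(1 for i in range(n) if pA[i] <= t1)
            counts[s, g] = joint
            if stratum and base:
                fold[s, g] = (joint / len(stratum)) / (base / n)
    return fold, counts


def oracle_closest_gene(chrom, pos, genes):
    """Exhaustive scan over (name, chrom, start, end) tuples; ties to the
    smaller start."""
    best = None
    for name, gc, start, end in genes:
        if gc != chrom:
            continue
        if start <= pos <= end:
            d = 0
        else:
            d = min(abs(pos - start), abs(pos - end))
        key = (d, start)
        if best is None or key < best[0]:
            best = (key, name, d)
    if best is None:
        return "NA", None
    return best[1], best[2]


def oracle_ols_f(y, X):
    """F statistic and p for the last column of X (with intercept prepended),
    via the normal equations and the partitioned-regression formula."""
    from scipy import stats

    X = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    t = beta[-1] / np.sqrt(cov[-1, -1])
    return t**2, 2 * stats.t.sf(abs(t), df)
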