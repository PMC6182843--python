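"""Shared fixtures helpers and independent brute-force oracles.

The oracles deliberately use naive loops and scalar arithmetic so they
stay independent of the vectorized implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from refstab.cq import CqMatrix


def make_matrix(values, genes=None, groups=None, times=None, assay="root_dehydration", accession="acc"):
    """CqMatrix from a 2-D array; metadata filled with distinct bio reps."""
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    groups = groups or ["control"] * n_samples
    times = times or [0] * n_samples
    meta = pd.DataFrame(
        {
            "assay": assay,
            "accession": accession,
            "group": groups,
            "time_min": times,
            "bio_rep": range(1, n_samples + 1),
            "tech_rep": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CqMatrix(pd.DataFrame(arr, index=genes, columns=sample_ids), meta)


# ---------------------------------------------------------------- oracles


def oracle_pairwise_sd(q: pd.DataFrame) -> pd.DataFrame:
    """Naive SD of pairwise log2 ratios (scalar loops)."""
    genes = list(q.index)
    out = pd.DataFrame(0.0, index=genes, columns=genes)
    for j in genes:
        for k in genes:
            if j == k:
                continue
            ratios = [
                math.log2(q.loc[j, s] / q.loc[k, s]) for s in q.columns
            ]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            out.loc[j, k] = math.sqrt(var)
    return out


def oracle_genorm_m(q: pd.DataFrame) -> pd.Series:
    v = oracle_pairwise_sd(q)
    genes = list(q.index)
    return pd.Series(
        {j: sum(v.loc[j, k] for k in genes if k != j) / (len(genes) - 1) for j in genes}
    )


def oracle_delta_ct_mean_sd(cq: pd.DataFrame) -> pd.Series:
    genes = list(cq.index)
    out = {}
    for i in genes:
        sds = []
        for k in genes:
            if k == i:
                continue
            diffs = [cq.loc[i, s] - cq.loc[k, s] for s in cq.columns]
            mean = sum(diffs) / len(diffs)
            var = sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)
            sds.append(math.sqrt(var))
        out[i] = sum(sds) / len(sds)
    return pd.Series(out)


def oracle_bestkeeper_r(cq: pd.DataFrame) -> pd.Series:
    """Pearson r of each gene's Cq against the per-sample geometric mean."""
    samples = list(cq.columns)
    index = []
    for s in samples:
        logs = [math.log(cq.loc[g, s]) for g in cq.index]
        index.append(math.exp(sum(logs) / len(logs)))
    out = {}
    for g in cq.index:
        xs = [cq.loc[g, s] for s in samples]
        mx, mi = sum(xs) / len(xs), sum(index) / len(index)
        num = sum((a - mx) * (b - mi) for a, b in zip(xs, index))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in xs) * sum((b - mi) ** 2 for b in index)
        )
        out[g] = num / den
    return pd.Series(out)


def oracle_normfinder(x: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Step-by-step model-based stability value (scalar arithmetic).

    x: genes x samples log2 expression; labels: sample -> group.
    """
    genes = list(x.index)
    G = len(genes)
    group_names = list(dict.fromkeys(labels))
    # per-sample centering
    z = {}
    for s in x.columns:
        col_mean = sum(x.loc[g, s] for g in genes) / G
        for g in genes:
            z[(g, s)] = x.loc[g, s] - col_mean

    zbar, gamma2, n_g = {}, {}, {}
    for grp in group_names:
        cols = [s for s in x.columns if labels[s] == grp]
        n_g[grp] = len(cols)
        s2 = {}
        for g in genes:
            vals = [z[(g, s)] for s in cols]
            m = sum(vals) / len(vals)
            zbar[(g, grp)] = m
            s2[g] = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
        total_s2 = sum(s2.values())
        for g in genes:
            corr = (s2[g] - total_s2 / (G * (G - 1))) * G / (G - 2)
            gamma2[(g, grp)] = max(corr, 0.0)

    if len(group_names) == 1:
        grp = group_names[0]
        return pd.Series({g: math.sqrt(gamma2[(g, grp)]) for g in genes})

    total_n = sum(n_g.values())
    rho = {}
    d_raw = {}
    for g in genes:
        gene_mean = sum(zbar[(g, grp)] * n_g[grp] for grp in group_names) / total_n
        for grp in group_names:
            d_raw[(g, grp)] = zbar[(g, grp)] - gene_mean
    for grp in group_names:
        ds = [d_raw[(g, grp)] for g in genes]
        dm = sum(ds) / len(ds)
        tau2 = max(sum((d - dm) ** 2 for d in ds) / (len(ds) - 1), 0.0)
        for g in genes:
            denom = tau2 + gamma2[(g, grp)] / n_g[grp]
            factor = tau2 / denom if denom > 0 else 0.0
            d_raw[(g, grp)] *= factor
    for g in genes:
        rho[g] = sum(
            abs(d_raw[(g, grp)]) + math.sqrt(gamma2[(g, grp)] / n_g[grp])
            for grp in group_names
        ) / len(group_names)
    return pd.Series(rho)


def ac_direct_sum(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided conditional Poisson p-value by direct log-gamma summation."""
    ratio = n2 / n1

    def log_pmf(k: int) -> float:
        return (
            k * math.log(ratio)
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * math.log1p(ratio)
        )

    lower = sum(math.exp(log_pmf(k)) for k in range(0, y + 1))
    # sum the upper tail until terms are negligible
    upper = 0.0
    k = y
    while True:
        term = math.exp(log_pmf(k))
        upper += term
        k += 1
        if term < 1e-18 and k > y + 10 * (x + y + 10):
            break
        if k > y + 2_000_000:  # pragma: no cover - safety net
            break
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_randomization_p(control, treated) -> float:
    """Exact fixed-reallocation p-value by explicit enumeration."""
    pooled = list(control) + list(treated)
    n1 = len(control)
    obs = abs(
        sum(treated) / len(treated) - sum(control) / len(control)
    )
    hits = total = 0
    for ctrl_idx in combinations(range(len(pooled)), n1):
        ctrl = [pooled[i] for i in ctrl_idx]
        trt = [pooled[i] for i in range(len(pooled)) if i not in ctrl_idx]
        stat = abs(sum(trt) / len(trt) - sum(ctrl) / len(ctrl))
        hits += stat >= obs - 1e-12
        total += 1
    return hits / total
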