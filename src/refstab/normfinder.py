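"""Model-based (NormFinder-style) expression-stability value.

Log-scale expression of gene i in sample j of group g is modelled as

    x_igj = alpha_i + b_j + d_ig + e_igj,   e ~ N(0, sigma2_ig)

where ``b_j`` is a sample loading effect (removed by centering each
sample across genes), ``d_ig`` is a systematic group effect and
``sigma2_ig`` the intragroup variance.  A gene's stability value
combines the shrunk group deviation with the sampling noise of its
group means:

    rho_i = mean over groups of ( |d~_ig| + sqrt(gamma2_ig / n_g) )

Lower rho means more stable.  The variance estimates are bias-corrected
for the centering step; the group deviations are shrunk toward zero by
the empirical-Bayes factor ``tau2 / (tau2 + gamma2_ig / n_g)`` with
``tau2`` the across-gene variance of the raw deviations in that group.
With a single group the stability value reduces to ``sqrt(gamma2_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from refstab.cq import CqMatrix
from refstab.genorm import _efficiency_series


@dataclass
class NormFinderResult:
    stability: pd.Series            # rho per gene (input gene order)
    intergroup_d: pd.DataFrame      # gene x group, shrunk deviations (log2 units)
    intragroup_var: pd.DataFrame    # gene x group, bias-corrected variances
    ranking: list[str]              # ascending rho
    tied: list[str]                 # genes sharing a rho with another gene

    def to_dict(self) -> dict:
        return {
            "stability": {g: float(v) for g, v in self.stability.items()},
            "ranking": self.ranking,
            "tied": self.tied,
        }


def _log2_expression(
    m: CqMatrix | pd.DataFrame,
    efficiencies: Mapping[str, float] | float | None,
) -> pd.DataFrame:
    """log2 relative quantities: x = (minCq - Cq) * log2(E) per gene."""
    cq = m.cq if isinstance(m, CqMatrix) else m
    if cq.isna().any().any():
        raise ValueError("stability analysis requires a complete Cq matrix")
    e = _efficiency_series(list(cq.index), efficiencies)
    scale = np.log2(e.to_numpy())[:, None]
    dcq = cq.min(axis=1).to_numpy()[:, None] - cq.to_numpy()
    return pd.DataFrame(dcq * scale, index=cq.index, columns=cq.columns)


def normfinder_stability(
    m: CqMatrix,
    groups: Mapping[str, str] | pd.Series | None = None,
    efficiencies: Mapping[str, float] | float | None = None,
) -> NormFinderResult:
    """Stability value rho per gene from intra- and intergroup variation.

    *groups* maps sample id to a group label; by default the ``group``
    metadata column (e.g. control vs treated) is used.  Intergroup mode
    requires at least two samples per group and three genes; with one
    group only the intragroup term is reported.
    """
    x = _log2_expression(m, efficiencies)
    genes = list(x.index)
    G = len(genes)
    if G < 3:
        raise ValueError("need at least 3 genes")
    if groups is None:
        labels = m.samples["group"].astype(str)
    else:
        labels = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        labels = labels.reindex(x.columns)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")
    group_names = list(dict.fromkeys(labels))

    # remove per-sample loading effects
    z = x - x.mean(axis=0)

    zbar = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    gamma2 = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    n_g = {}
    for g in group_names:
        cols = labels.index[labels == g]
        n = len(cols)
        if n < 2 and len(group_names) > 1:
            raise ValueError(f"group {g!r} has {n} sample(s); intergroup mode needs >= 2")
        sub = z[cols]
        zbar[g] = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        # centering across G genes biases the naive variance; correct and floor at 0
        corrected = (s2 - s2.sum() / (G * (G - 1))) * G / (G - 2)
        gamma2[g] = corrected.clip(lower=0.0)
        n_g[g] = n

    if len(group_names) == 1:
        rho = np.sqrt(gamma2[group_names[0]])
        d_shrunk = pd.DataFrame(0.0, index=genes, columns=group_names)
    else:
        weights = np.array([n_g[g] for g in group_names], dtype=float)
        gene_mean = (zbar * weights).sum(axis=1) / weights.sum()
        d_raw = zbar.sub(gene_mean, axis=0)
        d_shrunk = pd.DataFrame(index=genes, columns=group_names, dtype=float)
        for g in group_names:
            tau2 = max(float(d_raw[g].var(ddof=1)), 0.0)
            denom = tau2 + gamma2[g] / n_g[g]
            factor = np.where(denom > 0, tau2 / denom.where(denom > 0, 1.0), 0.0)
            d_shrunk[g] = d_raw[g] * factor
        per_group = d_shrunk.abs() + np.sqrt(
            gamma2 / pd.Series(n_g, dtype=float)
        )
        rho = per_group.mean(axis=1)

    rho = pd.Series(rho, index=genes, name="stability")
    order = sorted(range(G), key=lambda i: (rho.iloc[i], i))
    ranking = [genes[i] for i in order]
    counts = rho.round(12).value_counts()
    tied = [g for g in genes if counts.get(round(float(rho[g]), 12), 0) > 1]
    if tied:
        warnings.warn(f"tied stability values among {tied}; input order preserved", stacklevel=2)
    return NormFinderResult(
        stability=rho,
        intergroup_d=d_shrunk,
        intragroup_var=gamma2,
        ranking=ranking,
        tied=tied,
    )


def rank_by_stability(res: NormFinderResult) -> list[str]:
    """Gene list in ascending order of stability value (most stable first)."""
    return list(res.ranking)
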