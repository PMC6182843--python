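"""geNorm expression-stability statistic M and the V_n/n+1 criterion.

Cq values are first transformed to relative quantities
``Q = E**(minCq - Cq)`` (maximum quantity 1 per gene).  The stability
value M of a gene is the mean standard deviation of its pairwise
log2-ratios with every other candidate; the least stable gene (highest
M) is excluded stepwise until two remain, which form the most-stable
pair (unordered — the ratio-based statistic cannot order them).  The
pairwise variation V_n/n+1 between normalization factors built from the
n and n+1 best genes decides how many reference genes are needed: the
smallest n with V < 0.15 (conventional cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from refstab.cq import CqMatrix


def _efficiency_series(genes: list[str], efficiencies: Mapping[str, float] | float | None) -> pd.Series:
    if efficiencies is None:
        efficiencies = 2.0
    if isinstance(efficiencies, (int, float)):
        return pd.Series(float(efficiencies), index=genes)
    missing = [g for g in genes if g not in efficiencies]
    if missing:
        raise KeyError(f"no efficiency for gene(s) {missing} and no default given")
    return pd.Series({g: float(efficiencies[g]) for g in genes})


def cq_to_quantity(
    m: CqMatrix | pd.DataFrame,
    efficiencies: Mapping[str, float] | float | None = None,
) -> pd.DataFrame:
    """Relative quantities ``Q = E**(minCq - Cq)``, calibrated per gene.

    Each gene's lowest-Cq sample gets quantity 1.  *efficiencies* maps
    gene id to its amplification base E (default 2.0 = perfect doubling).
    """
    cq = m.cq if isinstance(m, CqMatrix) else m
    if cq.isna().any().any():
        raise ValueError("quantity transform requires a complete Cq matrix")
    e = _efficiency_series(list(cq.index), efficiencies)
    dcq = cq.min(axis=1).to_numpy()[:, None] - cq.to_numpy()
    q = np.power(e.to_numpy()[:, None], dcq)
    return pd.DataFrame(q, index=cq.index, columns=cq.columns)


def pairwise_variation_matrix(q: pd.DataFrame) -> pd.DataFrame:
    """Symmetric gene x gene matrix of SDs of pairwise log2 quantity ratios.

    ``V[j, k]`` is the sample SD (ddof=1) over samples of
    ``log2(Q_j / Q_k)``; the diagonal is zero.
    """
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if (q.to_numpy() <= 0).any():
        raise ValueError("quantities must be strictly positive")
    logq = np.log2(q.to_numpy())
    diff = logq[:, None, :] - logq[None, :, :]
    v = diff.std(axis=2, ddof=1)
    np.fill_diagonal(v, 0.0)
    return pd.DataFrame(v, index=q.index, columns=q.index)


@dataclass
class GeNormResult:
    """Stepwise M values, exclusion order, and the V_n/n+1 series."""

    m_values: pd.DataFrame          # rows: exclusion round, columns: gene (NaN once excluded)
    exclusion_order: list[str]      # least stable first
    final_pair: tuple[str, str]     # unordered most-stable pair (input order)
    ranking: list[str]              # most stable first; pair first, in input order
    v_series: pd.Series             # index n, value V_n/n+1
    optimal_n: int
    optimal_reached: bool
    cutoff: float = 0.15

    def to_dict(self) -> dict:
        return {
            "exclusion_order": self.exclusion_order,
            "final_pair": list(self.final_pair),
            "ranking": self.ranking,
            "m_values": {
                str(r): {g: v for g, v in row.dropna().items()}
                for r, row in self.m_values.iterrows()
            },
            "v_series": {f"V{n}/{n + 1}": float(v) for n, v in self.v_series.items()},
            "optimal_n": self.optimal_n,
            "optimal_reached": self.optimal_reached,
            "cutoff": self.cutoff,
        }


def _m_values(v: pd.DataFrame) -> pd.Series:
    """M_j = mean of V_jk over the other remaining genes."""
    g = v.shape[0]
    return v.sum(axis=1) / (g - 1)


def genorm_rank(q: pd.DataFrame, cutoff: float = 0.15) -> GeNormResult:
    """Stepwise geNorm ranking with normalization-factor pairwise variation.

    Each round recomputes M over the remaining genes and removes the gene
    with the highest M (ties broken by input gene order, with a warning)
    until two genes remain.  ``V_n/n+1`` is the SD over samples of
    ``log2(NF_n / NF_{n+1})`` where ``NF_n`` is the per-sample geometric
    mean of the n most stable genes' quantities; ``optimal_n`` is the
    smallest n with V below *cutoff* (flagged unreached otherwise).
    """
    genes = list(q.index)
    if len(genes) < 3:
        raise ValueError("geNorm ranking requires at least 3 genes")
    v_full = pairwise_variation_matrix(q)

    remaining = list(genes)
    exclusion_order: list[str] = []
    m_rows = []
    while len(remaining) > 2:
        m = _m_values(v_full.loc[remaining, remaining])
        m_rows.append(m.reindex(genes))
        worst_val = m.max()
        ties = m.index[m == worst_val].tolist()
        if len(ties) > 1:
            warnings.warn(
                f"tie on max M among {ties}; excluding {ties[0]} (input order)", stacklevel=2
            )
        worst = ties[0]
        exclusion_order.append(worst)
        remaining.remove(worst)
    m_rows.append(_m_values(v_full.loc[remaining, remaining]).reindex(genes))
    m_values = pd.DataFrame(m_rows)
    m_values.index.name = "round"

    final_pair = tuple(g for g in genes if g in remaining)  # input order
    ranking = list(final_pair) + list(reversed(exclusion_order))

    logq = np.log2(q.loc[ranking].to_numpy())
    v_list = {}
    for n in range(2, len(genes)):
        nf_n = logq[:n].mean(axis=0)       # log2 of geometric mean
        nf_n1 = logq[: n + 1].mean(axis=0)
        v_list[n] = float(np.std(nf_n - nf_n1, ddof=1))
    v_series = pd.Series(v_list, name="V")
    v_series.index.name = "n"

    below = [n for n, v in v_series.items() if v < cutoff]
    if below:
        optimal_n, reached = min(below), True
    else:
        optimal_n, reached = len(genes), False
    return GeNormResult(
        m_values=m_values,
        exclusion_order=exclusion_order,
        final_pair=final_pair,  # type: ignore[arg-type]
        ranking=ranking,
        v_series=v_series,
        optimal_n=optimal_n,
        optimal_reached=reached,
        cutoff=cutoff,
    )
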