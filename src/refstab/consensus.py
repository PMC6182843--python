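"""Cross-method comparison and aggregate reference-gene ranking.

Each stability method yields a ranking; the consensus report tabulates
per-method ranks (the geNorm most-stable pair shares rank 1.5, since
the ratio statistic cannot order it), counts top-k overlaps between
method pairs, and aggregates by the geometric mean of ranks.  The
selected reference set is the top n (default 3) by aggregate rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from refstab.genorm import GeNormResult


def ranks_from_order(order: Sequence[str]) -> pd.Series:
    """Rank series (1 = most stable) from an ordered gene list."""
    return pd.Series({g: float(i + 1) for i, g in enumerate(order)}, name="rank")


def genorm_ranks(res: GeNormResult) -> pd.Series:
    """geNorm ranks with the unordered most-stable pair tied at 1.5."""
    ranks = ranks_from_order(res.ranking)
    for g in res.final_pair:
        ranks[g] = 1.5
    return ranks


def method_ranks(
    genorm=None,
    normfinder=None,
    bestkeeper_order: Sequence[str] | None = None,
    delta_ct=None,
) -> dict[str, pd.Series]:
    """Assemble per-method rank series from result objects.

    ``bestkeeper_order`` is the output of
    :func:`refstab.descriptive.rank_bestkeeper`; the others are the
    result objects of their modules.  Only supplied methods appear.
    """
    out: dict[str, pd.Series] = {}
    if genorm is not None:
        out["genorm"] = genorm_ranks(genorm)
    if normfinder is not None:
        out["normfinder"] = ranks_from_order(normfinder.ranking)
    if bestkeeper_order is not None:
        out["bestkeeper"] = ranks_from_order(bestkeeper_order)
    if delta_ct is not None:
        out["delta_ct"] = ranks_from_order(delta_ct.ranking)
    return out


@dataclass
class ConsensusReport:
    rank_table: pd.DataFrame        # method x gene
    top_k_overlap: pd.DataFrame     # method x method, |top-k intersection|
    aggregate_rank: pd.Series       # geometric mean of per-method ranks
    selected: list[str]             # reference set, size n_select
    top_k_sets: dict[str, list[str]]
    k: int

    def to_dict(self) -> dict:
        return {
            "rank_table": {m: {g: float(v) for g, v in row.items()} for m, row in self.rank_table.iterrows()},
            "top_k_overlap": {
                m: {m2: int(v) for m2, v in row.items()} for m, row in self.top_k_overlap.iterrows()
            },
            "aggregate_rank": {g: float(v) for g, v in self.aggregate_rank.items()},
            "selected": self.selected,
            "top_k_sets": self.top_k_sets,
            "k": self.k,
        }


def build_consensus(
    rankings: Mapping[str, pd.Series],
    k: int = 4,
    n_select: int = 3,
) -> ConsensusReport:
    """Aggregate two or more method rankings over a common gene set.

    *rankings* maps method name to a rank series (1 = most stable, ties
    allowed).  Raises ``ValueError`` on mismatched gene sets.  The
    aggregate is the geometric mean of ranks per gene; the selected set
    is the top *n_select* by aggregate (ties broken by gene order).
    """
    if len(rankings) < 2:
        raise ValueError("consensus needs at least 2 method rankings")
    methods = list(rankings)
    gene_sets = [frozenset(r.index) for r in rankings.values()]
    if len(set(gene_sets)) != 1:
        raise ValueError("method rankings cover different gene sets")
    genes = list(rankings[methods[0]].index)

    table = pd.DataFrame({m: rankings[m].reindex(genes) for m in methods}).T
    table.index.name = "method"

    top_sets = {m: list(table.loc[m].nsmallest(k, keep="first").index) for m in methods}
    overlap = pd.DataFrame(
        [[len(set(top_sets[a]) & set(top_sets[b])) for b in methods] for a in methods],
        index=methods,
        columns=methods,
    )
    aggregate = pd.Series(
        np.exp(np.log(table.to_numpy(dtype=float)).mean(axis=0)), index=genes, name="aggregate_rank"
    )
    order = sorted(range(len(genes)), key=lambda i: (float(aggregate.iloc[i]), i))
    selected = [genes[i] for i in order[:n_select]]
    return ConsensusReport(
        rank_table=table,
        top_k_overlap=overlap,
        aggregate_rank=aggregate,
        selected=selected,
        top_k_sets=top_sets,
        k=k,
    )
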