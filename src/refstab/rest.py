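"""Efficiency-corrected relative expression with a randomization test.

The expression ratio of a target gene between treated and control
groups, normalized by one or more reference genes, is

    R = E_t ** dCq_t / geomean_r( E_r ** dCq_r )

with ``dCq = mean(control Cq) - mean(treated Cq)`` and E the
amplification base per gene.  Significance comes from a fixed
reallocation randomization test: whole samples' normalized quantities
are reallocated between the two groups (preserving sizes), and the
p-value is the fraction of allocations whose |log ratio| is at least
the observed one (the observed allocation counts, so p > 0).  All
C(n1+n2, n1) allocations are enumerated when feasible, otherwise a
seeded Monte-Carlo sample is used.

Calls: UR when R > 1 and p < alpha, DR when R < 1 and p < alpha,
otherwise ns.  Signed fold change follows the convention FC = R for
R >= 1 and FC = -1/R otherwise.  A cross-platform comparison (tag
sequencing vs qPCR) is "validated" when the qPCR call at any time point
matches the sequencing call.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from refstab.cq import CqMatrix
from refstab.genorm import _efficiency_series

CALLS = ("UR", "DR", "ns")


def _eff(gene: str, efficiencies: Mapping[str, float] | float | None) -> float:
    if efficiencies is None:
        return 2.0
    if isinstance(efficiencies, (int, float)):
        return float(efficiencies)
    return float(efficiencies[gene])


def pfaffl_ratio(
    target_control: Sequence[float],
    target_treated: Sequence[float],
    refs_control: Mapping[str, Sequence[float]],
    refs_treated: Mapping[str, Sequence[float]],
    efficiencies: Mapping[str, float] | float | None = None,
    target: str = "target",
) -> float:
    """Efficiency-corrected expression ratio normalized by reference genes.

    ``dCq`` is taken control minus treated per gene, so R > 1 means the
    target is more abundant in the treated group after normalization by
    the geometric mean of the reference signals.
    """
    tc = np.asarray(target_control, dtype=float)
    tt = np.asarray(target_treated, dtype=float)
    if tc.size == 0 or tt.size == 0:
        raise ValueError("both control and treated target replicates are required")
    if not refs_control:
        raise ValueError("reference set must be non-empty")
    e_t = _eff(target, efficiencies)
    num = e_t ** (tc.mean() - tt.mean())
    log_den = 0.0
    for ref, ctrl in refs_control.items():
        rc = np.asarray(ctrl, dtype=float)
        rt = np.asarray(refs_treated[ref], dtype=float)
        if rc.size == 0 or rt.size == 0:
            raise ValueError(f"reference {ref!r} lacks replicates on one side")
        log_den += (rc.mean() - rt.mean()) * math.log(_eff(ref, efficiencies))
    log_den /= len(refs_control)
    return float(num / math.exp(log_den))


def normalized_log_quantity(
    target_cq: Sequence[float],
    refs_cq: Mapping[str, Sequence[float]],
    efficiencies: Mapping[str, float] | float | None = None,
    target: str = "target",
) -> np.ndarray:
    """Per-sample log2 of target quantity over the reference geometric mean.

    Sample quantity is ``E**(-Cq)`` per gene; the normalization factor is
    the geometric mean of the reference quantities of the same sample.
    """
    t = np.asarray(target_cq, dtype=float)
    out = -t * math.log2(_eff(target, efficiencies))
    for ref, cq in refs_cq.items():
        out = out + np.asarray(cq, dtype=float) * math.log2(_eff(ref, efficiencies)) / len(refs_cq)
    return out


def randomization_test(
    log_q_control: Sequence[float],
    log_q_treated: Sequence[float],
    iterations: int = 2000,
    seed: int | None = None,
    max_exact: int = 100_000,
) -> tuple[float, int, str]:
    """Fixed reallocation randomization p-value for the expression ratio.

    The statistic is ``|mean(treated) - mean(control)|`` of per-sample
    log quantities (i.e. |log R|).  All C(n, n1) group reallocations are
    enumerated when their number is at most *max_exact*; otherwise
    *iterations* seeded random reallocations are drawn and the observed
    allocation is added to numerator and denominator.

    Returns ``(p, n_allocations, mode)`` with mode ``"exact"`` or
    ``"monte_carlo"``.
    """
    c = np.asarray(log_q_control, dtype=float)
    t = np.asarray(log_q_treated, dtype=float)
    n1, n2 = c.size, t.size
    if n1 < 1 or n2 < 1 or (n1 == 1 and n2 == 1):
        raise ValueError("randomization test needs more than one sample per side overall")
    pooled = np.concatenate([c, t])
    n = n1 + n2
    observed = abs(t.mean() - c.mean())
    total = math.comb(n, n1)
    if total <= max_exact:
        idx = np.fromiter(
            (i for comb in combinations(range(n), n1) for i in comb), dtype=np.intp
        ).reshape(total, n1)
        ctrl_sums = pooled[idx].sum(axis=1)
        grand = pooled.sum()
        stat = np.abs((grand - ctrl_sums) / n2 - ctrl_sums / n1)
        p = float((stat >= observed - 1e-12).sum()) / total
        return p, total, "exact"
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(iterations):
        perm = rng.permutation(pooled)
        stat = abs(perm[n1:].mean() - perm[:n1].mean())
        hits += stat >= observed - 1e-12
    return (hits + 1) / (iterations + 1), iterations, "monte_carlo"


def regulation_call(ratio: float, p: float, alpha: float = 0.05) -> str:
    """UR / DR / ns call from the ratio and its p-value."""
    if p < alpha and ratio > 1:
        return "UR"
    if p < alpha and ratio < 1:
        return "DR"
    return "ns"


def fc_from_ratio(ratio: float) -> float:
    """Signed fold change: FC = R for R >= 1, else -1/R (repression)."""
    if not ratio > 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return ratio if ratio >= 1 else -1.0 / ratio


def agreement(ht_call: str, qpcr_calls: Iterable[str]) -> bool:
    """Cross-platform validation: any time point repeats the sequencing call.

    ``ns`` counts as a call: a transcript unchanged in both platforms at
    some time point is in agreement.
    """
    calls = list(qpcr_calls)
    if not calls:
        raise ValueError("empty qPCR call list")
    for c in (ht_call, *calls):
        if c not in CALLS:
            raise ValueError(f"unknown regulation call {c!r}")
    return ht_call in calls


def summarize_agreement(comparisons: Iterable[Mapping]) -> tuple[int, int, int]:
    """(validated, total, rounded percent) over comparison records.

    Each record needs ``ht_call`` and ``qpcr_calls`` entries.
    """
    validated = 0
    total = 0
    for rec in comparisons:
        total += 1
        validated += agreement(rec["ht_call"], rec["qpcr_calls"])
    if total == 0:
        raise ValueError("no comparisons given")
    pct = int(round(100.0 * validated / total))
    return validated, total, pct


def relative_expression(
    m: CqMatrix,
    targets: Sequence[str],
    reference_set: Sequence[str],
    efficiencies: Mapping[str, float] | float | None = None,
    alpha: float = 0.05,
    iterations: int = 2000,
    seed: int | None = None,
    control_time: int = 0,
) -> pd.DataFrame:
    """Per-target, per-time expression calls against the time-0 control.

    For every (assay, accession, target, treated time) the treated
    biological replicates at that time are compared with the control
    group's replicates at *control_time*, yielding the normalized ratio,
    randomization p-value and UR/DR/ns call.  Expects a matrix whose
    technical replicates are already collapsed.
    """
    refs = list(reference_set)
    missing = [g for g in (*targets, *refs) if g not in m.genes]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing}")
    meta = m.samples
    rows = []
    rng = np.random.default_rng(seed)
    for (assay, accession), sub_meta in meta.groupby(["assay", "accession"], sort=False):
        ctrl_ids = sub_meta.index[
            (sub_meta["group"] == "control") & (sub_meta["time_min"] == control_time)
        ]
        if len(ctrl_ids) == 0:
            raise ValueError(f"no control samples at time {control_time} for {assay}/{accession}")
        treated_meta = sub_meta[sub_meta["group"] != "control"]
        for time in sorted(treated_meta["time_min"].unique()):
            trt_ids = treated_meta.index[treated_meta["time_min"] == time]
            for target in targets:
                refs_ctrl = {r: m.cq.loc[r, ctrl_ids].to_numpy() for r in refs}
                refs_trt = {r: m.cq.loc[r, trt_ids].to_numpy() for r in refs}
                ratio = pfaffl_ratio(
                    m.cq.loc[target, ctrl_ids].to_numpy(),
                    m.cq.loc[target, trt_ids].to_numpy(),
                    refs_ctrl,
                    refs_trt,
                    efficiencies,
                    target=target,
                )
                lq_ctrl = normalized_log_quantity(
                    m.cq.loc[target, ctrl_ids].to_numpy(), refs_ctrl, efficiencies, target
                )
                lq_trt = normalized_log_quantity(
                    m.cq.loc[target, trt_ids].to_numpy(), refs_trt, efficiencies, target
                )
                p, n_alloc, mode = randomization_test(
                    lq_ctrl,
                    lq_trt,
                    iterations=iterations,
                    seed=int(rng.integers(2**31 - 1)),
                )
                rows.append(
                    {
                        "assay": assay,
                        "accession": accession,
                        "gene": target,
                        "time_min": int(time),
                        "ratio": ratio,
                        "fold_change": fc_from_ratio(ratio),
                        "p_value": p,
                        "call": regulation_call(ratio, p, alpha),
                        "n_control": int(len(ctrl_ids)),
                        "n_treated": int(len(trt_ids)),
                        "allocations": n_alloc,
                        "mode": mode,
                    }
                )
    return pd.DataFrame(rows)
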