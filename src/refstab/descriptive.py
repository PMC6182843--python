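"""BestKeeper descriptive statistics and the pairwise delta-Ct method.

BestKeeper works directly on raw Cq values: per-gene descriptive
statistics (geometric/arithmetic mean, extremes, dispersion, x-fold
deviations on the linear scale) and a per-sample index — the geometric
mean of all candidates' Cq — against which each gene is scored by
Pearson correlation (higher r = more stable).  Genes whose Cq
dispersion exceeds one cycle are flagged inconsistent.

The delta-Ct method scores a gene by the average standard deviation of
its pairwise Cq differences with every other candidate (lower = more
stable).  At equal efficiencies it is algebraically identical to the
geNorm pairwise-variation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from refstab.cq import CqMatrix
from refstab.genorm import _efficiency_series


@dataclass
class BestKeeperResult:
    stats: pd.DataFrame   # one row per gene
    index: pd.Series      # per-sample geometric mean of Cq across genes

    def to_dict(self) -> dict:
        return {
            "stats": self.stats.to_dict(orient="index"),
            "index": {s: float(v) for s, v in self.index.items()},
        }


@dataclass
class DeltaCtResult:
    pair_sd: pd.DataFrame  # symmetric gene x gene SD of per-sample Cq differences
    mean_sd: pd.Series     # per-gene average over the other genes
    ranking: list[str]     # ascending mean SD

    def to_dict(self) -> dict:
        return {
            "mean_sd": {g: float(v) for g, v in self.mean_sd.items()},
            "ranking": self.ranking,
        }


def _signed_xfold(cq_extreme: np.ndarray, gm: np.ndarray, e: np.ndarray) -> np.ndarray:
    """x-fold deviation of an extreme Cq from the geometric mean.

    ``E**|Cq - gm|`` on the linear scale, signed negative when the
    extreme Cq lies below the geometric mean (over-expression).
    """
    mag = np.power(e, np.abs(cq_extreme - gm))
    return np.where(cq_extreme < gm, -mag, mag)


def bestkeeper(
    m: CqMatrix | pd.DataFrame,
    efficiencies: Mapping[str, float] | float | None = None,
    sd_mode: str = "sample_sd",
) -> BestKeeperResult:
    """BestKeeper descriptive statistics, index, and index correlations.

    ``sd_mode`` selects the dispersion statistic: ``sample_sd`` (ddof-1
    SD about the arithmetic mean) or ``mad`` (mean absolute deviation
    about the arithmetic mean, the original tool's variant).  x-fold
    columns convert cycle deviations to the linear scale with each
    gene's amplification base E; p-values for the index correlation are
    two-sided from the t distribution with n-2 df.
    """
    if sd_mode not in ("sample_sd", "mad"):
        raise ValueError("sd_mode must be 'sample_sd' or 'mad'")
    cq = m.cq if isinstance(m, CqMatrix) else m
    if cq.isna().any().any():
        raise ValueError("BestKeeper requires a complete Cq matrix")
    if (cq.to_numpy() <= 0).any():
        raise ValueError("geometric mean undefined for non-positive Cq")
    genes = list(cq.index)
    if len(genes) < 2:
        warnings.warn("single-gene panel: the index equals that gene's Cq", stacklevel=2)
    if len(genes) > 10:
        warnings.warn("BestKeeper panels above 10 candidates are unusual", stacklevel=2)
    e = _efficiency_series(genes, efficiencies).to_numpy()
    vals = cq.to_numpy(dtype=float)

    gm = np.exp(np.log(vals).mean(axis=1))
    am = vals.mean(axis=1)
    mn = vals.min(axis=1)
    mx = vals.max(axis=1)
    if sd_mode == "sample_sd":
        sd_stat = vals.std(axis=1, ddof=1)
    else:
        sd_stat = np.abs(vals - am[:, None]).mean(axis=1)
    cv_pct = 100.0 * sd_stat / am

    index = np.exp(np.log(vals).mean(axis=0))
    n = vals.shape[1]
    r = np.empty(len(genes))
    p = np.empty(len(genes))
    for i in range(len(genes)):
        if np.ptp(vals[i]) == 0 or np.ptp(index) == 0:
            r[i], p[i] = np.nan, np.nan
        else:
            r[i], p[i] = stats.pearsonr(vals[i], index)

    table = pd.DataFrame(
        {
            "gm": gm,
            "am": am,
            "min": mn,
            "max": mx,
            "sd": sd_stat,
            "cv_pct": cv_pct,
            "xfold_min": _signed_xfold(mn, gm, e),
            "xfold_max": _signed_xfold(mx, gm, e),
            "xfold_sd": np.power(e, sd_stat),
            "r_index": r,
            "p_value": p,
            "inconsistent": sd_stat > 1.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return BestKeeperResult(stats=table, index=pd.Series(index, index=cq.columns, name="bk_index"))


def rank_bestkeeper(stats: pd.DataFrame, demote_inconsistent: bool = True) -> list[str]:
    """Genes in descending order of correlation with the BestKeeper index.

    Genes flagged inconsistent (dispersion above one cycle) are demoted
    below all consistent genes by default.  Ties keep input order with a
    warning.
    """
    genes = list(stats.index)
    r = stats["r_index"]
    dup = r.round(12).duplicated(keep=False)
    if dup.any():
        warnings.warn(
            f"tied index correlations among {list(r.index[dup])}; input order preserved",
            stacklevel=2,
        )
    demote = stats["inconsistent"] if demote_inconsistent else pd.Series(False, index=stats.index)
    order = sorted(
        range(len(genes)),
        key=lambda i: (bool(demote.iloc[i]), -float(r.iloc[i]), i),
    )
    return [genes[i] for i in order]


def delta_ct_method(m: CqMatrix | pd.DataFrame) -> DeltaCtResult:
    """Average pairwise-SD stability (delta-Ct comparative method).

    ``pair_sd[i, k]`` is the ddof-1 SD over samples of ``Cq_i - Cq_k``;
    a gene's score is the mean over the other genes, ranked ascending.
    """
    cq = m.cq if isinstance(m, CqMatrix) else m
    if cq.isna().any().any():
        raise ValueError("delta-Ct method requires a complete Cq matrix")
    if cq.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    if cq.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = cq.to_numpy(dtype=float)
    diff = vals[:, None, :] - vals[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    np.fill_diagonal(sd, 0.0)
    pair_sd = pd.DataFrame(sd, index=cq.index, columns=cq.index)
    g = len(cq.index)
    mean_sd = pair_sd.sum(axis=1) / (g - 1)
    order = sorted(range(g), key=lambda i: (float(mean_sd.iloc[i]), i))
    return DeltaCtResult(
        pair_sd=pair_sd,
        mean_sd=mean_sd.rename("mean_sd"),
        ranking=[list(cq.index)[i] for i in order],
    )
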