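"""Poisson (Audic-Claverie) differential expression for tag counts.

Given a tag observed x times in a library of N1 total tags and y times
in a library of N2, the null distribution of y conditional on x is
negative binomial:

    p(y | x) = (N2/N1)**y * (x+y)! / ( x! y! (1 + N2/N1)**(x+y+1) )

The two-sided p-value doubles the smaller tail (capped at 1).  Tags
sequenced only once across the pair (singlets) are excluded, as are
sequences that are not 26 bases anchored on CATG.  Fold changes use
tags-per-million frequencies with zero counts replaced by one:
FC = R when R >= 1, else -1/R.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CALLS = ("UR", "DR", "ns")
TAG_LENGTH = 26
TAG_ANCHOR = "CATG"


def filter_tags(
    table: pd.DataFrame,
    singlet_mode: str = "total",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a tag-count table into kept and removed rows.

    *table* needs integer count columns ``x`` and ``y`` and may carry a
    ``sequence`` column.  Removal reasons: ``singlet`` (total count
    x + y == 1, or either count == 1 with ``singlet_mode='per_library'``),
    ``bad_length`` (sequence not 26 bases), ``bad_prefix`` (sequence not
    anchored on CATG).
    """
    if singlet_mode not in ("total", "per_library"):
        raise ValueError("singlet_mode must be 'total' or 'per_library'")
    x = table["x"].to_numpy()
    y = table["y"].to_numpy()
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative tag counts")
    reason = np.array([""] * len(table), dtype=object)
    if "sequence" in table.columns:
        seqs = table["sequence"].astype(str)
        bad_len = seqs.str.len() != TAG_LENGTH
        bad_prefix = ~seqs.str.startswith(TAG_ANCHOR) & ~bad_len
        reason[bad_len.to_numpy()] = "bad_length"
        reason[bad_prefix.to_numpy()] = "bad_prefix"
    if singlet_mode == "total":
        singlet = (x + y) == 1
    else:
        singlet = (x == 1) | (y == 1)
    singlet &= reason == ""
    reason[singlet] = "singlet"
    removed = table.loc[reason != ""].copy()
    removed["filtered_reason"] = reason[reason != ""]
    kept = table.loc[reason == ""].copy()
    return kept, removed


def ac_pvalue(x, y, n1, n2, alternative: str = "two-sided"):
    """Conditional Poisson p-value for a tag's counts in two libraries.

    Vectorized over ``x`` and ``y``.  The conditional null of y given x
    is negative binomial with size x+1 and success probability
    N1/(N1+N2); tails are evaluated in log-gamma space through the
    regularized incomplete beta function.  ``alternative`` is
    ``two-sided`` (double the smaller tail, capped at 1), ``greater``
    (y high) or ``less``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be > 0")
    pr = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, pr)      # P(Y <= y | x)
    upper = stats.nbinom.sf(y - 1, x + 1, pr)   # P(Y >= y | x)
    if alternative == "two-sided":
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    elif alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    if np.ndim(p) == 0:
        return float(p)
    return p


def fold_change(x, y, n1, n2):
    """Normalized ratio and signed fold change, zero counts replaced by one.

    Frequencies are tags per million: ``f = max(x,1)/N1 * 1e6`` and
    ``g = max(y,1)/N2 * 1e6``; ``R = g/f``; ``FC = R`` if R >= 1 else
    ``-1/R``.
    """
    x = np.maximum(np.asarray(x, dtype=float), 1.0)
    y = np.maximum(np.asarray(y, dtype=float), 1.0)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be > 0")
    f = x / n1 * 1e6
    g = y / n2 * 1e6
    r = g / f
    fc = np.where(r >= 1.0, r, -1.0 / r)
    if np.ndim(r) == 0:
        return float(r), float(fc)
    return r, fc


def de_call(ratio, p, alpha: float = 0.05):
    """UR / DR / ns per tag; a ratio of exactly 1 is never called."""
    ratio = np.asarray(ratio, dtype=float)
    p = np.asarray(p, dtype=float)
    call = np.full(ratio.shape, "ns", dtype=object)
    call[(p < alpha) & (ratio > 1)] = "UR"
    call[(p < alpha) & (ratio < 1)] = "DR"
    if call.ndim == 0:
        return str(call)
    return call


def tag_de_table(
    table: pd.DataFrame,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    singlet_mode: str = "total",
    alternative: str = "two-sided",
    bh: bool = False,
) -> pd.DataFrame:
    """Full differential-expression table for a pair of tag libraries.

    Filters singlets and malformed sequences, computes tags-per-million
    frequencies (raw counts), the zero-adjusted ratio and fold change,
    the conditional Poisson p-value and the UR/DR/ns call.  With
    ``bh=True`` calls are made on Benjamini-Hochberg adjusted p-values
    (off by default: the conventional workflow is per-tag p < alpha).
    """
    kept, removed = filter_tags(table, singlet_mode=singlet_mode)
    x = kept["x"].to_numpy()
    y = kept["y"].to_numpy()
    r, fc = fold_change(x, y, n1, n2)
    p = ac_pvalue(x, y, n1, n2, alternative=alternative)
    out = kept.copy()
    out["tpm1"] = x / n1 * 1e6
    out["tpm2"] = y / n2 * 1e6
    out["ratio"] = r
    out["fold_change"] = fc
    out["p_value"] = p
    if bh:
        from scipy.stats import false_discovery_control

        out["p_adjusted"] = false_discovery_control(p, method="bh")
        out["call"] = de_call(r, out["p_adjusted"].to_numpy(), alpha)
    else:
        out["call"] = de_call(r, p, alpha)
    removed = removed.reindex(columns=[*removed.columns])
    out.attrs["removed"] = removed
    return out
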