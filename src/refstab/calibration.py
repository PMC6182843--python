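"""Standard-curve regression and amplification-efficiency derivation.

A dilution series of known relative concentrations yields a regression of
Cq on log10(concentration); the slope determines the per-cycle
amplification base ``E = 10**(-1/slope)`` (E = 2 is perfect doubling) and
the percent efficiency ``(E - 1) * 100``.  Slopes within [-3.58, -3.10]
are accepted, the window conventionally quoted as 90-110% efficiency
(the exact endpoints are 90.26% and 110.17%; the slope window is the
operative rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Inclusive acceptance window for standard-curve slopes (cycles per log10 unit).
SLOPE_WINDOW = (-3.58, -3.10)


@dataclass
class StandardCurve:
    """Fitted standard curve and the efficiency derived from its slope."""

    gene: str
    slope: float
    y_intercept: float
    r2: float
    pearson_r: float
    efficiency_base_E: float
    efficiency_pct: float
    acceptable: bool
    reasons: tuple[str, ...] = ()
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "slope": self.slope,
            "y_intercept": self.y_intercept,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
            "efficiency_base_E": self.efficiency_base_E,
            "efficiency_pct": self.efficiency_pct,
            "acceptable": self.acceptable,
            "reasons": list(self.reasons),
            "n_points": self.n_points,
        }


def efficiency_from_slope(slope: float) -> tuple[float, float]:
    """Amplification base E and percent efficiency from a curve slope.

    ``E = 10**(-1/slope)``; percent efficiency is ``(E - 1) * 100``.
    The slope must be negative (Cq decreases with template amount).
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"slope must be finite and negative, got {slope}")
    e = 10.0 ** (-1.0 / slope)
    return e, (e - 1.0) * 100.0


def check_acceptance(slope: float, window: tuple[float, float] = SLOPE_WINDOW) -> tuple[bool, list[str]]:
    """Inclusive slope-window check, with reasons when a bound fails."""
    lo, hi = window
    reasons = []
    if slope < lo:
        reasons.append("efficiency below window (slope steeper than %.2f)" % lo)
    if slope > hi:
        reasons.append("efficiency above window (slope shallower than %.2f)" % hi)
    return not reasons, reasons


def fit_standard_curve(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    gene: str = "",
) -> StandardCurve:
    """Ordinary least squares of Cq on log10 relative concentration.

    *points* is a sequence of ``(log10_conc, cq)`` pairs or a DataFrame
    with ``log10_conc`` and ``cq`` columns; at least three points over at
    least two distinct concentrations are required.  ``r2`` is the squared
    Pearson correlation; the signed correlation is reported separately
    (display conventions sometimes print it with the slope's sign).
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_conc"].to_numpy(dtype=float)
        y = points["cq"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (log10_conc, cq) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 3:
        raise ValueError("need at least 3 standard-curve points")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all concentrations identical")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    e, e_pct = efficiency_from_slope(slope)
    acceptable, reasons = check_acceptance(slope)
    return StandardCurve(
        gene=gene,
        slope=slope,
        y_intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        pearson_r=float(fit.rvalue),
        efficiency_base_E=e,
        efficiency_pct=e_pct,
        acceptable=acceptable,
        reasons=tuple(reasons),
        n_points=int(x.size),
    )


def calibrate_panel(dilutions: pd.DataFrame) -> pd.DataFrame:
    """Fit a standard curve per gene from a table (gene, log10_conc, cq).

    Returns one row per gene mirroring the usual calibration report
    (slope, efficiency %, r2, y-intercept, acceptance).
    """
    rows = []
    for gene, grp in dilutions.groupby("gene", sort=False):
        curve = fit_standard_curve(grp[["log10_conc", "cq"]], gene=str(gene))
        rows.append(curve.to_dict())
    out = pd.DataFrame(rows)
    return out.drop(columns=["reasons"])
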