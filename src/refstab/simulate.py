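"""Seeded generators for Cq matrices, dilution series, and tag libraries.

The generators emulate the statistical structure a qPCR normalization
study assumes, with known ground truth:

* ``simulate_cq`` draws Cq values from an additive Gaussian model on the
  cycle (log2-quantity) scale::

      Cq = mu_gene + delta(group, time) + s_sample + e_bio + t_tech

  where ``s_sample`` is a loading effect shared by all genes of one RNA
  sample (the correlation that sample-centering methods exploit),
  ``e_bio`` is per-gene biological noise and ``t_tech`` per-well
  technical noise.
* ``simulate_dilution_series`` produces standard-curve points on a known
  efficiency.
* ``simulate_tags`` draws Poisson tag counts for two sequencing
  libraries at given depths, mixing null tags (equal rates) with
  designed fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from refstab.cq import LONG_COLUMNS, CqMatrix


@dataclass
class GeneSpec:
    """Ground-truth parameters for one simulated gene.

    ``delta`` is the treatment effect in cycles: either a scalar applied
    to every sample of a non-control group, or a mapping
    ``(group, time_min) -> cycles`` for time-resolved effects.  A gene
    with all deltas zero is "stable" by design.
    """

    gene: str
    baseline_mu: float
    noise_sd: float = 0.5
    delta: float | Mapping[tuple[str, int], float] = 0.0

    def delta_at(self, group: str, time_min: int, control_group: str) -> float:
        if isinstance(self.delta, Mapping):
            return float(self.delta.get((group, time_min), 0.0))
        return float(self.delta) if group != control_group else 0.0

    @property
    def max_abs_delta(self) -> float:
        if isinstance(self.delta, Mapping):
            return max((abs(v) for v in self.delta.values()), default=0.0)
        return abs(float(self.delta))


@dataclass
class CqSimConfig:
    """Design and noise levels for a simulated qPCR experiment.

    The design is fully crossed: every group is observed at every time
    with ``bio_reps`` biological x ``tech_reps`` technical replicates.
    """

    genes: Sequence[GeneSpec]
    groups: Sequence[str] = ("control", "treated")
    times: Sequence[int] = (0, 25, 75, 150)
    bio_reps: int = 3
    tech_reps: int = 3
    sample_effect_sd: float = 0.4
    tech_noise_sd: float = 0.2
    assay: str = "root_dehydration"
    accession: str = "synthetic"
    control_group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.sample_effect_sd < 0 or self.tech_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for g in self.genes:
            if g.noise_sd < 0:
                raise ValueError(f"gene {g.gene}: noise_sd must be >= 0")


def default_panel(seed: int = 0, unstable_delta: float = 1.5) -> CqSimConfig:
    """Seven-gene preset mimicking a typical candidate reference panel.

    Baselines span 15.6-21.6 cycles.  Residual biological noise is set so
    that the realized marginal Cq dispersions of the six stable genes land
    near the 0.45-0.60 cycle band reported for well-behaved reference
    candidates, while ``EF1a`` plays the designed unstable role: a
    treatment effect of *unstable_delta* cycles plus elevated noise,
    giving it a marginal dispersion around 1.4 cycles.
    """
    genes = [
        GeneSpec("UNK", 19.9, 0.42),
        GeneSpec("TUB", 19.8, 0.37),
        GeneSpec("FBOX", 21.6, 0.39),
        GeneSpec("UE21D", 18.4, 0.30),
        GeneSpec("UBQ10", 15.6, 0.17),
        GeneSpec("ACT", 20.4, 0.33),
        GeneSpec("EF1a", 16.6, 1.05, delta=unstable_delta),
    ]
    return CqSimConfig(genes=genes, sample_effect_sd=0.4, tech_noise_sd=0.2, seed=seed)


def simulate_cq(cfg: CqSimConfig) -> tuple[CqMatrix, pd.DataFrame]:
    """Draw a Cq matrix from the additive Gaussian model.

    Returns the matrix (one column per well, technical replicates not yet
    collapsed) and a ground-truth table with each gene's designed
    stability class (``stable`` iff all deltas are zero).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group in cfg.groups:
        for time in cfg.times:
            for bio in range(1, cfg.bio_reps + 1):
                s_eff = rng.normal(0.0, cfg.sample_effect_sd)
                bio_noise = {
                    g.gene: rng.normal(0.0, g.noise_sd) if g.noise_sd > 0 else 0.0
                    for g in cfg.genes
                }
                for tech in range(1, cfg.tech_reps + 1):
                    sid = f"{cfg.assay}:{cfg.accession}:{group}:t{time}:b{bio}:r{tech}"
                    for g in cfg.genes:
                        t_noise = (
                            rng.normal(0.0, cfg.tech_noise_sd) if cfg.tech_noise_sd > 0 else 0.0
                        )
                        cq = (
                            g.baseline_mu
                            + g.delta_at(group, time, cfg.control_group)
                            + s_eff
                            + bio_noise[g.gene]
                            + t_noise
                        )
                        rows.append(
                            {
                                "sample_id": sid,
                                "assay": cfg.assay,
                                "accession": cfg.accession,
                                "group": group,
                                "time_min": time,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "gene": g.gene,
                                "cq": cq,
                            }
                        )
    long = pd.DataFrame(rows, columns=LONG_COLUMNS)
    truth = pd.DataFrame(
        {
            "gene": [g.gene for g in cfg.genes],
            "baseline_mu": [g.baseline_mu for g in cfg.genes],
            "noise_sd": [g.noise_sd for g in cfg.genes],
            "max_abs_delta": [g.max_abs_delta for g in cfg.genes],
            "stable": [g.max_abs_delta == 0.0 for g in cfg.genes],
        }
    )
    return CqMatrix.from_long(long), truth


def simulate_dilution_series(
    true_efficiency_pct: float,
    intercept: float,
    points: int = 5,
    fold: float = 10.0,
    noise_sd: float = 0.0,
    reps: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Standard-curve points for a known amplification efficiency.

    The k-th dilution has relative concentration ``fold**-k`` (k = 0 the
    undiluted calibrator), so ``Cq = intercept + slope * log10(conc)``
    with ``slope = -1 / log10(1 + E%/100)``.  Gaussian noise of SD
    *noise_sd* cycles is added per replicate well.
    """
    e_base = 1.0 + true_efficiency_pct / 100.0
    if not 1.5 <= e_base <= 2.2:
        raise ValueError("efficiency outside the plausible 50-120% range")
    slope = -1.0 / np.log10(e_base)
    rng = np.random.default_rng(seed)
    log_conc = np.repeat(-np.arange(points) * np.log10(fold), reps)
    cq = intercept + slope * log_conc
    if noise_sd > 0:
        cq = cq + rng.normal(0.0, noise_sd, size=cq.shape)
    return pd.DataFrame({"log10_conc": log_conc, "cq": cq})


_BASES = np.array(list("ACGT"))


@dataclass
class TagSimConfig:
    """Per-tag rates (tags per million) for two libraries of given depths."""

    rates1: Sequence[float]
    rates2: Sequence[float]
    n1: int = 1_000_000
    n2: int = 1_000_000
    make_sequences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.rates1 = np.asarray(self.rates1, dtype=float)
        self.rates2 = np.asarray(self.rates2, dtype=float)
        if self.rates1.shape != self.rates2.shape:
            raise ValueError("rate vectors must have equal length")
        if (self.rates1 < 0).any() or (self.rates2 < 0).any():
            raise ValueError("rates must be >= 0")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library sizes must be > 0")

    @classmethod
    def null_and_de(
        cls,
        n_null: int,
        null_rate: float = 100.0,
        de_folds: Sequence[float] = (),
        de_base_rate: float = 100.0,
        n1: int = 1_000_000,
        n2: int = 1_000_000,
        make_sequences: bool = False,
        seed: int = 0,
    ) -> "TagSimConfig":
        """Mix of *n_null* equal-rate tags and one tag per designed fold."""
        r1 = [null_rate] * n_null + [de_base_rate] * len(de_folds)
        r2 = [null_rate] * n_null + [de_base_rate * f for f in de_folds]
        return cls(r1, r2, n1=n1, n2=n2, make_sequences=make_sequences, seed=seed)


def simulate_tags(cfg: TagSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw Poisson tag counts for a pair of libraries.

    Counts are ``Poisson(rate * library_size / 1e6)``.  Returns the count
    table (columns ``tag``, optional ``sequence``, ``x``, ``y``) and a
    ground-truth table with each tag's designed rates and fold.
    """
    rng = np.random.default_rng(cfg.seed)
    lam1 = cfg.rates1 * cfg.n1 / 1e6
    lam2 = cfg.rates2 * cfg.n2 / 1e6
    x = rng.poisson(lam1)
    y = rng.poisson(lam2)
    n = len(cfg.rates1)
    tags = [f"tag{i:06d}" for i in range(n)]
    table = pd.DataFrame({"tag": tags, "x": x, "y": y})
    if cfg.make_sequences:
        # 26-mers anchored at the CATG restriction site
        suffix = rng.choice(_BASES, size=(n, 22))
        table.insert(1, "sequence", ["CATG" + "".join(row) for row in suffix])
    with np.errstate(divide="ignore", invalid="ignore"):
        true_fold = np.where(
            cfg.rates1 > 0, cfg.rates2 / np.where(cfg.rates1 > 0, cfg.rates1, 1.0), np.inf
        )
    truth = pd.DataFrame(
        {
            "tag": tags,
            "rate1": cfg.rates1,
            "rate2": cfg.rates2,
            "true_fold": true_fold,
            "null": cfg.rates1 == cfg.rates2,
        }
    )
    return table, truth
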