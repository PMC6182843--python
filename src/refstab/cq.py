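"""Data model, validation and tabular I/O for quantification-cycle (Cq) data.

The canonical on-disk format is a long (tidy) delimited table with one row
per well: ``sample_id, assay, accession, group, time_min, bio_rep,
tech_rep, gene, cq``.  In memory the data live in a :class:`CqMatrix`,
a genes x samples grid of Cq values paired with per-sample metadata.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = [
    "sample_id",
    "assay",
    "accession",
    "group",
    "time_min",
    "bio_rep",
    "tech_rep",
    "gene",
    "cq",
]

META_COLUMNS = ["assay", "accession", "group", "time_min", "bio_rep", "tech_rep"]


class CqFormatError(ValueError):
    """A Cq table violates the expected file format (e.g. missing column)."""


class CqDataError(ValueError):
    """A Cq table is syntactically valid but contains inconsistent data."""


@dataclass
class CqMatrix:
    """Genes x samples grid of Cq values with per-sample metadata.

    Parameters
    ----------
    cq
        DataFrame indexed by gene id with one column per ``sample_id``.
        Entries may be NaN (missing wells).
    samples
        DataFrame indexed by ``sample_id`` with columns ``assay``,
        ``accession``, ``group``, ``time_min``, ``bio_rep``, ``tech_rep``.
        Column order must match ``cq.columns``.
    """

    cq: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        if self.cq.index.duplicated().any():
            dupes = self.cq.index[self.cq.index.duplicated()].tolist()
            raise CqDataError(f"duplicate gene ids: {dupes}")
        if self.samples.index.duplicated().any():
            dupes = self.samples.index[self.samples.index.duplicated()].tolist()
            raise CqDataError(f"duplicate sample ids: {dupes}")
        if list(self.cq.columns) != list(self.samples.index):
            raise CqDataError("cq columns and sample metadata index disagree")
        missing_meta = [c for c in META_COLUMNS if c not in self.samples.columns]
        if missing_meta:
            raise CqFormatError(f"sample metadata lacks columns: {missing_meta}")
        values = self.cq.to_numpy()
        if np.isinf(values).any():
            raise CqDataError("non-finite Cq values present")
        all_missing = self.cq.columns[self.cq.isna().all(axis=0)].tolist()
        if all_missing:
            raise CqDataError(f"samples with no Cq observation: {all_missing}")
        key = self.samples[META_COLUMNS]
        if key.duplicated().any():
            raise CqDataError(
                "duplicate (assay, accession, group, time_min, bio_rep, tech_rep) keys"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_genes(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]

    def to_long(self) -> pd.DataFrame:
        """Return the long (tidy) representation, one row per well."""
        long = (
            self.cq.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="sample_id", value_name="cq")
        )
        long = long.dropna(subset=["cq"])
        meta = self.samples.rename_axis("sample_id").reset_index()
        out = long.merge(meta, on="sample_id", how="left")[LONG_COLUMNS]
        # stable order: samples then genes, both in matrix order
        out["_s"] = out["sample_id"].map({s: i for i, s in enumerate(self.cq.columns)})
        out["_g"] = out["gene"].map({g: i for i, g in enumerate(self.cq.index)})
        out = out.sort_values(["_s", "_g"]).drop(columns=["_s", "_g"])
        return out.reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CqMatrix":
        missing = [c for c in LONG_COLUMNS if c not in long.columns]
        if missing:
            raise CqFormatError(f"missing mandatory column(s): {missing}")
        dup = long.duplicated(subset=["sample_id", "gene"], keep=False)
        if dup.any():
            keys = (
                long.loc[dup, ["sample_id", "gene"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise CqDataError(f"duplicate (sample, gene) rows: {sorted(keys)}")
        grid = long.pivot(index="gene", columns="sample_id", values="cq")
        meta = (
            long[["sample_id", *META_COLUMNS]]
            .drop_duplicates(subset="sample_id")
            .set_index("sample_id")
        )
        # preserve first-appearance order of genes and samples
        gene_order = list(dict.fromkeys(long["gene"]))
        sample_order = list(dict.fromkeys(long["sample_id"]))
        return cls(grid.loc[gene_order, sample_order], meta.loc[sample_order])

    def select(self, mask: pd.Series) -> "CqMatrix":
        """Subset samples by a boolean mask over the metadata index."""
        keep = self.samples.index[mask.reindex(self.samples.index).fillna(False)]
        return CqMatrix(self.cq[keep], self.samples.loc[keep])


def read_cq_table(
    path: str | Path,
    sep: str = ",",
    report_path: str | Path | None = None,
) -> CqMatrix:
    """Read a long-format Cq table from a delimited text file.

    Rows whose ``cq`` field does not parse as a number are rejected and
    counted; a JSON validation report is written to *report_path* when
    given.  Duplicate ``(sample_id, gene)`` rows raise :class:`CqDataError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in LONG_COLUMNS if c not in raw.columns]
    if missing:
        raise CqFormatError(f"{path.name}: missing mandatory column(s): {missing}")
    cq = pd.to_numeric(raw["cq"], errors="coerce")
    bad = cq.isna() & raw["cq"].notna()
    if bad.any():
        logger.warning("%s: rejected %d row(s) with unparseable Cq", path.name, int(bad.sum()))
    parsed = raw.loc[~bad].copy()
    parsed["cq"] = cq[~bad]
    for col in ("time_min", "bio_rep", "tech_rep"):
        parsed[col] = pd.to_numeric(parsed[col]).astype(int)
    if report_path is not None:
        report = {
            "path": str(path),
            "n_rows": int(len(raw)),
            "n_rejected": int(bad.sum()),
            "rejected_rows": raw.index[bad].tolist(),
        }
        Path(report_path).write_text(json.dumps(report, indent=2))
    return CqMatrix.from_long(parsed)


def write_cq_table(m: CqMatrix, path: str | Path, sep: str = ",") -> None:
    """Write the long-format representation of *m* to a delimited file."""
    m.to_long().to_csv(path, sep=sep, index=False, float_format="%.10g")


def collapse_technical_reps(m: CqMatrix) -> CqMatrix:
    """Average technical replicates, leaving one column per biological replicate.

    The collapsed Cq is the arithmetic mean of the non-missing technical
    Cqs of each (assay, accession, group, time, bio_rep, gene) cell; a cell
    whose technical replicates are all missing stays missing.  Collapsed
    samples carry ``tech_rep = 0``.
    """
    long = m.to_long()
    keys = ["assay", "accession", "group", "time_min", "bio_rep"]
    agg = long.groupby(keys + ["gene"], sort=False, as_index=False)["cq"].mean()
    agg["tech_rep"] = 0
    agg["sample_id"] = (
        agg["assay"].astype(str)
        + ":"
        + agg["accession"].astype(str)
        + ":"
        + agg["group"].astype(str)
        + ":t"
        + agg["time_min"].astype(str)
        + ":b"
        + agg["bio_rep"].astype(str)
    )
    return CqMatrix.from_long(agg[LONG_COLUMNS])


def complete_case(m: CqMatrix) -> tuple[CqMatrix, int]:
    """Drop samples with any missing gene (complete-case filter).

    The stability statistics all assume a complete genes x samples grid.
    Returns the filtered matrix and the number of samples dropped.
    """
    keep = m.cq.notna().all(axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d sample(s)", n_dropped)
    return CqMatrix(m.cq.loc[:, keep], m.samples.loc[keep[keep].index]), n_dropped


def cq_dispersion(
    m: CqMatrix,
    sd_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Cq dispersion screen within each assay.

    For every (assay, gene) with at least two observations, computes the
    sample standard deviation (ddof=1) of the Cq across all samples of that
    assay and the coefficient of variance ``cv_pct = 100 * sd / mean``.
    A gene passes the screen when ``sd < sd_threshold`` (default one
    cycle).  Genes with fewer than two observations in an assay are
    excluded with a warning.
    """
    long = m.to_long()
    rows = []
    for (assay, gene), grp in long.groupby(["assay", "gene"], sort=False):
        vals = grp["cq"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            warnings.warn(
                f"gene {gene!r} has fewer than 2 observations in assay {assay!r}; excluded",
                stacklevel=2,
            )
            continue
        sd = float(np.std(vals, ddof=1))
        mean = float(np.mean(vals))
        rows.append(
            {
                "assay": assay,
                "gene": gene,
                "mean_cq": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean,
                "passes_screen": bool(sd < sd_threshold),
            }
        )
    return pd.DataFrame(rows, columns=["assay", "gene", "mean_cq", "sd", "cv_pct", "passes_screen"])
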