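"""Published summary inputs from the cowpea root-stress qPCR study.

These are printed summary values (standard-curve slope magnitudes and
cross-platform regulation-call grids) that serve as inputs to the
calibration arithmetic and the agreement rule; the underlying raw Cq
and tag tables were not deposited.  Slopes are stored as printed
magnitudes; the fitted slopes are negative (see
:mod:`refstab.calibration`).

One printed efficiency (the LTP assay, slope magnitude 3.38) is
internally inconsistent with its slope at two decimals; the value
derived from the slope is kept here.
"""

from __future__ import annotations

#: Standard-curve slope magnitudes of the seven candidate reference-gene assays.
REFERENCE_SLOPES: dict[str, float] = {
    "ACT": 3.18,
    "TUB": 3.25,
    "EF1a": 3.38,
    "FBOX": 3.28,
    "UE21D": 3.30,
    "UBQ10": 3.40,
    "UNK": 3.35,
}

#: Standard-curve slope magnitudes of the four target-transcript assays.
TARGET_SLOPES: dict[str, float] = {
    "ChiB": 3.40,
    "LTP": 3.38,
    "CHI": 3.43,
    "CHS": 3.31,
}

#: All eleven assay slopes (reference candidates first).
PANEL_SLOPES: dict[str, float] = {**REFERENCE_SLOPES, **TARGET_SLOPES}

#: Published percent efficiencies for the rows whose printed value matches
#: the printed slope at two decimals (used as cross-checks).
PUBLISHED_EFFICIENCY_PCT: dict[str, float] = {
    "ACT": 106.28,
    "TUB": 103.09,
    "EF1a": 97.63,
    "FBOX": 101.78,
    "UE21D": 100.92,
    "UBQ10": 96.84,
    "UNK": 98.84,
    "ChiB": 96.84,
    "CHI": 95.68,
    "CHS": 100.50,
}

#: Cross-platform regulation calls for the four target transcripts:
#: the pooled-library sequencing call and the per-time qPCR calls (three
#: stress times per assay/accession class).
CROSS_PLATFORM_CALLS: list[dict] = [
    {"gene": "ChiB", "assay": "root_dehydration", "accession_class": "tolerant",
     "ht_call": "UR", "qpcr_calls": ["ns", "ns", "ns"]},
    {"gene": "ChiB", "assay": "root_dehydration", "accession_class": "sensitive",
     "ht_call": "ns", "qpcr_calls": ["UR", "ns", "ns"]},
    {"gene": "ChiB", "assay": "salt", "accession_class": "tolerant",
     "ht_call": "ns", "qpcr_calls": ["ns", "ns", "UR"]},
    {"gene": "ChiB", "assay": "salt", "accession_class": "sensitive",
     "ht_call": "UR", "qpcr_calls": ["DR", "DR", "ns"]},
    {"gene": "LTP", "assay": "root_dehydration", "accession_class": "tolerant",
     "ht_call": "UR", "qpcr_calls": ["ns", "ns", "UR"]},
    {"gene": "LTP", "assay": "root_dehydration", "accession_class": "sensitive",
     "ht_call": "DR", "qpcr_calls": ["ns", "ns", "ns"]},
    {"gene": "LTP", "assay": "salt", "accession_class": "tolerant",
     "ht_call": "UR", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "LTP", "assay": "salt", "accession_class": "sensitive",
     "ht_call": "DR", "qpcr_calls": ["ns", "ns", "ns"]},
    {"gene": "CHI", "assay": "root_dehydration", "accession_class": "tolerant",
     "ht_call": "UR", "qpcr_calls": ["ns", "UR", "UR"]},
    {"gene": "CHI", "assay": "root_dehydration", "accession_class": "sensitive",
     "ht_call": "UR", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "CHI", "assay": "salt", "accession_class": "tolerant",
     "ht_call": "UR", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "CHI", "assay": "salt", "accession_class": "sensitive",
     "ht_call": "ns", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "CHS", "assay": "root_dehydration", "accession_class": "tolerant",
     "ht_call": "UR", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "CHS", "assay": "root_dehydration", "accession_class": "sensitive",
     "ht_call": "ns", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "CHS", "assay": "salt", "accession_class": "tolerant",
     "ht_call": "ns", "qpcr_calls": ["UR", "UR", "UR"]},
    {"gene": "CHS", "assay": "salt", "accession_class": "sensitive",
     "ht_call": "UR", "qpcr_calls": ["UR", "UR", "ns"]},
]
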