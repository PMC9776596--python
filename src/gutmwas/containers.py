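"""Core data containers shared across the pipeline.

The pipeline moves species count data through three representations:

* :class:`ReferenceCatalog` — the species universe (ids, display names with a
  rank-initial naming protocol, genome lengths in bp).
* :class:`TaxProfile` — a samples × species matrix of (possibly averaged)
  read counts attributed to each species by one or more taxonomic
  classifiers.
* :class:`AbundanceMatrix` — genome-length- and depth-normalised relative
  abundances; every row lies on the simplex.

Per-species association screens all emit a common tidy ``AssociationTable``
(pandas DataFrame) schema so downstream consensus calls can join on
``species_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASSIFIERS = ("DeepMicrobes", "Kaiju", "Kraken2")

#: columns every association screen emits
ASSOCIATION_COLUMNS = [
    "species_id",
    "statistic",
    "effect_size",
    "direction",
    "p",
    "p_adj",
    "adjust_method",
]

RANK_INITIALS = frozenset("sgfocp")


def make_display_name(rank_initial: str, name: str, species_id: str) -> str:
    """Build a display name following the rank-initial naming protocol.

    The most specific known rank is prefixed as a single initial
    (s=species, g=genus, f=family, o=order, c=class, p=phylum), followed by
    the taxon name and the catalog identifier: ``g_Prevotella|UMGS2051``.
    """
    if rank_initial not in RANK_INITIALS:
        raise ValueError(f"unknown rank initial {rank_initial!r}")
    return f"{rank_initial}_{name}|{species_id}"


def parse_display_name(display_name: str) -> tuple[str, str, str]:
    """Invert :func:`make_display_name` -> (rank_initial, name, species_id)."""
    head, sep, species_id = display_name.rpartition("|")
    if not sep or "_" not in head:
        raise ValueError(f"malformed display name {display_name!r}")
    rank_initial, _, name = head.partition("_")
    if rank_initial not in RANK_INITIALS:
        raise ValueError(f"unknown rank initial in {display_name!r}")
    return rank_initial, name, species_id


@dataclass(frozen=True)
class ReferenceCatalog:
    """Species catalog: unique ids, display names and genome lengths."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("species_id", "display_name", "rank_initial", "genome_length_bp")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        ids = self.table["species_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate species ids in catalog")
        if (self.table["genome_length_bp"] < 1).any():
            raise ValueError("genome lengths must be >= 1 bp")

    @property
    def species_ids(self) -> pd.Index:
        return pd.Index(self.table["species_id"])

    def genome_lengths(self, species_ids) -> np.ndarray:
        s = self.table.set_index("species_id")["genome_length_bp"]
        return s.loc[list(species_ids)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceCatalog":
        return cls(pd.read_csv(path, sep="\t"))


COHORT_COLUMNS = [
    "patient_id",
    "sample_id",
    "sampling_day",
    "outcome",
    "grade",
    "conditioning",
    "cyclophosphamide",
    "disease_group",
    "dr_relationship",
    "donor_sex",
    "karnofsky_d0",
    "radiation_group",
    "recipient_age",
    "recipient_sex",
    "transplant_source",
]

#: base (reference) level first, alternate second, for each categorical
#: clinical covariate
CLINICAL_LEVELS = {
    "conditioning": ("non-myeloablative", "myeloablative"),
    "cyclophosphamide": ("none", "used"),
    "disease_group": ("acute leukemia", "other hematological malignancies"),
    "dr_relationship": ("related", "unrelated"),
    "donor_sex": ("male", "female"),
    "radiation_group": ("none", "irradiated"),
    "recipient_sex": ("male", "female"),
    "transplant_source": ("bone marrow", "peripheral blood"),
}


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a cohort table and return it unchanged."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    per_patient = cohort.groupby("patient_id")["outcome"].nunique()
    if (per_patient > 1).any():
        raise ValueError("a patient has more than one outcome")
    if (cohort["sampling_day"] > 0).any():
        raise ValueError("pre-transplant sampling days must be <= 0")
    cases = cohort["outcome"] == 1
    if cases.any() and (cohort.loc[cases, "grade"] < 2).any():
        raise ValueError("case grades must be >= 2")
    return cohort


@dataclass(frozen=True)
class TaxProfile:
    """Samples × species count matrix with classifier provenance.

    Counts are integers straight from a classifier parser and become reals
    after ensemble (arithmetic-mean) aggregation.
    """

    counts: pd.DataFrame = field(repr=False)
    classifiers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "classifiers", frozenset(self.classifiers))

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def species_ids(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, path) -> None:
        """Write the canonical wide TSV dialect (rows=samples, cols=species)."""
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class AbundanceMatrix:
    """Relative abundances; every row sums to one."""

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("negative abundances")
        rows = arr.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            bad = self.values.index[np.abs(rows - 1.0) > 1e-9][:5].tolist()
            raise ValueError(f"rows do not sum to 1, e.g. {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def species_ids(self) -> pd.Index:
        return self.values.columns

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
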