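"""Classifier-output ingestion, ensemble aggregation and normalisation.

Three taxonomic classifiers (DeepMicrobes, Kaiju, Kraken2) each produce a
per-sample species count table. This module parses their output dialects,
builds the seven arithmetic-mean ensemble configurations (all non-empty
classifier subsets), normalises counts by genome size and sequencing depth
into relative abundances, and applies the sample-level QC and
per-patient deduplication rules.

Supported dialects
------------------
``canonical_tsv``
    Wide interchange format: first column ``sample_id``, remaining columns
    species ids, integer counts. One file holds many samples.
``kraken2_report``
    The six-column Kraken2 report (percent, clade reads, direct reads,
    rank code, taxid, indented name). One file per sample; a directory of
    reports is read as one profile with sample ids taken from file stems.
    Species-level rows (rank code ``S``) are used; the taxid column is
    matched against catalog species ids. Unclassified (``U``) rows are
    ignored.
``kaiju_summary``
    The ``kaiju2table`` summary TSV (file, percent, reads, taxon_id,
    taxon_name); may hold many samples, sample ids from the ``file``
    column. ``unclassified`` rows are ignored.

All readers accept gzip-compressed files (``.gz`` suffix). Taxa present in
a file but absent from the catalog are dropped with a warning (classifier
databases drift); the drop count is returned alongside the profile.
"""

from __future__ import annotations

import gzip
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLASSIFIERS, AbundanceMatrix, ReferenceCatalog, TaxProfile

logger = logging.getLogger(__name__)

DIALECTS = ("canonical_tsv", "kraken2_report", "kaiju_summary")

#: QC threshold: samples with fewer reads than this after quality control
#: are removed (strictly-less-than semantics)
MIN_READS_QC = 1_000_000


class ParseError(ValueError):
    """Malformed classifier output; message names the offending line."""


@dataclass(frozen=True)
class ProfilingConfiguration:
    """One ensemble cell: a non-empty classifier subset × species set."""

    classifier_subset: frozenset
    species_set: str = "complete"  # or "reduced"

    def __post_init__(self) -> None:
        subset = frozenset(self.classifier_subset)
        if not subset:
            raise ValueError("classifier subset must be non-empty")
        unknown = subset - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if self.species_set not in ("complete", "reduced"):
            raise ValueError("species_set must be 'complete' or 'reduced'")
        object.__setattr__(self, "classifier_subset", subset)

    @property
    def label(self) -> str:
        names = ",".join(sorted(self.classifier_subset))
        return f"AM({names})|{self.species_set}"


def enumerate_configurations(species_sets=("complete", "reduced")):
    """All 7 non-empty classifier subsets crossed with the species sets."""
    configs = []
    for r in range(1, len(CLASSIFIERS) + 1):
        for subset in itertools.combinations(CLASSIFIERS, r):
            for sset in species_sets:
                configs.append(ProfilingConfiguration(frozenset(subset), sset))
    return configs


@dataclass(frozen=True)
class ReadResult:
    """A parsed profile plus the number of off-catalog taxa dropped."""

    profile: TaxProfile
    n_dropped: int
    dropped_ids: tuple = ()


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_kraken2_file(path) -> dict:
    """One Kraken2 report -> {taxon_key: direct species reads}."""
    counts: dict = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 fields, "
                                 f"got {len(fields)}")
            _, _, direct, rank, taxid, name = fields[:6]
            if rank == "U":
                continue
            if rank != "S":
                continue
            try:
                n = int(direct)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer read count "
                    f"{direct!r}") from exc
            counts[taxid.strip()] = counts.get(taxid.strip(), 0) + n
    return counts


def _parse_kaiju_file(path) -> dict:
    """Kaiju summary TSV -> {sample_id: {taxon_key: reads}}."""
    per_sample: dict = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_file = header.index("file")
            i_reads = header.index("reads")
            i_taxid = header.index("taxon_id")
            i_name = header.index("taxon_name")
        except ValueError as exc:
            raise ParseError(f"{path}: line 1: missing kaiju columns") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(header)} fields, got {len(fields)}")
            name = fields[i_name]
            if name.strip().lower() in ("unclassified", "cannot be assigned"):
                continue
            sample = Path(fields[i_file]).stem
            try:
                n = int(fields[i_reads])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer read "
                                 f"count {fields[i_reads]!r}") from exc
            per_sample.setdefault(sample, {})
            key = fields[i_taxid].strip()
            per_sample[sample][key] = per_sample[sample].get(key, 0) + n
    return per_sample


def _assemble(per_sample: dict, catalog: ReferenceCatalog,
              classifier_tag) -> ReadResult:
    known = set(catalog.species_ids)
    dropped = sorted(
        {t for counts in per_sample.values() for t in counts} - known
    )
    if dropped:
        logger.warning("dropped %d taxa absent from catalog (e.g. %s)",
                       len(dropped), dropped[:3])
    samples = sorted(per_sample)
    mat = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"),
        columns=catalog.species_ids, dtype=np.int64,
    )
    for s in samples:
        for taxon, n in per_sample[s].items():
            if taxon in known:
                mat.loc[s, taxon] = n
    profile = TaxProfile(mat, frozenset(classifier_tag))
    return ReadResult(profile, len(dropped), tuple(dropped))


def read_classifier_table(
    path,
    dialect: str,
    catalog: ReferenceCatalog,
    classifier: str | None = None,
) -> ReadResult:
    """Parse a classifier output file (or directory of per-sample files).

    Species absent from the file get count 0; taxa absent from the catalog
    are dropped with a logged warning. Returns the profile together with
    the dropped-taxon count.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of "
                         f"{DIALECTS}")
    tag = {classifier} if classifier else set()
    path = Path(path)

    if dialect == "canonical_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        known = set(catalog.species_ids)
        dropped = sorted(set(df.columns) - known)
        if dropped:
            logger.warning("dropped %d taxa absent from catalog", len(dropped))
        df = df.drop(columns=dropped)
        full = pd.DataFrame(0, index=df.index, columns=catalog.species_ids,
                            dtype=float)
        full.loc[:, df.columns] = df.to_numpy()
        if np.allclose(full.to_numpy(), np.round(full.to_numpy())):
            full = full.round().astype(np.int64)
        return ReadResult(TaxProfile(full, frozenset(tag)),
                          len(dropped), tuple(dropped))

    if dialect == "kraken2_report":
        if path.is_dir():
            files = sorted(p for p in path.iterdir()
                           if p.suffix in (".txt", ".tsv", ".report", ".gz"))
            per_sample = {
                p.name.removesuffix(".gz").rsplit(".", 1)[0]:
                    _parse_kraken2_file(p)
                for p in files
            }
        else:
            per_sample = {path.stem: _parse_kraken2_file(path)}
        return _assemble(per_sample, catalog, tag)

    per_sample = _parse_kaiju_file(path)
    return _assemble(per_sample, catalog, tag)


# ---------------------------------------------------------------------------
# writers (used by the synthetic generator to feed the parsers end-to-end)
# ---------------------------------------------------------------------------

def write_canonical_tsv(profile: TaxProfile, path) -> None:
    profile.to_tsv(path)


def write_kraken2_report(counts: pd.Series, catalog: ReferenceCatalog,
                         path, unclassified: int = 0) -> None:
    """Write one sample's counts as a Kraken2-style report file."""
    total = int(counts.sum()) + unclassified
    names = catalog.table.set_index("species_id")["display_name"]
    with open(path, "wt") as fh:
        if total:
            pct = 100.0 * unclassified / total
            fh.write(f"{pct:6.2f}\t{unclassified}\t{unclassified}\tU\t0\t"
                     f"unclassified\n")
        for sid, n in counts.items():
            if n == 0:
                continue
            pct = 100.0 * n / total if total else 0.0
            fh.write(f"{pct:6.2f}\t{int(n)}\t{int(n)}\tS\t{sid}\t"
                     f"    {names.get(sid, sid)}\n")


def write_kaiju_summary(profile: TaxProfile, catalog: ReferenceCatalog,
                        path) -> None:
    """Write a multi-sample Kaiju-style summary TSV."""
    names = catalog.table.set_index("species_id")["display_name"]
    with open(path, "wt") as fh:
        fh.write("file\tpercent\treads\ttaxon_id\ttaxon_name\n")
        for sample in profile.sample_ids:
            row = profile.counts.loc[sample]
            total = row.sum()
            for sid, n in row.items():
                if n == 0:
                    continue
                pct = 100.0 * n / total if total else 0.0
                fh.write(f"{sample}.fastq\t{pct:.6f}\t{int(n)}\t{sid}\t"
                         f"{names.get(sid, sid)}\n")


# ---------------------------------------------------------------------------
# ensemble aggregation, normalisation, QC, deduplication
# ---------------------------------------------------------------------------

def aggregate_profiles(
    profiles: list[TaxProfile] | dict,
    configuration: ProfilingConfiguration,
) -> TaxProfile:
    """Unweighted arithmetic mean of counts over the selected classifiers.

    Singleton subsets return that classifier's profile unchanged. All
    profiles must share sample ids and species columns.
    """
    if isinstance(profiles, dict):
        by_tag = {k: v for k, v in profiles.items()}
    else:
        by_tag = {}
        for p in profiles:
            for tag in p.classifiers:
                by_tag[tag] = p
    missing = configuration.classifier_subset - set(by_tag)
    if missing:
        raise ValueError(f"configuration needs classifiers {sorted(missing)}")
    selected = [by_tag[t] for t in sorted(configuration.classifier_subset)]
    ref = selected[0]
    for p in selected[1:]:
        if not ref.sample_ids.equals(p.sample_ids):
            raise ValueError("sample-id mismatch across classifier profiles")
        if not ref.species_ids.equals(p.species_ids):
            raise ValueError("species mismatch across classifier profiles")
    if len(selected) == 1:
        return ref
    mean = sum(p.counts.to_numpy(dtype=float) for p in selected) / len(selected)
    df = pd.DataFrame(mean, index=ref.sample_ids, columns=ref.species_ids)
    return TaxProfile(df, configuration.classifier_subset)


def normalize_abundance(profile: TaxProfile,
                        catalog: ReferenceCatalog) -> AbundanceMatrix:
    """Genome-size and depth normalisation: a_ij = (c_ij/L_j) / Σ_k c_ik/L_k.

    Dividing by genome length converts read counts to genome-copy
    proportions (long genomes attract proportionally more reads); the row
    closure removes sequencing-depth differences.
    """
    lengths = catalog.genome_lengths(profile.species_ids)
    per_copy = profile.counts.to_numpy(dtype=float) / lengths[None, :]
    totals = per_copy.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = profile.sample_ids[zero].tolist()
        raise ValueError(f"samples with all-zero counts: {bad[:5]}")
    ab = per_copy / totals[:, None]
    return AbundanceMatrix(
        pd.DataFrame(ab, index=profile.sample_ids, columns=profile.species_ids)
    )


def qc_filter_samples(read_counts, min_reads: int = MIN_READS_QC):
    """Drop samples with fewer than ``min_reads`` post-QC reads.

    Returns (retained sample ids, exclusion report DataFrame).
    """
    counts = pd.Series(read_counts)
    if (counts < 0).any():
        raise ValueError("negative read counts")
    keep = counts >= min_reads
    retained = counts.index[keep].tolist()
    report = pd.DataFrame(
        {"sample_id": counts.index[~keep], "reads": counts[~keep].to_numpy()}
    ).reset_index(drop=True)
    report["reason"] = f"<{min_reads} reads"
    return retained, report


def deduplicate_samples(abundance: AbundanceMatrix,
                        cohort: pd.DataFrame) -> AbundanceMatrix:
    """Collapse to one abundance row per patient.

    A patient with two samples on different days keeps the sample closest
    to transplant (day 0); two samples taken the same day are merged by the
    element-wise mean of their normalised abundances. The output is indexed
    by patient id.
    """
    meta = cohort.set_index("sample_id")
    missing = set(abundance.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from cohort: {sorted(missing)[:5]}")
    meta = meta.loc[abundance.sample_ids]

    rows = {}
    for patient, grp in meta.groupby("patient_id", sort=True):
        sample_ids = grp.index.tolist()
        if len(sample_ids) == 1:
            rows[patient] = abundance.values.loc[sample_ids[0]].to_numpy()
        elif len(sample_ids) == 2:
            days = grp["sampling_day"].to_numpy()
            if days[0] == days[1]:
                merged = abundance.values.loc[sample_ids].mean(axis=0).to_numpy()
                rows[patient] = merged / merged.sum()
            else:
                keep = sample_ids[int(np.argmax(days))]  # days <= 0
                rows[patient] = abundance.values.loc[keep].to_numpy()
        else:
            raise ValueError(
                f"patient {patient} has {len(sample_ids)} samples; at most "
                "two are supported")
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=abundance.species_ids)
    out.index.name = "patient_id"
    return AbundanceMatrix(out.sort_index())
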