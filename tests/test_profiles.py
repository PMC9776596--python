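import numpy as np
import pandas as pd
import pytest

from gutmwas.containers import CLASSIFIERS, AbundanceMatrix, TaxProfile
from gutmwas.profiles import (MIN_READS_QC, ParseError,
                              ProfilingConfiguration, aggregate_profiles,
                              deduplicate_samples, enumerate_configurations,
                              normalize_abundance, qc_filter_samples,
                              read_classifier_table, write_kaiju_summary,
                              write_kraken2_report)
from gutmwas.synthetic import generate_catalog, generate_cohort


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

def test_enumerate_configurations_counts():
    configs = enumerate_configurations()
    assert len(configs) == 14
    subsets = {c.classifier_subset for c in configs}
    assert len(subsets) == 7
    labels = {c.label for c in configs}
    assert len(labels) == 14


def test_configuration_validation():
    with pytest.raises(ValueError, match="non-empty"):
        ProfilingConfiguration(frozenset())
    with pytest.raises(ValueError, match="unknown"):
        ProfilingConfiguration(frozenset({"NotAClassifier"}))
    with pytest.raises(ValueError, match="species_set"):
        ProfilingConfiguration(frozenset({"Kaiju"}), "partial")


# ---------------------------------------------------------------------------
# parsers (fed by the package's own writers, end to end)
# ---------------------------------------------------------------------------

@pytest.fixture()
def catalog():
    return generate_catalog(12, seed=2)


@pytest.fixture()
def counts(catalog, rng):
    mat = rng.integers(0, 500, size=(3, 12))
    df = pd.DataFrame(mat, index=["s1", "s2", "s3"],
                      columns=catalog.species_ids)
    return TaxProfile(df, frozenset({"Kraken2"}))


def test_canonical_round_trip(tmp_path, catalog, counts):
    counts.to_tsv(tmp_path / "c.tsv")
    res = read_classifier_table(tmp_path / "c.tsv", "canonical_tsv", catalog,
                                classifier="Kraken2")
    pd.testing.assert_frame_equal(
        res.profile.counts, counts.counts, check_names=False)
    assert res.n_dropped == 0


def test_kraken2_round_trip(tmp_path, catalog, counts):
    d = tmp_path / "reports"
    d.mkdir()
    for sid in counts.sample_ids:
        write_kraken2_report(counts.counts.loc[sid], catalog,
                             d / f"{sid}.txt", unclassified=100)
    res = read_classifier_table(d, "kraken2_report", catalog,
                                classifier="Kraken2")
    pd.testing.assert_frame_equal(
        res.profile.counts, counts.counts, check_names=False)


def test_kaiju_round_trip(tmp_path, catalog, counts):
    path = tmp_path / "kaiju.tsv"
    write_kaiju_summary(counts, catalog, path)
    res = read_classifier_table(path, "kaiju_summary", catalog,
                                classifier="Kaiju")
    pd.testing.assert_frame_equal(
        res.profile.counts, counts.counts, check_names=False)


def test_kraken2_parse_error_names_line(tmp_path, catalog):
    path = tmp_path / "bad.txt"
    path.write_text("10.0\t5\t5\tS\tX1\tname\nbroken line\n")
    with pytest.raises(ParseError, match="line 2"):
        read_classifier_table(path, "kraken2_report", catalog)


def test_kraken2_non_integer_count(tmp_path, catalog):
    path = tmp_path / "bad.txt"
    path.write_text("10.0\t5\tfive\tS\tX1\tname\n")
    with pytest.raises(ParseError, match="non-integer"):
        read_classifier_table(path, "kraken2_report", catalog)


def test_kaiju_missing_columns(tmp_path, catalog):
    path = tmp_path / "bad.tsv"
    path.write_text("a\tb\tc\n1\t2\t3\n")
    with pytest.raises(ParseError, match="missing kaiju columns"):
        read_classifier_table(path, "kaiju_summary", catalog)


def test_unknown_dialect(tmp_path, catalog):
    with pytest.raises(ValueError, match="dialect"):
        read_classifier_table(tmp_path / "x.tsv", "metaphlan", catalog)


def test_off_catalog_taxa_dropped(tmp_path, catalog, counts):
    sid = counts.sample_ids[0]
    row = counts.counts.loc[sid].copy()
    path = tmp_path / f"{sid}.txt"
    write_kraken2_report(row, catalog, path)
    with open(path, "a") as fh:
        fh.write("1.00\t7\t7\tS\tNOT_A_SPECIES\t    mystery\n")
    res = read_classifier_table(path, "kraken2_report", catalog)
    assert res.n_dropped == 1
    assert res.dropped_ids == ("NOT_A_SPECIES",)
    np.testing.assert_array_equal(
        res.profile.counts.loc[sid].to_numpy(), row.to_numpy())


def test_gzip_supported(tmp_path, catalog, counts):
    import gzip

    sid = counts.sample_ids[0]
    plain = tmp_path / "r.txt"
    write_kraken2_report(counts.counts.loc[sid], catalog, plain)
    gz = tmp_path / "r.txt.gz"
    gz.write_bytes(gzip.compress(plain.read_bytes()))
    res = read_classifier_table(gz, "kraken2_report", catalog)
    np.testing.assert_array_equal(
        res.profile.counts.iloc[0].to_numpy(),
        counts.counts.loc[sid].to_numpy())


# ---------------------------------------------------------------------------
# aggregation / normalisation / QC / dedup
# ---------------------------------------------------------------------------

def test_aggregate_mean_of_two(catalog, rng):
    a = rng.integers(0, 100, size=(2, 12))
    b = rng.integers(0, 100, size=(2, 12))
    cols = catalog.species_ids
    p1 = TaxProfile(pd.DataFrame(a, index=["s1", "s2"], columns=cols),
                    frozenset({"Kaiju"}))
    p2 = TaxProfile(pd.DataFrame(b, index=["s1", "s2"], columns=cols),
                    frozenset({"Kraken2"}))
    config = ProfilingConfiguration(frozenset({"Kaiju", "Kraken2"}))
    merged = aggregate_profiles({"Kaiju": p1, "Kraken2": p2}, config)
    np.testing.assert_allclose(merged.counts.to_numpy(), (a + b) / 2.0)


def test_aggregate_singleton_identity(small_study):
    config = ProfilingConfiguration(frozenset({"Kaiju"}))
    merged = aggregate_profiles(small_study["profiles"], config)
    pd.testing.assert_frame_equal(merged.counts,
                                  small_study["profiles"]["Kaiju"].counts)


def test_aggregate_missing_classifier(small_study):
    config = ProfilingConfiguration(frozenset(CLASSIFIERS))
    partial = {k: v for k, v in small_study["profiles"].items()
               if k != "Kraken2"}
    with pytest.raises(ValueError, match="Kraken2"):
        aggregate_profiles(partial, config)


def test_normalize_abundance_formula(catalog, counts):
    ab = normalize_abundance(counts, catalog)
    lengths = catalog.genome_lengths(counts.species_ids)
    manual = counts.counts.to_numpy() / lengths
    manual = manual / manual.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(ab.to_numpy(), manual, atol=1e-15)
    np.testing.assert_allclose(ab.to_numpy().sum(axis=1), 1.0)


def test_normalize_rejects_zero_sample(catalog, counts):
    df = counts.counts.copy()
    df.iloc[0] = 0
    with pytest.raises(ValueError, match="all-zero"):
        normalize_abundance(TaxProfile(df), catalog)


def test_qc_filter_strictly_less_than():
    reads = pd.Series({"a": MIN_READS_QC, "b": MIN_READS_QC - 1,
                       "c": 2 * MIN_READS_QC})
    retained, report = qc_filter_samples(reads)
    assert set(retained) == {"a", "c"}
    assert report["sample_id"].tolist() == ["b"]
    with pytest.raises(ValueError, match="negative"):
        qc_filter_samples(pd.Series({"a": -1}))


def _dedup_setup(rng):
    cohort = generate_cohort(10, n_duplicate_patients=4, seed=3)
    n = len(cohort)
    x = rng.dirichlet(np.ones(6), size=n)
    ab = AbundanceMatrix(pd.DataFrame(
        x, index=cohort["sample_id"].to_numpy(),
        columns=[f"sp{i}" for i in range(6)]))
    return cohort, ab


def test_deduplicate_counts_and_rules(rng):
    cohort, ab = _dedup_setup(rng)
    out = deduplicate_samples(ab, cohort)
    assert len(out.sample_ids) == 10
    assert list(out.sample_ids) == sorted(cohort["patient_id"].unique())
    for patient, grp in cohort.groupby("patient_id"):
        if len(grp) == 1:
            expect = ab.values.loc[grp["sample_id"].iloc[0]].to_numpy()
        else:
            days = grp["sampling_day"].to_numpy()
            if days[0] == days[1]:
                merged = ab.values.loc[grp["sample_id"]].mean(axis=0)
                expect = (merged / merged.sum()).to_numpy()
            else:
                keep = grp["sample_id"].iloc[int(np.argmax(days))]
                expect = ab.values.loc[keep].to_numpy()
        np.testing.assert_allclose(out.values.loc[patient].to_numpy(),
                                   expect, atol=1e-12)


def test_deduplicate_rejects_three_samples(rng):
    cohort, ab = _dedup_setup(rng)
    dup_pat = cohort["patient_id"].value_counts().idxmax()
    extra = cohort[cohort["patient_id"] == dup_pat].iloc[[0]].copy()
    extra["sample_id"] = "S9999"
    extra["sampling_day"] = -1
    cohort3 = pd.concat([cohort, extra], ignore_index=True)
    x = np.vstack([ab.to_numpy(), ab.to_numpy()[[0]]])
    ab3 = AbundanceMatrix(pd.DataFrame(
        x, index=list(ab.sample_ids) + ["S9999"], columns=ab.species_ids))
    with pytest.raises(ValueError, match="samples"):
        deduplicate_samples(ab3, cohort3)


def test_deduplicate_rejects_unknown_sample(rng):
    cohort, ab = _dedup_setup(rng)
    bad = AbundanceMatrix(ab.values.rename(index={ab.sample_ids[0]: "SX"}))
    with pytest.raises(ValueError, match="missing from cohort"):
        deduplicate_samples(bad, cohort)
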