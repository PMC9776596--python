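"""Synthetic cohort, catalog and classifier-output generator.

The patient-level data behind the pre-transplant aGvHD association study is
access-restricted, so every downstream stage of this package is exercised on
synthetic data that emulates its published shape: a catalog of ~2505 gut
bacterial species, ~172 patients contributing ~181 stool samples (nine
patients with two samples each), roughly 23% aGvHD prevalence, and three
taxonomic classifiers whose classified-read fractions centre near 21%, 57%
and 74%.

Ground truth for recovery tests is carried by :class:`PlantedTruth`:
case-enriched/depleted species with known log2 fold-changes, an optional
shrinkage of case compositions toward their centroid (lowering within-group
beta diversity in the case group), and per-classifier detection rates and
species-level biases.

Latent compositions are log-normal (heavy-tailed rank-abundance curve)
closed to the simplex; the read simulator weights species by genome length,
so genome-size normalisation downstream is measurably consequential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CLASSIFIERS,
    CLINICAL_LEVELS,
    COHORT_COLUMNS,
    ReferenceCatalog,
    TaxProfile,
    make_display_name,
    validate_cohort,
)

# default classified-read fractions (mean of classified % per classifier)
DEFAULT_CLASSIFIER_RATES = {"DeepMicrobes": 0.21, "Kaiju": 0.57, "Kraken2": 0.74}

# base-abundance log-scale, spread of the log-normal rank-abundance curve
BASE_LOG_SIGMA = 2.0
# per-sample log-scale noise around each species' base abundance
WITHIN_LOG_SIGMA = 1.0
# spread of per-classifier, per-species multiplicative detection bias
CLASSIFIER_BIAS_SIGMA = 0.3

_GENERA = [
    "Prevotella", "Bacteroides", "Eggerthella", "Parabacteroides",
    "Peptoniphilus", "Fusobacterium", "Eubacterium", "Bacillus",
    "Clostridium", "Faecalibacterium", "Ruminococcus", "Blautia",
    "Roseburia", "Akkermansia", "Alistipes", "Dorea", "Lactobacillus",
    "Streptococcus", "Bifidobacterium", "Veillonella",
]


def generate_catalog(n_species: int, seed: int) -> ReferenceCatalog:
    """Draw a reference catalog of ``n_species`` gut bacterial species.

    Genome lengths are log-uniform in [1, 15] Mbp. About 40% of entries are
    known only to genus level or above and carry UMGS-style metagenomic
    ids; the rest are named species with GCF-style assembly ids.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    lengths = np.exp(
        rng.uniform(np.log(1e6), np.log(15e6), size=n_species)
    ).astype(int)
    rows = []
    for i in range(n_species):
        higher_rank = rng.random() < 0.4
        genus = _GENERA[rng.integers(len(_GENERA))]
        if higher_rank:
            species_id = f"UMGS{i + 1:04d}"
            rank = str(rng.choice(list("gfocp"), p=[0.6, 0.2, 0.1, 0.05, 0.05]))
            name = genus
        else:
            species_id = f"GCF_{900000000 + i:09d}"
            rank = "s"
            name = f"{genus} sp{i + 1}"
        rows.append(
            {
                "species_id": species_id,
                "display_name": make_display_name(rank, name, species_id),
                "rank_initial": rank,
                "genome_length_bp": int(lengths[i]),
            }
        )
    return ReferenceCatalog(pd.DataFrame(rows))


def _draw_covariates(rng: np.random.Generator, outcome: int) -> dict:
    """Clinical covariates with a mild logistic dependence on the outcome."""
    shift = 0.35 if outcome == 1 else 0.0
    base_p = {
        "conditioning": 0.45,
        "cyclophosphamide": 0.30,
        "disease_group": 0.40,
        "dr_relationship": 0.55,
        "donor_sex": 0.40,
        "radiation_group": 0.35,
        "recipient_sex": 0.40,
        "transplant_source": 0.85,
    }
    row = {}
    for var, (base, alt) in CLINICAL_LEVELS.items():
        p = base_p[var]
        logit = np.log(p / (1 - p)) + shift
        p_alt = 1 / (1 + np.exp(-logit))
        row[var] = alt if rng.random() < p_alt else base
    age = float(np.clip(rng.normal(55 + 3 * outcome, 12), 18, 78))
    row["recipient_age"] = round(age, 1)
    row["karnofsky_d0"] = float(rng.choice([60, 70, 80, 90, 100],
                                           p=[0.05, 0.1, 0.25, 0.35, 0.25]))
    return row


def generate_cohort(
    n_patients: int,
    frac_case: float = 39 / 172,
    n_duplicate_patients: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a pre-transplant cohort table (one row per stool sample).

    Returns ``n_patients + n_duplicate_patients`` sample rows: the duplicate
    patients contribute two samples each with independently drawn sampling
    days in [-61, 0] (about a third of the pairs land on the same day, so
    both the closest-day and the same-day merge rules downstream get
    exercised). The case fraction applies at the patient level; Karnofsky
    performance score is missing for exactly two patients whenever the
    cohort has at least two patients.
    """
    if not 0 < frac_case < 1:
        raise ValueError("frac_case must be in (0, 1)")
    if n_duplicate_patients > n_patients:
        raise ValueError("more duplicate patients than patients")
    rng = np.random.default_rng(seed)

    n_cases = int(round(frac_case * n_patients))
    outcomes = np.zeros(n_patients, dtype=int)
    outcomes[rng.choice(n_patients, size=n_cases, replace=False)] = 1

    # duplicates stratified roughly 1/3 cases, like the published cohort
    n_dup_cases = min(int(round(n_duplicate_patients / 3)), int(outcomes.sum()))
    n_dup_ctrl = n_duplicate_patients - n_dup_cases
    case_idx = np.flatnonzero(outcomes == 1)
    ctrl_idx = np.flatnonzero(outcomes == 0)
    dup_set = set(rng.choice(case_idx, size=n_dup_cases, replace=False).tolist())
    dup_set |= set(rng.choice(ctrl_idx, size=min(n_dup_ctrl, len(ctrl_idx)),
                              replace=False).tolist())
    dup_list = sorted(dup_set)
    same_day = {
        p for p in rng.permutation(dup_list)[: int(round(len(dup_list) / 3))]
    }

    rows = []
    sample_no = 0
    for i in range(n_patients):
        outcome = int(outcomes[i])
        cov = _draw_covariates(rng, outcome)
        grade = int(rng.integers(2, 5)) if outcome == 1 else 0
        n_samp = 2 if i in dup_set else 1
        day0 = int(rng.integers(-61, 1))
        for s in range(n_samp):
            if s == 0:
                day = day0
            elif i in same_day:
                day = day0
            else:
                day = int(rng.integers(-61, 1))
                while day == day0:
                    day = int(rng.integers(-61, 1))
            sample_no += 1
            rows.append(
                {
                    "patient_id": f"P{i + 1:04d}",
                    "sample_id": f"S{sample_no:04d}",
                    "sampling_day": day,
                    "outcome": outcome,
                    "grade": grade,
                    **cov,
                }
            )
    cohort = pd.DataFrame(rows)[COHORT_COLUMNS]

    if n_patients >= 2:
        missing = rng.choice(n_patients, size=2, replace=False)
        miss_ids = {f"P{i + 1:04d}" for i in missing}
        cohort.loc[cohort["patient_id"].isin(miss_ids), "karnofsky_d0"] = np.nan
    return validate_cohort(cohort)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into synthetic compositions.

    ``enriched`` / ``depleted`` map species ids to positive log2
    fold-changes (depleted species are down in cases by their stated
    factor). ``similarity_shrinkage`` pulls case compositions toward the
    case centroid, lowering within-group beta diversity for cases.
    """

    enriched: dict = field(default_factory=dict)
    depleted: dict = field(default_factory=dict)
    similarity_shrinkage: float = 0.0
    classifier_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASSIFIER_RATES)
    )

    def __post_init__(self) -> None:
        overlap = set(self.enriched) & set(self.depleted)
        if overlap:
            raise ValueError(f"species both enriched and depleted: {overlap}")
        if not 0 <= self.similarity_shrinkage < 1:
            raise ValueError("similarity_shrinkage must be in [0, 1)")
        for rate in self.classifier_rates.values():
            if not 0 < rate <= 1:
                raise ValueError("classifier rates must be in (0, 1]")

    @property
    def planted_ids(self) -> list:
        return sorted(self.enriched) + sorted(self.depleted)


def plant_effects(
    catalog: ReferenceCatalog,
    n_enriched: int,
    n_depleted: int,
    log2_fc: float,
    seed: int,
    similarity_shrinkage: float = 0.0,
) -> PlantedTruth:
    """Pick random catalog species and assign them the given |log2 FC|."""
    rng = np.random.default_rng(seed)
    picks = rng.choice(
        catalog.species_ids.to_numpy(), size=n_enriched + n_depleted, replace=False
    )
    return PlantedTruth(
        enriched={s: log2_fc for s in picks[:n_enriched]},
        depleted={s: log2_fc for s in picks[n_enriched:]},
        similarity_shrinkage=similarity_shrinkage,
    )


def generate_compositions(
    catalog: ReferenceCatalog,
    cohort: pd.DataFrame,
    truth: PlantedTruth,
    seed: int,
) -> pd.DataFrame:
    """Latent per-sample species compositions (rows on the simplex).

    Species base abundances are log-normal(0, 2); per-sample values add
    log-normal(0, 1) noise. Planted species are re-seeded at a mid-range
    base abundance (median of the drawn base means plus one log unit) so
    they stay prevalent after finite-depth sequencing; their fold-change is
    applied multiplicatively to case rows before closure. Case rows are
    then shrunk toward the case centroid by ``truth.similarity_shrinkage``.
    """
    unknown = set(truth.planted_ids) - set(catalog.species_ids)
    if unknown:
        raise ValueError(f"planted species not in catalog: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    species = catalog.species_ids
    n_samples, n_species = len(cohort), len(species)

    base = rng.normal(0.0, BASE_LOG_SIGMA, size=n_species)
    if truth.planted_ids:
        pos = species.get_indexer(truth.planted_ids)
        base[pos] = np.median(base) + 1.0

    log_x = base[None, :] + rng.normal(0.0, WITHIN_LOG_SIGMA,
                                       size=(n_samples, n_species))
    x = np.exp(log_x)

    is_case = (cohort["outcome"].to_numpy() == 1)
    for sid, lfc in truth.enriched.items():
        x[is_case, species.get_loc(sid)] *= 2.0 ** lfc
    for sid, lfc in truth.depleted.items():
        x[is_case, species.get_loc(sid)] /= 2.0 ** lfc

    x /= x.sum(axis=1, keepdims=True)
    if truth.similarity_shrinkage > 0 and is_case.sum() >= 2:
        centroid = x[is_case].mean(axis=0)
        s = truth.similarity_shrinkage
        x[is_case] = (1 - s) * x[is_case] + s * centroid
        x[is_case] /= x[is_case].sum(axis=1, keepdims=True)

    return pd.DataFrame(x, index=cohort["sample_id"].to_numpy(), columns=species)


def default_classifier_bias(
    catalog: ReferenceCatalog, classifier_name: str, seed: int
) -> np.ndarray:
    """Per-species multiplicative detection bias, fixed per classifier.

    Log-normal(0, 0.3) so ensemble averaging across classifiers is
    non-degenerate. Seeded from (seed, classifier name) so each classifier
    gets its own reproducible bias vector.
    """
    tag = CLASSIFIERS.index(classifier_name)
    rng = np.random.default_rng((seed, tag))
    return np.exp(rng.normal(0.0, CLASSIFIER_BIAS_SIGMA, size=len(catalog)))


def simulate_classifier_counts(
    compositions: pd.DataFrame,
    catalog: ReferenceCatalog,
    classifier_name: str,
    rate: float,
    bias,
    depth: int,
    seed: int,
) -> TaxProfile:
    """Simulate one classifier's species count table.

    Per sample, the number of classified reads is Binomial(depth, rate);
    those reads are distributed multinomially over species with weights
    proportional to composition × genome length × classifier bias. The
    genome-length weighting means raw counts over-represent large genomes,
    which the downstream normalisation must undo.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    species = compositions.columns
    lengths = catalog.genome_lengths(species)
    bias = np.broadcast_to(np.asarray(bias, dtype=float), (len(species),))

    weights = compositions.to_numpy() * lengths[None, :] * bias[None, :]
    weights /= weights.sum(axis=1, keepdims=True)
    classified = rng.binomial(depth, rate, size=len(compositions))
    counts = np.empty_like(weights, dtype=np.int64)
    for i in range(len(compositions)):
        counts[i] = rng.multinomial(classified[i], weights[i])
    df = pd.DataFrame(counts, index=compositions.index, columns=species)
    return TaxProfile(df, frozenset({classifier_name}))


def simulate_study(
    n_patients: int = 172,
    n_species: int = 2505,
    frac_case: float = 39 / 172,
    n_duplicate_patients: int = 9,
    truth: PlantedTruth | None = None,
    depth: int = 200_000,
    seed: int = 0,
) -> dict:
    """One-call end-to-end simulation of the study's raw inputs.

    Returns a dict with the catalog, cohort, latent compositions, the
    planted truth, and one :class:`TaxProfile` per classifier.
    """
    catalog = generate_catalog(n_species, seed)
    cohort = generate_cohort(n_patients, frac_case, n_duplicate_patients, seed + 1)
    if truth is None:
        truth = PlantedTruth()
    comps = generate_compositions(catalog, cohort, truth, seed + 2)
    profiles = {}
    for k, name in enumerate(CLASSIFIERS):
        rate = truth.classifier_rates.get(name, DEFAULT_CLASSIFIER_RATES[name])
        bias = default_classifier_bias(catalog, name, seed + 3)
        profiles[name] = simulate_classifier_counts(
            comps, catalog, name, rate, bias, depth, seed + 4 + k
        )
    return {
        "catalog": catalog,
        "cohort": cohort,
        "compositions": comps,
        "truth": truth,
        "profiles": profiles,
    }
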