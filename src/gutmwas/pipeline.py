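"""End-to-end pipeline orchestration: config, stages, manifest, logging.

The pipeline runs simulate/ingest → ensemble (QC, aggregation,
normalisation, per-patient deduplication) → permutation filtering →
diversity → dissimilarity inference (with the oversampling re-analysis) →
per-species screens → feature ranking → elastic-net benchmark → consensus.
Every stage writes tidy TSVs into the run directory; a JSON manifest
records the seed, configuration hash and library versions so any output can
be reproduced exactly. A stage failure aborts the run naming the stage.

Configuration is a single declarative YAML file; anything omitted falls
back to the defaults below, which mirror the study conditions (172
patients, nine with duplicate samples, 2505-species catalog, 39/172 case
fraction, 10,000 permutations for the distance-based tests).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (conditional_mi, fit_clinical_logistic, indval_g,
                          pointbiserial_rg, sign_association, spearman_assoc,
                          wilcoxon_screen)
from .benchmark import benchmark_configurations, crossval_elastic_net
from .consensus import consensus_species
from .containers import CLASSIFIERS, AbundanceMatrix, ReferenceCatalog
from .dissimilarity import (DistanceMatrix, anosim, bray_curtis,
                            dispersion_test, mwmote, permanova, rclr_distance)
from .diversity import (BETA_INDICES, alpha_diversity_table,
                        compare_group_alpha, compare_group_beta,
                        group_equalized_beta_test, pairwise_beta)
from .perfect import perfect_reduce
from .profiles import (ProfilingConfiguration, aggregate_profiles,
                       deduplicate_samples, normalize_abundance,
                       qc_filter_samples, read_classifier_table)
from .ranking import rank_features
from .synthetic import PlantedTruth, plant_effects, simulate_study

logger = logging.getLogger("gutmwas.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "mwas_run",
    "mode": "synthetic",          # or "real": parse classifier files
    "input": {},                  # real mode: {classifier: {path, dialect}}
    "synthetic": {
        "n_patients": 172,
        "n_species": 2505,
        "frac_case": 39 / 172,
        "n_duplicate_patients": 9,
        "depth": 2_000_000,
        "n_enriched": 5,
        "n_depleted": 5,
        "log2_fc": 2.0,
        "shrinkage": 0.3,
    },
    "qc": {"min_reads": 1_000_000},
    "ensemble": {"classifiers": list(CLASSIFIERS)},
    "perfect": {"alpha": 0.10, "n_perm": 99},
    "diversity": {"n_subsets": 1000, "alpha": 0.05},
    "distance": {"methods": ["robust_aitchison", "bray_curtis"]},
    "permanova": {
        "n_perm": 10_000,
        "terms": ["outcome", "disease_group", "recipient_age_ge60",
                  "recipient_sex"],
        "interactions": True,
    },
    "mwmote": {"n_synthetic": None, "k1": 5, "k2": 3, "k3": None,
               "target_imbalance": 0.9},
    "screens": {"n_perm": 10_000, "min_B": 0.2, "min_A": 0.5,
                "confounder": "disease_group"},
    "ranking": {"K": 10, "m": None, "bins": 4},
    "bench": {"enabled": True, "repeats": 2, "folds": 5,
              "l1_ratios": [0.2, 0.8], "Cs": [0.1, 1.0],
              "inner_selection": False},
    "consensus": {"alpha": 0.05, "top_n": 20},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _labels_for(abundance: AbundanceMatrix, cohort: pd.DataFrame) -> np.ndarray:
    by_patient = cohort.drop_duplicates("patient_id").set_index("patient_id")
    return by_patient.loc[abundance.sample_ids, "outcome"].to_numpy(dtype=int)


def _design_for(abundance: AbundanceMatrix, cohort: pd.DataFrame) -> pd.DataFrame:
    by_patient = cohort.drop_duplicates("patient_id").set_index("patient_id")
    d = by_patient.loc[abundance.sample_ids].copy()
    d["recipient_age_ge60"] = (d["recipient_age"] >= 60).astype(int)
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> None:
    s = cfg["synthetic"]
    truth_seed = cfg["seed"] + 17
    # plant effects on the same catalog the study draw will use
    from .synthetic import generate_catalog

    catalog_probe = generate_catalog(s["n_species"], cfg["seed"])
    truth = plant_effects(
        catalog_probe, s["n_enriched"], s["n_depleted"], s["log2_fc"],
        truth_seed, similarity_shrinkage=s["shrinkage"])
    study = simulate_study(
        n_patients=s["n_patients"], n_species=s["n_species"],
        frac_case=s["frac_case"],
        n_duplicate_patients=s["n_duplicate_patients"],
        truth=truth, depth=s["depth"], seed=cfg["seed"])
    study["catalog"].to_tsv(outdir / "catalog.tsv")
    study["cohort"].to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    for name, profile in study["profiles"].items():
        profile.to_tsv(outdir / f"counts_{name}.tsv")
    with open(outdir / "planted_truth.json", "w") as fh:
        json.dump({"enriched": truth.enriched, "depleted": truth.depleted,
                   "similarity_shrinkage": truth.similarity_shrinkage},
                  fh, indent=1)


def stage_ingest(cfg: dict, outdir: Path) -> None:
    catalog = ReferenceCatalog.from_tsv(outdir / "catalog.tsv") \
        if (outdir / "catalog.tsv").exists() else None
    if catalog is None:
        raise FileNotFoundError("catalog.tsv missing: provide a catalog "
                                "before ingesting classifier outputs")
    for name, spec_ in cfg["input"].items():
        path = Path(spec_["path"])
        if not path.exists():
            raise FileNotFoundError(f"classifier file missing: {path}")
        result = read_classifier_table(path, spec_["dialect"], catalog,
                                       classifier=name)
        result.profile.to_tsv(outdir / f"counts_{name}.tsv")
        logger.info("ingested %s (%d taxa dropped)", name, result.n_dropped)


def _load_profiles(cfg: dict, outdir: Path):
    catalog = ReferenceCatalog.from_tsv(outdir / "catalog.tsv")
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    profiles = {}
    for name in cfg["ensemble"]["classifiers"]:
        result = read_classifier_table(outdir / f"counts_{name}.tsv",
                                       "canonical_tsv", catalog,
                                       classifier=name)
        profiles[name] = result.profile
    return catalog, cohort, profiles


def stage_ensemble(cfg: dict, outdir: Path) -> None:
    catalog, cohort, profiles = _load_profiles(cfg, outdir)
    config = ProfilingConfiguration(
        frozenset(cfg["ensemble"]["classifiers"]), "complete")
    merged = aggregate_profiles(profiles, config)

    # QC on total (pre-classification) reads; in synthetic mode the
    # sequencing depth is uniform so this is a pass-through
    depth = cfg["synthetic"]["depth"] if cfg["mode"] == "synthetic" else None
    if depth is not None:
        read_counts = pd.Series(depth, index=merged.sample_ids)
        retained, report = qc_filter_samples(read_counts,
                                             cfg["qc"]["min_reads"])
        report.to_csv(outdir / "qc_exclusions.tsv", sep="\t", index=False)
        if not len(retained):
            raise ValueError("QC excluded every sample; check qc.min_reads")
        merged = type(merged)(merged.counts.loc[retained], merged.classifiers)
        cohort = cohort[cohort["sample_id"].isin(retained)]

    abundance = normalize_abundance(merged, catalog)
    abundance.to_tsv(outdir / "abundance_samples.tsv")
    patients = deduplicate_samples(abundance, cohort)
    patients.to_tsv(outdir / "abundance_patients.tsv")


def _load_patient_abundance(outdir: Path, reduced: bool = False):
    name = ("abundance_patients_reduced.tsv" if reduced
            else "abundance_patients.tsv")
    df = pd.read_csv(outdir / name, sep="\t", index_col=0)
    return AbundanceMatrix(df)


def stage_reduce(cfg: dict, outdir: Path) -> None:
    abundance = _load_patient_abundance(outdir)
    result = perfect_reduce(abundance, alpha=cfg["perfect"]["alpha"],
                            n_perm=cfg["perfect"]["n_perm"],
                            seed=cfg["seed"] + 29)
    pd.Series(result.retained, name="species_id").to_csv(
        outdir / "reduced_species.tsv", sep="\t", index=False)
    reduced = AbundanceMatrix(
        abundance.values[result.retained].div(
            abundance.values[result.retained].sum(axis=1), axis=0))
    reduced.to_tsv(outdir / "abundance_patients_reduced.tsv")
    logger.info("permutation filter retained %d/%d species (%.1f%%)",
                len(result.retained), len(result.order),
                100 * result.retained_fraction)


def stage_diversity(cfg: dict, outdir: Path) -> None:
    abundance = _load_patient_abundance(outdir, reduced=True)
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    labels = _labels_for(abundance, cohort)

    alpha_tab = alpha_diversity_table(abundance.values)
    alpha_tab.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    compare_group_alpha(alpha_tab, labels).to_csv(
        outdir / "alpha_comparison.tsv", sep="\t", index=False)

    distances = {idx: pairwise_beta(abundance.values, idx)
                 for idx in BETA_INDICES}
    compare_group_beta(distances, labels).to_csv(
        outdir / "beta_comparison.tsv", sep="\t", index=False)
    group_equalized_beta_test(
        distances, labels, n_subsets=cfg["diversity"]["n_subsets"],
        seed=cfg["seed"] + 31, alpha=cfg["diversity"]["alpha"]).to_csv(
        outdir / "beta_group_equalized.tsv", sep="\t", index=False)


def stage_dissim(cfg: dict, outdir: Path) -> None:
    abundance = _load_patient_abundance(outdir, reduced=True)
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    labels = _labels_for(abundance, cohort)
    design = _design_for(abundance, cohort)
    terms = cfg["permanova"]["terms"]
    n_perm = cfg["permanova"]["n_perm"]

    matrices = {}
    if "robust_aitchison" in cfg["distance"]["methods"]:
        matrices["robust_aitchison"] = rclr_distance(abundance)
    if "bray_curtis" in cfg["distance"]["methods"]:
        matrices["bray_curtis"] = bray_curtis(abundance)

    anosim_rows, disp_rows = [], []
    for name, D in matrices.items():
        tab = permanova(D, design, terms, n_perm=n_perm,
                        seed=cfg["seed"] + 37)
        tab.to_csv(outdir / f"permanova_{name}.tsv", sep="\t")
        r, p = anosim(D, labels, n_perm=n_perm, seed=cfg["seed"] + 41)
        anosim_rows.append({"distance": name, "R": r, "p": p,
                            "design": "unbalanced"})
        per_group, f, dp = dispersion_test(D, labels,
                                           n_perm=min(n_perm, 999),
                                           seed=cfg["seed"] + 43)
        disp_rows.append({"distance": name, "F": f, "p": dp,
                          **{f"dispersion_{g}": v
                             for g, v in per_group.items()}})

    # balanced re-analysis on the robust Aitchison path
    if "robust_aitchison" in matrices:
        mw = cfg["mwmote"]
        n_min = int((labels == 1).sum())
        n_maj = int((labels == 0).sum())
        n_syn = mw["n_synthetic"]
        if n_syn is None:
            n_syn = max(0, int(round(mw["target_imbalance"] * n_maj)) - n_min)
        X_aug, y_aug = mwmote(abundance, labels, n_syn, k1=mw["k1"],
                              k2=mw["k2"], k3=mw["k3"],
                              seed=cfg["seed"] + 47)
        ids = list(abundance.sample_ids) + [f"synthetic_{i}"
                                            for i in range(n_syn)]
        D_aug = rclr_distance(pd.DataFrame(X_aug, index=ids))
        design_aug = pd.concat(
            [design,
             design[labels == 1].sample(n=n_syn, replace=True,
                                        random_state=cfg["seed"] + 53)],
            ignore_index=True)
        tab = permanova(D_aug, design_aug, terms, n_perm=n_perm,
                        seed=cfg["seed"] + 59)
        tab.to_csv(outdir / "permanova_robust_aitchison_balanced.tsv",
                   sep="\t")
        r, p = anosim(D_aug, y_aug, n_perm=n_perm, seed=cfg["seed"] + 61)
        anosim_rows.append({"distance": "robust_aitchison", "R": r, "p": p,
                            "design": "mwmote_balanced"})
        if cfg["permanova"]["interactions"]:
            inter_tabs = []
            for other in terms[1:]:
                t2 = permanova(D_aug, design_aug,
                               [terms[0], other, f"{terms[0]}:{other}"],
                               n_perm=n_perm, seed=cfg["seed"] + 67)
                t2 = t2.reset_index()
                t2["model"] = f"{terms[0]}x{other}"
                inter_tabs.append(t2)
            pd.concat(inter_tabs, ignore_index=True).to_csv(
                outdir / "permanova_interactions_balanced.tsv", sep="\t",
                index=False)

    pd.DataFrame(anosim_rows).to_csv(outdir / "anosim.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(disp_rows).to_csv(outdir / "dispersion.tsv", sep="\t",
                                   index=False)


def stage_screen(cfg: dict, outdir: Path) -> None:
    abundance = _load_patient_abundance(outdir, reduced=True)
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    labels = _labels_for(abundance, cohort)
    design = _design_for(abundance, cohort)
    sc = cfg["screens"]
    X = abundance.values

    wilcoxon_screen(X, labels).to_csv(outdir / "screen_wilcoxon.tsv",
                                      sep="\t", index=False)
    indval_g(X, labels, min_B=sc["min_B"], min_A=sc["min_A"],
             n_perm=sc["n_perm"], seed=cfg["seed"] + 71).to_csv(
        outdir / "screen_indval.tsv", sep="\t", index=False)
    pointbiserial_rg(X, labels, n_perm=sc["n_perm"],
                     seed=cfg["seed"] + 73).to_csv(
        outdir / "screen_rg.tsv", sep="\t", index=False)
    sign_association(X, labels, n_perm=sc["n_perm"],
                     seed=cfg["seed"] + 79).to_csv(
        outdir / "screen_signassoc.tsv", sep="\t", index=False)
    conditional_mi(X, labels, design[sc["confounder"]].to_numpy()).to_csv(
        outdir / "screen_cmi.tsv", sep="\t", index=False)
    spearman_assoc(X, labels,
                   covariate=design[sc["confounder"]].to_numpy()).to_csv(
        outdir / "screen_spearman.tsv", sep="\t", index=False)

    fit = fit_clinical_logistic(cohort, mode="multivariable")
    tab = fit["table"].copy()
    tab.attrs = {}
    tab.to_csv(outdir / "clinical_logistic.tsv", sep="\t")
    with open(outdir / "clinical_logistic_fit.json", "w") as fh:
        json.dump({k: fit[k] for k in ("aic", "bic", "pseudo_r2_mcfadden",
                                       "pseudo_r2_cragg_uhler")}, fh,
                  indent=1)


def stage_rank(cfg: dict, outdir: Path) -> None:
    abundance = _load_patient_abundance(outdir, reduced=True)
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    labels = _labels_for(abundance, cohort)
    r = cfg["ranking"]
    table = rank_features(abundance.values, labels, K=r["K"], m=r["m"],
                          bins=r["bins"], seed=cfg["seed"] + 83)
    table.to_csv(outdir / "rank_table.tsv", sep="\t")


def stage_bench(cfg: dict, outdir: Path) -> None:
    if not cfg["bench"]["enabled"]:
        logger.info("benchmark disabled by config")
        return
    catalog, cohort, profiles = _load_profiles(cfg, outdir)
    # one representative sample per patient so CV folds never split a patient
    reps = (cohort.sort_values(["sampling_day", "sample_id"],
                               ascending=[False, True])
            .drop_duplicates("patient_id"))
    keep = reps["sample_id"].tolist()
    profiles = {name: type(p)(p.counts.loc[keep], p.classifiers)
                for name, p in profiles.items()}
    labels = reps.set_index("sample_id").loc[keep, "outcome"].to_numpy()
    b = cfg["bench"]
    table = benchmark_configurations(
        profiles, catalog, labels, seed=cfg["seed"] + 89,
        repeats=b["repeats"], folds=b["folds"],
        perfect_alpha=cfg["perfect"]["alpha"],
        perfect_n_perm=cfg["perfect"]["n_perm"],
        l1_ratios=tuple(b["l1_ratios"]), Cs=tuple(b["Cs"]))
    table.to_csv(outdir / "benchmark.tsv", sep="\t", index=False)


def stage_consensus(cfg: dict, outdir: Path) -> None:
    indicator = pd.concat([
        pd.read_csv(outdir / "screen_indval.tsv", sep="\t"),
        pd.read_csv(outdir / "screen_rg.tsv", sep="\t"),
        pd.read_csv(outdir / "screen_signassoc.tsv", sep="\t"),
    ], ignore_index=True)
    wilcoxon = pd.read_csv(outdir / "screen_wilcoxon.tsv", sep="\t")
    ranks = pd.read_csv(outdir / "rank_table.tsv", sep="\t",
                        index_col="species_id")
    call = consensus_species(indicator, wilcoxon, ranks,
                             alpha=cfg["consensus"]["alpha"],
                             top_n=cfg["consensus"]["top_n"])
    call.to_csv(outdir / "consensus_species.tsv", sep="\t", index=False)
    logger.info("consensus species: %d", len(call))


STAGES = [
    ("simulate", stage_simulate),
    ("ensemble", stage_ensemble),
    ("reduce", stage_reduce),
    ("diversity", stage_diversity),
    ("dissim", stage_dissim),
    ("screen", stage_screen),
    ("rank", stage_rank),
    ("bench", stage_bench),
    ("consensus", stage_consensus),
]


def run_pipeline(config_path=None, overrides: dict | None = None) -> Path:
    """Run every stage; returns the output directory."""
    cfg = load_config(config_path, overrides)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s "
                                           "%(levelname)s %(message)s"))
    root = logging.getLogger("gutmwas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        stages = list(STAGES)
        if cfg["mode"] == "real":
            stages[0] = ("ingest", stage_ingest)
        for name, fn in stages:
            t0 = time.time()
            try:
                fn(cfg, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
        _write_manifest(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _write_manifest(cfg: dict, outdir: Path) -> None:
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
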