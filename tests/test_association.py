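import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, pointbiserialr, spearmanr

from gutmwas.association import (CLINICAL_PREDICTORS, conditional_mi,
                                 fit_clinical_logistic, indval_g,
                                 pointbiserial_rg, prepare_clinical_design,
                                 sign_association, spearman_assoc,
                                 top_by_abs_rho, wilcoxon_screen)
from gutmwas.containers import ASSOCIATION_COLUMNS
from gutmwas.synthetic import generate_cohort


def _signal_data(rng, n=40, s=12):
    labels = np.array([1] * 15 + [0] * (n - 15))
    X = rng.lognormal(0, 1, size=(n, s))
    X[labels == 1, 0] *= 8.0   # enriched in cases
    X[labels == 1, 1] /= 8.0   # depleted in cases
    cols = [f"sp{i}" for i in range(s)]
    return pd.DataFrame(X, columns=cols), labels


# ---------------------------------------------------------------------------
# Wilcoxon screen
# ---------------------------------------------------------------------------

def test_wilcoxon_screen_oracle(rng):
    X, labels = _signal_data(rng)
    out = wilcoxon_screen(X, labels).set_index("species_id")
    assert list(out.reset_index().columns) == ASSOCIATION_COLUMNS
    for col in X.columns:
        expect = mannwhitneyu(X.loc[labels == 1, col],
                              X.loc[labels == 0, col],
                              alternative="two-sided").pvalue
        assert out.loc[col, "p"] == pytest.approx(expect, abs=1e-12)
    assert out.loc["sp0", "direction"] == "aGvHD"
    assert out.loc["sp1", "direction"] == "NaGvHD"
    assert out.loc["sp0", "effect_size"] > 1.5
    assert out.loc["sp1", "effect_size"] < -1.5


def test_wilcoxon_screen_constant_species(rng):
    X, labels = _signal_data(rng)
    X["flat"] = 1.0
    out = wilcoxon_screen(X, labels).set_index("species_id")
    assert np.isnan(out.loc["flat", "p"])
    with pytest.raises(ValueError, match="non-empty"):
        wilcoxon_screen(X, np.ones_like(labels))


def test_wilcoxon_log2fc_pseudocount(rng):
    X, labels = _signal_data(rng)
    X.loc[labels == 0, "sp0"] = 0.0  # absent in controls
    out = wilcoxon_screen(X, labels).set_index("species_id")
    assert np.isfinite(out.loc["sp0", "effect_size"])
    assert out.loc["sp0", "effect_size"] > 0


# ---------------------------------------------------------------------------
# indicator statistics
# ---------------------------------------------------------------------------

def test_indval_perfect_indicator(rng):
    X, labels = _signal_data(rng)
    X["only_case"] = np.where(labels == 1, 5.0, 0.0)
    out = indval_g(X, labels, n_perm=199, seed=0).set_index("species_id")
    assert out.loc["only_case", "effect_size"] == pytest.approx(1.0)
    assert out.loc["only_case", "direction"] == "aGvHD"
    assert out.loc["only_case", "p"] == pytest.approx(1 / 200)


def test_indval_prevalence_filter(rng):
    X, labels = _signal_data(rng)
    rare = np.zeros(len(labels))
    rare[:2] = 1.0  # prevalence 2/15 in cases < 0.2
    X["rare"] = rare
    out = indval_g(X, labels, n_perm=99, seed=0)
    assert "rare" not in set(out["species_id"])
    assert out.attrs["n_filtered_out"] >= 1


def test_pointbiserial_matches_scipy_when_balanced(rng):
    n = 30
    labels = np.array([1] * 15 + [0] * 15)
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    out = pointbiserial_rg(X, labels, n_perm=99, seed=0).set_index(
        "species_id")
    for col in X.columns:
        expect = pointbiserialr(labels, X[col]).correlation
        assert out.loc[col, "effect_size"] == pytest.approx(expect,
                                                            abs=1e-10)


def test_pointbiserial_group_equalization(rng):
    # the group-equalised r.g must be invariant to replicating the majority
    labels = np.array([1] * 10 + [0] * 10)
    X = pd.DataFrame({"a": rng.normal(size=20) + labels})
    r1 = pointbiserial_rg(X, labels, n_perm=99).loc[0, "effect_size"]
    X2 = pd.concat([X, X[labels == 0], X[labels == 0]], ignore_index=True)
    labels2 = np.concatenate([labels, np.zeros(20, dtype=int)])
    r2 = pointbiserial_rg(X2, labels2, n_perm=99).loc[0, "effect_size"]
    assert r1 != 0
    assert r1 == pytest.approx(r2, rel=1e-9)


def test_sign_association_pvalues_and_sidak(rng):
    X, labels = _signal_data(rng)
    out = sign_association(X, labels, n_perm=199, seed=0)
    assert (out["adjust_method"] == "Sidak").all()
    out = out.set_index("species_id")
    assert out.loc["sp0", "p"] <= 0.05
    assert out.loc["sp0", "direction"] == "aGvHD"
    assert out.loc["sp1", "direction"] == "NaGvHD"
    # permutation convention: p >= 1/(1+n_perm), never zero
    assert (out["p"] >= 1 / 200 - 1e-12).all()
    # Sidak: 1 - (1-p)^m
    m = out["p"].notna().sum()
    np.testing.assert_allclose(out["p_adj"],
                               1 - (1 - out["p"]) ** m, atol=1e-12)


# ---------------------------------------------------------------------------
# conditional MI / Spearman
# ---------------------------------------------------------------------------

def test_conditional_mi_detects_confounded_association(rng):
    n = 240
    z = rng.integers(0, 2, n)            # confounder
    labels = (rng.random(n) < 0.2 + 0.6 * z).astype(int)
    X = pd.DataFrame({
        "confounded": z * 10.0 + rng.normal(0, 0.1, n),  # only via z
        "direct": labels * 5.0 + rng.normal(0, 0.5, n),  # true signal
        "noise": rng.normal(size=n),
    })
    out = conditional_mi(X, labels, z).set_index("species_id")
    assert out.loc["direct", "effect_size"] > 0.3
    assert out.loc["confounded", "effect_size"] < 0.05
    # equal-frequency bins may straddle the cluster boundary, so the MI
    # with the binary confounder lands a little below H(z) = 1 bit
    assert out.loc["confounded", "mi_with_confounder"] > 0.8
    assert out.loc["noise", "effect_size"] < 0.1


def test_conditional_mi_small_level_policy(rng):
    n = 30
    z = np.array(["a"] * 28 + ["b", "b"])
    labels = rng.integers(0, 2, n)
    X = pd.DataFrame({"x": rng.normal(size=n)})
    with pytest.warns(UserWarning, match="merging"):
        conditional_mi(X, labels, z, min_level_size=5)
    with pytest.raises(ValueError, match="confounder levels"):
        conditional_mi(X, labels, z, min_level_size=5,
                       small_level_policy="raise")


def test_spearman_matches_scipy(rng):
    X, labels = _signal_data(rng)
    out = spearman_assoc(X, labels).set_index("species_id")
    for col in X.columns:
        expect = spearmanr(X[col], labels).statistic
        assert out.loc[col, "effect_size"] == pytest.approx(expect,
                                                            abs=1e-10)
    top = top_by_abs_rho(out.reset_index(), n=3)
    assert len(top) == 3
    assert top["effect_size"].abs().iloc[0] == out["effect_size"].abs().max()


# ---------------------------------------------------------------------------
# clinical logistic regression
# ---------------------------------------------------------------------------

def test_clinical_design_dichotomisation():
    cohort = generate_cohort(60, seed=4)
    design = prepare_clinical_design(cohort)
    assert len(design) == 60
    assert design.drop(columns="outcome").isin([0.0, 1.0]).all().all()
    assert not design.isna().any().any()  # Karnofsky imputed
    byp = cohort.drop_duplicates("patient_id").set_index("patient_id")
    expected_age = (byp["recipient_age"] >= 60).astype(float)
    pd.testing.assert_series_equal(design["recipient_age"], expected_age,
                                   check_names=False)


def test_clinical_karnofsky_imputed_within_outcome():
    cohort = generate_cohort(60, seed=4)
    byp = cohort.drop_duplicates("patient_id").set_index("patient_id")
    missing = byp.index[byp["karnofsky_d0"].isna()]
    assert len(missing) == 2
    design = prepare_clinical_design(cohort)
    for pid in missing:
        outcome = byp.loc[pid, "outcome"]
        med = byp.loc[byp["outcome"] == outcome, "karnofsky_d0"].median()
        assert design.loc[pid, "karnofsky_d0"] == float(med >= 90)


def test_clinical_logistic_fit_keys_and_modes():
    cohort = generate_cohort(150, seed=8)
    fit = fit_clinical_logistic(cohort, mode="multivariable")
    assert set(fit) >= {"table", "aic", "bic", "pseudo_r2_mcfadden",
                        "pseudo_r2_cragg_uhler"}
    tab = fit["table"]
    assert set(CLINICAL_PREDICTORS) <= set(tab.index)
    assert (tab["ci_low"] <= tab["beta"] + 1e-9).all()
    assert (tab["beta"] <= tab["ci_high"] + 1e-9).all()
    assert 0 <= fit["pseudo_r2_mcfadden"] <= 1
    assert 0 <= fit["pseudo_r2_cragg_uhler"] <= 1

    uni = fit_clinical_logistic(cohort, mode="univariable")
    assert list(uni["table"].index) == CLINICAL_PREDICTORS
    with pytest.raises(ValueError, match="mode"):
        fit_clinical_logistic(cohort, mode="bayesian")
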