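import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutmwas.diversity import (ALPHA_INDICES, BETA_INDICES, alpha_diversity,
                               alpha_diversity_table, beta_distance,
                               compare_group_alpha, compare_group_beta,
                               group_equalized_beta_test, kmer_f0,
                               pairwise_beta)

# ---------------------------------------------------------------------------
# alpha
# ---------------------------------------------------------------------------

P = np.array([0.5, 0.3, 0.2])


def test_alpha_hand_values():
    assert alpha_diversity(P, "berger_parker") == pytest.approx(0.5)
    assert alpha_diversity(P, "simpson") == pytest.approx(0.38)
    assert alpha_diversity(P, "inverse_simpson") == pytest.approx(1 / 0.38)
    assert alpha_diversity(P, "richness") == 3
    shannon = -(P * np.log(P)).sum()
    assert alpha_diversity(P, "shannon") == pytest.approx(shannon)
    assert alpha_diversity(P, "heip_evenness") == pytest.approx(
        (np.exp(shannon) - 1) / 2)
    # Strong: max_i (cum_i - i/S) with cum over sorted descending
    assert alpha_diversity(P, "strong") == pytest.approx(
        max(0.5 - 1 / 3, 0.8 - 2 / 3, 1.0 - 1.0))


def test_alpha_scale_invariance():
    counts = np.array([50.0, 30.0, 20.0, 0.0])
    for idx in ALPHA_INDICES:
        assert alpha_diversity(counts, idx) == pytest.approx(
            alpha_diversity(counts / counts.sum(), idx))


def test_alpha_zeros_ignored():
    assert alpha_diversity([0.5, 0.5, 0.0], "richness") == 2


def test_alpha_errors_and_warnings():
    with pytest.raises(ValueError, match="negative"):
        alpha_diversity([-0.1, 1.1], "shannon")
    with pytest.raises(ValueError, match="empty"):
        alpha_diversity([0.0, 0.0], "shannon")
    with pytest.raises(ValueError, match="unknown"):
        alpha_diversity(P, "chao1")
    with pytest.warns(UserWarning, match="Heip"):
        assert np.isnan(alpha_diversity([1.0], "heip_evenness"))


def test_alpha_table_shape(simplex_matrix):
    tab = alpha_diversity_table(simplex_matrix)
    assert tab.shape == (30, 7)
    assert list(tab.columns) == list(ALPHA_INDICES)
    assert np.isfinite(tab.to_numpy()).all()


def test_kmer_f0():
    assert kmer_f0(["ACGT"], 2) == 3  # AC, CG, GT
    assert kmer_f0(["ACGT", "ACGT"], 2) == 3  # duplicates do not add
    assert kmer_f0(["ACGT", "TTTT"], 2) == 4
    assert kmer_f0(["AC"], 3) == 0
    with pytest.raises(ValueError):
        kmer_f0(["ACGT"], 0)


# ---------------------------------------------------------------------------
# beta
# ---------------------------------------------------------------------------

def test_beta_hand_values():
    x = np.array([1.0, 0.0, 3.0])
    y = np.array([0.0, 2.0, 3.0])
    assert beta_distance(x, y, "manhattan") == pytest.approx(3.0)
    assert beta_distance(x, y, "euclidean") == pytest.approx(np.sqrt(5.0))
    assert beta_distance(x, y, "chebyshev") == pytest.approx(2.0)
    # canberra: |1-0|/1 + |0-2|/2 + 0 = 2
    assert beta_distance(x, y, "canberra") == pytest.approx(2.0)
    # clark: sqrt(1^2 + 1^2 + 0)
    assert beta_distance(x, y, "clark") == pytest.approx(np.sqrt(2.0))


def test_jaccard_nestedness_baselga_partition():
    # nested communities: turnover 0, nestedness = full jaccard
    x = np.array([1.0, 1.0, 1.0, 0.0])
    y = np.array([1.0, 1.0, 0.0, 0.0])
    # a=2, b=1, c=0 -> jac=1/3, jtu=0
    assert beta_distance(x, y, "jaccard_nestedness") == pytest.approx(1 / 3)
    # symmetric swap
    assert beta_distance(y, x, "jaccard_nestedness") == pytest.approx(1 / 3)
    # identical -> 0
    assert beta_distance(x, x, "jaccard_nestedness") == 0.0
    # equal richness, disjoint -> pure turnover, nestedness 0
    u = np.array([1.0, 1.0, 0.0, 0.0])
    v = np.array([0.0, 0.0, 1.0, 1.0])
    assert beta_distance(u, v, "jaccard_nestedness") == pytest.approx(0.0)


def test_horn_morisita_identity_and_range(rng):
    x = rng.random(10)
    assert beta_distance(x, x, "horn_morisita") == pytest.approx(0.0,
                                                                 abs=1e-12)
    y = rng.random(10)
    d = beta_distance(x, y, "horn_morisita")
    assert 0.0 <= d <= 1.0 + 1e-12
    # scale invariance in each argument
    assert beta_distance(3 * x, 0.5 * y, "horn_morisita") == pytest.approx(d)


def test_beta_unknown_index():
    with pytest.raises(ValueError, match="unknown"):
        beta_distance([1.0], [1.0], "braycurtis")


@pytest.mark.parametrize("index", BETA_INDICES)
def test_pairwise_matches_pointwise(index, simplex_matrix):
    X = simplex_matrix[:12]
    D = pairwise_beta(X, index)
    n = X.shape[0]
    for i in range(n):
        for j in range(i, n):
            expect = beta_distance(X[i], X[j], index)
            assert D.matrix[i, j] == pytest.approx(expect, abs=1e-10)
            assert D.matrix[j, i] == pytest.approx(expect, abs=1e-10)


@given(st.integers(0, 10_000))
@settings(max_examples=15, deadline=None)
def test_beta_symmetry_and_identity(seed):
    rng = np.random.default_rng(seed)
    x = rng.dirichlet(np.ones(8))
    y = rng.dirichlet(np.ones(8))
    for index in BETA_INDICES:
        d_xy = beta_distance(x, y, index)
        d_yx = beta_distance(y, x, index)
        assert d_xy == pytest.approx(d_yx, abs=1e-10)
        assert beta_distance(x, x, index) == pytest.approx(0.0, abs=1e-9)
        assert d_xy >= -1e-12


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _labelled_distances(rng, shrink=1.0):
    n1, n2 = 10, 14
    base = rng.normal(0, 1.5, size=30)
    case = np.exp(base + shrink * rng.normal(0, 1, size=(n1, 30)))
    ctrl = np.exp(base + rng.normal(0, 1, size=(n2, 30)))
    X = np.vstack([case, ctrl])
    X /= X.sum(axis=1, keepdims=True)
    labels = np.array([1] * n1 + [0] * n2)
    return {"canberra": pairwise_beta(X, "canberra"),
            "euclidean": pairwise_beta(X, "euclidean")}, labels


def test_compare_group_beta_schema_and_determinism(rng):
    distances, labels = _labelled_distances(rng)
    a = compare_group_beta(distances, labels, n_perm=99, seed=5)
    b = compare_group_beta(distances, labels, n_perm=99, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert set(a.columns) >= {"index", "mean_case", "mean_control",
                              "fold_change_pct", "p", "p_asymptotic",
                              "p_adj"}
    assert ((a["p"] > 0) & (a["p"] <= 1)).all()
    assert (a["p_adj"] >= a["p"] - 1e-12).all()  # BH never lowers the min p
    with pytest.raises(ValueError, match="p_mode"):
        compare_group_beta(distances, labels, p_mode="bootstrap")


def test_compare_group_beta_detects_case_shrinkage(rng):
    distances, labels = _labelled_distances(rng, shrink=0.25)
    res = compare_group_beta(distances, labels, n_perm=199, seed=1)
    assert (res["mean_case"] < res["mean_control"]).all()
    assert (res["p"] < 0.05).all()


def test_compare_group_beta_asymptotic_mode(rng):
    distances, labels = _labelled_distances(rng)
    res = compare_group_beta(distances, labels, p_mode="asymptotic")
    np.testing.assert_allclose(res["p"], res["p_asymptotic"])


def test_compare_group_alpha(rng):
    n = 40
    labels = np.array([1] * 15 + [0] * 25)
    tab = pd.DataFrame({"shannon": rng.normal(2, 0.3, n) + 0.8 * labels,
                        "richness": rng.normal(20, 2, n)})
    res = compare_group_alpha(tab, labels)
    res = res.set_index("index")
    assert res.loc["shannon", "p"] < 0.01
    assert res.loc["shannon", "mean_case"] > res.loc["shannon",
                                                     "mean_control"]
    assert (res["p_adj"] >= res["p"] - 1e-12).all()


def test_group_equalized_fraction_and_direction(rng):
    distances, labels = _labelled_distances(rng, shrink=0.2)
    res = group_equalized_beta_test(distances, labels, n_subsets=30,
                                    seed=0, n_perm=99)
    assert res["fraction_significant"].between(0, 1).all()
    assert (res.loc[res["fraction_significant"] > 0.5,
                    "direction"] == "case_lower").all()


def test_group_equalized_requires_two_groups(rng):
    distances, labels = _labelled_distances(rng)
    with pytest.raises(ValueError, match="two groups"):
        group_equalized_beta_test(distances, np.ones_like(labels))
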