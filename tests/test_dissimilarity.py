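import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway
from scipy.spatial.distance import pdist, squareform

from gutmwas.dissimilarity import (DistanceMatrix, anosim, bray_curtis,
                                   dispersion_test, mwmote, permanova,
                                   rclr_distance, rclr_transform)


def random_compositions(rng, n, s, sigma=1.5):
    x = np.exp(rng.normal(0.0, sigma, size=(n, s)))
    return x / x.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# DistanceMatrix / rclr / Bray-Curtis
# ---------------------------------------------------------------------------

def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="square"):
        DistanceMatrix(["a"], np.zeros((1, 2)))
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[1.0, 0], [0, 0]]))
    with pytest.raises(ValueError, match="NaN"):
        DistanceMatrix(["a", "b"], np.array([[0, np.nan], [np.nan, 0]]))
    DistanceMatrix(["a", "b"], np.array([[0, np.nan], [np.nan, 0]]),
                   allow_nan=True)


def test_rclr_zeros_kept_and_centering(rng):
    x = np.array([[4.0, 0.0, 1.0, 16.0]])
    out = rclr_transform(x)
    assert out[0, 1] == 0.0
    pos = x[0] > 0
    np.testing.assert_allclose(out[0, pos].mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(out[0, pos],
                               np.log(x[0, pos]) - np.log(x[0, pos]).mean())


def test_rclr_scale_invariance(rng):
    x = rng.random((5, 8)) + 0.1
    np.testing.assert_allclose(rclr_transform(x), rclr_transform(10 * x),
                               atol=1e-12)


def test_rclr_validation():
    with pytest.raises(ValueError, match="negative"):
        rclr_transform(np.array([[-1.0, 2.0]]))
    with pytest.raises(ValueError, match="positive entries"):
        rclr_transform(np.array([[1.0, 0.0, 0.0]]))


def test_rclr_distance_is_euclidean_on_transform(simplex_matrix):
    D = rclr_distance(simplex_matrix)
    manual = squareform(pdist(rclr_transform(simplex_matrix)))
    np.testing.assert_allclose(D.matrix, manual, atol=1e-12)


def test_bray_curtis_oracle(simplex_matrix):
    D = bray_curtis(simplex_matrix)
    manual = squareform(pdist(simplex_matrix, metric="braycurtis"))
    np.testing.assert_allclose(D.matrix, manual, atol=1e-12)
    assert D.matrix.max() <= 1.0 + 1e-12
    with pytest.raises(ValueError, match="negative"):
        bray_curtis(np.array([[-1.0, 2.0], [1.0, 1.0]]))


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM / dispersion
# ---------------------------------------------------------------------------

def test_permanova_equals_anova_on_1d_euclidean(rng):
    n = 30
    y = rng.normal(size=n)
    groups = np.repeat(["a", "b", "c"], 10)
    D = DistanceMatrix(list(range(n)),
                       np.abs(y[:, None] - y[None, :]))
    design = pd.DataFrame({"g": groups})
    tab = permanova(D, design, ["g"], n_perm=99, seed=0)
    f_classic = f_oneway(y[:10], y[10:20], y[20:]).statistic
    assert tab.loc["g", "F"] == pytest.approx(f_classic, abs=1e-8)
    assert tab.loc["g", "Df"] == 2
    assert tab.loc["Residual", "Df"] == 27


def test_permanova_sequential_terms_and_r2(rng):
    X = random_compositions(rng, 40, 20)
    D = rclr_distance(X)
    design = pd.DataFrame({
        "outcome": rng.integers(0, 2, 40),
        "sex": rng.choice(["m", "f"], 40),
    })
    tab = permanova(D, design, ["outcome", "sex", "outcome:sex"],
                    n_perm=99, seed=0)
    assert list(tab.index) == ["outcome", "sex", "outcome:sex", "Residual",
                               "Total"]
    np.testing.assert_allclose(tab["SumSq"].iloc[:4].sum(),
                               tab.loc["Total", "SumSq"], rtol=1e-10)
    assert tab.loc["Total", "R2"] == pytest.approx(1.0)
    assert ((tab["p"].iloc[:3] > 0) & (tab["p"].iloc[:3] <= 1)).all()


def test_permanova_detects_group_shift(rng):
    X = random_compositions(rng, 40, 20)
    labels = np.array([1] * 15 + [0] * 25)
    X[labels == 1, :4] *= 6.0
    X /= X.sum(axis=1, keepdims=True)
    D = rclr_distance(X)
    tab = permanova(D, pd.DataFrame({"outcome": labels}), ["outcome"],
                    n_perm=199, seed=0)
    assert tab.loc["outcome", "p"] < 0.05


def test_permanova_validation(rng):
    X = random_compositions(rng, 10, 8)
    D = rclr_distance(X)
    with pytest.raises(ValueError, match="size mismatch"):
        permanova(D, pd.DataFrame({"g": [1, 2]}), ["g"])
    with pytest.raises(ValueError, match="single level"):
        permanova(D, pd.DataFrame({"g": np.ones(10)}), ["g"])
    with pytest.raises(ValueError, match="not in design"):
        permanova(D, pd.DataFrame({"g": np.arange(10) % 2}), ["h"])


def test_anosim_range_and_separation(rng):
    X = random_compositions(rng, 30, 15)
    labels = np.array([1] * 12 + [0] * 18)
    X[labels == 1, :5] *= 8.0
    X /= X.sum(axis=1, keepdims=True)
    D = rclr_distance(X)
    r, p = anosim(D, labels, n_perm=199, seed=0)
    assert -1.0 <= r <= 1.0
    assert r > 0.2 and p < 0.05
    with pytest.raises(ValueError, match="two groups"):
        anosim(D, np.ones(30))


def test_dispersion_test_detects_heteroscedastic_group(rng):
    tight = rng.normal(0, 0.3, size=(20, 5))
    loose = rng.normal(0, 2.0, size=(20, 5))
    X = np.vstack([tight, loose])
    labels = np.array([0] * 20 + [1] * 20)
    D = DistanceMatrix(list(range(40)),
                       squareform(pdist(X)))
    per_group, f, p = dispersion_test(D, labels, n_perm=199, seed=0)
    assert per_group[1] > per_group[0]
    assert p < 0.05


# ---------------------------------------------------------------------------
# MWMOTE
# ---------------------------------------------------------------------------

def _imbalanced(rng, n_min=12, n_maj=40, s=6):
    minority = rng.normal(2.0, 0.5, size=(n_min, s))
    majority = rng.normal(0.0, 1.0, size=(n_maj, s))
    X = np.vstack([minority, majority])
    labels = np.array([1] * n_min + [0] * n_maj)
    return X, labels


def test_mwmote_counts_and_labels(rng):
    X, labels = _imbalanced(rng)
    X_aug, y_aug = mwmote(X, labels, n_synthetic=20, seed=0)
    assert X_aug.shape == (72, 6)
    assert (y_aug[-20:] == 1).all()
    np.testing.assert_array_equal(X_aug[:52], X)
    np.testing.assert_array_equal(y_aug[:52], labels)


def test_mwmote_synthetic_within_minority_box(rng):
    X, labels = _imbalanced(rng)
    X_aug, _ = mwmote(X, labels, n_synthetic=50, seed=1)
    synth = X_aug[len(X):]
    lo = X[labels == 1].min(axis=0)
    hi = X[labels == 1].max(axis=0)
    assert (synth >= lo - 1e-9).all() and (synth <= hi + 1e-9).all()


def test_mwmote_zero_and_validation(rng):
    X, labels = _imbalanced(rng)
    X0, y0 = mwmote(X, labels, n_synthetic=0)
    np.testing.assert_array_equal(X0, X)
    with pytest.raises(ValueError, match="binary"):
        mwmote(X, np.zeros(len(labels)), 5)
    X_small, labels_small = _imbalanced(rng, n_min=3)
    with pytest.raises(ValueError, match="too small"):
        mwmote(X_small, labels_small, 5)


def test_mwmote_deterministic(rng):
    X, labels = _imbalanced(rng)
    a, _ = mwmote(X, labels, n_synthetic=15, seed=9)
    b, _ = mwmote(X, labels, n_synthetic=15, seed=9)
    np.testing.assert_array_equal(a, b)
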