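"""Compositional distances and permutation inference on distance matrices.

Between-group structure in the deduplicated abundance table is tested on
two distances — robust Aitchison (centred log-ratio over the positive
entries of each row, zeros kept at 0, then Euclidean) and Bray-Curtis — via
three permutation procedures:

* PERMANOVA with sequential (Type-I) sums of squares over an ordered list
  of design terms, pseudo-F per term and free row permutation;
* ANOSIM on the ranks of all pairwise distances;
* a multivariate-dispersion homogeneity test (principal-coordinate
  embedding, distance to group centroid, one-way F with permutation p).

Because the aGvHD group is much smaller than the NaGvHD group and these
tests are sensitive to unbalanced designs, :func:`mwmote` implements
majority-weighted minority oversampling: informative borderline minority
samples receive selection weights from their closeness to the borderline
majority set, and synthetic samples are interpolated within average-linkage
clusters of the minority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata

from .containers import AbundanceMatrix

DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric distance matrix with sample ids."""

    ids: list
    matrix: np.ndarray = field(repr=False)
    allow_nan: bool = False

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "ids", list(self.ids))
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != mat.shape[0]:
            raise ValueError("id/matrix size mismatch")
        if np.isinf(mat).any():
            raise ValueError("infinite distances")
        if np.isnan(mat).any() and not self.allow_nan:
            raise ValueError("NaN distances (pass allow_nan=True to permit)")
        finite = np.isfinite(mat)
        if not np.allclose(mat[finite], mat.T[finite], atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(mat), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")


def _as_matrix(X):
    if isinstance(X, AbundanceMatrix):
        return X.to_numpy(), list(X.sample_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index)
    arr = np.asarray(X, dtype=float)
    return arr, list(range(arr.shape[0]))


def rclr_transform(arr: np.ndarray) -> np.ndarray:
    """Robust centred log-ratio: log(x / gmean of the row's positive
    entries) where x > 0, zero elsewhere. Scale-invariant per row."""
    if (arr < 0).any():
        raise ValueError("negative abundances")
    n_pos = (arr > 0).sum(axis=1)
    if (n_pos < 2).any():
        bad = np.flatnonzero(n_pos < 2)[:5].tolist()
        raise ValueError(f"rows with fewer than 2 positive entries: {bad}")
    out = np.zeros_like(arr, dtype=float)
    pos = arr > 0
    with np.errstate(divide="ignore"):
        logs = np.where(pos, np.log(arr, where=pos,
                                    out=np.zeros_like(arr, dtype=float)), 0.0)
    gmean_log = logs.sum(axis=1) / n_pos
    out[pos] = (logs - gmean_log[:, None])[pos]
    return out


def rclr_distance(X) -> DistanceMatrix:
    """Robust Aitchison distance: Euclidean on the rclr-transformed rows."""
    arr, ids = _as_matrix(X)
    clr = rclr_transform(arr)
    return DistanceMatrix(ids, squareform(pdist(clr, metric="euclidean")))


def bray_curtis(X) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    arr, ids = _as_matrix(X)
    if (arr < 0).any():
        raise ValueError("negative abundances")
    zero_rows = arr.sum(axis=1) == 0
    mat = squareform(pdist(arr, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn("all-zero rows; Bray-Curtis undefined for those pairs")
        return DistanceMatrix(ids, np.nan_to_num(mat, nan=np.nan),
                              allow_nan=True)
    return DistanceMatrix(ids, mat)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-coded columns (reference level dropped) for a main effect or
    a ':'-separated interaction term."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part not in design.columns:
            raise ValueError(f"term {part!r} not in design")
        col = design[part]
        if col.nunique() < 2:
            raise ValueError(f"term {part!r} has a single level")
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
    out = blocks[0]
    for blk in blocks[1:]:
        out = np.concatenate(
            [out[:, [i]] * blk for i in range(out.shape[1])], axis=1)
    return out


def _hat(Xd: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(Xd)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(Xd.shape)))
    q = q[:, :rank]
    return q @ q.T


def permanova(
    D: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-based multivariate ANOVA with sequential sums of squares.

    Terms (design columns or ``a:b`` interactions) enter in the given
    order; each term's pseudo-F is its sequential sum of squares over the
    residual mean square. p-values come from free row permutation with the
    (1 + exceedances) / (1 + n_perm) convention.
    """
    n = D.n
    if len(design) != n:
        raise ValueError("design/distance size mismatch")
    G = _gower_center(D.matrix)
    ss_total = float(np.trace(G))

    hats = [np.ones((n, n)) / n]
    Xd = np.ones((n, 1))
    dfs = []
    for term in terms:
        Xd = np.concatenate([Xd, _term_columns(design, term)], axis=1)
        H = _hat(Xd)
        df = int(round(np.trace(H) - np.trace(hats[-1])))
        if df < 1:
            raise ValueError(f"term {term!r} adds no degrees of freedom")
        dfs.append(df)
        hats.append(H)
    H_full = hats[-1]
    df_res = n - int(round(np.trace(H_full)))
    if df_res < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    diff_hats = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_hat = np.eye(n) - H_full

    def _f_stats(Gm):
        ss_terms = np.array([float(np.sum(Hd * Gm)) for Hd in diff_hats])
        ss_res = float(np.sum(resid_hat * Gm))
        ms_res = ss_res / df_res
        return ss_terms, ss_res, (ss_terms / np.array(dfs)) / ms_res

    ss_terms, ss_res, f_obs = _f_stats(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, _, f_p = _f_stats(Gp)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append({"term": term, "Df": dfs[k], "SumSq": ss_terms[k],
                     "R2": ss_terms[k] / ss_total, "F": f_obs[k],
                     "p": pvals[k]})
    rows.append({"term": "Residual", "Df": df_res, "SumSq": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "Df": n - 1, "SumSq": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(D: DistanceMatrix, labels, n_perm: int = DEFAULT_N_PERM,
           seed: int = 0) -> tuple[float, float]:
    """Analysis of similarities: R in [-1, 1] on ranked distances,
    permutation p (one-sided, R_perm >= R_obs)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two groups")
    condensed = squareform(D.matrix, checks=False)
    if np.allclose(condensed, condensed[0]):
        warnings.warn("all distances equal; ANOSIM R undefined")
        return float("nan"), float("nan")
    ranks = rankdata(condensed)
    n = D.n
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    M = condensed.size

    def _r(within_mask):
        return (ranks[~within_mask].mean() - ranks[within_mask].mean()) / (M / 2)

    r_obs = _r(within)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        lp = labels[rng.permutation(n)]
        wp = lp[iu[0]] == lp[iu[1]]
        if _r(wp) >= r_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# multivariate dispersion
# ---------------------------------------------------------------------------

def _pcoa_embed(D: DistanceMatrix):
    G = _gower_center(D.matrix)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) > 1e-10 * max(1.0, np.abs(vals).max())
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(np.abs(vals))[None, :]
    return coords, vals > 0


def dispersion_test(D: DistanceMatrix, labels, n_perm: int = 999,
                    seed: int = 0):
    """Homogeneity of multivariate dispersion.

    Samples are embedded by principal coordinates (negative eigenvalues
    kept on imaginary axes whose squared distances subtract); per-group
    distances to the group centroid feed a one-way F whose p-value comes
    from permuting group labels. Returns (per-group mean dispersion, F, p).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has a single sample")
    coords, positive = _pcoa_embed(D)
    pos_c, neg_c = coords[:, positive], coords[:, ~positive]

    def _dists(lab):
        d = np.empty(len(lab))
        for g in np.unique(lab):
            idx = lab == g
            d2 = ((pos_c[idx] - pos_c[idx].mean(axis=0)) ** 2).sum(axis=1)
            if neg_c.shape[1]:
                d2 = d2 - ((neg_c[idx] - neg_c[idx].mean(axis=0)) ** 2
                           ).sum(axis=1)
            d[idx] = np.sqrt(np.clip(d2, 0.0, None))
        return d

    def _f(dist, lab):
        grand = dist.mean()
        ssb = ssw = 0.0
        k = 0
        for g in np.unique(lab):
            idx = lab == g
            m = dist[idx].mean()
            ssb += idx.sum() * (m - grand) ** 2
            ssw += ((dist[idx] - m) ** 2).sum()
            k += 1
        df1, df2 = k - 1, len(lab) - k
        return (ssb / df1) / (ssw / df2) if ssw > 0 else np.inf

    dist_obs = _dists(labels)
    f_obs = _f(dist_obs, labels)
    per_group = {g: float(dist_obs[labels == g].mean()) for g in groups}

    rng = np.random.default_rng(seed)
    exceed = 0
    n = D.n
    for _ in range(n_perm):
        lp = labels[rng.permutation(n)]
        if _f(_dists(lp), lp) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return per_group, float(f_obs), float(p)


# ---------------------------------------------------------------------------
# MWMOTE
# ---------------------------------------------------------------------------

def mwmote(
    X,
    labels,
    n_synthetic: int,
    k1: int = 5,
    k2: int = 3,
    k3: int | None = None,
    seed: int = 0,
    cf_th: float = 5.0,
    cmax: float = 2.0,
    c_p: float = 3.0,
):
    """Majority-weighted minority oversampling.

    Three phases: (1) drop minority samples whose k1-neighbourhood is all
    majority (noise), collect the borderline majority set from the k2
    majority neighbours of the remainder, then the informative minority set
    from the k3 minority neighbours of that borderline set; (2) give each
    informative minority sample a selection weight from closeness and
    density factors toward the borderline majority set; (3) cluster the
    filtered minority set by average linkage and generate each synthetic
    sample as s = x + alpha (y - x), alpha ~ U(0,1), with x drawn by
    selection weight and y uniform from x's cluster. Returns the augmented
    (X, labels); synthetic rows can never leave the minority convex hull.
    """
    arr, ids = _as_matrix(X)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels != minority)
    if k3 is None:
        k3 = max(1, len(min_idx) // 2)
    if len(min_idx) < 2 * k2:
        raise ValueError("minority class too small for MWMOTE")
    if n_synthetic == 0:
        return np.asarray(arr), labels

    rng = np.random.default_rng(seed)
    S_min, S_maj = arr[min_idx], arr[maj_idx]

    # phase 1: informative minority / borderline majority
    d_all = cdist(S_min, arr)
    noise_free = []
    for i in range(len(min_idx)):
        order = np.argsort(d_all[i])
        nn = [j for j in order if j != min_idx[i]][:k1]
        if any(labels[j] == minority for j in nn):
            noise_free.append(i)
    if not noise_free:
        noise_free = list(range(len(min_idx)))
    S_minf = np.array(noise_free)

    d_min_maj = cdist(S_min[S_minf], S_maj)
    border_maj = np.unique(
        np.argsort(d_min_maj, axis=1)[:, :min(k2, len(maj_idx))].ravel())
    d_maj_min = cdist(S_maj[border_maj], S_min[S_minf])
    kk3 = min(k3, len(S_minf))
    informative = np.unique(np.argsort(d_maj_min, axis=1)[:, :kk3].ravel())

    # phase 2: selection weights (closeness x density toward border majority)
    d = d_maj_min[:, informative]  # border majority x informative minority
    nfeat = arr.shape[1]
    with np.errstate(divide="ignore"):
        closeness = np.where(d > 0, nfeat / d, cf_th)
    closeness = np.minimum(closeness, cf_th) / cf_th * cmax
    density = closeness / np.maximum(closeness.sum(axis=1, keepdims=True),
                                     1e-300)
    weight = (closeness * density).sum(axis=0)
    if weight.sum() <= 0:
        weight = np.ones_like(weight)
    prob = weight / weight.sum()

    # phase 3: cluster the filtered minority set, interpolate within cluster
    pool = S_min[S_minf]
    if len(pool) > 1:
        d_pool = cdist(pool, pool)
        np.fill_diagonal(d_pool, np.inf)
        t_h = c_p * d_pool.min(axis=1).mean()
        clusters = fcluster(linkage(pool, method="average"), t=t_h,
                            criterion="distance")
    else:
        clusters = np.array([1])

    synth = np.empty((n_synthetic, arr.shape[1]))
    for s in range(n_synthetic):
        pick = rng.choice(len(informative), p=prob)
        x_local = informative[pick]          # index into pool
        members = np.flatnonzero(clusters == clusters[x_local])
        y_local = members[rng.integers(len(members))]
        alpha = rng.random()
        synth[s] = pool[x_local] + alpha * (pool[y_local] - pool[x_local])

    X_aug = np.vstack([arr, synth])
    labels_aug = np.concatenate([labels,
                                 np.full(n_synthetic, minority,
                                         dtype=labels.dtype)])
    return X_aug, labels_aug
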