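"""Relief- and impurity-based feature ranking with median-rank consensus.

Thirteen ranking algorithms score every species against the binary outcome:
seven from the Relief family — the original Relief (one nearest hit/miss
per sampled instance) and six ReliefF-style extensions that differ in how
nearest neighbours are weighted (equal weights over K neighbours,
exponentially decaying rank weights, per-feature best K, inverse-distance
weights, a merit-weighted update, and a sampling-free myopic formulation) —
and six impurity measures computed on equal-frequency-discretised
abundances (gain ratio, minimum description length, the DKM index,
information gain under uniform class priors, and the Hellinger and
Euclidean distances between the class-conditional value distributions).

A species' consensus relevance is its median rank across the thirteen
algorithms; per-algorithm ranks are full permutations of 1..S (higher
score = rank 1, ties broken lexicographically by species id).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import gammaln

RELIEF_VARIANTS = (
    "Relief",
    "ReliefFequalK",
    "ReliefFexpRank",
    "ReliefFbestK",
    "MyopicReliefF",
    "ReliefFmerit",
    "ReliefFdistance",
)

IMPURITY_MEASURES = (
    "GainRatio",
    "MDL",
    "DKM",
    "UniformInf",
    "EqualHellinger",
    "DistEuclid",
)

ALL_ALGORITHMS = RELIEF_VARIANTS + IMPURITY_MEASURES


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    values = getattr(X, "values", X)
    if isinstance(values, pd.DataFrame):
        return values
    return pd.DataFrame(values)


def _minmax_scale(arr: np.ndarray) -> np.ndarray:
    lo = arr.min(axis=0)
    rng = arr.max(axis=0) - lo
    rng[rng == 0] = 1.0  # constant features contribute zero diff
    return (arr - lo) / rng


# ---------------------------------------------------------------------------
# Relief family
# ---------------------------------------------------------------------------

def relief_score(X, labels, variant: str = "ReliefFequalK",
                 K: int = 10, m: int | None = None, seed: int = 0,
                 sigma: float | None = None) -> pd.Series:
    """Relief-family feature weights for a binary outcome.

    Features are min-max scaled internally so diff(f, a, b) = |a_f - b_f|
    lies in [0, 1]. For each of ``m`` sampled instances (default: all, in
    order), the K nearest hits and misses (Manhattan distance on scaled
    features) decrement/increment each feature's weight by the
    neighbour-weighted mean diff:

        W[f] += sum_misses w diff(f, x, miss) - sum_hits w diff(f, x, hit)

    With two classes the ReliefF class-prior factor for misses is exactly
    one, so ``ReliefFequalK`` at K=1 coincides with the original Relief.
    ``MyopicReliefF`` ignores neighbourhoods entirely (see
    :func:`myopic_relief_score`).
    """
    if variant not in RELIEF_VARIANTS:
        raise ValueError(f"unknown relief variant {variant!r}")
    df = _as_frame(X)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("binary labels required")
    if variant == "MyopicReliefF":
        return myopic_relief_score(df, y)

    arr = _minmax_scale(df.to_numpy(dtype=float))
    n, S = arr.shape
    if variant == "Relief":
        K = 1
    min_class = min(int((y == g).sum()) for g in np.unique(y))
    if K >= min_class:
        import warnings
        warnings.warn(f"K={K} >= smallest class size {min_class}; reduced")
        K = max(1, min_class - 1)

    if m is None or m >= n:
        selected = np.arange(n)
    else:
        selected = np.random.default_rng(seed).choice(n, size=m,
                                                      replace=False)
    mm = len(selected)

    dist = cdist(arr, arr, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    if sigma is None:
        sigma = max(1.0, K / 2.0)

    W = np.zeros(S)
    W_by_k = np.zeros((K, S)) if variant == "ReliefFbestK" else None
    for i in selected:
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        other = np.flatnonzero(y != y[i])
        hits = same[np.argsort(dist[i, same])][:K]
        misses = other[np.argsort(dist[i, other])][:K]
        k_eff = min(len(hits), len(misses))
        hits, misses = hits[:k_eff], misses[:k_eff]
        dh = np.abs(arr[hits] - arr[i])    # k_eff x S
        dm = np.abs(arr[misses] - arr[i])

        if variant in ("Relief", "ReliefFequalK"):
            w = np.full(k_eff, 1.0 / k_eff)
            W += (w @ dm - w @ dh) / mm
        elif variant == "ReliefFexpRank":
            ranks = np.arange(1, k_eff + 1)
            w = np.exp(-((ranks / sigma) ** 2))
            w /= w.sum()
            W += (w @ dm - w @ dh) / mm
        elif variant == "ReliefFdistance":
            eps = 1e-12
            wh = 1.0 / (dist[i, hits] + eps)
            wm = 1.0 / (dist[i, misses] + eps)
            wh, wm = wh / wh.sum(), wm / wm.sum()
            W += (wm @ dm - wh @ dh) / mm
        elif variant == "ReliefFmerit":
            # each neighbour's update is spread over features in proportion
            # to that feature's share of the pair's total diff
            mh = dh / np.maximum(dh.sum(axis=1, keepdims=True), 1e-12)
            mm_w = dm / np.maximum(dm.sum(axis=1, keepdims=True), 1e-12)
            w = np.full(k_eff, 1.0 / k_eff)
            W += (w @ (dm * mm_w) - w @ (dh * mh)) / mm
        elif variant == "ReliefFbestK":
            ch = np.cumsum(dh, axis=0) / np.arange(1, k_eff + 1)[:, None]
            cm = np.cumsum(dm, axis=0) / np.arange(1, k_eff + 1)[:, None]
            W_by_k[:k_eff] += (cm - ch) / mm
    if variant == "ReliefFbestK":
        W = W_by_k.max(axis=0)
    return pd.Series(W, index=df.columns, name=variant)


def myopic_relief_score(X, labels) -> pd.Series:
    """Sampling-free Relief approximation via the Gini'-gain identity.

    On 4-bin equal-frequency discretised features:
    W(f) = sum_v w_v sum_c p(c|v)^2 - sum_c p(c)^2 with value weights
    w_v = p(v)^2 / sum_u p(u)^2 (the squared-prior weighting that makes the
    expression proportional to the large-sample Relief weight).
    """
    df = _as_frame(X)
    y = np.asarray(labels)
    out = {}
    for col in df.columns:
        table = _contingency(df[col].to_numpy(dtype=float), y, bins=4)
        n = table.sum()
        pv = table.sum(axis=1) / n
        pc = table.sum(axis=0) / n
        wv = pv ** 2 / (pv ** 2).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            pcv = table / table.sum(axis=1, keepdims=True)
        pcv = np.nan_to_num(pcv)
        gini = float((wv * (pcv ** 2).sum(axis=1)).sum() - (pc ** 2).sum())
        out[col] = gini if table.shape[0] > 1 else 0.0
    return pd.Series(out, name="MyopicReliefF")


# ---------------------------------------------------------------------------
# impurity measures
# ---------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    qs = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(qs, x, side="right")


def _contingency(x: np.ndarray, y: np.ndarray, bins: int) -> np.ndarray:
    xd = _discretize(x, bins)
    vals = np.unique(xd)
    classes = np.unique(y)
    table = np.zeros((vals.size, classes.size))
    for i, v in enumerate(vals):
        for j, c in enumerate(classes):
            table[i, j] = np.sum((xd == v) & (y == c))
    return table


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _info_gain(table: np.ndarray) -> float:
    n = table.sum()
    h_y = _entropy_bits(table.sum(axis=0) / n)
    h_y_given = 0.0
    for row in table:
        nv = row.sum()
        if nv > 0:
            h_y_given += (nv / n) * _entropy_bits(row / nv)
    return h_y - h_y_given


def _log2_multinomial(counts: np.ndarray) -> float:
    n = counts.sum()
    return (gammaln(n + 1) - gammaln(counts + 1).sum()) / np.log(2)


def _log2_comb(n: float, k: float) -> float:
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(2)


def impurity_score(X, labels, measure: str, bins: int = 4) -> pd.Series:
    """One impurity-based score per species (higher = more informative).

    Continuous abundances are discretised into ``bins`` equal-frequency
    bins; a feature that collapses to a single level scores 0.
    """
    if measure not in IMPURITY_MEASURES:
        raise ValueError(f"unknown impurity measure {measure!r}")
    df = _as_frame(X)
    y = np.asarray(labels)
    classes = np.unique(y)
    out = {}
    for col in df.columns:
        table = _contingency(df[col].to_numpy(dtype=float), y, bins)
        if table.shape[0] < 2:
            out[col] = 0.0
            continue
        n = table.sum()
        pv = table.sum(axis=1) / n
        class_tot = table.sum(axis=0)
        if measure == "GainRatio":
            split = _entropy_bits(pv)
            out[col] = _info_gain(table) / split if split > 0 else 0.0
        elif measure == "UniformInf":
            # reweight samples so every class has equal total mass
            w = (n / classes.size) / np.maximum(class_tot, 1e-300)
            out[col] = _info_gain(table * w[None, :])
        elif measure == "DKM":
            pc = class_tot / n
            dkm_prior = 2.0 * np.sqrt(pc[0] * pc[-1]) if classes.size == 2 \
                else 2.0 * np.sqrt(np.prod(pc))
            post = 0.0
            for row in table:
                nv = row.sum()
                if nv > 0:
                    q = row / nv
                    post += (nv / n) * 2.0 * np.sqrt(q[0] * q[-1])
            out[col] = dkm_prior - post
        elif measure == "MDL":
            C = classes.size
            prior = _log2_multinomial(class_tot) + _log2_comb(n + C - 1,
                                                              C - 1)
            post = 0.0
            for row in table:
                post += _log2_multinomial(row)
                post += _log2_comb(row.sum() + C - 1, C - 1)
            out[col] = (prior - post) / n
        elif measure in ("EqualHellinger", "DistEuclid"):
            with np.errstate(invalid="ignore", divide="ignore"):
                cond = table / np.maximum(class_tot[None, :], 1e-300)
            p0, p1 = cond[:, 0], cond[:, -1]
            if measure == "EqualHellinger":
                out[col] = float(
                    np.linalg.norm(np.sqrt(p0) - np.sqrt(p1)) / np.sqrt(2))
            else:
                out[col] = float(np.linalg.norm(p0 - p1))
    return pd.Series(out, name=measure)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def rank_features(X, labels, K: int = 10, m: int | None = None,
                  bins: int = 4, seed: int = 0,
                  log_transform: bool = True) -> pd.DataFrame:
    """Run all 13 algorithms and return the consensus rank table.

    With ``log_transform`` (default), non-negative abundances are log10
    transformed with a pseudo-count of half the smallest positive value
    before scoring: relative abundances span orders of magnitude, and
    min-max scaling of the raw values concentrates almost all mass near
    zero, starving the Relief neighbourhood geometry of contrast. The
    impurity measures and the myopic variant use equal-frequency
    discretisation and are invariant to this monotone transform.
    """
    df = _as_frame(X)
    if log_transform:
        arr = df.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("log_transform requires non-negative values")
        positives = arr[arr > 0]
        pseudo = positives.min() / 2.0 if positives.size else 1.0
        df = pd.DataFrame(np.log10(arr + pseudo), index=df.index,
                          columns=df.columns)
    scores = {}
    for variant in RELIEF_VARIANTS:
        scores[variant] = relief_score(df, labels, variant=variant, K=K,
                                       m=m, seed=seed)
    for measure in IMPURITY_MEASURES:
        scores[measure] = impurity_score(df, labels, measure, bins=bins)
    return median_rank_consensus(pd.DataFrame(scores))


def median_rank_consensus(score_table: pd.DataFrame,
                          algorithms=ALL_ALGORITHMS) -> pd.DataFrame:
    """Median rank across algorithms; rank 1 = highest score.

    Every algorithm column must be present (a missing ranker fails loudly).
    Ties break lexicographically by species id so each algorithm's ranks
    are a permutation of 1..S. Output is sorted ascending by median rank;
    per-algorithm ranks are retained for rank-dispersion box plots.
    """
    missing = set(algorithms) - set(score_table.columns)
    if missing:
        raise ValueError(f"missing ranking algorithms: {sorted(missing)}")
    S = len(score_table)
    ranks = pd.DataFrame(index=score_table.index)
    order_key = score_table.index.astype(str)
    for alg in algorithms:
        df = pd.DataFrame({"score": score_table[alg].to_numpy(),
                           "id": order_key}, index=score_table.index)
        ordered = df.sort_values(["score", "id"],
                                 ascending=[False, True]).index
        r = pd.Series(np.arange(1, S + 1), index=ordered)
        ranks[f"rank_{alg}"] = r.reindex(score_table.index)
    rank_arr = ranks.to_numpy()
    out = ranks.copy()
    for alg in algorithms:
        out[f"score_{alg}"] = score_table[alg]
    out["median_rank"] = np.median(rank_arr, axis=1)
    q3, q1 = np.percentile(rank_arr, [75, 25], axis=1)
    out["rank_iqr"] = q3 - q1
    out.index.name = "species_id"
    out = out.sort_index(key=lambda ix: ix.astype(str))
    return out.sort_values("median_rank", kind="stable")
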