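"""Alpha and beta diversity of gut microbial communities.

Seven abundance-based alpha indices (Berger-Parker dominance, Simpson's
dominance, Heip's evenness, inverse Simpson, richness, Shannon diversity,
Strong's dominance) plus a reference-free k-mer richness (F0, distinct
k-mer count) describe within-sample diversity. Ten beta indices (Canberra,
Chebyshev, Clark's divergence, correlation distance, Euclidean, geodesic,
Hellinger, Horn-Morisita dissimilarity, Jaccard nestedness, Manhattan)
describe between-sample community differences.

Group comparison treats "beta diversity of a group" as the distribution of
within-group pairwise distances; the two groups are compared per index by
the Wilcoxon rank-sum statistic with Benjamini-Hochberg adjustment across
the beta indices as one family (the alpha indices form their own family).
Pairwise distances that share a sample are not independent, so the
classical rank-sum null is badly anti-conservative here; by default the
rank-sum statistic is therefore referred to its exact label-permutation
null (samples, not distances, are permuted), and the classical asymptotic
p is reported alongside for comparability. Because the outcome groups are
unequal in size, a group-equalised variant repeats the test on random
subsets of the larger group drawn to the smaller group's size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .dissimilarity import DistanceMatrix

ALPHA_INDICES = (
    "berger_parker",
    "simpson",
    "heip_evenness",
    "inverse_simpson",
    "richness",
    "shannon",
    "strong",
)

def _frame_of(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    values = getattr(X, "values", X)
    if isinstance(values, pd.DataFrame):
        return values
    return pd.DataFrame(values)


BETA_INDICES = (
    "canberra",
    "chebyshev",
    "clark",
    "correlation",
    "euclidean",
    "geodesic",
    "hellinger",
    "horn_morisita",
    "jaccard_nestedness",
    "manhattan",
)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(p, index: str) -> float:
    """One alpha index of a relative-abundance vector (zeros allowed)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("empty community")
    p = p / total
    pos = p[p > 0]
    S = pos.size
    if index == "berger_parker":
        return float(pos.max())
    if index == "simpson":
        return float((pos ** 2).sum())
    if index == "inverse_simpson":
        return float(1.0 / (pos ** 2).sum())
    if index == "richness":
        return float(S)
    if index == "shannon":
        return float(-(pos * np.log(pos)).sum())
    if index == "heip_evenness":
        if S == 1:
            warnings.warn("Heip's evenness undefined for a single taxon")
            return float("nan")
        H = -(pos * np.log(pos)).sum()
        return float((np.exp(H) - 1.0) / (S - 1.0))
    if index == "strong":
        # max_i (cumulative share of i most abundant taxa - i/S)
        desc = np.sort(pos)[::-1]
        cum = np.cumsum(desc)
        i = np.arange(1, S + 1)
        return float(np.max(cum - i / S))
    raise ValueError(f"unknown alpha index {index!r}")


def alpha_diversity_table(X, indices=ALPHA_INDICES) -> pd.DataFrame:
    """Per-sample alpha values (rows=samples, columns=indices)."""
    df = _frame_of(X)
    out = {
        idx: [alpha_diversity(row, idx) for row in df.to_numpy(dtype=float)]
        for idx in indices
    }
    return pd.DataFrame(out, index=df.index)


def kmer_f0(reads, k: int) -> int:
    """Distinct k-mer count across a sample's reads (reference-free
    richness). Duplicate reads do not change the result."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kmers: set = set()
    for read in reads:
        for i in range(len(read) - k + 1):
            kmers.add(read[i:i + k])
    return len(kmers)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def _presence_counts(x, y):
    px, py = x > 0, y > 0
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    return a, b, c


def jaccard_nestedness(x, y) -> float:
    """Nestedness-resultant component of Jaccard dissimilarity
    (total Jaccard minus its turnover component), on presence/absence."""
    a, b, c = _presence_counts(np.asarray(x), np.asarray(y))
    if a + b + c == 0:
        warnings.warn("both communities empty; nestedness undefined")
        return float("nan")
    jac = (b + c) / (a + b + c)
    mn = min(b, c)
    jtu = 2 * mn / (a + 2 * mn) if (a + 2 * mn) > 0 else 0.0
    return jac - jtu


def horn_morisita(x, y) -> float:
    """Morisita-Horn dissimilarity (1 - overlap), 0 for identical rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        warnings.warn("empty community; Horn-Morisita undefined")
        return float("nan")
    lx = (x ** 2).sum() / X ** 2
    ly = (y ** 2).sum() / Y ** 2
    overlap = 2 * (x * y).sum() / ((lx + ly) * X * Y)
    return 1.0 - overlap


def beta_distance(x, y, index: str) -> float:
    """One beta index between two non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    if index == "canberra":
        denom = x + y
        mask = denom > 0
        return float(np.sum(np.abs(x - y)[mask] / denom[mask]))
    if index == "chebyshev":
        return float(np.max(np.abs(x - y)))
    if index == "clark":
        denom = x + y
        mask = denom > 0
        return float(np.sqrt(np.sum(((x - y)[mask] / denom[mask]) ** 2)))
    if index == "correlation":
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("zero-variance vector; correlation distance "
                          "undefined")
            return float("nan")
        r = np.corrcoef(x, y)[0, 1]
        return float(1.0 - r)
    if index == "euclidean":
        return float(np.linalg.norm(x - y))
    if index == "geodesic":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            warnings.warn("zero vector; geodesic distance undefined")
            return float("nan")
        # 2*arcsin(chord/2) == arccos(cos) but is well-conditioned near 0
        chord = np.linalg.norm(x / nx - y / ny)
        return float(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
    if index == "hellinger":
        px = x / x.sum() if x.sum() > 0 else x
        py = y / y.sum() if y.sum() > 0 else y
        return float(np.linalg.norm(np.sqrt(px) - np.sqrt(py)))
    if index == "horn_morisita":
        return horn_morisita(x, y)
    if index == "jaccard_nestedness":
        return jaccard_nestedness(x, y)
    if index == "manhattan":
        return float(np.sum(np.abs(x - y)))
    raise ValueError(f"unknown beta index {index!r}")


def pairwise_beta(X, index: str) -> DistanceMatrix:
    """All-pairs beta index over the rows of an abundance matrix."""
    df = _frame_of(X)
    arr = df.to_numpy(dtype=float)
    ids = list(df.index)
    n = arr.shape[0]

    scipy_name = {"canberra": "canberra", "chebyshev": "chebyshev",
                  "euclidean": "euclidean", "manhattan": "cityblock",
                  "correlation": "correlation"}
    if index in scipy_name:
        mat = squareform(pdist(arr, metric=scipy_name[index]))
    elif index == "hellinger":
        closed = arr / arr.sum(axis=1, keepdims=True)
        mat = squareform(pdist(np.sqrt(closed), metric="euclidean"))
    elif index == "geodesic":
        norms = np.linalg.norm(arr, axis=1)
        unit = arr / norms[:, None]
        chord = squareform(pdist(unit, metric="euclidean"))
        mat = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    elif index == "horn_morisita":
        totals = arr.sum(axis=1)
        lam = (arr ** 2).sum(axis=1) / totals ** 2
        cross = arr @ arr.T
        overlap = 2 * cross / ((lam[:, None] + lam[None, :])
                               * np.outer(totals, totals))
        mat = 1.0 - overlap
        np.fill_diagonal(mat, 0.0)
    elif index == "clark":
        mat = np.zeros((n, n))
        for i in range(n):
            diff = arr[i] - arr[i + 1:]
            s = arr[i] + arr[i + 1:]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(s > 0, diff / np.where(s > 0, s, 1.0), 0.0)
            d = np.sqrt((ratio ** 2).sum(axis=1))
            mat[i, i + 1:] = d
            mat[i + 1:, i] = d
    elif index == "jaccard_nestedness":
        pres = (arr > 0).astype(float)
        a = pres @ pres.T
        rs = pres.sum(axis=1).astype(float)
        b = rs[:, None] - a
        c = rs[None, :] - a
        union = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, (b + c) / union, np.nan)
            mn = np.minimum(b, c)
            jtu = np.where(a + 2 * mn > 0, 2 * mn / (a + 2 * mn), 0.0)
        mat = jac - jtu
        np.fill_diagonal(mat, 0.0)
    else:
        raise ValueError(f"unknown beta index {index!r}")
    # numerical guard: tiny negatives from floating point
    finite = np.isfinite(mat)
    mat[finite & (np.abs(mat) < 1e-12)] = 0.0
    return DistanceMatrix(ids, mat, allow_nan=True)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _within_group_distances(D: DistanceMatrix, labels) -> dict:
    labels = np.asarray(labels)
    out = {}
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = D.matrix[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(idx.size, k=1)]
        out[g] = vals[np.isfinite(vals)]
    return out


def _permutation_ranksum_p(D: DistanceMatrix, labels, case_label,
                           n_perm: int, rng) -> float:
    """Exact label-permutation p for the rank-sum comparison of within-group
    distances.

    Permuting sample labels keeps the two groups' pair counts fixed, so the
    Mann-Whitney U statistic (computed with midrank tie handling) is
    equivalent to the mean-rank difference and can be evaluated for all
    permutations at once from a single sort of the distances.
    """
    labels = np.asarray(labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    vals = D.matrix[iu]
    finite = np.isfinite(vals)
    order = np.argsort(vals[finite], kind="stable")
    i_idx = iu[0][finite][order]
    j_idx = iu[1][finite][order]
    v = vals[finite][order]
    # blocks of tied distance values, for midrank handling
    starts = np.flatnonzero(np.r_[True, v[1:] != v[:-1]])
    block_of = np.cumsum(np.r_[True, v[1:] != v[:-1]]) - 1

    perms = np.empty((n_perm + 1, n), dtype=labels.dtype)
    perms[0] = labels
    for t in range(n_perm):
        perms[t + 1] = labels[rng.permutation(n)]
    li = perms[:, i_idx]
    lj = perms[:, j_idx]
    same = li == lj
    case_pair = same & (li == case_label)
    ctrl_pair = same & ~(li == case_label)
    # per tied block: #ctrl pairs inside; #ctrl pairs strictly before it
    ctrl_in_block = np.add.reduceat(ctrl_pair, starts, axis=1)
    ctrl_before = np.cumsum(ctrl_in_block, axis=1) - ctrl_in_block
    # U = sum over case pairs of (#ctrl below + 0.5 * #ctrl tied)
    per_item = ctrl_before[:, block_of] + 0.5 * ctrl_in_block[:, block_of]
    U = np.where(case_pair, per_item, 0.0).sum(axis=1)
    m1 = case_pair[0].sum()
    m2 = ctrl_pair[0].sum()
    stat = np.abs(U - m1 * m2 / 2.0)
    exceed = int((stat[1:] >= stat[0]).sum())
    return (1.0 + exceed) / (1.0 + n_perm)


def compare_group_beta(distances: dict, labels, case_label=1,
                       bh_family: bool = True, p_mode: str = "permutation",
                       n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Compare within-group distance distributions per beta index.

    ``distances`` maps index name -> :class:`DistanceMatrix`. The rank-sum
    statistic compares the two groups' within-group distances; its p-value
    is computed by sample-label permutation by default (``p_mode =
    "permutation"``), because the distances are mutually dependent and the
    classical rank-sum null (reported as ``p_asymptotic``) is
    anti-conservative. Returns a tidy frame with p, BH-adjusted p (family =
    the provided indices) and the case/control mean fold change as percent
    difference.
    """
    if p_mode not in ("permutation", "asymptotic"):
        raise ValueError("p_mode must be 'permutation' or 'asymptotic'")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for index, D in distances.items():
        within = _within_group_distances(D, labels)
        case = within[case_label]
        ctrl_label = [g for g in within if g != case_label][0]
        ctrl = within[ctrl_label]
        if np.all(case == case[0]) and np.all(ctrl == ctrl[0]) \
                and case[0] == ctrl[0]:
            warnings.warn(f"{index}: all within-group distances identical; "
                          "test undefined")
            p = p_asym = np.nan
        else:
            p_asym = float(mannwhitneyu(case, ctrl,
                                        alternative="two-sided").pvalue)
            if p_mode == "permutation":
                p = _permutation_ranksum_p(D, labels, case_label, n_perm,
                                           rng)
            else:
                p = p_asym
        mc, mn = case.mean(), ctrl.mean()
        fold_pct = 100.0 * (mc / mn - 1.0) if mn > 0 else np.nan
        rows.append({"index": index, "mean_case": mc, "mean_control": mn,
                     "fold_change_pct": fold_pct, "p": p,
                     "p_asymptotic": p_asym})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if bh_family and mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"],
                                               method="fdr_bh")[1]
    elif mask.any():
        out.loc[mask, "p_adj"] = out.loc[mask, "p"]
    return out


def compare_group_alpha(alpha_table: pd.DataFrame, labels,
                        case_label=1) -> pd.DataFrame:
    """Wilcoxon comparison of per-sample alpha indices between groups,
    BH-adjusted across the alpha indices as one family."""
    labels = np.asarray(labels)
    rows = []
    for index in alpha_table.columns:
        vals = alpha_table[index].to_numpy(dtype=float)
        case = vals[labels == case_label]
        ctrl = vals[labels != case_label]
        case, ctrl = case[np.isfinite(case)], ctrl[np.isfinite(ctrl)]
        p = float(mannwhitneyu(case, ctrl, alternative="two-sided").pvalue) \
            if case.size and ctrl.size else np.nan
        fold_pct = (100.0 * (case.mean() / ctrl.mean() - 1.0)
                    if ctrl.size and ctrl.mean() != 0 else np.nan)
        rows.append({"index": index, "mean_case": case.mean(),
                     "mean_control": ctrl.mean(),
                     "fold_change_pct": fold_pct, "p": p})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"],
                                               method="fdr_bh")[1]
    return out


def group_equalized_beta_test(
    distances: dict,
    labels,
    n_subsets: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    case_label=1,
    p_mode: str = "permutation",
    n_perm: int = 199,
) -> pd.DataFrame:
    """Repeat the within-group beta comparison on size-equalised subsets.

    Each subset samples, without replacement, from the larger group a
    subset matching the smaller group's size; the per-index rank-sum test
    (permutation p by default, see :func:`compare_group_beta`) with BH
    adjustment is run on every subset. Returns per index the fraction of
    subsets significant at ``alpha`` (adjusted p) and the dominant
    direction of the effect.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if counts[0] == counts[1]:
        warnings.warn("groups already equal in size; nothing to equalise")
        base = compare_group_beta(distances, labels, case_label,
                                  p_mode=p_mode, n_perm=n_perm, seed=seed)
        base["fraction_significant"] = (base["p_adj"] <= alpha).astype(float)
        return base[["index", "fraction_significant"]]
    larger = groups[np.argmax(counts)]
    small_n = counts.min()
    large_idx = np.flatnonzero(labels == larger)
    keep_idx = np.flatnonzero(labels != larger)

    rng = np.random.default_rng(seed)
    sig = {index: 0 for index in distances}
    lower_in_case = {index: 0 for index in distances}
    for sub_i in range(n_subsets):
        sub = rng.choice(large_idx, size=small_n, replace=False)
        idx = np.concatenate([keep_idx, sub])
        sub_labels = labels[idx]
        sub_D = {
            name: DistanceMatrix([D.ids[i] for i in idx],
                                 D.matrix[np.ix_(idx, idx)], allow_nan=True)
            for name, D in distances.items()
        }
        res = compare_group_beta(sub_D, sub_labels, case_label,
                                 p_mode=p_mode, n_perm=n_perm,
                                 seed=seed + 7919 * (sub_i + 1))
        for _, r in res.iterrows():
            # "<=" so that a permutation test with alpha*(1+n_perm) integral
            # has exact size alpha under the add-one p convention
            if np.isfinite(r["p_adj"]) and r["p_adj"] <= alpha:
                sig[r["index"]] += 1
                if r["mean_case"] < r["mean_control"]:
                    lower_in_case[r["index"]] += 1
    rows = []
    for index in distances:
        frac = sig[index] / n_subsets
        direction = ("case_lower"
                     if sig[index] and lower_in_case[index] >= sig[index] / 2
                     else "case_higher" if sig[index] else "none")
        rows.append({"index": index, "fraction_significant": frac,
                     "direction": direction})
    return pd.DataFrame(rows)
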