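"""Per-species association screens and the clinical logistic regressions.

Each screen tests every species' abundance against the binary aGvHD outcome
and emits the shared tidy association-table schema (species_id, statistic,
effect_size, direction, p, p_adj, adjust_method) so the consensus caller
can join screens on species id:

* Wilcoxon rank-sum with a log2 fold-change of group-mean abundance;
* indicator-species statistics: group-equalised indicator value IndVal.g
  (geometric mean of specificity A and fidelity B) and the group-equalised
  point-biserial correlation r.g, both with permutation p-values;
* a sign-association permutation test for the group with higher mean
  abundance (Sidak-adjusted p alongside BH);
* plug-in conditional mutual information I(species; outcome | confounder)
  in bits on equal-frequency-discretised abundances;
* Spearman correlation against the outcome and a clinical covariate.

Permutation p-values use the (1 + exceedances) / (1 + n_perm) convention
throughout and are therefore never zero.

The clinical side fits univariable and multivariable logistic regressions
of aGvHD on ten pre-transplant covariates, with outcome-stratified median
imputation of missing Karnofsky scores and the dichotomisations used for
age (<60 vs >=60) and Karnofsky (<90 vs >=90).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .containers import ASSOCIATION_COLUMNS, CLINICAL_LEVELS

DEFAULT_N_PERM = 10_000


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    values = getattr(X, "values", X)
    if isinstance(values, pd.DataFrame):
        return values
    return pd.DataFrame(values)


def _finish_table(df: pd.DataFrame, method: str = "BH") -> pd.DataFrame:
    mask = df["p"].notna()
    df["p_adj"] = np.nan
    if mask.any():
        if method == "BH":
            df.loc[mask, "p_adj"] = multipletests(df.loc[mask, "p"],
                                                  method="fdr_bh")[1]
        elif method == "Sidak":
            m = int(mask.sum())
            df.loc[mask, "p_adj"] = 1.0 - (1.0 - df.loc[mask, "p"]) ** m
        else:
            df.loc[mask, "p_adj"] = df.loc[mask, "p"]
    df["adjust_method"] = method
    return df[ASSOCIATION_COLUMNS]


def _direction(diff: np.ndarray) -> np.ndarray:
    return np.where(diff > 0, "aGvHD", np.where(diff < 0, "NaGvHD", "none"))


# ---------------------------------------------------------------------------
# Wilcoxon screen
# ---------------------------------------------------------------------------

def wilcoxon_screen(X, labels) -> pd.DataFrame:
    """Rank-sum test per species with log2 fold-change of group means.

    Groups with zero mean abundance get a pseudo-count of half the smallest
    positive abundance in the matrix before the fold change is taken.
    """
    df = _as_frame(X)
    labels = np.asarray(labels)
    case, ctrl = df.to_numpy()[labels == 1], df.to_numpy()[labels == 0]
    if not case.size or not ctrl.size:
        raise ValueError("both groups must be non-empty")

    constant = np.array([np.unique(df[c]).size == 1 for c in df.columns])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = mannwhitneyu(case, ctrl, alternative="two-sided", axis=0).pvalue
    p = np.where(constant, np.nan, p)

    mc, mn = case.mean(axis=0), ctrl.mean(axis=0)
    positives = df.to_numpy()[df.to_numpy() > 0]
    pseudo = positives.min() / 2.0 if positives.size else 1e-12
    lfc = np.log2(np.where(mc > 0, mc, pseudo) / np.where(mn > 0, mn, pseudo))

    out = pd.DataFrame({
        "species_id": df.columns,
        "statistic": "wilcoxon_log2fc",
        "effect_size": lfc,
        "direction": _direction(mc - mn),
        "p": p,
    })
    return _finish_table(out)


# ---------------------------------------------------------------------------
# indicator species statistics
# ---------------------------------------------------------------------------

def _group_equalized_A(case_mean, ctrl_mean):
    tot = case_mean + ctrl_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        a_case = np.where(tot > 0, case_mean / tot, np.nan)
    return a_case


def indval_g(
    X, labels,
    min_B: float = 0.2,
    min_A: float = 0.5,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-equalised indicator value per species.

    Specificity A_g = group-mean abundance over the sum of both group
    means; fidelity B_g = within-group prevalence. IndVal.g =
    sqrt(A_g B_g) for the better group. Species whose best group fails
    B >= min_B or A >= min_A (inclusive bounds) are excluded before the
    permutation test; species absent everywhere are excluded with a note.
    """
    df = _as_frame(X)
    labels = np.asarray(labels)
    arr = df.to_numpy(dtype=float)
    is_case = labels == 1

    def _stat(case_mask):
        mc = arr[case_mask].mean(axis=0)
        mn = arr[~case_mask].mean(axis=0)
        a_case = _group_equalized_A(mc, mn)
        b_case = (arr[case_mask] > 0).mean(axis=0)
        b_ctrl = (arr[~case_mask] > 0).mean(axis=0)
        iv_case = np.sqrt(np.nan_to_num(a_case) * b_case)
        iv_ctrl = np.sqrt(np.nan_to_num(1 - a_case) * b_ctrl)
        best_case = iv_case >= iv_ctrl
        iv = np.where(best_case, iv_case, iv_ctrl)
        a_best = np.where(best_case, a_case, 1 - a_case)
        b_best = np.where(best_case, b_case, b_ctrl)
        return iv, a_best, b_best, best_case

    iv_obs, a_best, b_best, best_case = _stat(is_case)
    absent = arr.sum(axis=0) == 0
    passes = (~absent) & (b_best >= min_B) & (a_best >= min_A)
    if absent.any():
        warnings.warn(f"{int(absent.sum())} species absent everywhere; "
                      "excluded")

    rng = np.random.default_rng(seed)
    exceed = np.zeros(arr.shape[1])
    for _ in range(n_perm):
        perm_mask = np.zeros(len(labels), dtype=bool)
        perm_mask[rng.permutation(len(labels))[:is_case.sum()]] = True
        iv_p, _, _, _ = _stat(perm_mask)
        exceed += iv_p >= iv_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    out = pd.DataFrame({
        "species_id": df.columns[passes],
        "statistic": "indval_g",
        "effect_size": iv_obs[passes],
        "direction": np.where(best_case[passes], "aGvHD", "NaGvHD"),
        "p": p[passes],
    })
    out = _finish_table(out)
    out.attrs["n_filtered_out"] = int((~passes).sum())
    out.attrs["A"] = dict(zip(df.columns, a_best))
    out.attrs["B"] = dict(zip(df.columns, b_best))
    return out


def pointbiserial_rg(X, labels, n_perm: int = DEFAULT_N_PERM,
                     seed: int = 0) -> pd.DataFrame:
    """Group-equalised point-biserial correlation per species.

    Each group is weighted to equal total weight (as if the design were
    balanced), then the weighted Pearson correlation between abundance and
    the group indicator is computed. Two-sided permutation p on |r|.
    """
    df = _as_frame(X)
    labels = np.asarray(labels)
    arr = df.to_numpy(dtype=float)
    n = len(labels)
    y = (labels == 1).astype(float)

    def _rg(yv):
        n1 = yv.sum()
        n0 = n - n1
        w = np.where(yv == 1, 0.5 / n1, 0.5 / n0)
        mx = w @ arr
        my = w @ yv
        cov = (w[:, None] * (arr - mx) * (yv - my)[:, None]).sum(axis=0)
        vx = (w[:, None] * (arr - mx) ** 2).sum(axis=0)
        vy = (w * (yv - my) ** 2).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(vx > 0, cov / np.sqrt(vx * vy), np.nan)

    r_obs = _rg(y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(arr.shape[1])
    for _ in range(n_perm):
        r_p = _rg(y[rng.permutation(n)])
        exceed += np.abs(np.nan_to_num(r_p)) >= np.abs(np.nan_to_num(r_obs))
    p = np.where(np.isnan(r_obs), np.nan, (1.0 + exceed) / (1.0 + n_perm))

    out = pd.DataFrame({
        "species_id": df.columns,
        "statistic": "pointbiserial_rg",
        "effect_size": r_obs,
        "direction": _direction(np.nan_to_num(r_obs)),
        "p": p,
    })
    return _finish_table(out)


def sign_association(X, labels, n_perm: int = DEFAULT_N_PERM,
                     seed: int = 0) -> pd.DataFrame:
    """Permutation test of the group with higher mean abundance.

    The favoured direction is chosen from the data, so the permutation
    null uses the best-direction statistic |mean difference| on both
    sides, keeping the test exact. Sidak adjustment is reported (BH is a
    re-run with ``_finish_table``).
    """
    df = _as_frame(X)
    labels = np.asarray(labels)
    arr = df.to_numpy(dtype=float)
    is_case = labels == 1
    n1 = int(is_case.sum())

    def _absdiff(mask):
        return np.abs(arr[mask].mean(axis=0) - arr[~mask].mean(axis=0))

    diff = arr[is_case].mean(axis=0) - arr[~is_case].mean(axis=0)
    obs = np.abs(diff)
    tie = diff == 0
    if tie.any():
        warnings.warn(f"{int(tie.sum())} species with tied group means; "
                      "direction undefined")

    rng = np.random.default_rng(seed)
    exceed = np.zeros(arr.shape[1])
    for _ in range(n_perm):
        mask = np.zeros(len(labels), dtype=bool)
        mask[rng.permutation(len(labels))[:n1]] = True
        exceed += _absdiff(mask) >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    out = pd.DataFrame({
        "species_id": df.columns,
        "statistic": "sign_association",
        "effect_size": diff,
        "direction": _direction(diff),
        "p": np.where(tie, np.nan, p),
    })
    return _finish_table(out, method="Sidak")


# ---------------------------------------------------------------------------
# conditional mutual information
# ---------------------------------------------------------------------------

def _discretize_equal_freq(x: np.ndarray, nbins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, nbins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def _mi_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    xs, x_idx = np.unique(x, return_inverse=True)
    ys, y_idx = np.unique(y, return_inverse=True)
    joint = np.zeros((xs.size, ys.size))
    np.add.at(joint, (x_idx, y_idx), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def conditional_mi(
    X, labels, confounder,
    bins_rule: str = "cube_root",
    min_level_size: int = 5,
    small_level_policy: str = "merge",
) -> pd.DataFrame:
    """Conditional mutual information I(species; outcome | confounder).

    Abundances are discretised per species by equal-frequency binning with
    floor(N^(1/3)) bins (the ``cube_root`` rule). The CMI is the
    confounder-level-weighted average of the within-level MI, in bits; the
    marginal MI with the confounder is reported as a companion statistic.
    Confounder levels with fewer than ``min_level_size`` samples are merged
    into one pooled level (or the run fails if policy is ``raise``).
    """
    df = _as_frame(X)
    labels = np.asarray(labels)
    z = np.asarray(confounder)
    n = len(labels)
    if bins_rule == "cube_root":
        nbins = max(2, int(np.floor(n ** (1 / 3))))
    else:
        nbins = int(bins_rule)

    levels, counts = np.unique(z, return_counts=True)
    small = levels[counts < min_level_size]
    if small.size:
        if small_level_policy == "merge":
            warnings.warn(f"merging {small.size} small confounder levels")
            z = np.where(np.isin(z, small), "_pooled", z.astype(str))
        else:
            raise ValueError(f"confounder levels with <{min_level_size} "
                             f"samples: {small.tolist()}")

    rows = []
    for col in df.columns:
        xd = _discretize_equal_freq(df[col].to_numpy(dtype=float), nbins)
        cmi = 0.0
        for lev in np.unique(z):
            m = z == lev
            cmi += m.mean() * _mi_bits(xd[m], labels[m])
        rows.append({
            "species_id": col,
            "statistic": "conditional_mi_bits",
            "effect_size": cmi,
            "direction": "none",
            "p": np.nan,
            "mi_with_confounder": _mi_bits(xd, z),
        })
    out = pd.DataFrame(rows)
    out = _finish_table(out, method="none").join(
        pd.DataFrame(rows)["mi_with_confounder"])
    return out


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_assoc(X, labels, covariate=None) -> pd.DataFrame:
    """Spearman rho of every species against the outcome (and optionally a
    clinical covariate, added as ``rho_covariate``)."""
    df = _as_frame(X)
    labels = np.asarray(labels, dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, df.to_numpy(dtype=float))

    def _rho(target):
        rt = rankdata(target)
        rt = (rt - rt.mean()) / rt.std()
        rs = ranks - ranks.mean(axis=0)
        sd = rs.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, (rs * rt[:, None]).mean(axis=0) / sd,
                            np.nan)

    rho = _rho(labels)
    out = pd.DataFrame({
        "species_id": df.columns,
        "statistic": "spearman_rho",
        "effect_size": rho,
        "direction": _direction(np.nan_to_num(rho)),
        "p": np.nan,
    })
    out = _finish_table(out, method="none")
    if covariate is not None:
        cov = pd.factorize(np.asarray(covariate))[0].astype(float) \
            if not np.issubdtype(np.asarray(covariate).dtype, np.number) \
            else np.asarray(covariate, dtype=float)
        out["rho_covariate"] = _rho(cov)
    return out


def top_by_abs_rho(table: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Helper for the correlation heat-map: top-|rho| species."""
    return table.reindex(
        table["effect_size"].abs().sort_values(ascending=False).index
    ).head(n)


# ---------------------------------------------------------------------------
# clinical logistic regression
# ---------------------------------------------------------------------------

CLINICAL_PREDICTORS = [
    "conditioning", "cyclophosphamide", "disease_group", "dr_relationship",
    "donor_sex", "karnofsky_d0", "radiation_group", "recipient_age",
    "recipient_sex", "transplant_source",
]


def prepare_clinical_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with dichotomised, 0/1-coded predictors.

    Karnofsky missing values are imputed with the median across patients
    with the same outcome; age is dichotomised at 60, Karnofsky at 90.
    """
    pat = cohort.drop_duplicates("patient_id").set_index("patient_id").copy()
    for outcome in (0, 1):
        m = pat["outcome"] == outcome
        med = pat.loc[m, "karnofsky_d0"].median()
        pat.loc[m, "karnofsky_d0"] = pat.loc[m, "karnofsky_d0"].fillna(med)
    design = pd.DataFrame(index=pat.index)
    design["outcome"] = pat["outcome"].astype(int)
    for var, (_, alt) in CLINICAL_LEVELS.items():
        design[var] = (pat[var] == alt).astype(float)
    design["recipient_age"] = (pat["recipient_age"] >= 60).astype(float)
    design["karnofsky_d0"] = (pat["karnofsky_d0"] >= 90).astype(float)
    return design


def fit_clinical_logistic(cohort: pd.DataFrame,
                          mode: str = "multivariable") -> dict:
    """Logistic regression of aGvHD on the ten clinical predictors.

    Returns a dict with the coefficient ``table`` (beta, SE, z, p, 95% CI,
    VIF), AIC/BIC and the McFadden and Cragg-Uhler pseudo-R2 variants (for
    multivariable mode; univariable mode returns one single-predictor fit
    per row, VIF not applicable).
    """
    if mode not in ("univariable", "multivariable"):
        raise ValueError("mode must be univariable or multivariable")
    design = prepare_clinical_design(cohort)
    y = design.pop("outcome")

    def _fit(cols):
        Xd = sm.add_constant(design[cols], has_constant="add")
        model = sm.Logit(y, Xd)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:  # noqa: BLE001 - singular Hessian under
            # (quasi-)separation; BFGS still yields the point estimates,
            # though Wald standard errors may come out NaN
            try:
                res = model.fit(disp=0, maxiter=500, method="bfgs")
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"logistic fit failed (possible perfect separation) for "
                    f"{cols}: {exc}") from exc
            warnings.warn(
                f"quasi-separation in logistic fit for {cols}; standard "
                f"errors may be unavailable")
        if not res.mle_retvals.get("converged", True):
            warnings.warn(f"logistic fit did not converge for {cols}")
        return res

    if mode == "multivariable":
        res = _fit(CLINICAL_PREDICTORS)
        ci = res.conf_int()
        Xd = sm.add_constant(design[CLINICAL_PREDICTORS],
                             has_constant="add").to_numpy(dtype=float)
        vifs = [np.nan] + [variance_inflation_factor(Xd, i)
                           for i in range(1, Xd.shape[1])]
        table = pd.DataFrame({
            "beta": res.params, "se": res.bse, "z": res.tvalues,
            "p": res.pvalues, "ci_low": ci[0], "ci_high": ci[1],
            "vif": vifs,
        })
        n = len(y)
        mcfadden = 1.0 - res.llf / res.llnull
        cox_snell = 1.0 - np.exp(2.0 * (res.llnull - res.llf) / n)
        cragg_uhler = cox_snell / (1.0 - np.exp(2.0 * res.llnull / n))
        return {
            "mode": mode, "table": table, "aic": float(res.aic),
            "bic": float(res.bic),
            "pseudo_r2_mcfadden": float(mcfadden),
            "pseudo_r2_cragg_uhler": float(cragg_uhler),
        }

    rows = []
    for var in CLINICAL_PREDICTORS:
        res = _fit([var])
        ci = res.conf_int()
        rows.append({
            "variable": var, "beta": res.params[var], "se": res.bse[var],
            "z": res.tvalues[var], "p": res.pvalues[var],
            "ci_low": ci.loc[var, 0], "ci_high": ci.loc[var, 1],
            "vif": np.nan,
        })
    return {"mode": mode, "table": pd.DataFrame(rows).set_index("variable")}
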