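"""Multi-method consensus species call.

A species is called a consensus aGvHD-associated species when three
independent method families agree: (1) at least one indicator-species
statistic (IndVal.g, point-biserial r.g or the sign-association test) is
significant at the raw-p level alpha, (2) the Wilcoxon screen is
significant at the same level, and (3) the species' median rank across the
13 relief/impurity rankers is within the top ``top_n``. The intersection
criterion is deliberately conjunctive, so tightening alpha or top_n can
only remove species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def consensus_species(
    indicator: pd.DataFrame,
    wilcoxon: pd.DataFrame,
    ranks: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int = 20,
) -> pd.DataFrame:
    """Intersect the three method families into the consensus call.

    ``indicator`` may hold several stacked statistics (IndVal.g, r.g,
    sign-association) in the shared association-table schema; a species'
    indicator flag is set when any of them has raw p < alpha. Returns one
    row per consensus species sorted by median rank, with the per-family
    flags and a supporting snapshot of statistics.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ind_sig = (
        indicator[indicator["p"] < alpha]
        .groupby("species_id")
        .agg(indicator_stats=("statistic", lambda s: ",".join(sorted(set(s)))),
             indicator_min_p=("p", "min"))
    )
    wil = wilcoxon.set_index("species_id")
    wil_sig = wil[wil["p"] < alpha]
    rank_sig = ranks[ranks["median_rank"] <= top_n]

    species = sorted(
        set(ind_sig.index) & set(wil_sig.index) & set(rank_sig.index),
        key=str,
    )
    rows = []
    for sid in species:
        rows.append({
            "species_id": sid,
            "indicator": True,
            "wilcoxon": True,
            "rank_consensus": True,
            "direction": wil_sig.loc[sid, "direction"],
            "median_rank": float(rank_sig.loc[sid, "median_rank"]),
            "wilcoxon_p": float(wil_sig.loc[sid, "p"]),
            "log2_fold_change": float(wil_sig.loc[sid, "effect_size"]),
            "indicator_stats": ind_sig.loc[sid, "indicator_stats"],
            "indicator_min_p": float(ind_sig.loc[sid, "indicator_min_p"]),
        })
    out = pd.DataFrame(rows, columns=[
        "species_id", "indicator", "wilcoxon", "rank_consensus", "direction",
        "median_rank", "wilcoxon_p", "log2_fold_change", "indicator_stats",
        "indicator_min_p"])
    if len(out):
        out = out.sort_values("median_rank", kind="stable")
    return out.reset_index(drop=True)


def flag_table(
    indicator: pd.DataFrame,
    wilcoxon: pd.DataFrame,
    ranks: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int = 20,
) -> pd.DataFrame:
    """Per-species membership flags for all three families (diagnostics)."""
    all_ids = sorted(set(wilcoxon["species_id"]) | set(ranks.index.astype(str)),
                     key=str)
    ind_p = indicator.groupby("species_id")["p"].min()
    wil = wilcoxon.set_index("species_id")
    out = pd.DataFrame(index=pd.Index(all_ids, name="species_id"))
    out["indicator"] = ind_p.reindex(out.index).lt(alpha).fillna(False)
    out["wilcoxon"] = wil["p"].reindex(out.index).lt(alpha).fillna(False)
    med = ranks["median_rank"]
    med.index = med.index.astype(str)
    out["rank_consensus"] = med.reindex(out.index).le(top_n).fillna(False)
    out["consensus"] = out.all(axis=1)
    return out
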