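"""Perturbagen LFC scoring, directional drug ranking and conflict filtering.

The drug-by-gene score is the replicate-aggregated log2 fold change
log2(mean of treatment replicates) - log2(mean of control replicates),
means taken on the linear scale (log2-of-mean, not mean-of-log2).  Drugs
are ranked per plan target in the desired direction, drugs that move other
plan targets against their plane beyond a tolerance are excluded, and for
each target the surviving drug with the least guard-set damage is flagged
recommended.
"""

from __future__ import annotations

import difflib
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deg import RepositioningPlan
from .correlation import GuardSet
from .simulate import PerturbagenSet

__all__ = [
    "filter_perturbagens",
    "compute_drug_lfc",
    "rank_drugs_for_gene",
    "panel_conflict_score",
    "filter_contradictory",
    "guard_conflict_report",
]

_TABLE_COLS = [
    "drug_id",
    "target_gene",
    "plane",
    "target_lfc",
    "rank",
    "panel_conflict",
    "guard_conflict",
    "excluded",
    "exclusion_reason",
]


def filter_perturbagens(
    pset: PerturbagenSet, dose: str, time: str
) -> tuple[PerturbagenSet, pd.DataFrame]:
    """Keep treatment and control samples matching the dose/time criteria.

    Returns the filtered set and a dropped-drugs report (drug_id,
    n_samples_dropped) listing drugs whose every replicate failed the
    filter.
    """
    meta = pset.meta
    match = (meta["dose"] == dose) & (meta["time"] == time)
    treat = match & ~meta["is_control"]
    ctrl = match & meta["is_control"]
    if not treat.any():
        raise ValueError(f"no treatment samples at dose={dose!r}, time={time!r}")
    if not ctrl.any():
        raise ValueError(f"no control samples at dose={dose!r}, time={time!r}")
    kept_drugs = set(meta.loc[treat, "drug_id"])
    dropped = (
        meta[~meta["is_control"] & ~meta["drug_id"].isin(kept_drugs)]
        .groupby("drug_id")
        .size()
        .rename("n_samples_dropped")
        .reset_index()
    )
    keep = match
    sub = PerturbagenSet(
        values=pset.values.loc[:, keep[keep].index], meta=meta.loc[keep].copy()
    )
    return sub, dropped


def compute_drug_lfc(pset: PerturbagenSet, pseudocount: float = 0.0) -> pd.DataFrame:
    """Replicate-aggregated log2 fold change per (gene, drug) vs controls.

    lfc(g, d) = log2(mean over d's replicates of value(g, .) + pseudocount)
              - log2(mean over control samples of value(g, .) + pseudocount)
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {pseudocount!r}")
    meta = pset.meta
    ctrl_cols = meta.index[meta["is_control"]]
    ctrl_mean = pset.values[ctrl_cols].mean(axis=1) + pseudocount
    if (ctrl_mean <= 0).any():
        raise ValueError(
            "control mean is zero for some gene; supply a positive pseudocount"
        )
    drugs = sorted(meta.loc[~meta["is_control"], "drug_id"].unique())
    out = {}
    log_ctrl = np.log2(ctrl_mean)
    for d in drugs:
        cols = meta.index[(meta["drug_id"] == d) & ~meta["is_control"]]
        t_mean = pset.values[cols].mean(axis=1) + pseudocount
        if (t_mean <= 0).any():
            raise ValueError(
                f"treatment mean is zero for drug {d!r}; supply a positive pseudocount"
            )
        out[d] = np.log2(t_mean) - log_ctrl
    return pd.DataFrame(out, index=pset.values.index)


def rank_drugs_for_gene(
    lfc: pd.DataFrame, gene: str, plane: str, k: int = 50
) -> pd.DataFrame:
    """Top-k drugs moving ``gene`` along ``plane`` (Up: largest lfc first).

    Ties are broken lexicographically by drug id.  Returns columns drug_id,
    lfc, rank.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k!r}")
    if plane not in {"Up", "Down"}:
        raise ValueError(f"plane must be Up or Down, got {plane!r}")
    if gene not in lfc.index:
        near = difflib.get_close_matches(gene, list(lfc.index), n=3)
        raise KeyError(f"gene {gene!r} not in LFC matrix; nearest matches: {near}")
    row = lfc.loc[gene]
    df = pd.DataFrame({"drug_id": row.index, "lfc": row.to_numpy()})
    ascending = plane == "Down"
    df = df.sort_values(
        ["lfc", "drug_id"], ascending=[ascending, True], kind="mergesort"
    ).head(k)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def panel_conflict_score(
    drug: str,
    plan: RepositioningPlan,
    lfc: pd.DataFrame,
    exclude: str,
) -> float:
    """Total anti-plane movement a drug inflicts on the other plan targets.

    For each plan gene g != exclude the drug contributes
    max(0, s(g) * (-lfc(g, drug))) with s = +1 for plane Up and -1 for
    plane Down; 0 means the drug compromises no other target.
    """
    score = 0.0
    for g, p in plan.targets.items():
        if g == exclude:
            continue
        v = float(lfc.at[g, drug])
        s = 1.0 if p == "Up" else -1.0
        score += max(0.0, s * -v)
    return score


def _conflicting_genes(
    drug: str, plan: RepositioningPlan, lfc: pd.DataFrame, exclude: str
) -> list[str]:
    bad = []
    for g, p in plan.targets.items():
        if g == exclude:
            continue
        v = float(lfc.at[g, drug])
        s = 1.0 if p == "Up" else -1.0
        if s * -v > 0:
            bad.append(g)
    return bad


def filter_contradictory(
    ranked: Mapping[str, pd.DataFrame],
    plan: RepositioningPlan,
    lfc: pd.DataFrame,
    tau: float = 0.0,
) -> pd.DataFrame:
    """Exclude ranked drugs whose panel-conflict score exceeds ``tau``.

    ``ranked`` maps target gene -> output of :func:`rank_drugs_for_gene`.
    Surviving rows are re-ranked 1..k within each target; excluded rows are
    kept with a reason naming the compromised genes.
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau!r}")
    rows = []
    for gene, table in ranked.items():
        plane = plan.targets[gene]
        surviving = 0
        for _, r in table.iterrows():
            drug = r["drug_id"]
            conflict = panel_conflict_score(drug, plan, lfc, exclude=gene)
            excluded = conflict > tau
            reason = ""
            if excluded:
                bad = _conflicting_genes(drug, plan, lfc, exclude=gene)
                reason = f"anti-plane effect on {','.join(bad)} (conflict {conflict:.4g} > tau {tau:.4g})"
            else:
                surviving += 1
            rows.append(
                {
                    "drug_id": drug,
                    "target_gene": gene,
                    "plane": plane,
                    "target_lfc": float(r["lfc"]),
                    "rank": 0,
                    "panel_conflict": conflict,
                    "guard_conflict": 0.0,
                    "excluded": excluded,
                    "exclusion_reason": reason,
                }
            )
        if surviving == 0:
            warnings.warn(f"no candidate survives tau={tau} for target {gene!r}")
    df = pd.DataFrame(rows, columns=_TABLE_COLS)
    for gene, idx in df.groupby("target_gene").groups.items():
        sub = df.loc[idx]
        kept = sub[~sub["excluded"]]
        df.loc[kept.index, "rank"] = np.arange(1, len(kept) + 1)
    return df


def guard_conflict_report(
    candidates: pd.DataFrame,
    guards: Sequence[GuardSet],
    lfc: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score each candidate row against its target's guard genes.

    guard_conflict is the total downregulation a drug inflicts on the guard
    genes, sum over guard genes h of max(0, -lfc(h, drug)); rows whose
    target has no guard set score 0.  Per target the surviving
    (non-excluded) drug with minimal guard_conflict is flagged
    ``recommended`` (ties: larger |target_lfc|, then drug id).  Also
    returns a detail table with lfc per (drug, guard gene).
    """
    guard_by_cand = {g.candidate: g for g in guards}
    out = candidates.copy()
    out["guard_conflict"] = 0.0
    out["recommended"] = False
    detail_rows = []
    for i, row in out.iterrows():
        gset = guard_by_cand.get(row["target_gene"])
        if gset is None or not gset.guard_genes:
            continue
        total = 0.0
        for h in sorted(gset.guard_genes):
            v = float(lfc.at[h, row["drug_id"]]) if h in lfc.index else 0.0
            total += max(0.0, -v)
            detail_rows.append(
                {
                    "target_gene": row["target_gene"],
                    "drug_id": row["drug_id"],
                    "guard_gene": h,
                    "lfc": v,
                }
            )
        out.at[i, "guard_conflict"] = total
    for gene, idx in out.groupby("target_gene").groups.items():
        sub = out.loc[idx]
        kept = sub[~sub["excluded"]]
        if len(kept) == 0:
            continue
        order = kept.sort_values(
            ["guard_conflict", "target_lfc", "drug_id"],
            ascending=[True, True, True],
            key=lambda s: -s.abs() if s.name == "target_lfc" else s,
            kind="mergesort",
        )
        out.at[order.index[0], "recommended"] = True
    detail = pd.DataFrame(
        detail_rows, columns=["target_gene", "drug_id", "guard_gene", "lfc"]
    )
    return out, detail
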