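"""Correlated-gene modules, gene-set enrichment and guard sets.

For each repositioning candidate, the genes most positively correlated with
it (Pearson, across cells, within the variable-gene space) form its module;
modules are tested for over-representation in a gene-set collection by a
one-sided hypergeometric test, and the enriched terms matching guard
patterns (e.g. "MHC") define the candidate's guard genes — genes a
repurposed drug must not co-suppress.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .simulate import GeneSetCollection

__all__ = [
    "CorrelationModule",
    "GuardSet",
    "correlate_with_candidates",
    "hypergeometric_enrichment",
    "derive_guard_sets",
]


@dataclass
class CorrelationModule:
    """Top positively-correlated partners of one candidate gene.

    ``members`` has columns gene, r, pvalue, padj, rank and is sorted by
    descending r (ties broken by gene name); the candidate itself is never
    a member.
    """

    candidate: str
    members: pd.DataFrame
    n_constant_skipped: int = 0
    flag: str = ""  # "" | "zero-variance candidate"

    @property
    def genes(self) -> list[str]:
        return list(self.members["gene"])


def correlate_with_candidates(
    adata: ad.AnnData,
    variable_genes: Sequence[str],
    candidates: Sequence[str],
    r_min: float = 0.3,
    alpha: float = 0.05,
    top_n: int = 50,
) -> list[CorrelationModule]:
    """Pearson modules of each candidate within the variable-gene space.

    p-values come from the t-transform with n - 2 degrees of freedom
    (two-sided) and are Bonferroni-adjusted over the partner tests of each
    candidate.  Partners are retained iff r > r_min (signed, not absolute)
    and padj < alpha, then truncated to the ``top_n`` largest r.
    """
    if adata.n_obs < 3:
        raise ValueError("correlation needs at least 3 cells")
    missing = set(candidates) - set(adata.var_names)
    if missing:
        raise KeyError(f"candidates not measured: {sorted(missing)}")
    var_set = [g for g in variable_genes if g in set(adata.var_names)]
    if len(var_set) < len(list(variable_genes)):
        raise KeyError("variable_genes contains unmeasured genes")

    X = np.asarray(adata[:, var_set].X, dtype=float)
    n = X.shape[0]
    mean = X.mean(axis=0)
    centered = X - mean
    ss = np.sqrt((centered**2).sum(axis=0))
    constant = ss == 0
    pos = {g: i for i, g in enumerate(var_set)}

    cand_X = np.asarray(adata[:, list(candidates)].X, dtype=float)
    modules: list[CorrelationModule] = []
    for j, cand in enumerate(candidates):
        y = cand_X[:, j]
        yc = y - y.mean()
        sy = np.sqrt((yc**2).sum())
        empty = pd.DataFrame(columns=["gene", "r", "pvalue", "padj", "rank"])
        partners = [g for g in var_set if g != cand]
        m = len(partners)
        if sy == 0:
            modules.append(
                CorrelationModule(cand, empty, flag="zero-variance candidate")
            )
            continue
        idx = np.array([pos[g] for g in partners])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (centered[:, idx].T @ yc) / (ss[idx] * sy)
        skipped = int(constant[idx].sum())
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        pvalue = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
        padj = np.minimum(1.0, pvalue * m)  # Bonferroni over the partner tests
        df = pd.DataFrame({"gene": partners, "r": r, "pvalue": pvalue, "padj": padj})
        df = df[~np.isnan(df["r"])]
        df = df[(df["r"] > r_min) & (df["padj"] < alpha)]
        df = df.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
        df = df.head(top_n).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        modules.append(CorrelationModule(cand, df, n_constant_skipped=skipped))
    return modules


def hypergeometric_enrichment(
    module: CorrelationModule | Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
    top_terms: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a module in each term.

    Terms are intersected with the universe before testing; the upper-tail
    p is P[overlap >= observed] under sampling module_size genes from the
    universe.  BH adjustment is applied across the tested terms; terms with
    padj < alpha are returned sorted ascending by (padj, pvalue, term),
    truncated to ``top_terms``.
    """
    genes = module.genes if isinstance(module, CorrelationModule) else list(module)
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("enrichment universe is empty")
    outside = set(genes) - universe_set
    if outside:
        raise ValueError(f"module genes outside universe: {sorted(outside)}")
    cols = ["term", "overlap", "term_size", "module_size", "universe_size", "pvalue", "padj"]
    if not genes:
        return pd.DataFrame(columns=cols)
    module_set = set(genes)
    N = len(universe_set)
    rows = []
    for term, term_genes in collection.terms.items():
        tset = set(term_genes) & universe_set
        if not tset:
            continue
        K = len(tset)
        k = len(tset & module_set)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, len(module_set)))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "module_size": len(module_set),
                "universe_size": N,
                "pvalue": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    df = df[df["padj"] < alpha]
    df = df.sort_values(["padj", "pvalue", "term"], kind="mergesort").head(top_terms)
    return df.reset_index(drop=True)[cols]


@dataclass
class GuardSet:
    """Genes a drug targeting ``candidate`` must not co-suppress."""

    candidate: str
    guard_genes: set[str] = field(default_factory=set)
    source_terms: list[str] = field(default_factory=list)


def derive_guard_sets(
    enrichments: Mapping[str, pd.DataFrame],
    collection: GeneSetCollection,
    guard_term_patterns: Sequence[str],
    measured: Sequence[str],
) -> list[GuardSet]:
    """Guard genes per candidate from enriched terms matching name patterns.

    ``enrichments`` maps candidate -> its enrichment table.  A guard set is
    the union of genes of the candidate's enriched terms whose names match
    any pattern (case-insensitive regex search), intersected with the
    measured genes and excluding the candidate itself.
    """
    if not guard_term_patterns:
        raise ValueError("guard_term_patterns must be nonempty")
    regexes = [re.compile(p, re.IGNORECASE) for p in guard_term_patterns]
    measured_set = set(measured)
    guards: list[GuardSet] = []
    any_match = False
    for cand, enr in enrichments.items():
        matched = [
            t for t in enr["term"] if any(rx.search(t) for rx in regexes)
        ] if len(enr) else []
        genes: set[str] = set()
        for t in matched:
            genes |= set(collection.terms[t])
        genes &= measured_set
        genes.discard(cand)
        if matched:
            any_match = True
        guards.append(GuardSet(cand, genes, matched))
    if not any_match:
        warnings.warn(
            "no enriched term matched any guard pattern; all guard sets are empty"
        )
    return guards
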