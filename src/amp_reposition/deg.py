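"""Differential expression of the immunomodulatory panel.

Stages: per-cell log-normalization, variance-stabilized selection of the
most variable genes, a two-part hurdle test per subtype-vs-normal contrast
with an optional patient covariate, multiplicity-adjusted direction calls,
and derivation of the repositioning plan (which panel gene should be driven
Up or Down by a drug).

The hurdle test mirrors the structure of MAST-style single-cell DE: a
logistic component for detection (count > 0) and a Gaussian component on
the positive log-normalized values, each giving a likelihood-ratio
chi-square for the group effect; the two chi-squares and their degrees of
freedom are summed and referred to a chi-square distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_normalize",
    "select_variable_genes",
    "hurdle_deg_test",
    "classify_deregulation",
    "PanelAnnotation",
    "RepositioningPlan",
    "build_reposition_plan",
]


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Per-cell library-size log-normalization.

    value(g, c) = ln(1 + scale_factor * count(g, c) / total_counts(c)).
    Returns a new AnnData with normalized ``X``; raw counts are kept in
    ``layers["counts"]``.  Cells with zero total counts are rejected.
    """
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor!r}")
    counts = np.asarray(
        adata.layers["counts"] if "counts" in adata.layers else adata.X, dtype=float
    )
    if counts.min() < 0:
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        ids = list(adata.obs_names[zero])
        raise ValueError(f"cells with all-zero counts cannot be normalized: {ids}")
    norm = np.log1p(scale_factor * counts / totals[:, None])
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    out.layers["counts"] = counts
    return out


def select_variable_genes(adata: ad.AnnData, n_top: int = 3000) -> list[str]:
    """Rank genes by variance-stabilized standardized variance; return the top.

    The mean-variance trend of the raw counts is fit by lowess on
    (log10 mean, log10 variance); each gene's counts are standardized by the
    trend-predicted SD, clipped at sqrt(n_cells), and genes are ranked by
    the variance of the clipped standardized values (the Seurat-v3 "vst"
    ranking).  Constant genes have standardized variance zero.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top!r}")
    counts = np.asarray(
        adata.layers["counts"] if "counts" in adata.layers else adata.X, dtype=float
    )
    n_cells, n_genes = counts.shape
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds the {n_genes} measured genes")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    std_var = np.zeros(n_genes)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 2:
        lx = np.log10(mean[fit_mask])
        ly = np.log10(var[fit_mask])
        trend = lowess(ly, lx, frac=0.3, return_sorted=False)
        sd_hat = np.sqrt(10.0**trend)
        clip = np.sqrt(n_cells)
        z = (counts[:, fit_mask] - mean[fit_mask]) / sd_hat
        np.clip(z, -clip, clip, out=z)
        std_var[fit_mask] = z.var(axis=0, ddof=1)
    order = np.lexsort((np.asarray(adata.var_names), -std_var))
    return [adata.var_names[i] for i in order[:n_top]]


def _design(group: np.ndarray, patient: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(group)), group.astype(float)]
    if patient is not None:
        levels = pd.unique(patient)
        for lev in levels[1:]:  # drop first level
            cols.append((patient == lev).astype(float))
    return np.column_stack(cols)


def _logit_lr(y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray) -> float | None:
    """LR chi-square for the group column of a logistic model; None if degenerate."""
    if y.min() == y.max():
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=100)
            null = sm.Logit(y, X_null).fit(disp=0, maxiter=100)
        chi2 = 2.0 * (full.llf - null.llf)
    except Exception:
        return None
    if not np.isfinite(chi2):
        return None
    return max(chi2, 0.0)


def _gaussian_lr(y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray) -> float | None:
    """LR chi-square for the group column of a Gaussian linear model."""
    n = len(y)
    if n <= X_full.shape[1] or np.allclose(y, y[0]):
        return None
    beta_f, rss_f = _ols_rss(X_full, y)
    beta_n, rss_n = _ols_rss(X_null, y)
    if rss_f <= 0 or rss_n <= 0:
        return None
    chi2 = n * np.log(rss_n / rss_f)
    return max(float(chi2), 0.0)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def hurdle_deg_test(
    adata: ad.AnnData,
    group_a: Sequence[str] | np.ndarray,
    group_b: Sequence[str] | np.ndarray,
    genes: Sequence[str] | None = None,
    patient_key: str | None = "patient",
) -> pd.DataFrame:
    """Two-part hurdle test of group A vs group B on log-normalized values.

    Parameters
    ----------
    adata
        Log-normalized expression (output of :func:`log_normalize`).
    group_a, group_b
        Disjoint cell-id collections; every listed cell must exist.
    genes
        Genes to test (default: all).
    patient_key
        obs column used as a fixed-effect covariate in both hurdle
        components.  If any patient level lies entirely within one group the
        covariate is dropped for this contrast with a warning.

    Returns a DataFrame indexed by gene with columns ``lfc`` (log2 ratio of
    group means of expm1(normalized), pseudocount 1/n_smaller), ``pvalue``
    and ``flag`` ("" | "undetected").
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("both contrast groups must be nonempty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"cells in both groups: {sorted(overlap)[:5]}")
    cells = group_a + group_b
    sub = adata[cells]
    X = np.asarray(sub.X, dtype=float)
    group = np.r_[np.ones(len(group_a)), np.zeros(len(group_b))]

    patient = None
    if patient_key is not None and patient_key in sub.obs:
        patient = sub.obs[patient_key].to_numpy()
        for lev in pd.unique(patient):
            g = group[patient == lev]
            if g.min() == g.max():
                warnings.warn(
                    f"patient level {lev!r} occurs in only one group; "
                    "dropping the patient covariate for this contrast"
                )
                patient = None
                break

    X_full = _design(group, patient)
    X_null = np.delete(X_full, 1, axis=1)

    if genes is None:
        genes = list(adata.var_names)
    gene_pos = {g: i for i, g in enumerate(sub.var_names)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")

    n_a, n_b = len(group_a), len(group_b)
    eps = 1.0 / min(n_a, n_b)
    rows = []
    for g in genes:
        y = X[:, gene_pos[g]]
        detected = y > 0
        ya, yb = y[: n_a], y[n_a:]
        mean_a = np.expm1(ya).mean()
        mean_b = np.expm1(yb).mean()
        lfc = float(np.log2((mean_a + eps) / (mean_b + eps)))
        if not detected.any():
            rows.append({"gene": g, "lfc": 0.0, "pvalue": 1.0, "flag": "undetected"})
            continue
        chi2_total, df = 0.0, 0
        c = _logit_lr(detected.astype(float), X_full, X_null)
        if c is not None:
            chi2_total += c
            df += 1
        pos = detected
        c = _gaussian_lr(y[pos], X_full[pos], X_null[pos])
        if c is not None:
            chi2_total += c
            df += 1
        pvalue = float(scipy.stats.chi2.sf(chi2_total, df)) if df > 0 else 1.0
        rows.append({"gene": g, "lfc": lfc, "pvalue": pvalue, "flag": ""})
    return pd.DataFrame(rows).set_index("gene")


def classify_deregulation(
    records: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.25,
    mt_method: str = "bh",
) -> pd.DataFrame:
    """Adjust p-values per contrast and call each gene up / down / ns.

    ``records`` needs columns gene, contrast, lfc, pvalue (one row per gene
    x contrast).  Direction is ``up`` iff padj < alpha (strict) and
    lfc >= lfc_min, ``down`` iff padj < alpha and lfc <= -lfc_min, else
    ``ns``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if lfc_min < 0:
        raise ValueError(f"lfc_min must be nonnegative, got {lfc_min!r}")
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(mt_method.lower())
    if method is None:
        raise ValueError(f"mt_method must be 'bh' or 'bonferroni', got {mt_method!r}")
    if len(records) == 0:
        raise ValueError("no DEG records to classify")
    out = records.copy()
    out["padj"] = np.nan
    for _, idx in out.groupby("contrast").groups.items():
        p = out.loc[idx, "pvalue"].to_numpy()
        out.loc[idx, "padj"] = multipletests(p, method=method)[1]
    direction = np.where(
        (out["padj"] < alpha) & (out["lfc"] >= lfc_min),
        "up",
        np.where((out["padj"] < alpha) & (out["lfc"] <= -lfc_min), "down", "ns"),
    )
    out["direction"] = direction
    return out


@dataclass
class PanelAnnotation:
    """Therapeutic role and desired repositioning plane of one panel gene."""

    gene: str
    therapeutic_role: str
    dr_direction: str  # "Up" | "Down" | "None"

    def __post_init__(self) -> None:
        if self.dr_direction not in {"Up", "Down", "None"}:
            raise ValueError(
                f"dr_direction must be Up, Down or None, got {self.dr_direction!r}"
            )


@dataclass
class RepositioningPlan:
    """Map gene -> desired drug-induced plane, with supporting contrasts."""

    targets: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: p for g, p in self.targets.items() if p not in {"Up", "Down"}}
        if bad:
            raise ValueError(f"plan planes must be Up or Down: {bad}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "plane": p,
                "provenance": ";".join(self.provenance.get(g, {}).get("contrasts", [])),
                "role": self.provenance.get(g, {}).get("role", ""),
            }
            for g, p in self.targets.items()
        ]
        return pd.DataFrame(rows, columns=["gene", "plane", "provenance", "role"])


def build_reposition_plan(
    panel: Sequence[PanelAnnotation],
    deg: pd.DataFrame,
) -> RepositioningPlan:
    """Derive the repositioning plan from panel annotation and direction calls.

    A gene with annotated plane Down (it promotes the malignancy, so a drug
    should suppress it) enters the plan iff at least one contrast calls it
    up.  A gene with plane Up (it favors cancer elimination) enters iff at
    least one contrast calls it down or ns — i.e. the tumor has failed to
    raise it, so a drug may.  Genes annotated None never enter.
    """
    by_gene: Mapping[str, pd.DataFrame] = dict(tuple(deg.groupby("gene")))
    plan = RepositioningPlan()
    for ann in panel:
        if ann.dr_direction == "None":
            continue
        calls = by_gene.get(ann.gene)
        if calls is None:
            raise ValueError(f"panel gene {ann.gene!r} has no DEG record")
        if ann.dr_direction == "Down":
            support = calls.loc[calls["direction"] == "up", "contrast"]
        else:
            support = calls.loc[calls["direction"].isin(["down", "ns"]), "contrast"]
        if len(support) == 0:
            continue
        plan.targets[ann.gene] = ann.dr_direction
        plan.provenance[ann.gene] = {
            "contrasts": [str(c) for c in support],
            "role": ann.therapeutic_role,
        }
    if not plan.targets:
        raise ValueError("no actionable targets: the repositioning plan is empty")
    return plan
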