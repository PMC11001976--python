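"""Synthetic single-cell, perturbagen and gene-set generators.

Every downstream stage of the repositioning pipeline is exercised on data
from this module: a two-condition (malignant vs normal), multi-patient,
multi-subtype negative-binomial count matrix with dropout and patient batch
shifts; a DMSO-controlled perturbagen panel with replicates and planted
per-drug log2 effects; and a GMT-writable gene-set collection with an
optional planted term.

All randomness flows from one master seed per config.  Sub-streams are
derived with ``numpy.random.SeedSequence(seed, spawn_key=(k,))`` where ``k``
is a fixed per-generator index (0 = single-cell, 1 = perturbagen,
2 = gene sets), so each generator can be re-run independently and two calls
with the same config are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "ScSimConfig",
    "PerturbSimConfig",
    "GeneSetSimConfig",
    "GeneSetCollection",
    "PerturbagenSet",
    "simulate_sc_counts",
    "simulate_perturbagen_panel",
    "make_gene_sets",
]

# spawn_key indices of the per-generator random sub-streams
_STREAM_SC = 0
_STREAM_PERTURB = 1
_STREAM_GENESETS = 2

# SD of the log-normal spread of gene base means around base_mean
_GENE_MEAN_LOG_SD = 0.5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _require_positive_int(value, name: str) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool) or value <= 0:
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    return int(value)


def _require_nonneg_real(value, name: str) -> float:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a nonnegative finite real, got {value!r}")
    return float(value)


@dataclass
class ScSimConfig:
    """Configuration of the two-condition single-cell count simulator.

    Counts are negative binomial with gene base means drawn log-normally
    around ``base_mean``; genes in ``planted_lfc`` have their expected
    expression multiplied by ``2**lfc`` in the malignant condition before
    dropout.  ``coexpression`` optionally lists partner genes that share a
    per-cell log-normal latent factor with a candidate gene, planting a
    positive Pearson correlation for the correlation stage to recover.
    """

    n_genes: int = 500
    n_cells_per_group: int = 1000
    n_patients_per_group: int = 4
    panel_genes: Sequence[str] = ()
    planted_lfc: Mapping[str, float] = field(default_factory=dict)
    base_mean: float = 2.0
    dispersion: float = 2.0
    dropout_rate: float = 0.3
    batch_sd: float = 0.1
    seed: int = 0
    subtypes: Sequence[str] = ("TNBC", "ER+", "HER2+")
    coexpression: Mapping[str, Sequence[str]] = field(default_factory=dict)
    coexpression_strength: float = 2.0

    def validate(self) -> None:
        _require_positive_int(self.n_genes, "n_genes")
        _require_positive_int(self.n_cells_per_group, "n_cells_per_group")
        _require_positive_int(self.n_patients_per_group, "n_patients_per_group")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        if self.base_mean <= 0:
            raise ValueError(f"base_mean must be positive, got {self.base_mean!r}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be positive, got {self.dispersion!r}")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must lie in [0, 1], got {self.dropout_rate!r}")
        _require_nonneg_real(self.batch_sd, "batch_sd")
        _require_nonneg_real(self.coexpression_strength, "coexpression_strength")
        panel = set(self.panel_genes)
        missing = set(self.planted_lfc) - panel
        if missing:
            raise ValueError(
                f"planted_lfc keys must be panel genes; not in panel_genes: {sorted(missing)}"
            )
        for cand, partners in self.coexpression.items():
            if cand in set(partners):
                raise ValueError(f"coexpression partners of {cand} must not include itself")

    def gene_names(self) -> list[str]:
        """Gene universe: panel genes, then coexpression partners, then filler."""
        names: list[str] = list(dict.fromkeys(self.panel_genes))
        for cand, partners in self.coexpression.items():
            for g in [cand, *partners]:
                if g not in names:
                    names.append(g)
        if len(names) > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(names)} named genes"
            )
        filler = (f"G{i:04d}" for i in range(1, self.n_genes + 1))
        for g in filler:
            if len(names) == self.n_genes:
                break
            if g not in names:
                names.append(g)
        return names


def simulate_sc_counts(cfg: ScSimConfig) -> ad.AnnData:
    """Simulate a labeled malignant/normal count matrix.

    Returns an AnnData (cells x genes) with integer counts in ``X`` and
    obs columns ``condition`` ({malignant, normal}), ``subtype`` (one per
    malignant patient, "none" for normal cells) and ``patient``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_SC)
    genes = cfg.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # gene base means, shared by both conditions
    base = cfg.base_mean * np.exp(rng.normal(0.0, _GENE_MEAN_LOG_SD, size=n_genes))

    conditions = ("malignant", "normal")
    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    for cond in conditions:
        n_cells = cfg.n_cells_per_group
        n_pat = cfg.n_patients_per_group
        # even split of cells across patients; remainder to the first patients
        sizes = np.full(n_pat, n_cells // n_pat)
        sizes[: n_cells % n_pat] += 1
        lfc = np.zeros(n_genes)
        if cond == "malignant":
            for g, delta in cfg.planted_lfc.items():
                lfc[gene_idx[g]] = float(delta)
        for p in range(n_pat):
            tag = "M" if cond == "malignant" else "N"
            patient = f"P{tag}{p + 1:02d}"
            subtype = cfg.subtypes[p % len(cfg.subtypes)] if cond == "malignant" else "none"
            shift = np.exp(rng.normal(0.0, cfg.batch_sd))
            n_c = int(sizes[p])
            mu = np.tile(base * np.exp2(lfc) * shift, (n_c, 1))
            # shared latent per-cell factor plants positive co-expression
            for cand, partners in cfg.coexpression.items():
                z = rng.normal(0.0, 1.0, size=n_c)
                fac = np.exp(cfg.coexpression_strength * z - 0.5 * cfg.coexpression_strength**2)
                cols = [gene_idx[cand]] + [gene_idx[g] for g in partners]
                mu[:, cols] *= fac[:, None]
            r = cfg.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            if cfg.dropout_rate > 0:
                keep = rng.random(counts.shape) >= cfg.dropout_rate
                counts = counts * keep
            blocks.append(counts)
            for i in range(n_c):
                obs_rows.append(
                    {"condition": cond, "subtype": subtype, "patient": patient}
                )

    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i + 1:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["counts"] = adata.X.copy()
    return adata


@dataclass
class PerturbSimConfig:
    """Configuration of the DMSO-controlled perturbagen panel simulator.

    Drug ``d`` at gene ``g`` has expected linear-scale expression
    ``baseline_mean * 2**effect(d, g)`` with multiplicative log-normal noise
    of SD ``noise_sd`` (natural-log scale); controls are one pseudo-drug
    ``DMSO`` with ``is_control = True``.
    """

    n_genes: int = 200
    n_drugs: int = 20
    n_reps: int = 3
    n_control_reps: int = 6
    planted_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.1
    baseline_mean: float = 100.0
    dose_label: str = "10 uM"
    time_label: str = "24 h"
    seed: int = 0

    def validate(self) -> None:
        _require_positive_int(self.n_genes, "n_genes")
        _require_positive_int(self.n_drugs, "n_drugs")
        _require_positive_int(self.n_reps, "n_reps")
        if not isinstance(self.n_control_reps, (int, np.integer)) or self.n_control_reps < 2:
            raise ValueError(
                f"n_control_reps must be an integer >= 2 (control mean needs replicates), "
                f"got {self.n_control_reps!r}"
            )
        _require_nonneg_real(self.noise_sd, "noise_sd")
        if self.baseline_mean <= 0:
            raise ValueError(f"baseline_mean must be positive, got {self.baseline_mean!r}")
        if "DMSO" in self.planted_effects:
            raise ValueError("planted_effects must not target the DMSO control pseudo-drug")

    def gene_names(self) -> list[str]:
        names: list[str] = []
        for effects in self.planted_effects.values():
            for g in effects:
                if g not in names:
                    names.append(g)
        if len(names) > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(names)} planted-effect genes"
            )
        for i in range(1, self.n_genes + 1):
            if len(names) == self.n_genes:
                break
            g = f"G{i:04d}"
            if g not in names:
                names.append(g)
        return names

    def drug_names(self) -> list[str]:
        names = list(self.planted_effects)
        if len(names) > self.n_drugs:
            raise ValueError(
                f"n_drugs={self.n_drugs} too small for {len(names)} planted drugs"
            )
        for i in range(1, self.n_drugs + 1):
            if len(names) == self.n_drugs:
                break
            d = f"D{i:03d}"
            if d not in names:
                names.append(d)
        return sorted(names)


@dataclass
class PerturbagenSet:
    """Gene-by-sample linear-scale expression with per-sample metadata.

    ``values``: DataFrame, genes (rows) x samples (columns), positive reals.
    ``meta``: DataFrame indexed by sample id with columns drug_id, dose,
    time, replicate, is_control.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"drug_id", "dose", "time", "replicate", "is_control"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("values columns and metadata rows must match one-to-one")
        if not self.meta["is_control"].any():
            raise ValueError("perturbagen set needs at least one control sample")
        if self.meta["is_control"].all():
            raise ValueError("perturbagen set needs at least one treatment sample")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def simulate_perturbagen_panel(cfg: PerturbSimConfig) -> PerturbagenSet:
    """Simulate a replicate-structured perturbagen panel with DMSO controls."""
    cfg.validate()
    rng = _rng(cfg.seed, _STREAM_PERTURB)
    genes = cfg.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    drugs = cfg.drug_names()

    cols: list[str] = []
    meta_rows: list[dict] = []
    mat: list[np.ndarray] = []

    def _samples(drug: str, n_rep: int, is_control: bool) -> None:
        effect = np.zeros(len(genes))
        for g, delta in cfg.planted_effects.get(drug, {}).items():
            effect[gene_idx[g]] = float(delta)
        mu = cfg.baseline_mean * np.exp2(effect)
        for rep in range(1, n_rep + 1):
            noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=len(genes)))
            mat.append(mu * noise)
            sid = f"{drug}_r{rep}"
            cols.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "drug_id": drug,
                    "dose": cfg.dose_label,
                    "time": cfg.time_label,
                    "replicate": rep,
                    "is_control": is_control,
                }
            )

    _samples("DMSO", cfg.n_control_reps, True)
    for drug in drugs:
        _samples(drug, cfg.n_reps, False)

    values = pd.DataFrame(
        np.column_stack(mat), index=pd.Index(genes, name="gene"), columns=cols
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return PerturbagenSet(values=values, meta=meta)


class GeneSetCollection:
    """Named gene sets with descriptions (a GMT file in memory)."""

    def __init__(
        self,
        terms: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in terms.items():
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(list(genes)):
                warnings.warn(f"term {name!r} contains duplicate genes; deduplicated")
            if not unique:
                raise ValueError(f"term {name!r} is empty")
            self.terms[name] = unique
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __getitem__(self, name: str) -> list[str]:
        return self.terms[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {k: set(v) for k, v in self.terms.items()} == {
            k: set(v) for k, v in other.terms.items()
        }


@dataclass
class GeneSetSimConfig:
    """Configuration for the random gene-set collection generator."""

    n_terms: int = 20
    term_size_range: tuple[int, int] = (5, 40)
    planted_term: tuple[str, Sequence[str]] | None = None
    seed: int = 0

    def validate(self) -> None:
        _require_positive_int(self.n_terms, "n_terms")
        lo, hi = self.term_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"term_size_range must be a valid interval >= 1, got {self.term_size_range!r}")
        if self.planted_term is not None:
            name, genes = self.planted_term
            n_unique = len(set(genes))
            if not lo <= n_unique <= hi:
                raise ValueError(
                    f"planted_term size {n_unique} outside term_size_range {self.term_size_range!r}"
                )


def make_gene_sets(cfg: GeneSetSimConfig, universe: Sequence[str]) -> GeneSetCollection:
    """Random gene sets sampled from ``universe``; includes the planted term verbatim."""
    cfg.validate()
    universe = list(universe)
    if not universe:
        raise ValueError("gene universe must be nonempty")
    if cfg.planted_term is not None:
        name, genes = cfg.planted_term
        outside = set(genes) - set(universe)
        if outside:
            raise ValueError(f"planted_term genes outside universe: {sorted(outside)}")
    rng = _rng(cfg.seed, _STREAM_GENESETS)
    lo, hi = cfg.term_size_range
    lo = min(lo, len(universe))
    hi = min(hi, len(universe))
    terms: dict[str, list[str]] = {}
    if cfg.planted_term is not None:
        name, genes = cfg.planted_term
        terms[name] = list(genes)
    i = 0
    while len(terms) < cfg.n_terms:
        i += 1
        name = f"T{i:03d}"
        if name in terms:
            continue
        size = int(rng.integers(lo, hi + 1))
        terms[name] = list(rng.choice(universe, size=size, replace=False))
    return GeneSetCollection(terms)
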