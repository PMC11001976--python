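"""End-to-end orchestration: simulate -> deg -> correlate -> enrich -> reposition.

``run_all`` chains the five stages on a fully synthetic fixture, writes
every stage artifact under the configured output directory and finishes
with a manifest (inputs, parameters, seed, SHA-256 of every output) so two
runs with the same config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import logging
from contextlib import contextmanager
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import deg as deg_mod
from . import io as io_mod
from . import reposition as rep_mod
from .config import PipelineConfig
from .correlation import correlate_with_candidates, derive_guard_sets, hypergeometric_enrichment
from .simulate import (
    GeneSetSimConfig,
    PerturbSimConfig,
    ScSimConfig,
    make_gene_sets,
    simulate_perturbagen_panel,
    simulate_sc_counts,
)

__all__ = ["default_fixture_configs", "run_all", "default_panel_path"]

log = logging.getLogger("amp_reposition")

_FLOAT_FMT = "%.10g"

_HLA_GUARDS_B2M = ["HLA-A", "HLA-B", "HLA-C", "HLA-DMA", "HLA-DRA"]
_HLA_GUARDS_SLPI = ["HLA-DRB1", "HLA-E", "HLA-F"]
_MHC_TERM_GENES = sorted(set(_HLA_GUARDS_B2M + _HLA_GUARDS_SLPI + ["B2M"]))


def default_panel_path() -> Path:
    """Path of the packaged panel annotation table (therapeutic roles and planes)."""
    return Path(resources.files("amp_reposition") / "data" / "panel_annotation.tsv")


def default_fixture_configs(seed: int = 0, overrides: dict | None = None):
    """Study-condition configs of the default synthetic fixture.

    Plants the expression pattern the repositioning plan expects (B2M and
    SLPI up in malignant cells, the Up-plane genes down), co-expression of
    B2M/SLPI with HLA genes, an MHC gene-set term, and a perturbagen panel
    containing a clean and a guard-suppressing drug per Down target among
    null drugs.
    """
    panel_genes = [a.gene for a in io_mod.read_panel_annotation(default_panel_path())]
    sc = ScSimConfig(
        n_genes=500,
        n_cells_per_group=900,
        n_patients_per_group=3,
        panel_genes=panel_genes,
        planted_lfc={
            "B2M": 2.0,
            "SLPI": 2.0,
            "PIGR": -2.0,
            "DEFB1": -2.0,
            "LTF": -1.5,
            "CLU": -1.5,
            "S100A7": -1.0,
            "SCGB2A1": -1.0,
        },
        coexpression={
            "B2M": _HLA_GUARDS_B2M,
            "SLPI": _HLA_GUARDS_SLPI,
        },
        seed=seed,
    )
    if overrides:
        for key, value in overrides.items():
            if not hasattr(sc, key):
                raise ValueError(f"unknown simulate config key {key!r}")
            setattr(sc, key, value)

    # the "clean" drugs spare (mildly raise) the MHC guard genes, the "dirty"
    # one co-suppresses them — the contrast the guard report must expose
    guard_hit = {g: -1.5 for g in _HLA_GUARDS_B2M}
    guard_spare_b2m = {g: 0.3 for g in _HLA_GUARDS_B2M + _HLA_GUARDS_SLPI}
    guard_spare_slpi = {g: 0.3 for g in _HLA_GUARDS_B2M + _HLA_GUARDS_SLPI}
    perturb = PerturbSimConfig(
        n_genes=sc.n_genes,
        n_drugs=60,
        n_reps=3,
        n_control_reps=6,
        planted_effects={
            "DRUG_B2M_CLEAN": {"B2M": -2.0, **guard_spare_b2m},
            "DRUG_B2M_DIRTY": {"B2M": -2.5, **guard_hit},
            "DRUG_SLPI_CLEAN": {"SLPI": -2.0, **guard_spare_slpi},
            "DRUG_PIGR_UP": {"PIGR": 2.0},
            "DRUG_PANEL_UP": {
                g: 1.5 for g in ["DEFB1", "LTF", "CLU", "S100A7", "SCGB2A1"]
            },
        },
        seed=seed,
    )
    # perturbagen gene universe mirrors the single-cell one
    gs = GeneSetSimConfig(
        n_terms=20,
        term_size_range=(3, 40),
        planted_term=("MHC protein complex", _MHC_TERM_GENES),
        seed=seed,
    )
    return sc, perturb, gs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


@contextmanager
def _stage(name: str):
    """Label failures with the stage they occurred in; earlier stage outputs
    already on disk are left in place."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage on the synthetic fixture; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- simulate -----------------------------------------------------------
    with _stage("simulate"):
        sc_cfg, perturb_cfg, gs_cfg = default_fixture_configs(config.seed, config.simulate)
        log.info("simulate: %d genes, %d cells/group, seed %d", sc_cfg.n_genes,
                 sc_cfg.n_cells_per_group, config.seed)
        adata = simulate_sc_counts(sc_cfg)
        io_mod.write_expression(adata, out, prefix="counts")
        outputs += [out / "counts.mtx", out / "counts.genes.tsv", out / "counts.cells.tsv"]

        pset = simulate_perturbagen_panel(perturb_cfg)
        io_mod.write_perturbagen_set(pset, out, prefix="perturb")
        outputs += [out / "perturb.values.csv", out / "perturb.meta.tsv"]

        collection = make_gene_sets(gs_cfg, universe=list(adata.var_names))
        io_mod.write_gmt(collection, out / "gene_sets.gmt")
        outputs.append(out / "gene_sets.gmt")

        panel = io_mod.read_panel_annotation(default_panel_path())

    # --- deg ----------------------------------------------------------------
    with _stage("deg"):
        p = config.deg
        log.info("deg: alpha=%g lfc_min=%g mt=%s scale_factor=%g n_variable=%d",
                 p.alpha, p.lfc_min, p.mt_method, p.scale_factor, p.n_variable)
        norm = deg_mod.log_normalize(adata, scale_factor=p.scale_factor)
        n_var = min(p.n_variable, norm.n_vars)
        variable_genes = deg_mod.select_variable_genes(norm, n_top=n_var)

        panel_genes = [a.gene for a in panel if a.gene in set(norm.var_names)]
        is_mal = norm.obs["condition"] == "malignant"
        normal_cells = list(norm.obs_names[norm.obs["condition"] == "normal"])
        records = []
        for subtype in sorted(norm.obs.loc[is_mal, "subtype"].unique()):
            cells_a = list(norm.obs_names[is_mal & (norm.obs["subtype"] == subtype)])
            res = deg_mod.hurdle_deg_test(norm, cells_a, normal_cells, genes=panel_genes)
            res = res.reset_index()
            res["contrast"] = f"{subtype}_vs_normal"
            records.append(res)
        deg_raw = pd.concat(records, ignore_index=True)
        deg_table = deg_mod.classify_deregulation(
            deg_raw, alpha=p.alpha, lfc_min=p.lfc_min, mt_method=p.mt_method
        )
        _write_tsv(
            deg_table[["gene", "contrast", "lfc", "pvalue", "padj", "direction"]],
            out / "deg.tsv",
        )
        outputs.append(out / "deg.tsv")

        plan = deg_mod.build_reposition_plan(panel, deg_table)
        _write_tsv(plan.to_frame(), out / "plan.tsv")
        outputs.append(out / "plan.tsv")
        log.info("plan targets: %s", plan.targets)

    # --- correlate + enrich -------------------------------------------------
    with _stage("correlate/enrich"):
        c = config.correlate
        log.info("correlate: r_min=%g alpha=%g top_n=%d", c.r_min, c.alpha, c.top_n)
        candidates = list(plan.targets)
        modules = correlate_with_candidates(
            norm, variable_genes, candidates, r_min=c.r_min, alpha=c.alpha, top_n=c.top_n
        )
        mod_rows = []
        for m in modules:
            for _, r in m.members.iterrows():
                mod_rows.append({"candidate": m.candidate, **r.to_dict()})
        _write_tsv(
            pd.DataFrame(mod_rows, columns=["candidate", "gene", "r", "pvalue", "padj", "rank"]),
            out / "modules.tsv",
        )
        outputs.append(out / "modules.tsv")

        e = config.enrich
        log.info("enrich: alpha=%g top_terms=%d guard patterns=%s",
                 e.alpha, e.top_terms, e.guard_term_patterns)
        universe = list(norm.var_names)
        enrichments = {
            m.candidate: hypergeometric_enrichment(
                m, collection, universe, alpha=e.alpha, top_terms=e.top_terms
            )
            for m in modules
        }
        enr_rows = []
        for cand, enr in enrichments.items():
            for _, r in enr.iterrows():
                enr_rows.append({"candidate": cand, **r.to_dict()})
        _write_tsv(
            pd.DataFrame(
                enr_rows,
                columns=["candidate", "term", "overlap", "term_size", "module_size",
                         "universe_size", "pvalue", "padj"],
            ),
            out / "enrichment.tsv",
        )
        outputs.append(out / "enrichment.tsv")

        guards = derive_guard_sets(enrichments, collection, e.guard_term_patterns, universe)
        guard_rows = [
            {"candidate": g.candidate, "guard_gene": h, "source_term": ";".join(g.source_terms)}
            for g in guards
            for h in sorted(g.guard_genes)
        ]
        _write_tsv(
            pd.DataFrame(guard_rows, columns=["candidate", "guard_gene", "source_term"]),
            out / "guards.tsv",
        )
        outputs.append(out / "guards.tsv")

    # --- reposition ---------------------------------------------------------
    with _stage("reposition"):
        r = config.reposition
        log.info("reposition: dose=%r time=%r k=%d tau=%g pseudocount=%g",
                 r.dose, r.time, r.k, r.tau, r.pseudocount)
        filtered, dropped = rep_mod.filter_perturbagens(pset, dose=r.dose, time=r.time)
        _write_tsv(dropped, out / "dropped_drugs.tsv")
        outputs.append(out / "dropped_drugs.tsv")

        lfc = rep_mod.compute_drug_lfc(filtered, pseudocount=r.pseudocount)
        lfc.to_csv(out / "drug_lfc.csv", float_format=_FLOAT_FMT)
        outputs.append(out / "drug_lfc.csv")

        ranked = {
            gene: rep_mod.rank_drugs_for_gene(lfc, gene, plan.targets[gene], k=r.k)
            for gene in plan.targets
        }
        table = rep_mod.filter_contradictory(ranked, plan, lfc, tau=r.tau)
        table, detail = rep_mod.guard_conflict_report(table, guards, lfc)
        _write_tsv(table, out / "candidates.tsv")
        _write_tsv(detail, out / "guard_detail.tsv")
        outputs += [out / "candidates.tsv", out / "guard_detail.tsv"]

    # --- manifest -----------------------------------------------------------
    rows = [{"kind": "param", "name": "config", "value": repr(config.to_dict()), "sha256": ""}]
    rows.append({"kind": "param", "name": "seed", "value": str(config.seed), "sha256": ""})
    for path in outputs:
        rows.append(
            {"kind": "output", "name": path.name, "value": str(path), "sha256": _sha256(path)}
        )
    manifest = pd.DataFrame(rows, columns=["kind", "name", "value", "sha256"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
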