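"""Readers and writers for the pipeline's file formats.

Single-cell counts travel as a MatrixMarket triplet (genes x cells MTX,
genes TSV, cell-annotation TSV) or as one dense CSV; perturbagen panels as
a genes-x-samples CSV plus a sample-metadata TSV; gene sets as GMT; the
panel annotation as a three-column TSV (gene, role, dr_direction).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .deg import PanelAnnotation
from .simulate import GeneSetCollection, PerturbagenSet

__all__ = [
    "write_expression",
    "read_expression",
    "read_expression_csv",
    "write_expression_csv",
    "read_gmt",
    "write_gmt",
    "read_panel_annotation",
    "write_panel_annotation",
    "write_perturbagen_set",
    "read_perturbagen_set",
]

_ANNOT_COLS = ["cell_id", "condition", "subtype", "patient"]


def write_expression(adata: ad.AnnData, out_dir: str | Path, prefix: str = "counts") -> None:
    """Write counts as ``<prefix>.mtx`` (genes x cells) + genes/cells TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(
        adata.layers["counts"] if "counts" in adata.layers else adata.X
    )
    mat = scipy.sparse.csr_matrix(counts.T)  # genes x cells on disk
    scipy.io.mmwrite(str(out_dir / f"{prefix}.mtx"), mat, field="integer")
    pd.Series(adata.var_names, name="gene").to_csv(
        out_dir / f"{prefix}.genes.tsv", sep="\t", index=False
    )
    annot = adata.obs.reset_index(names="cell_id")[_ANNOT_COLS]
    annot.to_csv(out_dir / f"{prefix}.cells.tsv", sep="\t", index=False)


def read_expression(in_dir: str | Path, prefix: str = "counts") -> ad.AnnData:
    """Read the MTX triplet written by :func:`write_expression`."""
    in_dir = Path(in_dir)
    mtx_path = in_dir / f"{prefix}.mtx"
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    counts = np.asarray(scipy.sparse.csr_matrix(mat).todense()).T  # cells x genes
    genes = pd.read_csv(in_dir / f"{prefix}.genes.tsv", sep="\t")["gene"].astype(str)
    if genes.duplicated().any():
        dups = sorted(genes[genes.duplicated()].unique())
        raise ValueError(f"duplicate gene names: {dups}")
    if len(genes) != counts.shape[1]:
        raise ValueError(
            f"gene list has {len(genes)} entries but matrix has {counts.shape[1]} gene rows"
        )
    annot = pd.read_csv(in_dir / f"{prefix}.cells.tsv", sep="\t", dtype=str)
    missing_cols = set(_ANNOT_COLS) - set(annot.columns)
    if missing_cols:
        raise ValueError(f"cell annotation missing columns: {sorted(missing_cols)}")
    if annot["cell_id"].duplicated().any():
        dups = sorted(annot.loc[annot["cell_id"].duplicated(), "cell_id"].unique())
        raise ValueError(f"duplicate cell ids: {dups}")
    if len(annot) != counts.shape[0]:
        raise ValueError(
            f"annotation has {len(annot)} cells but matrix has {counts.shape[0]} cell columns"
        )
    if annot[_ANNOT_COLS].isna().any().any():
        bad = annot.loc[annot[_ANNOT_COLS].isna().any(axis=1), "cell_id"].tolist()
        raise ValueError(f"cell annotation has missing labels for: {bad}")
    obs = annot.set_index("cell_id")[["condition", "subtype", "patient"]]
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def write_expression_csv(adata: ad.AnnData, path: str | Path) -> None:
    """Dense CSV: genes x cells counts, first column gene, header = cell ids;
    cell labels in a sibling ``<path>.cells.tsv``."""
    counts = np.asarray(
        adata.layers["counts"] if "counts" in adata.layers else adata.X
    )
    df = pd.DataFrame(counts.T, index=adata.var_names, columns=adata.obs_names)
    df.index.name = "gene"
    df.to_csv(path)
    annot = adata.obs.reset_index(names="cell_id")[_ANNOT_COLS]
    annot.to_csv(str(path) + ".cells.tsv", sep="\t", index=False)


def read_expression_csv(path: str | Path) -> ad.AnnData:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene names: {sorted(df.index[df.index.duplicated()])}")
    annot = pd.read_csv(str(path) + ".cells.tsv", sep="\t", dtype=str)
    missing = set(df.columns) - set(annot["cell_id"])
    if missing:
        raise ValueError(f"cell annotation missing cell ids: {sorted(missing)}")
    obs = annot.set_index("cell_id").loc[list(df.columns), ["condition", "subtype", "patient"]]
    adata = ad.AnnData(
        X=df.to_numpy().T.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=df.index),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (term, description, genes...)."""
    terms: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        warnings.warn(f"GMT file {path} is empty")
        return GeneSetCollection({})
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
            )
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: term {name!r} has no genes")
        terms[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(terms, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.terms.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_panel_annotation(path: str | Path) -> list[PanelAnnotation]:
    """TSV with header gene, role, dr_direction (Up | Down | None)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "role", "dr_direction"}
    if not required <= set(df.columns):
        raise ValueError(f"panel annotation needs columns {sorted(required)}")
    if df["gene"].duplicated().any():
        raise ValueError(
            f"duplicate panel genes: {sorted(df.loc[df['gene'].duplicated(), 'gene'])}"
        )
    return [
        PanelAnnotation(r["gene"], r["role"], r["dr_direction"]) for _, r in df.iterrows()
    ]


def write_panel_annotation(panel: Sequence[PanelAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": a.gene, "role": a.therapeutic_role, "dr_direction": a.dr_direction}
            for a in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def write_perturbagen_set(pset: PerturbagenSet, out_dir: str | Path, prefix: str = "perturb") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pset.values.to_csv(out_dir / f"{prefix}.values.csv", float_format="%.10g")
    pset.meta.reset_index().to_csv(out_dir / f"{prefix}.meta.tsv", sep="\t", index=False)


def read_perturbagen_set(in_dir: str | Path, prefix: str = "perturb") -> PerturbagenSet:
    in_dir = Path(in_dir)
    values = pd.read_csv(in_dir / f"{prefix}.values.csv", index_col=0)
    meta = pd.read_csv(in_dir / f"{prefix}.meta.tsv", sep="\t").set_index("sample_id")
    meta["is_control"] = meta["is_control"].astype(bool)
    return PerturbagenSet(values=values, meta=meta)
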