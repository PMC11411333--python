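"""On-disk serialization of decompositions and PCA models (TSV + JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import PatternDecomposition
from .io import FLOAT_FMT
from .project import PCAModel


def save_decomposition(decomp: PatternDecomposition, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(decomp.A, index=decomp.gene_ids, columns=decomp.pattern_ids
                 ).rename_axis("gene_id").to_csv(
        outdir / "A.tsv", sep="\t", float_format=FLOAT_FMT)
    pd.DataFrame(decomp.P, index=decomp.pattern_ids, columns=decomp.sample_ids
                 ).rename_axis("pattern").to_csv(
        outdir / "P.tsv", sep="\t", float_format=FLOAT_FMT)
    scaling = pd.DataFrame({"gene_id": decomp.gene_ids,
                            "row_scaling": decomp.row_scaling})
    if decomp.intercept is not None:
        scaling["intercept"] = decomp.intercept
    scaling.to_csv(outdir / "row_scaling.tsv", sep="\t", index=False,
                   float_format="%.10g")
    meta = {
        "K": decomp.K,
        "seed": decomp.seed,
        "converged": decomp.converged,
        "final_objective": decomp.objective_trace[-1],
        "restart_stability": [round(float(s), 6)
                              for s in decomp.restart_stability],
    }
    (outdir / "decomposition.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_decomposition(outdir: str | Path) -> PatternDecomposition:
    outdir = Path(outdir)
    A = pd.read_csv(outdir / "A.tsv", sep="\t", index_col=0)
    P = pd.read_csv(outdir / "P.tsv", sep="\t", index_col=0)
    scaling = pd.read_csv(outdir / "row_scaling.tsv", sep="\t")
    meta = json.loads((outdir / "decomposition.json").read_text())
    return PatternDecomposition(
        A=A.to_numpy(float), P=P.to_numpy(float), K=int(meta["K"]),
        gene_ids=[str(g) for g in A.index],
        sample_ids=[str(s) for s in P.columns],
        row_scaling=scaling["row_scaling"].to_numpy(float),
        objective_trace=[float(meta["final_objective"])],
        restart_stability=np.asarray(meta["restart_stability"], float),
        seed=int(meta["seed"]), converged=bool(meta["converged"]),
        intercept=(scaling["intercept"].to_numpy(float)
                   if "intercept" in scaling.columns else None))


def save_pca_model(model: PCAModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"PC{i + 1}" for i in range(model.loadings.shape[1])]
    df = pd.DataFrame(model.loadings, index=model.gene_ids, columns=cols)
    df.insert(0, "center", model.center)
    df.rename_axis("gene_id").to_csv(outdir / "loadings.tsv", sep="\t",
                                     float_format="%.10g")
    (outdir / "model.json").write_text(json.dumps({
        "n_components": len(cols),
        "explained_variance_fraction":
            [float(f) for f in model.explained_variance_fraction],
    }, indent=2) + "\n", encoding="utf-8")


def load_pca_model(outdir: str | Path) -> PCAModel:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "loadings.tsv", sep="\t", index_col=0)
    meta = json.loads((outdir / "model.json").read_text())
    center = df.pop("center").to_numpy(float)
    return PCAModel(
        loadings=df.to_numpy(float), center=center,
        explained_variance_fraction=np.asarray(
            meta["explained_variance_fraction"], float),
        gene_ids=[str(g) for g in df.index])
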