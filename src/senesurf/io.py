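"""Plain-text I/O for pipeline artifacts.

PSM matrices travel as wide TSV (rows = proteins, columns = sample ids,
missing = empty field) alongside a design TSV; annotation tables are TSV;
single-cell data is written either as a MatrixMarket sparse triplet plus
cell/gene metadata TSVs or as a dense TSV for small fixtures. Every emitted
file set carries a sidecar JSON recording the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .funnel import AnnotationBundle
from .psm import PsmMatrix
from .sc import SingleCellBinary


def config_hash(config) -> str:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_sidecar(path: Path, config, seed: int) -> None:
    sidecar = {"config_hash": config_hash(config), "seed": int(seed)}
    Path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def write_psm(matrix: PsmMatrix, outdir: str | Path, config=None, seed: int = 0) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(outdir / "psm_matrix.tsv", sep="\t", na_rep="",
                         index_label="protein_id")
    matrix.design.to_csv(outdir / "design.tsv", sep="\t", index_label="sample_id")
    if config is not None:
        write_sidecar(outdir / "psm_matrix.meta.json", config, seed)


def read_psm(outdir: str | Path) -> PsmMatrix:
    outdir = Path(outdir)
    values = pd.read_csv(outdir / "psm_matrix.tsv", sep="\t", index_col="protein_id")
    design = pd.read_csv(outdir / "design.tsv", sep="\t", index_col="sample_id")
    return PsmMatrix(values=values, design=design)


def write_bundle(bundle: AnnotationBundle, outdir: str | Path,
                 config=None, seed: int = 0) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.surface_flags.rename("is_surface").to_csv(
        outdir / "surface_flags.tsv", sep="\t", index_label="protein_id"
    )
    bundle.homolog_map.to_csv(outdir / "homolog_map.tsv", sep="\t", index=False)
    bundle.tissue_atlas.to_csv(outdir / "tissue_atlas.tsv", sep="\t",
                               index_label="gene_id")
    rows = [
        {"signature": name, "protein_id": pid}
        for name, members in sorted(bundle.signatures.items())
        for pid in sorted(members)
    ]
    pd.DataFrame(rows, columns=["signature", "protein_id"]).to_csv(
        outdir / "signatures.tsv", sep="\t", index=False
    )
    bundle.lr_catalog.to_csv(outdir / "lr_catalog.tsv", sep="\t", index=False)
    if config is not None:
        write_sidecar(outdir / "bundle.meta.json", config, seed)


def read_bundle(outdir: str | Path) -> AnnotationBundle:
    outdir = Path(outdir)
    flags = pd.read_csv(outdir / "surface_flags.tsv", sep="\t",
                        index_col="protein_id")["is_surface"].astype(bool)
    homolog = pd.read_csv(outdir / "homolog_map.tsv", sep="\t")
    atlas = pd.read_csv(outdir / "tissue_atlas.tsv", sep="\t", index_col="gene_id")
    sig_df = pd.read_csv(outdir / "signatures.tsv", sep="\t")
    signatures = {
        name: frozenset(group["protein_id"])
        for name, group in sig_df.groupby("signature")
    }
    lr = pd.read_csv(outdir / "lr_catalog.tsv", sep="\t")
    return AnnotationBundle(
        surface_flags=flags,
        homolog_map=homolog,
        tissue_atlas=atlas,
        signatures=signatures,
        lr_catalog=lr,
    )


def write_sc(data: SingleCellBinary, outdir: str | Path, dense: bool = False,
             config=None, seed: int = 0) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dense:
        data.calls.to_csv(outdir / "sc_calls.tsv", sep="\t", index_label="cell_id")
    else:
        mat = sparse.csr_matrix(data.calls.to_numpy(dtype=np.int8))
        scipy_io.mmwrite(str(outdir / "sc_calls.mtx"), mat)
        pd.Series(data.calls.columns, name="gene").to_csv(
            outdir / "sc_genes.tsv", sep="\t", index=False
        )
    data.obs.to_csv(outdir / "sc_cells.tsv", sep="\t", index_label="cell_id")
    if config is not None:
        write_sidecar(outdir / "sc.meta.json", config, seed)


def read_sc(outdir: str | Path) -> SingleCellBinary:
    outdir = Path(outdir)
    obs = pd.read_csv(outdir / "sc_cells.tsv", sep="\t", index_col="cell_id")
    dense = outdir / "sc_calls.tsv"
    if dense.exists():
        calls = pd.read_csv(dense, sep="\t", index_col="cell_id")
    else:
        mat = scipy_io.mmread(str(outdir / "sc_calls.mtx")).toarray()
        genes = pd.read_csv(outdir / "sc_genes.tsv", sep="\t")["gene"]
        calls = pd.DataFrame(mat.astype(np.int8), index=obs.index, columns=genes)
    return SingleCellBinary(calls=calls.astype(np.int8), obs=obs)
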