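"""Plain-text readers and writers for the pipeline's table formats.

Counts travel as MTX (genes x cells) plus genes.tsv / cells.tsv; ISH
sections as nuclei.csv / puncta.csv / regions.csv (um, origin top-left,
y down, polygon vertices CCW-ordered); traces as a long-format
traces.csv (cell_id, region, condition, t_s, F).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from shapely.geometry import Polygon

from .simulate.ish import IshSection
from .simulate.traces import CalciumRecording


# -- count matrices ------------------------------------------------------

def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write matrix.mtx (genes x cells), genes.tsv and cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    mat = sparse.csr_matrix(x if not hasattr(x, "todense") else x)
    spio.mmwrite(str(outdir / "matrix.mtx"), mat.T.astype(int))
    pd.DataFrame({"gene": adata.var_names}).assign(
        **{c: adata.var[c].to_numpy() for c in adata.var.columns}
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame({"cell": adata.obs_names})
    for c in adata.obs.columns:
        cells[c] = adata.obs[c].to_numpy()
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a matrix written by :func:`write_counts`."""
    indir = Path(indir)
    mat = spio.mmread(str(indir / "matrix.mtx")).tocsr().T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    var = genes.set_index("gene")
    obs = cells.set_index("cell")
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=np.asarray(mat.todense(), dtype=np.int32),
                      obs=obs, var=var)


# -- ISH sections --------------------------------------------------------

def write_section(section: IshSection, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    section.nuclei.to_csv(outdir / "nuclei.csv", index=False)
    section.puncta.to_csv(outdir / "puncta.csv", index=False)
    rows = []
    for name, poly in section.regions.items():
        xs, ys = poly.exterior.coords.xy
        for i, (x, y) in enumerate(zip(xs[:-1], ys[:-1])):
            rows.append((name, i, x, y))
    pd.DataFrame(rows, columns=["region", "vertex_index", "x_um", "y_um"]
                 ).to_csv(outdir / "regions.csv", index=False)
    with open(outdir / "meta.csv", "w") as fh:
        fh.write("section_id,animal_id\n")
        fh.write(f"{section.section_id},{section.animal_id}\n")


def read_section(indir: str | Path) -> IshSection:
    indir = Path(indir)
    nuclei = pd.read_csv(indir / "nuclei.csv")
    puncta = pd.read_csv(indir / "puncta.csv")
    reg = pd.read_csv(indir / "regions.csv")
    regions = {
        name: Polygon(g.sort_values("vertex_index")[["x_um", "y_um"]].to_numpy())
        for name, g in reg.groupby("region")
    }
    meta_path = indir / "meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path).iloc[0]
        sid, animal = str(meta["section_id"]), str(meta["animal_id"])
    else:
        sid = animal = indir.name
    section = IshSection(sid, animal, regions, nuclei, puncta)
    section.validate()
    return section


# -- calcium traces ------------------------------------------------------

def recordings_to_frame(recordings: Iterable[CalciumRecording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        t = np.arange(len(rec.fluorescence)) / rec.sampling_rate
        rows.append(pd.DataFrame({
            "cell_id": rec.cell_id, "region": rec.region,
            "condition": rec.condition, "t_s": t, "F": rec.fluorescence}))
    return pd.concat(rows, ignore_index=True)


def frame_to_recordings(frame: pd.DataFrame) -> list[CalciumRecording]:
    out = []
    for (cell, cond), g in frame.groupby(["cell_id", "condition"], sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"trace {cell}/{cond} too short")
        dt = float(np.median(np.diff(t)))
        rate = 1.0 / dt
        rec = CalciumRecording(
            cell_id=str(cell), region=str(g["region"].iloc[0]),
            condition=str(cond), sampling_rate=rate,
            fluorescence=g["F"].to_numpy(dtype=float),
            duration=len(t) * dt)
        rec.validate()
        out.append(rec)
    return out


def write_traces(recordings: Iterable[CalciumRecording],
                 path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    recordings_to_frame(recordings).to_csv(path, index=False,
                                           float_format="%.5f")


def read_traces(path: str | Path) -> list[CalciumRecording]:
    return frame_to_recordings(pd.read_csv(path))
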