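"""ISH section quantification: puncta -> cells -> marker calls -> subtypes.

Cells are modelled as disks centred on DAPI nuclei with area 1.3x the
nuclear area.  Puncta above the fluorescence background threshold are
assigned to the nearest containing disk and counted per channel; counts
become +/- calls via per-marker thresholds, the ordered rule table maps
calls to subtypes, and per-region distributions are averaged across
sections (mean per section +/- SEM, plus fractions normalized to all
Slc1a3+ cells in the region).  A threshold sweep quantifies robustness
of the classification to the background-threshold choice.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import contains_xy

from .rules import (
    DEFAULT_RULES,
    MARKER_GENES,
    SubtypeRule,
    classify_count_table,
)
from .simulate.ish import IshSection

DEFAULT_INTENSITY_THR = 100.0
DEFAULT_THETA_HI = 5
DEFAULT_THETA_LO = 2
OUTSIDE = "outside"


def build_cell_polygons(nuclei: pd.DataFrame,
                        area_scale: float = 1.3) -> pd.DataFrame:
    """Disk per nucleus: area = area_scale * nuclear area.

    Returns a table (cell_id, x_um, y_um, radius_um); the radius is
    sqrt(scale * A / pi).
    """
    if area_scale <= 0:
        raise ValueError("area_scale must be positive")
    if len(nuclei) and (nuclei["area_um2"] <= 0).any():
        raise ValueError("nuclear areas must be positive")
    out = nuclei[["cell_id", "x_um", "y_um"]].copy()
    out["radius_um"] = np.sqrt(
        area_scale * nuclei["area_um2"].to_numpy() / np.pi)
    return out


def count_puncta(
    section: IshSection,
    polygons: pd.DataFrame,
    gene: str,
    intensity_thr: float = DEFAULT_INTENSITY_THR,
) -> pd.Series:
    """Per-cell count of above-threshold puncta of one channel.

    A punctum inside several overlapping disks is assigned to the cell
    with the nearest centroid; exact ties go to the lowest cell index.
    """
    available = sorted(section.puncta["gene"].unique())
    if gene not in available:
        raise ValueError(
            f"no channel for gene {gene!r}; available: {available}")
    counts = pd.Series(0, index=polygons["cell_id"], name=gene, dtype=int)
    if polygons.empty:
        return counts
    sel = section.puncta[
        (section.puncta["gene"] == gene)
        & (section.puncta["intensity"] > intensity_thr)]
    if sel.empty:
        return counts
    centers = polygons[["x_um", "y_um"]].to_numpy()
    radii = polygons["radius_um"].to_numpy()
    rmax = radii.max()
    tree = cKDTree(centers)
    pts = sel[["x_um", "y_um"]].to_numpy()
    neighbours = tree.query_ball_point(pts, rmax)
    for pt, cand in zip(pts, neighbours):
        if not cand:
            continue
        cand = np.array(sorted(cand))  # sorted -> ties pick lowest id
        d = np.linalg.norm(centers[cand] - pt, axis=1)
        inside = d <= radii[cand]
        if not inside.any():
            continue
        cand, d = cand[inside], d[inside]
        winner = cand[np.argmin(d)]
        counts.iloc[winner] += 1
    return counts


def _assign_regions(section: IshSection, polygons: pd.DataFrame) -> pd.Series:
    region = pd.Series(OUTSIDE, index=polygons["cell_id"], name="region",
                       dtype=object)
    xs = polygons["x_um"].to_numpy()
    ys = polygons["y_um"].to_numpy()
    for name, poly in section.regions.items():
        mask = contains_xy(poly, xs, ys)
        region.iloc[np.flatnonzero(mask)] = name
    return region


def quantify_section(
    section: IshSection,
    rules: tuple[SubtypeRule, ...] = DEFAULT_RULES,
    panel: str = "full",
    area_scale: float = 1.3,
    intensity_thr: float = DEFAULT_INTENSITY_THR,
    theta_hi: float | Mapping[str, float] = DEFAULT_THETA_HI,
    theta_lo: float | Mapping[str, float] = DEFAULT_THETA_LO,
) -> pd.DataFrame:
    """Full per-cell quantification of one section.

    Returns one row per nucleus: region (or "outside"), per-gene puncta
    counts (``n_<gene>``), astrocyte flag (Slc1a3 "+") and the rule-based
    subtype (non-astrocytes carry ``"non-astrocyte"``).
    """
    polygons = build_cell_polygons(section.nuclei, area_scale)
    counts = pd.DataFrame(index=polygons["cell_id"])
    present = set(section.puncta["gene"].unique())
    for gene in MARKER_GENES:
        if gene in present:
            counts[gene] = count_puncta(section, polygons, gene, intensity_thr)
        else:
            counts[gene] = 0
    subtype = classify_count_table(counts, rules, panel, theta_hi, theta_lo)
    out = pd.DataFrame({
        "section_id": section.section_id,
        "cell_id": counts.index,
        "region": _assign_regions(section, polygons).to_numpy(),
    }).set_index("cell_id")
    for gene in MARKER_GENES:
        out[f"n_{gene}"] = counts[gene]
    out["is_astrocyte"] = (subtype != "non-astrocyte").to_numpy()
    out["subtype"] = subtype.to_numpy()
    return out.reset_index()[["section_id", "cell_id", "region"]
                             + [f"n_{g}" for g in MARKER_GENES]
                             + ["is_astrocyte", "subtype"]]


def region_distribution(cell_calls: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per (region, subtype): mean count per section, SEM, and the
    fraction normalized to all Slc1a3+ cells of that region.

    Cells outside every region polygon are excluded.  With a single
    section SEM is 0 by convention and flagged in ``sem_defined``.
    """
    if not cell_calls:
        raise ValueError("need at least one quantified section")
    allc = pd.concat(cell_calls, ignore_index=True)
    allc = allc[allc["region"] != OUTSIDE]
    sections = sorted(allc["section_id"].unique())
    n_sec = len(sections)
    astro = allc[allc["is_astrocyte"]]
    subtypes = sorted(s for s in astro["subtype"].unique())
    rows = []
    for region in sorted(allc["region"].unique()):
        in_region = astro[astro["region"] == region]
        total_astro = len(in_region)
        for st in subtypes:
            per_sec = np.array([
                ((in_region["section_id"] == sec)
                 & (in_region["subtype"] == st)).sum()
                for sec in sections], dtype=float)
            mean = per_sec.mean() if n_sec else 0.0
            sem = (per_sec.std(ddof=1) / np.sqrt(n_sec)) if n_sec > 1 else 0.0
            frac = (per_sec.sum() / total_astro) if total_astro else 0.0
            rows.append((region, st, mean, sem, n_sec > 1, frac))
    out = pd.DataFrame(rows, columns=[
        "region", "subtype", "mean_count_per_section", "sem",
        "sem_defined", "astro_fraction"])
    return out


def threshold_sweep(
    sections: Sequence[IshSection],
    thr_grid: Sequence[float],
    rules: tuple[SubtypeRule, ...] = DEFAULT_RULES,
    panel: str = "full",
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Robustness of the subtype mapping to the fluorescence threshold.

    Re-runs count -> call -> classify for every threshold in the grid and
    reports (a) per region x subtype the range of normalized fractions
    over the grid and (b) the fraction of cells whose subtype label stays
    constant across the grid.
    """
    if len(thr_grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    frac_tables = []
    label_runs = []
    for thr in thr_grid:
        calls = [quantify_section(s, rules, panel, intensity_thr=thr, **kwargs)
                 for s in sections]
        dist = region_distribution(calls)
        dist["intensity_thr"] = thr
        frac_tables.append(dist)
        lab = pd.concat(calls, ignore_index=True)
        label_runs.append(lab.set_index(["section_id", "cell_id"])["subtype"])
    labels = pd.concat(label_runs, axis=1)
    stable = (labels.nunique(axis=1) == 1).mean()
    nonempty = [t for t in frac_tables if not t.empty]
    fracs = (pd.concat(nonempty, ignore_index=True) if nonempty
             else frac_tables[0])
    ranges = (fracs.groupby(["region", "subtype"])["astro_fraction"]
              .agg(["min", "max"]).reset_index())
    ranges["fraction_range"] = ranges["max"] - ranges["min"]
    stability = pd.DataFrame({"stable_label_fraction": [float(stable)],
                              "n_thresholds": [len(thr_grid)]})
    return {"fraction_ranges": ranges, "stability": stability,
            "per_threshold": fracs}
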