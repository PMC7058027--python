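"""Synthetic multiplexed-ISH sections with planted subtype placement.

Each section carries named region polygons (um, origin top-left, y down),
nuclei placed per region at the configured density, and per-channel
puncta.  A nucleus is assigned a true subtype from its region's profile;
"+" channels receive Poisson(puncta_mean_pos) puncta and "-" channels
Poisson(puncta_mean_neg), scattered inside the cell disk (1.3x the
nuclear area, drawn slightly inside the boundary so every signal punctum
falls within its generating disk).  Background puncta are uniform over
the section with a distinctly lower intensity than signal puncta, which
is what makes the intensity-threshold robustness sweep meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ..config import GeneratorConfig
from ..rules import MARKER_GENES

NON_ASTRO = "other"


@dataclass
class IshSection:
    """One quantified section: regions, nuclei and per-channel puncta."""

    section_id: str
    animal_id: str
    regions: dict[str, Polygon]
    nuclei: pd.DataFrame   # cell_id, x_um, y_um, area_um2
    puncta: pd.DataFrame   # gene, x_um, y_um, intensity

    def validate(self) -> None:
        if (self.nuclei["area_um2"] <= 0).any():
            raise ValueError("nuclear areas must be positive")
        if (self.puncta["intensity"] < 0).any():
            raise ValueError("puncta intensities must be non-negative")
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.regions[a].intersection(self.regions[b])
                if inter.area > 1e-6:
                    raise ValueError(
                        f"region polygons {a!r} and {b!r} overlap")


def box_polygon(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    """Axis-aligned rectangle as a CCW-closed polygon (y-down frame)."""
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def gen_ish_section(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[IshSection], pd.DataFrame]:
    """Generate the configured number of sections plus truth labels.

    Returns the sections and a truth table (section_id, cell_id,
    true_subtype) where non-astrocyte nuclei carry ``"other"``.
    Deterministic given config + seed.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    ish = cfg.ish
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    regions = {name: box_polygon(*bx) for name, bx in ish.region_boxes.items()}
    sections: list[IshSection] = []
    truth_rows: list[tuple[str, str, str]] = []

    for s in range(ish.n_sections):
        sid = f"section_{s + 1}"
        animal = f"animal_{s + 1}"
        nuc_rows: list[tuple[str, float, float, float]] = []
        subtype_of: list[str] = []
        for name, poly in regions.items():
            profile = ish.region_profiles.get(name, {})
            if not profile:
                continue
            area_mm2 = poly.area / 1e6
            n_nuc = rng.poisson(ish.nuclei_density_per_mm2 * area_mm2)
            if n_nuc == 0:
                continue
            x0, y0, x1, y1 = poly.bounds
            xs = rng.uniform(x0, x1, n_nuc)
            ys = rng.uniform(y0, y1, n_nuc)
            areas = np.clip(
                rng.normal(ish.nucleus_area_mean_um2,
                           ish.nucleus_area_sd_um2, n_nuc),
                ish.nucleus_area_min_um2, None)
            choices = list(profile)
            p = np.array([profile[c] for c in choices], dtype=float)
            leftover = 1.0 - p.sum()
            if leftover > 1e-9:
                choices.append(NON_ASTRO)
                p = np.append(p, leftover)
            p = p / p.sum()
            kinds = rng.choice(choices, size=n_nuc, p=p)
            for x, y, a, kind in zip(xs, ys, areas, kinds):
                nuc_rows.append((x, y, a))
                subtype_of.append(kind)
        nuclei = pd.DataFrame(nuc_rows, columns=["x_um", "y_um", "area_um2"])
        nuclei.insert(0, "cell_id",
                      [f"{sid}_c{i + 1:04d}" for i in range(len(nuclei))])

        # per-cell signal puncta
        punc_rows: list[tuple[str, float, float, float]] = []
        radii = np.sqrt(ish.area_scale * nuclei["area_um2"].to_numpy() / np.pi)
        for i, kind in enumerate(subtype_of):
            cx = nuclei["x_um"].iat[i]
            cy = nuclei["y_um"].iat[i]
            r = radii[i] * 0.9  # keep signal puncta inside the disk
            fp = cfg.fingerprint.get(kind)
            for gene in MARKER_GENES:
                state = fp.get(gene, "-") if fp is not None else "-"
                lam = (ish.puncta_mean_pos if state == "+"
                       else ish.puncta_mean_neg)
                n_p = rng.poisson(lam)
                if n_p == 0:
                    continue
                rad = r * np.sqrt(rng.random(n_p))
                ang = rng.uniform(0, 2 * np.pi, n_p)
                inten = np.clip(
                    rng.normal(ish.intensity_signal_mean,
                               ish.intensity_signal_sd, n_p), 0, None)
                for dx, dy, it in zip(rad * np.cos(ang), rad * np.sin(ang),
                                      inten):
                    punc_rows.append((gene, cx + dx, cy + dy, it))

        # uniform low-intensity background puncta per channel
        if ish.background_rate_per_um2 > 0:
            all_x = [b[0] for b in ish.region_boxes.values()] + \
                    [b[2] for b in ish.region_boxes.values()]
            all_y = [b[1] for b in ish.region_boxes.values()] + \
                    [b[3] for b in ish.region_boxes.values()]
            bx0, bx1 = min(all_x), max(all_x)
            by0, by1 = min(all_y), max(all_y)
            sect_area = (bx1 - bx0) * (by1 - by0)
            for gene in MARKER_GENES:
                n_b = rng.poisson(ish.background_rate_per_um2 * sect_area)
                if n_b == 0:
                    continue
                xs = rng.uniform(bx0, bx1, n_b)
                ys = rng.uniform(by0, by1, n_b)
                inten = np.clip(
                    rng.normal(ish.intensity_background_mean,
                               ish.intensity_background_sd, n_b), 0, None)
                for x, y, it in zip(xs, ys, inten):
                    punc_rows.append((gene, x, y, it))

        puncta = pd.DataFrame(
            punc_rows, columns=["gene", "x_um", "y_um", "intensity"])
        section = IshSection(sid, animal, regions, nuclei, puncta)
        section.validate()
        sections.append(section)
        truth_rows += [(sid, cid, kind) for cid, kind in
                       zip(nuclei["cell_id"], subtype_of)]

    truth = pd.DataFrame(truth_rows,
                         columns=["section_id", "cell_id", "true_subtype"])
    return sections, truth
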