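"""Synthetic gene x cell count matrices with planted ground truth.

Counts are negative-binomial per gene, with the mean set by the cell
type's fingerprint state (high / low-absent / housekeeping).  The gene
universe is built so that a fixed, known set of exactly
``planted_hvg_count`` genes exceeds the astrocyte-pass HVG thresholds
(ln-mean > 0.5, ln-variance/mean > 0.5) with margin, while every other
gene class sits clearly below one of the two thresholds:

* planted HVG genes are "high" in a subset of subtypes whose frequency
  mass lies inside ``hvg_freq_band`` (bimodal -> large mean and
  dispersion);
* housekeeping and pan-astrocyte genes are high in every cell
  (large mean, small dispersion);
* low genes are near-silent everywhere (small mean);
* marker genes follow the fingerprint; the ones whose pattern happens to
  fall inside the band (Gfap, Agt, Unc13c under the default fingerprint)
  are counted as part of the planted set.
"""

from __future__ import annotations

from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd

from ..config import (
    GeneratorConfig,
    HIGHER_ORDER_PANELS,
    default_astrocyte_config,
)
from ..rules import MARKER_GENES

GENE_CLASSES = ("marker", "hvg", "astro_common", "housekeeping", "low",
                "contaminant_panel")


def _admissible_patterns(freqs: dict[str, float],
                         band: tuple[float, float]) -> list[frozenset[str]]:
    """Nonempty proper subtype subsets with frequency mass inside band."""
    subtypes = sorted(freqs)
    out = []
    for r in range(1, len(subtypes)):
        for combo in combinations(subtypes, r):
            mass = sum(freqs[s] for s in combo)
            if band[0] <= mass <= band[1]:
                out.append(frozenset(combo))
    return out


def _build_gene_table(cfg: GeneratorConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    ex = cfg.expression
    subtypes = sorted(ex.subtype_freqs)
    band = ex.hvg_freq_band
    rows: list[tuple[str, str, frozenset[str], bool]] = []

    marker_in_band = 0
    for gene in MARKER_GENES:
        pattern = frozenset(
            s for s in subtypes if cfg.fingerprint[s].get(gene) == "+")
        mass = sum(ex.subtype_freqs[s] for s in pattern)
        planted = bool(pattern) and len(pattern) < len(subtypes) and (
            band[0] <= mass <= band[1])
        marker_in_band += planted
        rows.append((gene, "marker", pattern, planted))

    n_random = ex.planted_hvg_count - marker_in_band
    if n_random < 0:
        raise ValueError(
            "planted_hvg_count smaller than the number of in-band markers")
    admissible = _admissible_patterns(ex.subtype_freqs, band)
    if n_random > 0 and not admissible:
        raise ValueError(
            "no admissible HVG pattern exists for the configured "
            "subtype frequencies; set planted_hvg_count accordingly")
    for i in range(n_random):
        pattern = admissible[rng.integers(len(admissible))]
        rows.append((f"Hvg{i + 1:04d}", "hvg", pattern, True))

    common_names = ["Aqp4", "Apoe"] + [
        f"Astc{i + 1:03d}" for i in range(max(0, ex.n_astro_common - 2))]
    all_sub = frozenset(subtypes)
    for gene in common_names[: ex.n_astro_common]:
        rows.append((gene, "astro_common", all_sub, False))
    for i in range(ex.n_housekeeping):
        rows.append((f"Hk{i + 1:04d}", "housekeeping", frozenset(), False))
    for i in range(ex.n_low_genes):
        rows.append((f"Low{i + 1:04d}", "low", frozenset(), False))
    for celltype, panel in HIGHER_ORDER_PANELS.items():
        if celltype == "astrocyte":
            continue  # astrocyte panel genes already present
        for gene in panel:
            rows.append((gene, "contaminant_panel", frozenset({celltype}), False))

    table = pd.DataFrame(rows, columns=["gene", "gene_class", "pattern",
                                        "planted_hvg"])
    if table["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers in gene table")
    return table.set_index("gene")


def _type_profiles(cfg: GeneratorConfig, genes: pd.DataFrame,
                   types: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and NB shape matrices, types x genes."""
    nb = cfg.expression.nb
    n_genes = len(genes)
    mean = np.full((len(types), n_genes), nb.mean_low)
    shape = np.full((len(types), n_genes), nb.disp_low)
    cls = genes["gene_class"].to_numpy()
    patterns = genes["pattern"].to_numpy()
    house = cls == "housekeeping"
    for ti, t in enumerate(types):
        if t == "low_quality":
            continue
        member = np.array([t in p for p in patterns])
        hot = member & np.isin(cls, ("marker", "hvg", "astro_common",
                                     "contaminant_panel"))
        mean[ti, hot] = nb.mean_high
        shape[ti, hot] = nb.disp_high
        mean[ti, house] = nb.mean_house
        shape[ti, house] = nb.disp_house
    if "low_quality" in types:
        # a degraded library: the astrocyte-average profile scaled far
        # below the QC floor
        ti = types.index("low_quality")
        sub = sorted(cfg.expression.subtype_freqs)
        w = np.array([cfg.expression.subtype_freqs[s] for s in sub])
        idx = [types.index(s) for s in sub]
        avg = w @ mean[idx]
        mean[ti] = avg * nb.low_quality_scale
        shape[ti] = nb.disp_low
    return mean, shape


def _sample_nb(rng: np.random.Generator, mean: np.ndarray,
               shape: np.ndarray, n: int) -> np.ndarray:
    """n i.i.d. rows of NB counts with the given per-gene mean/shape."""
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=(n, len(mean))).astype(np.int32)


def gen_expression(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[ad.AnnData, pd.Series]:
    """Generate a synthetic count matrix with planted truth labels.

    Returns an AnnData (cells x genes, raw integer counts in ``X``, cell
    metadata ``region``/``batch``/``truth_label`` in ``obs``, gene class
    and planted-HVG flags in ``var``) and the truth-label Series.

    Astrocyte subtype labels are multinomial draws from
    ``subtype_freqs``; contaminant and low-quality cells are planted at
    their exact configured counts.  Deterministic given config + seed.
    """
    cfg = config or default_astrocyte_config()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    rng_genes, rng_labels, rng_counts, rng_meta = (
        np.random.default_rng(c) for c in ss.spawn(4))

    ex = cfg.expression
    genes = _build_gene_table(cfg, rng_genes)
    subtypes = sorted(ex.subtype_freqs)
    contaminants = sorted(ex.contaminant_counts)
    types = subtypes + contaminants
    if ex.n_low_quality:
        types = types + ["low_quality"]
    mean, shape = _type_profiles(cfg, genes, types)

    probs = np.array([ex.subtype_freqs[s] for s in subtypes])
    astro_labels = rng_labels.choice(subtypes, size=ex.n_astrocytes, p=probs)
    labels = list(astro_labels)
    for c in contaminants:
        labels += [c] * ex.contaminant_counts[c]
    labels += ["low_quality"] * ex.n_low_quality
    labels = np.array(labels, dtype=object)
    order = rng_labels.permutation(len(labels))
    labels = labels[order]

    counts = np.empty((len(labels), len(genes)), dtype=np.int32)
    for ti, t in enumerate(types):
        mask = labels == t
        if mask.any():
            counts[mask] = _sample_nb(rng_counts, mean[ti], shape[ti],
                                      int(mask.sum()))

    hp_prob = np.array([cfg.expression.hp_probs.get(t, 0.5) for t in labels])
    region = np.where(rng_meta.random(len(labels)) < hp_prob, "HP", "CX")
    batch = rng_meta.integers(1, ex.n_batches + 1, size=len(labels))

    obs = pd.DataFrame({
        "region": pd.Categorical(region, categories=["CX", "HP"]),
        "batch": [f"b{b}" for b in batch],
        "truth_label": labels,
    }, index=[f"cell_{i + 1:04d}" for i in range(len(labels))])
    var = pd.DataFrame({
        "gene_class": genes["gene_class"].to_numpy(),
        "planted_hvg": genes["planted_hvg"].to_numpy(),
    }, index=genes.index)

    adata = ad.AnnData(X=counts, obs=obs, var=var)
    truth = pd.Series(labels, index=adata.obs_names, name="truth_label")
    return adata, truth
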