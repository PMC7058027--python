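#!/usr/bin/env python
"""Single-cell pipeline over the simulated count matrix.

QC (54-transcript floor) -> ln-normalization -> all-cell HVG pass
(ln-mean > 0.3, dispersion > 0.1) -> clustering -> marker-panel typing
-> astrocyte extraction -> astrocyte HVG pass (0.5, 0.5) ->
re-clustering into subtypes -> marker calling and proportions.

Reads results/synthetic/counts (run 01_simulate.py first); writes the
qc report, HVG tables, cluster labels, marker tables and proportions
under results/sc/.
"""

from pathlib import Path

import pandas as pd

from astromap import io as aio
from astromap import sc
from astromap.config import HIGHER_ORDER_PANELS

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "sc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    adata = aio.read_counts(ROOT / "synthetic" / "counts")

    kept, discarded = sc.qc_filter_cells(adata)
    pd.DataFrame({"discarded_cell": discarded}).to_csv(
        OUT / "qc_discarded.csv", index=False)
    print(f"QC: {len(discarded)} of {adata.n_obs} libraries below the "
          f"{sc.QC_MIN_TOTAL}-transcript floor; {kept.n_obs} kept")

    norm = sc.ln_normalize(kept)
    hvg_all = sc.select_hvg(norm, *sc.HVG_ALL_CELLS)
    hvg_all.to_csv(OUT / "hvg_all_cells.csv")
    clusters = sc.cluster_cells(norm, hvg_all)
    typing = sc.assign_higher_order_types(norm, HIGHER_ORDER_PANELS, clusters)
    print(f"higher-order clustering: k={clusters.k}, panel typing {typing}")

    astro = sc.extract_type(kept, clusters, typing, "astrocyte")
    print(f"astrocyte extraction: {astro.n_obs} cells")

    astro_norm = sc.ln_normalize(astro)
    hvg_astro = sc.select_hvg(astro_norm, *sc.HVG_ASTROCYTES)
    hvg_astro.to_csv(OUT / "hvg_astrocytes.csv")
    print(f"astrocyte HVG pass: {int(hvg_astro.selected.sum())} genes "
          f"(ln-mean > {sc.HVG_ASTROCYTES[0]}, "
          f"dispersion > {sc.HVG_ASTROCYTES[1]})")

    sub = sc.cluster_cells(astro_norm, hvg_astro)
    pd.DataFrame({"cell": astro.obs_names, "cluster": sub.labels}).to_csv(
        OUT / "astrocyte_clusters.csv", index=False)
    print(f"astrocyte re-clustering: k={sub.k} subtypes "
          f"(best silhouette {max(sub.silhouette_by_k.values()):.3f})")

    markers = pd.concat(
        [sc.find_markers(astro_norm, sub, cl) for cl in range(sub.k)],
        ignore_index=True)
    markers.to_csv(OUT / "markers.csv", index=False)
    passing = markers[markers.passes]
    print(f"markers passing p<0.01 / fold>=1.28 / pct>0.25: "
          f"{len(passing)} records across {sub.k} clusters")

    props = sc.subtype_proportions(sub, astro.obs)
    props.to_csv(OUT / "proportions.csv")
    print("cluster proportions (fraction of astrocytes):")
    print(props["fraction"].round(4).to_string())


if __name__ == "__main__":
    main()
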