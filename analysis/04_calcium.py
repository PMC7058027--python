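#!/usr/bin/env python
"""Ca2+ transient analysis over the simulated recordings.

dF/F0 against the first-100-s baseline, four-threshold peak detection
(height 1.15, prominence 0.1, width 2 s, separation 1 s), per-cell
parameterization, PHE-responder filtering, Ward + silhouette clustering
of the z-scaled PHE parameters, and Kruskal-Wallis / Dunn / BH
comparisons across regions and clusters.

Reads results/synthetic/traces.csv (run 01_simulate.py first); writes
peaks.csv, cell_params.csv, clusters.csv, cluster_composition.csv and
stats.csv under results/calcium/.
"""

from pathlib import Path

import pandas as pd

from astromap import io as aio
from astromap.calcium import (
    analyze_recordings,
    cluster_physiology,
    compare_groups,
    filter_responders,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "calcium"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    recordings = aio.read_traces(ROOT / "synthetic" / "traces.csv")

    peaks, params = analyze_recordings(recordings)
    peaks.to_csv(OUT / "peaks.csv", index=False)
    params.to_csv(OUT / "cell_params.csv", index=False)
    n_cells = params.cell_id.nunique()
    print(f"{len(peaks)} transients detected across {n_cells} cells")

    retained, report = filter_responders(params)
    print(f"PHE responders: {report['n_responders']} of {n_cells}; "
          f"active under BASE {report['fraction_active_BASE']:.1%}, "
          f"under TTX {report['fraction_active_TTX']:.1%}")

    clusters, composition = cluster_physiology(retained)
    composition.to_csv(OUT / "cluster_composition.csv")
    phe = retained[(retained.condition == "PHE") & retained.active]
    labels = phe[["cell_id", "region"]].copy()
    labels["cluster"] = clusters.labels
    labels.to_csv(OUT / "clusters.csv", index=False)
    print(f"physiology clustering: k={clusters.k} "
          f"(best silhouette {max(clusters.silhouette_by_k.values()):.3f})")
    print("region composition per cluster:")
    print(composition.round(3).to_string())

    merged = retained.merge(labels[["cell_id", "cluster"]], on="cell_id")
    tables = [compare_groups(merged, "region", cond)
              for cond in ("BASE", "TTX", "PHE")]
    tables.append(compare_groups(merged, "cluster", "PHE"))
    stats = pd.concat(tables, ignore_index=True)
    stats.to_csv(OUT / "stats.csv", index=False)
    kw_phe = stats[(stats.test == "kruskal-wallis")].copy()
    sig = kw_phe[kw_phe.p_value < 0.05]
    print(f"Kruskal-Wallis: {len(sig)}/{len(kw_phe)} parameter x grouping "
          f"comparisons significant at p<0.05")


if __name__ == "__main__":
    main()
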