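#!/usr/bin/env python
"""Generate the three synthetic datasets with planted ground truth.

Writes under results/synthetic/:
  counts/    - 2031-library higher-order mixture (MTX + TSV), with 16
               planted below-QC-floor libraries and 204 contaminants
  ish/       - three ISH sections (nuclei/puncta/regions CSVs)
  traces.csv - 614 cells x three conditions (BASE/TTX/PHE) at 2 Hz
plus the truth tables the later scripts score against.
"""

from pathlib import Path

from astromap import io as aio
from astromap.config import GeneratorConfig, default_mixture_config
from astromap.simulate import gen_expression, gen_ish_section, gen_traces

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    adata, truth = gen_expression(default_mixture_config(seed=SEED))
    aio.write_counts(adata, OUT / "counts")
    truth.rename("truth_label").to_csv(OUT / "counts" / "truth_labels.csv")
    print(f"expression: {adata.n_obs} libraries x {adata.n_vars} genes "
          f"({(truth == 'low_quality').sum()} planted low-quality, "
          f"{truth.str.startswith('AST').sum()} astrocytes)")

    sections, ish_truth = gen_ish_section(GeneratorConfig(seed=SEED))
    for sec in sections:
        aio.write_section(sec, OUT / "ish" / sec.section_id)
    ish_truth.to_csv(OUT / "ish" / "truth_subtypes.csv", index=False)
    print(f"ish: {len(sections)} sections, "
          f"{sum(len(s.nuclei) for s in sections)} nuclei, "
          f"{sum(len(s.puncta) for s in sections)} puncta")

    recordings, trace_truth = gen_traces(GeneratorConfig(seed=SEED))
    aio.write_traces(recordings, OUT / "traces.csv")
    trace_truth.to_csv(OUT / "truth_regimes.csv", index=False)
    print(f"traces: {len(trace_truth)} cells x 3 conditions "
          f"({int(trace_truth.responder.sum())} PHE responders planted)")


if __name__ == "__main__":
    main()
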