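"""Shared fixtures: generated datasets are session-scoped because the
full-size planted runs (1811/2031 cells, 614 traced cells) are reused by
several tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from astromap import sc
from astromap.config import (
    GeneratorConfig,
    default_astrocyte_config,
    default_mixture_config,
)
from astromap.simulate import gen_expression, gen_ish_section, gen_traces

SEED = 1


@pytest.fixture(scope="session")
def astro_run():
    """Default 1811-astrocyte matrix plus its normalized form and truth."""
    adata, truth = gen_expression(default_astrocyte_config(seed=SEED))
    norm = sc.ln_normalize(adata)
    return {"adata": adata, "truth": truth, "norm": norm}


@pytest.fixture(scope="session")
def mixture_run():
    """Default 2031-library higher-order mixture with planted QC failures."""
    adata, truth = gen_expression(default_mixture_config(seed=SEED))
    return {"adata": adata, "truth": truth}


@pytest.fixture(scope="session")
def traces_run():
    """Default 614-cell three-condition trace simulation."""
    recordings, truth = gen_traces(GeneratorConfig(seed=SEED))
    return {"recordings": recordings, "truth": truth}


@pytest.fixture(scope="session")
def ish_run():
    """Default three-section ISH simulation."""
    sections, truth = gen_ish_section(GeneratorConfig(seed=SEED))
    return {"sections": sections, "truth": truth}


def two_type_config(n_cells: int = 300, seed: int = 0) -> GeneratorConfig:
    """Two well-separated planted expression blobs."""
    cfg = GeneratorConfig(seed=seed)
    cfg.expression.n_cells = n_cells
    cfg.expression.subtype_freqs = {"AST1": 0.5, "AST2": 0.5}
    cfg.expression.planted_hvg_count = 200
    cfg.expression.n_housekeeping = 100
    cfg.expression.n_low_genes = 50
    cfg.expression.hvg_freq_band = (0.3, 0.7)
    cfg.fingerprint = {
        "AST1": {g: "+" if g in ("Slc1a3", "Gfap", "Agt", "Ogt") else "-"
                 for g in ("Slc1a3", "Gfap", "Agt", "Unc13c", "Frzb",
                           "Ascl1", "Ogt", "Fam107a")},
        "AST2": {g: "+" if g in ("Slc1a3", "Unc13c", "Ogt") else "-"
                 for g in ("Slc1a3", "Gfap", "Agt", "Unc13c", "Frzb",
                           "Ascl1", "Ogt", "Fam107a")},
    }
    cfg.validate()
    return cfg


def single_type_config(n_cells: int = 200, seed: int = 0) -> GeneratorConfig:
    """One exchangeable cell population (no planted substructure)."""
    cfg = GeneratorConfig(seed=seed)
    cfg.expression.n_cells = n_cells
    cfg.expression.subtype_freqs = {"AST1": 1.0}
    cfg.expression.planted_hvg_count = 0
    cfg.expression.n_housekeeping = 150
    cfg.expression.n_low_genes = 50
    cfg.fingerprint = {
        "AST1": {g: "+" for g in ("Slc1a3", "Gfap", "Agt", "Unc13c", "Frzb",
                                  "Ascl1", "Ogt", "Fam107a")},
    }
    cfg.validate()
    return cfg
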