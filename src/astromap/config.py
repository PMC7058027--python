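"""Generator configuration: the planted study conditions.

Defaults encode the study design the package emulates: a 1811-cell
astrocyte population split over five subtypes (AST1 36.5% ... AST5 1.4%),
a 2031-library run containing 204 contaminating higher-order cells and 16
below-floor libraries, three ISH sections from three animals with
region-specific subtype placement, and 614 cells recorded for 300 s per
condition (BASE -> TTX -> PHE) at 2 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .rules import DEFAULT_RULES, FINGERPRINTS, MARKER_GENES, SUBTYPES, validate_rules

#: Printed subtype proportions: AST1 36.5%, AST5 1.4%.  AST2-AST4 splits
#: are Supplementary-only; the 0.25/0.30/0.071 fill is an arbitrary
#: placeholder that respects the printed extremes.
DEFAULT_SUBTYPE_FREQS: dict[str, float] = {
    "AST1": 0.365, "AST2": 0.25, "AST3": 0.30, "AST4": 0.071, "AST5": 0.014,
}

#: Planted contaminant composition of the higher-order mixture (counts sum
#: to 204 so that 2031 libraries - 16 low-quality - 204 contaminants leave
#: 1811 astrocytes).
DEFAULT_CONTAMINANT_COUNTS: dict[str, int] = {
    "neuron": 80, "oligodendrocyte": 50, "microglia": 34,
    "endothelial": 25, "opc": 15,
}

#: Marker panels used for higher-order cell typing.
HIGHER_ORDER_PANELS: dict[str, tuple[str, ...]] = {
    "astrocyte": ("Slc1a3", "Aqp4", "Apoe"),
    "neuron": ("Snap25", "Rbfox3", "Syt1"),
    "oligodendrocyte": ("Plp1", "Mbp", "Mog"),
    "microglia": ("Cx3cr1", "C1qa", "Csf1r"),
    "endothelial": ("Cldn5", "Flt1", "Pecam1"),
    "opc": ("Pdgfra", "Cspg4", "Sox10"),
}

#: Probability that a cell of a given subtype came from hippocampus (HP)
#: rather than cortex (CX): AST1/AST4 predominantly hippocampal, AST2
#: mainly cortical, AST3/AST5 uniform.
DEFAULT_HP_PROBS: dict[str, float] = {
    "AST1": 0.75, "AST2": 0.20, "AST3": 0.50, "AST4": 0.85, "AST5": 0.50,
}


@dataclass
class NBParams:
    """Per-level negative-binomial parameters (mean, shape r).

    ``high`` is the expressed state of a fingerprint "+" gene; ``low`` the
    absent/low "-" state; ``house`` the mid-level housekeeping state shared
    by all cell types.  ``low_quality_scale`` multiplies every mean for
    planted below-QC-floor libraries.
    """

    mean_high: float = 40.0
    disp_high: float = 8.0
    mean_low: float = 0.05
    disp_low: float = 5.0
    mean_house: float = 10.0
    disp_house: float = 10.0
    low_quality_scale: float = 0.001


@dataclass
class ExpressionParams:
    n_cells: int = 1811
    subtype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_FREQS))
    contaminant_counts: dict[str, int] = field(default_factory=dict)
    n_low_quality: int = 0
    planted_hvg_count: int = 886
    n_housekeeping: int = 600
    n_low_genes: int = 500
    n_astro_common: int = 20
    nb: NBParams = field(default_factory=NBParams)
    hp_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HP_PROBS))
    n_batches: int = 2
    #: admissible band for a planted-HVG pattern's frequency mass; keeps
    #: ln-mean and dispersion above the (0.5, 0.5) thresholds with margin
    hvg_freq_band: tuple[float, float] = (0.22, 0.78)

    @property
    def n_astrocytes(self) -> int:
        return self.n_cells - sum(self.contaminant_counts.values()) - self.n_low_quality


#: Default section layout (um, origin top-left, y down): stacked cortical
#: layers above a block of hippocampal strata.  Rectangles are listed as
#: (x0, y0, x1, y1) and expanded to CCW-closed polygons by the generator.
DEFAULT_REGION_BOXES: dict[str, tuple[float, float, float, float]] = {
    "L1":    (0.0, 0.0,    1000.0, 100.0),
    "L2/3":  (0.0, 100.0,  1000.0, 300.0),
    "L4":    (0.0, 300.0,  1000.0, 400.0),
    "L5":    (0.0, 400.0,  1000.0, 600.0),
    "L6":    (0.0, 600.0,  1000.0, 800.0),
    "SO":    (0.0, 900.0,  1000.0, 1000.0),
    "SP":    (0.0, 1000.0, 1000.0, 1060.0),
    "SR":    (0.0, 1060.0, 1000.0, 1250.0),
    "SLM":   (0.0, 1250.0, 1000.0, 1350.0),
    "SG":    (0.0, 1400.0, 1000.0, 1460.0),
    "DG":    (0.0, 1460.0, 1000.0, 1560.0),
}

#: Per-region astrocyte subtype composition; the "other" entry is the
#: fraction of non-astrocyte (Slc1a3-negative) nuclei.
DEFAULT_REGION_PROFILES: dict[str, dict[str, float]] = {
    "L1":   {"AST1": 0.45, "AST2": 0.10, "AST3": 0.20, "AST5": 0.05, "other": 0.20},
    "L2/3": {"AST1": 0.05, "AST2": 0.35, "AST3": 0.30, "AST5": 0.10, "other": 0.20},
    "L4":   {"AST1": 0.05, "AST2": 0.35, "AST3": 0.35, "AST5": 0.05, "other": 0.20},
    "L5":   {"AST1": 0.05, "AST2": 0.35, "AST3": 0.30, "AST5": 0.10, "other": 0.20},
    "L6":   {"AST2": 0.15, "AST3": 0.60, "AST5": 0.05, "other": 0.20},
    "SO":   {"AST1": 0.45, "AST3": 0.35, "other": 0.20},
    "SP":   {"AST1": 0.40, "AST3": 0.40, "other": 0.20},
    "SR":   {"AST1": 0.45, "AST3": 0.35, "other": 0.20},
    "SLM":  {"AST1": 0.50, "AST3": 0.22, "AST5": 0.08, "other": 0.20},
    "SG":   {"AST4": 0.65, "AST1": 0.08, "AST3": 0.07, "other": 0.20},
    "DG":   {"AST1": 0.30, "AST3": 0.25, "AST5": 0.25, "other": 0.20},
}


@dataclass
class IshParams:
    region_boxes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_BOXES))
    region_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_PROFILES.items()})
    nuclei_density_per_mm2: float = 300.0
    nucleus_area_mean_um2: float = 35.0
    nucleus_area_sd_um2: float = 6.0
    nucleus_area_min_um2: float = 10.0
    area_scale: float = 1.3
    puncta_mean_pos: float = 15.0
    puncta_mean_neg: float = 0.3
    background_rate_per_um2: float = 5e-5
    intensity_signal_mean: float = 200.0
    intensity_signal_sd: float = 25.0
    intensity_background_mean: float = 60.0
    intensity_background_sd: float = 15.0
    n_sections: int = 3


@dataclass
class ConditionParams:
    """Transient statistics of one recording regime.

    ``mean_events`` is the expected number of events in the recording
    (Poisson for BASE/TTX, jittered-count for planted PHE regimes);
    amplitudes are dF/F0 units, tau is the exponential decay constant (s).
    """

    mean_events: float
    amp_mean: float
    amp_sd: float
    tau_mean: float
    tau_sd: float


@dataclass
class TraceParams:
    n_cells: int = 614
    region_fractions: dict[str, float] = field(default_factory=lambda: {
        "L1": 1 / 3, "L3-5": 1 / 3, "CA1": 1 / 3})
    sampling_rate_hz: float = 2.0
    duration_s: float = 300.0
    baseline_window_s: float = 100.0
    f0: float = 100.0
    noise_sd: float = 0.02          # relative to F0
    non_responder_fraction: float = 0.2
    base: ConditionParams = field(default_factory=lambda: ConditionParams(
        mean_events=1.2, amp_mean=1.5, amp_sd=0.1, tau_mean=5.0, tau_sd=0.2))
    ttx: ConditionParams = field(default_factory=lambda: ConditionParams(
        mean_events=0.7, amp_mean=1.4, amp_sd=0.1, tau_mean=5.0, tau_sd=0.2))
    #: Three planted physiology regimes under PHE, separated in
    #: amplitude / frequency / width.
    phe_regimes: dict[str, ConditionParams] = field(default_factory=lambda: {
        "R1": ConditionParams(2.0, 1.5, 0.08, 4.0, 0.15),
        "R2": ConditionParams(4.0, 3.0, 0.08, 6.0, 0.15),
        "R3": ConditionParams(6.0, 5.0, 0.10, 9.0, 0.15)})
    #: Regime mixture per region (rows sum to 1): cortical fields are
    #: dominated by R2, CA1 by R1, R3 spread evenly.
    regime_probs_by_region: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "L1":   {"R1": 0.10, "R2": 0.60, "R3": 0.30},
            "L3-5": {"R1": 0.10, "R2": 0.60, "R3": 0.30},
            "CA1":  {"R1": 0.60, "R2": 0.10, "R3": 0.30}})
    event_count_jitter: float = 0.5
    amp_floor: float = 1.25          # keep planted events above detector height
    min_gap_tau_factor: float = 3.0  # event spacing >= factor * tau
    event_margin_start_s: float = 5.0
    event_margin_end_s: float = 25.0


@dataclass
class GeneratorConfig:
    seed: int = 0
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    ish: IshParams = field(default_factory=IshParams)
    traces: TraceParams = field(default_factory=TraceParams)
    fingerprint: dict[str, dict[str, str]] = field(
        default_factory=lambda: {k: dict(v) for k, v in FINGERPRINTS.items()})

    def validate(self) -> None:
        ex = self.expression
        _check_freqs("subtype_freqs", ex.subtype_freqs)
        if ex.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if ex.n_astrocytes < 0:
            raise ValueError("contaminants + low-quality exceed n_cells")
        for name, val in (("mean_high", ex.nb.mean_high),
                          ("disp_high", ex.nb.disp_high),
                          ("mean_house", ex.nb.mean_house),
                          ("disp_house", ex.nb.disp_house),
                          ("disp_low", ex.nb.disp_low)):
            if val <= 0:
                raise ValueError(f"nb.{name} must be strictly positive")
        # fingerprint must cover every (subtype, marker) pair any rule uses
        for rule in DEFAULT_RULES:
            for subtype in ex.subtype_freqs:
                fp = self.fingerprint.get(subtype)
                if fp is None:
                    raise ValueError(f"fingerprint missing subtype {subtype!r}")
                for gene in rule.genes:
                    if gene not in fp:
                        raise ValueError(
                            f"fingerprint for {subtype!r} missing gene {gene!r}")
        tr = self.traces
        _check_freqs("region_fractions", tr.region_fractions)
        for reg, probs in tr.regime_probs_by_region.items():
            _check_freqs(f"regime_probs_by_region[{reg}]", probs)
        if tr.duration_s < tr.baseline_window_s:
            raise ValueError(
                "duration per condition must cover the baseline window "
                f"({tr.baseline_window_s} s)")
        if tr.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        ish = self.ish
        if ish.area_scale <= 0:
            raise ValueError("area_scale must be positive")
        for reg, prof in ish.region_profiles.items():
            if reg not in ish.region_boxes:
                raise ValueError(f"region profile {reg!r} has no region box")
            total = sum(prof.values())
            if total > 1 + 1e-9 or any(v < 0 for v in prof.values()):
                raise ValueError(f"region profile {reg!r} fractions invalid")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _from_plain(cls, data)
        cfg.validate()
        return cfg


def _check_freqs(name: str, freqs: Mapping[str, float]) -> None:
    if not freqs:
        raise ValueError(f"{name} must be non-empty")
    if any(v < 0 for v in freqs.values()):
        raise ValueError(f"{name} has negative entries")
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(freqs.values())})")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls: type, data: Mapping[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        ftype = f.type if isinstance(f.type, type) else None
        target = {
            "expression": ExpressionParams, "ish": IshParams,
            "traces": TraceParams, "nb": NBParams,
            "base": ConditionParams, "ttx": ConditionParams,
        }.get(f.name, ftype)
        if dataclasses.is_dataclass(target) and isinstance(val, Mapping):
            kwargs[f.name] = _from_plain(target, val)
        elif f.name == "phe_regimes" and isinstance(val, Mapping):
            kwargs[f.name] = {k: _from_plain(ConditionParams, v)
                              for k, v in val.items()}
        elif f.name in ("region_boxes",) and isinstance(val, Mapping):
            kwargs[f.name] = {k: tuple(v) for k, v in val.items()}
        elif f.name == "hvg_freq_band":
            kwargs[f.name] = tuple(val)
        else:
            kwargs[f.name] = val
    return cls(**kwargs)


def default_astrocyte_config(seed: int = 0) -> GeneratorConfig:
    """1811 astrocytes, five subtypes, no contaminants (subtype pass)."""
    cfg = GeneratorConfig(seed=seed)
    cfg.validate()
    return cfg


def default_mixture_config(seed: int = 0) -> GeneratorConfig:
    """2031 libraries: 1811 astrocytes + 204 contaminants + 16 below-floor."""
    cfg = GeneratorConfig(seed=seed)
    cfg.expression.n_cells = 2031
    cfg.expression.contaminant_counts = dict(DEFAULT_CONTAMINANT_COUNTS)
    cfg.expression.n_low_quality = 16
    cfg.validate()
    return cfg
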