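"""Synthetic Ca2+ fluorescence traces for the BASE -> TTX -> PHE ladder.

Each cell is recorded for ``duration_s`` under each condition.  A trace
is F0 * (1 + sum of events) + Gaussian noise; events have an
instantaneous rise (snapped to the sample grid, so the planted amplitude
is the sampled maximum) and a single-exponential decay.  Event onsets
are confined to (baseline_window + margin, duration - margin) with a
minimum spacing of ``min_gap_tau_factor * tau`` so the 100 s baseline
stays event-free and neighbouring transients stay resolvable.

Under PHE every responder receives at least one event drawn from one of
three planted regimes (distinct amplitude / frequency / width), while a
configured non-responder fraction receives none; BASE and TTX event
counts are plain Poisson draws, so a realistic fraction of cells is
silent in those conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import ConditionParams, GeneratorConfig

CONDITIONS = ("BASE", "TTX", "PHE")


@dataclass
class CalciumRecording:
    """One cell x condition fluorescence series."""

    cell_id: str
    region: str
    condition: str
    sampling_rate: float
    fluorescence: np.ndarray
    duration: float

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration < 100:
            raise ValueError("duration must be >= 100 s (baseline window)")
        expected = int(round(self.duration * self.sampling_rate))
        if len(self.fluorescence) != expected:
            raise ValueError("series length != round(duration * rate)")


def _event_times(rng: np.random.Generator, n: int, window: tuple[float, float],
                 min_gap: float, rate: float) -> np.ndarray:
    """n onset times: an onset latency followed by a min-gap-spaced train.

    Transients start at a similar latency into the window across cells
    (as for a bath-applied agonist) and subsequent events follow with
    jittered spacing >= min_gap; gaps are compressed proportionally if a
    jittered train would overrun the window.  Times are snapped to the
    sample grid.
    """
    start, end = window
    span = end - start
    n = min(n, max(1, int(span // min_gap)))
    latency = min(abs(rng.normal(10.0, 5.0)), 0.3 * span)
    gaps = min_gap * (1.0 + rng.uniform(0, 0.3, max(n - 1, 0)))
    if gaps.size and latency + gaps.sum() > span:
        gaps *= (span - latency) / gaps.sum()
    t = start + latency + np.concatenate([[0.0], np.cumsum(gaps)])
    t = np.minimum(t, end)
    return np.round(t * rate) / rate


def _synth_condition(
    rng: np.random.Generator, params: ConditionParams, tp, n_events: int
) -> np.ndarray:
    """dF/F0 series (noise-free) for one condition."""
    n_samples = int(round(tp.duration_s * tp.sampling_rate_hz))
    t = np.arange(n_samples) / tp.sampling_rate_hz
    dff = np.zeros(n_samples)
    if n_events <= 0:
        return dff
    tau = max(0.5, rng.normal(params.tau_mean, params.tau_sd))
    window = (tp.baseline_window_s + tp.event_margin_start_s,
              tp.duration_s - tp.event_margin_end_s)
    times = _event_times(rng, n_events, window,
                         tp.min_gap_tau_factor * tau, tp.sampling_rate_hz)
    amp_cell = max(tp.amp_floor, rng.normal(params.amp_mean, params.amp_sd))
    for t0 in times:
        a = max(tp.amp_floor, amp_cell * (1 + rng.normal(0, 0.03)))
        mask = t >= t0 - 1e-9
        dff[mask] += a * np.exp(-(t[mask] - t0) / tau)
    return dff


def gen_traces(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[CalciumRecording], pd.DataFrame]:
    """Generate per-cell recordings for all three conditions plus truth.

    The truth table has one row per cell: region, planted PHE regime,
    responder flag, and the planted event count / amplitude / tau per
    condition.  Deterministic given config + seed.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    tp = cfg.traces
    if tp.duration_s < tp.baseline_window_s:
        raise ValueError("duration per condition must be >= 100 s")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    regions = sorted(tp.region_fractions)
    region_p = np.array([tp.region_fractions[r] for r in regions])
    n_samples = int(round(tp.duration_s * tp.sampling_rate_hz))

    recordings: list[CalciumRecording] = []
    truth_rows = []
    for i in range(tp.n_cells):
        cell_id = f"roi_{i + 1:04d}"
        region = rng.choice(regions, p=region_p)
        regime_probs = tp.regime_probs_by_region[region]
        regime_names = sorted(regime_probs)
        regime = rng.choice(
            regime_names, p=np.array([regime_probs[r] for r in regime_names]))
        responder = rng.random() >= tp.non_responder_fraction

        per_cond: dict[str, ConditionParams] = {
            "BASE": tp.base, "TTX": tp.ttx, "PHE": tp.phe_regimes[regime]}
        n_events: dict[str, int] = {}
        for cond in ("BASE", "TTX"):
            n_events[cond] = int(rng.poisson(per_cond[cond].mean_events))
        if responder:
            jitter = rng.normal(0, tp.event_count_jitter)
            n_events["PHE"] = max(
                1, int(round(per_cond["PHE"].mean_events + jitter)))
        else:
            n_events["PHE"] = 0

        for cond in CONDITIONS:
            dff = _synth_condition(rng, per_cond[cond], tp, n_events[cond])
            noise = rng.normal(0, tp.noise_sd, n_samples)
            f = tp.f0 * (1.0 + dff) + tp.f0 * noise
            rec = CalciumRecording(cell_id, region, cond,
                                   tp.sampling_rate_hz, f, tp.duration_s)
            rec.validate()
            recordings.append(rec)
        truth_rows.append((cell_id, region, regime, responder,
                           n_events["BASE"], n_events["TTX"], n_events["PHE"]))

    truth = pd.DataFrame(truth_rows, columns=[
        "cell_id", "region", "regime", "responder",
        "n_events_base", "n_events_ttx", "n_events_phe"])
    return recordings, truth
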