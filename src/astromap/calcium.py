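"""Ca2+ transient detection, parameterization and physiology clustering.

dF/F0 is computed against the mean fluorescence of the first 100 s of
each recording.  Transients are detected with four thresholds: peak
dF/F0 > 1.15, prominence >= 0.1, width at half prominence >= 2 s, and a
minimal separation of 1 s between peaks (the taller of two close peaks
survives).  Per cell and condition the mean amplitude, prominence,
width, peak time, peak frequency (Hz) and area under the dF/F0 curve are
reported; only cells responding to PHE are retained, physiology
clustering is Ward + silhouette on the z-scaled PHE parameters, and
group comparisons use Shapiro-Wilk (recorded), Kruskal-Wallis, and
Dunn's post hoc with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .simulate.traces import CalciumRecording
from .stats import (
    ClusterResult,
    dunn_posthoc,
    kruskal_wallis,
    shapiro_wilk,
    silhouette_select_k,
)

HEIGHT_THR = 1.15      # minimal peak dF/F0
MIN_WIDTH_S = 2.0      # minimal width at half prominence
MIN_SEP_S = 1.0        # minimal separation between peaks
MIN_PROM = 0.1         # minimal prominence (dF/F0)
BASELINE_WINDOW_S = 100.0

PARAM_COLUMNS = ("amplitude", "prominence", "width_s", "peak_time_s",
                 "frequency_hz", "auc")


@dataclass(frozen=True)
class Peak:
    time: float        # s
    amplitude: float   # dF/F0 at the maximum
    prominence: float  # dF/F0
    width: float       # s, at half prominence


def compute_dff(
    rec: CalciumRecording | np.ndarray,
    sampling_rate: float | None = None,
    baseline_window: float = BASELINE_WINDOW_S,
) -> np.ndarray:
    """(F - F0) / F0 with F0 = mean fluorescence over the first
    ``baseline_window`` seconds."""
    if isinstance(rec, CalciumRecording):
        f = np.asarray(rec.fluorescence, dtype=float)
        rate = rec.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare series")
        f = np.asarray(rec, dtype=float)
        rate = sampling_rate
    duration = len(f) / rate
    if duration < baseline_window:
        raise ValueError(
            f"recording of {duration:.1f} s is shorter than the "
            f"{baseline_window:.0f} s baseline window")
    n_base = int(round(baseline_window * rate))
    f0 = f[:n_base].mean()
    if f0 <= 0:
        raise ValueError("non-positive baseline F0: trace unusable")
    return (f - f0) / f0


def detect_transients(
    dff: np.ndarray,
    rate: float,
    height_thr: float = HEIGHT_THR,
    min_width_s: float = MIN_WIDTH_S,
    min_sep_s: float = MIN_SEP_S,
    min_prom: float = MIN_PROM,
) -> list[Peak]:
    """Four-threshold peak detection on a dF/F0 series.

    Candidates are local maxima above ``height_thr`` (boundary samples
    excluded); prominence uses the standard topographic definition and
    width is the interpolated crossing distance at amplitude minus half
    the prominence.  Candidates failing the prominence or width floors
    are removed first; survivors closer than ``min_sep_s`` are resolved
    greedily by descending amplitude.  Output is sorted by time.
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    dff = np.asarray(dff, dtype=float)
    if len(dff) < 3:
        return []
    idx, _ = signal.find_peaks(dff, height=height_thr)
    if len(idx) == 0:
        return []
    prom, lb, rb = signal.peak_prominences(dff, idx)
    widths, _, _, _ = signal.peak_widths(
        dff, idx, rel_height=0.5, prominence_data=(prom, lb, rb))
    widths_s = widths / rate
    keep = (prom >= min_prom) & (widths_s >= min_width_s)
    idx, prom, widths_s = idx[keep], prom[keep], widths_s[keep]
    # greedy separation: taller peaks claim their +/- min_sep_s window
    order = np.argsort(-dff[idx], kind="stable")
    chosen: list[int] = []
    for o in order:
        t = idx[o] / rate
        if all(abs(t - idx[c] / rate) >= min_sep_s for c in chosen):
            chosen.append(o)
    chosen.sort(key=lambda o: idx[o])
    return [Peak(time=idx[o] / rate, amplitude=float(dff[idx[o]]),
                 prominence=float(prom[o]), width=float(widths_s[o]))
            for o in chosen]


def summarize_cell(
    dff: np.ndarray,
    peaks: Sequence[Peak],
    duration: float,
    rate: float | None = None,
) -> dict:
    """Per-cell transient summary for one condition.

    Means are over the detected peaks (NaN and ``active=False`` when
    there are none); frequency = n_peaks / duration; AUC is the
    trapezoidal integral of the raw dF/F0 over the whole window,
    negative excursions included.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dff = np.asarray(dff, dtype=float)
    dt = duration / len(dff) if rate is None else 1.0 / rate
    auc = float(np.trapezoid(dff, dx=dt))
    n = len(peaks)
    if n == 0:
        return {"n_peaks": 0, "active": False, "amplitude": np.nan,
                "prominence": np.nan, "width_s": np.nan,
                "peak_time_s": np.nan, "frequency_hz": 0.0, "auc": auc}
    return {
        "n_peaks": n,
        "active": True,
        "amplitude": float(np.mean([p.amplitude for p in peaks])),
        "prominence": float(np.mean([p.prominence for p in peaks])),
        "width_s": float(np.mean([p.width for p in peaks])),
        "peak_time_s": float(np.mean([p.time for p in peaks])),
        "frequency_hz": n / duration,
        "auc": auc,
    }


def analyze_recordings(
    recordings: Iterable[CalciumRecording],
    baseline_window: float = BASELINE_WINDOW_S,
    **detect_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run dF/F0 -> detection -> summary over a set of recordings.

    Returns (peaks table, per cell x condition parameter table).
    """
    peak_rows = []
    param_rows = []
    for rec in recordings:
        dff = compute_dff(rec, baseline_window=baseline_window)
        peaks = detect_transients(dff, rec.sampling_rate, **detect_kwargs)
        for p in peaks:
            peak_rows.append((rec.cell_id, rec.region, rec.condition,
                              p.time, p.amplitude, p.prominence, p.width))
        summary = summarize_cell(dff, peaks, rec.duration, rec.sampling_rate)
        param_rows.append({"cell_id": rec.cell_id, "region": rec.region,
                           "condition": rec.condition, **summary})
    peaks_df = pd.DataFrame(peak_rows, columns=[
        "cell_id", "region", "condition", "time_s", "amplitude",
        "prominence", "width_s"])
    params_df = pd.DataFrame(param_rows)
    return peaks_df, params_df


def filter_responders(
    params: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Keep only cells with at least one PHE transient.

    Returns the retained parameter table (all conditions of responding
    cells) and a report with the fraction of PHE-responders that were
    also active under BASE and TTX.  Cells without a PHE recording are
    excluded with a warning.
    """
    has_phe = set(params.loc[params["condition"] == "PHE", "cell_id"])
    all_cells = set(params["cell_id"])
    missing = all_cells - has_phe
    if missing:
        warnings.warn(f"{len(missing)} cell(s) lack a PHE recording; excluded")
    phe = params[(params["condition"] == "PHE") & (params["n_peaks"] >= 1)]
    responders = set(phe["cell_id"])
    retained = params[params["cell_id"].isin(responders)].copy()
    report: dict[str, float] = {"n_responders": len(responders)}
    for cond in ("BASE", "TTX"):
        sub = retained[retained["condition"] == cond]
        report[f"fraction_active_{cond}"] = (
            float((sub["n_peaks"] >= 1).mean()) if len(sub) else np.nan)
    return retained, report


def cluster_physiology(
    params: pd.DataFrame,
    k_max: int = 8,
    include_peak_time: bool = True,
    no_structure_floor: float = 0.15,
) -> tuple[ClusterResult, pd.DataFrame]:
    """Ward + silhouette clustering of z-scaled PHE transient parameters.

    Constant parameter columns are dropped with a warning before
    scaling.  Returns the clustering plus the per-cluster region
    composition table.
    """
    phe = params[(params["condition"] == "PHE") & params["active"]].copy()
    cols = [c for c in PARAM_COLUMNS if include_peak_time or c != "peak_time_s"]
    if phe[cols].isna().any().any():
        raise ValueError("parameter vectors must be complete for clustering")
    if len(phe) < k_max + 1:
        raise ValueError("need more cells than k_max")
    x = phe[cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        dropped = [c for c, s in zip(cols, sd) if s == 0]
        warnings.warn(f"constant parameter column(s) dropped: {dropped}")
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    z = (x - x.mean(axis=0)) / sd
    result = silhouette_select_k(z, range(2, k_max + 1),
                                 no_structure_floor=no_structure_floor)
    phe["cluster"] = result.labels
    composition = pd.crosstab(phe["cluster"], phe["region"],
                              normalize="index")
    composition["n_cells"] = phe.groupby("cluster").size()
    return result, composition


def compare_groups(
    params: pd.DataFrame,
    grouping: str,
    condition: str = "PHE",
    parameters: Sequence[str] = PARAM_COLUMNS,
) -> pd.DataFrame:
    """Kruskal-Wallis + Dunn/BH comparisons of raw transient parameters.

    ``grouping`` is a column of ``params`` (region or cluster).  Per
    parameter: Shapiro-Wilk p per group is recorded (never branched on —
    analysis proceeds nonparametrically), then the omnibus KW test and
    Dunn's pairwise z tests, BH-adjusted within the parameter's pairwise
    family.  Groups with fewer than 2 observations are skipped with a
    warning.
    """
    sub = params[(params["condition"] == condition) & params["active"]]
    if grouping not in sub.columns:
        raise ValueError(f"grouping column {grouping!r} not present")
    rows = []
    for param in parameters:
        grouped = [(g, d[param].dropna().to_numpy())
                   for g, d in sub.groupby(grouping, observed=True)]
        small = [g for g, v in grouped if len(v) < 2]
        if small:
            warnings.warn(
                f"{param}: group(s) {small} have <2 observations; skipped")
        grouped = [(g, v) for g, v in grouped if len(v) >= 2]
        if len(grouped) < 2:
            warnings.warn(f"{param}: fewer than 2 usable groups; skipped")
            continue
        names = [str(g) for g, _ in grouped]
        values = [v for _, v in grouped]
        shapiro_p = {
            n: (shapiro_wilk(v).p_value if 3 <= len(v) <= 5000 else np.nan)
            for n, v in zip(names, values)}
        kw = kruskal_wallis(values)
        rows.append({"parameter": param, "test": "kruskal-wallis",
                     "group1": None, "group2": None,
                     "statistic": kw.statistic, "p_value": kw.p_value,
                     "p_adjusted": np.nan,
                     "shapiro_p": min(shapiro_p.values())})
        dunn = dunn_posthoc(values, names)
        for _, r in dunn.iterrows():
            rows.append({"parameter": param, "test": "dunn",
                         "group1": r["group1"], "group2": r["group2"],
                         "statistic": r["z"], "p_value": r["p_value"],
                         "p_adjusted": r["p_adjusted"],
                         "shapiro_p": np.nan})
    return pd.DataFrame(rows)
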