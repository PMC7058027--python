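"""dF/F0, four-threshold transient detection, parameterization,
responder filtering, physiology clustering and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from astromap.calcium import (
    HEIGHT_THR,
    MIN_PROM,
    MIN_SEP_S,
    MIN_WIDTH_S,
    analyze_recordings,
    cluster_physiology,
    compare_groups,
    compute_dff,
    detect_transients,
    filter_responders,
    summarize_cell,
)
from astromap.config import ConditionParams, GeneratorConfig
from astromap.simulate import gen_traces
from astromap.simulate.traces import CalciumRecording


def triangle_trace(rate=2.0, total_s=300.0, amp=2.0, rise_s=4.0):
    """Baseline then a symmetric triangle 0 -> amp -> 0."""
    n = int(total_s * rate)
    t = np.arange(n) / rate
    start = 150.0
    up = (t - start) / rise_s * amp
    down = amp - (t - start - rise_s) / rise_s * amp
    tri = np.where(t < start, 0.0,
                   np.where(t < start + rise_s, up,
                            np.where(t < start + 2 * rise_s, down, 0.0)))
    return np.maximum(tri, 0.0), rate


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        rec = CalciumRecording("c", "L1", "BASE", 2.0,
                               np.full(600, 37.0), 300.0)
        np.testing.assert_allclose(compute_dff(rec), 0.0)

    def test_direct_value(self):
        f = np.full(600, 100.0)
        f[400] = 250.0  # after the 100 s baseline window at 2 Hz
        rec = CalciumRecording("c", "L1", "BASE", 2.0, f, 300.0)
        assert compute_dff(rec)[400] == pytest.approx(1.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(np.full(99, 10.0), sampling_rate=1.0)

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            compute_dff(np.zeros(400), sampling_rate=2.0)


class TestDetectTransients:
    def test_flat_and_subthreshold_empty(self):
        assert detect_transients(np.zeros(600), 2.0) == []
        wobble = 1.0 + 0.05 * np.sin(np.linspace(0, 40, 600))
        assert detect_transients(wobble, 2.0) == []

    def test_triangle_closed_form(self):
        """Symmetric triangle 0->2 over 4 s then back at 2 Hz: one peak,
        amplitude 2, prominence 2, width 4 s at half prominence."""
        dff, rate = triangle_trace()
        peaks = detect_transients(dff, rate)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.amplitude == pytest.approx(2.0)
        assert p.prominence == pytest.approx(2.0)
        assert p.width == pytest.approx(4.0, abs=1e-6)

    def test_close_pair_keeps_taller(self):
        """Two candidate peaks 0.5 s apart: only the taller survives the
        1 s separation rule."""
        rate = 10.0
        dff = np.zeros(3000)
        i = 1500
        dff[i - 40: i + 1] = np.linspace(0, 2.0, 41)
        dff[i: i + 40] = np.linspace(2.0, 1.2, 40)
        j = i + 5  # 0.5 s later
        dff[j] = 1.5  # smaller local bump riding the decay
        peaks = detect_transients(dff, rate)
        times = [p.time for p in peaks]
        assert i / rate in times
        assert j / rate not in times

    def test_emitted_peaks_satisfy_all_four_thresholds(self, traces_run):
        """Re-validation: every peak from the default simulation obeys
        height, prominence, width, and separation thresholds."""
        peaks_df, _ = analyze_recordings(traces_run["recordings"][:90])
        assert len(peaks_df) > 50
        assert (peaks_df["amplitude"] > HEIGHT_THR).all()
        assert (peaks_df["prominence"] >= MIN_PROM).all()
        assert (peaks_df["width_s"] >= MIN_WIDTH_S).all()
        for _, g in peaks_df.groupby(["cell_id", "condition"]):
            assert (np.diff(np.sort(g["time_s"])) >= MIN_SEP_S).all()

    def test_threshold_monotonicity(self, traces_run):
        """Raising any one of the four thresholds never increases the
        number of detected peaks."""
        rec = next(r for r in traces_run["recordings"]
                   if r.condition == "PHE")
        dff = compute_dff(rec)
        rate = rec.sampling_rate
        base = len(detect_transients(dff, rate))
        for kwargs in ({"height_thr": 2.0}, {"min_prom": 0.5},
                       {"min_width_s": 5.0}, {"min_sep_s": 30.0}):
            assert len(detect_transients(dff, rate, **kwargs)) <= base

    def test_time_shift_equivariance(self):
        dff, rate = triangle_trace()
        shift = 40  # 20 s
        shifted = np.roll(dff, shift)
        p0 = detect_transients(dff, rate)
        p1 = detect_transients(shifted, rate)
        assert len(p0) == len(p1) == 1
        assert p1[0].time - p0[0].time == pytest.approx(shift / rate)
        assert p1[0].amplitude == p0[0].amplitude
        assert p1[0].width == pytest.approx(p0[0].width)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_transients(np.zeros(10), 0.0)


class TestSummarize:
    def test_inactive_cell(self):
        out = summarize_cell(np.zeros(600), [], 300.0)
        assert out["n_peaks"] == 0 and not out["active"]
        assert out["frequency_hz"] == 0.0
        assert np.isnan(out["amplitude"])

    def test_triangle_frequency_and_auc(self):
        """One triangle over 300 s: frequency 1/300 Hz, AUC = triangle
        area = 0.5 * 8 s * 2 = 8 dF/F0*s."""
        dff, rate = triangle_trace()
        peaks = detect_transients(dff, rate)
        out = summarize_cell(dff, peaks, 300.0, rate)
        assert out["frequency_hz"] == pytest.approx(1 / 300.0)
        assert out["auc"] == pytest.approx(8.0, rel=1e-6)

    def test_duplicated_peaks_mean_invariance(self):
        dff, rate = triangle_trace()
        peaks = detect_transients(dff, rate)
        once = summarize_cell(dff, peaks, 300.0, rate)
        twice = summarize_cell(dff, peaks * 2, 300.0, rate)
        assert twice["amplitude"] == once["amplitude"]
        assert twice["width_s"] == once["width_s"]
        assert twice["frequency_hz"] == pytest.approx(
            2 * once["frequency_hz"])


class TestResponderFilter:
    def params_table(self):
        return pd.DataFrame([
            {"cell_id": "a", "condition": "BASE", "n_peaks": 3, "active": True},
            {"cell_id": "a", "condition": "TTX", "n_peaks": 0, "active": False},
            {"cell_id": "a", "condition": "PHE", "n_peaks": 2, "active": True},
            {"cell_id": "b", "condition": "BASE", "n_peaks": 5, "active": True},
            {"cell_id": "b", "condition": "TTX", "n_peaks": 1, "active": True},
            {"cell_id": "b", "condition": "PHE", "n_peaks": 0, "active": False},
        ])

    def test_base_only_cell_dropped(self):
        retained, report = filter_responders(self.params_table())
        assert set(retained["cell_id"]) == {"a"}
        assert report["n_responders"] == 1
        assert report["fraction_active_BASE"] == 1.0
        assert report["fraction_active_TTX"] == 0.0

    def test_condition_subsets_nest(self, traces_run):
        _, params = analyze_recordings(traces_run["recordings"][:150])
        retained, _ = filter_responders(params)
        responders = set(retained["cell_id"])
        base_active = set(retained[(retained["condition"] == "BASE")
                                   & (retained["n_peaks"] >= 1)]["cell_id"])
        assert base_active <= responders

    def test_missing_phe_recording_warns(self):
        table = self.params_table().iloc[:2]  # cell a without its PHE row
        with pytest.warns(UserWarning, match="PHE"):
            retained, _ = filter_responders(table)
        assert retained.empty


class TestPhysiologyClustering:
    def test_two_planted_regimes_recovered(self):
        cfg = GeneratorConfig(seed=31)
        cfg.traces.n_cells = 120
        cfg.traces.phe_regimes = {
            "R1": ConditionParams(2.0, 1.5, 0.08, 4.0, 0.15),
            "R3": ConditionParams(6.0, 5.0, 0.10, 9.0, 0.15)}
        for probs in cfg.traces.regime_probs_by_region.values():
            probs.clear()
            probs.update({"R1": 0.5, "R3": 0.5})
        recs, truth = gen_traces(cfg)
        _, params = analyze_recordings(recs)
        retained, _ = filter_responders(params)
        res, _ = cluster_physiology(retained)
        assert res.k == 2
        phe = retained[(retained["condition"] == "PHE")
                       & retained["active"]].merge(truth, on=["cell_id"])
        assert adjusted_rand_score(phe["regime"], res.labels) > 0.9

    def test_duplication_invariance(self, traces_run):
        _, params = analyze_recordings(traces_run["recordings"][:240])
        retained, _ = filter_responders(params)
        res1, _ = cluster_physiology(retained)
        doubled = pd.concat([retained,
                             retained.assign(cell_id=retained.cell_id + "_d")],
                            ignore_index=True)
        res2, _ = cluster_physiology(doubled)
        assert res2.k == res1.k
        np.testing.assert_array_equal(res2.labels[: len(res1.labels)],
                                      res1.labels)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        n = 30
        params = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            "region": "L1", "condition": "PHE", "active": True,
            "n_peaks": 2,
            "amplitude": np.r_[rng.normal(1.5, 0.05, 15),
                               rng.normal(5.0, 0.05, 15)],
            "prominence": np.r_[rng.normal(1.5, 0.05, 15),
                                rng.normal(5.0, 0.05, 15)],
            "width_s": 3.0,  # constant
            "peak_time_s": rng.normal(150, 5, n),
            "frequency_hz": rng.normal(0.01, 0.001, n),
            "auc": np.r_[rng.normal(10, 1, 15), rng.normal(80, 1, 15)],
        })
        with pytest.warns(UserWarning, match="constant"):
            res, _ = cluster_physiology(params, k_max=5)
        assert res.k == 2


class TestCompareGroups:
    def make_params(self, groups):
        rows = []
        for gname, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"cell_id": f"{gname}{i}", "region": gname,
                             "condition": "PHE", "active": True,
                             "n_peaks": 1, "amplitude": float(v),
                             "prominence": 1.0, "width_s": 3.0,
                             "peak_time_s": 10.0, "frequency_hz": 0.01,
                             "auc": 5.0})
        return pd.DataFrame(rows)

    def test_hand_computed_h_with_ties(self):
        """KW H on 3 groups of 5 small integers matches the rank formula
        with tie correction, computed by hand."""
        groups = {"a": [1, 2, 2, 3, 4], "b": [2, 3, 3, 4, 5],
                  "c": [4, 5, 5, 6, 7]}
        params = self.make_params(groups)
        out = compare_groups(params, "region", "PHE",
                             parameters=["amplitude"])
        h_pkg = out[out.test == "kruskal-wallis"]["statistic"].iloc[0]
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        rs = np.split(ranks, 3)
        h = 12 / (n * (n + 1)) * sum(len(r) * r.mean() ** 2 for r in rs) \
            - 3 * (n + 1)
        _, t = np.unique(pooled, return_counts=True)
        h /= 1 - np.sum(t**3 - t) / (n**3 - n)
        assert h_pkg == pytest.approx(h)

    def test_identical_groups_nothing_significant(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        params = self.make_params({"a": base, "b": base, "c": base})
        out = compare_groups(params, "region", "PHE",
                             parameters=["amplitude"])
        kw = out[out.test == "kruskal-wallis"].iloc[0]
        assert kw.p_value > 0.95
        dunn = out[out.test == "dunn"]
        assert (dunn.p_adjusted > 0.05).all()

    def test_bh_adjusted_dominates_raw(self, traces_run):
        _, params = analyze_recordings(traces_run["recordings"][:300])
        retained, _ = filter_responders(params)
        out = compare_groups(retained, "region", "PHE")
        dunn = out[out.test == "dunn"]
        assert (dunn.p_adjusted >= dunn.p_value - 1e-12).all()

    def test_small_group_skipped_with_warning(self):
        params = self.make_params({"a": [1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            out = compare_groups(params, "region", "PHE",
                                 parameters=["amplitude"])
        assert out.empty  # only one usable group remains


class TestAmplitudeRecovery:
    def test_planted_amplitudes_within_ten_percent(self, traces_run):
        """With noise SD <= 0.05 * F0, recovered per-regime mean
        amplitudes land within 10% of the planted values."""
        cfg = GeneratorConfig()
        _, params = analyze_recordings(traces_run["recordings"])
        retained, _ = filter_responders(params)
        phe = retained[(retained["condition"] == "PHE")
                       & retained["active"]]
        merged = phe.merge(traces_run["truth"], on=["cell_id", "region"])
        for regime, cond in cfg.traces.phe_regimes.items():
            got = merged.loc[merged["regime"] == regime, "amplitude"].mean()
            assert got == pytest.approx(cond.amp_mean, rel=0.10)
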