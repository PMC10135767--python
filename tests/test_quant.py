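"""Normalization, background estimation and transient feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caflow as cf
from caflow.quant import (BACKGROUND_DOMAIN_AREA_UM2, CalciumTrace,
                          QCFailure, QuantConfig, analyze_trace,
                          background_intensity, cell_intensity,
                          classify_activated, detect_onset, extract_trace,
                          normalize, transient_features)
from conftest import analyze_stack


class TestNormalize:
    def test_reference_values(self):
        assert normalize(150.0, 150.0) == 0.0
        assert normalize(300.0, 150.0) == 1.0
        assert normalize(np.array([150.0, 300.0]),
                         np.array([150.0, 150.0])) == pytest.approx([0, 1])

    def test_non_positive_background_is_domain_error(self):
        with pytest.raises(ValueError):
            normalize(100.0, 0.0)
        with pytest.raises(ValueError):
            normalize(np.array([100.0]), np.array([-5.0]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(fic=st.fractions(min_value=0, max_value=10_000),
           fib=st.fractions(min_value="1/100", max_value=10_000),
           a=st.fractions(min_value="1/100", max_value=100))
    def test_scale_invariance_exact_arithmetic(self, fic, fib, a):
        """(a·F_IC, a·F_IB) yields exactly the same F_IN for any a > 0."""
        assert normalize(a * fic, a * fib) == normalize(fic, fib)

    def test_nan_frames_propagate(self):
        out = normalize(np.array([np.nan, 100.0]), np.array([50.0, 50.0]))
        assert np.isnan(out[0]) and out[1] == 1.0


class TestBackground:
    def test_constant_frame(self):
        frame = np.full((120, 120), 100.0)
        est = background_intensity(frame, (48.0, 48.0), 0.8)
        assert est.n_domains == 4
        assert est.value == pytest.approx(100.0)

    def test_cell_disk_does_not_touch_domains(self):
        """Domains sit 24 µm out (radius 6 µm); a 7.5 µm cell at the
        centroid leaves them reading pure background."""
        frame = np.full((120, 120), 100.0)
        yy, xx = np.mgrid[0:120, 0:120]
        x_um, y_um = (xx + 0.5) * 0.8, (yy + 0.5) * 0.8
        cell = (x_um - 48) ** 2 + (y_um - 48) ** 2 < 7.5 ** 2
        frame[cell] = 400.0
        est = background_intensity(frame, (48.0, 48.0), 0.8)
        assert est.value == pytest.approx(100.0)

    def test_linear_gradient_averages_to_centroid_value(self):
        """Symmetric domain placement cancels a linear gradient: F_IB is
        the gradient's value at the centroid."""
        yy, xx = np.mgrid[0:160, 0:160]
        frame = 100.0 + 0.5 * (xx + 0.5) * 0.8 + 0.25 * (yy + 0.5) * 0.8
        cx, cy = 64.0, 64.0
        est = background_intensity(frame, (cx, cy), 0.8)
        expected = 100.0 + 0.5 * cx + 0.25 * cy
        assert est.value == pytest.approx(expected, abs=0.2)

    def test_edge_and_exclusion_drop_domains(self):
        frame = np.full((120, 120), 100.0)
        # centroid near the left edge: the 180° domain falls off frame
        est = background_intensity(frame, (28.0, 48.0), 0.8)
        assert est.n_domains == 3
        # exclusion mask over two more domains -> below min, unreliable
        yy, xx = np.mgrid[0:120, 0:120]
        x_um, y_um = (xx + 0.5) * 0.8, (yy + 0.5) * 0.8
        excl = ((x_um - 52) ** 2 + (y_um - 48) ** 2 < 8 ** 2) | \
               ((x_um - 28) ** 2 + (y_um - 72) ** 2 < 8 ** 2)
        est = background_intensity(frame, (28.0, 48.0), 0.8,
                                   exclusion_mask=excl)
        assert est.n_domains < 2 and not est.ok

    def test_domain_geometry(self):
        """Domain area 36π µm² means radius exactly 6 µm."""
        assert np.sqrt(BACKGROUND_DOMAIN_AREA_UM2 / np.pi) == pytest.approx(6.0)


class TestCellIntensity:
    def test_uniform_and_split_disks(self):
        frame = np.full((20, 20), 300.0)
        rows, cols = np.mgrid[5:15, 5:15]
        rows, cols = rows.ravel(), cols.ravel()
        assert cell_intensity(frame, rows, cols) == 300.0
        frame[:, 10:] = 400.0
        frame[:, :10] = 200.0
        assert cell_intensity(frame, rows, cols) == 300.0

    def test_empty_mask_is_qc_failure(self):
        with pytest.raises(QCFailure):
            cell_intensity(np.ones((5, 5)), np.empty(0, int), np.empty(0, int))


class TestExtractTrace:
    def test_flat_cell_gives_constant_fin(self, single_cell_scene):
        """Noiseless non-activated rendered cell: F_IN constant to 1e-6."""
        stack, _ = single_cell_scene(activated=False, duration_s=65.0)
        from caflow.track import classify_firm_adhesion, detect_cells, link_tracks
        dets = [detect_cells(f, stack.pixel_size_um) for f in stack.frames]
        tracks = link_tracks(dets, stack.frame_interval_s)
        ev = classify_firm_adhesion(tracks[0])
        trace = extract_trace(stack, tracks[0], ev)
        assert trace.qc_fail_frac == 0.0
        assert np.nanmax(trace.f_in) - np.nanmin(trace.f_in) < 1e-6
        # row-wise identity against its own F_IC, F_IB
        good = np.isfinite(trace.f_in)
        recomputed = (trace.f_ic[good] - trace.f_ib[good]) / trace.f_ib[good]
        assert np.max(np.abs(trace.f_in[good] - recomputed)) <= 1e-9

    def test_peak_frame_matches_ground_truth(self, single_cell_scene):
        stack, truth = single_cell_scene(delay_s=20.0, rise_s=10.0,
                                         duration_s=70.0)
        from caflow.track import classify_firm_adhesion, detect_cells, link_tracks
        dets = [detect_cells(f, stack.pixel_size_um) for f in stack.frames]
        tracks = link_tracks(dets, stack.frame_interval_s)
        ev = classify_firm_adhesion(tracks[0])
        trace = extract_trace(stack, tracks[0], ev)
        t_peak = trace.t_rel_s[np.nanargmax(trace.f_in)]
        row = truth.cells.iloc[0]
        assert t_peak == pytest.approx(row.T_D_s + row.T_P_s, abs=0.1)

    def test_requires_firm_event(self, single_cell_scene):
        stack, _ = single_cell_scene(activated=False, duration_s=5.0)
        tr = cf.CellTrack(0, np.arange(3), np.arange(3.0) * 0.05,
                          np.full((3, 2), 48.0))
        with pytest.raises(ValueError):
            extract_trace(stack, tr, cf.AdhesionEvent(0, firm=False))

    def test_illumination_scale_invariance(self, single_cell_scene):
        """Multiplying the whole stack by a > 0 leaves F_IN and every
        feature unchanged."""
        stack, _ = single_cell_scene(duration_s=70.0)
        scaled = cf.ImageStack(stack.frames.astype(np.float64) * 2.0,
                               stack.pixel_size_um, stack.frame_interval_s)
        _, _, f1 = analyze_stack(stack)
        _, _, f2 = analyze_stack(scaled)
        assert len(f1) == len(f2) == 1
        assert f1[0].T_D_s == f2[0].T_D_s
        assert f1[0].T_P_s == f2[0].T_P_s
        assert f1[0].I_P == pytest.approx(f2[0].I_P, rel=1e-12)


def _make_trace(t, f_in, f_ib=100.0):
    f_ic = (1.0 + np.asarray(f_in)) * f_ib
    return CalciumTrace.from_raw("x", t, f_ic, f_ib)


class TestOnsetAndFeatures:
    def test_flat_noiseless_trace_has_no_onset(self):
        t = np.arange(0, 60, 0.05)
        trace = _make_trace(t, np.full(len(t), 0.5))
        assert detect_onset(trace) is None
        feats = transient_features(trace, None)
        assert not feats.activated
        assert feats.T_D_s is None and feats.I_P is None

    def test_noiseless_ramp_onset_recovered(self):
        """A rise starting at t = 40 s is localized to within a frame."""
        p = cf.TransientParams(plateau_level=150, delay_s=40, rise_s=20,
                               peak_ratio=3, decay_tau_s=60)
        t = np.arange(int(90 / 0.05)) * 0.05
        y = cf.trace_value(p, t)
        trace = CalciumTrace.from_raw("x", t, y, 60.0)
        onset = detect_onset(trace)
        assert onset == pytest.approx(40.0, abs=0.05)

    def test_noisy_onset_within_one_second(self):
        """At peak SNR 5 (20 fps) the onset error stays ≤ 1 s."""
        p = cf.TransientParams(plateau_level=150, delay_s=40, rise_s=20,
                               peak_ratio=3, decay_tau_s=60)
        t = np.arange(int(90 / 0.05)) * 0.05
        errs = []
        for seed in range(15):
            y = cf.simulate_trace(p, 0.05, 90, noise_sd=300 / 5, seed=seed)
            onset = detect_onset(CalciumTrace.from_raw("x", t, y, 60.0))
            assert onset is not None
            errs.append(abs(onset - 40.0))
        assert np.median(errs) <= 1.0

    def test_feature_roundtrip_noiseless(self):
        p = cf.TransientParams(plateau_level=150, delay_s=40, rise_s=20,
                               peak_ratio=3, decay_tau_s=60)
        t = np.arange(int(90 / 0.05)) * 0.05
        trace = CalciumTrace.from_raw("x", t, cf.trace_value(p, t), 60.0)
        feats = analyze_trace(trace)
        assert feats.activated
        assert feats.T_D_s == pytest.approx(40.0, abs=0.05)
        assert feats.T_P_s == pytest.approx(20.0, abs=0.05)
        assert feats.I_P == pytest.approx(3.0, rel=0.01)
        assert feats.T_D_s == feats.onset_time_rel_s
        assert feats.T_P_s == pytest.approx(
            feats.peak_time_rel_s - feats.onset_time_rel_s)

    def test_ip_conventions_differ_as_documented(self):
        """raw-ratio is the raw-intensity ratio (1+peak)/(1+plateau);
        normalized-ratio is the literal F_IN ratio."""
        t = np.arange(0, 60, 0.05)
        f_in = np.where(t < 30, 0.5, np.minimum(0.5 + (t - 30) * 0.6, 3.5))
        trace = _make_trace(t, f_in)
        onset = detect_onset(trace)
        raw = transient_features(trace, onset, QuantConfig())
        norm = transient_features(trace, onset,
                                  QuantConfig(ip_mode="normalized-ratio"))
        assert raw.I_P == pytest.approx(4.5 / 1.5, rel=1e-6)
        assert norm.I_P == pytest.approx(3.5 / 0.5, rel=1e-6)

    def test_peak_equal_to_plateau_is_non_activated(self):
        t = np.arange(0, 30, 0.05)
        trace = _make_trace(t, np.full(len(t), 1.0))
        feats = transient_features(trace, 10.0)  # forced onset, flat trace
        assert not feats.activated

    def test_activation_threshold_boundary_counts_as_activated(self):
        """I_P exactly at the threshold activates (≥ convention)."""
        # binary-exact grid: plateau F_IC 200, peak 300 over F_IB 100
        # -> raw-ratio I_P = (1+2)/(1+1) = exactly 1.5 = the threshold
        p = cf.TransientParams(plateau_level=200, delay_s=40, rise_s=20,
                               peak_ratio=1.5, decay_tau_s=30)
        t = np.arange(int(90 / 0.25)) * 0.25
        trace = CalciumTrace.from_raw("x", t, cf.trace_value(p, t), 100.0)
        feats = transient_features(trace, detect_onset(trace))
        assert feats.I_P == pytest.approx(1.5, abs=1e-12)
        assert feats.activated
        assert classify_activated(feats, threshold=1.5)

    def test_normalized_ratio_rejects_non_positive_plateau(self):
        t = np.arange(0, 60, 0.05)
        f_in = np.where(t < 30, -0.2, np.minimum(-0.2 + (t - 30) * 0.5, 2.0))
        trace = _make_trace(t, f_in)
        with pytest.raises(QCFailure):
            transient_features(trace, 30.0,
                               QuantConfig(ip_mode="normalized-ratio"))


class TestCohortClassification:
    def test_activated_and_flat_cells_classified(self):
        """Generated activated cells are labeled activated and flat cells
        are not, at moderate noise."""
        spec = {"a": cf.ParamDistributions(activated_fraction=0.5)}
        cohort = cf.generate_cohort(spec, 30, seed=8, mode="traces",
                                    noise_sd=10.0)
        feats = cf.features_from_traces(cohort.traces)
        merged = feats.merge(cohort.truth, on="cell_id",
                             suffixes=("", "_true"))
        agree = (merged.activated == merged.activated_true).mean()
        assert agree >= 0.95
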