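import numpy as np
import pytest

import caflow as cf


@pytest.fixture
def single_cell_scene():
    """Factory for a one-cell rendered scene with known ground truth."""

    def make(delay_s=31.23, rise_s=14.7, peak_ratio=2.6, activated=True,
             arrest_time_s=2.0, gaussian_sd=0.0, duration_s=65.0, seed=7,
             frame_interval_s=0.05):
        params = cf.TransientParams(
            plateau_level=150.0, delay_s=delay_s, rise_s=rise_s,
            peak_ratio=peak_ratio if activated else 1.0,
            decay_tau_s=40.0, activated=activated)
        cell = cf.CellSpec("c0", 48.0, 48.0, params,
                           entry_time_s=arrest_time_s,
                           arrest_time_s=arrest_time_s)
        scene = cf.SceneSpec(shape_px=(120, 120), pixel_size_um=0.8,
                             frame_interval_s=frame_interval_s,
                             duration_s=duration_s, cells=(cell,),
                             background_level=60.0, gaussian_sd=gaussian_sd,
                             seed=seed)
        return cf.render_stack(scene)

    return make


def analyze_stack(stack, quant_config=None):
    """Track → adhere → quantify one stack; returns (tracks, events, feats)."""
    from caflow.quant import QuantConfig, analyze_trace, extract_trace
    from caflow.track import classify_firm_adhesion, detect_cells, link_tracks

    cfg = quant_config or QuantConfig()
    dets = [detect_cells(f, stack.pixel_size_um) for f in stack.frames]
    tracks = link_tracks(dets, stack.frame_interval_s)
    events = [classify_firm_adhesion(tr) for tr in tracks]
    feats = []
    for tr, ev in zip(tracks, events):
        if ev.firm:
            feats.append(analyze_trace(extract_trace(stack, tr, ev, cfg), cfg))
    return tracks, events, feats


def brute_force_firm(track, window_s=60.0, threshold_um=10.0):
    """Independent all-windows oracle for the firm-adhesion criterion.

    Enumerates every window start; the endpoint is the first observation
    at or after start + window; firm iff any window's net displacement is
    strictly below the threshold.  Returns (firm, onset or None).
    """
    t = track.times_s
    xy = track.xy_um
    n = len(t)
    for i in range(n):
        j = None
        for k in range(i, n):
            if t[k] >= t[i] + window_s - 1e-9:
                j = k
                break
        if j is None:
            continue
        dx = xy[j][0] - xy[i][0]
        dy = xy[j][1] - xy[i][1]
        if (dx * dx + dy * dy) ** 0.5 < threshold_um:
            return True, float(t[i])
    return False, None


def random_walk_track(rng, track_id=0, n=120, dt=1.0, step_sd=1.0,
                      drift=(0.0, 0.0)):
    steps = rng.normal(0.0, step_sd, size=(n - 1, 2)) + np.asarray(drift)
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    frames = np.arange(n)
    return cf.CellTrack(track_id=track_id, frames=frames,
                        times_s=frames * dt, xy_um=xy)
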