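"""Normalized calcium traces and transient feature extraction.

For every firmly adhered cell the pipeline computes, per frame from arrest
onward,

    F_IN = (F_IC - F_IB) / F_IB

where F_IC is the mean cell fluorescence over the cell mask and F_IB the
local background: the mean of four round domains of area 36π µm² (radius
6 µm) placed 24 µm from the cell centroid at 0°/90°/180°/270°.  Domains
that fall off the frame or overlap another detected cell are dropped; at
least two usable domains are required, otherwise the frame is a QC
failure.

From the normalized trace three characteristics are extracted per cell:

* delay time ``T_D`` — time from arrest (t = 0) to the onset of the sharp
  fluorescence rise;
* peak time ``T_P`` — duration of the rise from onset to the trace
  maximum;
* peak calcium intensity ``I_P`` — peak-to-plateau fluorescence ratio.

"Sharp rise" is operationalized as the first time the trace exceeds the
running plateau mean by ``k`` plateau SDs (with an absolute floor) for
``m`` consecutive frames; the trigger time is then refined to the
least-squares breakpoint of a flat-plus-ramp model, which is what ``T_D``
reports.  The default I_P convention is the ratio of raw-equivalent
intensities, ``(1 + F_IN_peak) / (1 + F_IN_plateau)``, which is stable
when the plateau F_IN is near zero; the literal ratio of normalized values
is available as ``ip_mode="normalized-ratio"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import ImageStack
from .track import AdhesionEvent, CellTrack, Detection

__all__ = [
    "QuantConfig", "CalciumTrace", "TransientFeatures", "BackgroundEstimate",
    "QCFailure", "background_intensity", "cell_intensity", "normalize",
    "extract_trace", "detect_onset", "transient_features",
    "classify_activated", "analyze_trace", "features_from_traces",
]

BACKGROUND_DOMAIN_AREA_UM2 = 36.0 * math.pi   # => radius 6 µm
BACKGROUND_DISTANCE_UM = 24.0


class QCFailure(ValueError):
    """A trace or frame failed quality control."""


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of trace extraction and feature measurement."""

    # onset ("sharp increase") trigger
    k: float = 3.0                 # plateau SDs above the running mean
    m: int = 5                     # consecutive frames above threshold
    floor: float = 0.05            # absolute minimum rise, F_IN units
    min_plateau_s: float = 2.0     # data required before a candidate onset
    # features
    ip_mode: str = "raw-ratio"     # or "normalized-ratio"
    activation_threshold: float = 1.5
    smooth_s: float = 0.5          # rough-peak smoothing window
    # imaging
    mask_mode: str = "onset"       # freeze mask at arrest; or "frame"
    mask_core_quantile: float = 0.5  # keep the brighter part of the mask
    background_distance_um: float = BACKGROUND_DISTANCE_UM
    background_domain_area_um2: float = BACKGROUND_DOMAIN_AREA_UM2
    background_angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    min_background_domains: int = 2
    max_qc_fail_frac: float = 0.2


@dataclass
class BackgroundEstimate:
    """Local background level and how many domains produced it."""

    value: float
    n_domains: int

    @property
    def ok(self) -> bool:
        return math.isfinite(self.value)


@dataclass
class CalciumTrace:
    """Per-frame (F_IC, F_IB, F_IN) series for one firmly adhered cell.

    ``t_rel_s`` is measured from the arrest onset (t = 0 at onset) and is
    strictly increasing.  QC-failed frames carry NaN.
    """

    track_id: int | str
    t_rel_s: np.ndarray
    f_ic: np.ndarray
    f_ib: np.ndarray
    f_in: np.ndarray
    qc_fail_frac: float = 0.0
    condition: str | None = None

    @classmethod
    def from_raw(cls, track_id, t_rel_s, f_ic, f_ib,
                 condition: str | None = None) -> "CalciumTrace":
        """Build a trace from raw intensity series, computing F_IN."""
        t = np.asarray(t_rel_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_rel_s must be strictly increasing")
        f_ic = np.asarray(f_ic, dtype=float)
        f_ib = np.asarray(f_ib, dtype=float)
        if np.broadcast_shapes(f_ib.shape, f_ic.shape) != f_ic.shape:
            raise ValueError("f_ib must broadcast against f_ic")
        f_ib = np.broadcast_to(f_ib, f_ic.shape).copy()
        f_in = normalize(f_ic, f_ib)
        bad = ~(np.isfinite(f_ic) & np.isfinite(f_ib))
        return cls(track_id, t, f_ic, f_ib, f_in,
                   qc_fail_frac=float(bad.mean()), condition=condition)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"track_id": self.track_id, "t_rel_s": self.t_rel_s,
                           "F_IC": self.f_ic, "F_IB": self.f_ib,
                           "F_IN": self.f_in})
        if self.condition is not None:
            df.insert(0, "condition", self.condition)
        return df

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.t_rel_s)))


@dataclass
class TransientFeatures:
    """Per-cell transient characteristics.

    For a non-activated cell the three characteristics are undefined and
    stored as None.  ``T_D_s == onset_time_rel_s`` and
    ``T_P_s == peak_time_rel_s - onset_time_rel_s`` by construction.
    """

    track_id: int | str
    activated: bool
    T_D_s: float | None = None
    T_P_s: float | None = None
    I_P: float | None = None
    plateau_mean_fin: float | None = None
    onset_time_rel_s: float | None = None
    peak_time_rel_s: float | None = None
    condition: str | None = None
    qc_flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# elementary measurements


def normalize(f_ic, f_ib):
    """Normalized fluorescence intensity ``(F_IC - F_IB) / F_IB``.

    Scale-invariant: (a·F_IC, a·F_IB) gives the same value for any a > 0.
    Accepts scalars (exact arithmetic types included) or arrays; a
    non-positive background is a domain error.  NaN inputs (QC-failed
    frames) propagate as NaN.
    """
    if isinstance(f_ic, np.ndarray) or isinstance(f_ib, np.ndarray):
        f_ic = np.asarray(f_ic, dtype=float)
        f_ib = np.asarray(f_ib, dtype=float)
        if np.any(np.isfinite(f_ib) & (f_ib <= 0)):
            raise ValueError("background intensity F_IB must be positive")
        with np.errstate(invalid="ignore"):
            return (f_ic - f_ib) / f_ib
    if not f_ib > 0:
        raise ValueError("background intensity F_IB must be positive")
    return (f_ic - f_ib) / f_ib


def cell_intensity(frame: np.ndarray, rows: np.ndarray,
                   cols: np.ndarray) -> float:
    """Mean cell fluorescence intensity F_IC over a pixel mask."""
    if len(rows) == 0:
        raise QCFailure("empty cell mask")
    return float(np.asarray(frame, dtype=float)[rows, cols].mean())


def _domain_pixels(center_um: tuple[float, float], radius_um: float,
                   pixel_size_um: float,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray] | None:
    """Pixel indices of a round domain, or None if it leaves the frame."""
    cx, cy = center_um
    ny, nx = shape
    if (cx - radius_um < 0 or cx + radius_um > nx * pixel_size_um
            or cy - radius_um < 0 or cy + radius_um > ny * pixel_size_um):
        return None
    r0 = max(0, int((cy - radius_um) / pixel_size_um) - 1)
    r1 = min(ny, int((cy + radius_um) / pixel_size_um) + 2)
    c0 = max(0, int((cx - radius_um) / pixel_size_um) - 1)
    c1 = min(nx, int((cx + radius_um) / pixel_size_um) + 2)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x = (cc + 0.5) * pixel_size_um
    y = (rr + 0.5) * pixel_size_um
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius_um ** 2
    return rr[inside], cc[inside]


def background_domains(centroid_um: tuple[float, float], pixel_size_um: float,
                       shape: tuple[int, int],
                       distance_um: float = BACKGROUND_DISTANCE_UM,
                       domain_area_um2: float = BACKGROUND_DOMAIN_AREA_UM2,
                       angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0),
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pixel sets of the equidistant background domains that fit the frame."""
    radius = math.sqrt(domain_area_um2 / math.pi)
    out = []
    for ang in angles_deg:
        a = math.radians(ang)
        center = (centroid_um[0] + distance_um * math.cos(a),
                  centroid_um[1] + distance_um * math.sin(a))
        pix = _domain_pixels(center, radius, pixel_size_um, shape)
        if pix is not None:
            out.append(pix)
    return out


def background_intensity(frame: np.ndarray, centroid_um: tuple[float, float],
                         pixel_size_um: float,
                         distance_um: float = BACKGROUND_DISTANCE_UM,
                         domain_area_um2: float = BACKGROUND_DOMAIN_AREA_UM2,
                         angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0),
                         exclusion_mask: np.ndarray | None = None,
                         min_domains: int = 2) -> BackgroundEstimate:
    """Local background F_IB around a cell.

    Mean of the per-domain mean intensities over the usable domains: a
    domain is dropped when it extends past the frame edge or overlaps
    ``exclusion_mask`` (detected cells).  With fewer than ``min_domains``
    usable the estimate is NaN and the caller must QC-fail the frame.
    """
    frame = np.asarray(frame, dtype=float)
    means = []
    for rows, cols in background_domains(centroid_um, pixel_size_um,
                                         frame.shape, distance_um,
                                         domain_area_um2, angles_deg):
        if exclusion_mask is not None and exclusion_mask[rows, cols].any():
            continue
        means.append(frame[rows, cols].mean())
    if len(means) < min_domains:
        return BackgroundEstimate(value=float("nan"), n_domains=len(means))
    return BackgroundEstimate(value=float(np.mean(means)),
                              n_domains=len(means))


# --------------------------------------------------------------------------
# trace extraction from an image stack


def extract_trace(stack: ImageStack, track: CellTrack, adhesion: AdhesionEvent,
                  config: QuantConfig = QuantConfig(),
                  other_detections: list[list[Detection]] | None = None,
                  ) -> CalciumTrace:
    """Measure (F_IC, F_IB, F_IN) per frame from arrest onset onward.

    ``other_detections`` (per stack frame, detections not belonging to this
    track) build the exclusion mask for background domains, so a sliding
    cell passing through a domain drops that domain for that frame.

    The cell mask defaults to the detection mask at the arrest-onset frame,
    held fixed afterwards (``mask_mode="onset"``): an arrested cell does
    not move, and a frozen mask avoids the brightness-dependent
    segmentation bias a per-frame threshold mask would add to the
    peak/plateau ratio.  ``mask_mode="frame"`` uses each frame's own mask.
    In either mode F_IC is measured over the bright core of the mask (the
    pixels at or above the mask's ``mask_core_quantile`` intensity in the
    reference frame), which keeps background-level rim pixels — whose
    intensity does not follow the cell — out of the mean.

    Raises :class:`QCFailure` if more than ``max_qc_fail_frac`` of the
    frames fail QC.
    """
    if not adhesion.firm or adhesion.onset_time_s is None:
        raise ValueError("extract_trace requires a firm adhesion event")
    dt = stack.frame_interval_s
    onset_frame = int(round(adhesion.onset_time_s / dt))
    idx0 = int(np.searchsorted(track.frames, onset_frame))
    if idx0 >= track.n_points:
        raise ValueError("track has no detections after the arrest onset")

    frames = stack.frames
    n_frames = stack.n_frames
    track_pos = {int(f): i for i, f in enumerate(track.frames)}

    ref_det = track.detections[track_pos.get(onset_frame, idx0)]
    centroid = track.xy_um[track_pos.get(onset_frame, idx0)]

    def _core(rows: np.ndarray, cols: np.ndarray,
              ref_frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if len(rows) == 0 or config.mask_core_quantile <= 0:
            return rows, cols
        vals = ref_frame[rows, cols]
        keep = vals >= np.quantile(vals, config.mask_core_quantile)
        return rows[keep], cols[keep]

    core_rows, core_cols = _core(ref_det.rows, ref_det.cols,
                                 np.asarray(frames[onset_frame], dtype=float))
    domains = background_domains(
        tuple(centroid), stack.pixel_size_um, stack.shape_px,
        config.background_distance_um, config.background_domain_area_um2,
        config.background_angles_deg)

    frame_ids = np.arange(onset_frame, n_frames)
    t_rel = (frame_ids - onset_frame) * dt
    f_ic = np.full(len(frame_ids), np.nan)
    f_ib = np.full(len(frame_ids), np.nan)

    # vectorized domain means for the common no-exclusion case
    dom_means = np.array([frames[onset_frame:, rows, cols].mean(axis=1)
                          for rows, cols in domains], dtype=float)

    for j, f in enumerate(frame_ids):
        f = int(f)
        if config.mask_mode == "onset":
            rows, cols = core_rows, core_cols
        elif config.mask_mode == "frame":
            i = track_pos.get(f)
            if i is None:
                continue  # linking gap -> QC fail this frame
            det = track.detections[i]
            rows, cols = _core(det.rows, det.cols,
                               np.asarray(frames[f], dtype=float))
        else:
            raise ValueError(f"unknown mask_mode {config.mask_mode!r}")
        if len(rows) == 0:
            continue
        f_ic[j] = frames[f, rows, cols].mean()

        usable = np.ones(len(domains), dtype=bool)
        if other_detections is not None and other_detections[f]:
            excl = np.zeros(stack.shape_px, dtype=bool)
            for det in other_detections[f]:
                excl[det.rows, det.cols] = True
            for d, (drows, dcols) in enumerate(domains):
                if excl[drows, dcols].any():
                    usable[d] = False
        if usable.sum() >= config.min_background_domains:
            f_ib[j] = dom_means[usable, j].mean()

    bad = ~(np.isfinite(f_ic) & np.isfinite(f_ib))
    fail_frac = float(bad.mean())
    if fail_frac > config.max_qc_fail_frac:
        raise QCFailure(
            f"track {track.track_id}: {fail_frac:.0%} of frames failed QC")
    f_in = np.full_like(f_ic, np.nan)
    f_in[~bad] = normalize(f_ic[~bad], f_ib[~bad])
    return CalciumTrace(track.track_id, t_rel, f_ic, f_ib, f_in,
                        qc_fail_frac=fail_frac)


# --------------------------------------------------------------------------
# onset detection and feature extraction


def _moving_mean(y: np.ndarray, w: int) -> np.ndarray:
    """Centred moving mean with edge-shrinking windows (no padding bias)."""
    if w <= 1:
        return y
    n = len(y)
    c = np.concatenate([[0.0], np.cumsum(y)])
    h = w // 2
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + (w - h), 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _fit_flat_ramp(t: np.ndarray, y: np.ndarray, c_lo: int,
                   c_hi: int) -> tuple[int, float] | None:
    """Least-squares breakpoint of a flat-then-ramp model on y[0..c_hi].

    The model is ``y = a`` for ``i <= c`` and ``y = a + b (t_i - t_c)``
    after, continuous at the breakpoint with b > 0.  Returns (best c,
    slope b) or None if no admissible candidate exists.  Vectorized over
    candidates via prefix sums.
    """
    P = c_hi
    if P < c_lo + 2:
        return None
    ys, ts = y[:P + 1], t[:P + 1]
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    cy2 = np.concatenate([[0.0], np.cumsum(ys * ys)])
    ct = np.concatenate([[0.0], np.cumsum(ts)])
    ct2 = np.concatenate([[0.0], np.cumsum(ts * ts)])
    cty = np.concatenate([[0.0], np.cumsum(ts * ys)])
    c = np.arange(c_lo, P - 1)           # breakpoint candidates
    n2 = P - c
    t_c = ts[c]
    Sy2 = cy[P + 1] - cy[c + 1]
    St2 = ct[P + 1] - ct[c + 1]
    Stt2 = ct2[P + 1] - ct2[c + 1]
    Sty2 = cty[P + 1] - cty[c + 1]
    Sx = St2 - n2 * t_c
    Sxx = Stt2 - 2 * t_c * St2 + n2 * t_c * t_c
    Sxy = Sty2 - t_c * Sy2
    N = P + 1
    Stot = cy[P + 1]
    det = N * Sxx - Sx * Sx
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (Stot * Sxx - Sx * Sxy) / det
        b = (N * Sxy - Sx * Stot) / det
        sse = (cy2[P + 1] + N * a * a - 2 * a * Stot
               + b * b * Sxx + 2 * a * b * Sx - 2 * b * Sxy)
    bad = (det <= 0) | (b <= 0) | ~np.isfinite(sse)
    if bad.all():
        return None
    sse = np.where(bad, np.inf, sse)
    k = int(np.argmin(sse))
    return int(c[k]), float(b[k])


def _fit_corner(t: np.ndarray, y: np.ndarray, s: int,
                e: int) -> tuple[int, float] | None:
    """Least-squares rising/falling two-line corner on y[s..e].

    ``y = h + b1 (t - t_c)`` before the corner and ``h + b2 (t - t_c)``
    after, with b1 > 0 > b2.  Returns (corner index, height h) or None.
    """
    if e - s < 5:
        return None
    ys, ts = y[s:e + 1], t[s:e + 1]
    n = len(ys)
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    cy2 = np.concatenate([[0.0], np.cumsum(ys * ys)])
    ct = np.concatenate([[0.0], np.cumsum(ts)])
    ct2 = np.concatenate([[0.0], np.cumsum(ts * ts)])
    cty = np.concatenate([[0.0], np.cumsum(ts * ys)])
    c = np.arange(2, n - 2)             # local corner candidates
    t_c = ts[c]
    nL = c + 1.0
    nR = n - 1.0 - c
    SyL = cy[c + 1]
    SyR = cy[n] - cy[c + 1]
    StL = ct[c + 1]
    StR = ct[n] - ct[c + 1]
    SttL = ct2[c + 1]
    SttR = ct2[n] - ct2[c + 1]
    StyL = cty[c + 1]
    StyR = cty[n] - cty[c + 1]
    SxL = StL - nL * t_c
    SxR = StR - nR * t_c
    SxxL = SttL - 2 * t_c * StL + nL * t_c * t_c
    SxxR = SttR - 2 * t_c * StR + nR * t_c * t_c
    SxyL = StyL - t_c * SyL
    SxyR = StyR - t_c * SyR
    Sy = SyL + SyR
    N = float(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = N - SxL * SxL / SxxL - SxR * SxR / SxxR
        h = (Sy - SxL * SxyL / SxxL - SxR * SxyR / SxxR) / denom
        b1 = (SxyL - h * SxL) / SxxL
        b2 = (SxyR - h * SxR) / SxxR
        sse = (cy2[n] + h * h * N + b1 * b1 * SxxL + b2 * b2 * SxxR
               + 2 * h * (b1 * SxL + b2 * SxR)
               - 2 * h * Sy - 2 * b1 * SxyL - 2 * b2 * SxyR)
    bad = (SxxL <= 0) | (SxxR <= 0) | (b1 <= 0) | (b2 >= 0) | ~np.isfinite(sse)
    if bad.all():
        return None
    sse = np.where(bad, np.inf, sse)
    k = int(np.argmin(sse))
    return s + int(c[k]), float(h[k])


def _finite_series(trace: CalciumTrace) -> tuple[np.ndarray, np.ndarray]:
    good = np.isfinite(trace.f_in)
    return trace.t_rel_s[good], trace.f_in[good]


def detect_onset(trace: CalciumTrace, k: float = 3.0, m: int = 5,
                 floor: float = 0.05,
                 min_plateau_s: float = 2.0,
                 smooth_s: float = 0.5) -> float | None:
    """Time of the sharp fluorescence rise, or None for a flat trace.

    Trigger: the trace is lightly smoothed (``smooth_s`` moving mean,
    which keeps the crossing early enough that the running estimate is
    still an estimate of the plateau); the running plateau estimate is the
    mean and SD of the smoothed F_IN from t = 0 up to the candidate frame,
    and the trace activates at the first candidate exceeded by ``m``
    consecutive smoothed frames above ``mean + max(k·SD, floor)``.  The
    trigger time is then refined to the breakpoint of a least-squares
    flat-plus-ramp fit of the *unsmoothed* trace between t = 0 and the
    trace maximum, which localizes the onset to about one frame even when
    the trigger itself fires well into the rise.
    """
    t, y = _finite_series(trace)
    n = len(y)
    dt = float(np.median(np.diff(t))) if n > 1 else 0.0
    if n < 4 or dt <= 0:
        return None
    min_i = max(int(round(min_plateau_s / dt)), 2)
    if n < min_i + m:
        return None
    w = max(1, int(round(smooth_s / dt)))
    ys = _moving_mean(y, w)
    csum = np.cumsum(ys)
    csum2 = np.cumsum(ys * ys)
    counts = np.arange(1, n + 1, dtype=float)
    run_mean = csum / counts
    run_var = np.maximum(csum2 / counts - run_mean ** 2, 0.0)
    run_sd = np.sqrt(run_var)
    cand = np.arange(min_i, n - m + 1)
    thr = run_mean[cand - 1] + np.maximum(k * run_sd[cand - 1], floor)
    windows = np.lib.stride_tricks.sliding_window_view(ys, m)[cand]
    hit = (windows > thr[:, None]).all(axis=1)
    if not hit.any():
        return None
    i_trig = int(cand[np.argmax(hit)])

    p0 = i_trig + int(np.argmax(ys[i_trig:]))
    fit = _fit_flat_ramp(t, y, c_lo=min(min_i, i_trig) - 1, c_hi=p0)
    if fit is None:
        return float(t[i_trig])
    c = fit[0]
    # sub-frame refinement: the onset is where a free line through the
    # rise crosses the plateau level (exact for a noiseless linear rise);
    # trust region of one frame around the grid breakpoint
    if c + 2 <= p0:
        a0 = float(y[:c + 1].mean())
        beta, alpha = np.polyfit(t[c + 1:p0 + 1], y[c + 1:p0 + 1], 1)
        if beta > 0 and np.isfinite(alpha):
            t_star = (a0 - alpha) / beta
            return float(np.clip(t_star, t[c] - dt, t[c] + dt))
    return float(t[c])


def transient_features(trace: CalciumTrace, onset_time_rel_s: float | None,
                       config: QuantConfig = QuantConfig()) -> TransientFeatures:
    """Extract (T_D, T_P, I_P) given a detected onset time.

    With no onset the cell is non-activated and the characteristics are
    undefined.  The peak is the global maximum of F_IN after onset
    (earliest frame on ties) when the measured plateau noise is below the
    per-frame rise increment — i.e. when the raw argmax already localizes
    the corner — and otherwise the breakpoint of a least-squares two-line
    corner fit around the smoothed maximum, whose fitted height also
    de-noises the peak value.  The activation call additionally requires
    ``I_P >= activation_threshold`` (ties activate).
    """
    if onset_time_rel_s is None:
        return TransientFeatures(trace.track_id, activated=False,
                                 condition=trace.condition)
    t, y = _finite_series(trace)
    n = len(y)
    i0 = int(np.searchsorted(t, onset_time_rel_s - 1e-9))
    i0 = min(max(i0, 1), n - 2)
    plateau = y[:i0]                       # frames with t < onset
    if len(plateau) < 2:
        return TransientFeatures(trace.track_id, activated=False,
                                 condition=trace.condition,
                                 qc_flags=("short_plateau",))
    plateau_mean = float(plateau.mean())
    sigma = float(plateau.std(ddof=1)) if len(plateau) > 2 else 0.0
    dt = float(np.median(np.diff(t)))

    p_raw = i0 + int(np.argmax(y[i0:]))
    w = max(1, int(round(config.smooth_s / dt)))
    p0 = i0 + int(np.argmax(_moving_mean(y, w)[i0:]))
    rise_span = max(t[p0] - onset_time_rel_s, dt)
    slope_per_frame = (max(y[p0] - plateau_mean, 0.0) / rise_span) * dt

    flags: list[str] = []
    if sigma <= slope_per_frame:
        peak_i, peak_val = p_raw, float(y[p_raw])
        peak_time = float(t[peak_i])
    else:
        e = min(n - 1, p0 + max(20, (p0 - i0) // 2))
        fit = _fit_corner(t, y, i0, e)
        if fit is None:
            # degenerate window: fall back on the smoothed maximum (the
            # raw maximum would be inflated by ~2-3 noise SDs)
            peak_time = float(t[p0])
            peak_val = float(_moving_mean(y, w)[p0])
            flags.append("corner_fit_failed")
        else:
            peak_time = float(t[fit[0]])
            peak_val = fit[1]

    if config.ip_mode == "raw-ratio":
        denom = 1.0 + plateau_mean
        if denom <= 0:
            raise QCFailure("plateau raw-equivalent intensity is non-positive")
        ip = (1.0 + peak_val) / denom
    elif config.ip_mode == "normalized-ratio":
        if plateau_mean <= 0:
            raise QCFailure("plateau F_IN is non-positive; normalized-ratio "
                            "I_P undefined")
        ip = peak_val / plateau_mean
    else:
        raise ValueError(f"unknown ip_mode {config.ip_mode!r}")

    t_p = peak_time - onset_time_rel_s
    activated = ip >= config.activation_threshold and t_p > 0
    if not activated:
        return TransientFeatures(trace.track_id, activated=False,
                                 condition=trace.condition,
                                 qc_flags=tuple(flags))
    return TransientFeatures(
        trace.track_id, activated=True,
        T_D_s=float(onset_time_rel_s), T_P_s=float(t_p), I_P=float(ip),
        plateau_mean_fin=plateau_mean,
        onset_time_rel_s=float(onset_time_rel_s),
        peak_time_rel_s=float(peak_time),
        condition=trace.condition, qc_flags=tuple(flags))


def classify_activated(features: TransientFeatures,
                       threshold: float = 1.5) -> bool:
    """Activated ⇔ an onset was detected and I_P clears the threshold
    (a value exactly at the threshold counts as activated)."""
    return (features.onset_time_rel_s is not None
            and features.I_P is not None and features.I_P >= threshold)


def analyze_trace(trace: CalciumTrace,
                  config: QuantConfig = QuantConfig()) -> TransientFeatures:
    """Onset detection followed by feature extraction for one trace."""
    onset = detect_onset(trace, k=config.k, m=config.m, floor=config.floor,
                         min_plateau_s=config.min_plateau_s,
                         smooth_s=config.smooth_s)
    return transient_features(trace, onset, config)


def features_from_traces(traces: pd.DataFrame,
                         config: QuantConfig = QuantConfig()) -> pd.DataFrame:
    """Run feature extraction over a long-format trace table.

    ``traces`` needs columns (cell_id | track_id), t_rel_s, F_IC, F_IB and
    optionally condition.  Returns one row per cell with the activation
    call and (T_D_s, T_P_s, I_P, plateau_mean) where defined.
    """
    id_col = "cell_id" if "cell_id" in traces.columns else "track_id"
    rows = []
    for cid, sub in traces.groupby(id_col, sort=True):
        cond = (str(sub["condition"].iloc[0])
                if "condition" in sub.columns else None)
        trace = CalciumTrace.from_raw(cid, sub["t_rel_s"].to_numpy(),
                                      sub["F_IC"].to_numpy(),
                                      sub["F_IB"].to_numpy(), condition=cond)
        feats = analyze_trace(trace, config)
        rows.append({
            id_col: cid, "condition": cond, "activated": feats.activated,
            "T_D_s": feats.T_D_s, "T_P_s": feats.T_P_s, "I_P": feats.I_P,
            "plateau_mean": feats.plateau_mean_fin,
            "qc_flags": ";".join(feats.qc_flags),
        })
    return pd.DataFrame(rows)
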