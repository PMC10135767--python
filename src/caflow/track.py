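"""Cell detection, track linking and firm-adhesion classification.

Firm adhesion follows the flow-chamber operational definition: a cell is
firmly adherent if its travel displacement over some 1-min window is
strictly less than 10 µm; the start of the earliest qualifying window is
the arrest onset and defines t = 0 for the cell's calcium trace.  "Travel
displacement" is taken as the net Euclidean distance between the window's
first and last positions (the weaker and more common reading for
rolling-vs-arrest work); a cumulative path-length mode is available.

Detection is deliberately plain — smooth, global threshold, connected
components, size filter, intensity-weighted centroids — and linking is
greedy nearest-neighbour with documented deterministic tie-breaking.
Centroids are reported in µm with the pixel-centre convention
``(index + 0.5) × pixel_size`` (origin at the top-left corner, x rightward,
y downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters

__all__ = [
    "Detection", "DetectionConfig", "CellTrack", "AdhesionEvent",
    "detect_cells", "link_tracks", "classify_firm_adhesion",
    "count_firm_adherent",
]


@dataclass
class Detection:
    """One segmented cell in one frame."""

    centroid_um: tuple[float, float]   # (x, y)
    rows: np.ndarray                   # mask pixel indices
    cols: np.ndarray
    area_um2: float
    mean_intensity: float


@dataclass(frozen=True)
class DetectionConfig:
    """Segmentation knobs.

    The default threshold is ``median + k_sd × 1.4826 MAD`` of the
    smoothed frame with a small relative floor (``rel_floor × median``):
    robust statistics keep dim plateau cells detectable while another cell
    is at its bright calcium peak, where a mean/SD threshold would jump
    and break their tracks.  ``mean_sd`` (frame mean + k·SD) and ``otsu``
    are available.  Areas are physical (µm²) so the same config works
    across magnifications.
    """

    smooth_sigma_um: float = 1.0
    threshold_method: str = "robust"    # or "mean_sd", "otsu"
    k_sd: float = 3.0
    rel_floor: float = 0.05
    min_area_um2: float = 10.0
    max_area_um2: float = 2000.0


def detect_cells(frame: np.ndarray, pixel_size_um: float,
                 config: DetectionConfig = DetectionConfig()) -> list[Detection]:
    """Segment one frame into cell detections.

    Deterministic for a fixed frame and config; a frame with nothing above
    threshold (or nothing inside the size filter) yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    sigma_px = config.smooth_sigma_um / pixel_size_um
    smoothed = ndimage.gaussian_filter(frame, sigma_px) if sigma_px > 0 else frame
    if config.threshold_method == "robust":
        med = float(np.median(smoothed))
        mad_sigma = 1.4826 * float(np.median(np.abs(smoothed - med)))
        thr = med + max(config.k_sd * mad_sigma, config.rel_floor * med)
    elif config.threshold_method == "mean_sd":
        thr = smoothed.mean() + config.k_sd * smoothed.std()
    elif config.threshold_method == "otsu":
        thr = filters.threshold_otsu(smoothed)
    else:
        raise ValueError(f"unknown threshold_method {config.threshold_method!r}")
    mask = smoothed > thr
    if not mask.any():
        return []
    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    rows_all, cols_all = np.nonzero(mask)
    lab = labels[rows_all, cols_all]
    w = frame[rows_all, cols_all]
    counts = np.bincount(lab, minlength=n_labels + 1)[1:]
    wsum = np.bincount(lab, weights=w, minlength=n_labels + 1)[1:]
    rsum = np.bincount(lab, weights=w * rows_all, minlength=n_labels + 1)[1:]
    csum = np.bincount(lab, weights=w * cols_all, minlength=n_labels + 1)[1:]
    order = np.argsort(lab, kind="stable")
    bounds = np.searchsorted(lab[order], np.arange(1, n_labels + 2))
    out: list[Detection] = []
    for li in range(n_labels):
        area = counts[li] * pixel_size_um ** 2
        if not (config.min_area_um2 <= area <= config.max_area_um2):
            continue
        if wsum[li] <= 0:
            continue
        sel = order[bounds[li]:bounds[li + 1]]
        r = rsum[li] / wsum[li]
        c = csum[li] / wsum[li]
        out.append(Detection(
            centroid_um=((c + 0.5) * pixel_size_um, (r + 0.5) * pixel_size_um),
            rows=rows_all[sel], cols=cols_all[sel],
            area_um2=float(area),
            mean_intensity=float(wsum[li] / counts[li])))
    return out


@dataclass
class CellTrack:
    """One cell's time-indexed centroid positions and masks."""

    track_id: int
    frames: np.ndarray                       # strictly increasing frame indices
    times_s: np.ndarray
    xy_um: np.ndarray                        # (n, 2)
    detections: list[Detection] = field(default_factory=list, repr=False)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def span_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


class _OpenTrack:
    __slots__ = ("track_id", "frames", "xy", "detections", "last_frame")

    def __init__(self, track_id: int, frame: int, det: Detection):
        self.track_id = track_id
        self.frames = [frame]
        self.xy = [det.centroid_um]
        self.detections = [det]
        self.last_frame = frame


def link_tracks(detections_per_frame: list[list[Detection]],
                frame_interval_s: float,
                max_step_um: float = 10.0,
                max_gap: int = 2) -> list[CellTrack]:
    """Greedy nearest-neighbour linking of per-frame detections.

    For every frame, (track, detection) candidate pairs within
    ``max_step_um`` of the track's last position are sorted by
    (distance, track_id, detection index) and assigned first-come; leftover
    detections start new tracks; a track unmatched for more than
    ``max_gap`` frames is closed.  Fully deterministic.
    """
    if max_step_um <= 0 or frame_interval_s <= 0:
        raise ValueError("max_step_um and frame_interval_s must be positive")
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    next_id = 0
    for f, dets in enumerate(detections_per_frame):
        still_open: list[_OpenTrack] = []
        for tr in open_tracks:
            (closed if f - tr.last_frame > max_gap + 1 else still_open).append(tr)
        open_tracks = still_open
        pairs = []
        for tr in open_tracks:
            tx, ty = tr.xy[-1]
            for di, det in enumerate(dets):
                dx, dy = det.centroid_um
                d = float(np.hypot(dx - tx, dy - ty))
                if d <= max_step_um:
                    pairs.append((d, tr.track_id, di, tr))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, tid, di, tr in pairs:
            if tid in used_tracks or di in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(di)
            tr.frames.append(f)
            tr.xy.append(dets[di].centroid_um)
            tr.detections.append(dets[di])
            tr.last_frame = f
        for di, det in enumerate(dets):
            if di not in used_dets:
                open_tracks.append(_OpenTrack(next_id, f, det))
                next_id += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr.track_id)
    return [CellTrack(track_id=tr.track_id,
                      frames=np.asarray(tr.frames, dtype=int),
                      times_s=np.asarray(tr.frames, dtype=float) * frame_interval_s,
                      xy_um=np.asarray(tr.xy, dtype=float),
                      detections=tr.detections)
            for tr in closed]


@dataclass
class AdhesionEvent:
    """A track's firm-arrest classification.

    ``onset_time_s`` (absolute recording time) is defined only for firm
    tracks: the start of the earliest window whose displacement is below
    threshold.  ``flag`` carries QC notes such as ``insufficient_span``.
    """

    track_id: int
    firm: bool
    onset_time_s: float | None = None
    qualifying_window: tuple[float, float] | None = None
    flag: str = ""


def _window_displacements(track: CellTrack, window_s: float,
                          mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Displacement of every window [t_i, t_i + window_s] over the track.

    The window endpoint is the first observation at or after the start
    plus ``window_s`` (robust to linking gaps).  Returns (start indices,
    displacements); both empty if no complete window fits.
    """
    t = track.times_s
    n = len(t)
    # endpoint index for each start: first j with t[j] >= t[i] + window
    ends = np.searchsorted(t, t + window_s - 1e-9)
    starts = np.nonzero(ends < n)[0]
    if len(starts) == 0:
        return starts, np.empty(0)
    j = ends[starts]
    if mode == "net":
        disp = np.linalg.norm(track.xy_um[j] - track.xy_um[starts], axis=1)
    elif mode == "path":
        steps = np.linalg.norm(np.diff(track.xy_um, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        disp = cum[j] - cum[starts]
    else:
        raise ValueError(f"unknown displacement mode {mode!r}")
    return starts, disp


def classify_firm_adhesion(track: CellTrack,
                           window_s: float = 60.0,
                           threshold_um: float = 10.0,
                           mode: str = "net") -> AdhesionEvent:
    """Classify a track as firmly adherent or not.

    Firm ⇔ some window of duration ``window_s`` has travel displacement
    strictly below ``threshold_um`` (default: 10 µm over 1 min).  The
    window slides at frame resolution; the earliest qualifying window
    defines the arrest onset.  A track shorter than one window is not firm
    and is flagged ``insufficient_span``.
    """
    if window_s <= 0 or threshold_um <= 0:
        raise ValueError("window_s and threshold_um must be positive")
    if track.span_s < window_s - 1e-9:
        return AdhesionEvent(track.track_id, firm=False, flag="insufficient_span")
    starts, disp = _window_displacements(track, window_s, mode)
    if len(starts) == 0:
        return AdhesionEvent(track.track_id, firm=False, flag="insufficient_span")
    firm = disp < threshold_um          # strict inequality
    if not firm.any():
        return AdhesionEvent(track.track_id, firm=False)
    i = starts[int(np.argmax(firm))]
    onset = float(track.times_s[i])
    flag = ""
    # QC: motion after the arrest window (possible detachment)
    later = disp[starts >= i]
    if (later >= threshold_um).any():
        flag = "motion_after_onset"
    return AdhesionEvent(track.track_id, firm=True, onset_time_s=onset,
                         qualifying_window=(onset, onset + window_s),
                         flag=flag)


def count_firm_adherent(events: list[AdhesionEvent],
                        assay_duration_s: float = 420.0) -> int:
    """Number of distinct firm tracks arresting within the assay window
    (default 7 min)."""
    return sum(1 for e in events
               if e.firm and e.onset_time_s is not None
               and e.onset_time_s <= assay_duration_s)
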