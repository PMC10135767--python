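"""Synthetic flow-chamber time-lapse and calcium-trace generator.

Every downstream stage of the pipeline (tracking, arrest classification,
trace normalization, feature extraction, group statistics) is developed and
validated against recordings produced here, with full ground truth: true
centroids, true arrest times and the true transient parameters of every
cell.

The trace model is the canonical single-burst calcium transient of a cell
arresting on an adhesive substrate: the normalized fluorescence sits at a
low plateau for a latent delay T_D after arrest, rises over a peak time T_P
to ``plateau × I_P``, then relaxes exponentially back toward the plateau.
The rise is a linear ramp by default (the simplest shape with an
unambiguous peak time); a smoothstep alternative is available.  The decay
time constant is a free generator parameter — real boxplot data constrain
only the delay/rise/peak statistics, not the decay.

Scenes render each cell as an isotropic Gaussian-profile disk whose
brightness scales with its trace; cells occlude the uniform background
(bright dye-loaded cells dominate the substrate signal under them).
Translating (rolling/sliding) cells move along +x at a constant velocity
until their arrest time, if any.  Shear stress, ligand density and
treatment are condition *labels* whose only effect is to shift the
distributions the transient parameters are drawn from — no hydrodynamics
or bond mechanics are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "TransientParams", "CellSpec", "SceneSpec", "GroundTruth",
    "ParamDistributions", "Cohort",
    "simulate_trace", "trace_value", "render_stack", "generate_cohort",
    "shear_series_design", "ligand_series_design", "inhibitor_design",
    "knockdown_design",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class TransientParams:
    """Ground-truth parameters of one cell's calcium transient.

    ``plateau_level`` is the resting (mean cell) fluorescence in arbitrary
    units, ``delay_s`` the latency T_D between arrest and the onset of the
    rise, ``rise_s`` the peak time T_P, ``peak_ratio`` the peak calcium
    intensity I_P (peak / plateau fluorescence, dimensionless ≥ 1) and
    ``decay_tau_s`` the exponential relaxation constant.  A non-activated
    cell has a flat trace; its ``peak_ratio`` is 1 by definition.
    """

    plateau_level: float
    delay_s: float = 0.0
    rise_s: float = 1.0
    peak_ratio: float = 1.0
    decay_tau_s: float = 60.0
    activated: bool = True

    def __post_init__(self) -> None:
        for name in ("plateau_level", "delay_s", "rise_s", "peak_ratio",
                     "decay_tau_s"):
            _require_finite(name, getattr(self, name))
        if self.plateau_level <= 0:
            raise ValueError("plateau_level must be positive")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if self.rise_s <= 0:
            raise ValueError("rise_s must be positive")
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be positive")
        if self.peak_ratio < 1:
            raise ValueError("peak_ratio must be >= 1")
        if self.activated and self.peak_ratio <= 1:
            raise ValueError("an activated transient needs peak_ratio > 1")


def trace_value(params: TransientParams, t, rise_shape: str = "linear"):
    """Noiseless transient value at time(s) ``t`` (seconds after arrest).

    Piecewise: plateau for ``t < T_D``; monotone rise over
    ``[T_D, T_D + T_P]`` reaching ``plateau × I_P``; exponential relaxation
    toward the plateau with time constant ``decay_tau_s`` afterwards.
    """
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, params.plateau_level, dtype=float)
    if not params.activated:
        return out
    p = params.plateau_level
    amp = p * (params.peak_ratio - 1.0)
    td, tp = params.delay_s, params.rise_s
    rising = (t >= td) & (t <= td + tp)
    u = (t[rising] - td) / tp
    if rise_shape == "linear":
        ramp = u
    elif rise_shape == "smooth":
        ramp = u * u * (3.0 - 2.0 * u)  # smoothstep, same endpoints
    else:
        raise ValueError(f"unknown rise_shape {rise_shape!r}")
    out[rising] = p + amp * ramp
    falling = t > td + tp
    out[falling] = p + amp * np.exp(-(t[falling] - td - tp) / params.decay_tau_s)
    return out


def simulate_trace(params: TransientParams, frame_interval_s: float,
                   duration_s: float, noise_sd: float = 0.0,
                   seed: int | None = None,
                   rise_shape: str = "linear") -> np.ndarray:
    """Sample a transient on a regular frame grid with additive noise.

    Returns the intensity series at times ``k * frame_interval_s`` for
    ``k = 0 .. round(duration/interval) - 1``.  Identical seed and
    parameters give an identical series.
    """
    frame_interval_s = _require_finite("frame_interval_s", frame_interval_s)
    duration_s = _require_finite("duration_s", duration_s)
    noise_sd = _require_finite("noise_sd", noise_sd)
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if params.activated and duration_s <= params.delay_s + params.rise_s:
        raise ValueError("duration_s must exceed delay_s + rise_s")
    n = int(round(duration_s / frame_interval_s))
    if n < 2:
        raise ValueError("duration covers fewer than 2 frames")
    t = np.arange(n) * frame_interval_s
    y = trace_value(params, t, rise_shape=rise_shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return y


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: geometry, motion and its transient.

    The cell appears at ``entry_time_s`` at ``(x0_um, y0_um)``, translates
    along +x at ``velocity_um_s`` and stops at ``arrest_time_s`` (``None``
    means it never arrests and keeps sliding).  Its calcium trace starts at
    the plateau and, if it arrests and is activated, follows ``params``
    with time measured from the arrest.
    """

    cell_id: str
    x0_um: float
    y0_um: float
    params: TransientParams
    entry_time_s: float = 0.0
    velocity_um_s: float = 0.0
    arrest_time_s: float | None = None
    radius_um: float = 7.5

    def __post_init__(self) -> None:
        if self.entry_time_s < 0:
            raise ValueError("entry_time_s must be >= 0")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.arrest_time_s is not None and self.arrest_time_s < self.entry_time_s:
            raise ValueError("arrest_time_s must be >= entry_time_s")

    def position_um(self, t: float) -> tuple[float, float]:
        t_move = t if self.arrest_time_s is None else min(t, self.arrest_time_s)
        x = self.x0_um + self.velocity_um_s * (t_move - self.entry_time_s)
        return x, self.y0_um

    def amplitude(self, t: float, rise_shape: str = "linear") -> float:
        if self.arrest_time_s is None or t < self.arrest_time_s:
            return self.params.plateau_level
        return float(trace_value(self.params, t - self.arrest_time_s,
                                 rise_shape=rise_shape))


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one rendered recording."""

    shape_px: tuple[int, int]          # (ny, nx)
    pixel_size_um: float
    frame_interval_s: float
    duration_s: float
    cells: tuple[CellSpec, ...]
    background_level: float = 60.0
    gaussian_sd: float = 0.0
    poisson: bool = False
    rise_shape: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.background_level < 0 or self.gaussian_sd < 0:
            raise ValueError("background_level and gaussian_sd must be >= 0")
        ny, nx = self.shape_px
        fx, fy = nx * self.pixel_size_um, ny * self.pixel_size_um
        for cell in self.cells:
            if cell.arrest_time_s is not None and cell.params.activated:
                need = (cell.arrest_time_s + cell.params.delay_s
                        + cell.params.rise_s)
                if self.duration_s < need:
                    raise ValueError(
                        f"duration_s {self.duration_s} too short for cell "
                        f"{cell.cell_id} (arrest + delay + rise = {need:.1f} s)")
            # the cell must be inside the field at least once
            inside = False
            for t in (cell.entry_time_s,
                      cell.arrest_time_s if cell.arrest_time_s is not None
                      else self.duration_s):
                x, y = cell.position_um(min(t, self.duration_s))
                if -cell.radius_um < x < fx + cell.radius_um and \
                   -cell.radius_um < y < fy + cell.radius_um:
                    inside = True
            if not inside:
                raise ValueError(
                    f"cell {cell.cell_id} never intersects the field")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))


@dataclass
class GroundTruth:
    """True per-cell parameters and, for rendered scenes, true centroids.

    ``cells`` has one row per cell (cell_id, condition, entry/arrest times,
    T_D_s, T_P_s, I_P, activated, taxonomy, ...); ``centroids`` has one row
    per (cell, frame) the cell was rendered in.
    """

    cells: pd.DataFrame
    centroids: pd.DataFrame | None = None


def _taxonomy(cell: CellSpec) -> str:
    if cell.arrest_time_s is None:
        return "never-arrests"
    return "arrested-activated" if cell.params.activated else "arrested-non-activated"


def _snap(t: float | None, dt: float) -> float | None:
    """Snap a time to the acquisition frame grid (next frame at or after)."""
    if t is None:
        return None
    return dt * math.ceil(t / dt - 1e-9)


def render_stack(scene: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a scene to a 16-bit stack with matching ground truth.

    Entry and arrest times are snapped to the frame grid (sub-frame phase
    is unobservable in the recording); the snapped values are the ones
    recorded as ground truth.  Rendering is bit-reproducible per seed.
    """
    dt = scene.frame_interval_s
    px = scene.pixel_size_um
    ny, nx = scene.shape_px
    n_frames = scene.n_frames
    rng = np.random.default_rng(scene.seed)

    cells = [replace(c, entry_time_s=_snap(c.entry_time_s, dt),
                     arrest_time_s=_snap(c.arrest_time_s, dt))
             for c in scene.cells]

    frames = np.empty((n_frames, ny, nx), dtype=np.uint16)
    xs = (np.arange(nx) + 0.5) * px   # pixel-centre coordinates, µm
    ys = (np.arange(ny) + 0.5) * px
    cent_rows: list[tuple] = []

    for k in range(n_frames):
        t = k * dt
        img = np.full((ny, nx), scene.background_level, dtype=float)
        for cell in cells:
            if t < cell.entry_time_s - 1e-9:
                continue
            x, y = cell.position_um(t)
            sigma = cell.radius_um / 2.0
            half = 4.0 * sigma
            if x + half < 0 or x - half > nx * px or \
               y + half < 0 or y - half > ny * px:
                continue  # fully out of field this frame
            c0 = max(0, int((x - half) / px))
            c1 = min(nx, int((x + half) / px) + 1)
            r0 = max(0, int((y - half) / px))
            r1 = min(ny, int((y + half) / px) + 1)
            if c0 >= c1 or r0 >= r1:
                continue
            amp = cell.amplitude(t, rise_shape=scene.rise_shape)
            d2 = ((xs[c0:c1][None, :] - x) ** 2
                  + (ys[r0:r1][:, None] - y) ** 2)
            spot = amp * np.exp(-d2 / (2.0 * sigma * sigma))
            patch = img[r0:r1, c0:c1]
            np.maximum(patch, spot, out=patch)  # cell occludes background
            cent_rows.append((cell.cell_id, k, t, x, y))
        if scene.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if scene.gaussian_sd > 0:
            img = img + rng.normal(0.0, scene.gaussian_sd, size=img.shape)
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    fx, fy = nx * px, ny * px
    cell_rows = []
    for cell in cells:
        # a cell is edge-exiting if its centre leaves the field while alive
        exits = False
        for k in range(n_frames):
            t = k * dt
            if t < cell.entry_time_s - 1e-9:
                continue
            x, y = cell.position_um(t)
            if not (0 <= x <= fx and 0 <= y <= fy):
                exits = True
                break
        p = cell.params
        cell_rows.append({
            "cell_id": cell.cell_id,
            "entry_time_s": cell.entry_time_s,
            "arrest_time_s": (np.nan if cell.arrest_time_s is None
                              else cell.arrest_time_s),
            "x_arrest_um": cell.position_um(
                cell.arrest_time_s if cell.arrest_time_s is not None
                else scene.duration_s)[0],
            "y_arrest_um": cell.y0_um,
            "radius_um": cell.radius_um,
            "plateau_level": p.plateau_level,
            "T_D_s": p.delay_s,
            "T_P_s": p.rise_s,
            "I_P": p.peak_ratio,
            "decay_tau_s": p.decay_tau_s,
            "activated": p.activated,
            "taxonomy": _taxonomy(cell),
            "edge_exiting": exits,
        })
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows),
        centroids=pd.DataFrame(
            cent_rows, columns=["cell_id", "frame", "t_s", "x_um", "y_um"]),
    )
    stack = ImageStack(frames, px, dt)
    return stack, truth


# --------------------------------------------------------------------------
# Cohort generation: condition labels -> parameter distributions -> datasets


@dataclass(frozen=True)
class ParamDistributions:
    """Per-condition sampling distributions for transient parameters.

    Delay, rise and peak ratio are lognormal (median, geometric SD); the
    peak ratio is additionally floored at ``min_peak_ratio`` so every
    activated draw clears the activation threshold by construction.  The
    defaults are the package's reference condition; condition designs shift
    the medians.
    """

    median_delay_s: float = 30.0
    gsd_delay: float = 1.35
    median_rise_s: float = 15.0
    gsd_rise: float = 1.30
    median_peak_ratio: float = 2.5
    gsd_peak_ratio: float = 1.20
    min_peak_ratio: float = 1.6
    decay_tau_s: float = 40.0
    plateau_level: float = 150.0
    activated_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("median_delay_s", "gsd_delay", "median_rise_s",
                     "gsd_rise", "median_peak_ratio", "gsd_peak_ratio",
                     "min_peak_ratio", "decay_tau_s", "plateau_level",
                     "activated_fraction"):
            _require_finite(name, getattr(self, name))
        if not (0.0 <= self.activated_fraction <= 1.0):
            raise ValueError("activated_fraction must lie in [0, 1]")
        if min(self.gsd_delay, self.gsd_rise, self.gsd_peak_ratio) < 1.0:
            raise ValueError("geometric SDs must be >= 1")

    def sample(self, rng: np.random.Generator) -> TransientParams:
        if rng.random() >= self.activated_fraction:
            return TransientParams(plateau_level=self.plateau_level,
                                   peak_ratio=1.0, activated=False,
                                   decay_tau_s=self.decay_tau_s)
        delay = self.median_delay_s * math.exp(
            rng.normal(0.0, math.log(self.gsd_delay)))
        rise = self.median_rise_s * math.exp(
            rng.normal(0.0, math.log(self.gsd_rise)))
        ratio = max(self.min_peak_ratio,
                    self.median_peak_ratio * math.exp(
                        rng.normal(0.0, math.log(self.gsd_peak_ratio))))
        return TransientParams(plateau_level=self.plateau_level,
                               delay_s=delay, rise_s=rise, peak_ratio=ratio,
                               decay_tau_s=self.decay_tau_s, activated=True)


def shear_series_design() -> dict[str, ParamDistributions]:
    """Wall-shear-stress series, 0.15 / 0.30 / 0.60 dyn/cm².

    Higher shear accelerates the transient (smaller median delay and peak
    time) and strengthens it (larger median peak intensity) — the monotone
    effect directions of the flow-chamber shear experiment.
    """
    return {
        "0.15 dyn/cm2": ParamDistributions(median_delay_s=45.0,
                                           median_rise_s=20.0,
                                           median_peak_ratio=2.0),
        "0.30 dyn/cm2": ParamDistributions(median_delay_s=30.0,
                                           median_rise_s=15.0,
                                           median_peak_ratio=2.5),
        "0.60 dyn/cm2": ParamDistributions(median_delay_s=20.0,
                                           median_rise_s=10.0,
                                           median_peak_ratio=3.2),
    }


def ligand_series_design() -> dict[str, ParamDistributions]:
    """Ligand-density series (2 vs 20 µg/mL coating).

    Denser ligand sharply shortens the delay; peak time and intensity move
    in the same directions but only mildly.
    """
    return {
        "2 ug/mL": ParamDistributions(median_delay_s=55.0,
                                      median_rise_s=17.0,
                                      median_peak_ratio=2.3),
        "20 ug/mL": ParamDistributions(median_delay_s=25.0,
                                       median_rise_s=14.0,
                                       median_peak_ratio=2.6),
    }


def inhibitor_design() -> dict[str, ParamDistributions]:
    """Vehicle vs ER-channel inhibitor (no effect) vs membrane-channel
    blocker (slower, weaker transient)."""
    base = ParamDistributions()
    return {
        "DMSO": base,
        "2-APB": base,
        "LaCl3": ParamDistributions(median_delay_s=55.0, median_rise_s=25.0,
                                    median_peak_ratio=1.8),
    }


def knockdown_design() -> dict[str, ParamDistributions]:
    """Wild-type vs adaptor-knockdown cells (slower, weaker transient)."""
    return {
        "WT": ParamDistributions(),
        "shKindlin-3": ParamDistributions(median_delay_s=50.0,
                                          median_rise_s=24.0,
                                          median_peak_ratio=1.8),
    }


@dataclass
class Cohort:
    """A generated multi-condition dataset.

    ``mode == "traces"``: ``traces`` holds per-frame (condition, cell_id,
    t_rel_s, F_IC, F_IB) rows with t = 0 at arrest.  ``mode == "stack"``:
    ``scenes`` is a list of (condition, ImageStack, GroundTruth).  ``truth``
    always carries one row per cell.
    """

    mode: str
    truth: pd.DataFrame
    traces: pd.DataFrame | None = None
    scenes: list[tuple[str, ImageStack, GroundTruth]] | None = None


def generate_cohort(effect_spec: Mapping[str, ParamDistributions],
                    n_cells_per_condition: int,
                    seed: int,
                    mode: str = "traces",
                    frame_interval_s: float = 0.05,
                    background_level: float = 60.0,
                    noise_sd: float = 0.0,
                    duration_s: float | None = None,
                    post_peak_s: float = 15.0,
                    pixel_size_um: float = 0.8,
                    cells_per_scene: int = 1,
                    arrest_window_s: tuple[float, float] = (0.0, 5.0),
                    cell_radius_um: float = 7.5,
                    gaussian_sd: float = 0.0,
                    cell_spacing_um: float = 60.0,
                    field_margin_um: float = 40.0) -> Cohort:
    """Draw per-condition transient parameters and materialize a dataset.

    In ``traces`` mode each cell yields a bare fluorescence time series
    (cell intensity F_IC with additive Gaussian noise of SD ``noise_sd``,
    constant background F_IB) already referenced to arrest at t = 0.  In
    ``stack`` mode cells are placed on a grid, ``cells_per_scene`` at a
    time, appear at their (frame-grid) arrest time drawn from
    ``arrest_window_s``, and each scene is rendered to a 16-bit stack.
    ``duration_s`` defaults to covering every sampled ``arrest + delay +
    rise`` plus ``post_peak_s`` of decay.
    """
    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be >= 1")
    if not effect_spec:
        raise ValueError("effect_spec must name at least one condition")
    for cond, dist in effect_spec.items():
        if not isinstance(dist, ParamDistributions):
            raise TypeError(f"condition {cond!r} must map to ParamDistributions")
    if mode not in ("traces", "stack"):
        raise ValueError(f"unknown cohort mode {mode!r}")

    rng = np.random.default_rng(seed)
    dt = frame_interval_s

    sampled: list[dict] = []
    for cond, dist in effect_spec.items():
        for i in range(n_cells_per_condition):
            params = dist.sample(rng)
            if mode == "stack":
                arrest = _snap(rng.uniform(*arrest_window_s), dt)
            else:
                arrest = 0.0
            sampled.append({"condition": cond,
                            "cell_id": f"{cond}/{i:03d}",
                            "params": params, "arrest": arrest})

    if duration_s is None:
        need = max((s["arrest"] + s["params"].delay_s + s["params"].rise_s
                    for s in sampled if s["params"].activated),
                   default=0.0)
        duration_s = max(need + post_peak_s, 60.0 + max(s["arrest"] for s in sampled) + dt)

    truth_rows = []
    for s in sampled:
        p = s["params"]
        truth_rows.append({
            "condition": s["condition"], "cell_id": s["cell_id"],
            "arrest_time_s": s["arrest"], "plateau_level": p.plateau_level,
            "T_D_s": p.delay_s, "T_P_s": p.rise_s, "I_P": p.peak_ratio,
            "decay_tau_s": p.decay_tau_s, "activated": p.activated,
            "taxonomy": ("arrested-activated" if p.activated
                         else "arrested-non-activated"),
        })
    truth = pd.DataFrame(truth_rows)

    if mode == "traces":
        n = int(round(duration_s / dt))
        t = np.arange(n) * dt
        frames = []
        for s in sampled:
            y = trace_value(s["params"], t)
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=n)
            frames.append(pd.DataFrame({
                "condition": s["condition"], "cell_id": s["cell_id"],
                "t_rel_s": t, "F_IC": y, "F_IB": background_level,
            }))
        return Cohort(mode="traces", truth=truth,
                      traces=pd.concat(frames, ignore_index=True))

    # stack mode: pack cells_per_scene cells per rendered scene
    scenes: list[tuple[str, ImageStack, GroundTruth]] = []
    ncols = int(math.ceil(math.sqrt(cells_per_scene)))
    nrows = int(math.ceil(cells_per_scene / ncols))
    fx = 2 * field_margin_um + (ncols - 1) * cell_spacing_um
    fy = 2 * field_margin_um + (nrows - 1) * cell_spacing_um
    shape_px = (int(math.ceil(fy / pixel_size_um)),
                int(math.ceil(fx / pixel_size_um)))
    by_cond: dict[str, list[dict]] = {}
    for s in sampled:
        by_cond.setdefault(s["condition"], []).append(s)
    for cond, group in by_cond.items():
        for s0 in range(0, len(group), cells_per_scene):
            chunk = group[s0:s0 + cells_per_scene]
            cells = []
            for j, s in enumerate(chunk):
                r, c = divmod(j, ncols)
                cells.append(CellSpec(
                    cell_id=s["cell_id"],
                    x0_um=field_margin_um + c * cell_spacing_um,
                    y0_um=field_margin_um + r * cell_spacing_um,
                    params=s["params"],
                    entry_time_s=s["arrest"], velocity_um_s=0.0,
                    arrest_time_s=s["arrest"], radius_um=cell_radius_um))
            scene = SceneSpec(shape_px=shape_px, pixel_size_um=pixel_size_um,
                              frame_interval_s=dt, duration_s=duration_s,
                              cells=tuple(cells),
                              background_level=background_level,
                              gaussian_sd=gaussian_sd,
                              seed=int(rng.integers(0, 2**31 - 1)))
            stack, gt = render_stack(scene)
            gt.cells.insert(0, "condition", cond)
            scenes.append((cond, stack, gt))
    return Cohort(mode="stack", truth=truth, scenes=scenes)
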