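"""Synthetic spinal-cord movie generator with exact ground truth.

Emulates the structure of one-photon fluorescence movies through a
dorsal laminectomy window: bright tissue crossed by a dark, meandering
dorsal vein with ascending venule branches; two lateral strips of
Gaussian-blob neurons firing exponential-decay calcium transients;
large, predominantly rostrocaudal rigid shifts (up to hundreds of
pixels) plus per-frame jitter; a smooth rostrocaudal non-rigid
deformation; an independently moving bright occluding layer
(neovascularization, adhesive bubbles); exponential photobleaching; and
Poisson + read noise.

Every generated quantity — per-frame shift, deformation profile, cell
traces and footprints, vessel width, bleach trend, landmark positions —
is returned as :class:`GroundTruth`, so each pipeline stage can be
tested against exact expectations without any downloaded data.  All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from cordmotion.movie import MovieTensor
from cordmotion.quant import EncoderTrace, encoder_conversion_factor

__all__ = ["SimConfig", "GroundTruth", "make_movie", "make_feature_table", "make_encoder_trace"]


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults produce a 256 x 256, 200-frame movie at 20 Hz with
    rostrocaudal shifts up to 120 px — the large-displacement regime
    (at ~5.5 um/px, >650 um) — 0.5 px tracking-scale jitter, an 8 px
    rostrocaudal deformation, a moving occluder, mild bleaching, and
    shot + read noise.  Set amplitudes to zero to switch a nuisance
    off.
    """

    shape: Tuple[int, int] = (256, 256)
    n_frames: int = 200
    frame_rate: float = 20.0
    pixel_size: Optional[float] = 5.5

    # scene
    tissue_level: float = 100.0
    texture_amp: float = 15.0
    texture_sigma: float = 3.0

    # vessels (dark on bright tissue)
    vein_width_px: float = 11.0
    vein_depth: float = 60.0
    vein_meander_px: float = 10.0
    n_venules: int = 4
    venule_width_px: float = 5.0
    venule_depth: float = 40.0
    vein_width_schedule: Optional[np.ndarray] = None  # per-frame widths

    # cells: two lateral strips of Gaussian blobs
    cells_per_side: int = 15
    cell_radius_px: float = 3.0
    transient_rate_hz: float = 0.1
    transient_tau_s: float = 1.5
    transient_amp: float = 40.0

    # motion
    max_rc_shift_px: float = 120.0
    ml_shift_fraction: float = 0.05
    jitter_sigma_px: float = 0.5
    deform_amp_px: float = 0.0
    deform_wavelength_px: float = 128.0

    # occluder
    occluder_opacity: float = 0.0
    occluder_level: float = 220.0
    occluder_velocity_px: Tuple[float, float] = (0.8, 0.3)
    occluder_blobs: int = 3

    # bleach / noise
    bleach_rate: float = 0.1  # fractional decay over the whole movie
    photon_scale: float = 0.5  # photons per intensity unit; 0 disables
    read_noise_sigma: float = 1.0

    seed: int = 0


@dataclass
class GroundTruth:
    """Exact per-frame truth for a simulated movie.

    ``shifts`` are the apparent (x, y) displacement of the scene in each
    frame; a perfect rigid correction to frame ``t0`` translates frame
    ``t`` by ``shifts[t0] - shifts[t]``.  ``deform_profile_rc`` holds
    the rostrocaudal displacement as a function of the RC coordinate
    (the field is constant mediolaterally); ``deform_field(t)``
    materializes the full 2-D field.
    """

    shifts: np.ndarray  # (T, 2) as (dx, dy)
    deform_profile_rc: np.ndarray  # (T, Y)
    cell_centers: np.ndarray  # (n_cells, 2) as (x, y), scene coords
    cell_traces: np.ndarray  # (T, n_cells)
    cell_footprints: np.ndarray  # (n_cells, Y, X)
    vessel_width_px: np.ndarray  # (T,)
    bleach_trend: np.ndarray  # (T,)
    feature_points: Dict[str, Tuple[float, float]]  # scene coords (x, y)
    frame_shape: Tuple[int, int]

    def feature_positions(self, t: int) -> Dict[str, Tuple[float, float]]:
        """True (x, y) of each landmark in frame ``t`` (shift + deformation)."""
        dx, dy = self.shifts[t]
        out = {}
        for name, (x, y) in self.feature_points.items():
            yi = int(np.clip(round(y + dy), 0, self.deform_profile_rc.shape[1] - 1))
            out[name] = (x + dx, y + dy + self.deform_profile_rc[t, yi])
        return out

    def deform_field(self, t: int) -> np.ndarray:
        """(Y, X) rostrocaudal displacement field of frame ``t``."""
        return np.repeat(self.deform_profile_rc[t][:, None], self.frame_shape[1], axis=1)


# ----------------------------------------------------------------------
# scene construction
# ----------------------------------------------------------------------


def _vessel_layer(
    shape: Tuple[int, int],
    cfg: SimConfig,
    rng: np.random.Generator,
    vein_width: float,
) -> Tuple[np.ndarray, Dict[str, Tuple[float, float]], np.ndarray]:
    """Dark-vessel attenuation layer plus landmark (branch) points."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx = w / 2.0
    phase = rng.uniform(0, 2 * np.pi)
    center = cx + cfg.vein_meander_px * np.sin(2 * np.pi * yy[:, 0] / h + phase)
    dist = np.abs(xx - center[:, None])
    vein = cfg.vein_depth * np.exp(-((dist / (vein_width / 2.0)) ** 4))

    layer = vein.copy()
    features: Dict[str, Tuple[float, float]] = {}
    branch_ys = np.linspace(0.15 * h, 0.85 * h, cfg.n_venules)
    for i, by in enumerate(branch_ys):
        side = 1 if i % 2 == 0 else -1
        bx = center[int(by)]
        length = rng.uniform(0.25, 0.45) * w
        curve = rng.uniform(0.1, 0.3)
        s = np.linspace(0, 1, 200)
        px = bx + side * length * s
        py = by + curve * h * s**2 * (1 if i % 4 < 2 else -1)
        ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
        blank = np.zeros(shape)
        blank[py[ok].astype(int), px[ok].astype(int)] = 1.0
        tube = ndi.gaussian_filter(blank, cfg.venule_width_px / 2.355)
        if tube.max() > 0:
            layer += cfg.venule_depth * tube / tube.max()
        features[f"branch_{i}"] = (float(bx), float(by))
    # extra landmarks along the vein itself
    for j, vy in enumerate(np.linspace(0.1 * h, 0.9 * h, 4)):
        features[f"vein_{j}"] = (float(center[int(vy)]), float(vy))
    return layer, features, center


def _make_cells(
    shape: Tuple[int, int], cfg: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Footprints (n, Y, X) and centers (n, 2) in two lateral strips."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    centers = []
    strips = [
        (0.08 * w, 0.32 * w),  # left of the vein corridor
        (0.68 * w, 0.92 * w),  # right
    ]
    for lo, hi in strips:
        for _ in range(cfg.cells_per_side):
            centers.append((rng.uniform(lo, hi), rng.uniform(0.08 * h, 0.92 * h)))
    centers = np.array(centers)
    fps = np.empty((len(centers), h, w), dtype=np.float32)
    for i, (cx, cy) in enumerate(centers):
        fps[i] = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * cfg.cell_radius_px**2)))
    return fps, centers


def _make_traces(cfg: SimConfig, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson event times, instantaneous rise, exponential decay."""
    t = cfg.n_frames
    dt = 1.0 / cfg.frame_rate
    events = rng.random((t, n_cells)) < cfg.transient_rate_hz * dt
    kernel_len = max(int(5 * cfg.transient_tau_s / dt), 1)
    kernel = np.exp(-np.arange(kernel_len) * dt / cfg.transient_tau_s)
    traces = np.empty((t, n_cells))
    for c in range(n_cells):
        traces[:, c] = np.convolve(events[:, c].astype(float), kernel)[:t]
    return traces * cfg.transient_amp


def _shift_schedule(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth rostrocaudal shift trace reaching exactly the configured max."""
    t = cfg.n_frames
    walk = np.cumsum(rng.standard_normal(t))
    walk = ndi.gaussian_filter1d(walk, sigma=max(t / 40.0, 1.0))
    walk -= walk[0]
    peak = np.abs(walk).max()
    rc = walk / peak * cfg.max_rc_shift_px if peak > 0 else walk
    ml = rc * cfg.ml_shift_fraction
    jitter = rng.standard_normal((t, 2)) * cfg.jitter_sigma_px
    jitter[0] = 0
    shifts = np.column_stack([ml, rc]) + jitter  # (dx, dy); RC along rows
    shifts[0] = 0.0
    if cfg.max_rc_shift_px > 0:
        k = int(np.argmax(np.abs(shifts[:, 1])))
        shifts[k, 1] = np.sign(shifts[k, 1]) * cfg.max_rc_shift_px
    return shifts


def make_movie(config: Optional[SimConfig] = None) -> Tuple[MovieTensor, GroundTruth]:
    """Render a simulated movie and its exact ground truth.

    The static scene (tissue + vessels + cell footprints) lives on a
    canvas padded by the worst-case motion; each frame samples it at
    ``p - shift(t) - deform_t(p)`` (so scene content visibly moves by
    ``+shift``), then the occluder layer, bleaching, and noise are
    applied in that order.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    if cfg.vein_width_schedule is not None and len(cfg.vein_width_schedule) != cfg.n_frames:
        raise ValueError("vein_width_schedule must have one width per frame")

    shifts = _shift_schedule(cfg, rng)
    margin = int(np.ceil(np.abs(shifts).max() + cfg.deform_amp_px + 2))
    sh, sw = h + 2 * margin, w + 2 * margin

    texture = ndi.gaussian_filter(rng.standard_normal((sh, sw)), cfg.texture_sigma)
    texture *= cfg.texture_amp / max(texture.std(), 1e-12)
    base_widths = (
        np.asarray(cfg.vein_width_schedule, dtype=float)
        if cfg.vein_width_schedule is not None
        else np.full(cfg.n_frames, cfg.vein_width_px)
    )
    vessel_rng_state = rng.bit_generator.state
    vessels, features_scene, _ = _vessel_layer((sh, sw), cfg, rng, base_widths[0])
    footprints, centers = _make_cells((sh, sw), cfg, rng)
    traces = _make_traces(cfg, len(centers), rng)

    static = cfg.tissue_level + texture - vessels

    # occluder scene: bright blobs on an otherwise transparent layer
    occ_mask = np.zeros((sh, sw))
    if cfg.occluder_opacity > 0:
        for _ in range(cfg.occluder_blobs):
            oy, ox = rng.uniform(0, sh), rng.uniform(0, sw)
            yy, xx = np.mgrid[0:sh, 0:sw].astype(float)
            occ_mask += np.exp(-(((xx - ox) ** 2 + (yy - oy) ** 2) / (2 * (0.08 * sw) ** 2)))
        occ_mask = np.clip(occ_mask, 0, 1)

    phase = rng.uniform(0, 2 * np.pi)
    deform_profile = np.zeros((cfg.n_frames, h))
    if cfg.deform_amp_px > 0:
        # smooth, irregular amplitude trace in [0, deform_amp_px]
        amp_t = ndi.gaussian_filter1d(rng.standard_normal(cfg.n_frames), sigma=3.0)
        amp_t = np.abs(amp_t)
        amp_t = amp_t / max(amp_t.max(), 1e-12) * cfg.deform_amp_px
        y_axis = np.arange(h)
        for t in range(cfg.n_frames):
            deform_profile[t] = amp_t[t] * np.sin(2 * np.pi * y_axis / cfg.deform_wavelength_px + phase)

    bleach = np.exp(-cfg.bleach_rate * np.arange(cfg.n_frames) / max(cfg.n_frames - 1, 1))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    data = np.empty((cfg.n_frames, h, w), dtype=np.float32)
    rerender = cfg.vein_width_schedule is not None
    scene_vessels = vessels
    for t in range(cfg.n_frames):
        if rerender and (t == 0 or base_widths[t] != base_widths[t - 1]):
            r2 = np.random.default_rng(cfg.seed)
            r2.bit_generator.state = vessel_rng_state
            scene_vessels, _, _ = _vessel_layer((sh, sw), cfg, r2, base_widths[t])
        scene_t = cfg.tissue_level + texture - scene_vessels
        scene_t = scene_t + np.tensordot(traces[t], footprints, axes=(0, 0))
        dx, dy = shifts[t]
        u = deform_profile[t][:, None]
        src_y = yy + margin - dy - u
        src_x = xx + margin - dx
        frame = ndi.map_coordinates(scene_t, [src_y, src_x], order=1, mode="nearest")
        if cfg.occluder_opacity > 0:
            ovy, ovx = cfg.occluder_velocity_px
            occ_t = ndi.shift(occ_mask, (ovy * t, ovx * t), order=1, mode="grid-wrap")
            occ_t = occ_t[margin : margin + h, margin : margin + w]
            alpha = cfg.occluder_opacity * occ_t
            frame = (1 - alpha) * frame + alpha * cfg.occluder_level
        frame = frame * bleach[t]
        if cfg.photon_scale > 0:
            frame = rng.poisson(np.clip(frame, 0, None) * cfg.photon_scale) / cfg.photon_scale
        if cfg.read_noise_sigma > 0:
            frame = frame + rng.standard_normal((h, w)) * cfg.read_noise_sigma
        data[t] = frame

    # crop footprints/centers/features back to frame coordinates
    fp_crop = footprints[:, margin : margin + h, margin : margin + w]
    centers_frame = centers - margin
    features_frame = {k: (x - margin, y - margin) for k, (x, y) in features_scene.items()}
    gt = GroundTruth(
        shifts=shifts,
        deform_profile_rc=deform_profile,
        cell_centers=centers_frame,
        cell_traces=traces,
        cell_footprints=fp_crop,
        vessel_width_px=base_widths,
        bleach_trend=bleach,
        feature_points=features_frame,
        frame_shape=(h, w),
    )
    movie = MovieTensor(data, frame_rate=cfg.frame_rate, pixel_size=cfg.pixel_size)
    return movie, gt


# ----------------------------------------------------------------------


def make_feature_table(
    ground_truth: GroundTruth,
    likelihood_noise: float = 0.0,
    dropout: float = 0.0,
    jitter_sigma_px: float = 0.0,
    n_frames: Optional[int] = None,
    outlier_fraction: float = 0.0,
    outlier_px: float = 150.0,
    clean_frames: Tuple[int, ...] = (0,),
    seed: int = 0,
):
    """Feature tracks from the ground truth, with controllable defects.

    ``jitter_sigma_px`` adds Gaussian localization error;
    ``dropout`` drops a record with that probability (its likelihood
    falls below the 0.99 gate); ``outlier_fraction`` replaces records
    with gross mislocalizations (>= ``outlier_px`` away) that keep high
    likelihood — the failure mode the consensus fit must reject.
    ``clean_frames`` (default: the first frame) are exempt from dropout
    and outliers: they model the manually annotated reference frames a
    tracker is trained on.
    """
    from cordmotion.ldmcm import FeatureTrackTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    t_total = ground_truth.shifts.shape[0] if n_frames is None else n_frames
    rows = []
    for t in range(t_total):
        for name, (x, y) in ground_truth.feature_positions(t).items():
            px = x + rng.standard_normal() * jitter_sigma_px
            py = y + rng.standard_normal() * jitter_sigma_px
            lk = 1.0 if likelihood_noise == 0 else float(np.clip(1.0 - abs(rng.standard_normal()) * likelihood_noise, 0, 1))
            if t in clean_frames:
                pass
            elif dropout > 0 and rng.random() < dropout:
                lk = float(rng.uniform(0.0, 0.5))
            elif outlier_fraction > 0 and rng.random() < outlier_fraction:
                ang = rng.uniform(0, 2 * np.pi)
                radius = outlier_px * rng.uniform(1.0, 1.5)
                px += radius * np.cos(ang)
                py += radius * np.sin(ang)
            rows.append((name, t, px, py, lk))
    return FeatureTrackTable(
        pd.DataFrame(rows, columns=["feature_id", "frame", "x", "y", "likelihood"])
    )


def make_encoder_trace(
    speed_profile_cm_s: np.ndarray,
    frame_rate: float = 2000.0,
    wheel_radius_cm: float = 6.6,
    pulses_per_rev: int = 600,
) -> EncoderTrace:
    """Quadrature pulse channels reproducing a signed speed profile.

    Distance is integrated per sample and emitted as single-sample
    pulses (channel A for forward/CW, channel B for reverse/CCW),
    carrying the sub-pulse remainder, so decoding recovers the profile
    within one-pulse quantization.  The sample rate must satisfy
    ``rate >= |v| / Cp`` or pulses saturate at one per sample.
    """
    v = np.asarray(speed_profile_cm_s, dtype=float)
    cp = encoder_conversion_factor(wheel_radius_cm, pulses_per_rev)
    n = v.size
    a = np.zeros(n, dtype=int)
    b = np.zeros(n, dtype=int)
    carry = 0.0
    for i in range(n):
        carry += abs(v[i]) / frame_rate / cp
        if carry >= 1.0:
            if v[i] >= 0:
                a[i] = 1
            else:
                b[i] = 1
            carry -= 1.0
    return EncoderTrace(a, b, frame_rate, wheel_radius_cm, pulses_per_rev)
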