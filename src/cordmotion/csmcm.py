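"""CS-MCM: cross-session alignment and cell matching.

Fields of view recorded days to years apart drift, rotate, and change
appearance (vessel remodeling, brightness changes, different cameras).
CS-MCM pads all sessions to a common shape, removes large shifts with
user-supplied offsets or landmark tracks, runs a two-stage constrained
affine on per-session mean frames (translation+scale first, then with
rotation, never skew), and optionally refines the concatenated movie
against a single reference frame.  Cells extracted per session are then
matched across sessions by centroid distance and footprint shape
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from cordmotion.movie import MovieTensor
from cordmotion.registration import estimate_affine, estimate_rigid_from_points, estimate_translation
from cordmotion.transforms import Transform2D, warp

__all__ = [
    "Session",
    "CellMap",
    "pad_to_common_shape",
    "align_sessions",
    "refine_concatenated",
    "session_quality",
    "match_cells_across_sessions",
]


@dataclass
class Session:
    """One imaging session: a movie or mean frame plus declared geometry."""

    session_id: str
    frame: np.ndarray  # mean frame (2-D)
    movie: Optional[MovieTensor] = None
    camera_id: Optional[str] = None
    rotation_90: int = 0  # clockwise quarter-turns declared per camera
    flip_lr: bool = False

    def oriented_frame(self) -> np.ndarray:
        out = np.rot90(self.frame, -self.rotation_90)
        return out[:, ::-1] if self.flip_lr else out


@dataclass
class CellMap:
    """Per-session cell footprints from an external extraction tool."""

    session_id: str
    footprints: np.ndarray  # (n_cells, Y, X), non-negative
    cell_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.footprints = np.asarray(self.footprints, dtype=float)
        if self.footprints.ndim != 3:
            raise ValueError("footprints must be (n_cells, Y, X)")
        if (self.footprints < 0).any():
            raise ValueError("footprints must be non-negative")
        if self.cell_ids is None:
            self.cell_ids = [str(i) for i in range(self.footprints.shape[0])]

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) intensity-weighted centroids."""
        n, h, w = self.footprints.shape
        yy, xx = np.mgrid[0:h, 0:w]
        mass = self.footprints.sum(axis=(1, 2))
        cx = (self.footprints * xx).sum(axis=(1, 2)) / mass
        cy = (self.footprints * yy).sum(axis=(1, 2)) / mass
        return np.column_stack([cx, cy])


def pad_to_common_shape(frames: Sequence[np.ndarray]) -> List[np.ndarray]:
    """Pad every frame (with NaN) to the largest Y/X among the sessions.

    NaN rather than literal zero, so correlations and registration
    ignore the pads.
    """
    h = max(f.shape[0] for f in frames)
    w = max(f.shape[1] for f in frames)
    out = []
    for f in frames:
        pad = np.full((h, w), np.nan)
        pad[: f.shape[0], : f.shape[1]] = f
        out.append(pad)
    return out


def _init_transform(
    init, ref_frame: np.ndarray, mov_frame: np.ndarray
) -> Transform2D:
    """Initial large-shift correction: offsets, landmark tracks, or auto."""
    if init is None:
        return estimate_translation(mov_frame, ref_frame)
    if isinstance(init, Transform2D):
        return init
    if isinstance(init, (tuple, list)) and len(init) == 2 and np.isscalar(init[0]):
        return Transform2D.translation(float(init[0]), float(init[1]))
    # (ref_pts, mov_pts) landmark pairs from per-session mean-frame tracking
    ref_pts, mov_pts = init
    return estimate_rigid_from_points(np.asarray(ref_pts), np.asarray(mov_pts))


def align_sessions(
    sessions: Sequence[Session],
    reference_session: int = 0,
    init: Optional[Dict[str, object]] = None,
    smoothing_px: float = 30.0,
    pyramid_levels: int = 6,
) -> Dict[str, Transform2D]:
    """Two-stage constrained affine alignment of session mean frames.

    Each session's declared rotation/flip is applied, frames are padded
    to a common shape, an initial shift is removed (user offsets,
    landmark pairs, or phase correlation), then affine without rotation
    or skew followed by affine with rotation and no skew refines the
    fit.  Returns the composed transform per session mapping it onto the
    reference; the reference maps to identity.
    """
    frames = pad_to_common_shape([s.oriented_frame() for s in sessions])
    ref = frames[reference_session]
    out: Dict[str, Transform2D] = {}
    for i, sess in enumerate(sessions):
        if i == reference_session:
            out[sess.session_id] = Transform2D.identity("affine")
            continue
        mov = frames[i]
        t0 = _init_transform((init or {}).get(sess.session_id), ref, mov)
        mov1 = warp(mov, t0)
        a1 = estimate_affine(
            mov1, ref, allow_rotation=False,
            pyramid_levels=pyramid_levels, smoothing_px=smoothing_px,
        )
        mov2 = warp(mov1, a1)
        a2 = estimate_affine(
            mov2, ref, allow_rotation=True,
            pyramid_levels=pyramid_levels, smoothing_px=smoothing_px,
        )
        composed = a2.compose(a1).compose(t0)
        aligned = warp(mov, composed)
        if not np.isfinite(aligned).any():
            composed.flags["no_overlap"] = True
        out[sess.session_id] = composed
    return out


def refine_concatenated(
    aligned_movies: Sequence[MovieTensor],
    reference_frame: int = 0,
    max_frames: int = 20000,
) -> Tuple[MovieTensor, List[Transform2D]]:
    """Concatenate pre-aligned session movies and re-register every frame.

    All frames of the X x Y x (T*N) concatenated tensor are registered
    (translation) to the single reference frame, removing residual
    inter-session jitter.  Refuses movies above ``max_frames`` — stream
    session by session instead.
    """
    frames = [m.astype_float().data for m in aligned_movies]
    shape = frames[0].shape[1:]
    if any(f.shape[1:] != shape for f in frames):
        raise ValueError("sessions must be pre-aligned to a common shape")
    data = np.concatenate(frames, axis=0)
    if data.shape[0] > max_frames:
        raise MemoryError(
            f"{data.shape[0]} frames exceeds the in-memory limit ({max_frames}); "
            "process sessions in batches"
        )
    if not 0 <= reference_frame < data.shape[0]:
        raise ValueError("reference frame index out of range")
    ref = data[reference_frame]
    out = np.empty_like(data)
    transforms = []
    for t in range(data.shape[0]):
        try:
            tr = estimate_translation(data[t], ref)
        except ValueError:
            tr = Transform2D.translation(0.0, 0.0)
        tr.frame_index = t
        transforms.append(tr)
        out[t] = warp(data[t], tr)
    first = aligned_movies[0]
    return MovieTensor(out, frame_rate=first.frame_rate, pixel_size=first.pixel_size,
                       rc_axis=first.rc_axis), transforms


def session_quality(
    aligned_frames: Sequence[np.ndarray],
    reference: np.ndarray,
    vessel_enhance: bool = False,
) -> pd.DataFrame:
    """Pearson and Spearman correlation of each session frame to the reference.

    With ``vessel_enhance`` the correlation is computed on
    Frangi-filtered frames, a representation less influenced by
    baseline-brightness changes across sessions.  Constant frames yield
    NaN correlations.
    """
    from cordmotion.vessels import frangi_vesselness

    def enhance(frame: np.ndarray) -> np.ndarray:
        frame = np.where(np.isfinite(frame), frame, np.nanmean(frame))
        lo, hi = frame.min(), frame.max()
        if hi > lo:  # min-max first: exact invariance to gain/offset drift
            frame = (frame - lo) / (hi - lo) * 150.0
        return frangi_vesselness(frame)

    ref = np.asarray(reference, dtype=float)
    if vessel_enhance:
        ref = enhance(ref)
    rows = []
    for i, frame in enumerate(aligned_frames):
        frame = np.asarray(frame, dtype=float)
        if vessel_enhance:
            frame = enhance(frame)
        valid = np.isfinite(frame) & np.isfinite(ref)
        a, b = frame[valid], ref[valid]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            pear = spear = np.nan
        else:
            pear = float(np.corrcoef(a, b)[0, 1])
            spear = float(stats.spearmanr(a, b).statistic)
        rows.append({"session": i, "pearson": pear, "spearman": spear})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Cross-session cell identification
# ----------------------------------------------------------------------


def _shape_correlation(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    a = fp_a.ravel()
    b = fp_b.ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_cells_across_sessions(
    cell_maps: Sequence[CellMap],
    session_transforms: Optional[Dict[str, Transform2D]] = None,
    centroid_max_px: float = 5.0,
    min_shape_corr: float = 0.6,
    rounds: int = 1,
) -> pd.DataFrame:
    """Assign global cell IDs across sessions.

    Footprints are first warped into reference coordinates using the
    session transforms from :func:`align_sessions`.  The first session
    seeds the global registry; each subsequent session's cells are
    matched greedily by ascending centroid distance, gated at
    ``centroid_max_px`` (5 or 15 px in practice) and footprint
    correlation ``> min_shape_corr`` (0.6).  Additional ``rounds``
    re-center registry centroids on the mean of their matches and
    re-match.  Unmatched cells receive singleton global IDs.

    Returns a table (global_id, session_id, local_cell_id, centroid_x,
    centroid_y, shape_corr).
    """
    warped: List[CellMap] = []
    for cm in cell_maps:
        tf = (session_transforms or {}).get(cm.session_id)
        if tf is None:
            warped.append(cm)
        else:
            fps = np.stack(
                [np.nan_to_num(warp(fp, tf), nan=0.0) for fp in cm.footprints]
            ) if cm.footprints.shape[0] else cm.footprints
            warped.append(CellMap(cm.session_id, fps, cm.cell_ids))

    registry_centroids: List[np.ndarray] = []
    registry_fp: List[np.ndarray] = []
    assignments: List[Tuple[int, str, str, float, float, float]] = []

    def run_pass(seed_centroids, seed_fp):
        centroids = [np.asarray(c) for c in seed_centroids]
        fps = list(seed_fp)
        members: Dict[int, List[np.ndarray]] = {i: [] for i in range(len(centroids))}
        out: List[Tuple[int, str, str, float, float, float]] = []
        for cm in warped:
            n_cells = cm.footprints.shape[0]
            cents = cm.centroids() if n_cells else np.empty((0, 2))
            taken: set = set()
            matched_local: set = set()
            if centroids and n_cells:
                reg = np.asarray(centroids)
                d = np.hypot(*(cents[:, None, :] - reg[None, :, :]).transpose(2, 0, 1))
                for flat in np.argsort(d, axis=None):
                    li, gi = np.unravel_index(flat, d.shape)
                    if d[li, gi] > centroid_max_px:
                        break
                    if li in matched_local or gi in taken:
                        continue
                    sc = _shape_correlation(cm.footprints[li], fps[gi])
                    if sc <= min_shape_corr:
                        continue
                    matched_local.add(li)
                    taken.add(int(gi))
                    members[int(gi)].append(cents[li])
                    out.append(
                        (int(gi), cm.session_id, cm.cell_ids[li], cents[li][0], cents[li][1], sc)
                    )
            for li in range(n_cells):
                if li not in matched_local:
                    gid = len(centroids)
                    centroids.append(cents[li])
                    fps.append(cm.footprints[li])
                    members[gid] = [cents[li]]
                    out.append(
                        (gid, cm.session_id, cm.cell_ids[li], cents[li][0], cents[li][1], 1.0)
                    )
        return out, centroids, fps, members

    seeds: Tuple[list, list] = ([], [])
    for _ in range(max(rounds, 1)):
        assignments, cents, fps, members = run_pass(*seeds)
        # Re-center each global cell on the mean centroid of its matches,
        # tightening the distance gate for the next round.
        recentered = [
            np.mean(members[g], axis=0) if members.get(g) else cents[g]
            for g in range(len(cents))
        ]
        seeds = (recentered, fps)
    return pd.DataFrame(
        assignments,
        columns=["global_id", "session_id", "local_cell_id", "centroid_x", "centroid_y", "shape_corr"],
    )
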