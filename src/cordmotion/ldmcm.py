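"""LD-MCM: large-displacement motion correction from tracked landmarks.

Awake spinal cord movies show rostrocaudal shifts of hundreds of pixels
and occluding structures (neovascularization, adhesive bubbles, dust)
that move independently of the cord, defeating intensity-based
registration.  LD-MCM instead tracks stable vascular landmarks (dorsal
vein, ascending venules) with any point tracker that reports per-frame
(x, y, likelihood) — deep-learning pose estimators in practice, a
normalized-cross-correlation template tracker here — and treats the
tracks as control points for a per-frame robust rigid transform.

Pipeline: track ingestion -> likelihood gating -> feature-correlation QC
-> consensus rigid fit per frame (1,000 trials, 20 px inlier gate) ->
linear-interpolation warp -> residual translation pass on a stable
subregion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from cordmotion.movie import MovieTensor
from cordmotion.registration import estimate_rigid_from_points, estimate_translation
from cordmotion.transforms import Transform2D, warp

__all__ = [
    "FeatureTrackTable",
    "FeatureQCReport",
    "LdMcmConfig",
    "read_feature_table",
    "write_feature_table",
    "track_features_ncc",
    "filter_by_likelihood",
    "qc_features",
    "run_ld_mcm",
]

_COLUMNS = ["feature_id", "frame", "x", "y", "likelihood"]


@dataclass
class FeatureTrackTable:
    """Long-form per-feature, per-frame (x, y, likelihood) records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        lk = self.records["likelihood"]
        if ((lk < 0) | (lk > 1)).any():
            raise ValueError("likelihood must lie in [0, 1]")
        if self.records.duplicated(["feature_id", "frame"]).any():
            raise ValueError("duplicate (feature, frame) records")
        self.records = self.records[_COLUMNS].reset_index(drop=True)

    @property
    def feature_ids(self) -> List[str]:
        return list(dict.fromkeys(self.records["feature_id"]))

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.records["frame"].to_numpy())

    def points_at(self, frame: int) -> pd.DataFrame:
        return self.records[self.records["frame"] == frame]

    def positions(self, feature_id: str) -> pd.DataFrame:
        return self.records[self.records["feature_id"] == feature_id].sort_values("frame")


@dataclass
class FeatureQCReport:
    """Pairwise displacement-correlation QC of tracked features.

    ``correlation`` is the Spearman correlation matrix between the
    features' per-frame rostrocaudal displacement series; features whose
    mean correlation to all others falls below threshold were likely
    mislabeled on some sessions (vessel shrank or vanished) and are
    dropped.
    """

    feature_ids: List[str]
    correlation: np.ndarray
    mean_correlation: Dict[str, float]
    kept: List[str]
    dropped: List[str]
    inlier_counts: Optional[np.ndarray] = None


@dataclass
class LdMcmConfig:
    min_likelihood: float = 0.99
    trials: int = 1000
    inlier_px: float = 20.0
    seed: int = 0
    min_inliers: int = 2
    #: FOV motion is shared by all true landmarks, so a consensus
    #: covering less than this fraction of the frame's gated features
    #: is treated as a tracking failure, not a valid fit
    min_inlier_fraction: float = 0.5
    residual_pass: bool = True
    residual_region: Optional[Tuple[slice, slice]] = None
    residual_max_px: float = 5.0
    qc_min_mean_correlation: Optional[float] = None


# ----------------------------------------------------------------------
# Pose-estimation CSV dialect: 3 header rows (scorer / bodyparts /
# coords) and x, y, likelihood triplets per feature.
# ----------------------------------------------------------------------


def read_feature_table(path: Union[str, Path]) -> FeatureTrackTable:
    """Read tracks from a pose-estimation CSV (3-row header dialect)."""
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed 3-row-header CSV: {path}") from exc
    if df.columns.nlevels != 3:
        raise ValueError("expected 3 header rows: scorer / bodyparts / coords")
    rows = []
    bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y", "likelihood"):
            if coord not in sub.columns:
                raise ValueError(f"feature {bp!r} missing {coord!r} column")
        vals = sub[["x", "y", "likelihood"]].apply(pd.to_numeric, errors="raise")
        for frame, (x, y, lk) in zip(range(len(vals)), vals.to_numpy()):
            rows.append((bp, frame, float(x), float(y), float(lk)))
    return FeatureTrackTable(pd.DataFrame(rows, columns=_COLUMNS))


def write_feature_table(
    table: FeatureTrackTable, path: Union[str, Path], scorer: str = "cordmotion"
) -> Path:
    """Write tracks in the same 3-row-header CSV dialect (round-trips)."""
    frames = table.frames
    cols = {}
    for fid in table.feature_ids:
        pos = table.positions(fid).set_index("frame").reindex(frames)
        cols[(scorer, fid, "x")] = pos["x"].to_numpy()
        cols[(scorer, fid, "y")] = pos["y"].to_numpy()
        cols[(scorer, fid, "likelihood")] = pos["likelihood"].to_numpy()
    wide = pd.DataFrame(cols, index=frames)
    wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["scorer", "bodyparts", "coords"])
    wide.to_csv(path)
    return Path(path)


# ----------------------------------------------------------------------


def track_features_ncc(
    movie: MovieTensor,
    templates: Dict[str, Tuple[float, float]],
    reference_frame: int = 0,
    template_radius: int = 8,
    search_radius: int = 150,
) -> FeatureTrackTable:
    """Template tracker: NCC peak within a search window per feature.

    ``templates`` maps feature names to (x, y) positions annotated on
    the reference frame; a patch of ``template_radius`` around each is
    matched per frame by normalized cross-correlation, the peak NCC
    (clipped to [0, 1]) doubling as the likelihood.  Any tracker with
    this output contract can replace it — LD-MCM is agnostic to how the
    landmarks are found.
    """
    from skimage.feature import match_template

    data = movie.astype_float().data
    data = np.where(np.isnan(data), np.nanmean(data), data)
    ref = data[reference_frame]
    r = template_radius
    patches = {}
    for name, (x, y) in templates.items():
        xi, yi = int(round(x)), int(round(y))
        if not (r <= yi < ref.shape[0] - r and r <= xi < ref.shape[1] - r):
            raise ValueError(f"template {name!r} too close to the border")
        patches[name] = ref[yi - r : yi + r + 1, xi - r : xi + r + 1]
        if patches[name].shape[0] > ref.shape[0] or patches[name].shape[1] > ref.shape[1]:
            raise ValueError("template larger than frame")

    rows = []
    for t in range(data.shape[0]):
        frame = data[t]
        for name, (x0, y0) in templates.items():
            xi, yi = int(round(x0)), int(round(y0))
            y_lo = max(yi - search_radius - r, 0)
            y_hi = min(yi + search_radius + r + 1, frame.shape[0])
            x_lo = max(xi - search_radius - r, 0)
            x_hi = min(xi + search_radius + r + 1, frame.shape[1])
            window = frame[y_lo:y_hi, x_lo:x_hi]
            ncc = match_template(window, patches[name], pad_input=False)
            peak = np.unravel_index(np.argmax(ncc), ncc.shape)
            score = float(np.clip(ncc[peak], 0.0, 1.0))
            rows.append((name, t, x_lo + peak[1] + r, y_lo + peak[0] + r, score))
    return FeatureTrackTable(pd.DataFrame(rows, columns=_COLUMNS))


def filter_by_likelihood(table: FeatureTrackTable, min_likelihood: float = 0.99) -> FeatureTrackTable:
    """Drop records at or below the likelihood gate (per record, not per feature).

    Registration uses a strict gate (0.99); behavior analyses use a
    permissive one (0.1).  Frames left with no surviving record are
    listed in ``table.uncorrectable_frames`` downstream.
    """
    if not 0 <= min_likelihood <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if min_likelihood == 0:
        return FeatureTrackTable(table.records.copy())
    kept = table.records[table.records["likelihood"] > min_likelihood]
    return FeatureTrackTable(kept.copy())


def _rc_displacements(table: FeatureTrackTable, rc_axis: str = "y") -> pd.DataFrame:
    """Per-feature rostrocaudal displacement series (frame-indexed)."""
    coord = "y" if rc_axis == "y" else "x"
    wide = table.records.pivot(index="frame", columns="feature_id", values=coord)
    return wide - wide.mean(axis=0)


def qc_features(
    table: FeatureTrackTable,
    min_mean_correlation: float = 0.5,
    drop_list: Sequence[str] = (),
    rc_axis: str = "y",
) -> Tuple[FeatureTrackTable, FeatureQCReport]:
    """Drop features whose motion decorrelates from the ensemble.

    Large field-of-view motion is shared by all true landmarks, so each
    feature's per-frame rostrocaudal displacement should correlate with
    every other's.  A feature with low mean Spearman correlation is
    tracking something else (a vessel that shrank, an occluder) and is
    removed, improving the rigid fit.
    """
    ids = table.feature_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 features for meaningful correlation QC")
    disp = _rc_displacements(table, rc_axis)[ids]
    if disp.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    with np.errstate(invalid="ignore"):
        corr, _ = stats.spearmanr(disp.to_numpy(), nan_policy="omit")
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    mean_corr = {fid: float(np.nanmean(off[i])) for i, fid in enumerate(ids)}
    dropped = [
        fid for fid in ids
        if fid in drop_list or mean_corr[fid] < min_mean_correlation
    ]
    kept = [fid for fid in ids if fid not in dropped]
    filtered = FeatureTrackTable(
        table.records[table.records["feature_id"].isin(kept)].copy()
    )
    report = FeatureQCReport(ids, corr, mean_corr, kept, dropped)
    return filtered, report


# ----------------------------------------------------------------------


def estimate_frame_transforms(
    table: FeatureTrackTable,
    reference_frame: int,
    n_frames: int,
    config: LdMcmConfig,
) -> Tuple[List[Transform2D], np.ndarray]:
    """Per-frame consensus rigid transforms from gated feature tracks.

    Frames with fewer than ``min_inliers`` matched landmarks inherit the
    nearest corrected frame's transform and are flagged
    (``flags["interpolated"]``) so they are reported, never silently
    passed.
    """
    gated = filter_by_likelihood(table, config.min_likelihood)
    ref_pts_df = gated.points_at(reference_frame).set_index("feature_id")
    if len(ref_pts_df) < 2:
        raise ValueError("reference frame has fewer than 2 gated features")
    rng = np.random.default_rng(config.seed)

    transforms: List[Optional[Transform2D]] = [None] * n_frames
    inlier_counts = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        pts = gated.points_at(t).set_index("feature_id")
        common = [f for f in ref_pts_df.index if f in pts.index]
        if len(common) >= config.min_inliers:
            ref_xy = ref_pts_df.loc[common, ["x", "y"]].to_numpy()
            mov_xy = pts.loc[common, ["x", "y"]].to_numpy()
            try:
                tf = estimate_rigid_from_points(
                    ref_xy, mov_xy, trials=config.trials,
                    inlier_px=config.inlier_px, rng=rng,
                )
            except ValueError:
                tf = None
            needed = max(
                config.min_inliers,
                int(np.ceil(config.min_inlier_fraction * len(common))),
            )
            if tf is not None and tf.flags.get("n_inliers", 0) >= needed:
                tf.frame_index = t
                transforms[t] = tf
                inlier_counts[t] = tf.flags["n_inliers"]

    # Fill gaps from the nearest corrected frame, flagged.
    good = [t for t, tf in enumerate(transforms) if tf is not None]
    if not good:
        raise ValueError("no frame yielded a usable consensus transform")
    for t in range(n_frames):
        if transforms[t] is None:
            nearest = min(good, key=lambda g: abs(g - t))
            borrowed = transforms[nearest]
            tf = Transform2D(borrowed.kind, borrowed.matrix.copy(), t)
            tf.flags["interpolated"] = True
            transforms[t] = tf
    return transforms, inlier_counts  # type: ignore[return-value]


def _auto_residual_region(corrected: np.ndarray, size: int = 96) -> Tuple[slice, slice]:
    """Stable high-contrast patch of the corrected movie.

    The residual pass must avoid structures that move independently of
    the cord (occluders), so the score is spatial contrast of the mean
    frame divided by temporal variance, restricted to pixels valid in
    most frames.
    """
    import warnings

    from scipy.ndimage import uniform_filter

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_frame = np.nanmean(corrected, axis=0)
        temporal_var = np.nanvar(corrected, axis=0)
    valid_frac = np.isfinite(corrected).mean(axis=0)
    frame = np.where(np.isnan(mean_frame), np.nanmean(mean_frame), mean_frame)
    temporal_var = np.where(np.isnan(temporal_var), np.inf, temporal_var)
    h, w = frame.shape
    size = min(size, h, w)
    if size >= h and size >= w:
        return slice(0, h), slice(0, w)

    spatial_var = uniform_filter(frame**2, size) - uniform_filter(frame, size) ** 2
    score = spatial_var / (1.0 + uniform_filter(temporal_var, size))
    score[uniform_filter(valid_frac, size) < 0.9] = -np.inf
    half = size // 2
    sl_y = slice(half, max(h - half, half + 1))
    sl_x = slice(half, max(w - half, half + 1))
    interior = score[sl_y, sl_x]
    if not np.isfinite(interior).any():
        interior = spatial_var[sl_y, sl_x]
    iy, ix = np.unravel_index(np.argmax(interior), interior.shape)
    iy = min(iy, h - size)
    ix = min(ix, w - size)
    return slice(iy, iy + size), slice(ix, ix + size)


def run_ld_mcm(
    movie: MovieTensor,
    table: FeatureTrackTable,
    reference_frame: int = 0,
    config: Optional[LdMcmConfig] = None,
) -> Tuple[MovieTensor, List[Transform2D], FeatureQCReport]:
    """Full large-displacement correction of a movie.

    Per frame: gate tracks by likelihood, fit the consensus rigid
    transform to the reference frame's landmarks, warp with linear
    interpolation.  Then a residual translation pass (phase correlation
    against the reference frame) on a stable, high-contrast subregion
    mops up small frame-to-frame localization error.  Optionally a
    correlation QC pass removes misbehaving features first.
    """
    config = config or LdMcmConfig()
    n = movie.n_frames
    if not 0 <= reference_frame < n:
        raise ValueError("reference frame out of range")

    report = None
    if config.qc_min_mean_correlation is not None and len(table.feature_ids) >= 3:
        table, report = qc_features(table, config.qc_min_mean_correlation)
    transforms, inlier_counts = estimate_frame_transforms(table, reference_frame, n, config)
    if report is None:
        ids = table.feature_ids
        report = FeatureQCReport(ids, np.eye(len(ids)), {f: 1.0 for f in ids}, ids, [])
    report.inlier_counts = inlier_counts

    corrected = warp(movie, transforms)

    if config.residual_pass:
        region = config.residual_region
        if region is None:
            region = _auto_residual_region(corrected.data)
        from cordmotion.preprocess import normalize_frame_for_registration

        def _norm_patch(patch: np.ndarray) -> np.ndarray:
            return normalize_frame_for_registration(patch, complement=False)

        ref_patch = _norm_patch(corrected.data[reference_frame][region])
        data = corrected.data
        out = np.empty_like(data)
        for t in range(n):
            try:
                tr = estimate_translation(
                    _norm_patch(data[t][region]), ref_patch, upsample_factor=50
                )
            except ValueError:
                tr = Transform2D.translation(0.0, 0.0)
            # The point stage leaves sub-pixel error, so a large residual
            # estimate means the patch locked onto something else — except
            # on frames that inherited a neighbor's transform, where the
            # intensity pass is the actual correction.
            limit = (
                config.inlier_px
                if transforms[t].flags.get("interpolated")
                else config.residual_max_px
            )
            if np.hypot(tr.dx, tr.dy) > limit:
                tr = Transform2D.translation(0.0, 0.0)
            tr.frame_index = t
            out[t] = warp(data[t], tr)
            transforms[t] = tr.compose(transforms[t])
        corrected = corrected.with_data(out)
    return corrected, transforms, report
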