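"""Transform estimation: subpixel translation, constrained affine, and
robust rigid fits from control points.

These are the estimators shared by the three motion-correction tiers:
phase-correlation translation for residual rigid passes, a constrained
multi-resolution affine solver for cross-session alignment, and a
consensus-sampled (RANSAC) rigid fit from tracked landmarks for
large-displacement correction.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from skimage.registration import phase_cross_correlation

from cordmotion.transforms import Transform2D, warp

__all__ = ["estimate_translation", "estimate_affine", "estimate_rigid_from_points"]


def _fill_nan(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if np.isnan(frame).any():
        frame = np.where(np.isnan(frame), np.nanmean(frame), frame)
    return frame


def estimate_translation(
    moving: np.ndarray, fixed: np.ndarray, upsample_factor: int = 20
) -> Transform2D:
    """Subpixel translation aligning ``moving`` onto ``fixed``.

    Phase cross-correlation with Fourier upsampling.  The returned
    transform maps moving coordinates to fixed coordinates, i.e. warping
    ``moving`` by it maximizes correlation with ``fixed``.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError("frames must share a shape")
    mov_valid = np.isfinite(mov)
    fix_valid = np.isfinite(fix)
    if not (mov_valid.any() and fix_valid.any()):
        raise ValueError("all-missing frame")
    if np.nanstd(mov) == 0 or np.nanstd(fix) == 0:
        raise ValueError("constant frame: translation undefined")
    if mov_valid.all() and fix_valid.all():
        shift, _, _ = phase_cross_correlation(fix, mov, upsample_factor=upsample_factor)
    else:
        # Masked (Padfield) correlation: integer precision, but immune to
        # the sharp content/fill boundary a plain FFT correlation locks onto.
        shift = phase_cross_correlation(
            np.where(fix_valid, fix, 0.0), np.where(mov_valid, mov, 0.0),
            reference_mask=fix_valid, moving_mask=mov_valid,
        )[0]
    dy, dx = shift
    return Transform2D.translation(float(dx), float(dy))


# ----------------------------------------------------------------------
# Constrained affine, coarse-to-fine.
# ----------------------------------------------------------------------


def _params_to_matrix(p: np.ndarray, allow_rotation: bool, center: Tuple[float, float]) -> np.ndarray:
    """Parameter vector -> 2x3 matrix about the frame center.

    Without rotation: (tx, ty, sx, sy) — diagonal linear part.  With
    rotation: (tx, ty, sx, sy, theta) — rotation times axis scaling,
    never skew.
    """
    tx, ty, sx, sy = p[:4]
    lin = np.diag([sx, sy])
    if allow_rotation:
        th = p[4]
        c, s = np.cos(th), np.sin(th)
        lin = np.array([[c, -s], [s, c]]) @ lin
    cx, cy = center
    t = np.array([tx, ty]) + np.array([cx, cy]) - lin @ np.array([cx, cy])
    return np.column_stack([lin, t])


_BAD_COST = 1e12


def _smooth_masked(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that neither spreads nor invents NaN regions."""
    valid = np.isfinite(frame)
    if valid.all():
        return ndi.gaussian_filter(frame, sigma)
    num = ndi.gaussian_filter(np.where(valid, frame, 0.0), sigma)
    den = ndi.gaussian_filter(valid.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 0.3] = np.nan
    return out


def _halve_masked(frame: np.ndarray) -> np.ndarray:
    return _smooth_masked(frame, 1.0)[::2, ::2]


def _mse(moving: np.ndarray, fixed: np.ndarray, matrix: np.ndarray) -> float:
    out = warp(moving, Transform2D("affine", matrix))
    diff = out - fixed
    valid = np.isfinite(diff)
    n = valid.sum()
    if n < 0.25 * diff.size:
        # sloped penalty: less overlap costs more, steering back to support
        return _BAD_COST * (2.0 - n / diff.size)
    return float((diff[valid] ** 2).sum() / n)


def estimate_affine(
    moving: np.ndarray,
    fixed: np.ndarray,
    allow_rotation: bool = False,
    allow_skew: bool = False,
    pyramid_levels: int = 6,
    smoothing_px: float = 30.0,
    max_iter: int = 200,
) -> Transform2D:
    """Constrained affine (translation + per-axis scale, optional rotation).

    Multi-resolution inverse-mapping least squares: images are smoothed
    (Gaussian, sigma ``smoothing_px`` at the finest level, scaled with
    each pyramid level) and the constrained parameters minimized
    coarse-to-fine with a phase-correlation translation initializer.
    Skew is never estimated (``allow_skew`` is accepted for interface
    symmetry and must be False).
    """
    if allow_skew:
        raise NotImplementedError("skew estimation is intentionally unsupported")
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError("frames must share a shape")

    init = estimate_translation(mov, fix)
    n_params = 5 if allow_rotation else 4

    levels = []
    m, f = mov, fix
    for lev in range(pyramid_levels):
        levels.append((m, f, 2**lev))
        if min(m.shape) // 2 < 16 or lev == pyramid_levels - 1:
            break
        m = _halve_masked(m)
        f = _halve_masked(f)

    p = np.array([init.dx, init.dy, 1.0, 1.0, 0.0][:n_params])
    converged = True
    for m, f, factor in reversed(levels):
        # The pyramid supplies coarse-scale context; each level only needs
        # a mild blur.  smoothing_px sets the neighborhood at the original
        # scale; /16 maps it to a per-level Gaussian sigma (~2 px for 30).
        sigma = max(smoothing_px / 16.0, 0.75)
        ms = _smooth_masked(m, sigma)
        fs = _smooth_masked(f, sigma)
        center = ((m.shape[1] - 1) / 2.0, (m.shape[0] - 1) / 2.0)
        p_lvl = p.copy()
        p_lvl[0] /= factor
        p_lvl[1] /= factor

        def cost(q: np.ndarray) -> float:
            return _mse(ms, fs, _params_to_matrix(q, allow_rotation, center))

        # search window: modest refinement around the initializer — the
        # init pass has already removed gross shifts, and cross-session
        # scale/rotation changes are small (tissue growth, camera swap)
        span = max(m.shape) * 0.15
        bounds = [
            (p_lvl[0] - span, p_lvl[0] + span),
            (p_lvl[1] - span, p_lvl[1] + span),
            (0.8, 1.25),
            (0.8, 1.25),
        ]
        if allow_rotation:
            bounds.append((p_lvl[4] - 0.2, p_lvl[4] + 0.2))
        res = optimize.minimize(
            cost, p_lvl, method="Powell", bounds=bounds,
            options={"maxiter": max_iter, "xtol": 1e-4, "ftol": 1e-8},
        )
        converged = converged and bool(res.success)
        p = res.x.copy()
        p[0] *= factor
        p[1] *= factor

    center = ((mov.shape[1] - 1) / 2.0, (mov.shape[0] - 1) / 2.0)
    tf = Transform2D("affine", _params_to_matrix(p, allow_rotation, center))
    if not converged:
        tf.flags["converged"] = False
    return tf


# ----------------------------------------------------------------------
# Robust rigid fit from corresponding points.
# ----------------------------------------------------------------------


def _procrustes_rigid(mov: np.ndarray, ref: np.ndarray) -> Transform2D:
    """Least-squares rotation + translation (no scaling) mapping mov -> ref."""
    mc = mov.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mov - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    t = rc - r @ mc
    m = np.column_stack([r, t])
    return Transform2D("rigid", m)


def estimate_rigid_from_points(
    ref_pts: np.ndarray,
    mov_pts: np.ndarray,
    trials: int = 1000,
    inlier_px: float = 20.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Transform2D:
    """Consensus-sampled rigid transform from control-point pairs.

    Repeatedly (``trials`` times) fits a rigid transform to a random
    pair of correspondences, counts pairs whose post-transform residual
    is within ``inlier_px`` (20 px default), keeps the largest consensus
    set (ties broken by smaller inlier RMS), and refits on the inliers
    by 2-D Procrustes without scaling.  Rigid — not similarity, affine
    or projective — because large shifts must be removed while
    preserving image mass; residual non-rigid motion is handled
    downstream.

    The returned transform maps ``mov_pts`` onto ``ref_pts``.  Its
    ``flags`` record inlier count and indices.  Deterministic given
    ``seed`` (or an explicit ``rng``).
    """
    ref = np.asarray(ref_pts, dtype=float)
    mov = np.asarray(mov_pts, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("point sets must be matching (N, 2) arrays")
    n = ref.shape[0]
    if n < 2:
        raise ValueError("need at least 2 point pairs")
    if rng is None:
        rng = np.random.default_rng(seed)

    # Degenerate cloud: all moving points nearly coincident -> translation only.
    if np.ptp(mov, axis=0).max() < 1e-9:
        delta = (ref - mov).mean(axis=0)
        tf = Transform2D.translation(*delta)
        tf.flags.update(n_inliers=n, inliers=np.arange(n))
        return tf

    # Vectorized trials: a 2-point minimal sample determines the rigid
    # transform in closed form (segment angle for the rotation, midpoint
    # alignment for the translation).
    i_idx = rng.integers(0, n, size=trials)
    j_idx = rng.integers(0, n - 1, size=trials)
    j_idx = np.where(j_idx >= i_idx, j_idx + 1, j_idx)  # j != i, uniform
    dm = mov[j_idx] - mov[i_idx]
    dr = ref[j_idx] - ref[i_idx]
    ok = np.hypot(dm[:, 0], dm[:, 1]) > 1e-9
    ang = np.arctan2(dr[:, 1], dr[:, 0]) - np.arctan2(dm[:, 1], dm[:, 0])
    c, s = np.cos(ang), np.sin(ang)
    rot = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], 1)  # (T,2,2)
    mid_m = 0.5 * (mov[i_idx] + mov[j_idx])
    mid_r = 0.5 * (ref[i_idx] + ref[j_idx])
    t_vec = mid_r - np.einsum("tij,tj->ti", rot, mid_m)
    moved = np.einsum("tij,nj->tni", rot, mov) + t_vec[:, None, :]  # (T,N,2)
    resid = np.linalg.norm(moved - ref[None], axis=2)  # (T,N)
    inlier_mask = resid <= inlier_px
    counts = np.where(ok, inlier_mask.sum(axis=1), -1)
    if counts.max() < 2:
        raise ValueError("no consensus found among point pairs")
    # Truncated-quadratic (MSAC) score: a candidate only profits from a
    # point in proportion to how tightly it fits, so a tight consensus
    # beats a looser one that happens to absorb an extra gross outlier.
    score = np.minimum(resid, inlier_px) ** 2
    score = np.where(ok, score.sum(axis=1), np.inf)
    best_trial = int(np.argmin(score))
    best_inliers = inlier_mask[best_trial]
    # Iterated refit: refit on the consensus set, re-gate, repeat until
    # stable.  Then trim points whose residual is far outside the robust
    # scale of the set — the gate is generous (20 px), so a candidate can
    # absorb a gross mislocalization that would otherwise skew the fit.
    inliers = best_inliers
    for _ in range(5):
        tf = _procrustes_rigid(mov[inliers], ref[inliers])
        resid = np.hypot(*(tf.apply(mov) - ref).T)
        new = resid <= inlier_px
        if new.sum() < 2 or np.array_equal(new, inliers):
            break
        inliers = new
    r_in = resid[inliers]
    scale = 1.4826 * np.median(r_in)
    trim = resid <= max(3.0 * scale, 0.15 * inlier_px)
    if trim.sum() >= 2 and trim.sum() < inliers.sum():
        tf = _procrustes_rigid(mov[trim & inliers], ref[trim & inliers])
        resid = np.hypot(*(tf.apply(mov) - ref).T)
        inliers = resid <= inlier_px
    tf.flags.update(
        n_inliers=int(inliers.sum()),
        inliers=np.flatnonzero(inliers),
        inlier_rms=float(np.sqrt((resid[inliers] ** 2).mean())),
    )
    return tf
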