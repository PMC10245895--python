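"""Scalar quantification formulas: locomotion, sensory thresholds,
microglia asymmetry, stimulus response maps, bead profiles, and
cross-camera intensity normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from cordmotion.movie import MovieTensor

__all__ = [
    "EncoderTrace",
    "encoder_conversion_factor",
    "encoder_speed",
    "bodypart_speed",
    "sudo_threshold",
    "chaplan_updown",
    "load_k_table",
    "microglia_ratio",
    "stimulus_response_map",
    "bead_profile_normalize",
    "cross_camera_intensity_normalize",
]

#: forces (gram-force) of the von Frey filament series, numbered 1-9
VON_FREY_FORCES_GF = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0, 4.0)


@dataclass
class EncoderTrace:
    """Quadrature wheel-encoder samples: two binary channels A and B.

    A sample with A=1, B=0 is a clockwise pulse; B=1, A=0 a
    counterclockwise pulse.  ``pulses_per_rev`` (600) and
    ``wheel_radius_cm`` (6.6, wheel center to animal position) set the
    distance-per-pulse conversion.
    """

    a: np.ndarray
    b: np.ndarray
    frame_rate: float
    wheel_radius_cm: float = 6.6
    pulses_per_rev: int = 600

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        self.b = np.asarray(self.b)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("channels must be matching 1-D vectors")
        for ch in (self.a, self.b):
            if not np.isin(ch, (0, 1)).all():
                raise ValueError("encoder channels must be binary")
        if self.wheel_radius_cm <= 0 or self.frame_rate <= 0:
            raise ValueError("radius and frame rate must be positive")


def encoder_conversion_factor(radius_cm: float = 6.6, pulses_per_rev: int = 600) -> float:
    """Distance per encoder pulse: Cp = 2*pi*r / pulses_per_rev (cm)."""
    return 2.0 * np.pi * radius_cm / pulses_per_rev


def encoder_speed(trace: EncoderTrace) -> np.ndarray:
    """Locomotor speed (cm/s) decoded from the two encoder channels.

    Direction-resolved pulse detection::

        CW(t)  =  (A(t) > B(t))  >  (A(t+1) - A(t))
        CCW(t) = -[(B(t) > A(t)) >  (B(t+1) - B(t))]

    so an isolated A pulse counts clockwise, an isolated B pulse
    counterclockwise.  Total events v(t) = |CW + CCW| convert to cm/s
    via Cp * sample rate.  The first sample's speed is defined as 0.
    """
    a = trace.a.astype(int)
    b = trace.b.astype(int)
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    da = np.append(np.diff(a), 0)
    db = np.append(np.diff(b), 0)
    cw = ((a > b).astype(int) > da).astype(int)
    ccw = -(((b > a).astype(int) > db).astype(int))
    v = np.abs(cw + ccw).astype(float)
    v[0] = 0.0
    cp = encoder_conversion_factor(trace.wheel_radius_cm, trace.pulses_per_rev)
    return v * cp * trace.frame_rate


def decode_pulses(trace: EncoderTrace) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample CW and CCW pulse indicators (CW >= 0, CCW <= 0)."""
    a = trace.a.astype(int)
    b = trace.b.astype(int)
    da = np.append(np.diff(a), 0)
    db = np.append(np.diff(b), 0)
    cw = ((a > b).astype(int) > da).astype(int)
    ccw = -(((b > a).astype(int) > db).astype(int))
    return cw, ccw


def bodypart_speed(
    track: pd.DataFrame,
    fps: float,
    px_per_cm: float,
    min_likelihood: float = 0.1,
    smooth_window_s: Optional[float] = None,
) -> np.ndarray:
    """Body-part speed (cm/s) from a pose track.

    v(t) = dist(p(t), p(t-1)) / r with r the mean inter-frame interval;
    frames at or below the likelihood gate (0.1 by default) are excluded
    (NaN); the first frame's speed is set to zero.  An optional moving
    mean over ``smooth_window_s`` seconds (5 s / 100 frames at 20 Hz in
    practice) suppresses frame-to-frame tracking discrepancies while
    preserving the area under the curve.
    """
    if px_per_cm <= 0 or fps <= 0:
        raise ValueError("fps and px_per_cm must be positive")
    x = track["x"].to_numpy(dtype=float).copy()
    y = track["y"].to_numpy(dtype=float).copy()
    lk = track["likelihood"].to_numpy(dtype=float)
    bad = lk <= min_likelihood
    x[bad] = np.nan
    y[bad] = np.nan
    if np.isfinite(x).sum() < 2:
        raise ValueError("fewer than 2 valid frames")
    r = 1.0 / fps
    dist_px = np.hypot(np.diff(x), np.diff(y))
    speed = np.empty(x.size)
    speed[0] = 0.0
    speed[1:] = dist_px / r / px_per_cm
    if smooth_window_s:
        win = max(int(round(smooth_window_s * fps)), 1)
        kernel = np.ones(win)
        valid = np.isfinite(speed).astype(float)
        padded = np.where(np.isfinite(speed), speed, 0.0)
        num = np.convolve(padded, kernel, mode="same")
        den = np.convolve(valid, kernel, mode="same")
        with np.errstate(invalid="ignore"):
            speed = np.where(den > 0, num / den, np.nan)
    return speed


# ----------------------------------------------------------------------
# von Frey mechanical thresholds
# ----------------------------------------------------------------------


def sudo_threshold(final_filament: int, responded: bool) -> float:
    """Simplified up-down (SUDO) 50% paw-withdrawal threshold in gf.

    PWT = 10^(x*F' + B) with x = 0.24, B = -1.54 and F' the final
    filament number (1-9) adjusted by -0.5 if the animal responded to
    it, +0.5 if it did not.
    """
    if not 1 <= final_filament <= 9:
        raise ValueError("filament index must lie in 1..9")
    f_adj = final_filament + (-0.5 if responded else 0.5)
    return float(10.0 ** (0.24 * f_adj - 1.54))


def chaplan_updown(final_force_gf: float, k: float, d: float) -> float:
    """Classical up-down 50% threshold: T = 10^(log10(F) + k*D) (gf).

    ``F`` is the final filament force in gf, ``k`` the tabulated value
    for the observed response sequence (supply it, or look it up with
    :func:`load_k_table`), and ``D`` the mean log-force step between
    adjacent filaments in the series.
    """
    if final_force_gf <= 0:
        raise ValueError("force must be positive")
    if d <= 0:
        raise ValueError("step D must be positive")
    return float(10.0 ** (np.log10(final_force_gf) + k * d))


def load_k_table(path: Union[str, Path]) -> Dict[str, float]:
    """Read an up-down k lookup table from CSV.

    Expected columns: ``pattern`` (response sequence encoded as X =
    response, O = no response) and ``k``.  The classical table is
    published with the original up-down literature and is treated as
    user data; this package does not restate it.
    """
    df = pd.read_csv(path)
    if not {"pattern", "k"} <= set(df.columns):
        raise ValueError("k table needs 'pattern' and 'k' columns")
    return dict(zip(df["pattern"].astype(str), df["k"].astype(float)))


# ----------------------------------------------------------------------


def microglia_ratio(
    f_ipsi: np.ndarray,
    f_contra: np.ndarray,
    baseline_sessions: Optional[slice] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Ipsi/contra fluorescence asymmetry R = (Fi - Fc) / (Fi + Fc).

    R lies in [-1, 1] for non-negative inputs and is antisymmetric
    under side exchange.  With ``baseline_sessions`` the series is also
    returned normalized by subtracting the mean R over the baseline
    (pre-injury) sessions, removing per-animal baseline asymmetry.
    """
    fi = np.asarray(f_ipsi, dtype=float)
    fc = np.asarray(f_contra, dtype=float)
    if fi.shape != fc.shape:
        raise ValueError("side series must share a shape")
    total = fi + fc
    if np.any(total == 0):
        raise ValueError("zero total fluorescence")
    r = (fi - fc) / total
    if baseline_sessions is None:
        return r, None
    return r, r - np.nanmean(r[baseline_sessions])


def stimulus_response_map(
    dff_movie: MovieTensor,
    stim_frames: Sequence[int],
    window: Optional[int] = None,
    median_filter_size: int = 3,
    contour_thresholds: Sequence[float] = (),
) -> Tuple[np.ndarray, Dict[float, np.ndarray]]:
    """Post-stimulus mean projection and outermost activity contours.

    Averages the dF/F movie over a window after each stimulus (default
    3 s), median-filters the mean projection to suppress noise, and
    extracts for each threshold the outermost iso-contour — the one
    enclosing the largest area — which traces the edge of the bulk
    evoked activity.
    """
    data = dff_movie.astype_float().data
    n = data.shape[0]
    if window is None:
        window = max(int(round(3.0 * dff_movie.frame_rate)), 1)
    if window < 1:
        raise ValueError("window must be at least one frame")
    windows = []
    for s in stim_frames:
        if not 0 <= s < n:
            raise ValueError(f"stimulus frame {s} outside the movie")
        windows.append(data[s : min(s + window, n)])
    if not windows:
        raise ValueError("no stimulus frames given")
    projection = np.nanmean(np.concatenate(windows, axis=0), axis=0)
    projection = ndi.median_filter(projection, size=median_filter_size)

    from skimage import measure

    contours: Dict[float, np.ndarray] = {}
    for level in contour_thresholds:
        found = measure.find_contours(np.nan_to_num(projection), level)
        if not found:
            continue

        def enclosed_area(c: np.ndarray) -> float:
            y, x = c[:, 0], c[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

        contours[level] = max(found, key=enclosed_area)
    return projection, contours


def bead_profile_normalize(profile: np.ndarray) -> np.ndarray:
    """Min-max normalize an intensity profile to [0, 1] exactly."""
    profile = np.asarray(profile, dtype=float)
    lo, hi = np.nanmin(profile), np.nanmax(profile)
    if hi == lo:
        raise ValueError("constant profile cannot be normalized")
    return (profile - lo) / (hi - lo)


def cross_camera_intensity_normalize(
    session_intensities: Sequence[float], camera_ids: Sequence[str]
) -> np.ndarray:
    """Divide each session's intensity by its own camera's mean.

    Different cameras (and camera modes) have different gains; dividing
    every session by the mean intensity of all sessions acquired with
    the same camera puts the longitudinal curves on a common, unitless
    scale where each camera averages exactly 1.
    """
    vals = np.asarray(session_intensities, dtype=float)
    cams = np.asarray(camera_ids)
    if vals.shape != cams.shape:
        raise ValueError("one camera id per session")
    out = np.empty_like(vals)
    for cam in np.unique(cams):
        sel = cams == cam
        mean = vals[sel].mean()
        if mean == 0:
            raise ValueError(f"camera {cam!r} has zero mean intensity")
        out[sel] = vals[sel] / mean
    return out
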