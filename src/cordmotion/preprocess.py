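"""Per-frame preprocessing applied before and after registration.

The chain mirrors standard one-photon calcium-movie conditioning:
photobleaching detrend, spatial bandpass division (neuropil/background
suppression), frame normalization for intensity-based registration,
dF/F, motion borders, down-sampling, and 8-bit conversion for export to
feature trackers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from scipy import ndimage as ndi

from cordmotion.movie import MovieTensor

__all__ = [
    "PreprocessConfig",
    "detrend_movie",
    "spatial_bandpass_divide",
    "normalize_frame_for_registration",
    "compute_dff",
    "downsample",
    "convert_to_uint8",
    "pad_border",
]

#: denominators smaller than this (in absolute value) become missing
DIVISION_EPS = 1e-12


@dataclass
class PreprocessConfig:
    """Defaults for the whole preprocessing chain.

    ``bandpass_cutoff_cycles`` is in cycles per field of view (the
    low-pass band 0..cutoff is what each frame is divided by);
    ``pillbox_fraction`` sets the large-subtraction disk radius as a
    fraction of the smaller frame dimension; ``border_cap_px`` caps the
    post-registration border at 14 px regardless of measured motion.
    """

    detrend_order: int = 1
    bandpass_cutoff_cycles: float = 10.0
    pillbox_fraction: float = 0.1
    blur_disk_radius_px: int = 3
    dff_f0_mode: Literal["mean", "soft_min"] = "mean"
    soft_min_percentile: float = 0.1
    border_cap_px: int = 14
    spatial_ds: int = 1
    temporal_ds: int = 1
    clip_percentiles: Tuple[float, float] = (1.0, 99.99)

    def __post_init__(self) -> None:
        if self.detrend_order not in (1, 3):
            raise ValueError("detrend_order must be 1 or 3")
        if self.bandpass_cutoff_cycles <= 0 or self.pillbox_fraction <= 0:
            raise ValueError("cutoffs and radii must be positive")
        if self.blur_disk_radius_px <= 0:
            raise ValueError("blur radius must be positive")
        if not (0 < self.soft_min_percentile < 100):
            raise ValueError("percentile out of range")
        lo, hi = self.clip_percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("clip percentiles must satisfy 0 < lo < hi < 100")
        if self.spatial_ds not in (1, 2, 4) or self.temporal_ds not in (1, 4):
            raise ValueError("downsample factors limited to {1,2,4} / {1,4}")
        if self.border_cap_px < 0:
            raise ValueError("border cap must be >= 0")


# ----------------------------------------------------------------------


def detrend_movie(movie: MovieTensor, order: int = 1) -> MovieTensor:
    """Remove a slow photobleaching trend from the per-frame means.

    A polynomial of the given order (1 or 3) is fit to the sequence of
    per-frame mean intensities; the fitted value is subtracted from
    every pixel of the corresponding frame and the grand mean added
    back, so the movie keeps its original intensity range and never
    goes systematically negative.
    """
    if order not in (1, 3):
        raise ValueError("order must be 1 or 3")
    data = movie.astype_float().data
    t = data.shape[0]
    if t <= order:
        raise ValueError(f"need more than {order} frames to fit order-{order} trend")
    means = np.nanmean(data, axis=(1, 2))
    frames = np.arange(t, dtype=float)
    coeffs = np.polyfit(frames, means, order)
    fit = np.polyval(coeffs, frames)
    out = data - fit[:, None, None] + means.mean()
    return movie.with_data(out)


def _lowpass_mask(shape: Tuple[int, int], cutoff: float, edge: float = 2.0) -> np.ndarray:
    """Radially symmetric FFT low-pass, raised-cosine rolloff over `edge` cycles."""
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    r = np.hypot(fy[:, None], fx[None, :])  # cycles per FOV
    mask = np.zeros(shape)
    mask[r <= cutoff] = 1.0
    band = (r > cutoff) & (r < cutoff + edge)
    mask[band] = 0.5 * (1 + np.cos(np.pi * (r[band] - cutoff) / edge))
    return mask


def spatial_bandpass_divide(movie: MovieTensor, cutoff_cycles: float = 10.0) -> MovieTensor:
    """Divide each frame by its own low-pass (0..cutoff cycles) version.

    This flattens background fluctuations slower than ``cutoff_cycles``
    per field of view (neuropil, uneven illumination) while retaining
    high-frequency contrast; a spatially uniform frame maps to 1
    everywhere.  Frames must be strictly positive — shift the input
    first if necessary.  Near-zero low-pass denominators become NaN.
    """
    if cutoff_cycles < 1:
        raise ValueError("cutoff must be >= 1 cycle per FOV")
    data = movie.astype_float().data.astype(float, copy=True)
    mask = _lowpass_mask(data.shape[1:], cutoff_cycles)
    out = np.empty_like(data)
    for i, frame in enumerate(data):
        nan = np.isnan(frame)
        filled = np.where(nan, np.nanmean(frame), frame)
        low = np.fft.ifft2(np.fft.fft2(filled) * mask).real
        with np.errstate(divide="ignore", invalid="ignore"):
            res = np.where(np.abs(low) < DIVISION_EPS, np.nan, filled / low)
        res[nan] = np.nan
        out[i] = res
    return movie.with_data(out)


def _disk_kernel(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    k = (yy**2 + xx**2 <= radius**2).astype(float)
    return k / k.sum()


def _disk_convolve(frame: np.ndarray, radius: int) -> np.ndarray:
    """Disk-mean filter; FFT route for large kernels, edge-replicated."""
    kernel = _disk_kernel(radius)
    if radius <= 7:
        return ndi.convolve(frame, kernel, mode="nearest")
    from scipy.signal import fftconvolve

    padded = np.pad(frame, radius, mode="edge")
    out = fftconvolve(padded, kernel, mode="same")
    return out[radius:-radius, radius:-radius]


def normalize_frame_for_registration(
    frame: np.ndarray,
    pillbox_fraction: float = 0.1,
    blur_disk_radius: int = 3,
    complement: bool = True,
) -> np.ndarray:
    """Condition a frame for intensity-based registration.

    Steps: subtract the frame mean; subtract a pillbox-averaged (disk of
    radius one ``pillbox_fraction`` of the smaller dimension) version;
    smooth with a disk of radius ``blur_disk_radius``; optionally
    complement (max minus pixel), which turns dark vessels into the
    brightest structures — the landmarks registration locks onto.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 10:
        raise ValueError("frame must be 2-D and at least 10 x 10")
    radius = max(int(min(frame.shape) * pillbox_fraction), 1)
    nan = np.isnan(frame)
    if nan.all():
        raise ValueError("all-missing frame")
    filled = np.where(nan, np.nanmean(frame), frame)
    out = filled - filled.mean()
    out = out - _disk_convolve(out, radius)
    out = ndi.convolve(out, _disk_kernel(blur_disk_radius), mode="nearest")
    if complement:
        out = out.max() - out
    out[nan] = np.nan
    return out


def compute_dff(
    movie: MovieTensor,
    f0_mode: Literal["mean", "soft_min"] = "mean",
    percentile: float = 0.1,
) -> MovieTensor:
    """Relative fluorescence change (F - F0) / F0.

    F0 is the pixelwise temporal mean, or in ``soft_min`` mode the
    pixelwise low percentile (default bottom 0.1% of values over time),
    which tracks a quiescent baseline under sparse activity.  Pixels
    with non-positive F0 are marked missing.
    """
    data = movie.astype_float().data
    if np.nanmax(np.abs(data)) == 0:
        raise ValueError("all-zero movie has no baseline")
    if f0_mode == "mean":
        f0 = np.nanmean(data, axis=0)
    elif f0_mode == "soft_min":
        f0 = np.nanpercentile(data, percentile, axis=0)
    else:
        raise ValueError(f"unknown f0_mode {f0_mode!r}")
    f0 = np.where(f0 > DIVISION_EPS, f0, np.nan)
    return movie.with_data((data - f0[None]) / f0[None])


def downsample(movie: MovieTensor, spatial_factor: int = 1, temporal_factor: int = 1) -> MovieTensor:
    """Bilinear spatial and/or linear temporal down-sampling.

    Spatial factors 2 or 4 resample each frame on a grid of that pitch
    (bilinear); temporal factor 4 linearly interpolates each pixel's
    time series at T//4 points spanning the original endpoints.
    """
    if spatial_factor not in (1, 2, 4) or temporal_factor not in (1, 4):
        raise ValueError("factors limited to spatial {1,2,4}, temporal {1,4}")
    data = movie.astype_float().data.astype(float)
    t, y, x = data.shape
    if y < spatial_factor or x < spatial_factor or t < temporal_factor:
        raise ValueError("movie smaller than the requested factor")
    if spatial_factor > 1:
        from skimage.transform import resize

        ny, nx = y // spatial_factor, x // spatial_factor
        out = np.empty((data.shape[0], ny, nx))
        for i, frame in enumerate(data):
            out[i] = resize(frame, (ny, nx), order=1, anti_aliasing=False, mode="edge")
        data = out
    if temporal_factor > 1:
        nt = t // temporal_factor
        t_new = np.linspace(0, t - 1, nt)
        i0 = np.floor(t_new).astype(int)
        i1 = np.minimum(i0 + 1, t - 1)
        w = (t_new - i0)[:, None, None]
        data = data[i0] * (1 - w) + data[i1] * w
    new_rate = movie.frame_rate / temporal_factor
    new_px = movie.pixel_size * spatial_factor if movie.pixel_size else None
    out = movie.with_data(data)
    out.frame_rate = new_rate
    out.pixel_size = new_px
    return out


def convert_to_uint8(
    movie: MovieTensor, clip_percentiles: Tuple[float, float] = (1.0, 99.99)
) -> MovieTensor:
    """Convert to 8 bits for export to feature trackers.

    Soft min/max are the given percentiles of all pixel values (robust
    to outlier pixels); after min-max normalization the 8-bit values are
    shifted upward by 1% of the range — fully dark frames degrade
    feature-identification accuracy — via ``round(255*(0.01+0.99*M1))``.
    """
    lo_p, hi_p = clip_percentiles
    data = movie.astype_float().data
    lo = np.nanpercentile(data, lo_p)
    hi = np.nanpercentile(data, hi_p)
    if not hi > lo:
        raise ValueError("constant movie cannot be rescaled to 8 bits")
    m1 = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    mf = np.round(255.0 * (0.01 + 0.99 * m1))
    mf = np.where(np.isnan(data), 0, mf).astype(np.uint8)
    return movie.with_data(mf)


def pad_border(movie: MovieTensor, per_frame_max_motion: float, cap: int = 14) -> MovieTensor:
    """Mask a fixed border after registration.

    Differing per-frame motion leaves variable invalid margins; a fixed
    border of ``min(ceil(max motion), cap)`` pixels (cap 14 by default)
    is marked missing on every frame so all frames share one support.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    border = int(min(np.ceil(max(per_frame_max_motion, 0.0)), cap))
    data = movie.astype_float().data.astype(float, copy=True)
    if border > 0:
        data[:, :border, :] = np.nan
        data[:, -border:, :] = np.nan
        data[:, :, :border] = np.nan
        data[:, :, -border:] = np.nan
    return movie.with_data(data)
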