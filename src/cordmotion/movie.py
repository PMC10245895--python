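"""The in-memory movie container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["MovieTensor"]


@dataclass
class MovieTensor:
    """A T x Y x X fluorescence movie.

    Data are held as floating point internally regardless of the
    acquisition bit depth; invalid pixels (outside the warped support,
    behind borders, division guards) are marked NaN and are never
    extrapolated.

    Parameters
    ----------
    data:
        3-D array, frames first.
    frame_rate:
        Acquisition rate in Hz.
    pixel_size:
        Micrometres per pixel, if known.  Used only for unit conversion
        (e.g. vessel diameters in um).
    rc_axis:
        Which image axis is rostrocaudal: ``"y"`` (rows, default) or
        ``"x"`` (columns).  Spinal cord motion is rostrocaudal-dominant,
        so several operations treat this axis specially.
    """

    data: np.ndarray
    frame_rate: float = 30.0
    pixel_size: Optional[float] = None
    rc_axis: str = "y"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"movie data must be a 3-D (T, Y, X) array, got shape {self.data.shape}"
            )
        t, y, x = self.data.shape
        if t < 1 or y < 2 or x < 2:
            raise ValueError(f"movie too small: shape {self.data.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.rc_axis not in ("y", "x"):
            raise ValueError("rc_axis must be 'y' or 'x'")

    # -- convenience ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean T x Y x X mask of invalid (NaN) pixels."""
        return np.isnan(self.data)

    def astype_float(self) -> "MovieTensor":
        if np.issubdtype(self.data.dtype, np.floating):
            return self
        return self.with_data(self.data.astype(np.float32))

    def with_data(self, data: np.ndarray) -> "MovieTensor":
        """A copy of this movie's metadata around new pixel data."""
        return replace(self, data=data)

    def mean_frame(self, ignore_missing: bool = True) -> np.ndarray:
        if ignore_missing:
            return np.nanmean(self.data, axis=0)
        return self.data.mean(axis=0)
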