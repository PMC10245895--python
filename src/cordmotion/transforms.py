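"""2-D geometric transforms, displacement fields, and warping.

Conventions
-----------
* Points are ``(x, y)`` in pixel units, 0-based, x = columns.
* A :class:`Transform2D` maps moving-frame coordinates into fixed-frame
  coordinates: ``p_fixed = A @ p_moving + t``.
* ``warp`` resamples the moving image onto the fixed grid by inverse
  mapping with linear interpolation; pixels whose source falls outside
  the moving support (or touches a missing pixel) become NaN — the
  support is never extrapolated.
* A :class:`DisplacementField` stores per-pixel displacements on the
  fixed grid: the corrected image is ``moving(y + u_y, x + u_x)``.
  ``u_rc``/``u_ml`` name the rostrocaudal and mediolateral components
  according to the movie's ``rc_axis``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from cordmotion.movie import MovieTensor

__all__ = ["Transform2D", "DisplacementField", "warp", "save_transforms", "load_transforms"]


@dataclass
class Transform2D:
    """A translation, rigid, or affine 2-D transform.

    Internally always a 2x3 matrix ``[A | t]`` acting on ``(x, y)``
    column vectors.  ``kind`` records the constraint class the matrix
    was estimated under; a rigid transform's linear part is orthonormal
    with determinant +1.
    """

    kind: str  # translation | rigid | affine
    matrix: np.ndarray
    frame_index: Optional[int] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("transform matrix must be 2 x 3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite transform")
        if self.kind not in ("translation", "rigid", "affine"):
            raise ValueError(f"unknown transform kind {self.kind!r}")

    # -- constructors --------------------------------------------------
    @classmethod
    def identity(cls, kind: str = "rigid", frame_index: Optional[int] = None) -> "Transform2D":
        return cls(kind, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), frame_index)

    @classmethod
    def translation(cls, dx: float, dy: float, frame_index: Optional[int] = None) -> "Transform2D":
        return cls("translation", np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]]), frame_index)

    @classmethod
    def rigid(cls, dx: float, dy: float, theta: float, frame_index: Optional[int] = None) -> "Transform2D":
        c, s = np.cos(theta), np.sin(theta)
        return cls("rigid", np.array([[c, -s, dx], [s, c, dy]]), frame_index)

    @classmethod
    def affine(cls, matrix: np.ndarray, frame_index: Optional[int] = None) -> "Transform2D":
        return cls("affine", np.asarray(matrix, dtype=float), frame_index)

    # -- accessors -----------------------------------------------------
    @property
    def dx(self) -> float:
        return float(self.matrix[0, 2])

    @property
    def dy(self) -> float:
        return float(self.matrix[1, 2])

    @property
    def theta(self) -> float:
        """Rotation angle (rad) of the linear part (meaningful for rigid)."""
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    def as_homogeneous(self) -> np.ndarray:
        h = np.eye(3)
        h[:2] = self.matrix
        return h

    # -- algebra -------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` moving-frame (x, y) points to fixed-frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.matrix[:, 2]

    def compose(self, other: "Transform2D") -> "Transform2D":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        h = self.as_homogeneous() @ other.as_homogeneous()
        kind = "affine" if "affine" in (self.kind, other.kind) else (
            "translation" if self.kind == other.kind == "translation" else "rigid"
        )
        return Transform2D(kind, h[:2], self.frame_index)

    def invert(self) -> "Transform2D":
        h = np.linalg.inv(self.as_homogeneous())
        return Transform2D(self.kind, h[:2], self.frame_index)


@dataclass
class DisplacementField:
    """Per-pixel displacement (fixed grid -> moving frame sample points)."""

    u_rc: np.ndarray
    u_ml: np.ndarray
    frame_index: Optional[int] = None
    rc_axis: str = "y"

    def __post_init__(self) -> None:
        self.u_rc = np.asarray(self.u_rc, dtype=float)
        self.u_ml = np.asarray(self.u_ml, dtype=float)
        if self.u_rc.shape != self.u_ml.shape or self.u_rc.ndim != 2:
            raise ValueError("field components must be matching 2-D arrays")
        if not (np.all(np.isfinite(self.u_rc)) and np.all(np.isfinite(self.u_ml))):
            raise ValueError("non-finite displacement field")

    @property
    def u_y(self) -> np.ndarray:
        return self.u_rc if self.rc_axis == "y" else self.u_ml

    @property
    def u_x(self) -> np.ndarray:
        return self.u_ml if self.rc_axis == "y" else self.u_rc

    def constrain_axis(self) -> "DisplacementField":
        """Zero the mediolateral component exactly (idempotent).

        Spinal cord motion is rostrocaudal-dominant; registering with
        the mediolateral component removed avoids spurious lateral
        shifts, especially during bursts of neural activity.
        """
        return DisplacementField(
            self.u_rc.copy(), np.zeros_like(self.u_ml), self.frame_index, self.rc_axis
        )

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_rc, self.u_ml)


# ----------------------------------------------------------------------


def _warp_frame_transform(frame: np.ndarray, transform: Transform2D, order: int) -> np.ndarray:
    if np.array_equal(transform.matrix, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])):
        return np.asarray(frame, dtype=float).copy()
    inv = transform.invert().matrix
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]].astype(float)
    src_x = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
    src_y = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
    return ndi.map_coordinates(
        np.asarray(frame, dtype=float), [src_y, src_x], order=order,
        mode="constant", cval=np.nan,
    )


def _warp_frame_field(frame: np.ndarray, fld: DisplacementField, order: int) -> np.ndarray:
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]].astype(float)
    return ndi.map_coordinates(
        np.asarray(frame, dtype=float), [yy + fld.u_y, xx + fld.u_x], order=order,
        mode="constant", cval=np.nan,
    )


def warp(
    image: Union[np.ndarray, MovieTensor],
    transform: Union[Transform2D, DisplacementField, Sequence],
    interpolation: str = "linear",
) -> Union[np.ndarray, MovieTensor]:
    """Warp a frame or movie by a transform, a field, or one per frame.

    Linear interpolation by default ("nearest" also accepted).  NaNs in
    the input propagate to every output pixel whose interpolation stencil
    touches them, and out-of-support pixels are NaN.
    """
    order = {"linear": 1, "nearest": 0}[interpolation]

    def _one(frame: np.ndarray, tf) -> np.ndarray:
        if isinstance(tf, DisplacementField):
            return _warp_frame_field(frame, tf, order)
        return _warp_frame_transform(frame, tf, order)

    if isinstance(image, MovieTensor):
        data = image.astype_float().data
        if isinstance(transform, (Transform2D, DisplacementField)):
            per_frame: Sequence = [transform] * data.shape[0]
        else:
            per_frame = list(transform)
            if len(per_frame) != data.shape[0]:
                raise ValueError("need one transform per frame")
        out = np.empty(data.shape, dtype=float)
        for i in range(data.shape[0]):
            out[i] = _one(data[i], per_frame[i])
        return image.with_data(out)
    if not isinstance(transform, (Transform2D, DisplacementField)):
        raise TypeError("a bare frame takes a single transform or field")
    return _one(np.asarray(image), transform)


# ----------------------------------------------------------------------
# Serialization: one CSV row per frame transform.
# ----------------------------------------------------------------------


def save_transforms(transforms: Iterable[Transform2D], path: Union[str, Path]) -> Path:
    rows = []
    for i, t in enumerate(transforms):
        m = t.matrix
        rows.append(
            {
                "frame": t.frame_index if t.frame_index is not None else i,
                "kind": t.kind,
                "dx": t.dx, "dy": t.dy, "theta": t.theta,
                "a11": m[0, 0], "a12": m[0, 1], "a13": m[0, 2],
                "a21": m[1, 0], "a22": m[1, 1], "a23": m[1, 2],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def load_transforms(path: Union[str, Path]) -> List[Transform2D]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        m = np.array([[r.a11, r.a12, r.a13], [r.a21, r.a22, r.a23]])
        out.append(Transform2D(str(r["kind"]), m, int(r["frame"])))
    return out
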