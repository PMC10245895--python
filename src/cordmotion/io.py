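"""Movie I/O: multi-page TIFF, HDF5, and 8-bit AVI.

TIFF and HDF5 round-trip bit-exactly.  AVI export is deliberately lossy:
frames are converted to 8 bits (see
:func:`cordmotion.preprocess.convert_to_uint8`) because that is the
format pose-estimation trackers consume.  The AVI codepath writes and
reads uncompressed 8-bit grayscale RIFF/AVI (DIB frames); no third-party
codec is involved.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import tifffile

from cordmotion.movie import MovieTensor

__all__ = ["load_movie", "save_movie"]

_FORMATS = ("tiff", "hdf5", "avi")


def _infer_format(path: Union[str, Path], format: Optional[str]) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
        return format
    suffix = Path(path).suffix.lower()
    mapping = {
        ".tif": "tiff",
        ".tiff": "tiff",
        ".h5": "hdf5",
        ".hdf5": "hdf5",
        ".avi": "avi",
    }
    if suffix not in mapping:
        raise ValueError(f"cannot infer movie format from suffix {suffix!r}")
    return mapping[suffix]


def load_movie(
    path: Union[str, Path],
    format: Optional[str] = None,
    dataset: str = "/movie",
    frame_rate: float = 30.0,
    pixel_size: Optional[float] = None,
) -> MovieTensor:
    """Read a movie from disk into a :class:`MovieTensor`.

    ``format`` is inferred from the suffix when omitted.  A single-page
    TIFF or 2-D HDF5 dataset is rejected: movies are 3-D by contract
    (a one-frame movie is stored as shape ``(1, Y, X)``).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tiff":
        data = tifffile.imread(path)
        if data.ndim == 2:  # single page
            data = data[None]
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            obj = f[dataset]
            attrs = dict(obj.attrs)
            data = obj[()]
            frame_rate = float(attrs.get("frame_rate", frame_rate))
            if "pixel_size" in attrs and pixel_size is None:
                pixel_size = float(attrs["pixel_size"])
    else:
        data = _read_avi(path)
    if data.ndim != 3:
        raise ValueError(f"non-3-D array in {path}: shape {data.shape}")
    return MovieTensor(data, frame_rate=frame_rate, pixel_size=pixel_size)


def save_movie(
    movie: MovieTensor,
    path: Union[str, Path],
    format: Optional[str] = None,
    dataset: str = "/movie",
) -> Path:
    """Write a movie to disk; returns the path written.

    TIFF/HDF5 preserve dtype and values exactly.  AVI requires (or
    converts to) uint8 and drops NaN masks.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        # BigTIFF only when the payload would overflow classic TIFF.
        big = movie.data.nbytes > 2**32 - 2**25
        tifffile.imwrite(path, movie.data, bigtiff=big)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset(dataset, data=movie.data)
            dset.attrs["frame_rate"] = movie.frame_rate
            if movie.pixel_size is not None:
                dset.attrs["pixel_size"] = movie.pixel_size
    else:
        data = movie.data
        if data.dtype != np.uint8:
            from cordmotion.preprocess import convert_to_uint8

            data = convert_to_uint8(movie).data
        _write_avi(path, np.ascontiguousarray(data), fps=movie.frame_rate)
    return path


# ----------------------------------------------------------------------
# Minimal uncompressed 8-bit grayscale AVI (RIFF 'AVI ', DIB frames).
# Grayscale is stored as 8-bit palettized DIB with an identity palette;
# rows are bottom-up and padded to 4-byte boundaries, per the DIB spec.
# ----------------------------------------------------------------------


def _dib_frame(frame: np.ndarray, pad: int) -> bytes:
    rows = frame[::-1]  # bottom-up
    if pad:
        rows = np.pad(rows, ((0, 0), (0, pad)))
    return rows.tobytes()


def _write_avi(path: Path, data: np.ndarray, fps: float = 30.0) -> None:
    if data.dtype != np.uint8 or data.ndim != 3:
        raise ValueError("AVI writer expects a uint8 T x Y x X array")
    n, h, w = data.shape
    pad = (-w) % 4
    frame_bytes = (w + pad) * h
    usec_per_frame = int(round(1e6 / max(fps, 1e-6)))

    avih = struct.pack(
        "<14I", usec_per_frame, frame_bytes * int(round(fps)), 0, 0x10, n, 0, 1,
        frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, 1, int(round(fps)), 0, n,
        frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h,
    )
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    strf = bmih + palette

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        if len(payload) % 2:
            payload += b"\x00"
        return fourcc + struct.pack("<I", len(payload)) + payload

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"movi"
    index = []
    offset = 4  # relative to start of 'movi' fourcc
    for i in range(n):
        payload = _dib_frame(data[i], pad)
        movi_payload += chunk(b"00db", payload)
        index.append(struct.pack("<4sIII", b"00db", 0x10, offset, len(payload)))
        offset += 8 + len(payload) + (len(payload) % 2)
    movi = chunk(b"LIST", movi_payload)
    idx1 = chunk(b"idx1", b"".join(index))

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as f:
        f.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _read_avi(path: Path) -> np.ndarray:
    raw = Path(path).read_bytes()
    if raw[:4] != b"RIFF" or raw[8:12] != b"AVI ":
        raise ValueError(f"{path} is not an AVI file")

    frames = []
    w = h = None

    def parse(buf: bytes, start: int, end: int) -> None:
        nonlocal w, h
        pos = start
        while pos + 8 <= end:
            fourcc = buf[pos : pos + 4]
            (size,) = struct.unpack_from("<I", buf, pos + 4)
            body = pos + 8
            if fourcc == b"LIST":
                parse(buf, body + 4, body + size)
            elif fourcc == b"strf":
                bmih = struct.unpack_from("<IiiHHIIiiII", buf, body)
                w, h = bmih[1], abs(bmih[2])
                if bmih[4] != 8:
                    raise ValueError("only 8-bit grayscale AVI is supported")
            elif fourcc in (b"00db", b"00dc"):
                frames.append(buf[body : body + size])
            pos = body + size + (size % 2)

    parse(raw, 12, len(raw))
    if w is None or not frames:
        raise ValueError(f"no video frames found in {path}")
    pad = (-w) % 4
    stride = w + pad
    out = np.empty((len(frames), h, w), dtype=np.uint8)
    for i, payload in enumerate(frames):
        arr = np.frombuffer(payload[: stride * h], dtype=np.uint8).reshape(h, stride)
        out[i] = arr[::-1, :w]
    return out
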