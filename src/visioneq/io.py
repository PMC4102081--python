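"""Image readers and writers.

Grayscale images travel as PGM (P2 ascii / P5 binary, 8 or 16 bit), PNG
(8/16-bit gray) or a tiny raw-float raster for lossless round trips.
Integer formats are mapped to [0, 1] by dividing by the format maximum
(2^depth - 1); no gamma is applied or removed -- the flows operate on the
supplied code values, and the Naka-Rushton stage is the only nonlinearity
applied to radiance.  Radiance maps (kind="radiance") may hold values
above 1 and should use the raw-float format.

The raw float raster is: magic ``VQF1\\n``, one ascii line ``height width``,
then height*width little-endian float64 values, row-major.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "RAW_MAGIC"]

RAW_MAGIC = b"VQF1\n"


def _read_raw(path: Path) -> np.ndarray:
    blob = path.read_bytes()
    if not blob.startswith(RAW_MAGIC):
        raise ValueError(f"{path}: not a raw float raster (bad magic)")
    header_end = blob.index(b"\n", len(RAW_MAGIC))
    m = re.fullmatch(rb"(\d+) (\d+)", blob[len(RAW_MAGIC) : header_end])
    if not m:
        raise ValueError(f"{path}: malformed raw raster header")
    h, w = int(m.group(1)), int(m.group(2))
    data = np.frombuffer(blob, dtype="<f8", offset=header_end + 1)
    if data.size != h * w:
        raise ValueError(f"{path}: truncated raw raster ({data.size} of {h * w} values)")
    return data.reshape(h, w).copy()


def _write_raw(img: np.ndarray, path: Path) -> None:
    header = RAW_MAGIC + f"{img.shape[0]} {img.shape[1]}".encode() + b"\n"
    path.write_bytes(header + np.ascontiguousarray(img, dtype="<f8").tobytes())


def _read_pgm(path: Path) -> np.ndarray:
    blob = path.read_bytes()
    if blob[:2] not in (b"P2", b"P5"):
        raise ValueError(f"{path}: not a PGM file")
    # header tokens: magic, width, height, maxval; '#' comments allowed
    tokens: list[bytes] = []
    pos = 2
    while len(tokens) < 3:
        m = re.compile(rb"\s*(#[^\n]*\n|\S+)").match(blob, pos)
        if m is None:
            raise ValueError(f"{path}: truncated PGM header")
        pos = m.end()
        if not m.group(1).startswith(b"#"):
            tokens.append(m.group(1))
    w, h, maxval = (int(t) for t in tokens)
    if maxval not in (255, 65535):
        raise ValueError(f"{path}: unsupported PGM maxval {maxval} (expected 255 or 65535)")
    if blob[:2] == b"P2":
        vals = np.array(blob[pos:].split(), dtype=float)
    else:
        pos += 1  # single whitespace byte after maxval
        dtype = np.dtype(">u2") if maxval == 65535 else np.dtype("u1")
        vals = np.frombuffer(blob, dtype=dtype, offset=pos).astype(float)
    if vals.size != h * w:
        raise ValueError(f"{path}: truncated PGM data ({vals.size} of {h * w} pixels)")
    return vals.reshape(h, w) / maxval


def _write_pgm(img_int: np.ndarray, maxval: int, path: Path, ascii_: bool) -> None:
    h, w = img_int.shape
    if ascii_:
        body = "\n".join(" ".join(str(v) for v in row) for row in img_int.tolist())
        path.write_text(f"P2\n{w} {h}\n{maxval}\n{body}\n")
    else:
        dtype = np.dtype(">u2") if maxval == 65535 else np.dtype("u1")
        path.write_bytes(f"P5\n{w} {h}\n{maxval}\n".encode() + img_int.astype(dtype).tobytes())


def read_image(path: str | Path, kind: str = "gray") -> np.ndarray:
    """Read a grayscale image or radiance map as float64.

    ``kind="gray"`` requires values in [0, 1] after scaling and rejects
    anything else; ``kind="radiance"`` permits arbitrary nonnegative floats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".raw", ".npyraw", ".vqf"):
        img = _read_raw(path)
    elif suffix == ".pgm":
        img = _read_pgm(path)
    elif suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:
            raise ValueError(f"{path}: color PNG not supported; convert to grayscale")
        if arr.dtype == np.uint8:
            img = arr.astype(float) / 255.0
        elif arr.dtype == np.uint16:
            img = arr.astype(float) / 65535.0
        else:
            raise ValueError(f"{path}: unsupported PNG dtype {arr.dtype}")
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r} (PGM, PNG or raw raster)")
    if kind == "gray":
        if img.min() < 0 or img.max() > 1:
            raise ValueError(f"{path}: gray image values outside [0, 1]")
    elif kind == "radiance":
        if img.min() < 0:
            raise ValueError(f"{path}: radiance map has negative values")
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return img


def write_image(
    img: np.ndarray,
    path: str | Path,
    format: str | None = None,
    bit_depth: int = 16,
) -> None:
    """Write an image; deterministic bytes for identical input.

    Integer formats (``pgm``, ``pgm-ascii``, ``png``) clamp to [0, 1] and
    round half to even at the requested bit depth; ``raw`` stores float64
    losslessly.  ``format=None`` infers from the file suffix.
    """
    path = Path(path)
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if format is None:
        format = {".pgm": "pgm", ".png": "png", ".raw": "raw", ".npyraw": "raw", ".vqf": "raw"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "raw":
        _write_raw(img, path)
        return
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    maxval = (1 << bit_depth) - 1
    quant = np.rint(np.clip(img, 0.0, 1.0) * maxval).astype(int)  # rint: half to even
    if format == "pgm":
        _write_pgm(quant, maxval, path, ascii_=False)
    elif format == "pgm-ascii":
        _write_pgm(quant, maxval, path, ascii_=True)
    elif format == "png":
        iio.imwrite(path, quant.astype(np.uint8 if bit_depth == 8 else np.uint16))
    else:
        raise ValueError(f"unknown format {format!r}")
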