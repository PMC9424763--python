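"""Containers and I/O for MCARS hypercubes, spectra, masks and maps.

A hypercube stores raw CARS intensities on an ``(X, Y, N)`` grid (two
spatial axes, one wavenumber axis).  For curve resolution the cube is
*linearized* into an ``M x N`` data matrix with ``M = X * Y`` pixel spectra
as rows.  The pixel order is the raster-scan convention of point-scanning
microscopes: row ``i`` of the matrix is pixel ``(x, y)`` with
``i = y * X + x`` (x varies fastest).

Native container is HDF5 (``/cube`` float32 X x Y x N, ``/wavenumbers``
float64 N).  Multi-page TIFF (one page per wavenumber) and a plain-text
matrix dialect are import/export alternatives; masks travel as 8-bit PNG
with values {0, 255}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Unknown or malformed on-disk format."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavenumber axis needs at least 2 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavenumber axis must be finite")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)


@dataclass
class Hypercube:
    """Raw CARS intensities on an (X, Y, N) grid.

    Parameters
    ----------
    intensities
        Non-negative raw counts, shape ``(X, Y, N)``.
    axis
        Wavenumber axis of length N.
    pixel_pitch
        Optional lateral step in micrometres.
    allow_negative
        Accept negative intensities (possible after external
        preprocessing).  By default they are rejected because the
        non-negativity constraint of the curve resolution assumes
        non-negative data.
    """

    intensities: np.ndarray
    axis: WavenumberAxis
    pixel_pitch: float | None = None
    allow_negative: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities, dtype=float)
        if a.ndim != 3:
            raise ValueError("intensities must be (X, Y, N)")
        if a.shape[2] != len(self.axis):
            raise ValueError(
                f"axis length {len(self.axis)} does not match N={a.shape[2]}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("intensities must be finite")
        if not self.allow_negative and np.any(a < 0):
            raise ValueError(
                "negative intensities; pass allow_negative=True to accept"
            )
        self.intensities = a

    @property
    def shape_xy(self) -> tuple[int, int]:
        return self.intensities.shape[0], self.intensities.shape[1]


@dataclass
class DataMatrix:
    """Linearized hypercube: M pixel spectra (rows) for N Raman shifts."""

    values: np.ndarray
    shape_xy: tuple[int, int]
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        x, y = self.shape_xy
        if v.ndim != 2 or v.shape[0] != x * y:
            raise ValueError("values must be (X*Y, N)")
        if v.shape[1] != len(self.axis):
            raise ValueError("axis length does not match N")
        self.values = v
        self.shape_xy = (int(x), int(y))

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class Mask:
    """Boolean X x Y segmentation mask (True = inside)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.values = v.astype(bool)

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def flat(self) -> np.ndarray:
        """Mask in linearized pixel order (i = y*X + x)."""
        return self.values.T.reshape(-1)


# ---------------------------------------------------------------------------
# unfold / refold


def unfold(cube: Hypercube) -> DataMatrix:
    """Linearize a hypercube into an M x N matrix (raster order)."""
    x, y = cube.shape_xy
    d = cube.intensities.transpose(1, 0, 2).reshape(x * y, -1)
    return DataMatrix(values=d, shape_xy=(x, y), axis=cube.axis)


def refold(matrix: DataMatrix, k_maps: np.ndarray) -> np.ndarray:
    """Refold per-pixel values into K images of size X x Y.

    ``k_maps`` is ``(M,)`` or ``(M, K)``; returns ``(X, Y)`` or
    ``(X, Y, K)`` with image[k][x, y] = k_maps[y*X + x, k].
    """
    x, y = matrix.shape_xy
    c = np.asarray(k_maps, dtype=float)
    squeeze = c.ndim == 1
    if squeeze:
        c = c[:, None]
    if c.shape[0] != x * y:
        raise ValueError(f"expected {x * y} rows, got {c.shape[0]}")
    images = c.reshape(y, x, c.shape[1]).transpose(1, 0, 2)
    return images[:, :, 0] if squeeze else images


def refold_cube(matrix: DataMatrix) -> Hypercube:
    """Inverse of :func:`unfold`."""
    x, y = matrix.shape_xy
    cube = matrix.values.reshape(y, x, -1).transpose(1, 0, 2)
    return Hypercube(cube, matrix.axis, allow_negative=True)


# ---------------------------------------------------------------------------
# hypercube I/O


def save_hypercube(path: str | Path, cube: Hypercube, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=cube.intensities.astype(np.float32))
            f.create_dataset("wavenumbers", data=cube.axis.values.astype(np.float64))
            if cube.pixel_pitch is not None:
                f["cube"].attrs["pixel_pitch_um"] = float(cube.pixel_pitch)
    elif fmt == "tiff":
        # one page per wavenumber, page layout (Y, X); axis in the description
        pages = cube.intensities.transpose(2, 1, 0).astype(np.float32)
        desc = json.dumps({"wavenumbers_cm1": cube.axis.values.tolist()})
        tifffile.imwrite(path, pages, description=desc,
                         photometric="minisblack")
    elif fmt == "txt":
        x, y = cube.shape_xy
        d = unfold(cube).values
        with open(path, "w") as f:
            f.write(f"# X {x}\n# Y {y}\n")
            np.savetxt(f, cube.axis.values[None, :], fmt="%.6f")
            np.savetxt(f, d, fmt="%.8g")
    else:
        raise FormatError(f"unknown hypercube format: {fmt}")


def load_hypercube(path: str | Path, format: str | None = None,
                   allow_negative: bool = False) -> Hypercube:
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            cube = f["cube"][()].astype(float)
            wn = f["wavenumbers"][()].astype(float)
            pitch = f["cube"].attrs.get("pixel_pitch_um")
        return Hypercube(cube, WavenumberAxis(wn),
                         pixel_pitch=None if pitch is None else float(pitch),
                         allow_negative=allow_negative)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray().astype(float)
            desc = tf.pages[0].description
        try:
            wn = np.asarray(json.loads(desc)["wavenumbers_cm1"], dtype=float)
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError("TIFF lacks a wavenumber description") from exc
        if pages.ndim != 3 or pages.shape[0] != wn.size:
            raise FormatError("TIFF page count does not match wavenumber axis")
        return Hypercube(pages.transpose(2, 1, 0), WavenumberAxis(wn),
                         allow_negative=allow_negative)
    if fmt == "txt":
        with open(path) as f:
            header = [f.readline(), f.readline()]
            try:
                x = int(header[0].split()[-1])
                y = int(header[1].split()[-1])
            except (IndexError, ValueError) as exc:
                raise FormatError("text cube needs '# X nx' / '# Y ny' header") from exc
            body = np.loadtxt(f)
        wn, d = body[0], body[1:]
        if d.shape[0] != x * y:
            raise FormatError("text cube row count does not match X*Y")
        mat = DataMatrix(d, (x, y), WavenumberAxis(wn))
        cube = refold_cube(mat)
        cube.allow_negative = allow_negative
        if not allow_negative and np.any(cube.intensities < 0):
            raise ValueError("negative intensities; pass allow_negative=True")
        return cube
    raise FormatError(f"unknown hypercube format: {fmt}")


def _sniff_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    if suf in {".tif", ".tiff"}:
        return "tiff"
    if suf in {".txt", ".dat", ".tsv"}:
        return "txt"
    raise FormatError(f"cannot infer format from suffix {suf!r}")


# ---------------------------------------------------------------------------
# spectra I/O (CSV: first column wavenumber, one spectrum per further column)


def save_spectra(path: str | Path, axis: WavenumberAxis, spectra: np.ndarray,
                 names: list[str] | None = None) -> None:
    s = np.atleast_2d(np.asarray(spectra, dtype=float))
    if s.shape[1] != len(axis):  # rows are spectra of length N
        raise ValueError("spectra length does not match axis")
    cols = names or [f"component_{k + 1}" for k in range(s.shape[0])]
    df = pd.DataFrame({"wavenumber_cm1": axis.values})
    for name, row in zip(cols, s):
        df[name] = row
    df.to_csv(path, index=False)


def load_spectra(path: str | Path) -> tuple[WavenumberAxis, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("spectra CSV needs a wavenumber column plus spectra")
    axis = WavenumberAxis(df.iloc[:, 0].to_numpy(dtype=float))
    names = list(df.columns[1:])
    spectra = df.iloc[:, 1:].to_numpy(dtype=float).T
    return axis, spectra, names


# ---------------------------------------------------------------------------
# mask and map I/O


def save_mask(path: str | Path, mask: Mask) -> None:
    img = np.where(mask.values.T, 255, 0).astype(np.uint8)  # PNG rows = y
    iio.imwrite(path, img)


def load_mask(path: str | Path) -> Mask:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # tolerate grayscale saved with redundant channels
        if not np.all(img == img[..., :1]):
            raise FormatError("mask PNG must be single-channel")
        img = img[..., 0]
    vals = np.unique(img)
    if not np.all(np.isin(vals, [0, 255])):
        raise FormatError(f"mask PNG must contain only {{0, 255}}, got {vals.tolist()}")
    return Mask((img == 255).T)


def save_concentration_map(path: str | Path, image: np.ndarray) -> None:
    """Write one X x Y concentration map as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32).T)


def load_concentration_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float).T


def clip_negative(cube: Hypercube, warn: bool = True) -> Hypercube:
    """Clip negative intensities to zero (opt-in alternative to rejection)."""
    n_neg = int(np.sum(cube.intensities < 0))
    if n_neg and warn:
        warnings.warn(f"clipped {n_neg} negative intensities to zero")
    return Hypercube(np.clip(cube.intensities, 0, None), cube.axis,
                     pixel_pitch=cube.pixel_pitch)
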