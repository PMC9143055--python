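"""Data model and readers/writers for pixel-level MSI data.

The unit of work throughout the package is the per-run *spectral matrix*: a
dense ``M x N`` array of non-negative intensities, one row per pixel of the
raster (integer grid coordinates, nominal pixel pitch 85 um for DESI) and one
column per entry of a mass axis.  Runs are stored losslessly in a small HDF5
container; imzML files (continuous or processed mode) can be read into the
same in-memory representation via :func:`read_run`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MassAxis",
    "PeakList",
    "SpectralMatrix",
    "read_run",
    "write_run",
    "read_imzml",
    "read_annotations",
    "write_annotations",
]

ANNOTATION_COLUMNS = ["core_id", "slide_id", "patient_id", "label", "x_center", "y_center"]


@dataclass(frozen=True)
class MassAxis:
    """A strictly increasing m/z axis (Thomson), shared by a spectral matrix."""

    mz: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        object.__setattr__(self, "mz", mz)
        if mz.ndim != 1:
            raise ValidationError("mass axis must be one-dimensional")
        if mz.size and np.any(mz <= 0):
            raise ValidationError("mass axis values must be positive")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValidationError("mass axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other) -> bool:  # value equality, convenient in tests
        return isinstance(other, MassAxis) and np.array_equal(self.mz, other.mz)


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks (m/z, intensity, SNR) for one spectrum or run.

    Stored sorted by m/z; SNR values are non-negative (``inf`` is allowed for
    peaks whose noise estimate was zero).
    """

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        snr = np.asarray(self.snr, dtype=float)
        if not (mz.shape == intensity.shape == snr.shape) or mz.ndim != 1:
            raise ValidationError("peak list arrays must be 1-D and of equal length")
        if mz.size > 1 and np.any(np.diff(mz) < 0):
            raise ValidationError("peak list must be sorted by m/z")
        if np.any(snr < 0):
            raise ValidationError("peak SNR values must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "snr", snr)

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def empty(cls) -> "PeakList":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy())


@dataclass(frozen=True)
class SpectralMatrix:
    """Pixels x mass-axis intensity matrix for one MSI run.

    ``coords`` holds 0-based integer grid indices ``(x, y)`` per pixel; the
    physical position is ``index * pixel_size_um``.  Missing pixels of a
    non-rectangular ROI are simply absent rows.
    """

    run_id: str
    slide_id: str
    coords: np.ndarray  # (M, 2) int
    intensities: np.ndarray  # (M, N) float, >= 0
    axis: MassAxis
    pixel_size_um: float = 85.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=int)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "intensities", intensities)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError("coords must have shape (M, 2)")
        if intensities.ndim != 2:
            raise ValidationError("intensities must have shape (M, N)")
        if coords.shape[0] != intensities.shape[0]:
            raise ValidationError(
                f"coordinate rows ({coords.shape[0]}) != intensity rows ({intensities.shape[0]})"
            )
        if intensities.shape[1] != len(self.axis):
            raise ValidationError(
                f"intensity columns ({intensities.shape[1]}) != axis length ({len(self.axis)})"
            )
        if np.any(intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if coords.shape[0]:
            uniq = np.unique(coords, axis=0)
            if uniq.shape[0] != coords.shape[0]:
                raise ValidationError("duplicate pixel coordinates")

    @property
    def n_pixels(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.intensities.shape[1])

    def tic(self) -> np.ndarray:
        """Per-pixel total ion count (sum of the spectrum)."""
        return self.intensities.sum(axis=1)

    def mean_spectrum(self) -> np.ndarray:
        if self.n_pixels == 0:
            return np.zeros(self.n_features)
        return self.intensities.mean(axis=0)

    def with_intensities(self, intensities: np.ndarray, axis: MassAxis | None = None) -> "SpectralMatrix":
        return replace(self, intensities=intensities, axis=axis if axis is not None else self.axis)


def write_run(matrix: SpectralMatrix, path) -> None:
    """Write a run to the internal HDF5 container (lossless round-trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=matrix.intensities, compression="gzip", compression_opts=1)
        f.create_dataset("coords", data=matrix.coords)
        f.create_dataset("mz", data=matrix.axis.mz)
        f.attrs["run_id"] = matrix.run_id
        f.attrs["slide_id"] = matrix.slide_id
        f.attrs["pixel_size_um"] = matrix.pixel_size_um


def _read_internal(path) -> SpectralMatrix:
    with h5py.File(path, "r") as f:
        for key in ("intensities", "coords", "mz"):
            if key not in f:
                raise ValidationError(f"malformed run file {path}: missing dataset '{key}'")
        return SpectralMatrix(
            run_id=str(f.attrs.get("run_id", Path(path).stem)),
            slide_id=str(f.attrs.get("slide_id", Path(path).stem)),
            coords=f["coords"][()],
            intensities=f["intensities"][()],
            axis=MassAxis(f["mz"][()]),
            pixel_size_um=float(f.attrs.get("pixel_size_um", 85.0)),
        )


def read_imzml(path, pixel_size_um: float = 85.0) -> SpectralMatrix:
    """Read an imzML file (continuous or processed mode) into a SpectralMatrix.

    Processed-mode spectra are rasterised onto the union of the file's own m/z
    values (exact-value matching); for continuous mode the union equals the
    shared axis.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    n = len(parser.coordinates)
    spectra = []
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        spectra.append((np.asarray(mzs, dtype=float), np.asarray(ints, dtype=float)))
    if n == 0:
        return SpectralMatrix(path.stem, path.stem, np.empty((0, 2), int), np.empty((0, 0)), MassAxis(np.empty(0)), pixel_size_um)
    union = np.unique(np.concatenate([mz for mz, _ in spectra]))
    axis = MassAxis(union)
    intens = np.zeros((n, union.size))
    for i, (mz, it) in enumerate(spectra):
        idx = np.searchsorted(union, mz)
        np.add.at(intens[i], idx, it)
    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=int)  # imzML is 1-based
    return SpectralMatrix(path.stem, path.stem, coords, intens, axis, pixel_size_um)


def read_run(path, format: str = "internal") -> SpectralMatrix:
    """Read a run from disk; ``format`` is ``internal`` or ``imzml``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "internal":
        return _read_internal(path)
    if format == "imzml":
        return read_imzml(path)
    raise ValueError(f"unknown format {format!r}; expected 'internal' or 'imzml'")


def write_annotations(annotations: pd.DataFrame, path) -> None:
    """Write the core annotation table (one row per TMA core) as CSV."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns {missing}")
    annotations.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns {missing}")
    if df["core_id"].duplicated().any():
        raise ValidationError("annotation table has duplicate core_id values")
    return df
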