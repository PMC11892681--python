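"""MSI containers, imzML I/O and spectral preprocessing.

The preprocessing chain applied to every pixel before any downstream
statistics is: interpolation rebinning onto a uniform m/z axis (default
bin width 0.001 Da), root-mean-square normalisation of the rebinned
intensities, and (per experiment) a mean spectrum over all pixels of all
tissues for peak detection.

Coordinate convention: in memory pixel coordinates are 0-based with x
rightward and y downward; imzML files store them 1-based, and the reader
and writer translate at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter


@dataclass
class Spectrum:
    """A single mass spectrum: strictly ascending m/z with non-negative intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class MSIDataset:
    """Per-pixel spectra on an integer grid plus acquisition metadata."""

    pixels: list[tuple[int, int]]
    spectra: list[Spectrum]
    pixel_pitch: float = 50.0
    polarity: str = "negative"
    modality: str = "MALDI"
    tissue_id: str = ""
    experiment_id: str = ""
    arm: str = ""
    mass_range: tuple[float, float] = (70.0, 1000.0)

    def __post_init__(self) -> None:
        if len(self.pixels) != len(self.spectra):
            raise ValueError("one spectrum per pixel required")
        if len(self.pixels) == 0:
            raise ValueError("dataset has no pixels")
        if len(set(self.pixels)) != len(self.pixels):
            raise ValueError("pixel coordinates must be unique")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) bounding box of the pixel coordinates."""
        xs = [p[0] for p in self.pixels]
        ys = [p[1] for p in self.pixels]
        return (max(ys) + 1, max(xs) + 1)


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def write_imzml(dataset: MSIDataset, path: str | os.PathLike) -> Path:
    """Write ``dataset`` as processed-mode imzML 1.1 (paired .imzML/.ibd).

    Coordinates are serialised 1-based per the imzML convention.  Zero
    intensities are preserved.  Non-finite intensities are an error.
    """
    path = Path(path)
    for i, spec in enumerate(dataset.spectra):
        if not np.all(np.isfinite(spec.intensity)) or not np.all(np.isfinite(spec.mz)):
            raise ValueError(f"non-finite values in spectrum of pixel index {i}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(
        str(path),
        polarity=dataset.polarity,
        mode="processed",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        for (x, y), spec in zip(dataset.pixels, dataset.spectra):
            writer.addSpectrum(spec.mz, spec.intensity, (x + 1, y + 1, 1))
    return path


def read_imzml(path: str | os.PathLike, **metadata) -> MSIDataset:
    """Read an imzML/.ibd pair into an :class:`MSIDataset`.

    Accepts both continuous and processed dialects.  Study metadata that
    imzML does not carry (tissue_id, arm, ...) may be supplied as keyword
    arguments; a ``mass_range`` not supplied is inferred from the data.
    """
    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not path.exists():
        raise FileNotFoundError(path)
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary data file {ibd}")
    parser = ImzMLParser(str(path))
    pixels: list[tuple[int, int]] = []
    spectra: list[Spectrum] = []
    lo, hi = np.inf, -np.inf
    for i, (x, y, _z) in enumerate(parser.coordinates):
        try:
            mz, inten = parser.getspectrum(i)
        except Exception as exc:  # corrupt offsets/lengths
            raise IOError(f"failed to read pixel index {i} from {path}: {exc}") from exc
        mz = np.asarray(mz, dtype=float)
        inten = np.clip(np.asarray(inten, dtype=float), 0.0, None)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        pixels.append((int(x) - 1, int(y) - 1))
        spectra.append(Spectrum(mz, inten))
        if mz.size:
            lo = min(lo, float(mz[0]))
            hi = max(hi, float(mz[-1]))
    if not pixels:
        raise ValueError(f"{path} contains no pixels")
    metadata.setdefault("mass_range", (float(np.floor(lo)), float(np.ceil(hi))))
    return MSIDataset(pixels=pixels, spectra=spectra, **metadata)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def uniform_axis(mass_range: tuple[float, float], bin_width: float) -> np.ndarray:
    """Grid nodes of the uniform axis: low + i*w, anchored at mass_range.low."""
    low, high = mass_range
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if high <= low:
        raise ValueError("mass_range must have high > low")
    n = int(np.floor((high - low) / bin_width + 1e-9)) + 1
    return low + np.arange(n) * bin_width


def rebin_spectrum(
    spectrum: Spectrum,
    bin_width: float = 0.001,
    mass_range: tuple[float, float] | None = None,
) -> Spectrum:
    """Interpolation rebinning onto a uniform axis.

    The value at each bin centre is the linear interpolation of the input;
    outside the input support the value is zero.
    """
    if len(spectrum) < 2:
        raise ValueError("rebinning requires at least two points")
    if mass_range is None:
        mass_range = (float(spectrum.mz[0]), float(spectrum.mz[-1]))
    centres = uniform_axis(mass_range, bin_width)
    values = np.interp(centres, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    return Spectrum(centres, values)


def rms(intensity: np.ndarray) -> float:
    """Root mean square of an intensity vector."""
    intensity = np.asarray(intensity, dtype=float)
    return float(np.sqrt(np.mean(np.square(intensity))))


def rms_normalise(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the spectrum's root-mean-square equals 1.

    The RMS is taken over the full axis including zero bins.  An all-zero
    spectrum cannot be normalised and raises (callers exclude such pixels).
    """
    scale = rms(spectrum.intensity)
    if scale == 0:
        raise ValueError("cannot RMS-normalise an all-zero spectrum")
    return Spectrum(spectrum.mz, spectrum.intensity / scale)


def mean_spectrum(datasets: Iterable[MSIDataset | Sequence[Spectrum]]) -> Spectrum:
    """Pixel-wise arithmetic mean spectrum over all pixels of all datasets.

    All spectra must share an identical (rebinned) m/z axis.
    """
    total: np.ndarray | None = None
    axis: np.ndarray | None = None
    n = 0
    for ds in datasets:
        spectra = ds.spectra if isinstance(ds, MSIDataset) else ds
        for spec in spectra:
            if axis is None:
                axis = spec.mz
                total = np.zeros_like(spec.intensity)
            elif spec.mz.shape != axis.shape or not np.array_equal(spec.mz, axis):
                raise ValueError("all spectra must share the same m/z axis")
            total += spec.intensity
            n += 1
    if n == 0:
        raise ValueError("no spectra provided")
    return Spectrum(axis, total / n)
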