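"""Data model for hyperspectral XRF raster-scan maps.

A raster scan produces one photon-count spectrum per position on a regular
2-D grid.  The in-memory container is :class:`SpectralMap`: an integer count
cube of shape ``(rows, cols, n_channels)`` together with a linear energy
calibration and the pixel pitch of the scan stage.  Pixel coordinates are
``(row, col)``, 0-based, row 0 at the top of the image (raster order);
channel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "EnergyCalibration",
    "Spectrum",
    "SpectralMap",
    "EmissionLine",
    "mean_spectrum",
    "load_map",
    "save_map",
    "load_spectrum_csv",
    "save_spectrum_csv",
]


@dataclass(frozen=True)
class EnergyCalibration:
    """Linear channel-to-energy calibration ``E(i) = offset + gain * i``.

    Parameters
    ----------
    offset : float
        Energy of channel 0, keV.
    gain : float
        Channel width, keV per channel.  Must be positive so the energy
        axis is strictly increasing.
    n_channels : int
        Number of detector channels (>= 2).
    """

    offset: float
    gain: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")

    def channel_energy(self, i: int | np.ndarray) -> float | np.ndarray:
        """Energy (keV) at channel center ``i``; errors if out of range."""
        idx = np.asarray(i)
        if np.any(idx < 0) or np.any(idx >= self.n_channels):
            raise IndexError(
                f"channel index {i} out of range [0, {self.n_channels})"
            )
        out = self.offset + self.gain * idx
        return float(out) if out.ndim == 0 else out

    @property
    def energies(self) -> np.ndarray:
        """Energies (keV) of all channel centers."""
        return self.offset + self.gain * np.arange(self.n_channels)

    def energy_to_channel(self, energy: float) -> int:
        """Nearest channel whose center is closest to ``energy`` (keV)."""
        i = int(round((energy - self.offset) / self.gain))
        if i < 0 or i >= self.n_channels:
            raise IndexError(f"{energy} keV outside calibrated range")
        return i


def channel_energy(cal: EnergyCalibration, i: int) -> float:
    """Energy in keV at channel ``i`` under calibration ``cal``."""
    return cal.channel_energy(i)


@dataclass(frozen=True)
class Spectrum:
    """A single photon-count spectrum.

    ``counts`` are non-negative per channel; ``live_time`` (seconds) is
    optional and only used by the forward simulator — the spectral-density
    statistics are scale-free.
    """

    counts: np.ndarray
    calibration: EnergyCalibration
    live_time: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.shape[0] != self.calibration.n_channels:
            raise ValueError(
                f"counts length {counts.shape[0]} != calibration "
                f"n_channels {self.calibration.n_channels}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SpectralMap:
    """Hyperspectral XRF map: a count cube over a 2-D raster grid.

    Parameters
    ----------
    counts_cube : ndarray, shape (rows, cols, n_channels)
        Non-negative integer photon counts.
    calibration : EnergyCalibration
    pixel_pitch : (float, float)
        Scan step in µm along (row, col).
    metadata : dict
        Free-form acquisition metadata (e.g. ``beam_energy_keV``,
        ``dwell_s``).
    """

    counts_cube: np.ndarray
    calibration: EnergyCalibration
    pixel_pitch: tuple[float, float] = (100.0, 100.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cube = np.asarray(self.counts_cube)
        if cube.ndim != 3:
            raise ValueError("counts_cube must be rows x cols x channels")
        if cube.shape[2] != self.calibration.n_channels:
            raise ValueError(
                f"cube has {cube.shape[2]} channels, calibration expects "
                f"{self.calibration.n_channels}"
            )
        if np.any(cube < 0):
            raise ValueError("counts must be non-negative")
        if not all(p > 0 for p in self.pixel_pitch):
            raise ValueError("pixel_pitch must be positive")
        self.counts_cube = cube

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts_cube.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.counts_cube.shape[2]

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        """Spectrum of a single pixel."""
        return Spectrum(self.counts_cube[row, col], self.calibration)

    def total_counts(self) -> np.ndarray:
        """Per-pixel total counts image."""
        return self.counts_cube.sum(axis=2)


@dataclass(frozen=True)
class EmissionLine:
    """One characteristic emission line of an element.

    ``line_label`` is the Siegbahn group (Ka, Kb, La, Lb, Lg, Ma);
    ``relative_intensity`` is the branching fraction within that group.
    """

    element: str
    line_label: str
    energy: float
    relative_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("line energy must be positive")
        if not (0 < self.relative_intensity <= 1):
            raise ValueError("relative_intensity must be in (0, 1]")


def mean_spectrum(
    spectral_map: SpectralMap,
    region: Iterable[tuple[int, int]] | None = None,
) -> Spectrum:
    """Arithmetic-mean spectrum over a set of pixel coordinates.

    ``region`` is an iterable of ``(row, col)`` pairs; ``None`` means the
    whole map.  The result is real-valued (mean of integers).
    """
    cube = spectral_map.counts_cube
    if region is None:
        mean = cube.reshape(-1, cube.shape[2]).mean(axis=0)
        return Spectrum(mean, spectral_map.calibration)
    coords = list(region)
    if not coords:
        raise ValueError("region is empty")
    rows, cols = zip(*coords)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    nr, nc = spectral_map.shape
    if rows.min() < 0 or rows.max() >= nr or cols.min() < 0 or cols.max() >= nc:
        raise IndexError("region coordinates out of map bounds")
    mean = cube[rows, cols].mean(axis=0)
    return Spectrum(mean, spectral_map.calibration)


# ---------------------------------------------------------------------------
# File I/O.  HDF5 layout:
#   /counts  uint32 dataset, rows x cols x channels
#            attrs: offset_keV, gain_keV, pixel_pitch_um (2-vector),
#                   beam_energy_keV (optional)
#   /meta    free-form scalar attributes
#   /truth   optional group written by the phantom simulator
# ---------------------------------------------------------------------------

_REQUIRED_ATTRS = ("offset_keV", "gain_keV", "pixel_pitch_um")


def save_map(spectral_map: SpectralMap, path) -> None:
    """Write a :class:`SpectralMap` to HDF5 (counts stored as uint32)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(
            "counts",
            data=spectral_map.counts_cube.astype(np.uint32),
            compression="gzip",
            compression_opts=4,
        )
        cal = spectral_map.calibration
        ds.attrs["offset_keV"] = cal.offset
        ds.attrs["gain_keV"] = cal.gain
        ds.attrs["pixel_pitch_um"] = np.asarray(spectral_map.pixel_pitch, float)
        if "beam_energy_keV" in spectral_map.metadata:
            ds.attrs["beam_energy_keV"] = spectral_map.metadata["beam_energy_keV"]
        meta = f.create_group("meta")
        for key, value in spectral_map.metadata.items():
            try:
                meta.attrs[key] = value
            except TypeError:
                meta.attrs[key] = str(value)


def load_map(path) -> SpectralMap:
    """Read a :class:`SpectralMap` from HDF5, validating the layout."""
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise KeyError(f"{path}: missing dataset '/counts'")
        ds = f["counts"]
        for name in _REQUIRED_ATTRS:
            if name not in ds.attrs:
                raise KeyError(f"{path}: '/counts' missing attribute '{name}'")
        cube = ds[()]
        cal = EnergyCalibration(
            offset=float(ds.attrs["offset_keV"]),
            gain=float(ds.attrs["gain_keV"]),
            n_channels=cube.shape[2],
        )
        pitch = tuple(float(p) for p in ds.attrs["pixel_pitch_um"])
        metadata = {}
        if "beam_energy_keV" in ds.attrs:
            metadata["beam_energy_keV"] = float(ds.attrs["beam_energy_keV"])
        if "meta" in f:
            for key, value in f["meta"].attrs.items():
                metadata[key] = value
    return SpectralMap(cube, cal, pitch, metadata)


def save_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a single spectrum as 2-column CSV (energy_keV, counts)."""
    energies = spectrum.calibration.energies
    data = np.column_stack([energies, spectrum.counts])
    np.savetxt(path, data, delimiter=",", header="energy_keV,counts", comments="")


def load_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-column CSV spectrum; returns (energies_keV, counts)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1]
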