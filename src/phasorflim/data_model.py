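"""Core data types and persistence for spectral FLIM photon-count cubes.

A measurement is a 4-D array of photon counts indexed
``(row, col, spectral_channel, time_bin)`` plus acquisition metadata.
Time bins are half-open intervals ``[k*dt, (k+1)*dt)`` with
``dt = time_window_s / n_time_bins``; pixel indices are 0-based,
row-major, origin at the top-left.

Cubes persist to a single HDF5 file per field of view (dataset
``counts`` as uint32, metadata as attributes of group ``meta``).
Derived 2-D maps (intensity, lifetime, masks) are written as TIFF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import tifffile

__all__ = [
    "AcquisitionMetadata",
    "FLIMImage",
    "IntensityImage",
    "Mask",
    "default_metadata",
    "save_flim_cube",
    "load_flim_cube",
    "integrate_spectral",
    "integrate_time",
    "write_map_tiff",
    "write_mask_tiff",
]

#: Angular frequency of the fundamental harmonic: omega = 2*pi*repetition_rate.
TWO_PI = 2.0 * np.pi


class FormatError(ValueError):
    """Raised when a cube file is missing fields or violates invariants."""


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition parameters of a TCSPC spectral FLIM measurement.

    Parameters
    ----------
    repetition_rate_hz:
        Laser pulse repetition frequency in Hz.
    time_window_s:
        Span of the TCSPC histogram in seconds; must equal
        ``1 / repetition_rate_hz``.
    n_time_bins:
        Number of TCSPC time bins (>= 16).
    channel_centers_nm:
        Center wavelengths of the spectral detector channels,
        strictly increasing.
    channel_bandwidth_nm:
        Bandwidth of each spectral channel in nm.
    pixel_size_um:
        Lateral pixel size in micrometres.
    """

    repetition_rate_hz: float
    time_window_s: float
    n_time_bins: int
    channel_centers_nm: tuple[float, ...]
    channel_bandwidth_nm: float = 12.5
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        if self.repetition_rate_hz <= 0:
            raise ValueError("repetition_rate_hz must be positive")
        if self.n_time_bins < 16:
            raise ValueError("n_time_bins must be >= 16")
        rel = abs(self.time_window_s * self.repetition_rate_hz - 1.0)
        if rel > 1e-9:
            raise ValueError(
                "time_window_s must equal 1/repetition_rate_hz "
                f"(relative mismatch {rel:.2e})"
            )
        centers = np.asarray(self.channel_centers_nm, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("channel_centers_nm must be a non-empty 1-D sequence")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise ValueError("channel_centers_nm must be strictly increasing")
        object.__setattr__(self, "channel_centers_nm", tuple(float(c) for c in centers))

    @property
    def n_channels(self) -> int:
        return len(self.channel_centers_nm)

    @property
    def bin_width_s(self) -> float:
        return self.time_window_s / self.n_time_bins

    @property
    def bin_centers_s(self) -> np.ndarray:
        """Centers of the half-open time bins, ``(k + 1/2) * dt``."""
        dt = self.bin_width_s
        return (np.arange(self.n_time_bins) + 0.5) * dt

    @property
    def bin_edges_s(self) -> np.ndarray:
        return np.arange(self.n_time_bins + 1) * self.bin_width_s

    def omega(self, harmonic: int = 1) -> float:
        """Angular frequency ``2*pi*repetition_rate*harmonic`` (rad/s)."""
        return TWO_PI * self.repetition_rate_hz * harmonic


def default_metadata(
    n_time_bins: int = 256,
    repetition_rate_hz: float = 80e6,
    n_channels: int = 16,
    lambda_min_nm: float = 400.0,
    channel_bandwidth_nm: float = 12.5,
    pixel_size_um: float = 0.25,
) -> AcquisitionMetadata:
    """16-channel 400-600 nm detector at 80 MHz (12.5 ns window).

    Channel centers sit at ``lambda_min + bandwidth*(k + 1/2)``, i.e.
    406.25, 418.75, ..., 593.75 nm for the defaults.
    """
    centers = lambda_min_nm + channel_bandwidth_nm * (np.arange(n_channels) + 0.5)
    return AcquisitionMetadata(
        repetition_rate_hz=repetition_rate_hz,
        time_window_s=1.0 / repetition_rate_hz,
        n_time_bins=n_time_bins,
        channel_centers_nm=tuple(centers),
        channel_bandwidth_nm=channel_bandwidth_nm,
        pixel_size_um=pixel_size_um,
    )


@dataclass
class FLIMImage:
    """Per-pixel, per-spectral-channel TCSPC photon-count histograms.

    ``counts`` has shape ``(rows, cols, n_channels, n_time_bins)``.
    """

    counts: np.ndarray
    meta: AcquisitionMetadata

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValueError("counts must be 4-D (row, col, channel, time_bin)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be an integer array")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.shape[2] != self.meta.n_channels:
            raise ValueError(
                f"counts has {self.counts.shape[2]} channels, "
                f"metadata declares {self.meta.n_channels}"
            )
        if self.counts.shape[3] != self.meta.n_time_bins:
            raise ValueError(
                f"counts has {self.counts.shape[3]} time bins, "
                f"metadata declares {self.meta.n_time_bins}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]


@dataclass
class IntensityImage:
    """2-D intensity map integrated over a spectral band and all time bins."""

    values: np.ndarray
    band_nm: tuple[float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.size and self.values.min() < 0:
            raise ValueError("intensity values must be non-negative")


@dataclass
class Mask:
    """Boolean pixel mask with a free-text label."""

    flags: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("mask flags must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.flags.sum())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.flags & other.flags, f"{self.label}&{other.label}")


# ---------------------------------------------------------------------------
# Persistence

_META_FIELDS = (
    "repetition_rate_hz",
    "time_window_s",
    "n_time_bins",
    "channel_centers_nm",
    "channel_bandwidth_nm",
    "pixel_size_um",
)


def save_flim_cube(img: FLIMImage, path) -> None:
    """Write a cube and its metadata to a self-describing HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=img.counts.astype(np.uint32))
        meta = f.create_group("meta")
        for name in _META_FIELDS:
            meta.attrs[name] = getattr(img.meta, name)


def load_flim_cube(path) -> FLIMImage:
    """Read a cube written by :func:`save_flim_cube`.

    Raises
    ------
    FormatError
        If the file lacks the counts dataset or a metadata field, or the
        stored data violates a type invariant.
    """
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError("cube file missing dataset 'counts'")
        if "meta" not in f:
            raise FormatError("cube file missing group 'meta'")
        attrs = f["meta"].attrs
        kwargs = {}
        for name in _META_FIELDS:
            if name not in attrs:
                raise FormatError(f"cube file missing metadata field '{name}'")
            kwargs[name] = attrs[name]
        counts = f["counts"][()]
    kwargs["n_time_bins"] = int(kwargs["n_time_bins"])
    kwargs["channel_centers_nm"] = tuple(np.atleast_1d(kwargs["channel_centers_nm"]))
    try:
        meta = AcquisitionMetadata(**{k: kwargs[k] for k in _META_FIELDS})
        return FLIMImage(counts=counts, meta=meta)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_map_tiff(values: np.ndarray, path) -> None:
    """Write a 2-D float map (e.g. lifetime in ps) as 32-bit TIFF."""
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def write_mask_tiff(mask: Mask, path) -> None:
    """Write a mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, np.where(mask.flags, 255, 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# Band integration


def _channels_in_band(meta: AcquisitionMetadata, band_nm: Sequence[float]) -> np.ndarray:
    lo, hi = float(band_nm[0]), float(band_nm[1])
    if hi < lo:
        raise ValueError(f"band must satisfy low <= high, got ({lo}, {hi})")
    centers = np.asarray(meta.channel_centers_nm)
    idx = np.nonzero((centers >= lo) & (centers <= hi))[0]
    if idx.size == 0:
        raise ValueError(
            f"band [{lo}, {hi}] nm contains no spectral channel center "
            f"(centers span {centers[0]}-{centers[-1]} nm)"
        )
    return idx


def integrate_spectral(
    img: FLIMImage, band_nm: Sequence[float]
) -> tuple[np.ndarray, tuple[float, float]]:
    """Sum counts over all channels whose center lies in the closed band.

    Returns the 3-D decay image ``(row, col, time_bin)`` and the band as a
    ``(low, high)`` tuple. Total photons over the included channels are
    conserved.
    """
    idx = _channels_in_band(img.meta, band_nm)
    decays = img.counts[:, :, idx, :].sum(axis=2)
    return decays, (float(band_nm[0]), float(band_nm[1]))


def integrate_time(img: FLIMImage, band_nm: Sequence[float]) -> IntensityImage:
    """Intensity image: sum over the band's channels and all time bins."""
    decays, band = integrate_spectral(img, band_nm)
    return IntensityImage(
        values=decays.sum(axis=2),
        band_nm=band,
        provenance=f"integrate_time band {band[0]}-{band[1]} nm",
    )


def metadata_to_dict(meta: AcquisitionMetadata) -> dict:
    d = dataclasses.asdict(meta)
    d["channel_centers_nm"] = list(d["channel_centers_nm"])
    return d
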