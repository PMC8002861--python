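"""Per-pixel phasor transform and universal-circle geometry.

The phasor of a decay histogram is the pair of normalized Fourier
coefficients at a harmonic of the laser repetition angular frequency:

    g = sum_k c_k cos(n*omega*t_k) / sum_k c_k
    s = sum_k c_k sin(n*omega*t_k) / sum_k c_k

with ``t_k`` the time-bin centers and ``omega = 2*pi*repetition_rate``.
Single-exponential decays land on the universal semicircle of radius 0.5
centered at (0.5, 0); mixtures fall inside it (the transform is linear in
intensity), and rising excited-state-reaction profiles fall outside it.

No instrument calibration (reference-dye rotation/scale) is applied by
default: synthetic data has a delta IRF.  ``calibrate`` implements the
optional phasor-space similarity transform for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import AcquisitionMetadata

__all__ = [
    "PhasorField",
    "PhasorHistogram",
    "phasor_transform",
    "monoexp_phasor",
    "phase_lifetime",
    "modulation_lifetime",
    "circle_residual",
    "phasor_histogram",
    "calibrate",
]


@dataclass
class PhasorField:
    """Per-pixel (g, s) phasor coordinates at one harmonic."""

    g: np.ndarray
    s: np.ndarray
    omega_rad_per_s: float
    harmonic: int
    total_counts: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape


@dataclass
class PhasorHistogram:
    """2-D occupancy histogram over (g, s) bins."""

    counts: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray

    @property
    def mode(self) -> tuple[float, float]:
        """(g, s) bin-center of the most occupied bin."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            0.5 * (self.g_edges[i] + self.g_edges[i + 1]),
            0.5 * (self.s_edges[j] + self.s_edges[j + 1]),
        )


def phasor_transform(
    decays: np.ndarray,
    meta: AcquisitionMetadata,
    harmonic: int = 1,
    min_photons: float = 50.0,
) -> PhasorField:
    """Phasor field of a 3-D decay image ``(row, col, time_bin)``.

    Pixels with total counts below ``min_photons`` (or zero) are flagged
    invalid; their (g, s) are NaN.  Pass ``min_photons=0`` for noiseless
    profiles normalized to unit area.
    """
    decays = np.asarray(decays, dtype=float)
    if decays.ndim != 3:
        raise ValueError("decays must be 3-D (row, col, time_bin)")
    if decays.size and decays.min() < 0:
        raise ValueError("decay counts must be non-negative")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    if decays.shape[2] != meta.n_time_bins:
        raise ValueError("time axis inconsistent with metadata")

    omega = meta.omega(harmonic)
    t = meta.bin_centers_s
    cos_w = np.cos(omega * t)
    sin_w = np.sin(omega * t)
    total = decays.sum(axis=2)
    valid = (total > 0) & (total >= min_photons)
    if not valid.any():
        warnings.warn("phasor_transform: no valid pixels", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = decays @ cos_w / total
        s = decays @ sin_w / total
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorField(
        g=g, s=s, omega_rad_per_s=omega, harmonic=harmonic, total_counts=total, valid=valid
    )


def monoexp_phasor(tau_s: float, omega: float) -> tuple[float, float]:
    """Analytic phasor of a single-exponential decay.

    ``g = 1/(1+(w*tau)^2)``, ``s = w*tau/(1+(w*tau)^2)`` — exactly on the
    universal circle ``(g-1/2)^2 + s^2 = 1/4``.
    """
    if tau_s < 0:
        raise ValueError("tau must be non-negative")
    wt = omega * tau_s
    d = 1.0 + wt * wt
    return 1.0 / d, wt / d


def phase_lifetime(field: PhasorField) -> np.ndarray:
    """Phase lifetime map ``tau_phi = s / (g * omega)`` in picoseconds.

    NaN where the pixel is invalid or ``g <= 0``.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = field.s / (field.g * field.omega_rad_per_s)
    tau = np.where(field.valid & (field.g > 0), tau, np.nan)
    return tau * 1e12


def modulation_lifetime(field: PhasorField) -> np.ndarray:
    """Modulation lifetime map ``tau_m = sqrt(1/(g^2+s^2) - 1)/omega`` (ps).

    Equals the phase lifetime exactly on the universal circle; larger than
    it for interior (multi-exponential) points.  Points with
    ``g^2 + s^2 >= 1`` map to 0 ps.
    """
    m2 = field.g**2 + field.s**2
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.sqrt(np.clip(1.0 / m2 - 1.0, 0.0, None)) / field.omega_rad_per_s
    tau = np.where(field.valid & (m2 > 0), tau, np.nan)
    return tau * 1e12


def circle_residual(field: PhasorField) -> np.ndarray:
    """Signed distance to the universal semicircle.

    ``d = sqrt((g-1/2)^2 + s^2) - 1/2``: negative inside (lifetime
    mixtures), zero on the circle (single-exponential), positive outside
    (excited-state products, e.g. solvent-relaxation rise).
    """
    return np.hypot(field.g - 0.5, field.s) - 0.5


DEFAULT_G_RANGE = (-0.1, 1.1)
DEFAULT_S_RANGE = (-0.1, 0.7)


def phasor_histogram(
    field: PhasorField,
    n_bins: int = 128,
    g_range: tuple[float, float] = DEFAULT_G_RANGE,
    s_range: tuple[float, float] = DEFAULT_S_RANGE,
) -> PhasorHistogram:
    """Occupancy histogram of the valid pixels in phasor space."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    g = field.g[field.valid]
    s = field.s[field.valid]
    counts, g_edges, s_edges = np.histogram2d(
        g, s, bins=n_bins, range=[list(g_range), list(s_range)]
    )
    return PhasorHistogram(counts=counts, g_edges=g_edges, s_edges=s_edges)


def calibrate(field: PhasorField, rotation_rad: float = 0.0, scale: float = 1.0) -> PhasorField:
    """Optional instrument calibration: rotate and scale about the origin.

    Defaults to the identity; used to align a reference-dye phasor with
    its known position when working with measured (IRF-affected) data.
    """
    z = (field.g + 1j * field.s) * scale * np.exp(1j * rotation_rad)
    return PhasorField(
        g=z.real,
        s=z.imag,
        omega_rad_per_s=field.omega_rad_per_s,
        harmonic=field.harmonic,
        total_counts=field.total_counts,
        valid=field.valid,
    )
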