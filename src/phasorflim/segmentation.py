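"""Phasor-driven segmentation, intensity masks, and colocalization stats.

Circular regions of interest drawn in phasor space are remapped to the
image plane, producing masks of pixels with similar decays.  Intensity
masks keep the brightest top-N% of pixels ("2 percentile of the brightest
pixels" reads as top 2% of intensities).  Masked lifetime maps reduce to
normalized lifetime distributions whose weighted mean is
``tau_mean = sum_i tau_i * f_i_norm``.  Per-cell values aggregate as
mean +/- standard error (SD/sqrt(n), sample SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import IntensityImage, Mask
from .phasor import PhasorField

__all__ = [
    "PhasorROI",
    "LifetimeDistribution",
    "ColocalizationReport",
    "remap_phasor_roi",
    "brightest_percentile_mask",
    "lifetime_distribution",
    "tau_mean",
    "roi_pixel_fraction",
    "normalized_roi_intensity",
    "aggregate_cells",
]


@dataclass(frozen=True)
class PhasorROI:
    """Circular region of interest in (g, s) phasor space."""

    center_g: float
    center_s: float
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if not (np.isfinite(self.center_g) and np.isfinite(self.center_s)):
            raise ValueError("ROI center must be finite")


@dataclass
class LifetimeDistribution:
    """Binned lifetime frequencies normalized to 1 over a pixel population."""

    bin_centers_ps: np.ndarray
    freq_norm: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.bin_centers_ps = np.asarray(self.bin_centers_ps, dtype=float)
        self.freq_norm = np.asarray(self.freq_norm, dtype=float)
        if self.bin_centers_ps.size > 1 and not np.all(np.diff(self.bin_centers_ps) > 0):
            raise ValueError("bin centers must be strictly increasing")
        if abs(self.freq_norm.sum() - 1.0) > 1e-12:
            raise ValueError("normalized frequencies must sum to 1")


@dataclass
class ColocalizationReport:
    """Per-ROI pixel fractions, normalized co-stain intensity, lifetimes."""

    roi_labels: list[str]
    pixel_fraction_pct: dict[str, float]
    normalized_costain_intensity: dict[str, float]
    tau_mean_ps: dict[str, float]
    per_cell_values: dict[str, list[float]] = field(default_factory=dict)
    mean_se: dict[str, tuple[float, float]] = field(default_factory=dict)


def remap_phasor_roi(field_: PhasorField, roi: PhasorROI) -> Mask:
    """Image mask of valid pixels whose phasor lies inside the ROI circle."""
    d2 = (field_.g - roi.center_g) ** 2 + (field_.s - roi.center_s) ** 2
    with np.errstate(invalid="ignore"):
        flags = (d2 <= roi.radius**2) & field_.valid
    if not flags.any():
        warnings.warn(f"phasor ROI {roi.label!r} remaps to an empty mask", stacklevel=2)
    return Mask(flags, roi.label)


def brightest_percentile_mask(
    img: IntensityImage, top_percent: float, label: str = ""
) -> Mask:
    """Mask of the brightest ``top_percent`` % of pixels.

    The threshold is the ``100 - top_percent`` percentile of the intensity
    distribution; ties at the threshold are all included.
    """
    if not 0 < top_percent <= 100:
        raise ValueError("top_percent must lie in (0, 100]")
    values = img.values
    if values.size == 0:
        raise ValueError("image is empty")
    if values.min() == values.max():
        warnings.warn("constant image: brightest-percentile mask selects all pixels",
                      stacklevel=2)
        return Mask(np.ones_like(values, dtype=bool), label)
    threshold = np.percentile(values, 100.0 - top_percent)
    return Mask(values >= threshold, label)


def lifetime_distribution(
    lifetime_map: np.ndarray, mask: Mask, bin_width_ps: float = 50.0
) -> LifetimeDistribution:
    """Normalized histogram of masked (finite) lifetimes.

    Bins are aligned to multiples of ``bin_width_ps``; empty interior bins
    are kept so the support is contiguous.
    """
    if bin_width_ps <= 0:
        raise ValueError("bin_width_ps must be positive")
    values = np.asarray(lifetime_map, dtype=float)[mask.flags]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty mask (or no finite lifetimes under it)")
    lo = np.floor(values.min() / bin_width_ps) * bin_width_ps
    hi = np.ceil(values.max() / bin_width_ps) * bin_width_ps
    if hi <= lo:
        hi = lo + bin_width_ps
    edges = np.arange(lo, hi + 0.5 * bin_width_ps, bin_width_ps)
    counts, edges = np.histogram(values, bins=edges)
    freq = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return LifetimeDistribution(
        bin_centers_ps=centers, freq_norm=freq, n_pixels=int(values.size)
    )


def tau_mean(dist: LifetimeDistribution) -> float:
    """Distribution-weighted mean lifetime ``sum_i tau_i * f_i_norm`` (ps)."""
    return float(dist.bin_centers_ps @ dist.freq_norm)


def roi_pixel_fraction(probe_mask: Mask, roi_masks: list[Mask]) -> dict[str, float]:
    """Percentage of probe-labeled pixels falling inside each ROI mask.

    ``100 * |probe & roi| / |probe|`` per ROI; disjoint exhaustive ROIs
    therefore sum to at most 100%.
    """
    n_probe = probe_mask.n_pixels
    if n_probe == 0:
        raise ValueError("probe mask is empty")
    out: dict[str, float] = {}
    for roi in roi_masks:
        if roi.flags.shape != probe_mask.flags.shape:
            raise ValueError("mask shapes differ")
        out[roi.label] = 100.0 * np.count_nonzero(probe_mask.flags & roi.flags) / n_probe
    return out


def normalized_roi_intensity(
    costain: IntensityImage, roi_mask: Mask, bright_mask: Mask
) -> float:
    """Co-stain intensity in an ROI, normalized to its share of bright pixels.

    Implemented as

        N(ROI) = (sum_{p in ROI} I_p / sum_{p in image} I_p)
                 / (|bright & ROI| / |bright|)

    i.e. the ROI's share of total co-stain signal divided by the ROI's
    share of the bright-pixel population.  This is a declared
    interpretation of "normalized to the fraction of bright pixels"; the
    quantity is 1 for an ROI whose signal share matches its bright-pixel
    share.  NaN (flagged by warning) when the ROI contains no bright pixel.
    """
    if costain.values.shape != roi_mask.flags.shape != bright_mask.flags.shape:
        raise ValueError("shapes differ")
    n_bright = bright_mask.n_pixels
    if n_bright == 0:
        raise ValueError("bright mask is empty")
    n_overlap = np.count_nonzero(bright_mask.flags & roi_mask.flags)
    if n_overlap == 0:
        warnings.warn(
            f"ROI {roi_mask.label!r} contains no bright pixel; "
            "normalized intensity undefined",
            stacklevel=2,
        )
        return float("nan")
    total = costain.values.sum()
    if total == 0:
        return 0.0
    signal_share = costain.values[roi_mask.flags].sum() / total
    bright_share = n_overlap / n_bright
    return float(signal_share / bright_share)


def aggregate_cells(per_cell_values: list[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) over cells; n >= 2."""
    values = np.asarray(per_cell_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two cells to aggregate")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))
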