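"""End-to-end pipeline: simulate -> transform -> segment -> fit -> colocalize.

A run is fully described by a :class:`PipelineConfig` (loadable from
YAML/JSON) plus a seed; outputs are written to a run directory as TIFF
maps, CSV tables, and a machine-readable ``summary.json`` carrying the
config hash and seed so the run is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    FLIMImage,
    Mask,
    integrate_spectral,
    integrate_time,
    load_flim_cube,
    save_flim_cube,
    write_map_tiff,
    write_mask_tiff,
)
from .fitting import FitError, fit_biexponential, fit_monoexponential
from .phasor import circle_residual, monoexp_phasor, phase_lifetime, phasor_transform
from .segmentation import (
    PhasorROI,
    brightest_percentile_mask,
    lifetime_distribution,
    normalized_roi_intensity,
    remap_phasor_roi,
    roi_pixel_fraction,
    tau_mean,
)
from .synthetic import default_scene, render_scene

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "default_rois"]

log = logging.getLogger("phasorflim")

# spectral bands (nm): probe blue emission, solvent-relaxed green emission
# (540/50 nm detection), and the co-stain band
DEFAULT_BANDS = {
    "blue": (400.0, 475.0),
    "green": (515.0, 565.0),
    "costain": (575.0, 600.0),
    "full": (400.0, 600.0),
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (serialize with ``to_dict``)."""

    input_path: Optional[str] = None  # cube file; None -> simulate a scene
    scene: dict = field(
        default_factory=lambda: {
            "shape": [96, 96],
            "photons_per_pixel": 1e4,
            "costain_contrast": 10.0,
            "n_time_bins": 256,
        }
    )
    bands_nm: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    harmonic: int = 1
    min_photons: float = 50.0
    rois: Optional[list[dict]] = None  # None -> default_rois()
    probe_top_percent: float = 50.0
    costain_top_percent: float = 2.0
    lifetime_bin_ps: float = 50.0
    output_dir: str = "run"
    seed: int = 0
    save_cube: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands_nm.items():
            if not (400.0 <= lo <= hi <= 600.0):
                raise ValueError(f"band {name!r} must lie within 400-600 nm")
        for p in (self.probe_top_percent, self.costain_top_percent):
            if not 0 < p <= 100:
                raise ValueError("percentile thresholds must lie in (0, 100]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def default_rois(repetition_rate_hz: float = 80e6, radius: float = 0.05) -> list[PhasorROI]:
    """Circular phasor ROIs centered on the canonical compartment decays:
    gel 5.0 ns, fluid 4.0 ns, low-lifetime 3.0 ns mono points on the
    universal circle, plus the interior point of the 0.6/3.0 ns
    equal-amplitude biexponential."""
    omega = 2 * np.pi * repetition_rate_hz
    rois = []
    for label, tau_ns in (("tau_mono_gel", 5.0), ("tau_mono_fluid", 4.0), ("tau_mono_low", 3.0)):
        g, s = monoexp_phasor(tau_ns * 1e-9, omega)
        rois.append(PhasorROI(center_g=g, center_s=s, radius=radius, label=label))
    # intensity-weighted mixture of the 0.6/3.0 ns pure phasors (1/6, 5/6)
    g1, s1 = monoexp_phasor(0.6e-9, omega)
    g2, s2 = monoexp_phasor(3.0e-9, omega)
    rois.append(
        PhasorROI(
            center_g=(g1 + 5 * g2) / 6.0,
            center_s=(s1 + 5 * s2) / 6.0,
            radius=radius,
            label="tau_biexp_low",
        )
    )
    return rois


def _get_cube(config: PipelineConfig, seed: int):
    if config.input_path is not None:
        return load_flim_cube(config.input_path), None
    sc = config.scene
    from .data_model import default_metadata

    spec = default_scene(
        shape=tuple(sc.get("shape", [96, 96])),
        meta=default_metadata(n_time_bins=int(sc.get("n_time_bins", 256))),
        photons_per_pixel=float(sc.get("photons_per_pixel", 1e4)),
        costain_contrast=float(sc.get("costain_contrast", 10.0)),
        seed=seed,
    )
    img, truth = render_scene(spec)
    return img, truth


def run_pipeline(config: PipelineConfig, seed: Optional[int] = None) -> dict:
    """Execute the full pipeline and write the run directory.

    Returns the summary dictionary (also written as ``summary.json``).
    Deterministic for a fixed config + seed.
    """
    seed = config.seed if seed is None else seed
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": seed,
        },
        "config": config.to_dict(),
    }
    try:
        try:
            log.info("stage simulate/load: seed=%d", seed)
            img, truth = _get_cube(config, seed)
        except Exception as exc:  # noqa: BLE001
            raise StageError("input", str(exc)) from exc
        if config.save_cube:
            save_flim_cube(img, outdir / "cube.h5")

        try:
            log.info("stage integrate: bands=%s", config.bands_nm)
            band_decays = {
                name: integrate_spectral(img, band)[0]
                for name, band in config.bands_nm.items()
            }
            intensities = {
                name: integrate_time(img, band) for name, band in config.bands_nm.items()
            }
            for name, inten in intensities.items():
                write_map_tiff(inten.values, outdir / f"intensity_{name}.tif")
        except Exception as exc:  # noqa: BLE001
            raise StageError("integrate", str(exc)) from exc

        try:
            log.info("stage phasor: harmonic=%d min_photons=%g",
                     config.harmonic, config.min_photons)
            fields = {
                name: phasor_transform(
                    dec, img.meta, harmonic=config.harmonic, min_photons=config.min_photons
                )
                for name, dec in band_decays.items()
            }
            tau_map = phase_lifetime(fields["full"])
            write_map_tiff(np.nan_to_num(tau_map), outdir / "phase_lifetime_ps.tif")
            green_res = circle_residual(fields["green"])
            valid_green = fields["green"].valid
            mean_green_residual = (
                float(np.nanmean(green_res[valid_green])) if valid_green.any() else None
            )
            summary["phasor"] = {
                "valid_pixels": int(fields["full"].valid.sum()),
                "mean_green_circle_residual": mean_green_residual,
                "green_outside_semicircle": bool(
                    mean_green_residual is not None and mean_green_residual > 0
                ),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("phasor", str(exc)) from exc

        try:
            roi_defs = (
                [PhasorROI(**r) for r in config.rois]
                if config.rois is not None
                else default_rois(img.meta.repetition_rate_hz)
            )
            log.info("stage segment: %d phasor ROIs", len(roi_defs))
            import warnings as _warnings

            roi_masks = []
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # empty ROIs are reported in the summary
                for roi in roi_defs:
                    m = remap_phasor_roi(fields["full"], roi)
                    roi_masks.append(m)
                    write_mask_tiff(m, outdir / f"mask_{roi.label}.tif")
            probe_mask = brightest_percentile_mask(
                intensities["full"], config.probe_top_percent, label="probe"
            )
            costain_mask = brightest_percentile_mask(
                intensities["costain"], config.costain_top_percent, label="costain_bright"
            )
            write_mask_tiff(probe_mask, outdir / "mask_probe.tif")
            write_mask_tiff(costain_mask, outdir / "mask_costain_bright.tif")
        except Exception as exc:  # noqa: BLE001
            raise StageError("segment", str(exc)) from exc

        try:
            log.info("stage colocalize")
            fractions = roi_pixel_fraction(probe_mask, roi_masks)
            norm_int = {}
            dists = {}
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                for m in roi_masks:
                    norm_int[m.label] = normalized_roi_intensity(
                        intensities["costain"], m, costain_mask
                    )
                    if m.n_pixels:
                        d = lifetime_distribution(tau_map, m, config.lifetime_bin_ps)
                        dists[m.label] = tau_mean(d)
            costain_dist = lifetime_distribution(tau_map, costain_mask, config.lifetime_bin_ps)
            summary["colocalization"] = {
                "roi_pixel_fraction_pct": fractions,
                "normalized_costain_intensity": {
                    k: (None if np.isnan(v) else v) for k, v in norm_int.items()
                },
                "roi_tau_mean_ps": dists,
                "costain_mask_tau_mean_ps": tau_mean(costain_dist),
                "costain_mask_pixels": costain_dist.n_pixels,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("colocalize", str(exc)) from exc

        try:
            log.info("stage fit: per-ROI summed decays")
            rows = []
            for m in roi_masks:
                if m.n_pixels == 0:
                    continue
                hist = band_decays["full"][m.flags].sum(axis=0)
                if hist.sum() < 1000:
                    continue
                mono_fit = fit_monoexponential(hist, img.meta)
                row = {
                    "roi_label": m.label,
                    "n_pixels": m.n_pixels,
                    "mono_tau_ps": mono_fit.tau_ps,
                    "mono_residual": mono_fit.reduced_residual,
                }
                import warnings as _warnings

                try:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        bi = fit_biexponential(hist, img.meta)
                    row.update(
                        tau1_ps=bi.tau1_ps,
                        tau2_ps=bi.tau2_ps,
                        a1=bi.a1,
                        tau_amp_mean_ps=bi.tau_amp_mean_ps,
                        tau_int_mean_ps=bi.tau_int_mean_ps,
                        biexp_residual=bi.reduced_residual,
                        ill_separated=bi.ill_separated,
                    )
                except FitError as exc:
                    log.warning("biexp fit failed for ROI %s: %s", m.label, exc)
                rows.append(row)
            fit_table = pd.DataFrame(rows)
            fit_table.to_csv(outdir / "roi_fits.csv", index=False)
            summary["fits"] = rows
        except Exception as exc:  # noqa: BLE001
            raise StageError("fit", str(exc)) from exc

        if truth is not None:
            summary["ground_truth"] = {
                "compartments": {
                    name: int(m.n_pixels) for name, m in truth.true_masks.items()
                }
            }

        summary_json = json.dumps(summary, sort_keys=True, indent=2, allow_nan=False)
        (outdir / "summary.json").write_text(summary_json)
        log.info("run complete: %s", outdir / "summary.json")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
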