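"""Synthetic spectral-FLIM scene generator with exact ground truth.

Scenes are built from compartments (membrane ring, cytoplasm, lipid
droplets, acidic organelles, background), each carrying a decay model per
emission branch, a relative emission spectrum, and a photon budget.
Observed cubes are Poisson draws around the analytically known expected
counts, so every downstream stage can be validated against closed forms.

Decay physics
-------------
``mono``      exp(-t/tau), bin-integrated over the repetition window.
``biexp``     a1*exp(-t/tau1) + a2*exp(-t/tau2) with amplitude fractions
              a1 + a2 = 1; the photon (intensity) fraction of component i
              is a_i*tau_i / sum_j a_j*tau_j.
``excited_state_reaction``
              two-state relaxation: the locally excited state decays with
              total rate G_le + k_t (radiative/non-radiative plus transfer)
              feeding a relaxed state that decays with rate G_r.  The
              relaxed-state emission is proportional to
              exp(-G_r*t) - exp(-(G_le+k_t)*t), which rises from zero -- a
              non-exponential profile whose phasor falls outside the
              universal semicircle.  When the two total rates coincide the
              analytic limit ``t*exp(-G*t)`` is used.

Decays are truncated at the repetition window (no wrap-around) and
renormalized; excitation is a delta at t = 0 (no IRF convolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .data_model import AcquisitionMetadata, FLIMImage, Mask, default_metadata

__all__ = [
    "DecayModel",
    "Geometry",
    "CompartmentSpec",
    "SceneSpec",
    "GroundTruth",
    "expected_decay",
    "le_decay",
    "expected_cube",
    "render_scene",
    "poissonize",
    "gaussian_spectrum",
    "default_scene",
]

#: spectral channels with center >= this wavelength use the green-branch decay
GREEN_THRESHOLD_NM = 500.0

#: channels whose center falls in this closed band receive co-stain photons
COSTAIN_BAND_NM = (575.0, 600.0)


@dataclass(frozen=True)
class DecayModel:
    """Parametric fluorescence decay of one emission branch."""

    kind: str
    lifetimes_ns: tuple[float, ...] = ()
    amplitude_fractions: tuple[float, ...] = ()
    rate_le_per_ns: float = 0.0
    rate_transfer_per_ns: float = 0.0
    rate_r_per_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("mono", "biexp", "excited_state_reaction"):
            raise ValueError(f"unknown decay kind {self.kind!r}")
        object.__setattr__(self, "lifetimes_ns", tuple(float(t) for t in self.lifetimes_ns))
        object.__setattr__(
            self, "amplitude_fractions", tuple(float(a) for a in self.amplitude_fractions)
        )
        if self.kind == "mono":
            if len(self.lifetimes_ns) != 1:
                raise ValueError("mono decay needs exactly one lifetime")
        elif self.kind == "biexp":
            if len(self.lifetimes_ns) != 2:
                raise ValueError("biexp decay needs exactly two lifetimes")
            if len(self.amplitude_fractions) != 2:
                raise ValueError("biexp decay needs two amplitude fractions")
            if min(self.amplitude_fractions) < 0:
                raise ValueError("amplitude fractions must be non-negative")
            if abs(sum(self.amplitude_fractions) - 1.0) > 1e-12:
                raise ValueError("amplitude fractions must sum to 1")
        else:
            if min(self.rate_le_per_ns, self.rate_transfer_per_ns, self.rate_r_per_ns) <= 0:
                raise ValueError("excited_state_reaction requires all rates > 0")
        if any(t <= 0 for t in self.lifetimes_ns):
            raise ValueError("lifetimes must be positive")

    @property
    def mean_lifetime_ps(self) -> float:
        """Ground-truth mean lifetime: tau for mono, amplitude-weighted
        mean for biexp, relaxed-state lifetime for the reaction model."""
        if self.kind == "mono":
            return self.lifetimes_ns[0] * 1e3
        if self.kind == "biexp":
            a1, a2 = self.amplitude_fractions
            t1, t2 = self.lifetimes_ns
            return (a1 * t1 + a2 * t2) * 1e3
        return 1e3 / self.rate_r_per_ns


def mono(tau_ns: float) -> DecayModel:
    return DecayModel(kind="mono", lifetimes_ns=(tau_ns,))


def biexp(tau1_ns: float, tau2_ns: float, a1: float = 0.5) -> DecayModel:
    return DecayModel(
        kind="biexp", lifetimes_ns=(tau1_ns, tau2_ns), amplitude_fractions=(a1, 1.0 - a1)
    )


def _mono_bin_integrals(tau_s: float, edges_s: np.ndarray) -> np.ndarray:
    # integral of exp(-t/tau) over [t_k, t_{k+1}) divided by tau
    e = np.exp(-edges_s / tau_s)
    return e[:-1] - e[1:]


def expected_decay(
    model: DecayModel, meta: AcquisitionMetadata, branch: str = "emissive"
) -> np.ndarray:
    """Expected per-time-bin photon fractions (length n_time_bins, sum 1).

    Each fraction is the bin integral of the continuous decay, truncated at
    the repetition window and renormalized.  For the excited-state-reaction
    model the default ``branch="emissive"`` returns the relaxed-state
    (green) profile; use :func:`le_decay` for the locally excited (blue)
    branch, which is a plain mono-exponential at the LE total rate.
    """
    edges = meta.bin_edges_s
    if model.kind == "mono":
        tau = model.lifetimes_ns[0] * 1e-9
        frac = _mono_bin_integrals(tau, edges)
    elif model.kind == "biexp":
        (t1, t2) = (t * 1e-9 for t in model.lifetimes_ns)
        a1, a2 = model.amplitude_fractions
        # bin photons of component i are a_i * tau_i * (normalized mono bins)
        frac = a1 * t1 * _mono_bin_integrals(t1, edges) + a2 * t2 * _mono_bin_integrals(t2, edges)
    else:
        g_tot = (model.rate_le_per_ns + model.rate_transfer_per_ns) * 1e9
        g_r = model.rate_r_per_ns * 1e9
        if abs(g_tot - g_r) < 1e-9 * g_r:
            # degenerate limit: R(t) ~ t * exp(-g*t)
            g = g_r
            anti = -(edges / g + 1.0 / g**2) * np.exp(-g * edges)
            frac = anti[1:] - anti[:-1]
        else:
            e_r = np.exp(-g_r * edges)
            e_t = np.exp(-g_tot * edges)
            frac = (e_r[:-1] - e_r[1:]) / g_r - (e_t[:-1] - e_t[1:]) / g_tot
            frac /= g_tot - g_r  # keeps sign positive for either rate ordering
    total = frac.sum()
    if total <= 0:
        raise ValueError("decay profile has no photons inside the time window")
    frac = frac / total
    # clip tiny negative round-off
    return np.clip(frac, 0.0, None) / np.clip(frac, 0.0, None).sum()


def le_decay(model: DecayModel) -> DecayModel:
    """Locally excited (blue-branch) counterpart of a reaction model."""
    if model.kind != "excited_state_reaction":
        raise ValueError("le_decay is defined only for excited_state_reaction models")
    g_tot = model.rate_le_per_ns + model.rate_transfer_per_ns
    return mono(1.0 / g_tot)


# ---------------------------------------------------------------------------
# Geometry and scene specification


@dataclass(frozen=True)
class Geometry:
    """Parametric compartment shape.

    kind ``full``  -- every pixel (background / base layer)
    kind ``disk``  -- filled circle (center_row, center_col, radius)
    kind ``ring``  -- annulus between r_inner and r_outer around a center
    kind ``disks`` -- union of circles given as (row, col, radius) triples
    """

    kind: str
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0
    r_inner: float = 0.0
    r_outer: float = 0.0
    disks: tuple[tuple[float, float, float], ...] = ()

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        if self.kind == "full":
            return np.ones(shape, dtype=bool)
        if self.kind == "disk":
            rr = (rows - self.center[0]) ** 2 + (cols - self.center[1]) ** 2
            return rr <= self.radius**2
        if self.kind == "ring":
            rr = (rows - self.center[0]) ** 2 + (cols - self.center[1]) ** 2
            return (rr >= self.r_inner**2) & (rr <= self.r_outer**2)
        if self.kind == "disks":
            m = np.zeros(shape, dtype=bool)
            for r0, c0, rad in self.disks:
                m |= (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
            return m
        raise ValueError(f"unknown geometry kind {self.kind!r}")


@dataclass(frozen=True)
class CompartmentSpec:
    """One scene compartment: geometry plus photophysics."""

    name: str
    geometry: Geometry
    blue_decay: DecayModel
    green_decay: DecayModel
    emission_spectrum: tuple[float, ...]
    photons_per_pixel: float
    costain_intensity: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.emission_spectrum, dtype=float)
        if w.min() < 0:
            raise ValueError("spectrum weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("spectrum weights must sum to 1")
        if self.photons_per_pixel < 0:
            raise ValueError("photons_per_pixel must be non-negative")
        object.__setattr__(self, "emission_spectrum", tuple(float(x) for x in w))


@dataclass(frozen=True)
class SceneSpec:
    """Ordered compartment overlay; later entries overwrite earlier ones."""

    image_shape: tuple[int, int]
    compartments: tuple[CompartmentSpec, ...]
    meta: AcquisitionMetadata
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")
        if not self.compartments:
            raise ValueError("scene needs at least one compartment")
        if self.compartments[0].geometry.kind != "full":
            raise ValueError("first compartment must cover the full frame (kind 'full')")
        object.__setattr__(self, "compartments", tuple(self.compartments))


@dataclass
class GroundTruth:
    """Per-pixel truth for a rendered scene."""

    compartment_map: np.ndarray  # int labels = index into spec.compartments
    true_lifetime_map: np.ndarray  # mean lifetime in ps (blue-branch model)
    true_masks: dict[str, Mask]
    costain_map: np.ndarray  # expected co-stain photons per pixel


def gaussian_spectrum(
    meta: AcquisitionMetadata, center_nm: float, sigma_nm: float = 30.0
) -> tuple[float, ...]:
    """Normalized Gaussian emission weights over the detector channels."""
    c = np.asarray(meta.channel_centers_nm)
    w = np.exp(-0.5 * ((c - center_nm) / sigma_nm) ** 2)
    return tuple(w / w.sum())


def poissonize(expected: np.ndarray, seed: int) -> np.ndarray:
    """Elementwise Poisson draws from a non-negative expectation array."""
    expected = np.asarray(expected, dtype=float)
    if expected.size and expected.min() < 0:
        raise ValueError("expected counts must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.int64)


def _label_map(spec: SceneSpec) -> np.ndarray:
    labels = np.zeros(spec.image_shape, dtype=np.int32)
    for i, comp in enumerate(spec.compartments):
        labels[comp.geometry.rasterize(spec.image_shape)] = i
    return labels


def expected_cube(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Noiseless expected photon-count cube and the scene ground truth.

    Per pixel of compartment ``c`` the expectation in channel ``ch`` and
    time bin ``k`` is ``photons_per_pixel * spectrum[ch] * decay_frac[k]``,
    using the blue-branch decay for channel centers < 500 nm and the
    green branch otherwise.  Co-stain photons (``photons_per_pixel *
    costain_intensity``) are split evenly over the 575-600 nm channels with
    a green-branch time profile.
    """
    meta = spec.meta
    labels = _label_map(spec)
    centers = np.asarray(meta.channel_centers_nm)
    is_green = centers >= GREEN_THRESHOLD_NM
    in_costain = (centers >= COSTAIN_BAND_NM[0]) & (centers <= COSTAIN_BAND_NM[1])
    n_costain = int(in_costain.sum())

    cube = np.zeros(spec.image_shape + (meta.n_channels, meta.n_time_bins))
    lifetime = np.zeros(spec.image_shape)
    costain = np.zeros(spec.image_shape)
    masks: dict[str, Mask] = {}
    for i, comp in enumerate(spec.compartments):
        mask = labels == i
        masks[comp.name] = Mask(mask, comp.name)
        if not mask.any():
            continue
        lifetime[mask] = comp.blue_decay.mean_lifetime_ps
        if comp.photons_per_pixel == 0:
            continue
        blue_prof = expected_decay(comp.blue_decay, meta)
        green_prof = expected_decay(comp.green_decay, meta)
        per_channel = np.empty((meta.n_channels, meta.n_time_bins))
        w = np.asarray(comp.emission_spectrum)
        for ch in range(meta.n_channels):
            prof = green_prof if is_green[ch] else blue_prof
            per_channel[ch] = comp.photons_per_pixel * w[ch] * prof
        if comp.costain_intensity > 0 and n_costain:
            extra = comp.photons_per_pixel * comp.costain_intensity / n_costain
            per_channel[in_costain] += extra * green_prof
            costain[mask] = comp.photons_per_pixel * comp.costain_intensity
        cube[mask] = per_channel
    truth = GroundTruth(
        compartment_map=labels,
        true_lifetime_map=lifetime,
        true_masks=masks,
        costain_map=costain,
    )
    return cube, truth


def render_scene(spec: SceneSpec) -> tuple[FLIMImage, GroundTruth]:
    """Poisson-noised cube rendered from a scene spec (deterministic per seed)."""
    cube, truth = expected_cube(spec)
    counts = poissonize(cube, spec.seed)
    return FLIMImage(counts=counts, meta=spec.meta), truth


def default_scene(
    shape: tuple[int, int] = (96, 96),
    meta: Optional[AcquisitionMetadata] = None,
    photons_per_pixel: float = 1e4,
    seed: int = 0,
    costain_contrast: float = 10.0,
    green_rise: bool = False,
) -> SceneSpec:
    """PC-12-like default scene.

    A cell disk with a gel-phase plasma-membrane ring (mono 5.0 ns, ring
    thickness 3 px), fluid cytoplasm (mono 4.0 ns), spherical lipid
    droplets (mono 3.0 ns, bright in the 575-600 nm co-stain band), and
    acidic organelles with a biexponential 0.6 ns + 3.0 ns decay (equal
    amplitude fractions, amplitude-weighted mean 1.8 ns) that are also
    co-stain positive.  Droplet radii 3-6 px and the 10:1 co-stain
    contrast are configuration defaults, not measured values.

    With ``green_rise=True`` the viscous compartments (membrane ring and
    cytoplasm) emit a rising excited-state-reaction profile in the green
    branch -- slow solvent relaxation -- whose phasor falls outside the
    universal semicircle.
    """
    if meta is None:
        meta = default_metadata(n_time_bins=256)
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    cell_r = 0.42 * min(shape)
    blue_spec = gaussian_spectrum(meta, 440.0)
    droplet_r = 0.30 * cell_r
    # slow relaxed-state decay fed from the LE state at a comparable rate
    rise = DecayModel(
        kind="excited_state_reaction",
        rate_le_per_ns=0.5,
        rate_transfer_per_ns=0.5,
        rate_r_per_ns=1.0 / 3.0,
    )
    cyto_green = rise if green_rise else mono(4.0)
    ring_green = rise if green_rise else mono(5.0)
    if green_rise:
        # relaxed-state emission is red-shifted: give the viscous
        # compartments a second emission band around 540 nm
        g540 = np.asarray(gaussian_spectrum(meta, 540.0, 25.0))
        viscous_spec = tuple(0.65 * np.asarray(blue_spec) + 0.35 * g540)
    else:
        viscous_spec = blue_spec
    comps = (
        CompartmentSpec(
            name="background",
            geometry=Geometry(kind="full"),
            blue_decay=mono(4.0),
            green_decay=mono(4.0),
            emission_spectrum=blue_spec,
            photons_per_pixel=0.0,
        ),
        CompartmentSpec(
            name="cytoplasm",
            geometry=Geometry(kind="disk", center=(r0, c0), radius=cell_r - 3.0),
            blue_decay=mono(4.0),
            green_decay=cyto_green,
            emission_spectrum=viscous_spec,
            photons_per_pixel=photons_per_pixel,
            costain_intensity=0.1,
        ),
        CompartmentSpec(
            name="membrane_ring",
            geometry=Geometry(
                kind="ring", center=(r0, c0), r_inner=cell_r - 3.0, r_outer=cell_r
            ),
            blue_decay=mono(5.0),
            green_decay=ring_green,
            emission_spectrum=viscous_spec,
            photons_per_pixel=photons_per_pixel,
            costain_intensity=0.1,
        ),
        CompartmentSpec(
            name="lipid_droplet",
            geometry=Geometry(
                kind="disks",
                disks=(
                    (r0 - 0.45 * cell_r, c0 - 0.35 * cell_r, droplet_r),
                    (r0 + 0.15 * cell_r, c0 + 0.45 * cell_r, 0.8 * droplet_r),
                    (r0 + 0.45 * cell_r, c0 - 0.25 * cell_r, 0.6 * droplet_r),
                ),
            ),
            blue_decay=mono(3.0),
            green_decay=mono(3.0),
            emission_spectrum=gaussian_spectrum(meta, 470.0),
            photons_per_pixel=photons_per_pixel,
            costain_intensity=costain_contrast * 0.1,
        ),
        CompartmentSpec(
            name="acidic_organelle",
            geometry=Geometry(
                kind="disks",
                disks=(
                    (r0 - 0.1 * cell_r, c0 + 0.1 * cell_r, 0.7 * droplet_r),
                    (r0 + 0.5 * cell_r, c0 + 0.1 * cell_r, 0.5 * droplet_r),
                ),
            ),
            blue_decay=biexp(0.6, 3.0),
            green_decay=biexp(0.6, 3.0),
            emission_spectrum=gaussian_spectrum(meta, 480.0),
            photons_per_pixel=photons_per_pixel,
            costain_intensity=costain_contrast * 0.1,
        ),
    )
    return SceneSpec(image_shape=shape, compartments=comps, meta=meta, seed=seed)
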