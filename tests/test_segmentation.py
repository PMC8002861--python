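import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasorflim import IntensityImage, Mask, default_metadata
from phasorflim.phasor import monoexp_phasor, phasor_transform
from phasorflim.segmentation import (
    LifetimeDistribution,
    PhasorROI,
    aggregate_cells,
    brightest_percentile_mask,
    lifetime_distribution,
    normalized_roi_intensity,
    remap_phasor_roi,
    roi_pixel_fraction,
    tau_mean,
)


@pytest.fixture(scope="module")
def noiseless_field(noiseless_scene, scene_spec):
    """Full-band phasor field of the expected (noise-free) scene."""
    cube, truth = noiseless_scene
    decays = cube.sum(axis=2)
    field = phasor_transform(decays, scene_spec.meta, min_photons=1.0)
    return field, truth


class TestRemapPhasorROI:
    def test_membrane_ring_recovered_exactly(self, noiseless_field, scene_spec):
        field, truth = noiseless_field
        g, s = monoexp_phasor(5e-9, scene_spec.meta.omega())
        roi = PhasorROI(center_g=g, center_s=s, radius=0.02, label="gel")
        mask = remap_phasor_roi(field, roi)
        np.testing.assert_array_equal(mask.flags, truth.true_masks["membrane_ring"].flags)

    def test_all_compartments_recovered(self, noiseless_field, scene_spec):
        field, truth = noiseless_field
        omega = scene_spec.meta.omega()
        for name, tau in [("cytoplasm", 4e-9), ("lipid_droplet", 3e-9)]:
            g, s = monoexp_phasor(tau, omega)
            mask = remap_phasor_roi(field, PhasorROI(g, s, 0.02, name))
            np.testing.assert_array_equal(mask.flags, truth.true_masks[name].flags)

    def test_tiny_radius_empty_with_warning(self, noiseless_field):
        field, _ = noiseless_field
        with pytest.warns(UserWarning, match="empty"):
            mask = remap_phasor_roi(field, PhasorROI(0.0, 0.0, 1e-9, "nowhere"))
        assert mask.n_pixels == 0

    def test_whole_plane_roi_selects_all_valid(self, noiseless_field):
        field, _ = noiseless_field
        mask = remap_phasor_roi(field, PhasorROI(0.5, 0.0, 10.0, "everything"))
        assert mask.n_pixels == int(field.valid.sum())

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            PhasorROI(0.5, 0.2, 0.0, "bad")


class TestBrightestPercentileMask:
    def test_exact_count_distinct_values(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(10_000).reshape(100, 100).astype(float)
        mask = brightest_percentile_mask(IntensityImage(values, (575, 600)), 2.0)
        assert mask.n_pixels == 200

    def test_top_100_percent_selects_all(self):
        values = np.arange(16.0).reshape(4, 4)
        mask = brightest_percentile_mask(IntensityImage(values, (575, 600)), 100.0)
        assert mask.n_pixels == 16

    def test_constant_image_warns_and_selects_all(self):
        values = np.full((5, 5), 3.0)
        with pytest.warns(UserWarning, match="constant"):
            mask = brightest_percentile_mask(IntensityImage(values, (575, 600)), 2.0)
        assert mask.n_pixels == 25

    def test_droplet_mask_subset_of_truth(self, rendered_scene):
        from phasorflim import integrate_time

        img, truth = rendered_scene
        inten = integrate_time(img, (575, 600))
        costain_positive = (
            truth.true_masks["lipid_droplet"].flags
            | truth.true_masks["acidic_organelle"].flags
        )
        assert costain_positive.mean() > 0.02  # droplets occupy > 2% of area
        mask = brightest_percentile_mask(inten, 2.0)
        assert np.all(costain_positive[mask.flags])

    @given(st.integers(min_value=1, max_value=99), st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=30, deadline=None)
    def test_cardinality_matches_sort_oracle(self, top_percent, seed):
        rng = np.random.default_rng(seed)
        values = rng.permutation(400).reshape(20, 20).astype(float)
        mask = brightest_percentile_mask(IntensityImage(values, (575, 600)), float(top_percent))
        # oracle: sort and count values >= the (100-p) percentile
        thr = np.percentile(values, 100 - top_percent)
        assert mask.n_pixels == int(np.sum(np.sort(values.ravel()) >= thr))

    def test_invalid_percent(self):
        img = IntensityImage(np.arange(4.0).reshape(2, 2), (575, 600))
        with pytest.raises(ValueError):
            brightest_percentile_mask(img, 0.0)
        with pytest.raises(ValueError):
            brightest_percentile_mask(img, 101.0)


class TestLifetimeDistribution:
    def test_constant_map_single_bin(self):
        lt = np.full((10, 10), 3000.0)
        dist = lifetime_distribution(lt, Mask(np.ones((10, 10), bool)), 50.0)
        assert dist.freq_norm.max() == pytest.approx(1.0)
        assert dist.n_pixels == 100

    def test_two_equal_populations(self):
        lt = np.empty((2, 10))
        lt[0] = 2910.0
        lt[1] = 3110.0
        dist = lifetime_distribution(lt, Mask(np.ones((2, 10), bool)), 100.0)
        occupied = dist.freq_norm[dist.freq_norm > 0]
        np.testing.assert_allclose(occupied, [0.5, 0.5])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            lifetime_distribution(np.ones((4, 4)), Mask(np.zeros((4, 4), bool)), 50.0)

    def test_nan_lifetimes_ignored(self):
        lt = np.full((4, 4), 2000.0)
        lt[0, 0] = np.nan
        dist = lifetime_distribution(lt, Mask(np.ones((4, 4), bool)), 50.0)
        assert dist.n_pixels == 15

    def test_mode_at_true_droplet_lifetime(self, rendered_scene, scene_spec):
        from phasorflim import integrate_spectral
        from phasorflim.phasor import phase_lifetime

        img, truth = rendered_scene
        decays, _ = integrate_spectral(img, (400, 600))
        field = phasor_transform(decays, scene_spec.meta)
        tau_map = phase_lifetime(field)
        dist = lifetime_distribution(tau_map, truth.true_masks["lipid_droplet"], 50.0)
        mode = dist.bin_centers_ps[np.argmax(dist.freq_norm)]
        assert mode == pytest.approx(3000, abs=100)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(1)
        lt = rng.normal(3000, 150, (30, 30))
        dist = lifetime_distribution(lt, Mask(np.ones((30, 30), bool)), 50.0)
        assert dist.freq_norm.sum() == pytest.approx(1.0, abs=1e-12)


class TestTauMean:
    def test_delta_distribution(self):
        dist = LifetimeDistribution(np.array([2973.0]), np.array([1.0]), 10)
        assert tau_mean(dist) == pytest.approx(2973.0)

    def test_symmetric_two_bins(self):
        dist = LifetimeDistribution(np.array([2900.0, 3100.0]), np.array([0.5, 0.5]), 20)
        assert tau_mean(dist) == pytest.approx(3000.0)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_bounded_by_support(self, data):
        n = data.draw(st.integers(min_value=1, max_value=12))
        centers = np.cumsum(
            data.draw(
                st.lists(
                    st.floats(min_value=1, max_value=500), min_size=n, max_size=n
                )
            )
        )
        weights = np.array(
            data.draw(
                st.lists(
                    st.floats(min_value=1e-3, max_value=1.0), min_size=n, max_size=n
                )
            )
        )
        freq = weights / weights.sum()
        freq[-1] += 1.0 - freq.sum()  # exact normalization
        dist = LifetimeDistribution(centers, freq, n)
        m = tau_mean(dist)
        assert centers.min() - 1e-9 <= m <= centers.max() + 1e-9

    def test_refinement_invariance(self):
        # binning a continuous sample at 50 vs 25 ps moves tau_mean by
        # less than one coarse bin width
        rng = np.random.default_rng(2)
        lt = rng.normal(3000, 200, (50, 50))
        mask = Mask(np.ones((50, 50), bool))
        m50 = tau_mean(lifetime_distribution(lt, mask, 50.0))
        m25 = tau_mean(lifetime_distribution(lt, mask, 25.0))
        assert abs(m50 - m25) < 50.0


class TestRoiPixelFraction:
    def test_identity_roi(self):
        probe = Mask(np.eye(8, dtype=bool), "probe")
        rois = [Mask(np.eye(8, dtype=bool), "ROI 1"), Mask(np.zeros((8, 8), bool), "ROI 2")]
        frac = roi_pixel_fraction(probe, rois)
        assert frac["ROI 1"] == pytest.approx(100.0)
        assert frac["ROI 2"] == pytest.approx(0.0)

    def test_partition_sums_to_at_most_100(self, noiseless_field, scene_spec):
        field, truth = noiseless_field
        probe = Mask(truth.compartment_map > 0, "probe")
        rois = [truth.true_masks[n] for n in truth.true_masks]
        frac = roi_pixel_fraction(probe, rois)
        assert sum(frac.values()) <= 100.0 + 1e-9

    def test_fractions_match_truth_areas(self, rendered_scene):
        _, truth = rendered_scene
        probe = Mask(truth.compartment_map > 0, "probe")
        rois = [truth.true_masks["cytoplasm"], truth.true_masks["lipid_droplet"]]
        frac = roi_pixel_fraction(probe, rois)
        n_probe = probe.n_pixels
        assert frac["cytoplasm"] == pytest.approx(
            100 * truth.true_masks["cytoplasm"].n_pixels / n_probe
        )

    def test_empty_probe_raises(self):
        with pytest.raises(ValueError, match="empty"):
            roi_pixel_fraction(Mask(np.zeros((4, 4), bool)), [Mask(np.ones((4, 4), bool))])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            roi_pixel_fraction(Mask(np.ones((4, 4), bool)), [Mask(np.ones((5, 5), bool))])


class TestNormalizedRoiIntensity:
    def test_whole_image_roi_is_one(self):
        values = np.full((10, 10), 2.0)
        whole = Mask(np.ones((10, 10), bool), "all")
        out = normalized_roi_intensity(IntensityImage(values, (575, 600)), whole, whole)
        assert out == pytest.approx(1.0)

    def test_concentrated_signal_half_bright(self):
        # all co-stain signal inside an ROI holding half the bright pixels
        values = np.zeros((4, 4))
        values[0, :2] = 10.0
        roi = np.zeros((4, 4), bool)
        roi[0, :2] = True
        bright = np.zeros((4, 4), bool)
        bright[0, :4] = True  # 4 bright pixels, 2 inside the ROI
        out = normalized_roi_intensity(
            IntensityImage(values, (575, 600)), Mask(roi, "roi"), Mask(bright, "bright")
        )
        assert out == pytest.approx(2.0)

    def test_zero_costain_roi(self):
        values = np.zeros((4, 4))
        values[3, 3] = 5.0
        roi = np.zeros((4, 4), bool)
        roi[0, 0] = True
        bright = np.ones((4, 4), bool)
        out = normalized_roi_intensity(
            IntensityImage(values, (575, 600)), Mask(roi), Mask(bright)
        )
        assert out == pytest.approx(0.0)

    def test_no_bright_overlap_is_nan_with_warning(self):
        values = np.ones((4, 4))
        roi = np.zeros((4, 4), bool)
        roi[0, 0] = True
        bright = np.zeros((4, 4), bool)
        bright[3, 3] = True
        with pytest.warns(UserWarning, match="no bright pixel"):
            out = normalized_roi_intensity(
                IntensityImage(values, (575, 600)), Mask(roi), Mask(bright)
            )
        assert np.isnan(out)


class TestAggregateCells:
    def test_constant(self):
        mean, se = aggregate_cells([3, 3, 3])
        assert mean == 3
        assert se == 0

    def test_two_values(self):
        mean, se = aggregate_cells([2, 4])
        assert mean == pytest.approx(3.0)
        assert se == pytest.approx(1.0)  # SD = sqrt(2), SE = 1

    def test_single_value_raises(self):
        with pytest.raises(ValueError):
            aggregate_cells([3])

    def test_sampling_property(self):
        rng = np.random.default_rng(123)
        draws = rng.normal(2973, 130, 25)
        mean, se = aggregate_cells(list(draws))
        assert abs(mean - 2973) < 3 * se


class TestColocalizationOrdering:
    def test_costain_intensity_ordering(self, rendered_scene, scene_spec):
        """Normalized co-stain intensity must be maximal in the ROI
        engineered to colocalize with the co-stain (droplets), and the
        probe-pixel fraction highest in the dominant compartment ROI."""
        from phasorflim import integrate_spectral, integrate_time

        img, truth = rendered_scene
        decays, _ = integrate_spectral(img, (400, 600))
        field = phasor_transform(decays, scene_spec.meta)
        omega = scene_spec.meta.omega()
        rois = {}
        for label, tau in [("fluid", 4e-9), ("low", 3e-9)]:
            g, s = monoexp_phasor(tau, omega)
            rois[label] = remap_phasor_roi(field, PhasorROI(g, s, 0.03, label))
        costain = integrate_time(img, (575, 600))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bright = brightest_percentile_mask(costain, 50.0)
            n_fluid = normalized_roi_intensity(costain, rois["fluid"], bright)
            n_low = normalized_roi_intensity(costain, rois["low"], bright)
        assert n_low > n_fluid  # droplet ROI colocalizes with co-stain
        probe = Mask(truth.compartment_map > 0, "probe")
        frac = roi_pixel_fraction(probe, list(rois.values()))
        assert frac["fluid"] > frac["low"]  # cytoplasm dominates the scene
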