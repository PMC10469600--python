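"""Colony masking, radial distance fields and binned profiles."""

import numpy as np
import pytest

from dualreporter import colony as cm
from dualreporter import synth
from tests.conftest import brute_force_profile


def disk_mask_geometry(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


class TestMaskColony:
    @pytest.mark.parametrize("seed", range(3))
    def test_disk_mask_area_and_centroid_match_ground_truth(self, seed):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(300, 300), radius=100.0, boundary_amplitude=0.0,
            noise_sd=0.02 * (30000 - 12000), seed=seed))
        mask = cm.mask_colony(colony.image.brightfield)
        true_area = np.pi * 100.0**2
        assert abs(mask.area - true_area) / true_area < 0.05
        err = np.hypot(mask.centroid[0] - colony.true_center[0],
                       mask.centroid[1] - colony.true_center[1])
        assert err < 1.0

    def test_constant_image_raises_no_colony_found(self):
        with pytest.raises(cm.NoColonyFound):
            cm.mask_colony(np.full((100, 100), 500.0))

    def test_interior_dark_hole_is_filled_into_a_single_component(self):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(300, 300), radius=100.0, boundary_amplitude=0.0,
            noise_sd=50.0, seed=3))
        bf = colony.image.brightfield.astype(float)
        hole = disk_mask_geometry(bf.shape, (149.5, 149.5), 20)
        bf[hole] = 30000.0  # agar-level blob inside the colony
        mask = cm.mask_colony(bf)
        assert mask.mask[hole].all()
        from scipy import ndimage as ndi
        _, n_comp = ndi.label(mask.mask)
        assert n_comp == 1

    def test_irregular_boundary_colony_still_recovered(self):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(300, 300), radius=90.0, boundary_amplitude=0.05, seed=4))
        mask = cm.mask_colony(colony.image.brightfield)
        true_area = colony.true_mask.sum()
        assert abs(mask.area - true_area) / true_area < 0.05

    def test_works_for_bright_colony_on_dark_agar(self):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(300, 300), radius=80.0, boundary_amplitude=0.0,
            agar_level=5000.0, colony_level=25000.0, seed=5))
        mask = cm.mask_colony(colony.image.brightfield)
        assert abs(mask.area - np.pi * 80**2) / (np.pi * 80**2) < 0.05


class TestRadialDistanceField:
    def exact_mask(self, shape, center, radius):
        mask_arr = disk_mask_geometry(shape, center, radius)
        return cm.ColonyMask(mask=mask_arr, centroid=center,
                             boundary=np.argwhere(mask_arr).astype(float),
                             mean_radius=radius)

    def test_centroid_pixel_is_zero_percent(self):
        mask = self.exact_mask((101, 101), (50.0, 50.0), 30.0)
        field = cm.radial_distance_field(mask)
        assert field.percent[50, 50] == 0.0
        assert np.all(field.percent >= 0)

    def test_circle_boundary_sits_at_100_percent(self):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(300, 300), radius=100.0, boundary_amplitude=0.0, seed=6))
        mask = cm.mask_colony(colony.image.brightfield)
        field = cm.radial_distance_field(mask)
        boundary_vals = [field.percent[int(round(r)), int(round(c))]
                         for r, c in mask.boundary]
        assert np.mean(boundary_vals) == pytest.approx(100.0, abs=1.0)

    def test_ellipse_boundary_spans_100_with_mean_near_100(self):
        rr, cc = np.mgrid[0:201, 0:301]
        ellipse = ((rr - 100) / 50.0) ** 2 + ((cc - 150) / 100.0) ** 2 <= 1.0
        from skimage import measure
        boundary = max(measure.find_contours(ellipse.astype(float), 0.5), key=len)
        radii = np.hypot(boundary[:, 0] - 100, boundary[:, 1] - 150)
        mask = cm.ColonyMask(mask=ellipse, centroid=(100.0, 150.0),
                             boundary=boundary, mean_radius=float(radii.mean()))
        field = cm.radial_distance_field(mask)
        vals = np.array([field.percent[int(round(r)), int(round(c))] for r, c in boundary])
        assert vals.min() < 100 < vals.max()
        assert vals.mean() == pytest.approx(100.0, abs=2.0)


class TestRadialProfile:
    def field_for(self, colony):
        image = colony if isinstance(colony, cm.ColonyImage) else colony.image
        mask = cm.mask_colony(image.brightfield)
        return cm.radial_distance_field(mask)

    def test_uniform_channel_gives_flat_profile(self):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(300, 300), radius=100.0, noise_sd=0.0, background=0.0,
            boundary_amplitude=0.0, channels={"u": synth.Uniform(level=3000.0)},
            seed=7))
        field = self.field_for(colony)
        prof = cm.radial_profile(colony.image.channels, field)
        inside = prof.bins <= 95
        assert np.allclose(prof.means["u"][inside], 3000.0)

    def test_binned_means_equal_brute_force_group_by_oracle(self):
        rng = np.random.default_rng(0)
        channel = rng.uniform(0, 1000, size=(60, 60))
        mask_arr = disk_mask_geometry((60, 60), (29.5, 29.5), 20)
        mask = cm.ColonyMask(mask=mask_arr, centroid=(29.5, 29.5),
                             boundary=np.argwhere(mask_arr).astype(float),
                             mean_radius=20.0)
        field = cm.radial_distance_field(mask)
        prof = cm.radial_profile(channel, field, bin_resolution=1.0, max_percent=120.0)
        bins, counts, means = brute_force_profile(channel, field.percent, 1.0, 120.0)
        assert np.array_equal(prof.bins, bins)
        assert np.array_equal(prof.counts, counts)
        assert np.allclose(prof.means["signal"], means, rtol=0, atol=1e-10)

    def test_ring_profile_argmax_recovered_within_2_percent(self, ring_colony):
        field = self.field_for(ring_colony)
        prof = cm.radial_profile(ring_colony.image.channels, field)
        assert abs(prof.argmax_bin("ring") - 50.0) <= 2.0

    def test_no_bin_beyond_max_percent(self, ring_colony):
        field = self.field_for(ring_colony)
        prof = cm.radial_profile(ring_colony.image.channels["ring"], field,
                                 max_percent=120.0)
        assert prof.bins.max() <= 120.0

    def test_profile_invariant_to_90_degree_rotation(self, ring_colony):
        field = self.field_for(ring_colony)
        prof = cm.radial_profile({"ring": ring_colony.image.channels["ring"]}, field)
        rot = cm.ColonyImage(
            brightfield=np.rot90(ring_colony.image.brightfield).copy(),
            channels={"ring": np.rot90(ring_colony.image.channels["ring"]).copy()})
        field_r = self.field_for(rot)
        prof_r = cm.radial_profile(rot.channels, field_r)
        n = min(prof.bins.size, prof_r.bins.size)
        assert np.array_equal(prof.bins[:n], prof_r.bins[:n])
        scale = max(prof.means["ring"].max(), 1.0)
        assert np.allclose(prof.means["ring"][:n], prof_r.means["ring"][:n],
                           atol=0.02 * scale)

    @pytest.mark.parametrize("channel_fn", [
        synth.CenterPeaked(),
        synth.EdgePeaked(),
        synth.Ring(center=25.0),
        synth.Ring(center=75.0),
    ])
    def test_recovered_profile_tracks_generating_function(self, channel_fn):
        colony = synth.make_colony(synth.ColonySpec(
            shape=(384, 384), radius=120.0, channels={"ch": channel_fn}, seed=13))
        field = self.field_for(colony)
        prof = cm.radial_profile(colony.image.channels, field)
        truth = colony.true_profile.set_index("percent_radius")
        common = [b for b, c in zip(prof.bins, prof.counts)
                  if c >= 20 and b in truth.index and truth.loc[b, "n_pixels"] >= 20]
        expected = truth.loc[common, "mean_ch"].to_numpy()
        observed = prof.means["ch"][np.isin(prof.bins, common)]
        assert np.corrcoef(expected, observed)[0, 1] > 0.9
        # the recovered peak matches the generator's own binned peak
        true_peak = truth["mean_ch"].idxmax()
        assert abs(prof.argmax_bin("ch") - true_peak) <= 2.0

    def test_shape_mismatch_raises(self, ring_colony):
        field = self.field_for(ring_colony)
        with pytest.raises(cm.ProfileError):
            cm.radial_profile(np.zeros((10, 10)), field)


class TestNormalizeProfile:
    def make_profile(self):
        bins = np.arange(0.0, 121.0)
        means = {"a": np.linspace(10, 50, bins.size)}
        return cm.RadialProfile(bins=bins, counts=np.ones(bins.size, dtype=int),
                                means=means, bin_resolution=1.0, max_percent=120.0)

    def test_max_mode_puts_peak_inside_colony_at_one(self):
        prof = cm.normalize_profile(self.make_profile(), mode="max")
        inside = prof.bins <= 100
        assert prof.means["a"][inside].max() == pytest.approx(1.0)
        assert prof.normalization["a"] > 0

    def test_fixed_constant_divides_all_bins(self):
        base = self.make_profile()
        prof = cm.normalize_profile(base, mode=2.0)
        assert np.allclose(prof.means["a"], base.means["a"] / 2.0)

    def test_normalization_preserves_argmax(self):
        base = self.make_profile()
        prof = cm.normalize_profile(base, mode="max")
        assert np.argmax(prof.means["a"]) == np.argmax(base.means["a"])

    def test_zero_constant_raises(self):
        with pytest.raises(cm.ProfileError):
            cm.normalize_profile(self.make_profile(), mode=0.0)
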