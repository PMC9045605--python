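import numpy as np
import pytest
from scipy import ndimage as ndi

from histostack.io import SectionImage
from histostack.phantom import (
    PhantomSpec,
    build_phantom_dataset,
    distort_section,
    generate_label_volume,
    parse_interval,
    render_section,
    write_phantom,
)
from histostack.register2d import apply_transform, compose, invert


SMALL = dict(grid_shape=(64, 64, 18), vessel_count=3, vessel_radius_range=(2.0, 3.5))


class TestGeometry:
    def test_no_vessels_empty_volume(self):
        spec = PhantomSpec(seed=1, **{**SMALL, "vessel_count": 0})
        _, vessels = generate_label_volume(spec)
        assert not vessels.voxels.any()

    def test_determinism_bit_identical(self):
        a = generate_label_volume(PhantomSpec(seed=7, **SMALL))
        b = generate_label_volume(PhantomSpec(seed=7, **SMALL))
        np.testing.assert_array_equal(a[0].voxels, b[0].voxels)
        np.testing.assert_array_equal(a[1].voxels, b[1].voxels)

    def test_vessel_component_count_matches_request(self):
        spec = PhantomSpec(seed=2, grid_shape=(128, 128, 30), vessel_count=5, vessel_radius_range=(2.0, 4.0))
        _, vessels = generate_label_volume(spec)
        _, n = ndi.label(vessels.voxels, structure=np.ones((3, 3, 3)))
        assert n == 5

    def test_background_surrounds_brain(self):
        labels, _ = generate_label_volume(PhantomSpec(seed=3, **SMALL))
        border = labels.voxels.copy()
        border[:, 2:-2, 2:-2] = 0
        assert border.max() == 0  # in-plane border is background

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_label_volume(PhantomSpec(seed=0, grid_shape=(16, 16, 4)))


class TestRender:
    def test_noiseless_render_is_exact_lookup(self, small_phantom):
        z = 5
        labels = small_phantom.truth.label_volume.voxels[z]
        vessels = small_phantom.truth.vessel_volume.voxels[z]
        profile = {0: (200.0, 0.0), 1: (50.0, 0.0), 2: (100.0, 0.0), 3: (150.0, 0.0)}
        sec = render_section(labels, vessels, profile, z)
        lookup = np.choose(labels, [200.0, 50.0, 100.0, 150.0])
        lookup[vessels > 0] = 200.0
        np.testing.assert_array_equal(sec.pixels, lookup)

    def test_drift_is_linear_in_slice_index(self, small_phantom):
        labels = small_phantom.truth.label_volume.voxels[9]
        vessels = np.zeros_like(labels, dtype=bool)
        profile = {0: (200.0, 0.0), 1: (50.0, 0.0), 2: (100.0, 0.0), 3: (150.0, 0.0)}
        s0 = render_section(labels, vessels, profile, 0, drift_rate=0.5)
        s10 = render_section(labels, vessels, profile, 10, drift_rate=0.5)
        tissue = labels > 0
        diff = s10.pixels[tissue].mean() - s0.pixels[tissue].mean()
        assert diff == pytest.approx(5.0, abs=1e-9)

    def test_noise_sd_matches_request(self):
        labels = np.ones((128, 128), dtype=np.int16)
        vessels = np.zeros_like(labels, dtype=bool)
        sec = render_section(labels, vessels, {0: (200.0, 0.0), 1: (100.0, 2.0)}, 0, noise_seed=4)
        assert sec.pixels.std() == pytest.approx(2.0, rel=0.1)

    def test_missing_class_rejected(self):
        labels = np.array([[0, 1], [2, 0]])
        with pytest.raises(KeyError, match="2"):
            render_section(labels, np.zeros_like(labels, bool), {0: (1, 0), 1: (2, 0)}, 0)


class TestDistort:
    def _section(self, seed=0, n=64):
        r = np.random.default_rng(seed)
        return SectionImage(ndi.gaussian_filter(r.random((n, n)), 2) * 200, 200.0, "nissl", 0)

    def test_zero_amplitude_is_identity(self):
        sec = self._section()
        out, t = distort_section(sec, 0.0, (0.0, 0.0), seed=1)
        assert t.is_identity()
        np.testing.assert_allclose(out.pixels, sec.pixels, atol=1e-9)

    def test_mean_displacement_magnitude(self):
        # desk-scale raster: amplitude 10 px is realizable without the
        # invertibility safety rescale
        _, t = distort_section(self._section(n=128), 10.0, (0.0, 0.0), seed=5)
        mag = np.sqrt((t.field**2).sum(axis=0)).mean()
        assert 9.0 <= mag <= 11.0

    def test_same_seed_identical(self):
        a, _ = distort_section(self._section(), 6.0, (2.0, 3.0), seed=9)
        b, _ = distort_section(self._section(), 6.0, (2.0, 3.0), seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_warp_invertible(self):
        _, t = distort_section(self._section(), 8.0, (1.0, 2.0), seed=3)
        tinv = invert(t, n_iter=80, tol=1e-4)
        resid = compose(t, tinv).displacement()
        assert np.sqrt((resid**2).sum(axis=0)).mean() < 0.1

    def test_inverse_recovers_undistorted_rendering(self, small_phantom):
        key = (9, "nissl")
        warped = small_phantom.section(*key)
        clean = small_phantom.clean_sections[key]
        t = small_phantom.truth.true_fields[key]
        tinv = invert(t, n_iter=80, tol=1e-4)
        undone = apply_transform(warped.pixels, tinv)
        interior = ndi.binary_erosion(small_phantom.truth.label_volume.voxels[9] > 0, iterations=3)
        err = np.abs(undone - clean.pixels)[interior].mean()
        assert err < 0.05 * np.ptp(clean.pixels)


class TestDataset:
    def test_sampling_counts(self):
        spec = PhantomSpec(
            seed=4, grid_shape=(64, 64, 30), vessel_count=0,
            sampling_plan={"nissl": "1:3"}, plan_offsets={"nissl": 0},
        )
        ds = build_phantom_dataset(spec)
        assert sum(1 for s in ds.sections if s.stain == "nissl") == 10

    def test_full_coverage_under_default_plan(self, small_phantom):
        covered = {s.slice_index for s in small_phantom.sections}
        assert covered == set(range(18))

    def test_damaged_slice_omitted_from_stains_not_blockface(self):
        spec = PhantomSpec(
            seed=4, grid_shape=(64, 64, 12), vessel_count=0,
            sampling_plan={"nissl": "1:1"}, plan_offsets={"nissl": 0},
            damaged_slices=[5],
        )
        ds = build_phantom_dataset(spec)
        assert 5 not in {s.slice_index for s in ds.sections}
        assert ds.blockface.n_slices == 12

    def test_dataset_determinism(self):
        spec = PhantomSpec(seed=6, **SMALL)
        a = build_phantom_dataset(spec)
        b = build_phantom_dataset(spec)
        for sa, sb in zip(a.sections, b.sections):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)
        np.testing.assert_array_equal(a.blockface.voxels, b.blockface.voxels)

    def test_parse_interval(self):
        assert parse_interval("1:3") == 3
        with pytest.raises(ValueError):
            parse_interval("2:3")

    def test_write_phantom_layout(self, tmp_path):
        spec = PhantomSpec(
            seed=4, grid_shape=(32, 32, 8), vessel_count=0,
            sampling_plan={"nissl": "1:2"}, plan_offsets={"nissl": 0},
        )
        ds = build_phantom_dataset(spec)
        write_phantom(ds, tmp_path)
        assert len(list((tmp_path / "blockface").glob("*.tif"))) == 8
        assert len(list((tmp_path / "sections").glob("*.tif"))) == 4
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "truth" / "labels.nii.gz").exists()
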