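import numpy as np
import pytest

from histostack.io import Volume3D
from histostack.phantom import PhantomSpec, generate_label_volume, render_section
from histostack.reconstruct3d import (
    INTERPOLATED,
    MEASURED,
    MISSING,
    assemble,
    interslice_jump,
    linear_intensity_match,
    linear_z_interpolate,
    nlm_interpolate,
    nlm_slice_weights,
)
from histostack.stackalign import initialize_state


@pytest.fixture(scope="module")
def drifted_channel():
    """Perfectly aligned nissl channel sampled 1:3 with linear drift."""
    spec = PhantomSpec(seed=4, grid_shape=(64, 64, 30), vessel_count=2, vessel_radius_range=(2.0, 3.0))
    labels, vessels = generate_label_volume(spec)
    nz = 30
    flags = np.zeros(nz, bool)
    flags[0::3] = True
    vol = np.zeros((nz, 64, 64))
    guide = np.zeros((nz, 64, 64))
    for z in range(nz):
        guide[z] = render_section(
            labels.voxels[z], vessels.voxels[z], spec.stain_profiles["blockface"], z,
            noise_seed=900 + z, pixel_size=200.0, stain="blockface",
        ).pixels
        if flags[z]:
            vol[z] = render_section(
                labels.voxels[z], vessels.voxels[z], spec.stain_profiles["nissl"], z,
                drift_rate=0.5, noise_seed=z, pixel_size=200.0, stain="nissl",
            ).pixels
    masks = labels.voxels > 0
    return vol, guide, flags, masks


class TestIntensityMatch:
    def test_exact_two_slice_linear_case(self, rng):
        s1 = rng.random((40, 40)) * 100
        vol = np.stack([s1, 2 * s1 + 3])
        matched, params = linear_intensity_match(vol, [True, True], tissue_masks=np.ones((2, 40, 40), bool))
        assert params[1][0] == pytest.approx(2.0, abs=1e-9)
        assert params[1][1] == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(matched.voxels[1], s1, atol=1e-9)

    def test_no_drift_gains_near_identity(self):
        spec = PhantomSpec(seed=4, grid_shape=(64, 64, 12), vessel_count=0)
        labels, vessels = generate_label_volume(spec)
        flags = np.ones(12, bool)
        vol = np.stack(
            [
                render_section(
                    labels.voxels[z], vessels.voxels[z], spec.stain_profiles["nissl"], z,
                    drift_rate=0.0, noise_seed=z, pixel_size=200.0, stain="nissl",
                ).pixels
                for z in range(12)
            ]
        )
        _, params = linear_intensity_match(vol, flags, tissue_masks=labels.voxels > 0)
        gains = [params[z][0] for z in range(1, 12)]
        # per-slice gains wobble a little because the tissue-class mix (and
        # hence the intensity SD) changes between slices; what matters is
        # that there is no spurious systematic gain
        assert max(abs(g - 1.0) for g in gains) < 0.05
        assert abs(np.prod(gains) - 1.0) < 0.1

    def test_drift_removed_tenfold(self, drifted_channel):
        vol, _, flags, masks = drifted_channel
        before = interslice_jump(vol, flags, masks)
        matched, _ = linear_intensity_match(vol, flags, tissue_masks=masks)
        after = interslice_jump(matched.voxels, flags, masks)
        assert before >= 10.0 * after

    def test_thin_slice_passes_through(self, rng):
        vol = rng.random((3, 20, 20))
        masks = np.ones((3, 20, 20), bool)
        masks[1] = False
        masks[1, 0, :5] = True  # < 100 joint pixels
        matched, params = linear_intensity_match(vol, [True, True, True], tissue_masks=masks)
        assert params[1] == (1.0, 0.0)
        np.testing.assert_array_equal(matched.voxels[1], vol[1])


class TestNLM:
    def test_constant_channel_preserved(self):
        vol = np.full((9, 16, 16), 5.0)
        guide = np.random.default_rng(0).random((9, 16, 16))
        flags = np.zeros(9, bool)
        flags[[0, 4, 8]] = True
        out, prov = nlm_interpolate(vol, guide, flags, search_depth=4)
        np.testing.assert_allclose(out.voxels, 5.0, atol=1e-9)
        assert prov[1] == INTERPOLATED and prov[0] == MEASURED

    def test_weights_sum_to_one(self, drifted_channel):
        _, guide, flags, _ = drifted_channel
        w = nlm_slice_weights(guide, 1, [0, 3], patch_radius=2)
        np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-9)

    def test_wide_gap_flagged_missing(self):
        vol = np.zeros((12, 8, 8))
        guide = np.zeros((12, 8, 8))
        flags = np.zeros(12, bool)
        flags[0] = True
        vol[0] = 3.0
        out, prov = nlm_interpolate(vol, guide, flags, search_depth=2)
        assert prov[11] == MISSING
        np.testing.assert_allclose(out.voxels[11], 3.0)

    def test_beats_linear_on_held_out_slices(self, drifted_channel):
        vol, guide, flags, masks = drifted_channel
        matched, _ = linear_intensity_match(vol, flags, tissue_masks=masks)
        wins = 0
        total = 0
        for z in np.flatnonzero(flags)[2:-2]:
            f2 = flags.copy()
            f2[z] = False
            nlm, _ = nlm_interpolate(matched.voxels, guide, f2, search_depth=3)
            lin = linear_z_interpolate(matched.voxels, f2)
            m = masks[z]
            e_nlm = ((nlm.voxels[z] - matched.voxels[z]) ** 2)[m].mean()
            e_lin = ((lin[z] - matched.voxels[z]) ** 2)[m].mean()
            wins += e_nlm < e_lin
            total += 1
        assert wins / total >= 0.9


class TestAssemble:
    def test_clean_phantom_channels_match_truth(self, clean_phantom):
        state = initialize_state(clean_phantom.blockface, clean_phantom.sections)
        mcv = assemble(state, intensity_match=False)
        for stain, vol in mcv.channels.items():
            measured = [
                z for z, flag in enumerate(mcv.provenance[stain]) if flag == MEASURED
            ]
            for z in measured[:3]:
                truth = clean_phantom.clean_sections[(z, stain)].pixels
                mask = clean_phantom.truth.label_volume.voxels[z] > 0
                err = np.abs(vol.voxels[z] - truth)[mask].mean()
                assert err < 0.02 * np.ptp(truth)

    def test_interpolated_count_matches_plan(self, clean_phantom):
        state = initialize_state(clean_phantom.blockface, clean_phantom.sections)
        mcv = assemble(state)
        nz = clean_phantom.blockface.n_slices
        for stain in mcv.channels:
            n_measured = len(clean_phantom.spec.stain_slices(stain))
            prov = mcv.provenance[stain]
            assert sum(1 for p in prov if p == MEASURED) == n_measured
            assert sum(1 for p in prov if p != MEASURED) == nz - n_measured

    def test_outside_blockface_mask_is_background(self, clean_phantom):
        state = initialize_state(clean_phantom.blockface, clean_phantom.sections)
        mcv = assemble(state)
        labels = clean_phantom.truth.label_volume.voxels
        for stain, vol in mcv.channels.items():
            bg = clean_phantom.spec.stain_profiles[stain][0][0]
            corner = vol.voxels[:, :2, :2]
            assert np.abs(corner - bg).max() < 20.0
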