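"""Detection-stage contracts: background subtraction, resolution reduction,
pixel classification, the three-voxel rule, splitting, SNR, and validation."""

import numpy as np
import pytest
from scipy import ndimage

from clickmap3d import detection, synthgen
from clickmap3d.core import NucleusSet, Volume
from clickmap3d.detection import (classify_voxels, compute_snr, detect_nuclei,
                                  downsample_volume, subtract_background,
                                  threshold_classifier, train_pixel_classifier,
                                  validate_detection)


def _sphere_volume(centers_um, radius_um, shape, spacing, amplitude=100.0):
    img = synthgen._rasterize_spheres(
        np.atleast_2d(centers_um), np.full(len(np.atleast_2d(centers_um)), radius_um),
        shape, spacing) * amplitude
    return Volume(img, spacing)


class TestSubtractBackground:
    def test_constant_volume_maps_to_zero(self):
        vol = Volume(np.full((16, 16, 16), 37.0), spacing=2.0)
        out = subtract_background(vol, sigma_um=20.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_blob_peak_preserved_on_offset(self):
        # oracle: direct dense convolution with an explicit Gaussian kernel
        spacing = 2.0
        vol = _sphere_volume([16.0, 16.0, 16.0], 4.5, (16, 16, 16), spacing)
        offset = vol.with_data(vol.data + 100.0)
        sigma_um = 12.0
        out = subtract_background(offset, sigma_um)
        ax = np.arange(-8, 9) * spacing
        k1 = np.exp(-ax**2 / (2 * sigma_um**2))
        kern = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        kern /= kern.sum()
        from scipy.signal import fftconvolve
        # reflect-pad to match the filter's boundary handling
        pad = np.pad(offset.data.astype(float), 8, mode="reflect")
        smoothed = fftconvolve(pad, kern, mode="valid")
        expect = np.clip(offset.data - smoothed, 0, None)
        peak = vol.data.max()
        assert abs(out.data.max() - expect.max()) / peak < 0.05
        # far field (corner away from the blob) collapses to ~0
        assert out.data[0, 0, 0] < 0.05 * peak

    def test_small_sigma_warns(self):
        vol = Volume(np.zeros((8, 8, 8)), spacing=1.0)
        with pytest.warns(UserWarning):
            subtract_background(vol, sigma_um=2.0)
        with pytest.raises(ValueError):
            subtract_background(vol, sigma_um=0.0)


class TestDownsample:
    def test_identity_at_same_spacing(self):
        vol = Volume(np.random.default_rng(0).random((8, 8, 8)), spacing=3.65)
        out = downsample_volume(vol, 3.65)
        assert out is vol

    def test_block_mean_of_ones(self):
        vol = Volume(np.ones((8, 8, 8)), spacing=1.0)
        out = downsample_volume(vol, 4.0)
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out.data, 1.0)

    def test_integrated_intensity_conserved(self):
        rng = np.random.default_rng(5)
        vol = Volume(rng.random((12, 12, 12)), spacing=1.0)
        out = downsample_volume(vol, 3.0)
        mass_in = vol.data.sum() * vol.voxel_volume_um3
        mass_out = out.data.sum() * out.voxel_volume_um3
        assert abs(mass_out - mass_in) / mass_in < 0.01

    def test_upsampling_target_rejected(self):
        vol = Volume(np.ones((8, 8, 8)), spacing=2.0)
        with pytest.raises(ValueError):
            downsample_volume(vol, 1.0)

    def test_two_nuclei_remain_distinct_after_resolution_reduction(self):
        # two ~9 um nuclei 12 um apart, rendered fine then reduced to 3.65 um
        spacing_fine = 0.5
        c1 = np.array([20.0, 20.0, 20.0])
        c2 = c1 + np.array([12.0, 0.0, 0.0])
        fine = _sphere_volume([c1, c2], 4.5, (80, 80, 80), spacing_fine)
        coarse = downsample_volume(fine, 3.65)
        mask = coarse.with_data((coarse.data > 0.5 * coarse.data.max()).astype(np.uint8))
        found = detect_nuclei(mask, intensity=coarse, min_voxels=3)
        assert len(found) == 2
        d = np.linalg.norm(found.coords()[0] - found.coords()[1])
        assert abs(d - 12.0) < 2 * 3.65


class TestPixelClassifier:
    def _training_volume(self):
        rng = np.random.default_rng(11)
        vol = _sphere_volume([[16, 16, 16], [34, 30, 20]], 4.5, (48, 48, 48), 2.0)
        noisy = vol.with_data(vol.data + rng.normal(0, 1.0, vol.shape) ** 2)
        fg = [(tuple(i), "foreground") for i in np.argwhere(vol.data > 0)[:80]]
        bg = [(tuple(i), "background") for i in np.argwhere(vol.data == 0)[::947][:120]]
        return noisy, fg + bg

    def test_separable_labels_perfect_training_accuracy(self):
        vol, labels = self._training_volume()
        model = train_pixel_classifier(vol, labels, seed=0)
        mask = classify_voxels(model, vol)
        idx = np.array([l[0] for l in labels])
        want = np.array([1 if l[1] == "foreground" else 0 for l in labels])
        got = mask.data[tuple(idx.T)]
        assert (got == want).all()

    def test_training_deterministic_for_seed(self):
        import pickle
        vol, labels = self._training_volume()
        m1 = train_pixel_classifier(vol, labels, seed=42)
        m2 = train_pixel_classifier(vol, labels, seed=42)
        assert pickle.dumps(m1.forest) == pickle.dumps(m2.forest)

    def test_one_class_labels_rejected(self):
        vol, labels = self._training_volume()
        only_fg = [l for l in labels if l[1] == "foreground"]
        with pytest.raises(ValueError):
            train_pixel_classifier(vol, only_fg, seed=0)

    def test_model_archive_round_trip(self, tmp_path):
        vol, labels = self._training_volume()
        model = train_pixel_classifier(vol, labels, seed=0)
        path = tmp_path / "model.zip"
        model.save(path)
        back = detection.PixelClassifierModel.load(path)
        assert back.feature_scales == model.feature_scales
        assert back.label_provenance == model.label_provenance
        np.testing.assert_array_equal(classify_voxels(back, vol).data,
                                      classify_voxels(model, vol).data)

    def test_feature_scale_mismatch_rejected(self):
        vol, labels = self._training_volume()
        model = train_pixel_classifier(vol, labels, seed=0,
                                       feature_scales=(1.0, 2.0))
        model.feature_scales = (1.0,)  # simulate stale feature spec
        with pytest.raises(ValueError, match="feature"):
            classify_voxels(model, vol)

    def test_threshold_fallback_flagged_and_binary(self):
        model = threshold_classifier(10.0)
        assert model.mode == "threshold"
        vol = Volume(np.zeros((6, 6, 6)), spacing=1.0)
        mask = classify_voxels(model, vol)
        assert set(np.unique(mask.data)) == {0}


class TestDetectNuclei:
    def test_three_voxel_rule_on_mixed_component_sizes(self):
        # components of sizes 1, 2, 3, 5: only the last two survive
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[1, 1, 1] = 1                       # size 1
        data[4, 1, 1:3] = 1                     # size 2
        data[7, 1, 1:4] = 1                     # size 3
        data[1, 7, 1:6] = 1                     # size 5
        mask = Volume(data, spacing=3.65)
        found = detect_nuclei(mask, min_voxels=3, split=False)
        assert len(found) == 2
        assert sorted(found.points["component_size"]) == [3, 5]

    def test_empty_mask_gives_empty_set(self):
        found = detect_nuclei(Volume(np.zeros((5, 5, 5)), spacing=1.0))
        assert len(found) == 0

    def test_single_sphere_centroid_within_half_voxel(self):
        spacing = 3.65
        centre = np.array([20.0, 22.0, 24.0])
        vol = _sphere_volume(centre, 4.5, (12, 12, 12), spacing)
        mask = vol.with_data((vol.data > 0).astype(np.uint8))
        found = detect_nuclei(mask, intensity=vol)
        assert len(found) == 1
        assert np.linalg.norm(found.coords()[0] - centre) < 0.5 * spacing

    @pytest.mark.parametrize("method", ["volume", "watershed"])
    def test_dumbbell_splits_with_split_enabled(self, method):
        # touching spheres (centres one diameter apart) merge into one component
        spacing = 2.0
        r = 4.5
        c1 = np.array([20.0, 20.0, 20.0])
        c2 = c1 + np.array([2 * r, 0.0, 0.0])
        vol = _sphere_volume([c1, c2], r, (24, 20, 20), spacing)
        mask = vol.with_data((vol.data > 0).astype(np.uint8))
        lab, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
        assert n == 1  # genuinely merged into one component
        two = detect_nuclei(mask, intensity=vol, split=True, split_method=method,
                            expected_radius_um=r)
        one = detect_nuclei(mask, intensity=vol, split=False, expected_radius_um=r)
        assert len(two) == 2
        assert len(one) == 1
        got = sorted(two.coords()[:, 0])
        assert abs(got[0] - c1[0]) < spacing and abs(got[1] - c2[0]) < spacing

    def test_watershed_split_agrees_with_distance_maxima_oracle(self):
        # oracle: count local maxima of the exact EDT of the clean dumbbell
        spacing = 2.0
        r = 4.5
        c1 = np.array([20.0, 20.0, 20.0])
        c2 = c1 + np.array([2 * r, 0.0, 0.0])
        vol = _sphere_volume([c1, c2], r, (24, 20, 20), spacing)
        mask = (vol.data > 0)
        edt = ndimage.distance_transform_edt(mask, sampling=[spacing] * 3)
        mx = ndimage.maximum_filter(edt, size=3)
        n_peaks, _ = ndimage.label((edt == mx) & (edt > 0.8 * edt.max()))
        n_peak_groups = ndimage.label((edt == mx) & (edt > 0.8 * edt.max()),
                                      structure=np.ones((3, 3, 3)))[1]
        found = detect_nuclei(Volume(mask.astype(np.uint8), spacing), intensity=vol,
                              split_method="watershed", expected_radius_um=r)
        assert len(found) == n_peak_groups == 2

    def test_raising_min_voxels_never_increases_count(self):
        rng = np.random.default_rng(3)
        data = (rng.random((20, 20, 20)) > 0.8).astype(np.uint8)
        mask = Volume(data, spacing=1.0)
        counts = [len(detect_nuclei(mask, min_voxels=k, split=False))
                  for k in (1, 2, 3, 5, 8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_component_labeling_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(9)
        data = (rng.random((16, 16, 16)) > 0.75).astype(np.uint8)
        mask = Volume(data, spacing=1.0)
        found = detect_nuclei(mask, min_voxels=1, split=False)
        # brute-force BFS flood fill, 26-connected
        seen = np.zeros_like(data, dtype=bool)
        comps = 0
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)]
        for start in np.argwhere(data):
            start = tuple(start)
            if seen[start] or not data[start]:
                continue
            comps += 1
            stack = [start]
            seen[start] = True
            while stack:
                cur = stack.pop()
                for o in offs:
                    nb = tuple(np.array(cur) + o)
                    if all(0 <= nb[d] < 16 for d in range(3)) and data[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        assert len(found) == comps

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            detect_nuclei(Volume(np.full((4, 4, 4), 2.0), spacing=1.0))


class TestSNR:
    def test_uniform_volume_gives_one(self):
        vol = Volume(np.full((8, 8, 8), 13.0), spacing=1.0)
        roi_a = np.zeros((8, 8, 8), dtype=bool); roi_a[:2] = True
        roi_b = np.zeros((8, 8, 8), dtype=bool); roi_b[-2:] = True
        assert compute_snr(vol, roi_a, roi_b) == pytest.approx(1.0)

    def test_ratio_of_means(self):
        data = np.full((6, 6, 6), 10.0)
        data[:3] = 40.0
        vol = Volume(data, spacing=1.0)
        sig = np.zeros((6, 6, 6), dtype=bool); sig[:3] = True
        bg = np.zeros((6, 6, 6), dtype=bool); bg[3:] = True
        assert compute_snr(vol, sig, bg) == pytest.approx(4.0)

    def test_agrees_with_two_pass_mean_oracle(self, rng):
        data = rng.random((10, 10, 10)) + 0.5
        vol = Volume(data, spacing=1.0)
        sig = rng.random((10, 10, 10)) > 0.7
        bg = ~sig
        want = data[sig].sum() / sig.sum() / (data[bg].sum() / bg.sum())
        assert compute_snr(vol, sig, bg) == pytest.approx(want, rel=1e-12)

    def test_zero_background_rejected(self):
        vol = Volume(np.zeros((4, 4, 4)), spacing=1.0)
        roi = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            compute_snr(vol, roi, roi)


class TestValidation:
    def _scene(self, toy_atlas, centers, cluster_ids):
        import pandas as pd
        from clickmap3d.normalization import TransformChain
        nuclei = pd.DataFrame([
            {"x_um": c[0], "y_um": c[1], "z_um": c[2], "radius_um": 4.5,
             "cluster_id": cid} for c, cid in zip(centers, cluster_ids)])
        return synthgen.SyntheticScene(nuclei=nuclei, region_densities={}, seed=0,
                                       true_transform=TransformChain(),
                                       atlas=toy_atlas)

    def test_perfect_prediction_scores_one(self, toy_atlas):
        centers = [[240.0, 240.0, 120.0], [240.0, 240.0, 360.0]]
        scene = self._scene(toy_atlas, centers, [0, 1])
        pred = NucleusSet.from_array(centers, space="sample")
        rep = validate_detection(pred, scene)
        assert rep.signal_noise_accuracy == 1.0
        assert rep.count_accuracy == 1.0

    def test_partial_count_accuracy_two_thirds(self, toy_atlas):
        # true clusters of sizes [2, 2, 3]; predictions recover [2, 1, 3]
        base = np.array([240.0, 240.0, 120.0])
        centers, cids = [], []
        layout = {0: 2, 1: 2, 2: 3}
        for cid, size in layout.items():
            for k in range(size):
                centers.append(base + np.array([cid * 60.0, k * 10.0, 0.0]))
                cids.append(cid)
        scene = self._scene(toy_atlas, centers, cids)
        pred_pts = [c for c, cid in zip(centers, cids) if not (cid == 1 and c[1] > 245)]
        rep = validate_detection(NucleusSet.from_array(pred_pts, space="sample"), scene)
        assert rep.count_accuracy == pytest.approx(2 / 3)

    def test_empty_truth_rejected(self, toy_atlas):
        import pandas as pd
        from clickmap3d.normalization import TransformChain
        scene = synthgen.SyntheticScene(
            nuclei=pd.DataFrame(columns=["x_um", "y_um", "z_um", "radius_um",
                                         "cluster_id"]),
            region_densities={}, seed=0, true_transform=TransformChain(),
            atlas=toy_atlas)
        with pytest.raises(ValueError):
            validate_detection(NucleusSet.from_array(np.empty((0, 3)), space="sample"),
                               scene)

    def test_speckles_never_reported_as_nuclei(self, toy_atlas):
        """Single-voxel speckles fail the three-voxel rule by construction."""
        scene = synthgen.sample_nuclei(toy_atlas, {31: 800.0}, seed=6)
        params = synthgen.RenderParams()
        vol = synthgen.render_channels(scene, params, channels=("edu",), seed=6)["edu"]
        nucleus_mask = synthgen._rasterize_spheres(
            scene.centers_um(), scene.nuclei["radius_um"].to_numpy(),
            vol.shape, params.spacing_um) > 0
        speckled, positions = synthgen.inject_speckle(
            vol, 80, float(params.photon_scale), seed=8, exclude_mask=nucleus_mask)
        work = subtract_background(speckled, 15.0)
        mask = classify_voxels(threshold_classifier(0.3 * params.photon_scale), work)
        found = detect_nuclei(mask, intensity=work, min_voxels=3)
        if len(found):
            from scipy.spatial import cKDTree
            tree = cKDTree(found.coords())
            sp_um = (np.asarray(positions, float) + 0.5) * params.spacing_um
            d, _ = tree.query(sp_um)
            assert (d > params.spacing_um).all()
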