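"""3D smFISH spot detection, thresholding and compartment assignment."""

import numpy as np
import pytest
from scipy import ndimage

from decoyscan.fish import (ImageStack, NoSignalError, SpotSet, STRUCT_26,
                            assign_compartment, detect_spots, log_filter_3d,
                            log_kernel_3d, nuclear_mask_from_dapi,
                            remove_background, select_threshold)
from decoyscan.simulate import _render_gaussian_spots, gen_fish_stack


class TestLoGFilter:
    def test_constant_stack_gives_zero_response(self):
        out = log_filter_3d(np.full((8, 20, 20), 37.0))
        assert np.abs(out).max() < 1e-9 * 37.0

    def test_single_bright_voxel_peaks_at_itself(self):
        stack = np.zeros((9, 21, 21))
        stack[4, 10, 10] = 100.0
        out = log_filter_3d(stack)
        assert np.unravel_index(out.argmax(), out.shape) == (4, 10, 10)

    def test_matches_direct_convolution_oracle(self, rng):
        """FFT-free oracle: explicit sliding-window sum on a small stack
        with a planted Gaussian spot."""
        stack = 5.0 + _render_gaussian_spots((9, 15, 15),
                                             np.array([[4.0, 7.0, 7.0]]),
                                             50.0, 1.5)
        stack += rng.normal(0, 0.1, stack.shape)
        size, sigma = 7, 1.5
        kernel = log_kernel_3d(size=size, sigma=sigma)
        half = size // 2
        # ndimage's "reflect" repeats the edge sample: numpy's "symmetric"
        padded = np.pad(stack, half, mode="symmetric")
        expected = np.zeros_like(stack)
        for z in range(stack.shape[0]):
            for y in range(stack.shape[1]):
                for x in range(stack.shape[2]):
                    win = padded[z:z + size, y:y + size, x:x + size]
                    expected[z, y, x] = (win * kernel[::-1, ::-1, ::-1]).sum()
        got = log_filter_3d(stack, size=size, sigma=sigma)
        assert np.allclose(got, expected, atol=1e-9)

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError):
            log_filter_3d(np.zeros((1, 20, 20)))


class TestSelectThreshold:
    def test_flat_response_is_no_signal(self):
        with pytest.raises(NoSignalError):
            select_threshold(np.zeros((4, 8, 8)))

    def test_plateau_at_planted_count(self, rng):
        """Ten well-separated high-SNR spots: the count curve plateaus at
        10 and the selected threshold lies on that plateau."""
        pos = np.array([[4, 10 + 12 * i, 10 + 12 * j]
                        for i in range(5) for j in range(2)], dtype=float)
        stack = 10.0 + _render_gaussian_spots((9, 80, 40), pos, 200.0, 1.5)
        stack = np.clip(rng.poisson(stack) + rng.normal(0, 1, stack.shape),
                        0, None)
        f = log_filter_3d(stack)
        curve = select_threshold(f)
        n = ndimage.label(f > curve.selected_threshold, STRUCT_26)[1]
        assert n == 10
        assert curve.component_counts[curve.selected_index] == 10

    def test_noise_only_yields_few_components(self, rng):
        noise = np.clip(rng.poisson(np.full((8, 64, 64), 10.0))
                        + rng.normal(0, 1, (8, 64, 64)), 0, None)
        f = log_filter_3d(noise)
        curve = select_threshold(f)
        n = ndimage.label(f > curve.selected_threshold, STRUCT_26)[1]
        assert n <= 2

    def test_dim_spot_not_swallowed_by_bright_spot(self, rng):
        """Two spots with 10x intensity difference: the plateau at count 2
        is chosen, not the long tail at count 1."""
        dims = (8, 64, 64)
        stack = (10.0
                 + _render_gaussian_spots(dims, np.array([[4, 16, 16]]),
                                          300.0, 1.5)
                 + _render_gaussian_spots(dims, np.array([[4, 48, 48]]),
                                          30.0, 1.5))
        stack = np.clip(rng.poisson(stack) + rng.normal(0, 1, dims), 0, None)
        f = log_filter_3d(stack)
        curve = select_threshold(f)
        n = ndimage.label(f > curve.selected_threshold, STRUCT_26)[1]
        assert n == 2


class TestDetect:
    def test_all_zero_stack_is_no_signal(self):
        ss = detect_spots(np.zeros((6, 32, 32)))
        assert ss.no_signal and len(ss) == 0

    def test_planted_spots_counted_exactly(self):
        sig, _, truth = gen_fish_stack(dims=(8, 96, 96), n_spots=20,
                                       snr=10, seed=4)
        ss = detect_spots(sig)
        assert len(ss) == 20

    def test_count_invariant_to_intensity_scaling(self):
        sig, _, _ = gen_fish_stack(dims=(8, 96, 96), n_spots=15, seed=6)
        a = detect_spots(sig)
        b = detect_spots(sig.voxels * 11.0)
        assert len(a) == len(b)

    def test_precision_and_recall_on_synthetic_stacks(self):
        """Precision and recall >= 0.95 at SNR >= 5, low spot density."""
        from scipy.spatial import cKDTree
        precs, recs = [], []
        for seed in range(10):
            sig, _, truth = gen_fish_stack(dims=(8, 96, 96), n_spots=30,
                                           snr=5, seed=seed)
            ss = detect_spots(sig)
            got = np.array([[s.z, s.y, s.x] for s in ss.spots])
            tree = cKDTree(truth[["z", "y", "x"]].to_numpy())
            matched = sum(
                len(tree.query_ball_point(g, 2.5)) > 0 for g in got)
            precs.append(matched / max(len(got), 1))
            recs.append(matched / len(truth))
        assert np.mean(precs) >= 0.95
        assert np.mean(recs) >= 0.95

    def test_component_counting_matches_flood_fill(self, rng):
        """26-connectivity labelling agrees with a brute-force flood fill
        on small stacks."""
        def flood_count(binary):
            seen = np.zeros_like(binary, dtype=bool)
            n = 0
            idx = np.argwhere(binary)
            for start in map(tuple, idx):
                if seen[start]:
                    continue
                n += 1
                stack = [start]
                seen[start] = True
                while stack:
                    z, y, x = stack.pop()
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                q = (z + dz, y + dy, x + dx)
                                if (0 <= q[0] < binary.shape[0]
                                        and 0 <= q[1] < binary.shape[1]
                                        and 0 <= q[2] < binary.shape[2]
                                        and binary[q] and not seen[q]):
                                    seen[q] = True
                                    stack.append(q)
            return n

        for _ in range(5):
            binary = rng.random((10, 12, 12)) < 0.15
            assert ndimage.label(binary, STRUCT_26)[1] == flood_count(binary)


class TestBackground:
    def _spotset(self, coords, channel, n_voxels=10):
        from decoyscan.fish import Spot
        return SpotSet(
            spots=[Spot(z=z, y=y, x=x, n_voxels=n_voxels, peak=1.0,
                        channel=channel) for z, y, x in coords],
            channel=channel,
        )

    def test_single_channel_only_size_filter(self):
        from dataclasses import replace
        ss = self._spotset([(1, 1, 1), (2, 10, 10)], "a")
        ss.spots[0] = replace(ss.spots[0], n_voxels=500)
        out, frac = remove_background([ss], min_voxels=2, max_voxels=100)
        assert len(out[0]) == 1
        assert frac == pytest.approx(0.5)

    def test_cross_channel_spot_removed_from_both(self):
        a = self._spotset([(2, 10, 10), (2, 40, 40)], "a")
        b = self._spotset([(2, 10.5, 10.5)], "b")
        out, frac = remove_background([a, b])
        assert [len(o) for o in out] == [1, 0]
        assert frac == pytest.approx(2 / 3)

    def test_small_artifact_fraction(self):
        """A few cross-channel artifacts among many true spots gives a
        sub-percent removed fraction."""
        rng = np.random.default_rng(0)
        true_a = [(float(z), float(y), float(x)) for z, y, x in
                  rng.uniform(10, 400, (500, 3))]
        true_b = [(float(z), float(y), float(x)) for z, y, x in
                  rng.uniform(500, 900, (495, 3))]
        shared = [(450.0, 450.0, 450.0 + 10 * i) for i in range(5)]
        a = self._spotset(true_a + shared, "a")
        b = self._spotset(true_b + shared, "b")
        out, frac = remove_background([a, b])
        assert frac == pytest.approx(10 / 1005, abs=1e-9)


class TestCompartments:
    def test_all_spots_inside_mask_are_nuclear(self):
        sig, dapi, truth = gen_fish_stack(dims=(8, 96, 96), n_spots=20,
                                          cyto_fraction=0.0, seed=8)
        ss = assign_compartment(detect_spots(sig), dapi)
        assert ss.compartment_fractions()["nuclear"] == 1.0

    def test_planted_split_recovered(self):
        sig, dapi, truth = gen_fish_stack(n_spots=500, cyto_fraction=0.94,
                                          dims=(10, 256, 256),
                                          nucleus_radius_xy=60.0, seed=9)
        ss = assign_compartment(detect_spots(sig), dapi)
        fr = ss.compartment_fractions()
        assert fr["cytoplasmic"] == pytest.approx(0.94, abs=0.03)

    def test_missing_dapi_warns_and_omits_labels(self):
        sig, _, _ = gen_fish_stack(dims=(8, 64, 64), n_spots=5, seed=10)
        ss = detect_spots(sig)
        with pytest.warns(UserWarning, match="DAPI"):
            out = assign_compartment(ss, None)
        assert out.compartment_fractions() is None

    def test_empty_spotset_has_no_fractions(self):
        assert SpotSet(spots=[]).compartment_fractions() is None

    def test_nuclear_mask_fills_holes(self):
        dapi = np.zeros((4, 40, 40))
        dapi[:, 10:30, 10:30] = 100.0
        dapi[:, 19:21, 19:21] = 0.0  # hole inside the nucleus
        mask = nuclear_mask_from_dapi(dapi)
        assert mask[20, 20]
        assert not mask[5, 5]
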