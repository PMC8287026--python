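"""Segmentation: RPE detection, flattening, node detection, path search."""

import numpy as np
import pytest

from ocupulse import segmentation, synthetic
from ocupulse.segmentation import (
    FrameUnusableError,
    SegmentationConfig,
    build_graph_and_search,
    choroidal_thickness,
    detect_rpe,
    find_inflection_nodes,
    flatten_frame,
)

from conftest import small_params
from oracles import enumerate_path_cost


def _band_frame(depth=120, width=40, band=(48, 52), level=200.0, bg=20.0):
    frame = np.full((depth, width), bg)
    frame[band[0]:band[1] + 1, :] = level
    return frame


class TestDetectRpe:
    def test_posterior_edge_of_single_band(self):
        frame = _band_frame()
        prof = detect_rpe(frame, config=SegmentationConfig(smoothing_sigma=0.5,
                                                           rpe_median_window=3))
        assert np.all(np.abs(prof - 52) <= 1)

    def test_uniform_frame_is_unusable(self):
        with pytest.raises(FrameUnusableError):
            detect_rpe(np.full((100, 30), 80.0))

    def test_recovers_tilt_slope(self, clean_sequence):
        seq, truth = clean_sequence
        prof = detect_rpe(seq.frames[0], seq.on_region)
        cols = seq.included_columns()
        slope = np.polyfit(cols, prof[cols], 1)[0]
        true_slope = truth.params.tilt_px_per_ascan
        assert slope == pytest.approx(true_slope, rel=0.10)


class TestFlatten:
    def test_flattening_removes_tilt(self, clean_sequence):
        seq, _ = clean_sequence
        frame = seq.frames[0]
        prof = detect_rpe(frame, seq.on_region)
        flat, shifts, ref = flatten_frame(frame, prof, seq.on_region)
        prof2 = detect_rpe(flat, seq.on_region)
        cols = seq.included_columns()
        assert np.var(prof2[cols]) <= 1.0

    def test_already_flat_is_identity(self):
        frame = _band_frame()
        prof = np.full(frame.shape[1], 52.0)
        flat, shifts, _ = flatten_frame(frame, prof)
        assert np.array_equal(shifts, np.zeros_like(shifts))
        assert np.array_equal(flat, frame)

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(3)
        frame = rng.random((80, 20)) * 100
        prof = 40.0 + np.linspace(-5, 5, 20)
        flat, shifts, _ = flatten_frame(frame, prof)
        for col in range(20):
            s = shifts[col]
            if s > 0:
                assert np.array_equal(flat[s:, col], frame[:-s, col])
            elif s < 0:
                assert np.array_equal(flat[:s, col], frame[-s:, col])

    def test_excessive_shift_rejected(self):
        frame = _band_frame(depth=60)
        prof = np.full(frame.shape[1], 40.0)
        prof[0] = -100.0
        with pytest.raises(ValueError):
            flatten_frame(frame, prof, reference_row=30)


class TestInflectionNodes:
    def test_logistic_step_yields_single_node_at_centre(self):
        rows = np.arange(220, dtype=float)
        profile = 80.0 + 80.0 / (1.0 + np.exp(-(rows - 140.0) / 3.0))
        depths, grads = find_inflection_nodes(profile, rpe_depth_px=60.0)
        assert len(depths) >= 1
        strongest = depths[np.argmax(grads)]
        assert abs(strongest - 140) <= 1

    def test_monotone_decreasing_profile_has_no_nodes(self):
        profile = np.linspace(200.0, 10.0, 150)
        depths, _ = find_inflection_nodes(profile, rpe_depth_px=20.0)
        assert depths.size == 0

    def test_two_steps_ordered_by_height(self):
        rows = np.arange(260, dtype=float)
        profile = (
            60.0
            + 20.0 / (1.0 + np.exp(-(rows - 120.0) / 2.5))
            + 80.0 / (1.0 + np.exp(-(rows - 160.0) / 2.5))
        )
        depths, grads = find_inflection_nodes(profile, rpe_depth_px=60.0)
        near_120 = [g for d, g in zip(depths, grads) if abs(d - 120) <= 3]
        near_160 = [g for d, g in zip(depths, grads) if abs(d - 160) <= 3]
        assert near_120 and near_160
        assert max(near_160) > max(near_120)


class TestGraphSearch:
    def test_unique_candidates_followed(self):
        nodes = [[140.0]] * 5
        grads = [[5.0]] * 5
        path = build_graph_and_search(nodes, grads)
        assert np.allclose(path, 140.0)

    def test_strong_edge_beats_decoy(self):
        nodes = [[100.0, 140.0]] * 5
        grads = [[1.0, 9.0]] * 5
        path = build_graph_and_search(nodes, grads)
        assert np.allclose(path, 140.0)

    def test_displaced_outlier_bridged_by_interpolation(self):
        nodes = [[140.0], [140.0], [90.0], [140.0], [140.0]]
        grads = [[5.0], [5.0], [9.0], [5.0], [5.0]]
        path = build_graph_and_search(nodes, grads, max_jump_px=15.0)
        assert np.allclose(path, 140.0)  # outlier at 90 skipped, interpolated

    def test_empty_columns_interpolated(self):
        nodes = [[100.0], [], [], [106.0]]
        grads = [[5.0], [], [], [5.0]]
        path = build_graph_and_search(nodes, grads, max_jump_px=5.0)
        assert np.allclose(path, [100.0, 102.0, 104.0, 106.0])

    def test_infeasible_instance_raises(self):
        with pytest.raises(FrameUnusableError):
            build_graph_and_search([[10.0]], [[1.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """DP path cost equals brute-force enumeration on random toys."""
        rng = np.random.default_rng(seed)
        for _ in range(40):
            ncols = int(rng.integers(2, 7))
            nodes, grads = [], []
            for _ in range(ncols):
                k = int(rng.integers(0, 5))
                nodes.append(np.sort(rng.integers(0, 60, size=k)).astype(float))
                grads.append(rng.random(k) * 10)
            mj = float(rng.integers(5, 25))
            expected = enumerate_path_cost(nodes, grads, mj)
            try:
                _, cost = build_graph_and_search(
                    nodes, grads, max_jump_px=mj, return_cost=True
                )
            except FrameUnusableError:
                assert not np.isfinite(expected)
            else:
                assert cost == pytest.approx(expected, abs=1e-9)


class TestChoroidalThickness:
    def test_scaled_depth_difference(self):
        cht = choroidal_thickness(np.full(10, 150.0), np.full(10, 50.0), 3.87)
        assert cht == pytest.approx(387.0)

    def test_zero_thickness(self):
        assert choroidal_thickness(np.full(4, 80.0), np.full(4, 80.0), 3.87) == 0.0

    def test_exclusion_equivalence(self):
        csi = np.concatenate([np.full(10, 150.0), np.full(10, 999.0)])
        rpe = np.concatenate([np.full(10, 50.0), np.full(10, 0.0)])
        included = np.arange(10)
        both = choroidal_thickness(csi, rpe, 3.87, included=included)
        alone = choroidal_thickness(csi[:10], rpe[:10], 3.87)
        assert both == alone

    def test_no_valid_columns_raises(self):
        with pytest.raises(FrameUnusableError):
            choroidal_thickness(np.full(4, np.nan), np.full(4, 50.0), 3.87)


class TestSegmentSequence:
    def test_noise_free_recovery_within_one_pixel(self, clean_segmentation):
        seq, truth, wf, seg = clean_segmentation
        err_um = np.abs(wf.cht_um - truth.cht_um_per_frame[seg.usable])
        assert err_um.max() <= seq.axial_spacing_um_per_px

    def test_default_speckle_mean_error_within_two_pixels(self, noisy_segmentation):
        seq, truth, wf, seg = noisy_segmentation
        err_um = np.abs(wf.cht_um - truth.cht_um_per_frame[seg.usable])
        assert err_um.mean() <= 2 * seq.axial_spacing_um_per_px

    def test_corrupted_frames_dropped_rest_intact(self, clean_sequence):
        seq, truth = clean_sequence
        frames = seq.frames.copy()
        rng = np.random.default_rng(0)
        bad = [3, 17, 44]
        for i in bad:
            frames[i] = rng.random(frames[i].shape) * 255
        seq2 = synthetic.BScanSequence(
            frames=frames,
            timestamps_s=seq.timestamps_s,
            axial_spacing_um_per_px=seq.axial_spacing_um_per_px,
            on_region=seq.on_region,
        )
        wf, seg = segmentation.segment_sequence(seq2)
        assert not seg.usable[bad].any()
        assert set(seg.drop_reasons) == set(bad)
        good = seg.usable
        err_um = np.abs(seg.cht_um[good] - truth.cht_um_per_frame[good])
        assert err_um.max() <= seq.axial_spacing_um_per_px

    def test_uniform_offset_leaves_path_unchanged(self, clean_sequence):
        """Node detection rests on intensity differences, not absolute level."""
        seq, _ = clean_sequence
        sub = synthetic.BScanSequence(
            frames=seq.frames[:3],
            timestamps_s=seq.timestamps_s[:3],
            axial_spacing_um_per_px=seq.axial_spacing_um_per_px,
            on_region=seq.on_region,
        )
        shifted = synthetic.BScanSequence(
            frames=seq.frames[:3] + 30.0,
            timestamps_s=seq.timestamps_s[:3],
            axial_spacing_um_per_px=seq.axial_spacing_um_per_px,
            on_region=seq.on_region,
        )
        _, seg_a = segmentation.segment_sequence(sub)
        _, seg_b = segmentation.segment_sequence(shifted)
        assert np.allclose(seg_a.csi_depth_px, seg_b.csi_depth_px, equal_nan=True)

    def test_on_region_content_is_irrelevant(self, clean_sequence):
        seq, _ = clean_sequence
        lo, hi = seq.on_region
        frames = seq.frames[:3].copy()
        rng = np.random.default_rng(7)
        frames[:, :, lo:hi] = rng.random(frames[:, :, lo:hi].shape) * 255
        scrambled = synthetic.BScanSequence(
            frames=frames,
            timestamps_s=seq.timestamps_s[:3],
            axial_spacing_um_per_px=seq.axial_spacing_um_per_px,
            on_region=seq.on_region,
        )
        sub = synthetic.BScanSequence(
            frames=seq.frames[:3],
            timestamps_s=seq.timestamps_s[:3],
            axial_spacing_um_per_px=seq.axial_spacing_um_per_px,
            on_region=seq.on_region,
        )
        wf_a, _ = segmentation.segment_sequence(sub)
        wf_b, _ = segmentation.segment_sequence(scrambled)
        assert np.allclose(wf_a.cht_um, wf_b.cht_um)

    def test_too_few_usable_frames_raises(self):
        rng = np.random.default_rng(5)
        seq = synthetic.BScanSequence(
            frames=rng.random((4, 60, 30)),
            timestamps_s=np.arange(4.0),
            axial_spacing_um_per_px=3.87,
        )
        with pytest.raises(FrameUnusableError):
            segmentation.segment_sequence(seq)
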