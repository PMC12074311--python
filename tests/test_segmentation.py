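"""TFHS: per-stage oracles and whole-pipeline invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tflime as tl
from tflime.config import TfhsParams
from tflime.segmentation import (
    Peak,
    TFBlock,
    cluster_peaks,
    detect_peaks,
    expand_boundaries,
    fill_equidistant,
    prune_low_energy,
    resolve_overlaps,
    segment,
    split_temporal,
)

DEFAULTS = TfhsParams()


def _brute_force_peaks(mag, params):
    """Literal evaluation of the peak conditions, with plateau suppression."""
    mu, sigma = mag.mean(), mag.std()
    out = []
    n_frames, n_bins = mag.shape
    for l in range(n_frames):
        row = mag[l]
        for k in range(n_bins):
            v = row[k]
            if v <= 0:
                continue
            if v < params.energy_threshold_factor * row.max():
                continue
            if v < mu + params.noise_suppression * sigma:
                continue
            if k > 0 and row[k - 1] > v:
                continue
            if k < n_bins - 1 and row[k + 1] > v:
                continue
            # leftmost representative of an equal-valued run, and the run
            # must be strictly above each neighbour it has
            if k > 0 and row[k - 1] == v:
                continue
            run_end = k
            while run_end + 1 < n_bins and row[run_end + 1] == v:
                run_end += 1
            if run_end - k + 1 == n_bins:
                continue
            if k > 0 and row[k - 1] >= v:
                continue
            if run_end < n_bins - 1 and row[run_end + 1] >= v:
                continue
            out.append((l, k))
    return out


class TestDetectPeaks:
    def test_single_row_spectrum_one_peak(self):
        mag = np.array([[0.0, 1.0, 5.0, 1.0, 0.0]])
        params = TfhsParams(energy_threshold_factor=0.5, noise_suppression=0.0)
        peaks = detect_peaks(mag, params)
        assert [(p.frame, p.bin) for p in peaks] == [(0, 2)]

    def test_constant_matrix_has_no_peaks(self):
        peaks = detect_peaks(np.full((4, 6), 3.0), DEFAULTS)
        assert peaks == []

    def test_zero_matrix_has_no_peaks(self):
        assert detect_peaks(np.zeros((4, 6)), DEFAULTS) == []

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.zeros((0, 5)), DEFAULTS)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_conditions(self, seed):
        r = np.random.default_rng(seed)
        mag = r.exponential(size=(6, 12))
        params = TfhsParams(noise_suppression=float(r.uniform(0, 2)))
        got = [(p.frame, p.bin) for p in detect_peaks(mag, params)]
        assert got == _brute_force_peaks(mag, params)

    def test_boundary_bins_use_single_neighbour(self):
        mag = np.array([[5.0, 1.0, 0.5, 1.0, 0.2, 4.0]])
        params = TfhsParams(energy_threshold_factor=0.01, noise_suppression=0.0)
        bins = {p.bin for p in detect_peaks(mag, params)}
        assert 0 in bins and 5 in bins


class TestClusterPeaks:
    @staticmethod
    def _peak(frame, bin_, mag, norm_mag):
        return Peak(frame=frame, bin=bin_, magnitude=mag, norm_bin=0.0, norm_mag=norm_mag)

    def test_identical_features_form_one_cluster(self):
        peaks = [self._peak(0, 5, 2.0, 0.8), self._peak(1, 5, 2.0, 0.8)]
        clusters = cluster_peaks(peaks, DEFAULTS)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_distant_bins_separate(self):
        # two tones 6 bins apart, equal magnitude: distance 6 > eps
        peaks = [self._peak(l, 4, 1.0, 1.0) for l in range(3)] + [
            self._peak(l, 10, 1.0, 1.0) for l in range(3)
        ]
        clusters = cluster_peaks(peaks, DEFAULTS)
        assert len(clusters) == 2
        assert {p.bin for p in clusters[0]} in ({4}, {10})

    def test_singleton_is_noise(self):
        assert cluster_peaks([self._peak(0, 3, 1.0, 1.0)], DEFAULTS) == []

    def test_empty_input(self):
        assert cluster_peaks([], DEFAULTS) == []

    @given(seed=st.integers(0, 200))
    @settings(max_examples=25, deadline=None)
    def test_cluster_members_are_density_reachable(self, seed):
        # every clustered pair is connected through steps of length <= eps
        r = np.random.default_rng(seed)
        peaks = [
            self._peak(int(l), int(b), float(m), float(m))
            for l, b, m in zip(
                r.integers(0, 10, 12), r.integers(0, 20, 12), r.uniform(0, 1, 12)
            )
        ]
        for cluster in cluster_peaks(peaks, DEFAULTS):
            feats = np.array([[p.bin, p.norm_mag] for p in cluster], float)
            if len(feats) == 1:
                continue
            d = np.linalg.norm(feats[:, None] - feats[None, :], axis=2)
            # connectivity via eps-graph (boolean transitive closure)
            adj = d <= DEFAULTS.cluster_radius
            reach = adj.copy()
            for _ in range(len(feats)):
                reach = reach | (reach @ adj)
            assert reach.all()


class TestSplitTemporal:
    @pytest.mark.parametrize(
        "frames, gap, expected",
        [
            ([1, 2, 3, 7, 8], 1, [[1, 2, 3], [7, 8]]),
            ([5], 1, [[5]]),
            ([2, 4, 6], 2, [[2, 4, 6]]),
            ([2, 4, 7], 2, [[2, 4], [7]]),
        ],
    )
    def test_split_against_scan_oracle(self, frames, gap, expected):
        peaks = [Peak(f, 0, 1.0, 0.0, 1.0) for f in frames]
        subsets = split_temporal(peaks, gap)
        assert [[p.frame for p in s] for s in subsets] == expected

    def test_empty(self):
        assert split_temporal([], 1) == []


class TestExpandBoundaries:
    def _block_for_profile(self, profile, params, center):
        # one-frame matrix whose band profile is the row itself
        mag = np.array([profile], float)
        subset = [Peak(0, center, profile[center], 0.0, 1.0)]
        return expand_boundaries(mag, subset, params)

    def test_steep_decay_confines_block_to_seed(self):
        # profile [0.1, 2, 5, 2.2, 0.1]: neighbours sit below 0.6 * 5
        params = TfhsParams(energy_decay=0.6, global_energy=1.2)
        block = self._block_for_profile([0.1, 2.0, 5.0, 2.2, 0.1], params, 2)
        assert (block.bin_lo, block.bin_hi) == (2, 2)

    def test_gentle_shoulder_included(self):
        # 4.0 >= 0.6 * 5 and above the global floor, 0.1 stops the walk
        params = TfhsParams(energy_decay=0.6, global_energy=0.1)
        block = self._block_for_profile([0.1, 4.0, 5.0, 4.0, 0.1], params, 2)
        assert (block.bin_lo, block.bin_hi) == (1, 3)

    def test_single_bin_band(self):
        mag = np.array([[2.0]])
        block = expand_boundaries(mag, [Peak(0, 0, 2.0, 0.0, 1.0)], DEFAULTS)
        assert (block.bin_lo, block.bin_hi) == (0, 0)

    def test_flat_profile_expands_to_edges(self):
        params = TfhsParams(energy_decay=1.0, global_energy=0.5)
        block = self._block_for_profile([3.0] * 7, params, 3)
        assert (block.bin_lo, block.bin_hi) == (0, 6)

    def test_local_minimum_included_then_stops(self):
        # walk right: 3.0 at index 3 is a local minimum (3 < 5 and 3 < 4):
        # it is absorbed and the walk stops before the 4.0 beyond it
        params = TfhsParams(energy_decay=0.5, global_energy=0.01)
        block = self._block_for_profile([0.1, 5.0, 4.0, 3.0, 4.0, 0.1], params, 1)
        assert block.bin_hi == 3

    def test_frame_span_is_subset_extent(self):
        mag = np.ones((6, 5))
        subset = [Peak(2, 2, 1.0, 0.5, 1.0), Peak(4, 2, 1.0, 0.5, 1.0)]
        block = expand_boundaries(mag, subset, DEFAULTS)
        assert (block.frame_lo, block.frame_hi) == (2, 4)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            expand_boundaries(np.ones((3, 3)), [], DEFAULTS)


class TestResolveOverlaps:
    def test_duplicate_blocks_collapse_to_one(self):
        mag = np.ones((4, 6))
        blocks = [TFBlock(0, 1, 0, 3), TFBlock(0, 1, 0, 3)]
        assert len(resolve_overlaps(blocks, mag, 0.3)) == 1

    def test_disjoint_blocks_unchanged(self):
        mag = np.ones((4, 6))
        blocks = [TFBlock(0, 1, 0, 2), TFBlock(2, 3, 3, 5)]
        assert set(resolve_overlaps(blocks, mag, 0.3)) == set(blocks)

    def test_partial_overlap_resolved_to_disjoint_cells(self):
        # A=(0,1,0,3), B=(0,1,2,5): Jaccard = 4/12 >= 0.3
        mag = np.ones((2, 6))
        mag[:, :4] += 1.0  # A has the larger mean, keeps the contested cells
        blocks = [TFBlock(0, 1, 0, 3), TFBlock(0, 1, 2, 5)]
        resolved = resolve_overlaps(blocks, mag, 0.3)
        covered = np.zeros((2, 6), dtype=int)
        for b in resolved:
            covered[b.frame_lo : b.frame_hi + 1, b.bin_lo : b.bin_hi + 1] += 1
        assert covered.max() == 1
        assert TFBlock(0, 1, 0, 3) in resolved
        assert TFBlock(0, 1, 4, 5) in resolved

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30, deadline=None)
    def test_output_always_pairwise_disjoint(self, seed):
        r = np.random.default_rng(seed)
        mag = r.uniform(0.1, 1.0, size=(8, 10))
        blocks = []
        for _ in range(r.integers(1, 8)):
            f0, f1 = sorted(r.integers(0, 8, 2))
            k0, k1 = sorted(r.integers(0, 10, 2))
            blocks.append(TFBlock(int(f0), int(f1), int(k0), int(k1)))
        covered = np.zeros((8, 10), dtype=int)
        for b in resolve_overlaps(blocks, mag, 0.3):
            covered[b.frame_lo : b.frame_hi + 1, b.bin_lo : b.bin_hi + 1] += 1
        assert covered.max() <= 1


class TestPruneAndFill:
    def test_zero_region_block_dropped(self):
        mag = np.ones((4, 4))
        mag[2:, 2:] = 0.0
        blocks = [TFBlock(2, 3, 2, 3), TFBlock(0, 1, 0, 1)]
        kept = prune_low_energy(blocks, mag, DEFAULTS)
        assert kept == [TFBlock(0, 1, 0, 1)]

    def test_mean_below_fraction_of_global_mean_dropped(self):
        mag = np.full((2, 4), 1.0)
        mag[:, 0] = 0.4  # block mean 0.4 < 0.5 * global mean (= 0.425)
        blocks = [TFBlock(0, 1, 0, 0)]
        assert prune_low_energy(blocks, mag, DEFAULTS) == []

    def test_block_with_global_max_retained(self):
        mag = np.random.default_rng(0).uniform(size=(5, 5))
        l, k = np.unravel_index(mag.argmax(), mag.shape)
        blocks = [TFBlock(int(l), int(l), int(k), int(k))]
        assert prune_low_energy(blocks, mag, DEFAULTS) == blocks

    def test_fill_tiles_bare_matrix(self):
        tiles = fill_equidistant((4, 4), [], 2)
        assert len(tiles) == 4
        assert all(t.n_cells == 4 and t.origin == "fill" for t in tiles)

    def test_fill_skips_full_cover_block(self):
        assert fill_equidistant((4, 4), [TFBlock(0, 3, 0, 3)], 2) == []

    def test_fill_clips_around_blocks_and_edges(self):
        tiles = fill_equidistant((5, 5), [TFBlock(0, 2, 0, 2)], 2)
        covered = np.zeros((5, 5), dtype=int)
        covered[0:3, 0:3] = 1
        for t in tiles:
            covered[t.frame_lo : t.frame_hi + 1, t.bin_lo : t.bin_hi + 1] += 1
        assert (covered == 1).all()


class TestSegmentPipeline:
    def test_zero_matrix_yields_pure_fill(self):
        seg = segment(np.zeros((6, 8)), DEFAULTS)
        assert all(b.origin == "fill" for b in seg.blocks)
        assert (seg.labels() >= 0).all()

    def test_fallback_unit_tiles_cover_every_cell(self):
        params = TfhsParams(fill_window=1)
        seg = segment(np.zeros((5, 7)), params)
        assert len(seg) == 35

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_partition_property(self, seed):
        r = np.random.default_rng(seed)
        mag = r.exponential(size=(r.integers(3, 12), r.integers(3, 20)))
        seg = segment(mag, DEFAULTS)
        counts = np.zeros(seg.matrix_shape, dtype=int)
        for b in seg.blocks:
            counts[b.frame_lo : b.frame_hi + 1, b.bin_lo : b.bin_hi + 1] += 1
        assert (counts == 1).all()

    def test_determinism(self, rng):
        mag = rng.exponential(size=(10, 30))
        assert segment(mag, DEFAULTS).blocks == segment(mag, DEFAULTS).blocks

    def test_scale_covariance(self, rng):
        mag = rng.exponential(size=(10, 30))
        assert segment(mag, DEFAULTS).blocks == segment(mag * 37.5, DEFAULTS).blocks

    def test_noiseless_tone_block_matches_activity(self, single_tone_sample):
        series, spec, mask = single_tone_sample
        seg = segment(tl.magnitude(tl.stft(series, tl.DEFAULT_STFT)), DEFAULTS)
        peak_blocks = [b for b in seg.blocks if b.origin == "peak"]
        assert len(peak_blocks) == 1
        block = peak_blocks[0]
        tone_bin = round(spec.components[0].frequency * 128 / 200)
        assert block.bin_lo <= tone_bin <= block.bin_hi
        assert tl.iou(seg.peak_region(), mask) > 0.8

    def test_json_round_trip_fields(self, rng):
        import json

        mag = rng.exponential(size=(6, 10))
        seg = segment(mag, DEFAULTS)
        payload = json.loads(seg.to_json(mag))
        assert payload["matrix_shape"] == [6, 10]
        assert len(payload["blocks"]) == len(seg)
        assert {"frame_lo", "frame_hi", "bin_lo", "bin_hi", "origin", "mean_magnitude"} <= set(
            payload["blocks"][0]
        )
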