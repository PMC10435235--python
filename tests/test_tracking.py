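"""XYT connected-component tracking and averaged-trace extraction."""

import numpy as np
import pytest

from adhesionlag import TwoChannelMovie, extract_traces, track_clusters


def bfs_components_3d(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D boolean volume by explicit BFS."""
    if connectivity == 26:
        neigh = [
            (dt, dy, dx)
            for dt in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dt, dy, dx) != (0, 0, 0)
        ]
    else:  # 6: faces only
        neigh = [
            (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1),
        ]
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    it = np.ndindex(mask.shape)
    for idx in it:
        if mask[idx] and not seen[idx]:
            comp = set()
            queue = [idx]
            seen[idx] = True
            while queue:
                t, y, x = queue.pop()
                comp.add((t, y, x))
                for dt, dy, dx in neigh:
                    n = (t + dt, y + dy, x + dx)
                    if (
                        0 <= n[0] < mask.shape[0]
                        and 0 <= n[1] < mask.shape[1]
                        and 0 <= n[2] < mask.shape[2]
                        and mask[n]
                        and not seen[n]
                    ):
                        seen[n] = True
                        queue.append(n)
            comps.append(comp)
    return comps


def blob_volume(frames: list[int], shape=(10, 12, 12), pos=(4, 4), size=3) -> np.ndarray:
    vol = np.zeros(shape, dtype=bool)
    for f in frames:
        vol[f, pos[0] : pos[0] + size, pos[1] : pos[1] + size] = True
    return vol


class TestTrackClusters:
    @pytest.mark.parametrize("frames,kept", [([5, 6], 0), ([5, 6, 7], 1)])
    def test_persistence_filter_three_frames(self, frames, kept):
        """A blob present in 2 frames is discarded; 3 frames is kept."""
        labels, tracks = track_clusters(blob_volume(frames), min_frames=3)
        assert len(tracks) == kept
        assert (labels.max() > 0) == bool(kept)

    def test_disjoint_blobs_get_distinct_labels(self):
        vol = blob_volume([0, 1, 2], pos=(1, 1)) | blob_volume([5, 6, 7], pos=(8, 8))
        labels, tracks = track_clusters(vol, min_frames=3)
        assert len(tracks) == 2
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_canonical_labels_ordered_by_first_appearance(self):
        vol = blob_volume([4, 5, 6], pos=(1, 1)) | blob_volume([0, 1, 2], pos=(8, 8))
        _, tracks = track_clusters(vol, min_frames=3)
        assert tracks[0].first_frame == 0 and tracks[1].first_frame == 4

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_oracle_partition(self, seed, connectivity):
        """Random small volumes: labelling equals a BFS flood fill up to
        relabelling, including the distinct-frame persistence filter."""
        rng = np.random.default_rng(seed)
        vol = rng.random((8, 16, 16)) < 0.25
        labels, tracks = track_clusters(vol, min_frames=3, connectivity_3d=connectivity)
        expected = [
            comp
            for comp in bfs_components_3d(vol, connectivity)
            if len({t for t, _, _ in comp}) >= 3
        ]
        got = [set(zip(*np.nonzero(labels == t.cluster_id))) for t in tracks]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_partition_property(self):
        """Per frame, label areas sum to the retained mask area."""
        rng = np.random.default_rng(1)
        vol = rng.random((8, 20, 20)) < 0.3
        labels, _ = track_clusters(vol, min_frames=2)
        for f in range(vol.shape[0]):
            assert (labels[f] > 0).sum() == sum(
                (labels[f] == k).sum() for k in np.unique(labels[f]) if k > 0
            )

    def test_invariant_to_frame_content_permutation_of_disjoint_blobs(self):
        """Canonical relabelling gives the same partition regardless of
        which disjoint blob the labeller happens to visit first."""
        a = blob_volume([0, 1, 2], pos=(1, 1))
        b = blob_volume([0, 1, 2], pos=(8, 8))
        l1, t1 = track_clusters(a | b)
        # same geometry built in reverse order is literally the same volume,
        # so canonical ordering must assign label 1 to the scanline-first blob
        assert l1[0, 1, 1] == 1 and l1[0, 8, 8] == 2
        assert [t.cluster_id for t in t1] == [1, 2]


class TestExtractTraces:
    def _movie(self, n_frames=6, shape=(8, 8)):
        rng = np.random.default_rng(42)
        data = rng.uniform(10, 100, (n_frames, 2, *shape))
        return TwoChannelMovie(data)

    def _track_and_labels(self, frames, masks, shape=(8, 8), n_frames=6):
        labels = np.zeros((n_frames, *shape), dtype=int)
        for f, m in zip(frames, masks):
            labels[f][m] = 1
        from adhesionlag.model import ClusterTrack

        track = ClusterTrack(cluster_id=1, frames=np.array(frames), max_area_px=1)
        return track, labels

    def test_single_tracked_frame_equals_mask_trace(self):
        movie = self._movie()
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 3:5] = True
        track, labels = self._track_and_labels([3], [mask])
        traces = extract_traces(track, labels, movie)
        for ch in range(2):
            expected = movie.data[:, ch][:, mask].mean(axis=1)
            np.testing.assert_allclose(traces[ch], expected)

    def test_identical_masks_average_to_single_mask_trace(self):
        movie = self._movie()
        mask = np.zeros((8, 8), dtype=bool)
        mask[5:7, 1:4] = True
        track, labels = self._track_and_labels([1, 2, 3], [mask, mask, mask])
        traces = extract_traces(track, labels, movie)
        expected = movie.data[:, 0][:, mask].mean(axis=1)
        np.testing.assert_allclose(traces[0], expected, atol=1e-12)

    def test_matches_explicit_loop_oracle(self):
        """Three differing masks vs direct voxel loops."""
        movie = self._movie()
        rng = np.random.default_rng(5)
        frames = [1, 2, 4]
        masks = [rng.random((8, 8)) < 0.3 for _ in frames]
        masks = [m if m.any() else np.eye(8, dtype=bool) for m in masks]
        track, labels = self._track_and_labels(frames, masks)
        traces = extract_traces(track, labels, movie)
        for ch in range(2):
            oracle = np.zeros(movie.n_frames)
            for m in masks:
                per_time = []
                for t in range(movie.n_frames):
                    vals = [movie.data[t, ch, y, x] for y, x in zip(*np.nonzero(m))]
                    per_time.append(sum(vals) / len(vals))
                oracle += np.array(per_time)
            oracle /= len(masks)
            np.testing.assert_allclose(traces[ch], oracle, atol=1e-9)

    def test_empty_mask_frame_rejected(self):
        movie = self._movie()
        from adhesionlag.model import ClusterTrack

        track = ClusterTrack(cluster_id=1, frames=np.array([0]), max_area_px=0)
        labels = np.zeros((6, 8, 8), dtype=int)  # label 1 never present
        with pytest.raises(ValueError):
            extract_traces(track, labels, movie)
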