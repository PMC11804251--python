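"""Rescaling, robust normalization, chunk coverage, class balancing."""

import numpy as np
import pytest

from tomopick import (
    ParticleSet,
    Volume,
    balance_chunks,
    chunk_volume,
    compute_scale,
    render_labels,
    resize_volume,
    robust_normalize,
)


class TestComputeScale:
    @pytest.mark.parametrize(
        "voxel_size, diameter, target, expected",
        [
            (5.0, 200.0, 10, 0.25),   # 40 px particle -> shrink 4x
            (10.0, 100.0, 10, 1.0),   # already at target
            (13.5, 135.0, 10, 1.0),
            (10.0, 50.0, 10, 2.0),    # small particle -> upscale
        ],
    )
    def test_arithmetic(self, voxel_size, diameter, target, expected):
        assert compute_scale(voxel_size, diameter, target) == pytest.approx(expected)

    def test_rescaled_voxel_size(self):
        scale = compute_scale(5.0, 200.0, 10)
        assert 5.0 / scale == pytest.approx(20.0)


class TestResizeVolume:
    def test_identity_at_scale_one(self, random_volume):
        out = resize_volume(random_volume, 1.0)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_constant_volume_stays_constant(self):
        vol = Volume(np.full((16, 16, 16), 3.25, dtype=np.float32), voxel_size=4.0)
        out = resize_volume(vol, 0.5)
        assert out.shape == (8, 8, 8)
        np.testing.assert_allclose(out.data, 3.25, rtol=1e-6)
        assert out.voxel_size == pytest.approx(8.0)

    def test_down_up_round_trip_preserves_mass(self):
        """A delta spike downscaled then upscaled keeps its integrated mass
        within 10% — anti-aliased linear resampling neither swallows nor
        invents intensity."""
        vol = Volume(np.zeros((16, 16, 16), dtype=np.float32))
        vol.data[8, 8, 8] = 1.0
        down = resize_volume(vol, 0.5)
        up = resize_volume(down, 2.0)
        assert up.data.sum() == pytest.approx(vol.data.sum(), rel=0.1)

    def test_label_diameter_tracks_target_after_scaling(self):
        """compute_scale + resize keeps the rendered particle span at the
        target size within one voxel."""
        ps = ParticleSet(np.array([[24.0, 24.0, 24.0]]), diameter=400.0, voxel_size=10.0)
        label = render_labels(ps, (48, 48, 48))  # particle is 40 px wide here
        scale = compute_scale(10.0, 400.0, 10)
        small = resize_volume(label, scale)
        profile = small.data[small.shape[0] // 2, small.shape[1] // 2, :]
        span = np.sum(profile > 1e-3)
        assert abs(span - 10) <= 1

    def test_degenerate_output_rejected(self):
        with pytest.raises(ValueError):
            resize_volume(Volume(np.zeros((4, 4, 4))), 0.01)


class TestRobustNormalize:
    def test_median_iqr_arithmetic(self):
        # values with median 3 and IQR 2: a voxel at 5 maps to 1.0
        data = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 25, dtype=np.float32)[:125]
        vol = Volume(np.sort(data).reshape(5, 5, 5))
        out = robust_normalize(vol)
        idx = np.unravel_index(np.argmax(vol.data == 5.0), vol.shape)
        assert out.data[idx] == pytest.approx(1.0, abs=1e-5)
        assert np.median(out.data) == pytest.approx(0.0, abs=1e-6)

    def test_idempotent_on_normalized_volume(self, random_volume):
        once = robust_normalize(random_volume)
        twice = robust_normalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)

    def test_constant_volume_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="interquartile"):
            robust_normalize(Volume(np.full((8, 8, 8), 7.0)))

    def test_output_statistics(self, random_volume):
        out = robust_normalize(random_volume)
        q25, q75 = np.percentile(out.data, [25, 75])
        assert q75 - q25 == pytest.approx(1.0, abs=1e-5)


class TestChunkVolume:
    @pytest.mark.parametrize(
        "dim, expected_origins",
        [
            (64, [0]),
            (96, [0, 32]),
            (100, [0, 32, 36]),  # clamped final window
            (128, [0, 32, 64]),
            (130, [0, 32, 64, 66]),
        ],
    )
    def test_axis_origins(self, dim, expected_origins):
        chunks = chunk_volume(np.zeros((dim, 64, 64), dtype=np.float32))
        z_origins = sorted({o[0] for o in chunks.origins})
        assert z_origins == expected_origins

    @pytest.mark.parametrize("dim, count", [(64, 1), (96, 8), (100, 27)])
    def test_chunk_counts(self, dim, count):
        assert len(chunk_volume(np.zeros((dim,) * 3, dtype=np.float32))) == count

    def test_full_coverage_and_origin_bounds(self, rng):
        for shape in [(64, 96, 100), (70, 64, 65)]:
            chunks = chunk_volume(np.zeros(shape, dtype=np.float32))
            covered = np.zeros(shape, dtype=bool)
            for (oz, oy, ox), cube in chunks:
                assert all(0 <= o <= d - 64 for o, d in zip((oz, oy, ox), shape))
                covered[oz : oz + 64, oy : oy + 64, ox : ox + 64] = True
            assert covered.all()

    def test_small_volume_zero_padded(self):
        chunks = chunk_volume(np.ones((20, 64, 64), dtype=np.float32))
        assert chunks.padding == (44, 0, 0)
        assert len(chunks) == 1
        cube = chunks.cubes[0]
        assert cube.shape == (64, 64, 64)
        assert np.all(cube[:20] == 1) and np.all(cube[20:] == 0)

    def test_chunks_copy_source_values(self, rng):
        data = rng.normal(size=(96, 64, 64)).astype(np.float32)
        chunks = chunk_volume(data)
        for (oz, oy, ox), cube in chunks:
            np.testing.assert_array_equal(cube, data[oz : oz + 64, oy : oy + 64, ox : ox + 64])


class TestBalanceChunks:
    def _make_sets(self, n_pos, n_neg, size=8):
        cubes = []
        for i in range(n_pos):
            c = np.zeros((size,) * 3, dtype=np.float32)
            c[0, 0, i % size] = 1.0
            cubes.append(c)
        cubes += [np.zeros((size,) * 3, dtype=np.float32) for _ in range(n_neg)]
        from tomopick.preprocess import ChunkSet

        origins = [(i, 0, 0) for i in range(len(cubes))]
        images = ChunkSet(origins, [np.full((size,) * 3, float(i), dtype=np.float32)
                                    for i in range(len(cubes))], size, size, (size,) * 3)
        labels = ChunkSet(origins, cubes, size, size, (size,) * 3)
        return images, labels

    def test_equal_number_rule(self):
        images, labels = self._make_sets(5, 12)
        pairs = balance_chunks(images, labels, seed=0)
        assert len(pairs) == 10
        n_pos = sum(1 for _, lbl in pairs if np.any(lbl > 0))
        assert n_pos == 5

    def test_clamped_when_negatives_scarce(self):
        images, labels = self._make_sets(5, 3)
        pairs = balance_chunks(images, labels, seed=0)
        assert len(pairs) == 8

    def test_deterministic_for_seed(self):
        images, labels = self._make_sets(4, 20)
        a = balance_chunks(images, labels, seed=7)
        b = balance_chunks(images, labels, seed=7)
        for (ia, la), (ib, lb) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)

    def test_no_duplicate_negatives(self):
        images, labels = self._make_sets(6, 10)
        pairs = balance_chunks(images, labels, seed=3)
        neg_ids = [img[0, 0, 0] for img, lbl in pairs if not np.any(lbl > 0)]
        assert len(neg_ids) == len(set(neg_ids))

    def test_zero_positives_rejected(self):
        images, labels = self._make_sets(0, 5)
        with pytest.raises(ValueError, match="positive"):
            balance_chunks(images, labels, seed=0)
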