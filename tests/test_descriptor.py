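"""Counter-color similarity, texton indexing, and histogram behavior."""

import numpy as np
import pytest

from qdcp.colorspace import OrientationField, md_decompose, rgb_to_ycbcr
from qdcp.descriptor import (
    orientation_similarity,
    qdcp_feature,
    qdcp_index_image,
    texton_histogram,
    threshold_to_angle,
)
from qdcp.exceptions import EmptyValidRegionError, InvalidInputError
from qdcp.sampling import NeighborhoodSpec, build_rotation_code_table

from conftest import naive_qdcp_index, orientation_of, random_rgb


class TestOrientationSimilarity:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0, 0), (1, 0, 0), 1.0),
            ((1, 0, 0), (0, 1, 0), 0.0),
            ((1, 0, 0), (0.6, 0.8, 0), 0.6),
        ],
    )
    def test_known_cosines(self, u, v, expected):
        assert orientation_similarity(u, v) == pytest.approx(expected)

    def test_clamped_to_unit_interval(self):
        # antiparallel vectors with round-off cannot escape [-1, 1]
        u = np.array([1.0, 1e-8, 0.0]) / np.sqrt(1 + 1e-16)
        assert -1.0 <= orientation_similarity(u, -u) <= 1.0

    def test_rejects_non_unit(self):
        with pytest.raises(InvalidInputError):
            orientation_similarity((2, 0, 0), (1, 0, 0))


class TestThresholdToAngle:
    def test_angles(self):
        assert threshold_to_angle(1.0) == pytest.approx(0.0)
        assert threshold_to_angle(0.0) == pytest.approx(90.0)
        assert threshold_to_angle(0.8) == pytest.approx(36.8699, abs=1e-3)
        assert int(threshold_to_angle(0.8)) == 36

    def test_out_of_range(self):
        with pytest.raises(InvalidInputError):
            threshold_to_angle(1.2)


def _two_color_orientation():
    """5x5 field: columns 0-2 point along x, columns 3-4 along y."""
    vecs = np.zeros((5, 5, 3))
    vecs[:, :3] = (1, 0, 0)
    vecs[:, 3:] = (0, 1, 0)
    return OrientationField(vecs)


class TestQdcpIndexImage:
    def test_constant_orientation_codes_zero(self, n8_table):
        vecs = np.tile(np.array([0.6, 0.8, 0.0]), (7, 7, 1))
        idx = qdcp_index_image(OrientationField(vecs), NeighborhoodSpec(), 1.0)
        assert np.all(idx.labels[idx.valid_mask] == n8_table.label_of[0])

    def test_t_o_minus_one_codes_zero(self, rng, n8_table):
        orient = orientation_of(random_rgb(rng))
        idx = qdcp_index_image(orient, NeighborhoodSpec(), -1.0)
        assert np.all(idx.labels[idx.valid_mask] == n8_table.label_of[0])

    def test_t_o_above_one_codes_all_ones(self, rng, n8_table):
        orient = orientation_of(random_rgb(rng))
        idx = qdcp_index_image(orient, NeighborhoodSpec(), 1.0 + 1e-9)
        assert np.all(idx.labels[idx.valid_mask] == n8_table.label_of[255])

    def test_two_color_hand_example(self, n4_table):
        # cols 0-2 along x, cols 3-4 along y; N=4, R=1, T_O=0.5:
        # col 1 sees identical colors everywhere -> code 0;
        # col 2 has exactly one discordant (east) neighbor -> raw code 1;
        # col 3 has exactly one discordant (west) neighbor -> same orbit.
        orient = _two_color_orientation()
        idx = qdcp_index_image(orient, NeighborhoodSpec(4, 1.0), 0.5)
        lab = idx.labels
        assert np.all(lab[1:4, 1] == n4_table.label_of[0])
        assert np.all(lab[1:4, 2] == n4_table.label_of[1])
        assert np.all(lab[1:4, 3] == n4_table.label_of[1])
        # and the naive per-pixel oracle agrees everywhere
        ref = naive_qdcp_index(orient, NeighborhoodSpec(4, 1.0), 0.5, n4_table)
        np.testing.assert_array_equal(lab[idx.valid_mask], ref[idx.valid_mask])

    def test_matches_naive_oracle_on_random_images(self, rng, n8_table):
        spec = NeighborhoodSpec()
        for _ in range(5):
            orient = orientation_of(random_rgb(rng))
            idx = qdcp_index_image(orient, spec, 0.8, n8_table)
            ref = naive_qdcp_index(orient, spec, 0.8, n8_table)
            np.testing.assert_array_equal(idx.labels, ref)

    def test_border_mask_width(self, rng):
        orient = orientation_of(random_rgb(rng, 10, 12))
        idx = qdcp_index_image(orient, NeighborhoodSpec(8, 1.5), 0.8)
        expected = np.zeros((10, 12), dtype=bool)
        expected[2:-2, 2:-2] = True
        np.testing.assert_array_equal(idx.valid_mask, expected)
        assert np.all(idx.labels[~idx.valid_mask] == -1)

    def test_too_small_image_raises(self):
        vecs = np.tile(np.array([1.0, 0.0, 0.0]), (2, 2, 1))
        with pytest.raises(EmptyValidRegionError):
            qdcp_index_image(OrientationField(vecs), NeighborhoodSpec(), 0.8)


class TestTextonHistogram:
    def test_constant_image_single_bin(self, n8_table):
        vecs = np.tile(np.array([1.0, 0.0, 0.0]), (6, 6, 1))
        idx = qdcp_index_image(OrientationField(vecs), NeighborhoodSpec(), 0.8)
        h = texton_histogram(idx, normalize=False)
        assert h.bins[n8_table.label_of[0]] == 16  # 4x4 interior
        assert h.bins.sum() == h.n_valid == 16

    def test_normalized_sums_to_one(self, rng):
        orient = orientation_of(random_rgb(rng))
        idx = qdcp_index_image(orient, NeighborhoodSpec(), 0.9)
        h = texton_histogram(idx, normalize=True)
        assert h.bins.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.bins >= 0)
        assert len(h.bins) == 36


class TestQdcpFeaturePipeline:
    @pytest.mark.parametrize("k", [0.25, 0.5, 2.0])
    def test_illumination_scale_invariance(self, counter_image, k):
        base = qdcp_feature(counter_image, normalize=False).bins
        scaled = qdcp_feature(counter_image.pixels * k, normalize=False).bins
        np.testing.assert_array_equal(base, scaled)

    @pytest.mark.parametrize("quarter_turns", [1, 2, 3])
    def test_rotation_invariance(self, counter_image, quarter_turns):
        base = qdcp_feature(counter_image, normalize=False).bins
        rot = qdcp_feature(
            np.ascontiguousarray(np.rot90(counter_image.pixels, quarter_turns)),
            normalize=False,
        ).bins
        np.testing.assert_array_equal(base, rot)

    def test_t_o_monotone_zero_code_count(self, counter_image, n8_table):
        # each bit is non-decreasing in T_O, so the all-agree (code 0)
        # count can only shrink as the threshold rises: coarse-to-fine
        orient = orientation_of(counter_image)
        zero = n8_table.label_of[0]
        counts = []
        for t_o in (-1, -0.5, 0, 0.5, 0.75, 0.8, 0.85, 0.9, 1):
            idx = qdcp_index_image(orient, NeighborhoodSpec(), t_o, n8_table)
            counts.append(int((idx.labels[idx.valid_mask] == zero).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_single_pixel_image_raises(self):
        with pytest.raises(EmptyValidRegionError):
            qdcp_feature(np.full((1, 1, 3), 0.5))
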