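"""Circular neighborhoods, bilinear sampling, rotation-invariant codes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sympy import divisors, totient

from qdcp.colorspace import OrientationField
from qdcp.exceptions import InvalidInputError, OutOfBoundsError
from qdcp.sampling import (
    NeighborhoodSpec,
    bilinear_sample,
    build_rotation_code_table,
    neighbor_offsets,
    rotation_invariant_code,
)


def necklace_count(n: int) -> int:
    """Closed-form number of binary necklaces of length n (Burnside)."""
    return sum(totient(d) * 2 ** (n // d) for d in divisors(n)) // n


class TestNeighborOffsets:
    def test_cardinal_directions_n4(self):
        off = neighbor_offsets(NeighborhoodSpec(4, 1.0))
        np.testing.assert_allclose(
            off, [(1, 0), (0, 1), (-1, 0), (0, -1)], atol=1e-12
        )

    def test_diagonal_sample_n8(self):
        off = neighbor_offsets(NeighborhoodSpec(8, 1.0))
        np.testing.assert_allclose(off[1], (np.sqrt(2) / 2,) * 2, atol=1e-12)

    def test_antipodal_pair_n2_r2(self):
        off = neighbor_offsets(NeighborhoodSpec(2, 2.0))
        np.testing.assert_allclose(off, [(2, 0), (-2, 0)], atol=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(InvalidInputError):
            NeighborhoodSpec(1, 1.0)
        with pytest.raises(InvalidInputError):
            NeighborhoodSpec(8, 0.0)


class TestBilinearSample:
    def test_integer_point_is_exact(self, rng):
        field = rng.uniform(size=(7, 9))
        assert bilinear_sample(field, (3, 5)) == field[5, 3]

    def test_scalar_midpoint(self):
        field = np.array([[2.0, 4.0]])
        assert bilinear_sample(field, (0.5, 0.0)) == pytest.approx(3.0)

    def test_affine_fields_sampled_exactly(self, rng):
        # bilinear interpolation reproduces f(x, y) = a + b x + c y exactly
        a, b, c = 0.3, -1.2, 2.5
        xx, yy = np.meshgrid(np.arange(8), np.arange(6))
        field = a + b * xx + c * yy
        for _ in range(20):
            x = rng.uniform(0, 7)
            y = rng.uniform(0, 5)
            assert bilinear_sample(field, (x, y)) == pytest.approx(
                a + b * x + c * y, abs=1e-9
            )

    def test_orientation_midpoint_renormalized(self):
        vecs = np.zeros((1, 2, 3))
        vecs[0, 0] = (1, 0, 0)
        vecs[0, 1] = (0, 1, 0)
        out = bilinear_sample(OrientationField(vecs), (0.5, 0.0))
        np.testing.assert_allclose(out, (np.sqrt(2) / 2, np.sqrt(2) / 2, 0))
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds(self):
        with pytest.raises(OutOfBoundsError):
            bilinear_sample(np.zeros((4, 4)), (3.5, 1.0))
        with pytest.raises(OutOfBoundsError):
            bilinear_sample(np.zeros((4, 4)), (-0.1, 1.0))


class TestRotationCodeTable:
    def test_n8_has_36_labels(self):
        assert build_rotation_code_table(8).n_labels == 36

    def test_n4_matches_brute_force_orbits(self):
        # independent orbit enumeration over all 16 raw 4-bit codes
        def orbit_min(c, n=4):
            vals = []
            for s in range(n):
                rot = ((c << s) | (c >> (n - s))) & (2**n - 1)
                vals.append(rot)
            return min(vals)

        table = build_rotation_code_table(4)
        expected = sorted({orbit_min(c) for c in range(16)})
        assert table.n_labels == 6
        assert sorted(table.label_of) == expected
        np.testing.assert_array_equal(
            table.minimized_code_of, [orbit_min(c) for c in range(16)]
        )

    @pytest.mark.parametrize("n", range(2, 13))
    def test_label_count_matches_necklace_closed_form(self, n):
        assert build_rotation_code_table(n).n_labels == necklace_count(n)

    @pytest.mark.parametrize("n", [2, 5, 8, 10])
    def test_rotation_fixed_codes(self, n):
        table = build_rotation_code_table(n)
        assert table.minimized_code_of[0] == 0
        assert table.minimized_code_of[2**n - 1] == 2**n - 1

    def test_minimized_not_exceeding_raw(self):
        table = build_rotation_code_table(8)
        assert np.all(table.minimized_code_of <= np.arange(256))

    def test_out_of_range_n(self):
        with pytest.raises(InvalidInputError):
            build_rotation_code_table(1)
        with pytest.raises(InvalidInputError):
            build_rotation_code_table(17)


class TestRotationInvariantCode:
    @pytest.mark.parametrize("n", [4, 8, 10])
    def test_orbit_constancy_exhaustive(self, n):
        # every raw code agrees with all of its cyclic shifts
        table = build_rotation_code_table(n)
        for code in range(2**n):
            bits = [(code >> i) & 1 for i in range(n)]
            ref = rotation_invariant_code(bits, table)
            for s in range(1, n):
                shifted = bits[s:] + bits[:s]
                assert rotation_invariant_code(shifted, table) == ref

    def test_single_set_bit_minimizes_to_one(self, n8_table):
        labels = {
            rotation_invariant_code([int(i == k) for i in range(8)], n8_table)
            for k in range(8)
        }
        assert labels == {n8_table.label_of[1]}

    def test_all_zeros(self, n8_table):
        assert rotation_invariant_code([0] * 8, n8_table) == n8_table.label_of[0]

    def test_length_mismatch(self, n8_table):
        with pytest.raises(InvalidInputError):
            rotation_invariant_code([0, 1], n8_table)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    n=st.integers(2, 12),
    data=st.data(),
)
def test_orbit_constancy_property(n, data):
    table = build_rotation_code_table(n)
    code = data.draw(st.integers(0, 2**n - 1))
    shift = data.draw(st.integers(0, n - 1))
    bits = [(code >> i) & 1 for i in range(n)]
    shifted = bits[shift:] + bits[:shift]
    assert rotation_invariant_code(bits, table) == rotation_invariant_code(
        shifted, table
    )
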