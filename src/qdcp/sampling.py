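"""Circular-neighborhood geometry and rotation-invariant code tables.

Shared machinery for both the counter-color descriptor and LBP: the N
equally spaced sample points on a radius-R circle around each pixel,
bilinear interpolation of scalar and vector fields at those (generally
non-integer) points, and the cyclic-shift-minimization table that maps
raw N-bit neighborhood codes onto rotation-invariant labels.

Coordinate convention: ``x`` is the column index and ``y`` the row
index, both 0-based, with pixel centers at integer coordinates.  Angles
are measured counterclockwise with y increasing downward; sample k sits
at ``angle_origin + 2*pi*k/N``.  Any consistent convention produces the
same rotation-invariant histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .colorspace import ACHROMATIC_ORIENTATION, MagnitudeImage, OrientationField
from .exceptions import InvalidInputError, OutOfBoundsError

__all__ = [
    "NeighborhoodSpec",
    "RotationCodeTable",
    "neighbor_offsets",
    "bilinear_sample",
    "build_rotation_code_table",
    "rotation_invariant_code",
]

#: Offsets closer than this to an integer are snapped onto it, so that
#: samples at (numerically) integer coordinates return stored values exactly.
_SNAP_EPS = 1e-9

_DEGENERATE_NORM = 1e-12


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling geometry: N samples on a circle of radius R."""

    n_samples: int = 8
    radius: float = 1.0
    angle_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InvalidInputError("n_samples must be at least 2")
        if self.radius <= 0:
            raise InvalidInputError("radius must be positive")

    @property
    def border(self) -> int:
        """Width of the border band whose pixels lack a full neighborhood."""
        return int(np.ceil(self.radius))


def neighbor_offsets(spec: NeighborhoodSpec) -> np.ndarray:
    """Return the N (dx, dy) sample offsets of the circular neighborhood.

    Offset k is ``R * (cos(theta_k), sin(theta_k))`` with
    ``theta_k = angle_origin + 2*pi*k/N``; values are snapped to the
    nearest integer when within 1e-9 to keep exactly-cardinal samples on
    pixel centers.
    """
    k = np.arange(spec.n_samples)
    theta = spec.angle_origin + 2.0 * np.pi * k / spec.n_samples
    off = np.stack([spec.radius * np.cos(theta), spec.radius * np.sin(theta)], axis=1)
    snapped = np.round(off)
    off = np.where(np.abs(off - snapped) < _SNAP_EPS, snapped, off)
    return off


def _bilinear_weights(x: float, y: float):
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    if fx < _SNAP_EPS:
        fx = 0.0
    elif fx > 1.0 - _SNAP_EPS:
        x0, fx = x0 + 1, 0.0
    if fy < _SNAP_EPS:
        fy = 0.0
    elif fy > 1.0 - _SNAP_EPS:
        y0, fy = y0 + 1, 0.0
    return x0, y0, fx, fy


def bilinear_sample(field, point: tuple[float, float]):
    """Bilinearly interpolate a field at a real-valued (x, y) point.

    Scalar fields return a float; orientation fields return the
    componentwise interpolation renormalized to unit length (degenerate
    interpolants fall back to the achromatic orientation).  At integer
    coordinates the stored value is returned exactly.
    """
    if isinstance(field, MagnitudeImage):
        arr = field.values
    elif isinstance(field, OrientationField):
        arr = field.vectors
    else:
        arr = np.asarray(field, dtype=float)
    is_vector = arr.ndim == 3
    h, w = arr.shape[:2]
    x, y = float(point[0]), float(point[1])
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise OutOfBoundsError(
            f"sample point ({x}, {y}) outside pixel-center hull "
            f"[0, {w - 1}] x [0, {h - 1}]"
        )
    x0, y0, fx, fy = _bilinear_weights(x, y)
    # two-stage lerp: exact on constant fields (a + t*(b - a) returns a
    # when b == a, which plain weight sums do not guarantee in floats)
    top = arr[y0, x0]
    if fx > 0.0:
        top = top + fx * (arr[y0, x0 + 1] - top)
    val = top
    if fy > 0.0:
        bottom = arr[y0 + 1, x0]
        if fx > 0.0:
            bottom = bottom + fx * (arr[y0 + 1, x0 + 1] - bottom)
        val = top + fy * (bottom - top)
    if not is_vector:
        return float(val)
    norm = np.sqrt(val[0] ** 2 + val[1] ** 2 + val[2] ** 2)
    if norm <= _DEGENERATE_NORM:
        return ACHROMATIC_ORIENTATION.copy()
    return val / norm


def sample_neighbor_stack(arr: np.ndarray, spec: NeighborhoodSpec) -> np.ndarray:
    """Sample all N neighbors for every interior pixel at once.

    ``arr`` is (H, W) or (H, W, C); the result is (H-2b, W-2b, N[, C])
    where b is the border width.  The arithmetic mirrors
    :func:`bilinear_sample` term for term so the two paths agree
    bit-for-bit.  Orientation renormalization is NOT applied here.
    """
    b = spec.border
    h, w = arr.shape[:2]
    if h - 2 * b < 1 or w - 2 * b < 1:
        from .exceptions import EmptyValidRegionError

        raise EmptyValidRegionError(
            f"image of shape {(h, w)} has no interior pixels for radius "
            f"{spec.radius} (needs at least {2 * b + 1} per side)"
        )
    offsets = neighbor_offsets(spec)
    out = np.empty((h - 2 * b, w - 2 * b, spec.n_samples) + arr.shape[2:], arr.dtype)

    def block(y0: int, x0: int) -> np.ndarray:
        return arr[b + y0 : h - b + y0, b + x0 : w - b + x0]

    for k, (dx, dy) in enumerate(offsets):
        x0, y0, fx, fy = _bilinear_weights(float(dx), float(dy))
        top = block(y0, x0)
        if fx > 0.0:
            top = top + fx * (block(y0, x0 + 1) - top)
        val = top
        if fy > 0.0:
            bottom = block(y0 + 1, x0)
            if fx > 0.0:
                bottom = bottom + fx * (block(y0 + 1, x0 + 1) - bottom)
            val = top + fy * (bottom - top)
        out[:, :, k] = val
    return out


@dataclass
class RotationCodeTable:
    """Cyclic-shift minimization of N-bit codes and dense relabeling.

    ``minimized_code_of[c]`` is the minimum over all cyclic bit
    rotations of code c; codes in the same rotation orbit share it.
    ``label_of`` maps each distinct minimized code to a dense label in
    0..P-1 (ascending code order) so histograms have exactly P bins —
    P is the number of binary necklaces of length N (36 for N = 8).
    """

    neighborhood_size: int
    minimized_code_of: np.ndarray
    label_of: dict[int, int] = field(repr=False)
    dense_label_of_code: np.ndarray = field(repr=False)

    @property
    def n_labels(self) -> int:
        return len(self.label_of)


@lru_cache(maxsize=None)
def build_rotation_code_table(n: int) -> RotationCodeTable:
    """Build the rotation-invariant code table for an N-sample ring."""
    if not 2 <= n <= 16:
        raise InvalidInputError(f"neighborhood size must be in [2, 16], got {n}")
    codes = np.arange(2**n, dtype=np.uint32)
    minimized = codes.copy()
    mask = np.uint32(2**n - 1)
    rotated = codes.copy()
    for _ in range(n - 1):
        # one left cyclic shift of the n-bit pattern
        rotated = ((rotated << np.uint32(1)) | (rotated >> np.uint32(n - 1))) & mask
        minimized = np.minimum(minimized, rotated)
    distinct = np.unique(minimized)
    label_of = {int(c): i for i, c in enumerate(distinct)}
    dense = np.searchsorted(distinct, minimized).astype(np.int32)
    return RotationCodeTable(n, minimized, label_of, dense)


def rotation_invariant_code(bits, table: RotationCodeTable) -> int:
    """Dense rotation-invariant label of an N-tuple of {0, 1} bits.

    Bit k (neighbor k) carries weight 2**k; the raw code is minimized
    over cyclic shifts and mapped to its dense label, so any cyclic
    rotation of ``bits`` yields the same output.
    """
    bits = np.asarray(bits, dtype=np.int64)
    n = table.neighborhood_size
    if bits.shape != (n,):
        raise InvalidInputError(
            f"expected {n} bits for this table, got shape {bits.shape}"
        )
    if not np.all((bits == 0) | (bits == 1)):
        raise InvalidInputError("bits must be 0 or 1")
    raw = int((bits << np.arange(n)).sum())
    return int(table.dense_label_of_code[raw])
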