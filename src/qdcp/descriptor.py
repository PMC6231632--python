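"""The counter-color texton descriptor: similarity, coding, histograms.

For every interior pixel p the N neighbor orientations on the sampling
circle are compared with the center orientation through the inner
product ``m_{p,i} = I_O(p) . I_O(i)`` (the cosine of the chromaticity
angle; 1 means co-linear colors, small values mean counter colors).
Each comparison is binarized against a threshold T_O — bit i is set iff
``m_{p,i} < T_O``, i.e. iff the neighbor's color differs from the
center's by more than ``arccos(T_O)`` degrees — and the resulting N-bit
word is reduced to a rotation-invariant texton label by cyclic-shift
minimization.  The image is summarized by the histogram of these
labels.

Small T_O keeps only strong counter-color transitions (a coarse
descriptor); T_O near 1 reacts to the slightest chromaticity change (a
fine but noise-sensitive descriptor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import (
    ACHROMATIC_ORIENTATION,
    ColorImage,
    OrientationField,
    md_decompose,
    to_color_space,
)
from .exceptions import EmptyValidRegionError, InvalidInputError
from .sampling import (
    NeighborhoodSpec,
    RotationCodeTable,
    build_rotation_code_table,
    sample_neighbor_stack,
)

__all__ = [
    "SimilarityVector",
    "TextonIndexImage",
    "FeatureHistogram",
    "orientation_similarity",
    "threshold_to_angle",
    "similarity_stack",
    "qdcp_index_image",
    "texton_histogram",
    "qdcp_feature",
    "DEFAULT_T_O",
    "DEFAULT_T_O_GRID",
]

#: Default similarity threshold: cos 36.87 deg, inside the recommended
#: (0.75, 0.85) band for stained-tissue images.
DEFAULT_T_O = 0.80

#: Default model-selection grid for T_O.
DEFAULT_T_O_GRID = tuple(np.round(np.arange(0.55, 1.0001, 0.05), 2))

_DEGENERATE_NORM = 1e-12
_UNIT_TOL = 1e-6


@dataclass
class SimilarityVector:
    """The N center-vs-neighbor cosines at one pixel, with their bits."""

    values: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not -1.0 <= self.threshold <= 1.0:
            raise InvalidInputError("threshold must lie in [-1, 1]")

    @property
    def bits(self) -> np.ndarray:
        # strict inequality: equality with the threshold leaves the bit 0
        return (self.values < self.threshold).astype(np.uint8)


@dataclass
class TextonIndexImage:
    """Per-pixel texton labels with a validity mask for the border band.

    ``labels`` is H x W int; invalid (border) pixels hold -1.
    """

    labels: np.ndarray
    valid_mask: np.ndarray
    n_labels: int

    @property
    def valid_labels(self) -> np.ndarray:
        return self.labels[self.valid_mask]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class FeatureHistogram:
    """Fixed-length texton-label histogram (counts or L1 frequencies)."""

    bins: np.ndarray
    normalized: bool
    n_valid: int

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)


def orientation_similarity(u, v) -> float:
    """Inner product of two unit 3-vectors, clamped to [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    for vec in (u, v):
        norm = np.sqrt(vec[0] ** 2 + vec[1] ** 2 + vec[2] ** 2)
        if abs(norm - 1.0) > _UNIT_TOL:
            raise InvalidInputError(
                f"orientation vectors must be unit length (norm {norm:.8f})"
            )
    m = u[0] * v[0] + u[1] * v[1] + u[2] * v[2]
    return float(min(1.0, max(-1.0, m)))


def threshold_to_angle(t_o: float) -> float:
    """Color-separation angle, in degrees, corresponding to threshold T_O."""
    if not -1.0 <= t_o <= 1.0:
        raise InvalidInputError(f"T_O must lie in [-1, 1], got {t_o}")
    return float(np.degrees(np.arccos(t_o)))


def similarity_stack(orient: OrientationField, spec: NeighborhoodSpec) -> np.ndarray:
    """Cosine similarities m_{p,i} for all interior pixels and neighbors.

    Returns (H-2b, W-2b, N): neighbor orientations are bilinearly
    interpolated, renormalized to unit length (achromatic fallback for
    degenerate interpolants), and dotted with the center orientation.
    This stack is threshold-free, so a T_O grid search binarizes it
    repeatedly without resampling.
    """
    vec = orient.vectors
    b = spec.border
    samples = sample_neighbor_stack(vec, spec)  # (h, w, N, 3)
    norm = np.sqrt(
        samples[..., 0] ** 2 + samples[..., 1] ** 2 + samples[..., 2] ** 2
    )
    degenerate = norm <= _DEGENERATE_NORM
    samples = samples / np.where(degenerate, 1.0, norm)[..., None]
    samples[degenerate] = ACHROMATIC_ORIENTATION
    center = vec[b : vec.shape[0] - b, b : vec.shape[1] - b]
    m = (
        samples[..., 0] * center[..., 0, None]
        + samples[..., 1] * center[..., 1, None]
        + samples[..., 2] * center[..., 2, None]
    )
    return np.clip(m, -1.0, 1.0)


def _codes_to_index_image(
    bits: np.ndarray, shape: tuple[int, int], border: int, table: RotationCodeTable
) -> TextonIndexImage:
    n = table.neighborhood_size
    weights = (1 << np.arange(n)).astype(np.int64)
    raw = bits.astype(np.int64) @ weights
    labels = np.full(shape, -1, dtype=np.int32)
    h, w = shape
    labels[border : h - border, border : w - border] = table.dense_label_of_code[raw]
    mask = np.zeros(shape, dtype=bool)
    mask[border : h - border, border : w - border] = True
    return TextonIndexImage(labels, mask, table.n_labels)


def qdcp_index_image(
    orient: OrientationField,
    spec: NeighborhoodSpec,
    t_o: float,
    table: RotationCodeTable | None = None,
) -> TextonIndexImage:
    """Rotation-invariant counter-color texton label at every interior pixel."""
    if table is None:
        table = build_rotation_code_table(spec.n_samples)
    if table.neighborhood_size != spec.n_samples:
        raise InvalidInputError("code table does not match the neighborhood size")
    if not np.isfinite(t_o):
        raise InvalidInputError(f"T_O must be finite, got {t_o}")
    # cosines live in [-1, 1]; thresholds outside that range are legal but
    # degenerate (all-zero or all-one codes), useful as boundary checks
    m = similarity_stack(orient, spec)
    bits = m < t_o
    return _codes_to_index_image(bits, orient.shape, spec.border, table)


def texton_histogram(idx: TextonIndexImage, normalize: bool = True) -> FeatureHistogram:
    """Histogram of texton labels over the valid pixels."""
    n_valid = idx.n_valid
    if n_valid == 0:
        raise EmptyValidRegionError("index image has no valid pixels")
    bins = np.bincount(idx.valid_labels, minlength=idx.n_labels).astype(float)
    if normalize:
        bins = bins / n_valid
    return FeatureHistogram(bins, normalized=normalize, n_valid=n_valid)


def qdcp_feature(
    img: ColorImage | np.ndarray,
    spec: NeighborhoodSpec | None = None,
    t_o: float = DEFAULT_T_O,
    color_space: str = "ycbcr",
    normalize: bool = True,
) -> FeatureHistogram:
    """Full pipeline: color conversion, MD decomposition, coding, histogram."""
    spec = spec or NeighborhoodSpec()
    converted = to_color_space(img, color_space)
    _, orient = md_decompose(converted)
    idx = qdcp_index_image(orient, spec, t_o)
    return texton_histogram(idx, normalize=normalize)
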