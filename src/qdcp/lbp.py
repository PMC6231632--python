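"""Rotation-invariant LBP on scalar images.

LBP codes the order relation between each interior pixel and its N
circle neighbors: bit i is set iff the (bilinearly interpolated)
neighbor value is >= the center value.  The same cyclic-shift
minimization used for the counter-color descriptor reduces the code to
one of the P rotation-invariant labels, so LBP and counter-color
histograms share bin semantics and fuse cleanly.

Used on the color-magnitude image as the brightness-texture half of the
fused descriptor, and on the luma channel as the grayscale baseline.
"""

from __future__ import annotations

import numpy as np

from .colorspace import ColorImage, MagnitudeImage, md_decompose, to_color_space
from .descriptor import (
    FeatureHistogram,
    TextonIndexImage,
    _codes_to_index_image,
    texton_histogram,
)
from .exceptions import InvalidInputError
from .sampling import (
    NeighborhoodSpec,
    RotationCodeTable,
    build_rotation_code_table,
    sample_neighbor_stack,
)

__all__ = ["lbp_index_image", "lbp_feature"]

LBP_SOURCES = ("magnitude", "luma")


def lbp_index_image(
    scalar: MagnitudeImage | np.ndarray,
    spec: NeighborhoodSpec,
    table: RotationCodeTable | None = None,
) -> TextonIndexImage:
    """Rotation-invariant LBP label at every interior pixel.

    Comparison convention: bit = 1 iff neighbor >= center (ties set the
    bit), so a constant image codes as all-ones.
    """
    if table is None:
        table = build_rotation_code_table(spec.n_samples)
    if table.neighborhood_size != spec.n_samples:
        raise InvalidInputError("code table does not match the neighborhood size")
    arr = scalar.values if isinstance(scalar, MagnitudeImage) else np.asarray(
        scalar, dtype=float
    )
    b = spec.border
    samples = sample_neighbor_stack(arr, spec)  # (h, w, N)
    center = arr[b : arr.shape[0] - b, b : arr.shape[1] - b]
    bits = samples >= center[..., None]
    return _codes_to_index_image(bits, arr.shape, b, table)


def lbp_feature(
    img: ColorImage | np.ndarray,
    source: str = "magnitude",
    spec: NeighborhoodSpec | None = None,
    normalize: bool = True,
) -> FeatureHistogram:
    """LBP histogram of an RGB image's magnitude or luma component.

    ``source='magnitude'`` codes the Euclidean norm of the YCbCr color
    vectors (the fusion ingredient); ``source='luma'`` codes the Y
    channel alone (the grayscale comparison baseline).
    """
    if source not in LBP_SOURCES:
        raise InvalidInputError(
            f"unknown LBP source {source!r}; expected one of {LBP_SOURCES}"
        )
    spec = spec or NeighborhoodSpec()
    ycbcr = to_color_space(img, "ycbcr")
    if source == "magnitude":
        scalar, _ = md_decompose(ycbcr)
        arr = scalar.values
    else:
        arr = ycbcr.pixels[..., 0]
    idx = lbp_index_image(arr, spec)
    return texton_histogram(idx, normalize=normalize)
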