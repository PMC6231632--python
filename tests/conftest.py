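"""Shared fixtures and independent reference (oracle) implementations.

The oracles deliberately use slow per-pixel Python loops built only on
the pointwise public primitives (`bilinear_sample`,
`orientation_similarity`, `rotation_invariant_code`), so they share no
code path with the vectorized index-image implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from qdcp.colorspace import OrientationField, md_decompose
from qdcp.sampling import (
    NeighborhoodSpec,
    bilinear_sample,
    build_rotation_code_table,
    neighbor_offsets,
    rotation_invariant_code,
)
from qdcp.descriptor import orientation_similarity
from qdcp.synthetic import StainTextureParams, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def counter_image():
    return generate_image(StainTextureParams(seed=11), "counter")


@pytest.fixture
def smooth_image():
    return generate_image(StainTextureParams(seed=11), "smooth")


def random_rgb(rng, h=16, w=16):
    """Random positive RGB image (no exact zeros, no exact ties)."""
    return rng.uniform(0.05, 1.0, size=(h, w, 3))


def naive_qdcp_index(orient: OrientationField, spec: NeighborhoodSpec, t_o, table):
    """Per-pixel reference for the counter-color index image."""
    vec = orient.vectors
    h, w = vec.shape[:2]
    b = spec.border
    offsets = neighbor_offsets(spec)
    labels = np.full((h, w), -1, dtype=int)
    for r in range(b, h - b):
        for c in range(b, w - b):
            center = vec[r, c]
            bits = []
            for dx, dy in offsets:
                nb = bilinear_sample(orient, (c + dx, r + dy))
                m = orientation_similarity(center, nb)
                bits.append(1 if m < t_o else 0)
            labels[r, c] = rotation_invariant_code(bits, table)
    return labels


def naive_lbp_index(scalar: np.ndarray, spec: NeighborhoodSpec, table):
    """Per-pixel reference for the LBP index image (neighbor >= center)."""
    h, w = scalar.shape
    b = spec.border
    offsets = neighbor_offsets(spec)
    labels = np.full((h, w), -1, dtype=int)
    for r in range(b, h - b):
        for c in range(b, w - b):
            bits = []
            for dx, dy in offsets:
                nb = bilinear_sample(scalar, (c + dx, r + dy))
                bits.append(1 if nb >= scalar[r, c] else 0)
            labels[r, c] = rotation_invariant_code(bits, table)
    return labels


def orientation_of(img):
    """YCbCr orientation field of an RGB image (pipeline front half)."""
    from qdcp.colorspace import rgb_to_ycbcr

    pixels = img.pixels if hasattr(img, "pixels") else img
    return md_decompose(rgb_to_ycbcr(pixels))[1]


@pytest.fixture
def n8_table():
    return build_rotation_code_table(8)


@pytest.fixture
def n4_table():
    return build_rotation_code_table(4)
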