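"""Color-space conversion and magnitude-direction (MD) decomposition.

A color image is a map from the pixel grid to 3-vectors in some color
space.  Every color vector ``I(p)`` factors uniquely into a scalar
brightness ``I_M(p) = ||I(p)||`` and a unit-length chromaticity
orientation ``I_O(p) = I(p) / I_M(p)``; the counter-color descriptor is
computed entirely from the orientation field, which makes it invariant
to global brightness scaling.

Achromatic convention: a vector of (near-)zero magnitude has no defined
direction; such pixels are assigned the unit vector ``(1, 0, 0)`` (the
luma axis in YCbCr), keeping the orientation field total and unit-norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

from .exceptions import InvalidInputError

__all__ = [
    "ColorImage",
    "COLOR_SPACES",
    "YCBCR_MATRIX",
    "ACHROMATIC_ORIENTATION",
    "rgb_to_ycbcr",
    "md_decompose",
    "to_color_space",
    "load_rgb",
]

COLOR_SPACES = ("rgb", "ycbcr", "cielab", "i1h2h3")

#: Bare RGB -> YCbCr matrix (no studio-swing offsets).  Rows: Y, Cb, Cr.
YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.596, -0.274, -0.322],
        [0.211, -0.523, 0.312],
    ]
)

#: Orientation assigned to zero-magnitude (true black) pixels.
ACHROMATIC_ORIENTATION = np.array([1.0, 0.0, 0.0])

#: Magnitudes at or below this are treated as degenerate (achromatic).
DEGENERACY_EPS = 1e-12


@dataclass
class ColorImage:
    """An H x W grid of 3-component color vectors in a named space.

    ``pixels`` is float with shape (H, W, 3).  ``value_range`` is the
    nominal range of channel 1 (Y for YCbCr, L* for CIELab) and is
    informational only.
    """

    pixels: np.ndarray
    space: str = "rgb"
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"pixels must have shape (H, W, 3), got {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidInputError("image must contain at least one pixel")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("pixel values must be finite")
        space = self.space.lower()
        if space not in COLOR_SPACES:
            raise InvalidInputError(
                f"unknown color space {self.space!r}; expected one of {COLOR_SPACES}"
            )
        self.space = space
        if self.space == "rgb" and np.any(self.pixels < 0):
            raise InvalidInputError("RGB pixel values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MagnitudeImage:
    """Per-pixel Euclidean norms of the color vectors (brightness)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class OrientationField:
    """Per-pixel unit-length color direction vectors (chromaticity)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]


def _as_color_image(img, space: str | None = None) -> ColorImage:
    if isinstance(img, ColorImage):
        return img
    return ColorImage(np.asarray(img, dtype=float), space or "rgb")


def load_rgb(pixels: np.ndarray) -> ColorImage:
    """Wrap a decoded image array as an RGB :class:`ColorImage` in [0, 1].

    8-bit integer input is divided by 255; float input is assumed to be
    scaled to [0, 1] already.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / 255.0
    return ColorImage(arr.astype(float), "rgb")


def rgb_to_ycbcr(img: ColorImage | np.ndarray) -> ColorImage:
    """Apply the bare linear RGB -> YCbCr transform pixelwise.

    No studio-swing offsets are added, so Cb/Cr are signed and the
    chromaticity orientations occupy most of the upper unit hemisphere,
    widening the useful range of the similarity threshold to [-1, 1].
    """
    img = _as_color_image(img)
    if img.space != "rgb":
        raise InvalidInputError(f"expected an RGB image, got space {img.space!r}")
    out = img.pixels @ YCBCR_MATRIX.T
    return ColorImage(out, "ycbcr", value_range=(0.0, 1.0))


def _rgb_to_i1h2h3(pixels: np.ndarray) -> np.ndarray:
    # Ohta-style stain-friendly axes: intensity plus two hue-like opponents.
    r, g, b = pixels[..., 0], pixels[..., 1], pixels[..., 2]
    i1 = (r + g + b) / 3.0
    h2 = r - b
    h3 = (2.0 * g - r - b) / 2.0
    return np.stack([i1, h2, h3], axis=-1)


def to_color_space(img: ColorImage | np.ndarray, target: str) -> ColorImage:
    """Convert an RGB image to ``target`` in {rgb, ycbcr, cielab, i1h2h3}.

    CIELab uses the D65 white point (standard sRGB-companded transform);
    I1H2H3 is the linear Ohta-style intensity/opponent transform.
    """
    img = _as_color_image(img)
    if img.space != "rgb":
        raise InvalidInputError(f"expected an RGB image, got space {img.space!r}")
    target = str(target).lower()
    if target == "rgb":
        return ColorImage(img.pixels.copy(), "rgb", img.value_range)
    if target == "ycbcr":
        return rgb_to_ycbcr(img)
    if target == "cielab":
        lab = _skcolor.rgb2lab(np.clip(img.pixels, 0.0, 1.0))
        return ColorImage(lab, "cielab", value_range=(0.0, 100.0))
    if target == "i1h2h3":
        return ColorImage(_rgb_to_i1h2h3(img.pixels), "i1h2h3", img.value_range)
    raise InvalidInputError(
        f"unknown target color space {target!r}; expected one of {COLOR_SPACES}"
    )


def md_decompose(img: ColorImage | np.ndarray) -> tuple[MagnitudeImage, OrientationField]:
    """Split a color image into magnitude and unit orientation fields.

    ``pixel = magnitude * orientation`` reconstructs the input wherever
    the magnitude exceeds the degeneracy threshold; degenerate pixels
    receive the achromatic orientation (1, 0, 0).
    """
    if isinstance(img, ColorImage):
        pixels = img.pixels
    else:
        pixels = np.asarray(img, dtype=float)
    mag = np.sqrt(
        pixels[..., 0] ** 2 + pixels[..., 1] ** 2 + pixels[..., 2] ** 2
    )
    degenerate = mag <= DEGENERACY_EPS
    safe = np.where(degenerate, 1.0, mag)
    orient = pixels / safe[..., None]
    orient[degenerate] = ACHROMATIC_ORIENTATION
    return MagnitudeImage(mag), OrientationField(orient)
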