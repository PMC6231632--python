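"""Synthetic two-class stained-texture image generator.

Emulates the statistical contrast the counter-color descriptor is built
for, without requiring external pathology image sets:

* class ``counter`` — a background stain chromaticity with
  Poisson-scattered soft-edged disks of a second, well-separated stain
  chromaticity (think glomerular tufts in a Masson's trichrome section:
  red muscle/cytoplasm interleaved with blue-green collagen);
* class ``smooth`` — a single chromaticity everywhere, carrying only a
  brightness texture (think a lymphocyte crop: smooth color, texture in
  luminance alone).

Brightness is a clipped, smoothed random field applied multiplicatively
to the unit chroma vector, so the two classes share identical
brightness-texture statistics and differ purely in chromaticity
orientation — exactly the quantity the counter-color descriptor codes,
which keeps brightness-descriptor ablations meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .colorspace import ColorImage
from .exceptions import InvalidInputError

__all__ = ["StainTextureParams", "generate_image", "generate_dataset", "CLASSES"]

CLASSES = ("counter", "smooth")

#: Masson's-trichrome-like stain directions (RGB, unnormalized):
#: a red (muscle/cytoplasm) background and a blue-green (collagen) foreground.
_DEFAULT_BG = (0.80, 0.35, 0.40)
_DEFAULT_FG_HINT = (0.25, 0.65, 0.70)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rotate_towards(u: np.ndarray, hint: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit vector at exactly ``angle_deg`` from u, in the plane of (u, hint)."""
    w = hint - (hint @ u) * u
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        raise InvalidInputError("chroma hint is collinear with the background chroma")
    w = w / norm
    theta = np.radians(angle_deg)
    return np.cos(theta) * u + np.sin(theta) * w


@dataclass(frozen=True)
class StainTextureParams:
    """Generator settings; defaults model small stained-tissue patches."""

    image_size: tuple[int, int] = (64, 64)
    bg_chroma: tuple[float, float, float] = _DEFAULT_BG
    fg_chroma: tuple[float, float, float] | None = None
    chroma_separation_deg: float = 40.0
    blob_density: float = 80.0  # expected disks per 100 x 100 px
    blob_radius_range: tuple[float, float] = (2.0, 4.0)
    brightness_field_sigma: float = 6.0  # px, smoothing scale of the field
    brightness_noise_sd: float = 0.03  # relative multiplicative noise
    seed: int = 0

    def resolve_chromas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit bg/fg chroma pair at exactly the requested separation."""
        bg = _unit(self.bg_chroma)
        if self.fg_chroma is not None:
            fg = _unit(self.fg_chroma)
        else:
            fg = _rotate_towards(bg, _unit(_DEFAULT_FG_HINT), self.chroma_separation_deg)
        for name, vec in (("bg_chroma", bg), ("fg_chroma", fg)):
            if np.any(vec <= 0):
                raise InvalidInputError(
                    f"{name} has non-positive components, not a valid RGB stain color"
                )
        angle = np.degrees(np.arccos(np.clip(bg @ fg, -1.0, 1.0)))
        if abs(angle - self.chroma_separation_deg) > 0.1:
            raise InvalidInputError(
                f"bg/fg chroma pair is {angle:.2f} deg apart, but "
                f"chroma_separation_deg={self.chroma_separation_deg}"
            )
        return bg, fg


def _brightness_field(rng: np.random.Generator, h: int, w: int,
                      sigma: float, noise_sd: float) -> np.ndarray:
    """Smoothed positive brightness field with multiplicative pixel noise."""
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
    sd = base.std()
    if sd > 0:
        base = base / sd
    bright = 0.70 + 0.12 * base
    bright = bright * (1.0 + noise_sd * rng.standard_normal((h, w)))
    # clip the scalar only: chroma components are <= 1, so pixel = chroma * b
    # stays in [0, 1] and the clip never touches the orientation
    return np.clip(bright, 0.05, 1.0)


def _blob_alpha(rng: np.random.Generator, h: int, w: int,
                density: float, radius_range: tuple[float, float]) -> np.ndarray:
    """Foreground mixing weight: soft-edged disks, half-pixel linear ramp.

    The ramp is sub-pixel so adjacent pixels can realize the full
    stain-to-stain chromaticity step (a multi-pixel ramp would halve
    the per-pixel angular change and hide the counter-color structure
    from a unit-radius sampling ring), while still giving the bilinear
    sampler a continuous edge rather than a binary mask.
    """
    alpha = np.zeros((h, w))
    n_blobs = rng.poisson(density * h * w / 1e4)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(*radius_range)
        d = np.hypot(yy - cy, xx - cx)
        ramp = np.clip((r - d) / 0.5, 0.0, 1.0)  # 1 inside, 0.5-px edge
        alpha = np.maximum(alpha, ramp)
    return alpha


def generate_image(params: StainTextureParams, class_label: str) -> ColorImage:
    """One synthetic stained patch of the requested class (seeded)."""
    if class_label not in CLASSES:
        raise InvalidInputError(
            f"unknown class {class_label!r}; expected one of {CLASSES}"
        )
    bg, fg = params.resolve_chromas()
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    bright = _brightness_field(
        rng, h, w, params.brightness_field_sigma, params.brightness_noise_sd
    )
    if class_label == "counter":
        alpha = _blob_alpha(rng, h, w, params.blob_density, params.blob_radius_range)
    else:
        alpha = np.zeros((h, w))
    chroma = (1.0 - alpha[..., None]) * bg + alpha[..., None] * fg
    chroma = chroma / np.linalg.norm(chroma, axis=-1, keepdims=True)
    pixels = chroma * bright[..., None]
    return ColorImage(pixels, "rgb")


def generate_dataset(
    n_per_class: int,
    params: StainTextureParams | None = None,
    seed: int | None = None,
) -> tuple[list[ColorImage], np.ndarray]:
    """Balanced two-class dataset of 2 * n_per_class seeded images.

    Per-image seeds are spawned deterministically from the master seed,
    so the same call reproduces the same dataset bit for bit.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be at least 1")
    params = params or StainTextureParams()
    master = params.seed if seed is None else seed
    seeds = np.random.SeedSequence(master).generate_state(2 * n_per_class)
    images: list[ColorImage] = []
    labels: list[str] = []
    for i in range(n_per_class):
        for j, cls in enumerate(CLASSES):
            img_seed = int(seeds[2 * i + j]) % (2**31)
            images.append(generate_image(replace(params, seed=img_seed), cls))
            labels.append(cls)
    return images, np.array(labels)
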