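"""Fusing counter-color and LBP textons into a single feature vector.

Two schemes:

* concatenation (``QDCP-LBP``): the two P-bin histograms side by side,
  a 2P-vector — cheap, but discards which textons co-occur;
* joint (``QDCP/LBP``): the P x P co-occurrence table of (counter-color
  label, LBP label) pairs over the shared valid pixels, flattened
  row-major with the counter-color label as the row — a P^2-vector that
  keeps co-occurrence at the price of sparsity on small images.

For the standard 8-sample ring (P = 36) the lengths are 72 and 1296.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptor import FeatureHistogram, TextonIndexImage
from .exceptions import EmptyValidRegionError, InvalidInputError

__all__ = ["FusedFeature", "fuse_concat", "fuse_joint"]


@dataclass
class FusedFeature:
    """Fused feature vector with its scheme and provenance sizes."""

    vector: np.ndarray
    scheme: str  # "concat" | "joint"
    n_labels: int
    normalized: bool

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)


def fuse_concat(h_qdcp: FeatureHistogram, h_lbp: FeatureHistogram) -> FusedFeature:
    """Concatenate the two histograms (counter-color block first)."""
    if h_qdcp.bins.shape != h_lbp.bins.shape:
        raise InvalidInputError(
            f"histogram lengths differ: {h_qdcp.bins.shape} vs {h_lbp.bins.shape}"
        )
    if h_qdcp.normalized != h_lbp.normalized:
        raise InvalidInputError("histograms must share their normalization state")
    return FusedFeature(
        np.concatenate([h_qdcp.bins, h_lbp.bins]),
        scheme="concat",
        n_labels=len(h_qdcp.bins),
        normalized=h_qdcp.normalized,
    )


def fuse_joint(
    qdcp_idx: TextonIndexImage,
    lbp_idx: TextonIndexImage,
    normalize: bool = True,
) -> FusedFeature:
    """Flattened P x P co-occurrence table of the two label images.

    Cell (a, b) counts valid pixels carrying counter-color label a and
    LBP label b; row sums reproduce the counter-color histogram and
    column sums the LBP histogram.
    """
    if qdcp_idx.labels.shape != lbp_idx.labels.shape or not np.array_equal(
        qdcp_idx.valid_mask, lbp_idx.valid_mask
    ):
        raise InvalidInputError("index images must share shape and valid mask")
    if qdcp_idx.n_labels != lbp_idx.n_labels:
        raise InvalidInputError("index images must share the label alphabet")
    p = qdcp_idx.n_labels
    a = qdcp_idx.valid_labels
    b = lbp_idx.valid_labels
    if a.size == 0:
        raise EmptyValidRegionError("index images have no valid pixels")
    table = np.bincount(a * p + b, minlength=p * p).astype(float)
    if normalize:
        table = table / a.size
    return FusedFeature(table, scheme="joint", n_labels=p, normalized=normalize)
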