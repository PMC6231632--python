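"""scikit-learn style transformers over the descriptor pipeline.

Each estimator consumes a list (or array) of RGB images — either
:class:`~qdcp.colorspace.ColorImage` instances or H x W x 3 arrays —
and produces a 2-D feature matrix, one histogram (or fused vector) per
image.  ``fit`` validates parameters and builds the rotation-invariant
code table; the transformers are otherwise stateless, so they compose
with :class:`sklearn.pipeline.Pipeline` and the model-selection tools,
including grid search over the similarity threshold ``t_o``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .colorspace import COLOR_SPACES, md_decompose, to_color_space
from .descriptor import (
    DEFAULT_T_O,
    qdcp_index_image,
    texton_histogram,
)
from .exceptions import InvalidInputError
from .fusion import fuse_concat, fuse_joint
from .lbp import LBP_SOURCES, lbp_index_image
from .sampling import NeighborhoodSpec, build_rotation_code_table

__all__ = ["QDCPDescriptor", "LBPDescriptor", "FusedDescriptor", "DESCRIPTOR_NAMES"]

#: Named configurations accepted by the CLI and evaluation harness.
DESCRIPTOR_NAMES = ("qdcp", "lbp-luma", "lbp-magnitude", "qdcp-lbp", "qdcp-joint-lbp")


class _RingDescriptorBase(BaseEstimator, TransformerMixin):
    """Shared circular-neighborhood plumbing for the texton transformers."""

    def __init__(self, n_samples=8, radius=1.0, normalize=True):
        self.n_samples = n_samples
        self.radius = radius
        self.normalize = normalize

    def _spec(self) -> NeighborhoodSpec:
        return NeighborhoodSpec(self.n_samples, self.radius)

    def fit(self, X, y=None):
        spec = self._spec()
        self.code_table_ = build_rotation_code_table(spec.n_samples)
        self.n_labels_ = self.code_table_.n_labels
        return self

    def transform(self, X):
        if not hasattr(self, "code_table_"):
            self.fit(X)
        rows = [self._transform_one(img) for img in X]
        return np.vstack(rows)

    def _transform_one(self, img) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class QDCPDescriptor(_RingDescriptorBase):
    """Counter-color texton histogram transformer.

    Parameters
    ----------
    t_o : float
        Similarity threshold in [-1, 1]; neighbor colors whose cosine
        with the center falls below it count as counter colors.
    color_space : str
        Space in which orientations are taken; YCbCr by default (its
        signed chroma axes spread stain orientations over most of the
        upper hemisphere).
    n_samples, radius : ring geometry (8 samples, unit radius default).
    normalize : L1-normalize the histogram (frequencies) if True.
    """

    def __init__(self, n_samples=8, radius=1.0, t_o=DEFAULT_T_O,
                 color_space="ycbcr", normalize=True):
        super().__init__(n_samples, radius, normalize)
        self.t_o = t_o
        self.color_space = color_space

    def fit(self, X, y=None):
        if str(self.color_space).lower() not in COLOR_SPACES:
            raise InvalidInputError(f"unknown color space {self.color_space!r}")
        if not -1.0 <= self.t_o <= 1.0:
            raise InvalidInputError(f"t_o must lie in [-1, 1], got {self.t_o}")
        return super().fit(X, y)

    def _transform_one(self, img) -> np.ndarray:
        converted = to_color_space(img, self.color_space)
        _, orient = md_decompose(converted)
        idx = qdcp_index_image(orient, self._spec(), self.t_o, self.code_table_)
        return texton_histogram(idx, normalize=self.normalize).bins


class LBPDescriptor(_RingDescriptorBase):
    """Rotation-invariant LBP histogram transformer.

    ``source='magnitude'`` codes the YCbCr color-vector norm;
    ``source='luma'`` codes the Y channel (the grayscale baseline).
    """

    def __init__(self, n_samples=8, radius=1.0, source="magnitude", normalize=True):
        super().__init__(n_samples, radius, normalize)
        self.source = source

    def fit(self, X, y=None):
        if self.source not in LBP_SOURCES:
            raise InvalidInputError(f"unknown LBP source {self.source!r}")
        return super().fit(X, y)

    def _scalar(self, img) -> np.ndarray:
        ycbcr = to_color_space(img, "ycbcr")
        if self.source == "magnitude":
            mag, _ = md_decompose(ycbcr)
            return mag.values
        return ycbcr.pixels[..., 0]

    def _transform_one(self, img) -> np.ndarray:
        idx = lbp_index_image(self._scalar(img), self._spec(), self.code_table_)
        return texton_histogram(idx, normalize=self.normalize).bins


class FusedDescriptor(_RingDescriptorBase):
    """Fused counter-color + LBP transformer.

    ``scheme='concat'`` concatenates the two histograms (length 2P);
    ``scheme='joint'`` flattens their P x P co-occurrence table
    (length P^2).  The LBP half always runs on the magnitude image.
    """

    def __init__(self, n_samples=8, radius=1.0, t_o=DEFAULT_T_O,
                 color_space="ycbcr", scheme="concat", normalize=True):
        super().__init__(n_samples, radius, normalize)
        self.t_o = t_o
        self.color_space = color_space
        self.scheme = scheme

    def fit(self, X, y=None):
        if self.scheme not in ("concat", "joint"):
            raise InvalidInputError(f"unknown fusion scheme {self.scheme!r}")
        if str(self.color_space).lower() not in COLOR_SPACES:
            raise InvalidInputError(f"unknown color space {self.color_space!r}")
        if not -1.0 <= self.t_o <= 1.0:
            raise InvalidInputError(f"t_o must lie in [-1, 1], got {self.t_o}")
        return super().fit(X, y)

    def _transform_one(self, img) -> np.ndarray:
        spec = self._spec()
        converted = to_color_space(img, self.color_space)
        mag, orient = md_decompose(converted)
        q_idx = qdcp_index_image(orient, spec, self.t_o, self.code_table_)
        ycbcr_mag, _ = md_decompose(to_color_space(img, "ycbcr"))
        l_idx = lbp_index_image(ycbcr_mag.values, spec, self.code_table_)
        if self.scheme == "concat":
            return fuse_concat(
                texton_histogram(q_idx, self.normalize),
                texton_histogram(l_idx, self.normalize),
            ).vector
        return fuse_joint(q_idx, l_idx, normalize=self.normalize).vector


def make_descriptor(name: str, **kwargs):
    """Descriptor transformer from a CLI-style name."""
    name = str(name).lower()
    if name == "qdcp":
        return QDCPDescriptor(**kwargs)
    if name == "lbp-luma":
        return LBPDescriptor(source="luma", **kwargs)
    if name == "lbp-magnitude":
        return LBPDescriptor(source="magnitude", **kwargs)
    if name == "qdcp-lbp":
        return FusedDescriptor(scheme="concat", **kwargs)
    if name == "qdcp-joint-lbp":
        return FusedDescriptor(scheme="joint", **kwargs)
    raise InvalidInputError(
        f"unknown descriptor {name!r}; expected one of {DESCRIPTOR_NAMES}"
    )
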