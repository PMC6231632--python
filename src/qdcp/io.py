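"""Dataset directory conventions and feature/report serialization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorspace import ColorImage, load_rgb
from .exceptions import FormatError, InvalidInputError

__all__ = [
    "DatasetManifest",
    "load_dataset",
    "load_image",
    "save_image",
    "write_features",
    "read_features",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class DatasetManifest:
    """Class-labeled image paths, lexicographically ordered."""

    paths: list[Path]
    labels: list[str]
    source_root: Path

    def __len__(self) -> int:
        return len(self.paths)

    def load_images(self) -> list[ColorImage]:
        return [load_image(p) for p in self.paths]


def load_image(path) -> ColorImage:
    """Decode a PNG/TIFF into an RGB ColorImage scaled to [0, 1]."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # surface the offending path
        raise InvalidInputError(f"cannot decode image {path}: {exc}") from exc
    return load_rgb(arr)


def save_image(img: ColorImage, path) -> None:
    """Write an RGB ColorImage as an 8-bit PNG/TIFF."""
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_dataset(root) -> DatasetManifest:
    """Enumerate a class-per-subdirectory tree or a CSV manifest.

    A directory is scanned for subdirectories (the class labels), each
    containing images; a ``.csv`` file is read as columns
    ``(image_path, class_label)`` with paths relative to its parent.
    Enumeration is lexicographic, so re-runs produce identical order.
    """
    root = Path(root)
    if root.is_file() and root.suffix.lower() == ".csv":
        df = pd.read_csv(root)
        if not {"image_path", "class_label"}.issubset(df.columns):
            raise FormatError(
                f"manifest {root} must have columns image_path, class_label"
            )
        base = root.parent
        paths = [base / p for p in df["image_path"]]
        labels = [str(x) for x in df["class_label"]]
        order = np.argsort([str(p) for p in paths], kind="stable")
        paths = [paths[i] for i in order]
        labels = [labels[i] for i in order]
    elif root.is_dir():
        paths, labels = [], []
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            for f in sorted(sub.iterdir()):
                if f.suffix.lower() in _IMAGE_SUFFIXES:
                    paths.append(f)
                    labels.append(sub.name)
    else:
        raise InvalidInputError(f"{root} is neither a directory nor a CSV manifest")
    if not paths:
        raise InvalidInputError(f"no images found under {root}")
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise InvalidInputError(f"missing image file: {missing[0]}")
    if len(set(labels)) < 2:
        raise InvalidInputError(
            f"classification needs at least 2 classes, found {sorted(set(labels))}"
        )
    return DatasetManifest(paths, labels, root)


def write_features(path, paths, labels, features: np.ndarray) -> None:
    """CSV feature table: path, label, bin_000... (12 significant digits)."""
    features = np.asarray(features, dtype=float)
    cols = [f"bin_{j:03d}" for j in range(features.shape[1])]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "label", list(labels))
    df.insert(0, "path", [str(p) for p in paths])
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path) -> tuple[list[str], list[str], np.ndarray]:
    """Inverse of :func:`write_features`."""
    df = pd.read_csv(path)
    if len(df.columns) < 3 or list(df.columns[:2]) != ["path", "label"]:
        raise FormatError(f"{path} is not a feature table (path, label, bin_*)")
    bin_cols = list(df.columns[2:])
    if any(not c.startswith("bin_") for c in bin_cols):
        raise FormatError(f"{path} has unexpected feature columns")
    return (
        [str(p) for p in df["path"]],
        [str(x) for x in df["label"]],
        df[bin_cols].to_numpy(dtype=float),
    )
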