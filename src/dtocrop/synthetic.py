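"""Synthetic drone-style crop imagery and feature tables.

Real crop-patch collections pair small multi-band image tiles with one class
label per tile.  No public accession exists for the six-class drone set this
package emulates, so this module generates statistically controlled stand-ins:
each class has a per-band mean reflectance *signature*; patches are the
signature plus optional low-frequency spatial texture plus i.i.d. Gaussian
pixel noise, clipped to [0, 1].  The model is deliberately the simplest one
under which feature-extractor hyperparameters matter; it makes no claim of
radiometric fidelity.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical parameters and seed give bit-identical datasets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

__all__ = [
    "ClassSpec",
    "LabeledImageSet",
    "FeatureTable",
    "generate_imageset",
    "generate_feature_table",
    "reference_class_specs",
    "REFERENCE_CLASS_COUNTS",
    "save_imageset",
    "load_imageset",
    "export_png",
    "load_image_directory",
]

#: Class names and patch counts of the six-class drone-imagery collection the
#: generator emulates (2,075 + 1,661 + 1,270 + 750 + 363 + 331 = 6,450).
REFERENCE_CLASS_COUNTS: dict[str, int] = {
    "Maize": 2075,
    "Banana": 1661,
    "Forest": 1270,
    "Other": 750,
    "Legume": 363,
    "Structure": 331,
}


@dataclass(frozen=True)
class ClassSpec:
    """Generative description of one crop class.

    Parameters
    ----------
    name : str
        Class label.
    count : int
        Number of patches to generate (>= 1).
    signature : ndarray
        Per-band mean intensity in [0, 1]; length must equal the dataset
        band count.
    texture_scale : float, default 0.0
        Amplitude of smoothed (spatially correlated) within-patch texture.
    """

    name: str
    count: int
    signature: np.ndarray
    texture_scale: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "signature", np.asarray(self.signature, dtype=float))
        if self.count < 1:
            raise ConfigurationError(f"class {self.name!r}: count must be >= 1, got {self.count}")
        if self.texture_scale < 0:
            raise ValueError(f"class {self.name!r}: texture_scale must be >= 0")
        sig = self.signature
        if sig.ndim != 1 or np.any(sig < 0) or np.any(sig > 1):
            raise ConfigurationError(
                f"class {self.name!r}: signature must be a 1-D vector with entries in [0, 1]"
            )


@dataclass
class LabeledImageSet:
    """Multi-band image patches with integer class labels.

    ``patches`` has shape (n_samples, n_bands, height, width) with intensities
    in [0, 1]; ``labels[i]`` indexes ``class_names``.
    """

    patches: np.ndarray
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.patches.ndim != 4:
            raise ValueError("patches must be a 4-axis array (sample, band, height, width)")
        if len(self.labels) != len(self.patches):
            raise ValueError(
                f"labels length {len(self.labels)} != sample count {len(self.patches)}"
            )
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels must index class_names")

    @property
    def n_samples(self) -> int:
        return self.patches.shape[0]

    @property
    def n_bands(self) -> int:
        return self.patches.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.patches[indices], self.labels[indices], list(self.class_names))


@dataclass
class FeatureTable:
    """Dense per-sample feature matrix with integer labels."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError(f"labels length {len(self.labels)} != row count {self.X.shape[0]}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[indices], self.labels[indices], self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        names = self.feature_names or [f"f{i}" for i in range(self.X.shape[1])]
        df = pd.DataFrame(self.X, columns=names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", np.arange(len(self.labels)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        import pandas as pd

        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(df[feat_cols].to_numpy(float), df["label"].to_numpy(int), feat_cols)


def generate_imageset(
    specs: Sequence[ClassSpec],
    bands: int = 3,
    patch_size: int = 32,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> LabeledImageSet:
    """Generate a labeled multi-band patch dataset.

    Each patch of class *k* is ``signature_k + texture + noise`` clipped to
    [0, 1], where the texture term is Gaussian-smoothed white noise scaled by
    the class's ``texture_scale`` and the noise term is i.i.d. ``N(0,
    noise_sd^2)`` per pixel.  With ``noise_sd = 0`` and ``texture_scale = 0``
    every pixel equals the class signature exactly.

    Raises
    ------
    ConfigurationError
        If a class signature length does not match ``bands``.
    ValueError
        If ``noise_sd`` is negative or preconditions on sizes fail.
    """
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    if patch_size < 4:
        raise ConfigurationError(f"patch_size must be >= 4, got {patch_size}")
    if bands < 1:
        raise ConfigurationError(f"bands must be >= 1, got {bands}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    for spec in specs:
        if len(spec.signature) != bands:
            raise ConfigurationError(
                f"class {spec.name!r}: signature length {len(spec.signature)} != bands {bands}"
            )

    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for k, spec in enumerate(specs):
        shape = (spec.count, bands, patch_size, patch_size)
        block = np.broadcast_to(spec.signature[None, :, None, None], shape).copy()
        if spec.texture_scale > 0:
            texture = gaussian_filter(rng.standard_normal(shape), sigma=(0, 0, 2.0, 2.0))
            block += spec.texture_scale * texture
        if noise_sd > 0:
            block += noise_sd * rng.standard_normal(shape)
        np.clip(block, 0.0, 1.0, out=block)
        blocks.append(block)
        labels.append(np.full(spec.count, k, dtype=int))

    return LabeledImageSet(
        np.concatenate(blocks), np.concatenate(labels), [s.name for s in specs]
    )


def generate_feature_table(
    n_per_class: Sequence[int],
    n_features: int,
    class_sep: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Class-conditional Gaussian clusters in feature space.

    Class centroids sit at ``class_sep`` times a seeded random unit direction;
    samples are centroid + standard-normal noise.  ``class_sep = 0`` collapses
    every class onto one distribution.  The centroid draw precedes the sample
    draw, so for a fixed seed the cluster geometry changes only in scale as
    ``class_sep`` varies.
    """
    if class_sep < 0:
        raise ValueError(f"class_sep must be >= 0, got {class_sep}")
    if n_features < 1:
        raise ConfigurationError(f"n_features must be >= 1, got {n_features}")
    if any(c < 1 for c in n_per_class):
        raise ConfigurationError("all class counts must be >= 1")

    rng = np.random.default_rng(seed)
    C = len(n_per_class)
    directions = rng.standard_normal((C, n_features))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    centroids = class_sep * directions

    rows, labels = [], []
    for k, count in enumerate(n_per_class):
        rows.append(centroids[k] + rng.standard_normal((count, n_features)))
        labels.append(np.full(count, k, dtype=int))
    return FeatureTable(np.concatenate(rows), np.concatenate(labels))


def reference_class_specs(
    scale: float = 0.1, bands: int = 3, texture_scale: float = 0.05
) -> list[ClassSpec]:
    """Six-class emulation profile with the reference class imbalance.

    Counts are the reference collection's per-class patch counts multiplied by
    ``scale`` (rounded half-up, minimum 1); ``scale = 1`` reproduces the full
    6,450-patch structure.  Signatures are evenly spaced per-band means chosen
    so classes are spectrally distinct.
    """
    if scale <= 0:
        raise ConfigurationError("scale must be > 0")
    specs = []
    C = len(REFERENCE_CLASS_COUNTS)
    for k, (name, count) in enumerate(REFERENCE_CLASS_COUNTS.items()):
        # Distinct signature per class: band means walk a ramp offset per class.
        base = 0.2 + 0.6 * k / (C - 1)
        sig = np.clip(base + 0.08 * np.arange(bands) * (1 if k % 2 == 0 else -1), 0.05, 0.95)
        n = max(1, int(np.floor(count * scale + 0.5)))
        specs.append(ClassSpec(name=name, count=n, signature=sig, texture_scale=texture_scale))
    return specs


# ---------------------------------------------------------------------------
# IO: packed-array + CSV manifest layout, PNG export, directory-per-class read
# ---------------------------------------------------------------------------

def save_imageset(imageset: LabeledImageSet, directory: str | Path) -> None:
    """Write ``patches.npy`` plus a ``labels.csv`` manifest (sample_id, class_name)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "patches.npy", imageset.patches)
    with open(directory / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "class_name"])
        for i, lab in enumerate(imageset.labels):
            writer.writerow([i, imageset.class_names[lab]])


def load_imageset(directory: str | Path) -> LabeledImageSet:
    """Read the layout written by :func:`save_imageset`."""
    directory = Path(directory)
    patches = np.load(directory / "patches.npy")
    names_in_order: list[str] = []
    labels = []
    with open(directory / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["class_name"]
            if name not in names_in_order:
                names_in_order.append(name)
            labels.append(names_in_order.index(name))
    return LabeledImageSet(patches, np.asarray(labels), names_in_order)


def export_png(imageset: LabeledImageSet, directory: str | Path) -> None:
    """Export patches as 8-bit PNGs in a directory-per-class layout.

    The first three bands map to RGB (single-band data exports greyscale).
    """
    from PIL import Image

    directory = Path(directory)
    for i, (patch, lab) in enumerate(zip(imageset.patches, imageset.labels)):
        cls_dir = directory / imageset.class_names[lab]
        cls_dir.mkdir(parents=True, exist_ok=True)
        arr = (np.clip(patch, 0, 1) * 255).astype(np.uint8)
        if arr.shape[0] >= 3:
            img = Image.fromarray(np.moveaxis(arr[:3], 0, -1), mode="RGB")
        else:
            img = Image.fromarray(arr[0], mode="L")
        img.save(cls_dir / f"patch_{i:05d}.png")


def load_image_directory(directory: str | Path) -> LabeledImageSet:
    """Read a directory-per-class layout of PNG/TIFF patches.

    Class order is sorted directory-name order; all patches must share one
    shape.  Channel-last images are converted to band-first [0, 1] floats.
    """
    from PIL import Image

    directory = Path(directory)
    class_dirs = sorted(p for p in directory.iterdir() if p.is_dir())
    if not class_dirs:
        raise ConfigurationError(f"no class subdirectories under {directory}")
    patches, labels, names = [], [], []
    for k, cls_dir in enumerate(class_dirs):
        names.append(cls_dir.name)
        files = sorted(
            p for p in cls_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        for f in files:
            arr = np.asarray(Image.open(f), dtype=float) / 255.0
            if arr.ndim == 2:
                arr = arr[None, :, :]
            else:
                arr = np.moveaxis(arr, -1, 0)
            patches.append(arr)
            labels.append(k)
    return LabeledImageSet(np.stack(patches), np.asarray(labels), names)
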