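"""Pluggable patch-to-feature extraction.

The built-in extractor is a seeded random convolutional filter bank
(``"convbank"``): a small stack of fixed random convolution stages with
optional ReLU and max-pooling, collapsed by global mean + standard-deviation
pooling per filter map, giving ``2 * n_filters`` features regardless of depth.
No convolutional weight is ever trained; the *architecture* (filter count,
kernel size, pooling, depth, activation) is the search space a swarm optimizer
tunes by validation error.  Any external network (a pretrained deep extractor,
for instance) can stand in via :func:`register_extractor`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, ContractViolation, RegistrationError
from .synthetic import FeatureTable, LabeledImageSet

__all__ = [
    "SearchSpace",
    "ExtractorHyperparams",
    "decode_hyperparams",
    "encode_hyperparams",
    "default_search_space",
    "ConvBankExtractor",
    "extract_features",
    "register_extractor",
    "get_extractor",
    "registered_extractors",
    "KERNEL_GRID",
    "POOL_GRID",
    "POOL_STRIDE_GRID",
]

KERNEL_GRID = (3, 5, 7)
POOL_GRID = (2, 4)
POOL_STRIDE_GRID = (1, 2, 3, 4)


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box for a population optimizer, with coordinate names."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ConfigurationError("lower and upper must be 1-D vectors of equal length")
        if self.lower.size == 0:
            raise ConfigurationError("search space must have at least one dimension")
        if not np.all(self.lower < self.upper):
            raise ConfigurationError("lower must be element-wise strictly below upper")
        if self.names is not None and len(self.names) != self.lower.size:
            raise ConfigurationError("names length must match dimensionality")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lower, self.upper)


@dataclass(frozen=True)
class ExtractorHyperparams:
    """Architecture of the convolutional filter bank.

    The decoder only ever produces n_filters in [2, 64], kernel_size in
    {3, 5, 7}, pool_size in {2, 4}, pool_stride in {1..4}, n_stages in [1, 3];
    the dataclass itself additionally admits kernel_size 1 and pool_size 1
    (no pooling) so degenerate configurations can be constructed directly.
    """

    n_filters: int = 8
    kernel_size: int = 3
    pool_size: int = 2
    pool_stride: int = 2
    n_stages: int = 1
    use_relu: bool = True

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ConfigurationError("n_filters must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd and >= 1")
        if self.pool_size < 1 or self.pool_stride < 1 or self.n_stages < 1:
            raise ConfigurationError("pool_size, pool_stride and n_stages must be >= 1")


def default_search_space() -> SearchSpace:
    """The 6-D box the stage-1 optimizer searches over.

    Coordinates decode by floor-to-grid: [n_filters, kernel index, pool index,
    pool-stride index, n_stages, use_relu].
    """
    return SearchSpace(
        lower=np.array([2.0, 0.0, 0.0, 0.0, 1.0, 0.0]),
        upper=np.array([65.0, 3.0, 2.0, 4.0, 4.0, 2.0]),
        names=("n_filters", "kernel_size", "pool_size", "pool_stride", "n_stages", "use_relu"),
    )


def _floor_index(x: float, n: int) -> int:
    return min(int(np.floor(x)), n - 1)


def decode_hyperparams(position: np.ndarray, space: SearchSpace | None = None) -> ExtractorHyperparams:
    """Map a continuous optimizer position to a legal architecture.

    Decoding is total: the position is clipped into the box first, then each
    coordinate is floored onto its discrete grid, so every real vector of the
    right dimension decodes without error and positions differing below the
    rounding granularity decode identically.
    """
    space = space or default_search_space()
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dim,):
        raise ContractViolation(
            f"position has shape {position.shape}, expected ({space.dim},)"
        )
    if space.dim != 6:
        raise ContractViolation("convbank decoding requires the 6-D architecture space")
    x = space.clip(position)
    return ExtractorHyperparams(
        n_filters=int(np.clip(np.floor(x[0]), 2, 64)),
        kernel_size=KERNEL_GRID[_floor_index(x[1], len(KERNEL_GRID))],
        pool_size=POOL_GRID[_floor_index(x[2], len(POOL_GRID))],
        pool_stride=POOL_STRIDE_GRID[_floor_index(x[3], len(POOL_STRIDE_GRID))],
        n_stages=int(np.clip(np.floor(x[4]), 1, 3)),
        use_relu=bool(_floor_index(x[5], 2)),
    )


def encode_hyperparams(hp: ExtractorHyperparams) -> np.ndarray:
    """Inverse of :func:`decode_hyperparams` up to rounding (cell midpoints)."""
    return np.array(
        [
            hp.n_filters + 0.5,
            KERNEL_GRID.index(hp.kernel_size) + 0.5,
            POOL_GRID.index(hp.pool_size) + 0.5,
            POOL_STRIDE_GRID.index(hp.pool_stride) + 0.5,
            hp.n_stages + 0.5,
            1.5 if hp.use_relu else 0.5,
        ]
    )


class ConvBankExtractor(TransformerMixin, BaseEstimator):
    """Fixed random convolutional filter bank with global mean/std pooling.

    Parameters mirror :class:`ExtractorHyperparams`; ``random_state`` seeds the
    filter draw (filters ~ N(0, 1/fan_in), fixed thereafter), so the transform
    is a pure function of (patches, architecture, seed).  Output dimensionality
    is ``2 * n_filters``: the global mean and standard deviation of each final
    filter map.
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel_size: int = 3,
        pool_size: int = 2,
        pool_stride: int | None = None,
        n_stages: int = 1,
        use_relu: bool = True,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.n_stages = n_stages
        self.use_relu = use_relu
        self.random_state = random_state

    @classmethod
    def from_hyperparams(cls, hp: ExtractorHyperparams, random_state: int = 0) -> "ConvBankExtractor":
        return cls(
            n_filters=hp.n_filters,
            kernel_size=hp.kernel_size,
            pool_size=hp.pool_size,
            pool_stride=hp.pool_stride,
            n_stages=hp.n_stages,
            use_relu=hp.use_relu,
            random_state=random_state,
        )

    def fit(self, X, y=None):
        """Draw the fixed filter bank for the input's band count."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ContractViolation("expected patches of shape (samples, bands, height, width)")
        rng = np.random.default_rng(self.random_state)
        k = self.kernel_size
        filters = []
        in_maps = X.shape[1]
        for _ in range(self.n_stages):
            fan_in = in_maps * k * k
            filters.append(rng.standard_normal((self.n_filters, in_maps, k, k)) / np.sqrt(fan_in))
            in_maps = self.n_filters
        self.filters_ = filters
        self.n_features_out_ = 2 * self.n_filters
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ContractViolation("expected patches of shape (samples, bands, height, width)")
        maps = X
        stride = self.pool_stride if self.pool_stride is not None else self.pool_size
        for s, filt in enumerate(self.filters_):
            k = filt.shape[-1]
            if maps.shape[2] < k or maps.shape[3] < k:
                raise ConfigurationError(
                    f"stage {s}: spatial size {maps.shape[2]}x{maps.shape[3]} smaller than "
                    f"kernel {k}x{k}; reduce depth or pooling"
                )
            windows = sliding_window_view(maps, (k, k), axis=(2, 3))
            maps = np.einsum("nmhwij,fmij->nfhw", windows, filt, optimize=True)
            if self.use_relu:
                np.maximum(maps, 0.0, out=maps)
            if self.pool_size > 1:
                if maps.shape[2] < self.pool_size or maps.shape[3] < self.pool_size:
                    raise ConfigurationError(
                        f"stage {s}: spatial size {maps.shape[2]}x{maps.shape[3]} smaller "
                        f"than pool {self.pool_size}; reduce depth or pooling"
                    )
                pooled = sliding_window_view(maps, (self.pool_size, self.pool_size), axis=(2, 3))
                pooled = pooled[:, :, ::stride, ::stride]
                maps = pooled.max(axis=(-2, -1))
        mean = maps.mean(axis=(2, 3))
        std = maps.std(axis=(2, 3))
        return np.concatenate([mean, std], axis=1)

    def feature_names(self) -> list[str]:
        return [f"mean_{i}" for i in range(self.n_filters)] + [
            f"std_{i}" for i in range(self.n_filters)
        ]


def extract_features(images: LabeledImageSet, hp: ExtractorHyperparams, seed: int = 0) -> FeatureTable:
    """Run the conv-bank extractor over an image set; pure in (images, hp, seed)."""
    ext = ConvBankExtractor.from_hyperparams(hp, random_state=seed).fit(images.patches)
    return FeatureTable(ext.transform(images.patches), images.labels, ext.feature_names())


# ---------------------------------------------------------------------------
# Extractor registry: name -> callable(LabeledImageSet) -> FeatureTable
# ---------------------------------------------------------------------------

_EXTRACTORS: dict[str, Callable[[LabeledImageSet], FeatureTable]] = {}


def register_extractor(name: str, fn: Callable[[LabeledImageSet], FeatureTable]) -> None:
    """Register a named extractor; duplicate names are rejected."""
    if name in _EXTRACTORS:
        raise RegistrationError(f"extractor {name!r} is already registered")
    _EXTRACTORS[name] = fn


def registered_extractors() -> tuple[str, ...]:
    return tuple(_EXTRACTORS)


def get_extractor(name: str) -> Callable[[LabeledImageSet], FeatureTable]:
    """Look up an extractor, wrapped with a row-count contract check."""
    try:
        fn = _EXTRACTORS[name]
    except KeyError:
        raise RegistrationError(
            f"unknown extractor {name!r}; registered: {sorted(_EXTRACTORS)}"
        ) from None

    def checked(images: LabeledImageSet) -> FeatureTable:
        table = fn(images)
        if table.n_samples != images.n_samples:
            raise ContractViolation(
                f"extractor {name!r} returned {table.n_samples} rows for "
                f"{images.n_samples} input samples"
            )
        return table

    return checked


def _default_convbank(images: LabeledImageSet) -> FeatureTable:
    return extract_features(images, ExtractorHyperparams(), seed=0)


register_extractor("convbank", _default_convbank)
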