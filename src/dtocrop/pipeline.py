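"""End-to-end two-stage crop-classification pipeline.

Flow: stratified train/test split -> stage 1 (a DTO swarm tunes the feature
extractor's architecture by the validation error of a quick fixed-size ELM)
-> stage 2 (MSCA tunes the final ELM's hidden size, ridge coefficient and
activation on the stage-1 winner's features) -> final ELM fit on the full
training side -> per-class / macro evaluation of both sides.

Both stages minimize the classifier error rate (misclassified / total * 100)
on an inner validation split carved out of the training side; the test side
is never touched before the final evaluation.  Everything is reproducible
from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin

from . import __version__ as _pkg_version
from .elm import ELMClassifier
from .errors import ConfigurationError
from .features import (
    ConvBankExtractor,
    ExtractorHyperparams,
    SearchSpace,
    decode_hyperparams,
    default_search_space,
    extract_features,
    get_extractor,
    _floor_index,
)
from .metrics import EvaluationReport, error_rate_fitness
from .optimizers import DTOConfig, MSCAConfig, OptimizeResult, optimize
from .synthetic import ClassSpec, FeatureTable, LabeledImageSet, REFERENCE_CLASS_COUNTS, generate_imageset

__all__ = [
    "PipelineConfig",
    "RunReport",
    "split_indices",
    "stratified_split",
    "stage1_tune_extractor",
    "stage2_tune_elm",
    "TwoStageCropClassifier",
    "run",
    "compact_search_space",
    "smoke_profile",
]

logger = logging.getLogger(__name__)

ACTIVATION_CHOICES = ("sigmoid", "relu", "tanh")


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def split_indices(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified split by largest-remainder rounding.

    Per-class test quotas are ``count * test_fraction`` floored, with the
    leftover slots (so the test side totals ``round(N * test_fraction)``)
    assigned to the classes with the largest fractional remainders.  Per-class
    proportions are preserved to within one sample; the two index sets are
    disjoint, exhaustive and sorted.
    """
    labels = np.asarray(labels, dtype=int)
    if not (0.0 < test_fraction < 1.0):
        raise ConfigurationError("test fraction must be in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"class {cls} has only {cnt} sample(s); need at least 2 to split")
    quotas = counts * test_fraction
    base = np.floor(quotas).astype(int)
    target = int(np.floor(len(labels) * test_fraction + 0.5))
    leftover = target - base.sum()
    # distribute remaining slots by largest fractional remainder, low class first on ties
    order = np.lexsort((np.arange(len(classes)), -(quotas - base)))
    n_test = base.copy()
    for idx in order[: max(leftover, 0)]:
        n_test[idx] += 1

    rng = np.random.default_rng(seed)
    test_parts = []
    for cls, k in zip(classes, n_test):
        idx = np.flatnonzero(labels == cls)
        test_parts.append(rng.permutation(idx)[:k])
    test_idx = np.sort(np.concatenate(test_parts))
    mask = np.ones(len(labels), dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


def _parse_ratio(ratio) -> float:
    """Accept '80:20', (0.8, 0.2) or a train fraction; return the test fraction."""
    if isinstance(ratio, str):
        tr, ts = (float(p) for p in ratio.split(":"))
        return ts / (tr + ts)
    if isinstance(ratio, (tuple, list)):
        tr, ts = float(ratio[0]), float(ratio[1])
        return ts / (tr + ts)
    frac = float(ratio)
    if not (0.0 < frac < 1.0):
        raise ConfigurationError("train fraction must be in (0, 1)")
    return 1.0 - frac


def stratified_split(dataset, ratio, seed: int):
    """Split a LabeledImageSet or FeatureTable into (train, test)."""
    test_fraction = _parse_ratio(ratio)
    train_idx, test_idx = split_indices(dataset.labels, test_fraction, seed)
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def compact_search_space() -> SearchSpace:
    """Desk-scale stage-1 box: as :func:`default_search_space` but with the
    filter count capped at 16, keeping tuning runs fast."""
    full = default_search_space()
    upper = full.upper.copy()
    upper[0] = 17.0
    return SearchSpace(lower=full.lower, upper=upper, names=full.names)


@dataclass
class PipelineConfig:
    """Everything :func:`run` needs; reproducible from (config, seed)."""

    split_ratio: str = "80:20"
    val_fraction: float = 0.2
    dto: DTOConfig = field(default_factory=lambda: DTOConfig(m=6, T=8))
    msca: MSCAConfig = field(default_factory=lambda: MSCAConfig(m=6, T=8))
    extractor: str = "convbank"
    extractor_space: SearchSpace = field(default_factory=compact_search_space)
    extractor_candidates: tuple[str, ...] | None = None
    quick_hidden: int = 50
    quick_alpha: float = 1e-3
    quick_activation: str = "sigmoid"
    elm_hidden_range: tuple[int, int] = (10, 200)
    elm_log10_alpha: tuple[float, float] = (-6.0, 2.0)
    elm_activations: tuple[str, ...] = ACTIVATION_CHOICES
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigurationError("val_fraction must be in (0, 1)")
        _parse_ratio(self.split_ratio)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extractor_space"] = {
            "lower": self.extractor_space.lower.tolist(),
            "upper": self.extractor_space.upper.tolist(),
            "names": list(self.extractor_space.names or []),
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "dto" in raw and isinstance(raw["dto"], dict):
            raw["dto"] = DTOConfig(**raw["dto"])
        if "msca" in raw and isinstance(raw["msca"], dict):
            raw["msca"] = MSCAConfig(**raw["msca"])
        if "extractor_space" in raw and isinstance(raw["extractor_space"], dict):
            sp = raw["extractor_space"]
            raw["extractor_space"] = SearchSpace(
                lower=np.asarray(sp["lower"], float),
                upper=np.asarray(sp["upper"], float),
                names=tuple(sp.get("names") or ()) or None,
            )
        for key in ("elm_hidden_range", "elm_log10_alpha", "elm_activations", "extractor_candidates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage 1: extractor architecture search (DTO)
# ---------------------------------------------------------------------------

def stage1_tune_extractor(
    train: LabeledImageSet,
    cfg: PipelineConfig,
    algo: str = "dto",
) -> tuple[ExtractorHyperparams | str, OptimizeResult]:
    """Minimize inner-validation error over extractor configurations.

    By default the search space is the conv-bank architecture box and
    positions decode to :class:`ExtractorHyperparams`.  If
    ``cfg.extractor_candidates`` names registered extractors, the space is a
    1-D grid over those names instead.  The fitness of a candidate is the
    error rate of a quick fixed-size ELM trained on the inner-training side
    and scored on the inner-validation side; identical decoded candidates
    share one evaluation (decoding is piecewise constant).
    """
    if len(np.unique(train.labels)) < 2:
        raise ValueError("stage 1 requires at least two classes in the training data")
    inner_train, inner_val = split_indices(train.labels, cfg.val_fraction, cfg.seed + 1)
    cache: dict = {}

    if cfg.extractor_candidates is not None:
        names = cfg.extractor_candidates
        space = SearchSpace(np.array([0.0]), np.array([float(len(names))]), ("extractor",))

        def decode(pos):
            return names[_floor_index(space.clip(pos)[0], len(names))]

        def features_for(name: str) -> FeatureTable:
            return get_extractor(name)(train)

    else:
        space = cfg.extractor_space

        def decode(pos):
            return decode_hyperparams(pos, space)

        def features_for(hp: ExtractorHyperparams) -> FeatureTable:
            return extract_features(train, hp, seed=cfg.seed)

    def fitness(position: np.ndarray) -> float:
        candidate = decode(position)
        if candidate in cache:
            return cache[candidate]
        try:
            table = features_for(candidate)
            model = ELMClassifier(
                n_hidden=cfg.quick_hidden,
                activation=cfg.quick_activation,
                alpha=cfg.quick_alpha,
                random_state=cfg.seed,
            ).fit(table.X[inner_train], table.labels[inner_train])
            err = error_rate_fitness(
                table.labels[inner_val], model.predict(table.X[inner_val])
            )
        except ConfigurationError as exc:
            # infeasible architecture (e.g. maps shrink below the kernel):
            # worst possible error rate keeps the fitness finite
            logger.info("stage 1 candidate %s infeasible: %s", candidate, exc)
            err = 100.0
        except Exception:
            logger.exception("stage 1 candidate %r failed", candidate)
            raise RuntimeError(f"stage 1 failed while evaluating candidate {candidate!r}")
        cache[candidate] = err
        return err

    opt_cfg = cfg.dto if algo == "dto" else cfg.msca
    result = optimize(fitness, space, algo=algo, cfg=opt_cfg)
    return decode(result.x), result


# ---------------------------------------------------------------------------
# Stage 2: ELM parameter search (MSCA)
# ---------------------------------------------------------------------------

def _decode_elm_settings(position: np.ndarray, cfg: PipelineConfig, space: SearchSpace) -> dict:
    x = space.clip(np.asarray(position, float))
    lo, hi = cfg.elm_hidden_range
    return {
        "n_hidden": int(np.clip(np.floor(x[0]), lo, hi)),
        "alpha": float(10.0 ** x[1]),
        "activation": cfg.elm_activations[_floor_index(x[2], len(cfg.elm_activations))],
    }


def elm_search_space(cfg: PipelineConfig) -> SearchSpace:
    """3-D box over (hidden size, log10 ridge, activation index)."""
    lo, hi = cfg.elm_hidden_range
    return SearchSpace(
        lower=np.array([float(lo), cfg.elm_log10_alpha[0], 0.0]),
        upper=np.array([hi + 1.0, cfg.elm_log10_alpha[1], float(len(cfg.elm_activations))]),
        names=("n_hidden", "log10_alpha", "activation"),
    )


def stage2_tune_elm(
    features: FeatureTable,
    cfg: PipelineConfig,
    algo: str = "msca",
) -> tuple[dict, OptimizeResult]:
    """Minimize inner-validation error over (L, lambda, activation).

    Hidden size decodes by flooring onto the integer grid, the ridge
    coefficient is searched on a log10 scale, and the activation by index.
    """
    inner_train, inner_val = split_indices(features.labels, cfg.val_fraction, cfg.seed + 2)
    space = elm_search_space(cfg)
    cache: dict = {}

    def fitness(position: np.ndarray) -> float:
        settings = _decode_elm_settings(position, cfg, space)
        key = (settings["n_hidden"], settings["activation"], round(settings["alpha"], 12))
        if key in cache:
            return cache[key]
        model = ELMClassifier(**settings, random_state=cfg.seed).fit(
            features.X[inner_train], features.labels[inner_train]
        )
        err = error_rate_fitness(
            features.labels[inner_val], model.predict(features.X[inner_val])
        )
        cache[key] = err
        return err

    opt_cfg = cfg.msca if algo == "msca" else cfg.dto
    result = optimize(fitness, space, algo=algo, cfg=opt_cfg)
    return _decode_elm_settings(result.x, cfg, space), result


# ---------------------------------------------------------------------------
# Estimator facade and orchestration
# ---------------------------------------------------------------------------

class TwoStageCropClassifier(ClassifierMixin, BaseEstimator):
    """Swarm-tuned extractor + ELM as one sklearn-style classifier.

    ``fit(X, y)`` expects patches of shape (samples, bands, height, width)
    and runs both tuning stages plus the final ELM fit on the data it is
    given (use :func:`run` for the outer train/test protocol and reports).

    Attributes after fitting: ``extractor_hp_``, ``extractor_``, ``elm_``,
    ``elm_settings_``, ``stage1_history_``, ``stage2_history_``.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def _cfg(self) -> PipelineConfig:
        return self.config if self.config is not None else PipelineConfig()

    def fit(self, X, y):
        cfg = self._cfg()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        images = LabeledImageSet(X, y_idx, [str(c) for c in self.classes_])

        t0 = time.perf_counter()
        best, s1 = stage1_tune_extractor(images, cfg)
        logger.info("stage 1 done in %.1fs: %s (err %.2f%%)", time.perf_counter() - t0, best, s1.fun)
        self.extractor_hp_ = best
        self.stage1_history_ = s1.history

        if isinstance(best, str):
            table = get_extractor(best)(images)
            self.extractor_ = best
        else:
            self.extractor_ = ConvBankExtractor.from_hyperparams(best, random_state=cfg.seed).fit(X)
            table = FeatureTable(self.extractor_.transform(X), y_idx)

        t1 = time.perf_counter()
        settings, s2 = stage2_tune_elm(table, cfg)
        logger.info("stage 2 done in %.1fs: %s (err %.2f%%)", time.perf_counter() - t1, settings, s2.fun)
        self.elm_settings_ = settings
        self.stage2_history_ = s2.history

        self.elm_ = ELMClassifier(**settings, random_state=cfg.seed).fit(table.X, y_idx)
        return self

    def _features(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if isinstance(self.extractor_, str):
            images = LabeledImageSet(X, np.zeros(len(X), int), ["_"])
            return get_extractor(self.extractor_)(images).X
        return self.extractor_.transform(X)

    def predict(self, X):
        return self.classes_[self.elm_.predict(self._features(X))]

    def decision_function(self, X):
        return self.elm_.decision_function(self._features(X))


@dataclass
class RunReport:
    """Results of one end-to-end run: tuned settings, both evaluation
    reports, optimizer histories and provenance."""

    extractor_hp: ExtractorHyperparams | str
    elm_settings: dict
    report_train: EvaluationReport
    report_test: EvaluationReport
    stage1_history: np.ndarray
    stage2_history: np.ndarray
    provenance: dict

    def to_dict(self) -> dict:
        hp = self.extractor_hp
        return {
            "extractor_hp": asdict(hp) if isinstance(hp, ExtractorHyperparams) else hp,
            "elm_settings": self.elm_settings,
            "report_train": self.report_train.to_dict(),
            "report_test": self.report_test.to_dict(),
            "stage1_history": self.stage1_history.tolist(),
            "stage2_history": self.stage2_history.tolist(),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def run(config: PipelineConfig, dataset: LabeledImageSet) -> RunReport:
    """Execute the full protocol and (optionally) write artifacts.

    Split tags follow the ratio: an 80:20 split labels the sides TR80/TS20.
    When ``config.outdir`` is set, the per-split reports, confusion matrices,
    optimizer histories and a ``run.json`` are written there.
    """
    test_fraction = _parse_ratio(config.split_ratio)
    tr_tag = f"TR{round((1 - test_fraction) * 100)}"
    ts_tag = f"TS{round(test_fraction * 100)}"

    train, test = stratified_split(dataset, config.split_ratio, config.seed)
    logger.info("split %s: %d train / %d test", config.split_ratio, train.n_samples, test.n_samples)

    est = TwoStageCropClassifier(config).fit(train.patches, train.labels)

    report_train = EvaluationReport.from_predictions(
        train.labels, est.predict(train.patches), dataset.class_names, split_tag=tr_tag
    )
    report_test = EvaluationReport.from_predictions(
        test.labels, est.predict(test.patches), dataset.class_names, split_tag=ts_tag
    )

    report = RunReport(
        extractor_hp=est.extractor_hp_,
        elm_settings=est.elm_settings_,
        report_train=report_train,
        report_test=report_test,
        stage1_history=est.stage1_history_,
        stage2_history=est.stage2_history_,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": _pkg_version,
            "n_train": train.n_samples,
            "n_test": test.n_samples,
        },
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_train.to_csv(outdir / "report_train.csv")
        report_test.to_csv(outdir / "report_test.csv")
        report_train.confusion_to_csv(outdir / "confusion_train.csv")
        report_test.confusion_to_csv(outdir / "confusion_test.csv")
        for name, hist in (("stage1", est.stage1_history_), ("stage2", est.stage2_history_)):
            pd.DataFrame(
                {"iteration": np.arange(len(hist)), "f_gbest": hist}
            ).to_csv(outdir / f"history_{name}.csv", index=False)
        (outdir / "run.json").write_text(report.to_json())

    return report


# ---------------------------------------------------------------------------
# Smoke profile: the desk-scale end-to-end study condition
# ---------------------------------------------------------------------------

def smoke_profile(seed: int = 0, n_per_class: int = 60) -> tuple[LabeledImageSet, PipelineConfig]:
    """Well-separated six-class dataset plus a small two-stage config.

    Six classes with the reference class names, ``n_per_class`` patches each,
    spectrally distinct signatures, mild texture and pixel noise; both swarm
    stages run m=6, T=8.
    """
    C = len(REFERENCE_CLASS_COUNTS)
    specs = []
    for k, name in enumerate(REFERENCE_CLASS_COUNTS):
        base = 0.15 + 0.7 * k / (C - 1)
        sig = np.clip(base + 0.06 * np.arange(3) * (1 if k % 2 == 0 else -1), 0.05, 0.95)
        specs.append(ClassSpec(name=name, count=n_per_class, signature=sig, texture_scale=0.05))
    dataset = generate_imageset(specs, bands=3, patch_size=32, noise_sd=0.05, seed=seed)
    config = PipelineConfig(
        dto=DTOConfig(m=6, T=8, seed=seed),
        msca=MSCAConfig(m=6, T=8, seed=seed),
        seed=seed,
    )
    return dataset, config
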