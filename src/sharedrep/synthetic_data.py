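"""Synthetic paired two-modality category data.

Generates pools of class-structured "visual" (28x28) and "auditory"
(14x56 spectrogram-like) arrays in [0, 1] so that the whole pipeline —
dataset assembly, autoencoder training, information analysis, unit
typology, transfer evaluation — runs without any external downloads.
Class identity is carried by smoothed random prototype patterns; the
auditory modality has ``n_sources`` sub-prototypes per class, emulating
the same digit spoken by different speakers. The downstream analysis is
agnostic to image content, so any class-separable pattern family serves.

Also provides planted-activation fixtures: unit responses drawn from
known per-(digit, modality) bin distributions whose stimulus-specific
information is available in closed form, used as oracles for the
information analysis and the unit classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

VISUAL_SHAPE = (28, 28)
AUDITORY_SHAPE = (14, 56)

Modality = Literal["visual", "auditory"]

# substream tags so every consumer of the master seed gets an
# independent, reproducible generator
_TAG_VISUAL_PROTO = 1
_TAG_VISUAL_TRAIN = 2
_TAG_VISUAL_TEST = 3
_TAG_AUDIO_PROTO = 4
_TAG_AUDIO_NOISE = 5
_TAG_AUDIO_SPLIT = 6
_TAG_PLANT = 7
_TAG_VISUAL_BASIS = 8
_TAG_AUDIO_BASIS = 9


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for the synthetic two-modality generator.

    ``per_class_train``/``per_class_test`` give the visual sample counts
    per class (defaults 500/50). The auditory pool holds
    ``audio_per_class`` samples per class for each of train and test
    (default 50 each, i.e. a 100-per-class raw pool split in half),
    drawn from ``n_sources`` sub-prototypes per class.

    Within-class variability has a structured and an unstructured
    component: each sample deforms its prototype along
    ``n_variation_fields`` smooth basis patterns with coefficients of
    standard deviation ``variation_scale`` (reconstructable shape
    variation, as in real handwriting or speech), plus iid pixel noise
    of standard deviation ``noise_sd``.
    """

    n_classes: int = 10
    per_class_train: int = 500
    per_class_test: int = 50
    audio_per_class: int = 50
    n_sources: int = 2
    noise_sd: float = 0.05
    variation_scale: float = 0.4
    n_variation_fields: int = 4
    prototype_separation: float = 1.0
    seed: int = 0
    visual_shape: tuple[int, int] = VISUAL_SHAPE
    auditory_shape: tuple[int, int] = AUDITORY_SHAPE

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        for name in ("per_class_train", "per_class_test", "audio_per_class"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_sources < 1:
            raise ConfigurationError("n_sources must be >= 1")
        if self.noise_sd < 0 or self.variation_scale < 0:
            raise ConfigurationError("noise_sd and variation_scale must be >= 0")
        if self.n_variation_fields < 0:
            raise ConfigurationError("n_variation_fields must be >= 0")
        for name in ("visual_shape", "auditory_shape"):
            shape = getattr(self, name)
            if len(shape) != 2 or any(int(s) < 1 for s in shape):
                raise ConfigurationError(f"{name} must be two positive ints")


@dataclass
class ModalityPool:
    """A pool of single-modality samples with class labels.

    ``arrays`` has shape (n, rows, cols) with all values in [0, 1];
    ``source_ids`` indexes the sub-prototype each sample came from
    (always 0 for the visual modality).
    """

    modality: str
    arrays: np.ndarray
    labels: np.ndarray
    source_ids: np.ndarray
    grid_shape: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        if self.arrays.ndim != 3 or self.arrays.shape[1:] != tuple(self.grid_shape):
            raise ConfigurationError(
                f"arrays shape {self.arrays.shape} does not match grid {self.grid_shape}"
            )
        if len(self.labels) != len(self.arrays):
            raise ConfigurationError("labels length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.arrays)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def flat(self) -> np.ndarray:
        """Samples flattened row-major to (n, rows*cols)."""
        return self.arrays.reshape(len(self.arrays), -1)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 2.0) -> np.ndarray:
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    return g


def _contrast(z: np.ndarray, separation: float) -> np.ndarray:
    """Map a standardized smooth field to a high-contrast pattern.

    Real digit images and spectrograms are sparse and near-binary:
    bright strokes / energy bands on a dark background. A soft
    threshold at the field's 70th percentile keeps ~30% of the grid
    "on"; ``separation`` scales the contrast gain (0 gives a flat
    mid-gray grid)."""
    gain = 5.0 * separation
    thresh = np.quantile(z, 0.7, axis=(-2, -1), keepdims=True)
    return 1.0 / (1.0 + np.exp(-gain * (z - thresh)))


def _class_fields(config: GeneratorConfig, modality: Modality) -> np.ndarray:
    """Standardized smooth prototype fields (pre-contrast)."""
    if modality == "visual":
        rng = _rng(config.seed, _TAG_VISUAL_PROTO)
        fields = np.empty((config.n_classes, *config.visual_shape))
        for c in range(config.n_classes):
            fields[c] = _smooth_field(rng, config.visual_shape)
        return fields
    if modality == "auditory":
        rng = _rng(config.seed, _TAG_AUDIO_PROTO)
        fields = np.empty((config.n_classes, config.n_sources, *config.auditory_shape))
        for c in range(config.n_classes):
            base = _smooth_field(rng, config.auditory_shape)
            for s in range(config.n_sources):
                z = base + 0.6 * _smooth_field(rng, config.auditory_shape)
                fields[c, s] = (z - z.mean()) / max(z.std(), 1e-12)
        return fields
    raise ConfigurationError(f"unknown modality {modality!r}")


def _variation_basis(config: GeneratorConfig, modality: Modality) -> np.ndarray:
    """Smooth standardized basis patterns for structured within-class
    deformation, shared across classes within a modality."""
    if modality == "visual":
        rng, shape = _rng(config.seed, _TAG_VISUAL_BASIS), config.visual_shape
    else:
        rng, shape = _rng(config.seed, _TAG_AUDIO_BASIS), config.auditory_shape
    return np.array([_smooth_field(rng, shape)
                     for _ in range(config.n_variation_fields)])


def class_prototypes(config: GeneratorConfig, modality: Modality) -> np.ndarray:
    """Deterministic per-class prototype patterns in [0, 1].

    Visual: one prototype per class, shape (n_classes, rows, cols).
    Auditory: ``n_sources`` sub-prototypes per class, shape
    (n_classes, n_sources, rows, cols). Patterns are sparse
    high-contrast smoothed fields; contrast scales with
    ``prototype_separation``.
    """
    return _contrast(_class_fields(config, modality), config.prototype_separation)


def _render(rng: np.random.Generator, field: np.ndarray, basis: np.ndarray,
            n: int, config: GeneratorConfig) -> np.ndarray:
    """Render n samples: prototype field deformed along the variation
    basis, contrast-mapped, plus pixel noise, clipped to [0, 1]."""
    fields = np.repeat(field[None], n, axis=0)
    if config.variation_scale > 0 and len(basis):
        coeff = rng.normal(0.0, config.variation_scale, (n, len(basis)))
        fields = fields + np.tensordot(coeff, basis, axes=1)
    out = _contrast(fields, config.prototype_separation)
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0)


def generate_pool(
    config: GeneratorConfig,
    modality: Modality,
    role: Literal["train", "test"] = "train",
) -> ModalityPool:
    """Generate a single-modality pool of noisy prototype variations.

    Visual train/test pools are drawn independently
    (``per_class_train``/``per_class_test`` samples per class). The
    auditory modality mirrors a fixed recording pool of
    ``2 * audio_per_class`` samples per class (balanced across
    sub-prototype "speakers") randomly split in half into train and
    test, so the two roles are disjoint. Deterministic given
    ``config.seed``.
    """
    if role not in ("train", "test"):
        raise ConfigurationError(f"unknown role {role!r}")
    if modality == "visual":
        fields = _class_fields(config, "visual")
        basis = _variation_basis(config, "visual")
        n = config.per_class_train if role == "train" else config.per_class_test
        rng = _rng(config.seed, _TAG_VISUAL_TRAIN if role == "train" else _TAG_VISUAL_TEST)
        arrays, labels = [], []
        for c in range(config.n_classes):
            arrays.append(_render(rng, fields[c], basis, n, config))
            labels.append(np.full(n, c))
        return ModalityPool(
            modality="visual",
            arrays=np.concatenate(arrays),
            labels=np.concatenate(labels),
            source_ids=np.zeros(n * config.n_classes, dtype=int),
            grid_shape=config.visual_shape,
            seed=config.seed,
        )
    if modality == "auditory":
        full = _audio_raw_pool(config)
        idx = _audio_split_indices(config)[0 if role == "train" else 1]
        return ModalityPool(
            modality="auditory",
            arrays=full[0][idx],
            labels=full[1][idx],
            source_ids=full[2][idx],
            grid_shape=config.auditory_shape,
            seed=config.seed,
        )
    raise ConfigurationError(f"unknown modality {modality!r}")


def _audio_raw_pool(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The raw auditory pool: 2*audio_per_class samples per class."""
    fields = _class_fields(config, "auditory")
    basis = _variation_basis(config, "auditory")
    rng = _rng(config.seed, _TAG_AUDIO_NOISE)
    per_class = 2 * config.audio_per_class
    arrays, labels, sources = [], [], []
    for c in range(config.n_classes):
        # balance samples over sub-prototypes
        counts = np.bincount(np.arange(per_class) % config.n_sources,
                             minlength=config.n_sources)
        for s in range(config.n_sources):
            arrays.append(_render(rng, fields[c, s], basis, int(counts[s]), config))
            labels.append(np.full(int(counts[s]), c))
            sources.append(np.full(int(counts[s]), s))
    return np.concatenate(arrays), np.concatenate(labels), np.concatenate(sources)


def _audio_split_indices(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class 50/50 split of the raw auditory pool."""
    per_class = 2 * config.audio_per_class
    rng = _rng(config.seed, _TAG_AUDIO_SPLIT)
    train_idx, test_idx = [], []
    for c in range(config.n_classes):
        base = c * per_class
        perm = rng.permutation(per_class)
        train_idx.append(base + perm[: config.audio_per_class])
        test_idx.append(base + perm[config.audio_per_class:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


# ---------------------------------------------------------------------------
# Planted activations: oracle fixtures with closed-form information
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedUnit:
    """One unit's planted response plan.

    ``dist_visual`` and ``dist_auditory`` are (n_classes, n_bins) row
    distributions over response bins; ``visual_digits`` /
    ``auditory_digits`` record the digits the unit was planted to be
    selective for (ground truth for classifier recovery tests).
    """

    dist_visual: np.ndarray
    dist_auditory: np.ndarray
    visual_digits: frozenset[int] = frozenset()
    auditory_digits: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for name in ("dist_visual", "dist_auditory"):
            d = getattr(self, name)
            if d.ndim != 2:
                raise ValueError(f"{name} must be 2-D (classes x bins)")
            if np.any(d < 0) or not np.allclose(d.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must be distributions summing to 1")


@dataclass(frozen=True)
class PlantedActivationSpec:
    units: tuple[PlantedUnit, ...]
    n_bins: int = 10

    def __post_init__(self) -> None:
        for u in self.units:
            if u.dist_visual.shape[1] != self.n_bins or u.dist_auditory.shape[1] != self.n_bins:
                raise ValueError("unit distribution bin count mismatch")


def closed_form_information(dist: np.ndarray) -> np.ndarray:
    """Exact per-class stimulus-specific information for planted rows.

    ``dist`` is (n_classes, n_bins) with rows P(r|s); classes are
    equiprobable so the marginal is the row mean. Returns bits per
    class. 0·log0 terms contribute 0.
    """
    dist = np.asarray(dist, dtype=float)
    marginal = dist.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dist / np.where(marginal > 0, marginal, 1.0), 1.0)
        terms = np.where(dist > 0, dist * np.log2(ratio), 0.0)
    return terms.sum(axis=1)


def selective_unit(
    n_classes: int,
    n_bins: int,
    visual_digits: Sequence[int] = (),
    auditory_digits: Sequence[int] = (),
    peak_bin: int | None = None,
) -> PlantedUnit:
    """Build a planted unit responding in the top bin for its selective
    digits and uniformly otherwise (a sharply informative plan)."""
    if peak_bin is None:
        peak_bin = n_bins - 1

    def build(digits: Sequence[int]) -> np.ndarray:
        d = np.full((n_classes, n_bins), 1.0 / n_bins)
        for dig in digits:
            d[dig] = 0.0
            d[dig, peak_bin] = 1.0
        return d

    return PlantedUnit(
        dist_visual=build(visual_digits),
        dist_auditory=build(auditory_digits),
        visual_digits=frozenset(int(d) for d in visual_digits),
        auditory_digits=frozenset(int(d) for d in auditory_digits),
    )


def plant_activations(
    spec: PlantedActivationSpec,
    n_per_class: int,
    seed: int,
):
    """Sample an activation matrix realizing the planted plan.

    For every class and both single-modality conditions, draws
    ``n_per_class`` responses per unit from the planted bin
    distributions and maps them to bin-center activation values in
    [0, 1]. Returns an :class:`~sharedrep.info_analysis.ActivationMatrix`
    with ``visual_only`` and ``audio_only`` condition tags.
    """
    from .info_analysis import ActivationMatrix

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    n_units = len(spec.units)
    n_classes = spec.units[0].dist_visual.shape[0]
    centers = (np.arange(spec.n_bins) + 0.5) / spec.n_bins
    rng = _rng(seed, _TAG_PLANT)

    blocks, labels, conditions = [], [], []
    for cond, attr in (("visual_only", "dist_visual"), ("audio_only", "dist_auditory")):
        for c in range(n_classes):
            resp = np.empty((n_per_class, n_units))
            for j, unit in enumerate(spec.units):
                p = getattr(unit, attr)[c]
                bins = rng.choice(spec.n_bins, size=n_per_class, p=p)
                resp[:, j] = centers[bins]
            blocks.append(resp)
            labels.append(np.full(n_per_class, c))
            conditions.extend([cond] * n_per_class)
    return ActivationMatrix(
        responses=np.concatenate(blocks),
        labels=np.concatenate(labels),
        conditions=np.array(conditions),
    )
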