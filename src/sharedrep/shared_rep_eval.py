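"""Shared-representation learning: frozen-encoder transfer evaluation.

A supervised classification head — two dense layers of 64 rectified
linear units with 20% dropout each, then a 10-way softmax — is stacked
on the final encoding layer of a trained bimodal autoencoder. The
encoder weights stay frozen; only the head is trained, with labels from
a single modality's test-condition subset (e.g. visual-only pairs).
Cross-modal transfer is then measured as categorical accuracy on the
*other* modality's subset, which the head never saw labels for: above-
chance cross-modal accuracy requires a modality-invariant code in the
frozen layer.

Statistical floor: :func:`label_shuffle_null` retrains the head on
permuted labels to obtain the null distribution of cross-modal
accuracy; an encoder "transfers" when its accuracy clears the null's
upper percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    DTYPE,
    Dense,
    categorical_cross_entropy,
    cce_grad_dz,
    one_hot,
)
from .bimodal_autoencoder import BimodalAutoencoder
from .dataset_builder import StimulusSet


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class HeadSpec:
    """Supervised head configuration: ``n_hidden`` relu layers of
    ``width`` units with ``dropout`` applied to each during training,
    softmax output over ``n_classes``."""

    train_modality: str = "visual_only"
    n_classes: int = 10
    width: int = 64
    n_hidden: int = 2
    dropout: float = 0.2
    epochs: int = 50
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_modality not in ("visual_only", "audio_only"):
            raise EvaluationError("train_modality must be a single-modality condition")
        if not 0 <= self.dropout < 1:
            raise EvaluationError("dropout must lie in [0, 1)")


@dataclass
class TransferResult:
    """Categorical accuracies of a trained head.

    ``accuracies`` maps condition subset -> top-1 accuracy;
    ``history`` holds per-epoch training loss (and test accuracies when
    a test set was supplied during training)."""

    accuracies: dict[str, float] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)
    train_modality: str = "visual_only"
    replicate: int = 0

    @property
    def cross_modal(self) -> float:
        other = "audio_only" if self.train_modality == "visual_only" else "visual_only"
        return self.accuracies[other]

    @property
    def same_modality(self) -> float:
        return self.accuracies[self.train_modality]


class ClassifierHead:
    """The trainable supervised head (encoder outputs are its inputs)."""

    def __init__(self, spec: HeadSpec, n_inputs: int):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 37)))
        dims = [n_inputs] + [spec.width] * spec.n_hidden
        self.hidden = [Dense(dims[i], dims[i + 1], "relu", rng)
                       for i in range(spec.n_hidden)]
        self.out = Dense(dims[-1], spec.n_classes, "softmax", rng)
        self._drop_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 41)))
        self.history: list[dict] = []

    def predict_proba(self, codes: np.ndarray) -> np.ndarray:
        h = codes.astype(DTYPE)
        for layer in self.hidden:
            h = layer.forward(h, cache=False)
        return self.out.forward(h, cache=False)

    def predict(self, codes: np.ndarray) -> np.ndarray:
        return self.predict_proba(codes).argmax(axis=1)

    def _step(self, codes: np.ndarray, targets: np.ndarray) -> float:
        p = self.spec.dropout
        h = codes
        masks = []
        for layer in self.hidden:
            h = layer.forward(h, cache=True)
            if p > 0:  # inverted dropout so inference needs no rescaling
                mask = (self._drop_rng.random(h.shape) >= p).astype(DTYPE) / DTYPE(1 - p)
                h = h * mask
                masks.append(mask)
        y = self.out.forward(h, cache=True)
        loss = categorical_cross_entropy(y, targets)
        grad = self.out.backward(cce_grad_dz(y, targets), grad_is_dz=True)
        for layer, mask in zip(reversed(self.hidden), reversed(masks) if masks else [None] * len(self.hidden)):
            if mask is not None:
                grad = grad * mask
            grad = layer.backward(grad)
        return loss

    def fit(self, codes: np.ndarray, labels: np.ndarray,
            eval_fn=None) -> "ClassifierHead":
        codes = codes.astype(DTYPE)
        targets = one_hot(labels, self.spec.n_classes)
        n = len(codes)
        bs = min(self.spec.batch_size, n)
        rng = np.random.default_rng(np.random.SeedSequence((self.spec.seed, 43)))
        for epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                total += self._step(codes[idx], targets[idx]) * len(idx)
            rec = {"epoch": epoch, "loss": total / n}
            if eval_fn is not None:
                rec.update(eval_fn(self))
            self.history.append(rec)
        return self


def _subset_codes(model: BimodalAutoencoder, data: StimulusSet, condition: str):
    sub = data.subset(condition)
    codes = model.encode(sub).responses
    labels = sub.label_a if condition == "audio_only" else sub.label_v
    return codes, labels


def train_head(
    model: BimodalAutoencoder,
    head: HeadSpec,
    train_subset: StimulusSet,
    test_set: StimulusSet | None = None,
) -> ClassifierHead:
    """Train the supervised head on the frozen final encoding layer.

    ``train_subset`` must contain the head's training-modality
    condition; labels come from that modality. The encoder is read-only
    here — its weight checksum is verified unchanged as the frozen
    contract. When ``test_set`` is given, per-epoch accuracies on both
    single-modality subsets are recorded in the head's history.
    """
    before = model.encoder_checksum()
    codes, labels = _subset_codes(model, train_subset, head.train_modality)
    if len(codes) == 0:
        raise EvaluationError("training subset is empty")
    clf = ClassifierHead(head, n_inputs=codes.shape[1])

    eval_fn = None
    if test_set is not None:
        held = {cond: _subset_codes(model, test_set, cond)
                for cond in ("visual_only", "audio_only")}

        def eval_fn(h: ClassifierHead) -> dict:
            return {cond: float((h.predict(c) == l).mean())
                    for cond, (c, l) in held.items()}

    clf.fit(codes, labels, eval_fn=eval_fn)
    if model.encoder_checksum() != before:
        raise EvaluationError("frozen-encoder contract violated during head training")
    return clf


def evaluate_cross_modal(
    model: BimodalAutoencoder,
    head: ClassifierHead,
    test: StimulusSet,
    replicate: int = 0,
) -> TransferResult:
    """Categorical accuracy of the trained head on each single-modality
    test subset (same-modality and cross-modal)."""
    accs = {}
    for cond in ("visual_only", "audio_only"):
        codes, labels = _subset_codes(model, test, cond)
        accs[cond] = float((head.predict(codes) == labels).mean())
    return TransferResult(accuracies=accs, history=list(head.history),
                          train_modality=head.spec.train_modality,
                          replicate=replicate)


def label_shuffle_null(
    model: BimodalAutoencoder,
    head: HeadSpec,
    train_subset: StimulusSet,
    test: StimulusSet,
    n_shuffles: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of cross-modal accuracy under destroyed
    labels: the head is retrained ``n_shuffles`` times on permuted
    training labels and evaluated cross-modally each time."""
    import dataclasses

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 47)))
    codes, labels = _subset_codes(model, train_subset, head.train_modality)
    cross_cond = "audio_only" if head.train_modality == "visual_only" else "visual_only"
    test_codes, test_labels = _subset_codes(model, test, cross_cond)
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        spec_k = dataclasses.replace(head, seed=int(rng.integers(2**31)))
        clf = ClassifierHead(spec_k, n_inputs=codes.shape[1])
        clf.fit(codes, rng.permutation(labels))
        out[k] = float((clf.predict(test_codes) == test_labels).mean())
    return out
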