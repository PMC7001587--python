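"""Assembly of paired bimodal training and test sets.

Takes single-modality pools and produces stimulus sets of
(visual, auditory) pairs: label-matched ("consistent") or deliberately
label-mismatched ("inconsistent", the control), followed by
modality-dropout augmentation — the set is tripled with copies in which
one modality's input is zeroed while reconstruction targets keep both
original arrays, so one third of training examples carry only visual
input, one third only auditory, one third both.

Networks consume each pair as two row-major flattened vectors (visual
784 + auditory 784 by default); the flattening order is fixed here and
nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .synthetic_data import GeneratorConfig, ModalityPool, generate_pool

CONDITIONS = ("both", "visual_only", "audio_only")


class DatasetError(ValueError):
    """Invalid pool combination or stimulus-set state."""


@dataclass
class StimulusSet:
    """Paired bimodal stimuli with per-pair condition tags.

    ``x_v``/``x_a`` are the network inputs (zeroed for the dropped
    modality); ``t_v``/``t_a`` are the reconstruction targets and always
    hold the original arrays. All four are flat (n, d) float arrays.
    """

    x_v: np.ndarray
    x_a: np.ndarray
    t_v: np.ndarray
    t_a: np.ndarray
    label_v: np.ndarray
    label_a: np.ndarray
    condition: np.ndarray
    role: str
    consistency: str
    seed: int

    def __len__(self) -> int:
        return len(self.x_v)

    @property
    def n_pairs(self) -> int:
        return len(self.x_v)

    def inputs(self) -> np.ndarray:
        """Concatenated (visual | auditory) input matrix, shape (n, d_v + d_a)."""
        return np.concatenate([self.x_v, self.x_a], axis=1)

    def subset(self, condition: str) -> "StimulusSet":
        if condition not in CONDITIONS:
            raise DatasetError(f"unknown condition {condition!r}")
        mask = self.condition == condition
        if not mask.any():
            raise DatasetError(f"no pairs with condition {condition!r}")
        return self._take(np.flatnonzero(mask))

    def _take(self, idx: np.ndarray) -> "StimulusSet":
        return StimulusSet(
            x_v=self.x_v[idx], x_a=self.x_a[idx],
            t_v=self.t_v[idx], t_a=self.t_a[idx],
            label_v=self.label_v[idx], label_a=self.label_a[idx],
            condition=self.condition[idx],
            role=self.role, consistency=self.consistency, seed=self.seed,
        )


def _check_pools(visual: ModalityPool, audio: ModalityPool) -> np.ndarray:
    cv, ca = visual.classes, audio.classes
    if not np.array_equal(cv, ca):
        raise DatasetError(f"pool class sets differ: {cv.tolist()} vs {ca.tolist()}")
    return cv


def _assemble(visual: ModalityPool, audio: ModalityPool, audio_idx: np.ndarray,
              role: str, consistency: str, seed: int) -> StimulusSet:
    x_v = visual.flat()
    x_a = audio.flat()[audio_idx]
    return StimulusSet(
        x_v=x_v, x_a=x_a, t_v=x_v.copy(), t_a=x_a.copy(),
        label_v=visual.labels.copy(), label_a=audio.labels[audio_idx].copy(),
        condition=np.full(len(x_v), "both"),
        role=role, consistency=consistency, seed=seed,
    )


def pair_consistent(visual: ModalityPool, audio: ModalityPool, seed: int,
                    role: str = "train") -> StimulusSet:
    """Pair every visual sample with a uniformly drawn auditory sample
    of the same class (with replacement)."""
    _check_pools(visual, audio)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    audio_idx = np.empty(visual.n_samples, dtype=int)
    for c in visual.classes:
        v_rows = np.flatnonzero(visual.labels == c)
        a_rows = np.flatnonzero(audio.labels == c)
        audio_idx[v_rows] = rng.choice(a_rows, size=len(v_rows), replace=True)
    return _assemble(visual, audio, audio_idx, role, "consistent", seed)


def pair_inconsistent(visual: ModalityPool, audio: ModalityPool, seed: int,
                      role: str = "train") -> StimulusSet:
    """Pair every visual sample with an auditory sample of a uniformly
    drawn *different* class (the control pairing)."""
    classes = _check_pools(visual, audio)
    if len(classes) < 2:
        raise DatasetError("inconsistent pairing requires at least 2 classes")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 13)))
    audio_idx = np.empty(visual.n_samples, dtype=int)
    for c in visual.classes:
        v_rows = np.flatnonzero(visual.labels == c)
        a_rows = np.flatnonzero(audio.labels != c)
        audio_idx[v_rows] = rng.choice(a_rows, size=len(v_rows), replace=True)
    return _assemble(visual, audio, audio_idx, role, "inconsistent", seed)


def pair_test(visual: ModalityPool, audio: ModalityPool, seed: int) -> StimulusSet:
    """Test pairing: the i-th visual variation of each class paired with
    the i-th (seeded-shuffled) auditory variation of the same class."""
    _check_pools(visual, audio)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 17)))
    audio_idx = np.empty(visual.n_samples, dtype=int)
    for c in visual.classes:
        v_rows = np.flatnonzero(visual.labels == c)
        a_rows = rng.permutation(np.flatnonzero(audio.labels == c))
        audio_idx[v_rows] = a_rows[np.arange(len(v_rows)) % len(a_rows)]
    return _assemble(visual, audio, audio_idx, "test", "consistent", seed)


def augment_modality_dropout(base: StimulusSet) -> StimulusSet:
    """Triple a both-modality set with single-modality copies.

    Returns the union of three copies of ``base``: unchanged,
    visual-only (auditory input zeroed), auditory-only (visual input
    zeroed). Reconstruction targets keep the original arrays in every
    copy, so the network must reconstruct both modalities from one.
    """
    if not np.all(base.condition == "both"):
        raise DatasetError("input already augmented: found non-'both' conditions")
    n = len(base)
    x_v = np.concatenate([base.x_v, base.x_v, np.zeros_like(base.x_v)])
    x_a = np.concatenate([base.x_a, np.zeros_like(base.x_a), base.x_a])
    tile = lambda a: np.concatenate([a, a, a])
    condition = np.concatenate([
        np.full(n, "both"), np.full(n, "visual_only"), np.full(n, "audio_only")
    ])
    return StimulusSet(
        x_v=x_v, x_a=x_a, t_v=tile(base.t_v), t_a=tile(base.t_a),
        label_v=tile(base.label_v), label_a=tile(base.label_a),
        condition=condition,
        role=base.role, consistency=base.consistency, seed=base.seed,
    )


def build_datasets(config: GeneratorConfig):
    """Build one (train_consistent, train_inconsistent, test) triple.

    All three are modality-dropout augmented; the test set pairs the
    held-out visual and auditory variations class by class.
    """
    vis_train = generate_pool(config, "visual", "train")
    vis_test = generate_pool(config, "visual", "test")
    aud_train = generate_pool(config, "auditory", "train")
    aud_test = generate_pool(config, "auditory", "test")
    s = config.seed
    train_c = augment_modality_dropout(pair_consistent(vis_train, aud_train, s))
    train_i = augment_modality_dropout(pair_inconsistent(vis_train, aud_train, s))
    test = augment_modality_dropout(pair_test(vis_test, aud_test, s))
    return train_c, train_i, test


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Derive an independent sub-seed for one replicate (< 2**31)."""
    ss = np.random.SeedSequence((int(master_seed), 101, int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_replicates(n_replicates: int, config: GeneratorConfig):
    """Independent dataset triples for replicate simulations.

    Each replicate regenerates pools and pairings under its own derived
    seed; the study protocol uses 10 replicates per condition.
    """
    if n_replicates < 1:
        raise DatasetError("n_replicates must be >= 1")
    out = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=replicate_seed(config.seed, r))
        out.append(build_datasets(cfg))
    return out
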