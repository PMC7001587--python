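"""Pairing, modality-dropout augmentation, and replicate protocol."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from sharedrep.dataset_builder import (
    DatasetError,
    augment_modality_dropout,
    build_datasets,
    make_replicates,
    pair_consistent,
    pair_inconsistent,
    pair_test,
    replicate_seed,
)
from sharedrep.synthetic_data import GeneratorConfig, generate_pool


@pytest.fixture
def pools(tiny_config):
    return (generate_pool(tiny_config, "visual", "train"),
            generate_pool(tiny_config, "auditory", "train"))


class TestPairConsistent:
    def test_labels_always_match(self, pools):
        ss = pair_consistent(*pools, seed=1)
        assert np.array_equal(ss.label_v, ss.label_a)
        assert len(ss) == pools[0].n_samples

    def test_single_sample_pools_forced_pairing(self):
        cfg = GeneratorConfig(n_classes=4, per_class_train=1, audio_per_class=1,
                              seed=3)
        vis = generate_pool(cfg, "visual", "train")
        aud = generate_pool(cfg, "auditory", "train")
        ss = pair_consistent(vis, aud, seed=0)
        aud_flat = aud.flat()
        for c in range(4):
            row = ss.x_a[ss.label_v == c][0]
            np.testing.assert_array_equal(row, aud_flat[aud.labels == c][0])

    def test_determinism(self, pools):
        a = pair_consistent(*pools, seed=5)
        b = pair_consistent(*pools, seed=5)
        np.testing.assert_array_equal(a.x_a, b.x_a)

    def test_study_scale_pair_count(self):
        """10 classes x 500 visual paired with 50 audio each -> 5,000
        label-matched pairs before augmentation."""
        cfg = GeneratorConfig(seed=1)
        vis = generate_pool(cfg, "visual", "train")
        aud = generate_pool(cfg, "auditory", "train")
        ss = pair_consistent(vis, aud, seed=1)
        assert len(ss) == 5000
        assert np.all(ss.label_v == ss.label_a)

    def test_class_mismatch_rejected(self, pools):
        vis, aud = pools
        bad = dataclasses.replace(
            GeneratorConfig(n_classes=3, per_class_train=4, audio_per_class=3),
            seed=7)
        aud3 = generate_pool(bad, "auditory", "train")
        with pytest.raises(DatasetError):
            pair_consistent(vis, aud3, seed=0)


class TestPairInconsistent:
    def test_labels_never_match(self, pools):
        ss = pair_inconsistent(*pools, seed=2)
        assert np.all(ss.label_v != ss.label_a)

    def test_two_class_pools_forced_swap(self):
        cfg = GeneratorConfig(n_classes=2, per_class_train=3, audio_per_class=3,
                              seed=9)
        vis = generate_pool(cfg, "visual", "train")
        aud = generate_pool(cfg, "auditory", "train")
        ss = pair_inconsistent(vis, aud, seed=0)
        assert np.all(ss.label_a == 1 - ss.label_v)

    def test_single_class_rejected(self):
        cfg = GeneratorConfig(n_classes=1, per_class_train=2, audio_per_class=2,
                              seed=9)
        vis = generate_pool(cfg, "visual", "train")
        aud = generate_pool(cfg, "auditory", "train")
        with pytest.raises(DatasetError):
            pair_inconsistent(vis, aud, seed=0)

    def test_partners_uniform_over_other_classes(self):
        """For a fixed visual class, audio partner labels are compatible
        with uniform draws over the 9 other classes (chi-square)."""
        cfg = GeneratorConfig(per_class_train=300, audio_per_class=5, seed=12,
                              visual_shape=(4, 4), auditory_shape=(2, 8))
        vis = generate_pool(cfg, "visual", "train")
        aud = generate_pool(cfg, "auditory", "train")
        ss = pair_inconsistent(vis, aud, seed=3)
        partners = ss.label_a[ss.label_v == 0]
        observed = np.bincount(partners, minlength=10)[1:]
        _, p = stats.chisquare(observed)
        assert p > 0.001


class TestAugmentation:
    def test_triples_and_splits_equally(self, pools):
        base = pair_consistent(*pools, seed=1)
        aug = augment_modality_dropout(base)
        assert len(aug) == 3 * len(base)
        for cond in ("both", "visual_only", "audio_only"):
            assert (aug.condition == cond).sum() == len(base)

    def test_single_pair_gives_three_conditions(self, pools):
        base = pair_consistent(*pools, seed=1)._take(np.array([0]))
        aug = augment_modality_dropout(base)
        assert sorted(aug.condition) == ["audio_only", "both", "visual_only"]

    def test_dropped_modalities_exactly_zero(self, pools):
        aug = augment_modality_dropout(pair_consistent(*pools, seed=1))
        assert np.all(aug.x_a[aug.condition == "visual_only"] == 0.0)
        assert np.all(aug.x_v[aug.condition == "audio_only"] == 0.0)

    def test_targets_keep_original_arrays(self, pools):
        base = pair_consistent(*pools, seed=1)
        aug = augment_modality_dropout(base)
        for cond in ("both", "visual_only", "audio_only"):
            sel = aug.condition == cond
            np.testing.assert_array_equal(aug.t_v[sel], base.t_v)
            np.testing.assert_array_equal(aug.t_a[sel], base.t_a)

    def test_label_multiset_preserved_per_condition(self, pools):
        base = pair_consistent(*pools, seed=1)
        aug = augment_modality_dropout(base)
        for cond in ("both", "visual_only", "audio_only"):
            sel = aug.condition == cond
            assert np.array_equal(np.sort(aug.label_v[sel]), np.sort(base.label_v))

    def test_double_augmentation_rejected(self, pools):
        aug = augment_modality_dropout(pair_consistent(*pools, seed=1))
        with pytest.raises(DatasetError):
            augment_modality_dropout(aug)

    def test_study_scale_counts(self):
        """5,000 consistent pairs augment to 15,000; the 500-pair test
        build augments to 1,500 with exact one-third condition splits."""
        cfg = GeneratorConfig(seed=2)
        train_c, _, test = build_datasets(cfg)
        assert len(train_c) == 15000
        assert len(test) == 1500
        for cond in ("both", "visual_only", "audio_only"):
            assert (test.condition == cond).sum() == 500


class TestReplicates:
    def test_replicate_count_and_distinct_seeds(self, tiny_config):
        reps = make_replicates(3, tiny_config)
        assert len(reps) == 3
        seeds = {triple[0].seed for triple in reps}
        assert len(seeds) == 3

    def test_reproducible(self, tiny_config):
        a = make_replicates(2, tiny_config)
        b = make_replicates(2, tiny_config)
        for (ta, _, _), (tb, _, _) in zip(a, b):
            np.testing.assert_array_equal(ta.x_v, tb.x_v)
            np.testing.assert_array_equal(ta.x_a, tb.x_a)

    def test_test_sets_augmented_with_equal_thirds(self, tiny_config):
        (_, _, test), = make_replicates(1, tiny_config)
        n = len(test) // 3
        for cond in ("both", "visual_only", "audio_only"):
            assert (test.condition == cond).sum() == n

    def test_consistent_and_inconsistent_roles(self, tiny_config):
        (train_c, train_i, _), = make_replicates(1, tiny_config)
        both_c = train_c.condition == "both"
        both_i = train_i.condition == "both"
        assert np.all(train_c.label_v[both_c] == train_c.label_a[both_c])
        assert np.all(train_i.label_v[both_i] != train_i.label_a[both_i])

    def test_invalid_count_rejected(self, tiny_config):
        with pytest.raises(DatasetError):
            make_replicates(0, tiny_config)

    def test_replicate_seed_below_2_31(self):
        assert all(0 <= replicate_seed(123, r) < 2**31 for r in range(20))


class TestSubset:
    def test_subset_filters_condition(self, pools):
        aug = augment_modality_dropout(pair_consistent(*pools, seed=1))
        sub = aug.subset("visual_only")
        assert np.all(sub.condition == "visual_only")
        assert len(sub) == len(aug) // 3

    def test_missing_condition_rejected(self, pools):
        base = pair_consistent(*pools, seed=1)
        with pytest.raises(DatasetError):
            base.subset("visual_only")
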