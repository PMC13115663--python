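"""Cross-validation protocol: folds, masking, metrics, leakage hygiene,
training behavior and the disease hold-out ranking."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from mvhagcn.data_io import AssociationMatrix, ContractError, EntityIndex
from mvhagcn.model import ModelConfig
from mvhagcn.similarity import gip_kernel
from mvhagcn.synthetic import SyntheticConfig, generate_bundle, planted_truth
from mvhagcn.train_eval import (
    TrainConfig,
    _ordered_views,
    _pairs_and_labels,
    audit_fold,
    compute_static_views,
    disease_holdout_rank,
    evaluate,
    make_folds,
    mask_test_associations,
    run_ablation,
    run_cv,
    train_model,
)

from conftest import auc_concordance

FAST_MODEL = ModelConfig(embed_dim=32, n_heads=2, mlp_hidden=32, seed=5)
FAST_TRAIN = TrainConfig(epochs=60)


@pytest.fixture(scope="module")
def assoc_10x8():
    rng = np.random.default_rng(0)
    values = (rng.random((10, 8)) < 0.25).astype(float)
    values[0, 0] = 1.0
    idx = EntityIndex(
        tuple(f"m{i}" for i in range(10)), tuple(f"d{j}" for j in range(8))
    )
    return AssociationMatrix(values, idx)


class TestMakeFolds:
    def test_even_split_of_ten_positives(self):
        idx = EntityIndex(tuple(f"m{i}" for i in range(5)), tuple(f"d{j}" for j in range(4)))
        values = np.zeros((5, 4))
        values.flat[[0, 2, 5, 7, 9, 10, 12, 14, 17, 19]] = 1
        plan = make_folds(AssociationMatrix(values, idx), 5, 1)
        assert [len(f.test_pos) for f in plan.folds] == [2, 2, 2, 2, 2]

    def test_test_positives_partition_all_positives(self, assoc_10x8):
        plan = make_folds(assoc_10x8, 5, 3)
        all_pos = {tuple(p) for p in np.argwhere(assoc_10x8.values == 1)}
        covered = set()
        for f in plan.folds:
            chunk = {tuple(p) for p in f.test_pos}
            assert not covered & chunk
            covered |= chunk
        assert covered == all_pos

    def test_negatives_are_zero_entries_and_disjoint(self, assoc_10x8):
        plan = make_folds(assoc_10x8, 4, 3)
        seen = set()
        for f in plan.folds:
            for p in f.test_neg:
                assert assoc_10x8.values[p[0], p[1]] == 0
                assert tuple(p) not in seen
                seen.add(tuple(p))
            assert len(f.test_neg) == pytest.approx(len(f.test_pos), abs=1)

    def test_same_seed_reproducible(self, assoc_10x8):
        p1 = make_folds(assoc_10x8, 5, 9)
        p2 = make_folds(assoc_10x8, 5, 9)
        for f1, f2 in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(f1.test_pos, f2.test_pos)
            np.testing.assert_array_equal(f1.train_neg, f2.train_neg)

    def test_insufficient_zeros_rejected(self):
        idx = EntityIndex(("m1", "m2"), ("d1", "d2"))
        values = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ContractError):
            make_folds(AssociationMatrix(values, idx), 2, 0)


class TestMasking:
    def test_mask_and_count(self, assoc_10x8):
        plan = make_folds(assoc_10x8, 5, 3)
        fold = plan.folds[0]
        masked = mask_test_associations(assoc_10x8, fold)
        n_pos = int(assoc_10x8.values.sum())
        assert masked.values.sum() == n_pos - len(fold.test_pos)
        # unmasking restores the original
        restored = masked.values.copy()
        restored[fold.test_pos[:, 0], fold.test_pos[:, 1]] = 1.0
        np.testing.assert_array_equal(restored, assoc_10x8.values)

    def test_gip_changes_under_masking(self, assoc_10x8):
        fold = make_folds(assoc_10x8, 5, 3).folds[0]
        masked = mask_test_associations(assoc_10x8, fold)
        full = gip_kernel(assoc_10x8, "mirna").values
        masked_k = gip_kernel(masked, "mirna").values
        assert not np.allclose(full, masked_k)

    def test_fold_audit_passes(self, assoc_10x8):
        for fold in make_folds(assoc_10x8, 5, 3).folds:
            audit_fold(assoc_10x8, fold, mask_test_associations(assoc_10x8, fold))


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert m.auc == 1.0 and m.aupr == 1.0 and m.acc == 1.0

    def test_full_inversion(self):
        m = evaluate(np.array([0.4, 0.6]), np.array([1, 0]))
        assert m.auc == 0.0

    def test_matches_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = rng.integers(10, 200)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 5, size=n) / 4.0  # coarse grid forces ties
            m = evaluate(scores, labels)
            assert m.auc == pytest.approx(auc_concordance(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        perm = rng.permutation(40)
        m1 = evaluate(scores, labels)
        m2 = evaluate(scores[perm], labels[perm])
        assert m1 == m2


class TestTraining:
    def test_loss_decreases(self, small_bundle):
        static = compute_static_views(small_bundle)
        fold = make_folds(small_bundle.associations, 5, 2).folds[0]
        masked = mask_test_associations(small_bundle.associations, fold)
        mv, dv = _ordered_views(static, masked)
        pairs, labels = _pairs_and_labels(fold.train_pos, fold.train_neg)
        model = train_model(mv, dv, masked, pairs, labels, FAST_MODEL, FAST_TRAIN)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_cv_deterministic_under_seed(self, small_bundle):
        static = compute_static_views(small_bundle)
        kwargs = dict(k=3, seed=4, static_views=static)
        r1 = run_cv(small_bundle, FAST_MODEL, FAST_TRAIN, **kwargs)
        r2 = run_cv(small_bundle, FAST_MODEL, FAST_TRAIN, **kwargs)
        assert r1.fold_metrics == r2.fold_metrics
        for a, b in zip(r1.loss_histories, r2.loss_histories):
            np.testing.assert_array_equal(a, b)

    def test_ablation_none_reproduces_cv(self, small_bundle):
        static = compute_static_views(small_bundle)
        r1 = run_cv(small_bundle, FAST_MODEL, FAST_TRAIN, k=3, seed=4, static_views=static)
        r2 = run_ablation(
            small_bundle, "none", FAST_MODEL, FAST_TRAIN, k=3, seed=4, static_views=static
        )
        assert r1.fold_metrics == r2.fold_metrics

    def test_multisource_ablation_uses_single_gip_view(self, small_bundle):
        static = compute_static_views(small_bundle)
        fold = make_folds(small_bundle.associations, 3, 2).folds[0]
        masked = mask_test_associations(small_bundle.associations, fold)
        mv, dv = _ordered_views(static, masked)
        pairs, labels = _pairs_and_labels(fold.train_pos, fold.train_neg)
        cfg = ModelConfig(
            embed_dim=32, n_heads=2, mlp_hidden=32, seed=5, ablate=("multisource",)
        )
        model = train_model(mv, dv, masked, pairs, labels, cfg, FAST_TRAIN)
        assert len(model._Sm) == 1 and len(model._Sd) == 1
        assert model.fusion.alpha.shape == (1,)

    def test_unknown_ablation_variant_rejected(self, small_bundle):
        with pytest.raises(ContractError):
            run_ablation(small_bundle, "w/o XYZ", FAST_MODEL, FAST_TRAIN)


class TestDiseaseHoldout:
    def test_returned_length_and_no_target_training_pairs(self, small_bundle):
        target = small_bundle.index.disease_ids[0]
        ranked = disease_holdout_rank(
            small_bundle, target, 12, FAST_MODEL, FAST_TRAIN, seed=3
        )
        assert len(ranked) == 12
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_unknown_disease_rejected(self, small_bundle):
        with pytest.raises(ContractError):
            disease_holdout_rank(small_bundle, "not-a-disease", 5, FAST_MODEL, FAST_TRAIN)

    def test_planted_block_enrichment_in_top_candidates(self):
        """miRNAs from a held-out disease's block should be enriched among
        its top-ranked candidates relative to a uniform draw.

        The fixture uses few, large blocks: a held-out disease is scored
        purely through its similarity row, and with many small blocks that
        row is swamped by the background-similarity floor of the unrelated
        majority (the trivial propagation scorer fails there too). Evidence
        is combined over three held-out targets (Fisher's method over
        hypergeometric tails).
        """
        from scipy.stats import chi2

        cfg = SyntheticConfig(
            n_mirna=45,
            n_disease=15,
            n_blocks=3,
            within_block_assoc_prob=0.4,
            background_assoc_prob=0.02,
            seed=21,
        )
        bundle = generate_bundle(cfg)
        labels = planted_truth(cfg)
        mb, db = labels[:45], labels[45:]
        mirna_pos = {m: i for i, m in enumerate(bundle.index.mirna_ids)}
        from mvhagcn.train_eval import compute_static_views

        static = compute_static_views(bundle)
        log_ps = []
        for target_j in (0, 5, 9):
            ranked = disease_holdout_rank(
                bundle,
                bundle.index.disease_ids[target_j],
                15,
                ModelConfig(embed_dim=64, n_heads=2, mlp_hidden=64, seed=9),
                TrainConfig(epochs=400),
                seed=9,
                static_views=static,
            )
            top = np.array([mirna_pos[m] for m, _ in ranked])
            block = db[target_j]
            in_block = int((mb[top] == block).sum())
            n_block = int((mb == block).sum())
            log_ps.append(np.log(hypergeom.sf(in_block - 1, 45, n_block, 15)))
        combined = chi2.sf(-2 * np.sum(log_ps), df=2 * len(log_ps))
        assert combined < 0.05, f"combined enrichment p={combined:.3g}"
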