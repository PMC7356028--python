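import numpy as np
import pandas as pd
import pytest

from pairiface import classifier as clf
from pairiface import features as ft
from pairiface.labeling import PairLabelSet
from pairiface.synthetic import gen_separable_table

FAST = clf.FAST_GRID


def random_stack(rng, m, n):
    mats = {f: rng.uniform(0, 1, size=(m, n)) for f in ft.ALL_FEATURES}
    return ft.FeatureStack(matrices=mats, feature_order=ft.ALL_FEATURES)


def stack_and_labels_with_signal(rng, m, n, n_pos, signal=0.5):
    """Stack whose features are uniformly shifted on the positive cells."""
    pos = set()
    while len(pos) < n_pos:
        pos.add((int(rng.integers(1, m + 1)), int(rng.integers(1, n + 1))))
    labels = PairLabelSet(M=m, N=n, positives=frozenset(pos))
    mats = {}
    mask = labels.as_matrix().astype(bool)
    for f in ft.ALL_FEATURES:
        base = rng.normal(0.3, 0.08, size=(m, n))
        base[mask] += signal
        mats[f] = np.clip(base, 0, 1)
    return ft.FeatureStack(matrices=mats, feature_order=ft.ALL_FEATURES), labels


class TestAssembleTable:
    def test_shape_and_columns(self, rng):
        stack = random_stack(rng, 4, 3)
        labels = PairLabelSet(M=4, N=3, positives=frozenset({(2, 2)}))
        table = clf.assemble_table("c1", stack, labels)
        assert len(table) == 12
        assert list(table.columns[:3]) == ["complex_id", "i", "j"]
        assert list(table.columns[3:-1]) == list(ft.ALL_FEATURES)
        assert table["label"].sum() == 1
        row = table[(table.i == 2) & (table.j == 2)]
        assert row["label"].item() == 1
        assert row["CMI"].item() == stack["CMI"][1, 1]

    def test_grid_mismatch_rejected(self, rng):
        stack = random_stack(rng, 4, 3)
        labels = PairLabelSet(M=3, N=4, positives=frozenset())
        with pytest.raises(ValueError, match="does not match"):
            clf.assemble_table("c1", stack, labels)


class TestDownsampleMajority:
    def make_table(self, n_pos, n_neg, rng):
        table = gen_separable_table(n_pos=n_pos, n_neg=n_neg, seed=int(rng.integers(1e6)))
        return table

    def test_ratio_arithmetic(self, rng):
        out = clf.downsample_majority(self.make_table(100, 10_000, rng), ratio=5, seed=1)
        assert len(out) == 600
        assert out["label"].sum() == 100

    def test_undersupplied_negatives_all_kept(self, rng):
        out = clf.downsample_majority(self.make_table(100, 300, rng), ratio=5, seed=1)
        assert len(out) == 400

    def test_deterministic_under_seed(self, rng):
        table = self.make_table(50, 2000, rng)
        a = clf.downsample_majority(table, ratio=5, seed=9)
        b = clf.downsample_majority(table, ratio=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_never_drops_positives(self, rng):
        table = self.make_table(80, 5000, rng)
        out = clf.downsample_majority(table, ratio=2, seed=0)
        assert out["label"].sum() == 80

    def test_no_positives_rejected(self, rng):
        table = self.make_table(10, 100, rng)
        with pytest.raises(ValueError, match="positive"):
            clf.downsample_majority(table[table.label == 0], ratio=5, seed=0)


class TestGridSearchFit:
    def test_separable_table_high_f1(self):
        table = gen_separable_table(n_pos=150, n_neg=750, shift=0.4, seed=0)
        model = clf.grid_search_fit(table, grid=FAST, seed=0)
        assert model.holdout_f1 >= 0.95

    def test_single_class_rejected(self):
        table = gen_separable_table(n_pos=10, n_neg=100, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            clf.grid_search_fit(table[table.label == 0].assign(label=0), grid=FAST)

    def test_feature_order_stored(self):
        table = gen_separable_table(n_pos=60, n_neg=300, seed=1)
        model = clf.grid_search_fit(table, grid=FAST, seed=1)
        assert model.feature_order == tuple(ft.ALL_FEATURES)
        assert len(model.feature_order) == 18

    def test_metadata_roundtrip(self, tmp_path):
        table = gen_separable_table(n_pos=60, n_neg=300, seed=2)
        model = clf.grid_search_fit(
            table, grid=FAST, seed=2, kernel_spec={"size": 5, "decay": 0.1}
        )
        path = tmp_path / "model.joblib"
        model.save(path)
        again = clf.TrainedModel.load(path)
        assert again.metadata() == model.metadata()


class TestPredictMatrix:
    def fitted_model(self, seed=0):
        table = gen_separable_table(n_pos=120, n_neg=600, seed=seed)
        return clf.grid_search_fit(table, grid=FAST, seed=seed)

    def test_constant_stack_constant_probability(self, rng):
        model = self.fitted_model()
        mats = {f: np.full((4, 5), 0.4) for f in ft.ALL_FEATURES}
        stack = ft.FeatureStack(matrices=mats, feature_order=ft.ALL_FEATURES)
        prob, binary = clf.predict_matrix(model, stack)
        assert len(np.unique(prob)) == 1
        assert set(np.unique(binary)) <= {0, 1}

    def test_binary_consistent_with_threshold(self, rng):
        model = self.fitted_model()
        stack = random_stack(rng, 6, 6)
        prob, binary = clf.predict_matrix(model, stack)
        np.testing.assert_array_equal(binary, (prob > 0.5).astype(int))
        assert prob.min() >= 0 and prob.max() <= 1

    def test_planted_pairs_score_above_background(self, rng):
        model = self.fitted_model()
        stack, labels = stack_and_labels_with_signal(rng, 12, 10, n_pos=8)
        prob, _ = clf.predict_matrix(model, stack)
        mask = labels.as_matrix().astype(bool)
        assert prob[mask].mean() > prob[~mask].mean()

    def test_missing_feature_listed(self, rng):
        model = self.fitted_model()
        mats = {f: rng.uniform(size=(3, 3)) for f in ft.BASE_FEATURES}
        stack = ft.FeatureStack(matrices=mats, feature_order=ft.BASE_FEATURES)
        with pytest.raises(ValueError, match="ECMI"):
            clf.predict_matrix(model, stack)


class TestEvaluate:
    def test_perfect_prediction(self):
        labels = PairLabelSet(M=5, N=4, positives=frozenset({(1, 1), (2, 3)}))
        report = clf.evaluate(labels.as_matrix(), labels)
        assert report.accuracy == 1.0
        assert report.mcc == pytest.approx(1.0)
        assert report.f1_macro == pytest.approx(1.0)

    def test_all_negative_on_ten_percent_positives(self):
        # closed-form confusion arithmetic: 90 TN, 10 FN
        pos = frozenset((i, 1) for i in range(1, 11))
        labels = PairLabelSet(M=10, N=10, positives=pos)
        report = clf.evaluate(np.zeros((10, 10), dtype=int), labels)
        assert report.accuracy == pytest.approx(0.9)
        assert report.tp == 0 and report.fn == 10
        assert report.mcc == pytest.approx(0.0)
        assert report.recall_macro == pytest.approx(0.5)  # mean(1.0, 0.0)
        assert report.specificity == pytest.approx(1.0)

    def test_internal_consistency(self, rng):
        labels = PairLabelSet(
            M=8, N=8, positives=frozenset({(1, 2), (3, 4), (5, 6)})
        )
        pred = rng.integers(0, 2, size=(8, 8))
        report = clf.evaluate(pred, labels)
        assert report.n_pairs == 64
        recomputed_acc = (report.tp + report.tn) / report.n_pairs
        assert report.accuracy == pytest.approx(recomputed_acc)
        assert -1 <= report.mcc <= 1
        assert 0 <= report.specificity <= 1


class TestLeaveOneOut:
    def make_complexes(self, rng, n=3):
        out = []
        for k in range(n):
            stack, labels = stack_and_labels_with_signal(rng, 10, 8, n_pos=6)
            out.append((f"c{k}", stack, labels))
        return out

    def test_fold_bookkeeping(self, rng):
        complexes = self.make_complexes(rng)
        reports = clf.leave_one_out(complexes, grid=FAST, seed=0)
        assert set(reports) == {"c0", "c1", "c2"}

    def test_no_leakage(self, rng):
        complexes = self.make_complexes(rng)
        results = clf.leave_one_out(complexes, grid=FAST, seed=0, return_models=True)
        for held_id, (model, _) in results.items():
            assert held_id not in model.training_complexes
            assert len(model.training_complexes) == 2

    def test_duplicate_ids_rejected(self, rng):
        complexes = self.make_complexes(rng)
        complexes.append(complexes[0])
        with pytest.raises(ValueError, match="duplicate"):
            clf.leave_one_out(complexes, grid=FAST)

    def test_signal_beats_label_permutation(self, rng):
        complexes = self.make_complexes(rng, n=3)
        reports = clf.leave_one_out(complexes, grid=FAST, seed=0)
        signal_recall = np.mean(
            [r.tp / max(1, r.tp + r.fn) for r in reports.values()]
        )
        # permuted labels: same stacks, positives at random positions
        permuted = []
        for cid, stack, labels in complexes:
            k = len(labels.positives)
            pos = set()
            while len(pos) < k:
                pos.add(
                    (int(rng.integers(1, labels.M + 1)), int(rng.integers(1, labels.N + 1)))
                )
            permuted.append(
                (cid, stack, PairLabelSet(M=labels.M, N=labels.N, positives=frozenset(pos)))
            )
        null_reports = clf.leave_one_out(permuted, grid=FAST, seed=0)
        null_recall = np.mean(
            [r.tp / max(1, r.tp + r.fn) for r in null_reports.values()]
        )
        assert signal_recall > null_recall


class TestFeatureImportance:
    def test_entries_sum_to_one(self):
        table = gen_separable_table(n_pos=80, n_neg=400, seed=3)
        model = clf.grid_search_fit(table, grid=FAST, seed=3)
        ranked = clf.feature_importance(model)
        assert len(ranked) == 18
        assert sum(v for _, v in ranked) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for _, v in ranked)
        assert [v for _, v in ranked] == sorted((v for _, v in ranked), reverse=True)

    def test_informative_feature_ranks_top(self):
        top3_hits = 0
        for seed in range(10):
            table = gen_separable_table(
                n_pos=80, n_neg=400, seed=seed, informative=("CMI", "ECMI")
            )
            model = clf.grid_search_fit(table, grid=FAST, seed=seed)
            top3 = {name for name, _ in clf.feature_importance(model)[:3]}
            if top3 & {"CMI", "ECMI"}:
                top3_hits += 1
        assert top3_hits >= 9

    def test_row_order_invariance_of_ranking(self):
        # shuffling rows must not change which features dominate
        table = gen_separable_table(
            n_pos=60, n_neg=300, seed=4, informative=("CMI", "ECMI")
        )
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m1 = clf.grid_search_fit(table, grid=FAST, seed=4)
        m2 = clf.grid_search_fit(shuffled, grid=FAST, seed=4)
        top1 = {name for name, _ in clf.feature_importance(m1)[:2]}
        top2 = {name for name, _ in clf.feature_importance(m2)[:2]}
        assert top1 == top2 == {"CMI", "ECMI"}

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        model = clf.TrainedModel(
            forest=RandomForestClassifier(),
            hyperparameters={},
            feature_order=tuple(ft.ALL_FEATURES),
        )
        with pytest.raises(ValueError, match="not fitted"):
            clf.feature_importance(model)
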