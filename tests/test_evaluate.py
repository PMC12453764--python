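"""Protocol: split/fold invariants, metric formulas vs brute force and
scikit-learn, grid-search enumeration, and the three-variant experiment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from dermapatch.evaluate import (
    stratified_split, kfold, compute_metrics, rank_auc, grid_search,
    run_experiment, ExperimentConfig, TUNING_GRID, MlpModel,
)
from _oracles import auc_pairwise, metrics_bruteforce


class TestSplits:
    def test_balanced_100_sample_split(self):
        labels = np.array([0, 1] * 50)
        sp = stratified_split(labels, seed=0)
        assert len(sp.train) == 70 and len(sp.val) == 15 and len(sp.test) == 15
        assert labels[sp.train].sum() == 35
        assert labels[sp.val].sum() in (7, 8)
        assert labels[sp.test].sum() in (7, 8)

    def test_partition_and_determinism(self, rng):
        labels = rng.integers(0, 2, 57)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        a = stratified_split(labels, seed=3)
        b = stratified_split(labels, seed=3)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
        allidx = np.concatenate([a.train, a.val, a.test])
        assert sorted(allidx) == list(range(len(labels)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.zeros(50, dtype=int))

    def test_proportions_within_one_sample_for_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(40, 200))
            labels = rng.integers(0, 2, n)
            if min(np.bincount(labels, minlength=2)) < 7:
                continue
            sp = stratified_split(labels, seed=int(rng.integers(1000)))
            for part, frac in ((sp.train, 0.70), (sp.val, 0.15), (sp.test, 0.15)):
                for c in (0, 1):
                    nc = int(np.sum(labels == c))
                    got = int(np.sum(labels[part] == c))
                    assert abs(got - nc * frac) <= 1.0


class TestKfold:
    def test_exact_division(self):
        labels = np.array([0, 1] * 5)
        plan = kfold(labels, k=5, seed=0)
        for fold in plan.folds:
            assert len(fold) == 2
            assert labels[fold].sum() == 1

    def test_partition_law(self, rng):
        labels = rng.integers(0, 2, 43)
        labels[:10] = 0
        labels[10:20] = 1
        plan = kfold(labels, k=5, seed=2)
        allidx = np.concatenate(plan.folds)
        assert sorted(allidx) == list(range(43))

    def test_remainder_distribution(self):
        labels = np.array([0] * 6 + [1] * 5)
        plan = kfold(labels, k=5, seed=1)
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [2, 2, 2, 2, 3]

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            kfold(np.array([0] * 10 + [1] * 3), k=5)


class TestMetrics:
    def test_known_confusion_counts(self):
        """90 TP, 10 FN, 95 TN, 5 FP."""
        labels = np.array([1] * 100 + [0] * 100)
        pred = np.array([1] * 90 + [0] * 10 + [0] * 95 + [1] * 5)
        m = compute_metrics(labels, pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (90, 10, 95, 5)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.95)
        assert m.accuracy == pytest.approx(0.925)
        assert m.precision == pytest.approx(18 / 19)
        assert m.f1 == pytest.approx(0.9231, abs=1e-4)

    def test_auc_four_point_example(self):
        auc = rank_auc(np.array([0, 1, 0, 1]), np.array([0.1, 0.35, 0.4, 0.8]))
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(labels, (scores >= 0.5).astype(int), scores)
        assert m.auc == 1.0
        pts = np.array(m.roc_points)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(1.0)

    def test_matches_bruteforce_and_sklearn_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], n)  # with ties
            m = compute_metrics(labels, pred, scores)
            ref = metrics_bruteforce(labels, pred)
            for key in ("tp", "fp", "tn", "fn"):
                assert getattr(m, key) == ref[key]
            for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
                got, want = getattr(m, key), ref[key]
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want)
            if len(np.unique(labels)) == 2:
                assert m.auc == pytest.approx(auc_pairwise(labels, scores))
                assert m.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_undefined_ratios_are_explicit(self):
        m = compute_metrics(np.array([0, 0]), np.array([0, 0]))
        assert m.sensitivity is None and m.precision is None and m.f1 is None
        assert m.specificity == 1.0

    def test_auc_invariant_under_monotone_transforms(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:5], labels[5:10] = 0, 1
        scores = rng.random(60)
        base = rank_auc(labels, scores)
        for f in (lambda s: 3 * s + 2, np.exp, lambda s: s ** 3,
                  lambda s: np.log(s + 1e-9)):
            assert rank_auc(labels, f(scores)) == pytest.approx(base, abs=1e-12)


class TestGridSearch:
    def test_single_point_grid(self):
        best, table = grid_search({"lr": [0.1]}, lambda p: 1.0)
        assert best == {"lr": 0.1}
        assert len(table) == 1

    def test_cartesian_enumeration(self):
        space = {"lr": [0.01, 0.001, 0.0005], "batch": [8, 16, 32]}
        calls = []
        grid_search(space, lambda p: calls.append(dict(p)) or 0.0)
        assert len(calls) == 9
        assert calls[0] == {"lr": 0.01, "batch": 8}

    def test_tie_goes_to_earliest_cell(self):
        best, _ = grid_search({"a": [1, 2, 3]}, lambda p: 0.5)
        assert best == {"a": 1}

    def test_failures_recorded_search_continues(self):
        def fn(p):
            if p["a"] == 2:
                raise RuntimeError("boom")
            return p["a"]
        best, table = grid_search({"a": [1, 2, 3]}, fn)
        assert best == {"a": 3}
        assert table["error"].notna().sum() == 1

    def test_full_tuning_grid_is_243_cells(self):
        best, table = grid_search(TUNING_GRID, lambda p: p["learning_rate"])
        assert len(table) == 3 ** 5
        assert best["learning_rate"] == 0.01  # max metric, earliest in order

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search({}, lambda p: 0.0)


class TestExperiment:
    def test_report_structure_and_determinism(self):
        from dermapatch.synthdata import SynthConfig, generate_cohort
        cohort = generate_cohort(SynthConfig(
            n_images=60, image_size=(64, 64), lesion_axes_range=(13.0, 16.0),
            lesion_intensity_shift=0.3, seed=5))
        cfg = ExperimentConfig(seed=5, fcrn_epochs=1, per_class_patches=50,
                               map_stride=32)
        r1 = run_experiment(cohort, cfg)
        assert set(r1["variants"]) == {"image_only", "clinical_only", "fused"}
        for runs in r1["variants"].values():
            assert {"val", "test", "history", "seed"} <= set(runs[0])
            for split in ("val", "test"):
                m = runs[0][split]
                for v in (m.accuracy, m.auc):
                    assert v is None or 0.0 <= v <= 1.0
        r2 = run_experiment(cohort, cfg)
        for name in r1["variants"]:
            assert (r1["variants"][name][0]["val"].accuracy
                    == r2["variants"][name][0]["val"].accuracy)

    def test_single_class_cohort_rejected(self):
        from dermapatch.synthdata import SynthConfig, generate_cohort
        cohort = generate_cohort(SynthConfig(n_images=10, prevalence=0.0, seed=1))
        with pytest.raises(ValueError):
            run_experiment(cohort, ExperimentConfig(seed=1))


class TestMlpBaseline:
    def test_shapes_and_softmax(self, rng):
        model = MlpModel(7, seed=0)
        probs = model.predict_proba(rng.normal(size=(5, 7)))
        assert probs.shape == (5, 2)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-9


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from([0, 1]), min_size=20, max_size=120))
def test_split_invariants_property(labels):
    labels = np.array(labels)
    if min(np.bincount(labels, minlength=2)) < 7:
        return
    sp = stratified_split(labels, seed=1)
    combined = np.concatenate([sp.train, sp.val, sp.test])
    assert len(set(combined)) == len(labels)
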