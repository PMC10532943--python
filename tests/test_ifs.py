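"""Incremental feature selection: subset grids, CV evaluation, selection rules."""

import numpy as np
import pytest

from scmarkers import (
    FeatureList,
    IFSConfig,
    SmoteConfig,
    SyntheticSpec,
    ValidationError,
    build_subsets,
    evaluate_subset,
    generate_dataset,
    planted_markers,
    run_ifs,
)
from scmarkers.ifs import stratified_folds


def flist(n, method="toy"):
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    return FeatureList(method, genes, list(np.linspace(1, 0, n)))


class TestBuildSubsets:
    def test_2000_gene_list_interval_10_gives_200_subsets(self):
        subsets = build_subsets(flist(2000), interval=10, cap=2000)
        assert len(subsets) == 200
        assert [len(s) for s in subsets] == list(range(10, 2001, 10))

    def test_partial_final_subset(self):
        subsets = build_subsets(flist(25), interval=10, cap=2000)
        assert [len(s) for s in subsets] == [10, 20, 25]

    def test_interval_one_gives_every_size(self):
        subsets = build_subsets(flist(7), interval=1, cap=2000)
        assert [len(s) for s in subsets] == list(range(1, 8))

    def test_prefix_nesting(self):
        subsets = build_subsets(flist(30), interval=10, cap=30)
        for a, b in zip(subsets, subsets[1:]):
            assert b[: len(a)] == a

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            build_subsets(FeatureList("toy", [], []), interval=10)


class TestStratifiedFolds:
    def test_partition_and_stratification(self):
        labels = np.asarray(["A"] * 30 + ["B"] * 10 + ["C"] * 2, dtype=object)
        folds = stratified_folds(labels, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(42))
        for f in folds:
            a_count = np.sum(labels[f] == "A")
            assert a_count == 6  # 30 / 5 exactly

    def test_tiny_class_tolerated(self):
        labels = np.asarray(["A"] * 20 + ["B"] * 2, dtype=object)
        folds = stratified_folds(labels, 10, seed=0)
        assert sum(np.sum(labels[f] == "B") for f in folds) == 2


@pytest.fixture(scope="module")
def marker_ds():
    spec = SyntheticSpec(
        n_classes=3, n_genes=60, markers_per_class=3,
        class_sizes=[200, 200, 200], effect_size=3.0, dropout_rate=0.0, seed=21,
    )
    return generate_dataset(spec), planted_markers(spec)


class TestEvaluateSubset:
    def test_planted_markers_classify_nearly_perfectly(self, marker_ds):
        ds, markers = marker_ds
        genes = [g for gs in markers.values() for g in gs]
        cfg = IFSConfig(cv_folds=5, classifier="decision_tree", seed=0)
        s = evaluate_subset(ds, genes, cfg)
        assert s.weighted_f1 >= 0.95

    def test_pure_noise_subset_is_chance_level(self):
        spec = SyntheticSpec(
            n_classes=2, n_genes=40, markers_per_class=1,
            class_sizes=[150, 150], effect_size=0.0, seed=5,
        )
        ds = generate_dataset(spec)
        cfg = IFSConfig(cv_folds=5, classifier="decision_tree", seed=1)
        s = evaluate_subset(ds, ds.gene_ids[:10], cfg)
        assert abs(s.acc - 0.5) < 0.12  # Monte-Carlo tolerance

    def test_per_fold_acc_count_equals_folds(self, marker_ds):
        ds, markers = marker_ds
        genes = next(iter(markers.values()))
        cfg = IFSConfig(cv_folds=7, classifier="decision_tree", seed=0)
        s = evaluate_subset(ds, genes, cfg)
        assert len(s.per_fold_acc) == 7

    def test_empty_gene_set_rejected(self, marker_ds):
        ds, _ = marker_ds
        with pytest.raises(ValidationError):
            evaluate_subset(ds, [], IFSConfig(seed=0))

    def test_leaky_smote_mode_inflates_metrics(self, marker_ds):
        # balancing before the CV split leaks synthetic near-copies into
        # test folds, so measured weighted F1 can only look better
        spec = SyntheticSpec(
            n_classes=3, n_genes=40, markers_per_class=2,
            class_sizes=[120, 20, 8], effect_size=1.0, dropout_rate=0.3, seed=13,
        )
        ds = generate_dataset(spec)
        genes = ds.gene_ids[:15]
        clean = evaluate_subset(
            ds, genes, IFSConfig(cv_folds=5, classifier="decision_tree", seed=2)
        )
        leaky = evaluate_subset(
            ds, genes,
            IFSConfig(
                cv_folds=5, classifier="decision_tree", seed=2,
                smote=SmoteConfig(before_cv=True),
            ),
        )
        assert leaky.weighted_f1 >= clean.weighted_f1 - 0.02


class TestRunIfs:
    def test_record_count_and_grid(self, marker_ds):
        ds, _ = marker_ds
        fl = FeatureList("toy", ds.gene_ids, list(np.linspace(1, 0, 60)))
        cfg = IFSConfig(interval=25, cap=60, cv_folds=3, classifier="decision_tree", seed=0)
        res = run_ifs(ds, fl, cfg)
        assert [r.k for r in res.records] == [25, 50, 60]

    def test_zero_delta_makes_feasible_equal_optimal(self, marker_ds):
        ds, _ = marker_ds
        fl = FeatureList("toy", ds.gene_ids, list(np.linspace(1, 0, 60)))
        cfg = IFSConfig(
            interval=20, cap=60, cv_folds=3, classifier="decision_tree",
            feasible_delta=0.0, seed=0,
        )
        res = run_ifs(ds, fl, cfg)
        assert res.feasible_k == res.optimal_k

    def test_feasible_is_smallest_within_delta(self, marker_ds):
        ds, markers = marker_ds
        # markers first: performance saturates early, so a generous delta
        # must pick the first subset size
        genes = [g for gs in markers.values() for g in gs]
        rest = [g for g in ds.gene_ids if g not in genes]
        fl = FeatureList("toy", genes + rest, list(np.linspace(1, 0, 60)))
        cfg = IFSConfig(
            interval=9, cap=27, cv_folds=3, classifier="decision_tree",
            feasible_delta=1.0, seed=0,
        )
        res = run_ifs(ds, fl, cfg)
        assert res.feasible_k == 9
        assert res.feasible_k <= res.optimal_k

    def test_prefix_independence_of_records(self, marker_ds):
        # records for a given k are identical whether the cap is 20 or 60
        ds, _ = marker_ds
        fl = FeatureList("toy", ds.gene_ids, list(np.linspace(1, 0, 60)))
        short = run_ifs(
            ds, fl, IFSConfig(interval=10, cap=20, cv_folds=3,
                              classifier="decision_tree", seed=4)
        )
        long = run_ifs(
            ds, fl, IFSConfig(interval=10, cap=60, cv_folds=3,
                              classifier="decision_tree", seed=4)
        )
        for a, b in zip(short.records, long.records[:2]):
            assert a.k == b.k
            assert a.summary.weighted_f1 == b.summary.weighted_f1
            assert a.summary.per_fold_acc == b.summary.per_fold_acc

    def test_determinism(self, marker_ds):
        ds, _ = marker_ds
        fl = FeatureList("toy", ds.gene_ids[:20], list(np.linspace(1, 0, 20)))
        cfg = IFSConfig(interval=10, cap=20, cv_folds=3, seed=6,
                        classifier="random_forest",
                        classifier_params={"n_estimators": 10})
        a = run_ifs(ds, fl, cfg)
        b = run_ifs(ds, fl, cfg)
        assert [r.summary.weighted_f1 for r in a.records] == [
            r.summary.weighted_f1 for r in b.records
        ]

    def test_marker_recovery_in_optimal_subset(self, marker_ds):
        ds, markers = marker_ds
        planted = [g for gs in markers.values() for g in gs]
        rest = [g for g in ds.gene_ids if g not in planted]
        fl = FeatureList("toy", planted + rest, list(np.linspace(1, 0, 60)))
        cfg = IFSConfig(interval=10, cap=60, cv_folds=3,
                        classifier="decision_tree", seed=0)
        res = run_ifs(ds, fl, cfg)
        optimal_genes = set(fl.top(res.optimal_k))
        assert len(optimal_genes & set(planted)) >= 0.9 * len(planted)
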