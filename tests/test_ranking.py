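"""Per-scheme ranking oracles on small instances, plus shared invariants."""

import numpy as np
import pytest

from scmarkers import (
    LabeledDataset,
    McfsParams,
    MrmrParams,
    SyntheticSpec,
    ValidationError,
    generate_dataset,
    planted_markers,
    rank_features,
    rank_gbt,
    rank_lasso,
    rank_mcfs,
    rank_mrmr,
    rank_rf,
)
from scmarkers.ranking import discretize, mutual_information


@pytest.fixture(scope="module")
def planted_ds():
    spec = SyntheticSpec(
        n_classes=4, n_genes=80, markers_per_class=2,
        class_sizes=[60, 40, 30, 20], effect_size=3.0, dropout_rate=0.0, seed=11,
    )
    return generate_dataset(spec), planted_markers(spec)


def perfect_separator_dataset(seed=0):
    """One gene at 10 in class A and 0 elsewhere, 49 pure-noise genes."""
    rng = np.random.default_rng(seed)
    n = 40
    X = rng.uniform(0, 1, (n, 50))
    labels = np.asarray(["A"] * 20 + ["B"] * 20, dtype=object)
    X[:20, 7] = 10.0
    X[20:, 7] = 0.0
    return LabeledDataset(
        matrix=X,
        gene_ids=[f"g{i:02d}" for i in range(50)],
        cell_ids=[f"c{i:02d}" for i in range(n)],
        labels=labels,
    )


class TestLasso:
    def test_perfect_separator_ranks_first(self):
        ds = perfect_separator_dataset()
        fl = rank_lasso(ds, seed=0)
        assert fl.genes[0] == "g07"

    def test_constant_matrix_gives_all_zero_scores_in_tiebreak_order(self):
        ds = perfect_separator_dataset()
        const = LabeledDataset(
            matrix=np.ones_like(ds.matrix), gene_ids=ds.gene_ids,
            cell_ids=ds.cell_ids, labels=ds.labels,
        )
        fl = rank_lasso(const, seed=0)
        assert all(s == 0.0 for s in fl.scores)
        assert fl.genes == sorted(ds.gene_ids)

    def test_row_duplication_leaves_order_unchanged(self):
        ds = perfect_separator_dataset()
        doubled = LabeledDataset(
            matrix=np.vstack([ds.matrix, ds.matrix]),
            gene_ids=ds.gene_ids,
            cell_ids=ds.cell_ids + [c + "x" for c in ds.cell_ids],
            labels=np.concatenate([ds.labels, ds.labels]),
        )
        assert rank_lasso(ds, seed=0).genes == rank_lasso(doubled, seed=0).genes


class TestGbt:
    def test_markers_lead_on_planted_instance(self, planted_ds):
        ds, markers = planted_ds
        planted = {g for gs in markers.values() for g in gs}
        fl = rank_gbt(ds, seed=0, min_child_samples=5)
        assert planted <= set(fl.top(16))

    def test_split_count_conservation(self, planted_ds):
        ds, _ = planted_ds
        fl = rank_gbt(ds, seed=0)
        scores = np.asarray(fl.scores)
        assert np.all(scores >= 0)
        assert np.allclose(scores, np.round(scores))
        import lightgbm as lgb

        model = lgb.LGBMClassifier(
            random_state=0, n_jobs=1, deterministic=True,
            force_row_wise=True, verbose=-1,
        )
        model.fit(ds.matrix, ds.label_codes())
        total = model.booster_.feature_importance("split").sum()
        assert scores.sum() == total


class TestMcfs:
    def test_unsampled_gene_scores_zero(self, planted_ds):
        ds, _ = planted_ds
        params = McfsParams(n_subsets=1, trees_per_subset=1, subset_size=10, seed=0)
        fl = rank_mcfs(ds, params)
        nonzero = [g for g, s in zip(fl.genes, fl.scores) if s > 0]
        assert len(nonzero) <= 10

    def test_single_tree_u0_v0_matches_direct_tree_walk(self, planted_ds):
        # with one tree and u=v=0, RI(g) is the plain sum of information
        # gains at the nodes splitting on g; verify by walking the same tree
        from sklearn.tree import DecisionTreeClassifier

        ds, _ = planted_ds
        params = McfsParams(
            n_subsets=1, trees_per_subset=1, subset_size=80, u=0.0, v=0.0,
            train_fraction=0.7, seed=3,
        )
        fl = rank_mcfs(ds, params)
        got = dict(zip(fl.genes, fl.scores))

        # reproduce the sampling exactly as the implementation seeds it
        rng = np.random.default_rng(np.random.SeedSequence([3, 0x3C55]))
        cols = np.sort(rng.choice(80, size=80, replace=False))
        n = ds.n_cells
        n_train = int(round(0.7 * n))
        perm = rng.permutation(n)
        tr = perm[:n_train]
        tree = DecisionTreeClassifier(
            criterion="entropy", random_state=int(rng.integers(2**31))
        )
        tree.fit(ds.matrix[np.ix_(tr, cols)], ds.label_codes()[tr])
        t = tree.tree_
        expected = {}
        for node in range(t.node_count):
            l, r = t.children_left[node], t.children_right[node]
            if l == -1:
                continue
            w = t.weighted_n_node_samples
            gain = t.impurity[node] - (
                w[l] / w[node] * t.impurity[l] + w[r] / w[node] * t.impurity[r]
            )
            gid = ds.gene_ids[cols[int(t.feature[node])]]
            expected[gid] = expected.get(gid, 0.0) + gain
        for gid, val in expected.items():
            assert got[gid] == pytest.approx(val, rel=1e-9)

    def test_markers_beat_background_at_scale(self, planted_ds):
        ds, markers = planted_ds
        planted = {g for gs in markers.values() for g in gs}
        params = McfsParams(n_subsets=40, trees_per_subset=5, subset_size=16, seed=1)
        fl = rank_mcfs(ds, params)
        scores = dict(zip(fl.genes, fl.scores))
        bg = [scores[g] for g in ds.gene_ids if g not in planted]
        cutoff = np.percentile(bg, 95)
        assert all(scores[g] > cutoff for g in planted)


class TestMrmr:
    def test_first_pick_is_brute_force_mi_argmax(self):
        spec = SyntheticSpec(
            n_classes=2, n_genes=6, markers_per_class=1,
            class_sizes=[30, 30], effect_size=3.0, dropout_rate=0.0, seed=8,
        )
        ds = generate_dataset(spec)
        params = MrmrParams(n_select=6)
        fl = rank_mrmr(ds, params)
        states = discretize(ds.matrix, params.discretization)
        y = ds.label_codes()
        mis = {g: mutual_information(states[:, j], y) for j, g in enumerate(ds.gene_ids)}
        best = max(sorted(mis), key=lambda g: mis[g])
        assert fl.genes[0] == best

    def test_duplicate_of_selected_gene_deferred(self):
        rng = np.random.default_rng(0)
        n = 60
        base = np.zeros((n, 5))
        y = np.asarray(["A"] * 30 + ["B"] * 30, dtype=object)
        base[:, 0] = np.r_[rng.normal(3, 0.3, 30), rng.normal(0, 0.3, 30)]  # strong
        base[:, 1] = base[:, 0]  # exact copy
        base[:, 2] = np.r_[rng.normal(2, 1.0, 30), rng.normal(0, 1.0, 30)]  # weaker
        base[:, 3] = rng.normal(1, 1, n)  # noise
        base[:, 4] = rng.normal(1, 1, n)  # noise
        ds = LabeledDataset(
            matrix=np.abs(base),
            gene_ids=["copy0", "copy1", "weak", "noise1", "noise2"],
            cell_ids=[f"c{i}" for i in range(n)],
            labels=y,
        )
        fl = rank_mrmr(ds, MrmrParams(n_select=5))
        first, second = fl.genes[0], fl.genes[1]
        assert first in ("copy0", "copy1")
        assert second not in ("copy0", "copy1")

    def test_constant_genes_have_zero_mi_and_sort_by_tiebreak(self):
        # constants have zero relevance AND zero redundancy, so they rank
        # after informative genes and among themselves by gene id
        X = np.abs(np.random.default_rng(1).normal(1, 1, (40, 4)))
        X[:20, 0] += 4.0  # strongly informative
        X[:, 2] = 1.0
        X[:, 3] = 1.0
        y = np.asarray(["A"] * 20 + ["B"] * 20, dtype=object)
        ds = LabeledDataset(
            matrix=X, gene_ids=["a", "b", "z1", "z2"],
            cell_ids=[f"c{i}" for i in range(40)], labels=y,
        )
        states = discretize(ds.matrix, ("mean_std", 1.0))
        assert mutual_information(states[:, 2], ds.label_codes()) == 0.0
        fl = rank_mrmr(ds, MrmrParams(n_select=4))
        assert fl.genes[0] == "a"
        assert fl.genes.index("z1") < fl.genes.index("z2")

    def test_n_select_larger_than_genes_rejected(self, planted_ds):
        ds, _ = planted_ds
        with pytest.raises(ValidationError):
            rank_mrmr(ds, MrmrParams(n_select=81))

    def test_unselected_remainder_has_nan_scores(self, planted_ds):
        ds, _ = planted_ds
        fl = rank_mrmr(ds, MrmrParams(n_select=10))
        assert len(fl.genes) == 80
        assert all(np.isnan(s) for s in fl.scores[10:])
        assert fl.genes[10:] == sorted(fl.genes[10:])


class TestRf:
    def test_impurity_importances_normalized(self, planted_ds):
        ds, _ = planted_ds
        fl = rank_rf(ds, seed=0)
        scores = np.asarray(fl.scores)
        assert np.all(scores >= 0)
        assert scores.sum() == pytest.approx(1.0)

    def test_markers_lead_on_planted_instance(self, planted_ds):
        ds, markers = planted_ds
        planted = {g for gs in markers.values() for g in gs}
        fl = rank_rf(ds, seed=0)
        assert planted <= set(fl.top(16))

    def test_permutation_importance_of_unused_gene_is_zero(self):
        ds = perfect_separator_dataset()
        # a constant gene is never used by any tree
        X = ds.matrix.copy()
        X[:, 3] = 0.0
        ds2 = LabeledDataset(
            matrix=X, gene_ids=ds.gene_ids, cell_ids=ds.cell_ids, labels=ds.labels
        )
        fl = rank_rf(ds2, seed=0, importance="permutation")
        scores = dict(zip(fl.genes, fl.scores))
        assert scores["g03"] == 0.0


class TestSharedInvariants:
    @pytest.mark.parametrize("method", ["lasso", "gbt", "mcfs", "mrmr", "rf"])
    def test_full_permutation_and_determinism(self, planted_ds, method):
        ds, _ = planted_ds
        kwargs = dict(
            mcfs_params=McfsParams(n_subsets=5, trees_per_subset=2, seed=4),
            mrmr_params=MrmrParams(n_select=20),
        )
        a = rank_features(ds, method, seed=4, **kwargs)
        b = rank_features(ds, method, seed=4, **kwargs)
        assert sorted(a.genes) == sorted(ds.gene_ids)
        assert a.genes == b.genes
        finite = [s for s in a.scores if not np.isnan(s)]
        assert finite == sorted(finite, reverse=True) or method == "mrmr"
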