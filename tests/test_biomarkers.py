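"""Biomarker ranking: feature assembly per platform group, stratified
70/30 splitting, accuracy with Wilson CI, importance recovery of planted
markers, local surrogate explanations, and recurrence tallies."""

import numpy as np
import pandas as pd
import pytest

from genesift import simulate
from genesift.biomarkers import (
    FeatureTable,
    assemble_features,
    local_explanations,
    split_70_30,
    tally_recurrence,
    train_and_score,
    _fit_model,
)


def _planted_table(n=60, n_noise=40, sep=3.0, seed=0, group="A") -> FeatureTable:
    """One perfectly informative marker among Gaussian noise markers."""
    rng = np.random.default_rng(seed)
    y = pd.Series(["case"] * (n // 2) + ["control"] * (n // 2),
                  index=[f"S{i:03d}" for i in range(n)])
    X = pd.DataFrame(rng.normal(size=(n, n_noise)),
                     index=y.index,
                     columns=[f"M{i:03d}" for i in range(n_noise)])
    signal = np.where(y == "case", sep, 0.0) + rng.normal(scale=0.3, size=n)
    X["MSIG"] = signal
    m2g = {c: f"GENE_{c}" for c in X.columns}
    return FeatureTable(group_id=group, X=X, y=y, marker_to_gene=m2g)


class TestAssembleFeatures:
    def _datasets(self):
        cat = simulate.generate_catalog(40, 4, seed=2)
        return cat, simulate.generate_expression(
            cat, [("D1", "P1", 10, 10), ("D2", "P1", 8, 8), ("D3", "P2", 9, 9)],
            de_fraction=0.2, effect_size=2.5, seed=3)

    def test_single_dataset_group_matches_normalized_restriction(self):
        cat, datasets = self._datasets()
        genes = set(list(datasets[0].truth_deg)[:5])
        tables = assemble_features(datasets, genes, {"B": ["D3"]},
                                   normalize=None)
        (tb,) = tables
        markers = sorted(m for m, g in datasets[2].marker_to_gene.items()
                         if g in genes)
        assert list(tb.X.columns) == markers
        assert tb.X.shape[0] == 18
        assert np.allclose(tb.X.to_numpy(),
                           datasets[2].matrix.loc[markers].T.to_numpy())

    def test_two_dataset_group_concatenates_samples_intersects_markers(self):
        cat, datasets = self._datasets()
        genes = set(datasets[0].truth_deg)
        tables = assemble_features(datasets, genes, {"A": ["D1", "D2"]})
        (ta,) = tables
        assert ta.X.shape[0] == 20 + 16
        m1 = {m for m in datasets[0].matrix.index
              if datasets[0].marker_to_gene[m] in genes}
        m2 = {m for m in datasets[1].matrix.index
              if datasets[1].marker_to_gene[m] in genes}
        assert set(ta.X.columns) == m1 & m2

    def test_marker_absent_from_one_member_dropped(self):
        cat, datasets = self._datasets()
        genes = set(datasets[0].truth_deg)
        victim = next(m for m in datasets[1].matrix.index
                      if datasets[1].marker_to_gene[m] in genes)
        datasets[1].matrix = datasets[1].matrix.drop(index=victim)
        tables = assemble_features(datasets, genes, {"A": ["D1", "D2"]})
        assert victim not in tables[0].X.columns

    def test_tmm_normalization_applied(self):
        cat = simulate.generate_catalog(60, 4, seed=5)
        datasets = simulate.generate_expression(
            cat, [("D1", "P1", 8, 8)], de_fraction=0.2, scale="counts", seed=6)
        genes = set(datasets[0].truth_deg)
        raw = assemble_features(datasets, genes, {"B": ["D1"]}, normalize=None)
        tmm = assemble_features(datasets, genes, {"B": ["D1"]}, normalize="tmm")
        assert not np.allclose(raw[0].X.to_numpy(), tmm[0].X.to_numpy())


class TestSplit7030:
    def test_balanced_ten_gives_seven_three(self):
        table = _planted_table(n=10, n_noise=3)
        train, test = split_70_30(table, seed=1)
        assert len(train.y) == 7 and len(test.y) == 3
        assert set(train.y) == set(test.y) == {"case", "control"}

    def test_deterministic_given_seed(self):
        table = _planted_table(n=20, n_noise=5)
        a1 = split_70_30(table, seed=5)
        a2 = split_70_30(table, seed=5)
        assert list(a1[0].X.index) == list(a2[0].X.index)

    def test_disjoint_and_exhaustive(self):
        table = _planted_table(n=34, n_noise=5)
        train, test = split_70_30(table, seed=9)
        assert set(train.X.index) | set(test.X.index) == set(table.X.index)
        assert set(train.X.index) & set(test.X.index) == set()

    @pytest.mark.parametrize("seed", range(25))
    def test_class_proportions_within_one_sample(self, seed):
        rng = np.random.default_rng(seed)
        n_case, n_ctrl = int(rng.integers(4, 30)), int(rng.integers(4, 30))
        y = pd.Series(["case"] * n_case + ["control"] * n_ctrl,
                      index=[f"S{i}" for i in range(n_case + n_ctrl)])
        X = pd.DataFrame(rng.normal(size=(len(y), 3)), index=y.index,
                         columns=["a", "b", "c"])
        table = FeatureTable("g", X, y, {c: c for c in X.columns})
        train, _ = split_70_30(table, seed=seed)
        assert len(train.y) == int(np.ceil(0.7 * len(y)))
        for cls, n_cls in (("case", n_case), ("control", n_ctrl)):
            got = (train.y == cls).sum()
            assert abs(got - 0.7 * n_cls) <= 1.0

    def test_singleton_class_rejected(self):
        y = pd.Series(["case", "control", "control"], index=["a", "b", "c"])
        X = pd.DataFrame(np.zeros((3, 2)), index=y.index, columns=["m1", "m2"])
        with pytest.raises(ValueError, match="stratify"):
            split_70_30(FeatureTable("g", X, y, {"m1": "", "m2": ""}), seed=0)


class TestTrainAndScore:
    @pytest.mark.parametrize("algorithm", ["decision_tree", "random_forest",
                                           "extra_trees"])
    def test_separable_marker_perfect_accuracy_and_rank_one(self, algorithm):
        table = _planted_table(sep=4.0, seed=3)
        train, test = split_70_30(table, seed=3)
        rep = train_and_score(train, test, algorithm, n_trees=100, seed=3)
        assert rep.accuracy == 1.0
        assert rep.importances[0][0] == "MSIG"
        assert rep.importances[0][2] == "GENE_MSIG"

    def test_importances_sum_to_100_nonnegative(self):
        table = _planted_table(seed=4)
        train, test = split_70_30(table, seed=4)
        rep = train_and_score(train, test, "random_forest", n_trees=100, seed=4)
        vals = [v for _, v, _ in rep.importances]
        assert all(v >= 0 for v in vals)
        assert sum(vals) == pytest.approx(100.0)
        assert vals == sorted(vals, reverse=True)

    def test_permuted_labels_wilson_ci_covers_half(self):
        """With labels shuffled, accuracy is chance and the 95% Wilson CI
        covers 0.5 in most runs."""
        covered = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table = _planted_table(n=60, n_noise=20, sep=3.0, seed=seed)
            y_perm = pd.Series(rng.permutation(table.y.to_numpy()),
                               index=table.y.index)
            shuffled = FeatureTable(table.group_id, table.X, y_perm,
                                    dict(table.marker_to_gene))
            train, test = split_70_30(shuffled, seed=seed)
            rep = train_and_score(train, test, "random_forest",
                                  n_trees=100, seed=seed)
            covered += rep.ci_low <= 0.5 <= rep.ci_high
        assert covered >= 0.9 * n_seeds - 1

    def test_ci_contains_point_and_shrinks_with_test_size(self):
        small = _planted_table(n=20, n_noise=10, seed=1)
        large = _planted_table(n=200, n_noise=10, seed=1)
        reps = []
        for table in (small, large):
            train, test = split_70_30(table, seed=1)
            reps.append(train_and_score(train, test, "decision_tree", seed=1))
        for rep in reps:
            assert rep.ci_low <= rep.accuracy <= rep.ci_high
        assert (reps[1].ci_high - reps[1].ci_low) < (reps[0].ci_high - reps[0].ci_low)

    def test_unknown_algorithm_and_empty_test_rejected(self):
        table = _planted_table(n=20, n_noise=4)
        train, test = split_70_30(table, seed=0)
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_and_score(train, test, "svm")
        empty = FeatureTable.__new__(FeatureTable)
        empty.group_id, empty.X = "g", test.X.iloc[:0]
        empty.y, empty.marker_to_gene = test.y.iloc[:0], {}
        with pytest.raises(ValueError, match="empty test"):
            train_and_score(train, empty, "decision_tree")


class _ConstantModel:
    def predict(self, X):
        return np.full(len(X), 0.7)


class _LinearModel:
    def __init__(self, coef):
        self.coef = np.asarray(coef)

    def predict(self, X):
        return X @ self.coef


class TestLocalExplanations:
    def test_constant_model_all_weights_near_zero(self):
        table = _planted_table(n=40, n_noise=10, seed=2)
        weights = local_explanations(_ConstantModel(), table.X.iloc[0].to_numpy(),
                                     table, n_perturbations=5000, seed=0,
                                     n_features_out=11)
        assert all(abs(w) < 0.01 for _, w in weights)

    def test_linear_black_box_recovered(self):
        """Surrogate weights correlate > 0.95 with the true coefficients of
        a linear model (up to the per-feature standardization)."""
        rng = np.random.default_rng(7)
        n, d = 50, 8
        y = pd.Series(["case"] * 25 + ["control"] * 25,
                      index=[f"S{i}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, d)), index=y.index,
                         columns=[f"M{i}" for i in range(d)])
        table = FeatureTable("g", X, y, {c: c for c in X.columns})
        coef = rng.normal(size=d)
        got = dict(local_explanations(_LinearModel(coef), X.iloc[3].to_numpy(),
                                      table, n_perturbations=4000, seed=1,
                                      n_features_out=d))
        sds = X.std(axis=0, ddof=1).to_numpy()
        true_std = coef * sds  # surrogate acts on standardized coordinates
        fitted = np.array([got[f"M{i}"] for i in range(d)])
        r = np.corrcoef(fitted, true_std)[0, 1]
        assert r > 0.95

    def test_deterministic_given_seed(self):
        table = _planted_table(n=30, n_noise=6, seed=5)
        model = _LinearModel(np.ones(7))
        a = local_explanations(model, table.X.iloc[1].to_numpy(), table, 500, seed=3)
        b = local_explanations(model, table.X.iloc[1].to_numpy(), table, 500, seed=3)
        assert a == b

    def test_location_shift_of_background_feature_invariant(self):
        table = _planted_table(n=30, n_noise=6, seed=8)
        model = _LinearModel(np.arange(7, dtype=float))
        inst = table.X.iloc[2].to_numpy()
        base = local_explanations(model, inst, table, 1000, seed=2)
        shifted_X = table.X.copy()
        shifted_X["M001"] = shifted_X["M001"] + 100.0
        shifted = FeatureTable(table.group_id, shifted_X, table.y,
                               dict(table.marker_to_gene))
        after = local_explanations(model, inst, shifted, 1000, seed=2)
        assert [m for m, _ in base] == [m for m, _ in after]
        assert [w for _, w in base] == pytest.approx([w for _, w in after])

    def test_zero_variance_feature_excluded(self):
        table = _planted_table(n=30, n_noise=5, seed=9)
        X = table.X.copy()
        X["M000"] = 1.0
        flat = FeatureTable(table.group_id, X, table.y, dict(table.marker_to_gene))
        weights = local_explanations(_ConstantModel(), X.iloc[0].to_numpy(),
                                     flat, 200, seed=0, n_features_out=10)
        assert "M000" not in {m for m, _ in weights}


class TestTallyRecurrence:
    def _report(self, markers, seed=0):
        table = _planted_table(n=20, n_noise=4, seed=seed)
        train, test = split_70_30(table, seed=seed)
        rep = train_and_score(train, test, "decision_tree", seed=seed)
        return rep

    def test_single_report_full_topk_counts_one(self):
        rep = self._report([], seed=1)
        tally = tally_recurrence([rep], top_k=len(rep.importances))
        assert set(tally.marker_counts.values()) == {1}

    def test_recurrent_planted_marker_counted_per_report(self):
        reps = []
        for seed in range(4):
            table = _planted_table(sep=4.0, seed=seed)
            train, test = split_70_30(table, seed=seed)
            for algo in ("decision_tree", "random_forest"):
                reps.append(train_and_score(train, test, algo,
                                            n_trees=60, seed=seed))
        tally = tally_recurrence(reps, top_k=3)
        assert tally.marker_counts["MSIG"] == len(reps)
        assert max(tally.gene_counts, key=tally.gene_counts.get) == "GENE_MSIG"
        # gene count >= max of its markers' counts
        for g, c in tally.gene_counts.items():
            marker_max = max(c2 for m, c2 in tally.marker_counts.items()
                             if reps[0].importances and g == f"GENE_{m}")
            assert c >= marker_max

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            tally_recurrence([], top_k=5)
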