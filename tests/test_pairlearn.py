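"""Pairwise comparison matrix, ERT training, LCO-CV and win-count ranking."""

import numpy as np
import pytest

from clusterrank.features import ClusterFeatureVector
from clusterrank.pairlearn import (
    ComparisonRecord,
    ConfusionCounts,
    ErtConfig,
    build_comparison_matrix,
    classification_metrics,
    comparison_feature_names,
    leave_complex_out_cv,
    rank_clusters,
    train_ert,
)

BENCHMARK_CLUSTER_COUNTS = {  # cluster counts (> 5 members, post clash removal), 11 training targets
    "T29": 49, "T30": 24, "T32": 12, "T35": 12, "T39": 44, "T40": 57,
    "T41": 25, "T46": 35, "T47": 20, "T53": 42, "T54": 49,
}


def make_vector(cluster_id, value, min_lrmsd, n_desc=1):
    names = [
        f"{stat}_N_D{j}" for j in range(n_desc) for stat in ("MIN", "Q1", "AVG", "Q3", "MAX")
    ] + ["SIZE"]
    values = np.full(len(names), float(value))
    return ClusterFeatureVector(
        cluster_id=cluster_id, feature_names=names, values=values, min_lrmsd=min_lrmsd
    )


def synthetic_targets(n_targets, k_clusters, rng, noise=0.0):
    """Targets whose cluster feature value is (noisily) monotone in LRMSD."""
    targets = {}
    for t in range(n_targets):
        vectors = []
        lrmsds = rng.permutation(np.linspace(1.0, 30.0, k_clusters))
        for c in range(k_clusters):
            value = lrmsds[c] + rng.normal(0.0, noise)
            vectors.append(make_vector(c + 1, value, float(lrmsds[c])))
        targets[f"T{t:02d}"] = vectors
    return targets


class TestComparisonMatrix:
    def test_pair_count_and_width(self, rng):
        targets = {"T1": [make_vector(i + 1, i, float(i + 1), n_desc=109) for i in range(5)]}
        records = build_comparison_matrix(targets)
        assert len(records) == 5 * 4 // 2
        assert all(r.features.shape == (1092,) for r in records)

    def test_benchmark_cluster_counts_give_7248_records(self):
        targets = {
            t: [make_vector(i + 1, i, float(i + 1)) for i in range(k)]
            for t, k in BENCHMARK_CLUSTER_COUNTS.items()
        }
        records = build_comparison_matrix(targets)
        assert len(records) == 7248

    def test_label_rule_and_antisymmetry(self):
        lo = make_vector(1, 0.0, 3.0)
        hi = make_vector(2, 1.0, 5.0)
        rec = build_comparison_matrix({"T1": [lo, hi]})[0]
        assert rec.label == 1  # C1 slot (lower id) has lower min LRMSD
        # swap roles by renumbering: now the lower id has the higher LRMSD
        lo2 = make_vector(2, 0.0, 3.0)
        hi2 = make_vector(1, 1.0, 5.0)
        rec2 = build_comparison_matrix({"T1": [lo2, hi2]})[0]
        assert rec2.label == 0

    def test_equal_min_lrmsd_pair_excluded(self):
        targets = {"T1": [make_vector(1, 0, 4.0), make_vector(2, 1, 4.0),
                          make_vector(3, 2, 9.0)]}
        with pytest.warns(UserWarning, match="tie"):
            records = build_comparison_matrix(targets)
        assert len(records) == 2  # only the two pairs involving cluster 3

    def test_single_cluster_target_skipped(self):
        targets = {"T1": [make_vector(1, 0, 1.0)],
                   "T2": [make_vector(1, 0, 1.0), make_vector(2, 1, 2.0)]}
        with pytest.warns(UserWarning, match="<2 clusters"):
            records = build_comparison_matrix(targets)
        assert {r.target_id for r in records} == {"T2"}

    def test_no_cross_target_pairs(self, rng):
        targets = synthetic_targets(3, 4, rng)
        records = build_comparison_matrix(targets)
        assert len(records) == 3 * 6
        assert all(r.cluster_n_id != r.cluster_m_id for r in records)

    def test_comparison_feature_names_prefixing(self):
        names = comparison_feature_names(["MIN_N_CP_TB", "SIZE"])
        assert names == ["C1_MIN_N_CP_TB", "C1_SIZE", "C2_MIN_N_CP_TB", "C2_SIZE"]


class TestMetrics:
    def test_arithmetic_example(self):
        m = classification_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m == pytest.approx(
            {"recall": 0.75, "precision": 0.75, "f1": 0.75, "accuracy": 0.8}
        )

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=4, fp=0, fn=0, tn=6))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_zero_conventions(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=2))
        assert m["recall"] == 0.0 and m["f1"] == 0.0

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))


def separable_records(n, rng, n_targets=2):
    """Label equals the sign of a single feature."""
    records = []
    for i in range(n):
        x = rng.normal(size=6)
        records.append(
            ComparisonRecord(
                target_id=f"T{i % n_targets}",
                cluster_n_id=1,
                cluster_m_id=2,
                features=x,
                label=int(x[0] > 0),
            )
        )
    return records


def comparison_shaped_records(n, rng, n_targets=2):
    """Pair-shaped records: label says whether the C1 half has lower value."""
    records = []
    for i in range(n):
        v1, v2 = rng.normal(scale=4.0, size=2)
        features = np.concatenate(
            [make_vector(1, v1, None).values, make_vector(2, v2, None).values]
        )
        records.append(
            ComparisonRecord(
                target_id=f"T{i % n_targets}",
                cluster_n_id=1,
                cluster_m_id=2,
                features=features,
                label=int(v1 < v2),
            )
        )
    return records


class TestTrainErt:
    def test_oob_accuracy_on_separable_set(self, rng):
        records = separable_records(200, rng)
        model = train_ert(records, ErtConfig(n_trees=200, seed=1))
        assert model.oob_score is not None and model.oob_score > 0.95

    def test_probabilities_well_formed(self, rng):
        records = separable_records(50, rng)
        model = train_ert(records, ErtConfig(n_trees=30, seed=2))
        X = np.vstack([r.features for r in records])
        proba = model.predict_proba(X)
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(model.predict(X)) <= {0, 1}

    def test_seeded_determinism(self, rng):
        records = separable_records(60, rng)
        X = np.vstack([r.features for r in records])
        p1 = train_ert(records, ErtConfig(n_trees=50, seed=7)).predict_proba(X)
        p2 = train_ert(records, ErtConfig(n_trees=50, seed=7)).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_error(self, rng):
        records = separable_records(40, rng)
        ones = [r for r in records if r.label == 1]
        with pytest.raises(ValueError, match="single class"):
            train_ert(ones, ErtConfig(n_trees=10, seed=0))

    def test_max_features_is_floor_sqrt(self):
        assert ErtConfig.resolved_max_features(1092) == 33
        assert ErtConfig.resolved_max_features(4) == 2
        assert ErtConfig.resolved_max_features(1) == 1

    def test_save_load_roundtrip(self, rng, tmp_path):
        from clusterrank.pairlearn import RankerModel

        records = separable_records(50, rng)
        model = train_ert(records, ErtConfig(n_trees=20, seed=3))
        model.save(tmp_path / "model.joblib")
        loaded = RankerModel.load(tmp_path / "model.joblib")
        X = np.vstack([r.features for r in records])
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
        assert loaded.config == model.config


class TestLeaveComplexOutCv:
    def test_one_fold_per_target(self, rng):
        targets = synthetic_targets(11, 4, rng)
        records = build_comparison_matrix(targets)
        cv = leave_complex_out_cv(records, ErtConfig(n_trees=20, seed=0))
        assert len(cv.per_fold) == 11
        assert sorted(cv.per_fold["target_id"]) == sorted(targets)

    def test_train_and_test_targets_disjoint(self, rng):
        targets = synthetic_targets(3, 4, rng)
        records = build_comparison_matrix(targets)
        cv = leave_complex_out_cv(records, ErtConfig(n_trees=10, seed=0))
        per_target = {t: sum(r.target_id == t for r in records) for t in targets}
        for _, row in cv.per_fold.iterrows():
            assert row["n_test"] == per_target[row["target_id"]]

    def test_cv_accuracy_tracks_oob_on_identical_generative_process(self, rng):
        """Two exchangeable targets: held-out accuracy ~ OOB estimate."""
        gaps = []
        for seed in range(5):
            local = np.random.default_rng(seed)
            records = separable_records(160, local, n_targets=2)
            cfg = ErtConfig(n_trees=150, seed=seed)
            cv = leave_complex_out_cv(records, cfg)
            oob = train_ert(records, cfg).oob_score
            gaps.append(cv.mean["accuracy"] - oob)
        assert abs(np.mean(gaps)) < 0.1

    def test_single_target_error(self, rng):
        records = separable_records(20, rng, n_targets=1)
        with pytest.raises(ValueError, match="two targets"):
            leave_complex_out_cv(records, ErtConfig(n_trees=5, seed=0))


class TestRankClusters:
    @pytest.fixture
    def oracle_model(self, rng):
        """A classifier trained to near-perfection on the value comparison."""
        records = comparison_shaped_records(400, rng)
        return train_ert(records, ErtConfig(n_trees=200, seed=5))

    def _cluster(self, cid, value):
        return make_vector(cid, value, None)

    def test_transitive_oracle_gives_clean_tournament(self, oracle_model):
        clusters = [self._cluster(i + 1, v) for i, v in enumerate([5.0, -5.0, 1.0, 9.0])]
        result = rank_clusters(oracle_model, clusters)
        by_id = result.table.set_index("cluster_id")
        assert by_id.loc[2, "wins"] == 3 and by_id.loc[2, "rank"] == 1
        assert list(result.ranked_cluster_ids) == [2, 3, 1, 4]  # ascending value
        assert by_id["wins"].sum() == 4 * 3 // 2

    def test_two_clusters(self, oracle_model):
        result = rank_clusters(
            oracle_model, [self._cluster(1, 4.0), self._cluster(2, -4.0)]
        )
        assert result.rank_of(2) == 1 and result.rank_of(1) == 2

    def test_matches_bruteforce_tournament_oracle(self, oracle_model, rng):
        clusters = [self._cluster(i + 1, rng.normal(scale=4.0)) for i in range(6)]
        result = rank_clusters(oracle_model, clusters)
        # independent loop over all pairs using plain predict
        wins = {c.cluster_id: 0 for c in clusters}
        ordered = sorted(clusters, key=lambda c: c.cluster_id)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                x = np.concatenate([ordered[a].values, ordered[b].values])
                label = oracle_model.predict(x.reshape(1, -1))[0]
                winner = ordered[a] if label == 1 else ordered[b]
                wins[winner.cluster_id] += 1
        for c in clusters:
            assert int(result.table.set_index("cluster_id").loc[c.cluster_id, "wins"]) == wins[c.cluster_id]
        assert sum(wins.values()) == 6 * 5 // 2

    def test_ranks_are_a_permutation(self, oracle_model, rng):
        clusters = [self._cluster(i + 1, rng.normal()) for i in range(5)]
        result = rank_clusters(oracle_model, clusters)
        assert sorted(result.table["rank"]) == [1, 2, 3, 4, 5]

    def test_dimension_mismatch_error(self, oracle_model):
        bad = make_vector(1, 0.0, None, n_desc=3)
        with pytest.raises(ValueError, match="dimension mismatch"):
            rank_clusters(oracle_model, [bad, make_vector(2, 1.0, None, n_desc=3)])
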