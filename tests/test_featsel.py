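"""Descriptor screening, collinearity, RFE and transform sweeps."""

import itertools

import numpy as np
import pytest

from clusterrank.descriptors import DescriptorMeta, DescriptorTable
from clusterrank.featsel import (
    dimension_grid,
    feature_importance_report,
    mannwhitney_screen,
    ppmcc_analysis,
    recursive_feature_elimination,
    transform_sweep,
)
from clusterrank.pairlearn import ComparisonRecord, ErtConfig, train_ert


def screening_setup(cor_values, inc_values):
    """One target whose clusters are singleton wrappers around given values."""
    all_vals = np.concatenate([cor_values, inc_values]).astype(float)
    table = DescriptorTable(
        target_id="T1",
        model_ids=[f"m{i}" for i in range(len(all_vals))],
        descriptor_names=["N_X"],
        values=all_vals.reshape(-1, 1),
        standardized=True,
    )
    members = [([f"m{i}"], True) for i in range(len(cor_values))] + [
        ([f"m{i + len(cor_values)}"], False) for i in range(len(inc_values))
    ]
    return {"T1": table}, {"T1": members}


class TestMannWhitneyScreen:
    def test_identical_distributions_not_significant(self):
        vals = np.arange(10, dtype=float)
        tables, members = screening_setup(vals, vals + 0.0001)
        (res,) = mannwhitney_screen(tables, members)
        assert res.significance_tier == "ns"
        assert res.p_value > 0.5

    def test_fully_separated_groups_top_tier(self):
        tables, members = screening_setup(
            np.linspace(0, 1, 20), np.linspace(10, 11, 20)
        )
        (res,) = mannwhitney_screen(tables, members)
        assert res.significance_tier == "***"
        assert res.p_value < 1e-4

    def test_u_statistic_and_pvalue_match_exhaustive_enumeration(self):
        """Small-sample U and its p-value against brute-force enumeration."""
        x = np.array([0.3, 1.9, 2.2, 4.5])
        y = np.array([1.1, 2.8, 3.3, 0.9])
        tables, members = screening_setup(x, y)
        (res,) = mannwhitney_screen(tables, members)

        def u_of(a, b):
            return sum(
                1.0 if ai > bi else (0.5 if ai == bi else 0.0)
                for ai in a
                for bi in b
            )

        u_obs = u_of(x, y)
        assert res.u_statistic == pytest.approx(u_obs)
        # exact two-sided p: enumerate all C(8,4) group assignments
        pooled = np.concatenate([x, y])
        n1 = len(x)
        stats_null = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(combo)] = True
            stats_null.append(u_of(pooled[mask], pooled[~mask]))
        stats_null = np.array(stats_null)
        mu = n1 * (len(pooled) - n1) / 2.0
        p_exact = np.mean(np.abs(stats_null - mu) >= abs(u_obs - mu) - 1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_empty_group_error(self):
        tables, members = screening_setup(np.arange(4.0), np.arange(4.0))
        members["T1"] = [(m, True) for m, _ in members["T1"]]
        with pytest.raises(ValueError, match="non-empty"):
            mannwhitney_screen(tables, members)


class TestPpmcc:
    def _table(self, columns):
        values = np.column_stack(columns).astype(float)
        return DescriptorTable(
            target_id="T1",
            model_ids=[f"m{i}" for i in range(values.shape[0])],
            descriptor_names=[f"N_D{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        summary = ppmcc_analysis(self._table([x, 2 * x, -x]))
        assert summary.matrix[0, 1] == pytest.approx(1.0)
        assert summary.matrix[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(summary.matrix), 1.0)
        np.testing.assert_allclose(summary.matrix, summary.matrix.T)

    def test_planted_block_partner_counts(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d3 = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to x
        d4 = np.array([1.0, -3.0, 3.0, -1.0])  # orthogonal to x and d3
        summary = ppmcc_analysis(self._table([x, 2 * x, -x, d3, d4]))
        assert summary.partner_counts == {
            "N_D0": 2, "N_D1": 2, "N_D2": 2, "N_D3": 0, "N_D4": 0
        }

    def test_zero_variance_descriptor_flagged_as_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        const = np.full(4, 7.0)
        summary = ppmcc_analysis(self._table([x, const]))
        assert summary.degenerate == ["N_D1"]
        assert summary.matrix[0, 1] == 0.0


def labelled_records(rng, n_targets=3, per_target=40, n_noise=8, n_constant=0,
                     n_informative=1, noise_sd=0.05):
    """Records whose label follows the sum of informative feature differences."""
    records = []
    n_feat = n_informative + n_noise + n_constant
    names = (
        [f"INF{i}" for i in range(n_informative)]
        + [f"NOI{i}" for i in range(n_noise)]
        + [f"CON{i}" for i in range(n_constant)]
    )
    for t in range(n_targets):
        for i in range(per_target):
            s1, s2 = rng.normal(scale=2.0, size=2)
            x = np.empty(n_feat)
            x[:n_informative] = s1 + rng.normal(0, noise_sd, n_informative)
            x[n_informative : n_informative + n_noise] = rng.normal(size=n_noise)
            x[n_informative + n_noise :] = 1.0
            # fold the "C2 half" into the same vector: append mirrored block
            y = np.empty(n_feat)
            y[:n_informative] = s2 + rng.normal(0, noise_sd, n_informative)
            y[n_informative : n_informative + n_noise] = rng.normal(size=n_noise)
            y[n_informative + n_noise :] = 1.0
            records.append(
                ComparisonRecord(
                    target_id=f"T{t}",
                    cluster_n_id=1,
                    cluster_m_id=2,
                    features=np.concatenate([x, y]),
                    label=int(s1 < s2),
                )
            )
    feature_names = [f"C1_{n}" for n in names] + [f"C2_{n}" for n in names]
    return records, feature_names


class TestRfe:
    def test_constant_features_dropped_first(self, rng):
        records, names = labelled_records(
            rng, n_noise=9, n_constant=5, per_target=30
        )  # 30 features total, 10 of them constant across the two slots
        cfg = ErtConfig(n_trees=60, seed=0)
        path = recursive_feature_elimination(records, cfg, names, step=10)
        survivors_round2 = set(path.rounds[1]["features"])
        assert not any("CON" in f for f in survivors_round2)

    def test_informative_features_survive_to_small_sizes(self):
        """5 informative + 95 noise: the signal survives elimination to size 20."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            records, names = labelled_records(
                rng, n_targets=3, per_target=40, n_informative=5, n_noise=45
            )  # 100 features total over both slots, 10 informative
            cfg = ErtConfig(n_trees=60, seed=seed)
            path = recursive_feature_elimination(records, cfg, names, step=10)
            at_20 = next(r for r in path.rounds if r["size"] == 20)
            informative = {f for f in names if "INF" in f}
            assert informative <= set(at_20["features"]), f"seed {seed}"

    def test_sizes_decrease_by_step_and_sets_are_nested(self, rng):
        records, names = labelled_records(rng, n_noise=14, per_target=25)  # 30 features
        cfg = ErtConfig(n_trees=30, seed=1)
        path = recursive_feature_elimination(records, cfg, names, step=5)
        sizes = [r["size"] for r in path.rounds]
        assert sizes == list(range(30, 9, -5))
        for prev, cur in zip(path.rounds, path.rounds[1:]):
            assert set(cur["features"]) < set(prev["features"])

    def test_selected_size_maximises_f1(self, rng):
        records, names = labelled_records(rng, n_noise=9, per_target=25)
        cfg = ErtConfig(n_trees=30, seed=2)
        path = recursive_feature_elimination(records, cfg, names, step=5)
        best_f1 = max(r["f1"] for r in path.rounds)
        assert any(
            r["size"] == path.selected_size and r["f1"] == best_f1
            for r in path.rounds
        )


class TestTransformSweep:
    def test_grid_from_1092_ends_at_2(self):
        grid = dimension_grid(1092, step=10)
        assert grid[0] == 1092 and grid[-1] == 2
        assert all(a - b == 10 for a, b in zip(grid, grid[1:]))

    def test_bottom_up_anchor(self):
        grid = dimension_grid(25, step=10, anchor="bottom_up")
        assert grid == [22, 12, 2]

    def test_full_rank_pca_matches_untransformed_baseline(self):
        """A full-rank rotation should not destroy information for the ERT."""
        from clusterrank.pairlearn import leave_complex_out_cv

        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            records, names = labelled_records(rng, n_noise=5, per_target=30)
            cfg = ErtConfig(n_trees=60, seed=seed)
            baseline = leave_complex_out_cv(records, cfg, names).mean["accuracy"]
            sweep = transform_sweep(records, "PCA", cfg, step=10)
            full_rank = sweep.per_dimension.iloc[0]
            assert full_rank["dimension"] == 12
            deltas.append(full_rank["accuracy"] - baseline)
        assert abs(np.mean(deltas)) < 0.08

    def test_transformers_fit_on_training_folds_only(self, rng):
        """Leakage audit: no held-out record ever reaches a transformer fit."""
        records, names = labelled_records(rng, n_noise=5, per_target=20)
        # tag each record's first feature with a target marker
        for r in records:
            r.features[0] = {"T0": 100.0, "T1": 200.0, "T2": 300.0}[r.target_id]
        fit_calls = []

        class SpyPCA:
            def __init__(self, dim, seed):
                from sklearn.decomposition import PCA

                self.inner = PCA(n_components=dim, random_state=seed)

            def fit_transform(self, X):
                fit_calls.append(set(np.round(X[:, 0]).astype(int)))
                return self.inner.fit_transform(X)

            def transform(self, X):
                return self.inner.transform(X)

        def factory(method, dim, seed):
            return SpyPCA(dim, seed)

        cfg = ErtConfig(n_trees=10, seed=0)
        transform_sweep(records, "PCA", cfg, step=10, transformer_factory=factory)
        # only the final refit on all records may see all three targets;
        # every cross-validation fit must exclude exactly one
        assert sum(len(c) == 3 for c in fit_calls) == 1
        assert fit_calls[-1] == {100, 200, 300}
        for markers in fit_calls[:-1]:
            assert len(markers) == 2

    def test_transform_is_deterministic_on_heldout_rows(self, rng):
        records, names = labelled_records(rng, n_noise=5, per_target=20)
        cfg = ErtConfig(n_trees=10, seed=0)
        sweep = transform_sweep(records, "PCA", cfg, step=10)
        X = np.vstack([r.features for r in records])
        t1 = sweep.best_transformer.transform(X[:3])
        t2 = sweep.best_transformer.transform(X[:3])
        np.testing.assert_array_equal(t1, t2)


class TestFeatureImportance:
    def test_importances_normalised_and_planted_feature_first(self):
        meta = [DescriptorMeta("N_SIG", "rc"), DescriptorMeta("N_JUNK", "ve")]
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            records = []
            for i in range(120):
                x = rng.normal(size=4)  # C1_MIN_N_SIG, C1_MIN_N_JUNK, C2_...
                records.append(
                    ComparisonRecord(
                        target_id=f"T{i % 2}",
                        cluster_n_id=1,
                        cluster_m_id=2,
                        features=x,
                        label=int(x[0] > 0),
                    )
                )
            names = ["C1_MIN_N_SIG", "C1_MIN_N_JUNK", "C2_MIN_N_SIG", "C2_MIN_N_JUNK"]
            model = train_ert(records, ErtConfig(n_trees=80, seed=seed), names)
            table, curves = feature_importance_report(model, meta)
            assert table["importance"].sum() == pytest.approx(1.0, abs=1e-8)
            assert table.iloc[0]["feature"] == "C1_MIN_N_SIG", f"seed {seed}"

    def test_constant_feature_has_zero_importance(self, rng):
        records = []
        for i in range(80):
            x = rng.normal(size=4)
            x[1] = 1.0  # constant: never split on
            records.append(
                ComparisonRecord(
                    target_id=f"T{i % 2}", cluster_n_id=1, cluster_m_id=2,
                    features=x, label=int(x[0] > 0),
                )
            )
        model = train_ert(records, ErtConfig(n_trees=50, seed=0))
        assert model.estimator.feature_importances_[1] == 0.0

    def test_category_curves_reach_one(self, rng):
        meta = [DescriptorMeta("N_A", "rc"), DescriptorMeta("N_B", "cs")]
        records = [
            ComparisonRecord(
                target_id=f"T{i % 2}", cluster_n_id=1, cluster_m_id=2,
                features=rng.normal(size=4), label=i % 2,
            )
            for i in range(60)
        ]
        names = ["C1_MIN_N_A", "C1_Q1_N_B", "C2_MIN_N_A", "C2_Q1_N_B"]
        model = train_ert(records, ErtConfig(n_trees=30, seed=0), names)
        _, curves = feature_importance_report(model, meta)
        assert curves.iloc[-1].drop("rank").tolist() == [1.0, 1.0]
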