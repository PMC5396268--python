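"""Pairwise cluster comparison learning and win-count ranking.

Rather than scoring clusters one at a time, the ranking task is cast as a
binary classification over cluster *pairs*: a training example concatenates
the feature vectors of clusters n and m of the same target (1092 features
when each cluster carries 546) and is labelled 1 exactly when
``min(LRMSD_n) < min(LRMSD_m)``.  An extremely randomized trees (ERT)
ensemble is trained on all unordered within-target pairs, evaluated with
leave-complex-out cross-validation (every fold holds out one target
entirely), and clusters of a new target are ranked by the number of
pairwise comparisons they are predicted to win.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from .features import ClusterFeatureVector, feature_name

__all__ = [
    "ComparisonRecord",
    "ErtConfig",
    "ConfusionCounts",
    "RankerModel",
    "RankResult",
    "CvResult",
    "build_comparison_matrix",
    "comparison_feature_names",
    "stack_records",
    "train_ert",
    "classification_metrics",
    "confusion_from_predictions",
    "leave_complex_out_cv",
    "rank_clusters",
]


@dataclass
class ComparisonRecord:
    """One pairwise cluster comparison (features of n then m)."""

    target_id: str
    cluster_n_id: int
    cluster_m_id: int
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.cluster_n_id == self.cluster_m_id:
            raise ValueError("a cluster cannot be compared with itself")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        self.features = np.asarray(self.features, dtype=float)


@dataclass
class ErtConfig:
    """Extremely-randomized-trees hyperparameters.

    Defaults: 3000 bootstrapped trees, gini splits, ``floor(sqrt(p))``
    features per split (33 at p = 1092), depth cap 100, single-sample
    leaves, out-of-bag generalisation estimate.
    """

    n_trees: int = 3000
    bootstrap: bool = True
    split_criterion: str = "gini"
    max_depth: int = 100
    min_samples_leaf: int = 1
    use_oob: bool = True
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    @staticmethod
    def resolved_max_features(n_features: int) -> int:
        return max(1, math.floor(math.sqrt(n_features)))

    def make_estimator(self) -> ExtraTreesClassifier:
        return ExtraTreesClassifier(
            n_estimators=self.n_trees,
            bootstrap=self.bootstrap,
            criterion=self.split_criterion,
            max_features="sqrt",  # floor(sqrt(n_features))
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            oob_score=self.use_oob and self.bootstrap,
            random_state=self.seed,
            n_jobs=self.n_jobs,
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def comparison_feature_names(cluster_feature_names: list[str]) -> list[str]:
    """C1_-prefixed then C2_-prefixed copies of the cluster feature names."""
    out = []
    for slot in ("C1", "C2"):
        for name in cluster_feature_names:
            if name == "SIZE":
                out.append(feature_name(slot, "SIZE"))
            else:
                stat, desc = name.split("_", 1)
                out.append(feature_name(slot, stat, desc))
    return out


def build_comparison_matrix(
    targets: dict[str, list[ClusterFeatureVector]],
) -> list[ComparisonRecord]:
    """All unordered within-target cluster pairs, canonically oriented.

    For each target, every unordered pair appears exactly once, with the
    lower cluster_id in the C1 slot; the label is 1 iff the C1 cluster's
    minimum LRMSD is strictly smaller.  Pairs with exactly equal minima are
    excluded (label undefined); targets with fewer than two clusters are
    skipped.  Cross-target pairs are never formed.
    """
    records: list[ComparisonRecord] = []
    for target_id in sorted(targets):
        vectors = targets[target_id]
        if len(vectors) < 2:
            warnings.warn(f"target {target_id!r} has <2 clusters; skipped")
            continue
        missing = [v.cluster_id for v in vectors if v.min_lrmsd is None]
        if missing:
            raise ValueError(
                f"target {target_id!r}: clusters {missing[:5]} lack min LRMSD"
            )
        ordered = sorted(vectors, key=lambda v: v.cluster_id)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                n, m = ordered[a], ordered[b]
                if n.min_lrmsd == m.min_lrmsd:
                    warnings.warn(
                        f"target {target_id!r}: clusters {n.cluster_id}/"
                        f"{m.cluster_id} tie on min LRMSD; pair excluded"
                    )
                    continue
                records.append(
                    ComparisonRecord(
                        target_id=target_id,
                        cluster_n_id=n.cluster_id,
                        cluster_m_id=m.cluster_id,
                        features=np.concatenate([n.values, m.values]),
                        label=int(n.min_lrmsd < m.min_lrmsd),
                    )
                )
    return records


def stack_records(
    records: list[ComparisonRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack records into (X, y, target_ids)."""
    if not records:
        raise ValueError("no comparison records")
    X = np.vstack([r.features for r in records])
    y = np.array([r.label for r in records], dtype=int)
    groups = np.array([r.target_id for r in records], dtype=object)
    return X, y, groups


@dataclass
class RankerModel:
    """Fitted pairwise comparison classifier plus its provenance."""

    estimator: ExtraTreesClassifier
    config: ErtConfig
    feature_names: list[str]
    oob_score: float | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)

    def save(self, path) -> None:
        joblib.dump(
            {
                "estimator": self.estimator,
                "config": asdict(self.config),
                "feature_names": self.feature_names,
                "oob_score": self.oob_score,
                "manifest": self.manifest,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "RankerModel":
        blob = joblib.load(path)
        return cls(
            estimator=blob["estimator"],
            config=ErtConfig(**blob["config"]),
            feature_names=blob["feature_names"],
            oob_score=blob["oob_score"],
            manifest=blob["manifest"],
        )


def train_ert(
    records: list[ComparisonRecord],
    config: ErtConfig,
    feature_names: list[str] | None = None,
) -> RankerModel:
    """Fit the ERT on comparison records; seeded runs are reproducible."""
    X, y, groups = stack_records(records)
    if len(records) < 2:
        raise ValueError("need at least two records to train")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    est = config.make_estimator()
    with warnings.catch_warnings():
        # small bootstraps can leave a few samples without OOB predictions
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    oob = float(est.oob_score_) if getattr(est, "oob_score", False) else None
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature name count does not match feature dimension")
    manifest = {
        "n_records": len(records),
        "target_ids": sorted(set(groups)),
        "seed": config.seed,
    }
    return RankerModel(
        estimator=est,
        config=config,
        feature_names=list(feature_names),
        oob_score=oob,
        manifest=manifest,
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Recall, precision, F1 (harmonic mean) and accuracy.

    Ratios with a zero denominator are reported as 0 by convention.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    accuracy = (c.tp + c.tn) / c.total
    return {"recall": recall, "precision": precision, "f1": f1, "accuracy": accuracy}


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


@dataclass
class CvResult:
    """Leave-complex-out cross-validation outcome."""

    per_fold: pd.DataFrame  # one row per held-out target
    mean: dict[str, float]
    sd: dict[str, float]
    fold_models: dict[str, RankerModel] = field(default_factory=dict)
    fold_predictions: dict[str, np.ndarray] = field(default_factory=dict)
    fold_importances: dict[str, np.ndarray] = field(default_factory=dict)


METRIC_NAMES = ("recall", "precision", "f1", "accuracy")


def leave_complex_out_cv(
    records: list[ComparisonRecord],
    config: ErtConfig,
    feature_names: list[str] | None = None,
    keep_models: bool = False,
) -> CvResult:
    """One fold per target: train on all other targets, test on that one.

    Returns per-fold and mean +/- sd recall/precision/F1/accuracy.  Folds
    whose held-out records are single-class get metrics where defined and
    are flagged in the per-fold table.
    """
    X, y, groups = stack_records(records)
    target_ids = sorted(set(groups))
    if len(target_ids) < 2:
        raise ValueError("leave-complex-out CV needs at least two targets")
    rows = []
    result = CvResult(per_fold=pd.DataFrame(), mean={}, sd={})
    for held_out in target_ids:
        test_mask = groups == held_out
        train_records = [r for r, t in zip(records, test_mask) if not t]
        model = train_ert(train_records, config, feature_names)
        y_pred = model.predict(X[test_mask])
        y_test = y[test_mask]
        metrics = classification_metrics(confusion_from_predictions(y_test, y_pred))
        single_class = len(np.unique(y_test)) < 2
        rows.append(
            {"target_id": held_out, **metrics, "n_test": int(test_mask.sum()),
             "single_class_test": single_class}
        )
        result.fold_predictions[held_out] = y_pred
        result.fold_importances[held_out] = model.estimator.feature_importances_
        if keep_models:
            result.fold_models[held_out] = model
    per_fold = pd.DataFrame(rows)
    result.per_fold = per_fold
    result.mean = {m: float(per_fold[m].mean()) for m in METRIC_NAMES}
    result.sd = {m: float(per_fold[m].std(ddof=1)) for m in METRIC_NAMES}
    return result


@dataclass
class RankResult:
    """Win-count ranking of one target's clusters."""

    table: pd.DataFrame  # cluster_id, wins, tie_break_key, rank

    @property
    def ranked_cluster_ids(self) -> list[int]:
        return self.table.sort_values("rank")["cluster_id"].tolist()

    def rank_of(self, cluster_id: int) -> int:
        row = self.table[self.table["cluster_id"] == cluster_id]
        if row.empty:
            raise KeyError(f"cluster {cluster_id} not ranked")
        return int(row["rank"].iloc[0])


def rank_clusters(
    model: RankerModel, clusters: list[ClusterFeatureVector]
) -> RankResult:
    """Round-robin tournament ranking by predicted pairwise wins.

    Every unordered pair is evaluated once in canonical slot order (lower
    cluster_id as C1); a predicted label of 1 is a win for the C1 cluster,
    otherwise for C2.  Clusters are ranked by descending wins; ties break
    by descending summed class-1 probability margin, then ascending
    cluster_id.
    """
    if len(clusters) < 2:
        raise ValueError("need at least two clusters to rank")
    ordered = sorted(clusters, key=lambda v: v.cluster_id)
    dim = len(ordered[0].values) * 2
    if dim != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: clusters give {dim}, "
            f"model expects {model.n_features}"
        )
    pairs = [
        (ordered[a], ordered[b])
        for a in range(len(ordered))
        for b in range(a + 1, len(ordered))
    ]
    X = np.vstack([np.concatenate([n.values, m.values]) for n, m in pairs])
    proba = model.predict_proba(X)
    class_one = list(model.estimator.classes_).index(1)
    p1 = proba[:, class_one]
    wins = {v.cluster_id: 0 for v in ordered}
    margin = {v.cluster_id: 0.0 for v in ordered}
    for (n, m), p in zip(pairs, p1):
        if p > 0.5:
            wins[n.cluster_id] += 1
        else:
            wins[m.cluster_id] += 1
        # symmetric margin: positive evidence for the predicted winner
        margin[n.cluster_id] += 2 * p - 1
        margin[m.cluster_id] -= 2 * p - 1
    table = pd.DataFrame(
        {
            "cluster_id": [v.cluster_id for v in ordered],
            "wins": [wins[v.cluster_id] for v in ordered],
            "tie_break_key": [margin[v.cluster_id] for v in ordered],
        }
    )
    table = table.sort_values(
        by=["wins", "tie_break_key", "cluster_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.sort_values("cluster_id").reset_index(drop=True)
    return RankResult(table=table)
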