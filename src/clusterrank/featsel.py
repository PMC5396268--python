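"""Descriptor screening, collinearity, recursive feature elimination and
dimensionality-reduction sweeps.

* **Screening** — per descriptor, a two-sided Mann-Whitney U test compares
  near-native clusters (containing at least one acceptable-or-better model)
  against incorrect clusters, with significance tiers *** / ** / * at
  p < 1e-4 / 1e-3 / 1e-2.
* **Collinearity** — Pearson correlations between all descriptor pairs;
  |r| > 0.6 counts as a strong correlation partner.
* **RFE** — repeatedly run leave-complex-out CV, average the per-fold ERT
  feature importances, and drop the ten least important features per round.
* **Transform sweep** — factor analysis / PCA / RBF-kernel PCA fitted on
  the training folds only, over a dimension grid descending in steps of ten.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, FactorAnalysis, KernelPCA

from .descriptors import DescriptorMeta, DescriptorTable
from .pairlearn import (
    METRIC_NAMES,
    ComparisonRecord,
    ErtConfig,
    RankerModel,
    classification_metrics,
    confusion_from_predictions,
    leave_complex_out_cv,
    stack_records,
    train_ert,
)

__all__ = [
    "ScreenResult",
    "CorrelationSummary",
    "RfePath",
    "SweepResult",
    "mannwhitney_screen",
    "ppmcc_analysis",
    "recursive_feature_elimination",
    "transform_sweep",
    "feature_importance_report",
]

SIGNIFICANCE_TIERS = (("***", 1e-4), ("**", 1e-3), ("*", 1e-2))
STRONG_CORRELATION = 0.6


@dataclass(frozen=True)
class ScreenResult:
    descriptor: str
    u_statistic: float
    p_value: float
    significance_tier: str


def _tier(p: float) -> str:
    for symbol, threshold in SIGNIFICANCE_TIERS:
        if p < threshold:
            return symbol
    return "ns"


def mannwhitney_screen(
    tables: dict[str, DescriptorTable],
    cluster_members: dict[str, list[tuple[list[str], bool]]],
    unit: str = "cluster",
) -> list[ScreenResult]:
    """Mann-Whitney U screen of descriptors: near-native vs incorrect.

    ``cluster_members`` maps each target to ``(member_model_ids,
    is_near_native)`` entries.  With ``unit="cluster"`` each cluster
    contributes its member median per descriptor (the screening
    observation); ``unit="model"`` pools raw member values instead.  Tables
    must be standardised.  Tests are two-sided; the exact null distribution
    is used for small tie-free groups, the tie-corrected normal
    approximation otherwise.
    """
    names = None
    groups: dict[bool, list[np.ndarray]] = {True: [], False: []}
    for target_id, entries in cluster_members.items():
        table = tables[target_id]
        if not table.standardized:
            raise ValueError(f"table for {target_id!r} is not standardized")
        if names is None:
            names = table.descriptor_names
        elif table.descriptor_names != names:
            raise ValueError("descriptor names differ across targets")
        for member_ids, is_near_native in entries:
            rows = table.rows(member_ids)
            if unit == "cluster":
                groups[is_near_native].append(np.median(rows, axis=0))
            elif unit == "model":
                groups[is_near_native].extend(rows)
            else:
                raise ValueError(f"unknown screening unit {unit!r}")
    if not groups[True] or not groups[False]:
        raise ValueError("both near-native and incorrect groups must be non-empty")
    cor = np.vstack(groups[True])
    inc = np.vstack(groups[False])
    results = []
    for j, name in enumerate(names):
        x, y = cor[:, j], inc[:, j]
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        results.append(
            ScreenResult(
                descriptor=name,
                u_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                significance_tier=_tier(float(res.pvalue)),
            )
        )
    return results


@dataclass
class CorrelationSummary:
    descriptor_names: list[str]
    matrix: np.ndarray  # D x D Pearson correlations
    partner_counts: dict[str, int]  # partners with |r| > 0.6
    degenerate: list[str] = field(default_factory=list)  # zero-variance


def ppmcc_analysis(tables: dict[str, DescriptorTable] | DescriptorTable) -> CorrelationSummary:
    """Pairwise Pearson correlations of descriptors over pooled models.

    Zero-variance descriptors have undefined correlations; they are
    reported as 0 and flagged.
    """
    if isinstance(tables, DescriptorTable):
        tables = {tables.target_id: tables}
    names = None
    blocks = []
    for table in tables.values():
        if names is None:
            names = table.descriptor_names
        elif table.descriptor_names != names:
            raise ValueError("descriptor names differ across targets")
        blocks.append(table.values)
    values = np.vstack(blocks)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 observations per descriptor")
    sd = values.std(axis=0)
    degenerate = [n for n, s in zip(names, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.corrcoef(values, rowvar=False)
    matrix = np.where(np.isfinite(matrix), matrix, 0.0)
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip((matrix + matrix.T) / 2.0, -1.0, 1.0)
    strong = (np.abs(matrix) > STRONG_CORRELATION) & ~np.eye(len(names), dtype=bool)
    counts = {n: int(strong[i].sum()) for i, n in enumerate(names)}
    return CorrelationSummary(
        descriptor_names=list(names),
        matrix=matrix,
        partner_counts=counts,
        degenerate=degenerate,
    )


@dataclass
class RfePath:
    """Metrics and retained features at every elimination round."""

    rounds: list[dict]  # {"size", "features", metric means}
    selected_size: int
    selected_features: list[str]

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: r[k] for k in ("size", *METRIC_NAMES)} for r in self.rounds]
        )


def _subset_records(
    records: list[ComparisonRecord], keep_idx: np.ndarray
) -> list[ComparisonRecord]:
    return [dc_replace(r, features=r.features[keep_idx]) for r in records]


def recursive_feature_elimination(
    records: list[ComparisonRecord],
    config: ErtConfig,
    feature_names: list[str],
    step: int = 10,
) -> RfePath:
    """Drop the ``step`` least important features per round, CV-averaged.

    Each round runs leave-complex-out CV on the current feature set,
    averages the per-fold ERT importances, records the mean metrics, and
    removes the ``step`` lowest-importance features.  Elimination stops
    once the set would shrink to ``2*step`` or fewer.  The selected size
    maximises mean F1 (ties prefer the smaller set).
    """
    if len(feature_names) != records[0].features.shape[0]:
        raise ValueError("feature_names length does not match records")
    if len(feature_names) <= step:
        raise ValueError("feature count must exceed the elimination step")
    current = np.arange(len(feature_names))
    rounds: list[dict] = []
    while True:
        sub = _subset_records(records, current)
        cv = leave_complex_out_cv(sub, config, [feature_names[i] for i in current])
        importances = np.mean(list(cv.fold_importances.values()), axis=0)
        rounds.append(
            {
                "size": len(current),
                "features": [feature_names[i] for i in current],
                **cv.mean,
            }
        )
        if len(current) <= 2 * step:
            break
        # stable tie-break: among equal importances drop the later index
        order = np.argsort(importances, kind="stable")
        drop_local = set(order[:step].tolist())
        current = np.array(
            [idx for k, idx in enumerate(current) if k not in drop_local]
        )
    best = min(rounds, key=lambda r: (-r["f1"], r["size"]))
    return RfePath(
        rounds=rounds,
        selected_size=best["size"],
        selected_features=best["features"],
    )


def _default_transformer_factory(method: str, dim: int, seed: int):
    if method == "PCA":
        return PCA(n_components=dim, random_state=seed)
    if method == "FA":
        return FactorAnalysis(n_components=dim, max_iter=500, random_state=seed)
    if method == "KPCA_rbf":
        # gamma defaults to 1/n_features inside scikit-learn
        return KernelPCA(n_components=dim, kernel="rbf", random_state=seed)
    raise ValueError(f"unknown transform method {method!r}")


def dimension_grid(n_features: int, step: int = 10, anchor: str = "top_down") -> list[int]:
    """Dimension ladder for the transform sweep.

    ``top_down`` (default) descends from the full feature count in steps of
    ``step`` while at least 2; ``bottom_up`` ascends 2, 2+step, ... and is
    returned in descending order for comparability.
    """
    if anchor == "top_down":
        grid = list(range(n_features, 1, -step))
    elif anchor == "bottom_up":
        grid = sorted(range(2, n_features + 1, step), reverse=True)
    else:
        raise ValueError(f"unknown grid anchor {anchor!r}")
    if not grid:
        raise ValueError("empty dimension grid")
    return grid


@dataclass
class SweepResult:
    method: str
    per_dimension: pd.DataFrame  # dimension + mean metrics
    best_dimension: int
    best_transformer: object
    best_model: RankerModel


def transform_sweep(
    records: list[ComparisonRecord],
    method: str,
    config: ErtConfig,
    step: int = 10,
    anchor: str = "top_down",
    transformer_factory=None,
) -> SweepResult:
    """Evaluate a dimensionality-reduction method over a descending grid.

    For every dimension, each leave-complex-out fold fits the transformer
    on the training records only, transforms both splits, and trains and
    evaluates the ERT on the transformed features; mean metrics per
    dimension are reported.  The returned best model (highest mean F1)
    is refit on all records at the winning dimension.  Dimensions
    exceeding what a fold can support are skipped.
    """
    factory = transformer_factory or _default_transformer_factory
    X, y, groups = stack_records(records)
    target_ids = sorted(set(groups))
    if len(target_ids) < 2:
        raise ValueError("transform sweep needs >=2 targets for LCO folds")
    max_train = min(int((groups != t).sum()) for t in target_ids)
    rows = []
    for dim in dimension_grid(X.shape[1], step=step, anchor=anchor):
        if dim > X.shape[1] or dim > max_train:
            warnings.warn(f"dimension {dim} unsupported by fold sizes; skipped")
            continue
        fold_metrics = []
        for held_out in target_ids:
            test_mask = groups == held_out
            transformer = factory(method, dim, config.seed)
            Xtr = transformer.fit_transform(X[~test_mask])
            Xte = transformer.transform(X[test_mask])
            est = config.make_estimator()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                est.fit(Xtr, y[~test_mask])
            y_pred = est.predict(Xte)
            fold_metrics.append(
                classification_metrics(
                    confusion_from_predictions(y[test_mask], y_pred)
                )
            )
        rows.append(
            {
                "dimension": dim,
                **{
                    m: float(np.mean([fm[m] for fm in fold_metrics]))
                    for m in METRIC_NAMES
                },
            }
        )
    if not rows:
        raise ValueError("no feasible dimensions on the grid")
    per_dimension = pd.DataFrame(rows)
    best_row = per_dimension.sort_values(
        by=["f1", "dimension"], ascending=[False, True]
    ).iloc[0]
    best_dim = int(best_row["dimension"])
    transformer = factory(method, best_dim, config.seed)
    X_best = transformer.fit_transform(X)
    best_records = [
        dc_replace(r, features=X_best[i]) for i, r in enumerate(records)
    ]
    model = train_ert(
        best_records, config, [f"{method}_{k}" for k in range(best_dim)]
    )
    return SweepResult(
        method=method,
        per_dimension=per_dimension,
        best_dimension=best_dim,
        best_transformer=transformer,
        best_model=model,
    )


def _descriptor_of_feature(feature: str) -> str:
    """Strip slot and stat prefixes: C1_Q1_N_CP_TB -> N_CP_TB."""
    parts = feature.split("_")
    if parts[0] in ("C1", "C2"):
        parts = parts[1:]
    if parts and parts[0] in ("MIN", "Q1", "AVG", "Q3", "MAX"):
        parts = parts[1:]
    return "_".join(parts)


def feature_importance_report(
    model: RankerModel, metadata: list[DescriptorMeta]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked feature importances and per-category cumulative usage curves.

    Importances are normalised to sum to one.  The curves give, for each
    descriptor category and rank r, the fraction of that category's
    features appearing among the top r (SIZE features fall in category
    ``size``).
    """
    importances = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    category_of = {m.name: m.category for m in metadata}
    feats = model.feature_names
    cats = [
        "size" if f.endswith("SIZE") else category_of.get(_descriptor_of_feature(f), "mi")
        for f in feats
    ]
    table = pd.DataFrame(
        {"feature": feats, "importance": importances, "category": cats}
    ).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    curves = {}
    for cat in sorted(set(cats)):
        member = (table["category"] == cat).to_numpy()
        n_cat = member.sum()
        curves[cat] = np.cumsum(member) / n_cat
    curve_df = pd.DataFrame(curves)
    curve_df.insert(0, "rank", np.arange(1, len(table) + 1))
    return table, curve_df
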