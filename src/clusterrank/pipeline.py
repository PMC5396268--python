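"""End-to-end orchestration: filter → cluster → features → train/rank.

The training pipeline consumes a benchmark directory (one sub-directory per
target holding ``models.pdb``, ``reference.pdb`` and ``descriptors.csv``,
plus a ``manifest.yaml`` naming the training/hold-out split) and produces a
fitted pairwise ranker together with its leave-complex-out CV report and a
reproducibility manifest of per-stage counts.  Ranking a new target needs
no reference structure: the reference is only ever read by the quality /
labelling stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .clustering import (
    Cluster,
    apply_size_cutoff,
    attach_enrichment,
    gromos_cluster,
    pairwise_lrmsd_matrix,
    select_enrichment_representatives,
)
from .descriptors import (
    DescriptorTable,
    compute_builtin_descriptors,
    read_descriptor_table,
    standardize_per_target,
)
from .features import ClusterFeatureVector, build_cluster_features
from .pairlearn import (
    CvResult,
    ErtConfig,
    RankerModel,
    RankResult,
    build_comparison_matrix,
    comparison_feature_names,
    leave_complex_out_cv,
    rank_clusters,
    train_ert,
)
from .quality import lrmsd
from .structures import ComplexModel, filter_clashed, read_models, truncate_to_shared_residues

logger = logging.getLogger("clusterrank")

__all__ = [
    "PipelineConfig",
    "PreparedTarget",
    "TrainResult",
    "prepare_target",
    "run_train",
    "run_rank",
]


@dataclass
class PipelineConfig:
    """Protocol constants and knobs for an end-to-end run."""

    clustering_cutoff: float = 10.0  # Å, primary decoy clustering
    sub_cluster_cutoff: float = 3.0  # Å, enrichment sub-clustering
    size_cutoff: int = 5  # keep clusters with size strictly greater
    always_include: dict[str, list[int]] = field(default_factory=dict)
    enrichment_top_n: int = 10
    ert: ErtConfig = field(default_factory=ErtConfig)
    rfe_step: int = 10
    transform_step: int = 10
    size_counts_enrichment: bool = False
    missing_policy: str = "drop"
    receptor_chains: list[str] = field(default_factory=lambda: ["A"])
    ligand_chains: list[str] = field(default_factory=lambda: ["B"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clustering_cutoff <= 0 or self.sub_cluster_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ert = ErtConfig(**raw.pop("ert", {}))
        return cls(ert=ert, **raw)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, ert=replace(self.ert, seed=seed))


@dataclass
class PreparedTarget:
    """A target after filtering, clustering and feature construction."""

    target_id: str
    clusters: list[Cluster]
    feature_vectors: list[ClusterFeatureVector]
    table: DescriptorTable
    counts: dict


def _load_target_models(
    target_dir: Path, target_id: str, config: PipelineConfig, with_reference: bool
) -> tuple[list[ComplexModel], ComplexModel | None]:
    models = read_models(
        target_dir / "models.pdb",
        set(config.receptor_chains),
        set(config.ligand_chains),
        target_id,
    )
    reference = None
    ref_path = target_dir / "reference.pdb"
    if with_reference and ref_path.exists():
        reference = read_models(
            ref_path, set(config.receptor_chains), set(config.ligand_chains), target_id
        )[0]
    everything = models + ([reference] if reference is not None else [])
    everything = truncate_to_shared_residues(everything)
    if reference is not None:
        return everything[:-1], everything[-1]
    return everything, None


def _load_descriptors(
    target_dir: Path, target_id: str, models: list[ComplexModel], config: PipelineConfig
) -> DescriptorTable:
    csv_path = target_dir / "descriptors.csv"
    if csv_path.exists():
        return read_descriptor_table(
            csv_path,
            target_id,
            known_model_ids=[m.model_id for m in models],
            missing_policy=config.missing_policy,
        )
    logger.info("%s: no descriptors.csv, computing built-in descriptors", target_id)
    return compute_builtin_descriptors(models, target_id)


def _restrict_table(table: DescriptorTable, model_ids: list[str]) -> DescriptorTable:
    present = [m for m in model_ids if m in set(table.model_ids)]
    return DescriptorTable(
        target_id=table.target_id,
        model_ids=present,
        descriptor_names=table.descriptor_names,
        values=table.rows(present),
        standardized=table.standardized,
    )


def prepare_target(
    target_dir: str | Path,
    target_id: str,
    config: PipelineConfig,
    with_reference: bool = True,
) -> PreparedTarget:
    """Filter, cluster and featurise one target.

    With a reference structure present (training mode), per-cluster minimum
    LRMSD labels are computed over original decoys only.  Enrichment pose
    sets, when provided as ``enrichment/cluster_<id>.pdb``, are
    clash-filtered, sub-clustered, and their representatives attached for
    descriptor aggregation.
    """
    target_dir = Path(target_dir)
    models, reference = _load_target_models(target_dir, target_id, config, with_reference)
    n_in = len(models)
    models, removed, removal_report = filter_clashed(models)
    if not models:
        raise ValueError(f"{target_id}: all models removed by clash filtering")
    for mid, n_clashes in removal_report:
        logger.warning("%s: removed %s (%d clashes)", target_id, mid, n_clashes)

    dm = pairwise_lrmsd_matrix(models)
    clusters = gromos_cluster(dm, config.clustering_cutoff)
    kept_clusters = apply_size_cutoff(
        clusters,
        min_size_exclusive=config.size_cutoff,
        always_include=set(config.always_include.get(target_id, [])),
    )

    by_id = {m.model_id: m for m in models}
    if reference is not None:
        model_lrmsd = {m.model_id: lrmsd(m, reference) for m in models}
        kept_clusters = [
            replace_min_lrmsd(c, min(model_lrmsd[m] for m in c.member_ids))
            for c in kept_clusters
        ]

    # optional enrichment pose sets, one multi-MODEL file per cluster
    enrichment_models: list[ComplexModel] = []
    enr_dir = target_dir / "enrichment"
    if enr_dir.is_dir():
        enriched = []
        for c in kept_clusters:
            pdb = enr_dir / f"cluster_{c.cluster_id}.pdb"
            if not pdb.exists():
                enriched.append(c)
                continue
            poses = read_models(
                pdb, set(config.receptor_chains), set(config.ligand_chains), target_id
            )
            for p in poses:
                p.source = "enrichment"
            poses, _, _ = filter_clashed(poses)
            reps = select_enrichment_representatives(
                poses, config.sub_cluster_cutoff, config.enrichment_top_n
            )
            enrichment_models.extend(reps)
            enriched.append(attach_enrichment(c, reps))
        kept_clusters = enriched

    table = _load_descriptors(
        target_dir, target_id, models + enrichment_models, config
    )
    table = _restrict_table(
        table, [m.model_id for m in models] + [m.model_id for m in enrichment_models]
    )
    table = standardize_per_target(table)

    vectors = [
        build_cluster_features(c, table, config.size_counts_enrichment)
        for c in kept_clusters
    ]
    counts = {
        "models_in": n_in,
        "models_kept": len(models),
        "models_removed": len(removed),
        "clusters": len(clusters),
        "clusters_kept": len(kept_clusters),
        "sum_cluster_sizes": int(sum(c.size for c in clusters)),
        "enrichment_models": len(enrichment_models),
    }
    assert counts["models_in"] == counts["models_kept"] + counts["models_removed"]
    assert counts["sum_cluster_sizes"] == counts["models_kept"]
    return PreparedTarget(
        target_id=target_id,
        clusters=kept_clusters,
        feature_vectors=vectors,
        table=table,
        counts=counts,
    )


def replace_min_lrmsd(cluster: Cluster, value: float) -> Cluster:
    return replace(cluster, min_lrmsd_to_reference=value)


@dataclass
class TrainResult:
    model: RankerModel
    cv: CvResult
    records: list
    feature_names: list[str]
    manifest: dict
    prepared: dict[str, PreparedTarget]


def run_train(
    benchmark_dir: str | Path, config: PipelineConfig
) -> TrainResult:
    """Train the pairwise ranker on a benchmark's training targets.

    Executes filter → cluster → (enrich) → standardise → features →
    comparisons → leave-complex-out CV → final fit, and assembles a
    manifest of per-stage counts and seeds.
    """
    benchmark_dir = Path(benchmark_dir)
    manifest_path = benchmark_dir / "manifest.yaml"
    if manifest_path.exists():
        bench_manifest = yaml.safe_load(manifest_path.read_text())
        train_targets = bench_manifest.get(
            "train_targets", bench_manifest.get("targets", [])
        )
        config = replace(
            config,
            receptor_chains=bench_manifest.get("receptor_chains", config.receptor_chains),
            ligand_chains=bench_manifest.get("ligand_chains", config.ligand_chains),
        )
    else:
        train_targets = sorted(p.name for p in benchmark_dir.iterdir() if p.is_dir())
    if len(train_targets) < 2:
        raise ValueError("training needs at least two targets (cross-validation)")

    prepared: dict[str, PreparedTarget] = {}
    for target_id in train_targets:
        logger.info("preparing %s", target_id)
        prepared[target_id] = prepare_target(
            benchmark_dir / target_id, target_id, config, with_reference=True
        )

    targets_map = {t: p.feature_vectors for t, p in prepared.items()}
    records = build_comparison_matrix(targets_map)
    if not records:
        raise ValueError("no comparison records could be built")
    feature_names = comparison_feature_names(
        next(iter(prepared.values())).feature_vectors[0].feature_names
    )
    cv = leave_complex_out_cv(records, config.ert, feature_names)
    model = train_ert(records, config.ert, feature_names)
    manifest = {
        "seed": config.seed,
        "targets": {t: p.counts for t, p in prepared.items()},
        "n_records": len(records),
        "n_features": len(feature_names),
        "cv_mean": cv.mean,
        "oob_score": model.oob_score,
    }
    model.manifest.update(manifest)
    return TrainResult(
        model=model,
        cv=cv,
        records=records,
        feature_names=feature_names,
        manifest=manifest,
        prepared=prepared,
    )


def run_rank(
    model: RankerModel, target_dir: str | Path, config: PipelineConfig, target_id: str | None = None
) -> RankResult:
    """Rank one target's clusters with a fitted model (reference-free)."""
    target_dir = Path(target_dir)
    target_id = target_id or target_dir.name
    prep = prepare_target(target_dir, target_id, config, with_reference=False)
    if len(prep.feature_vectors) < 2:
        raise ValueError(
            f"{target_id}: fewer than 2 clusters survive the size cutoff "
            f"(> {config.size_cutoff}); nothing to rank"
        )
    return rank_clusters(model, prep.feature_vectors)
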