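"""GROMOS-style clustering of docked poses by pairwise ligand RMSD.

The clustering is the iterative neighbour-count algorithm popularised by
the GROMOS/GROMACS analysis tools: repeatedly take the unassigned model
with the most unassigned neighbours within the cutoff as a cluster centroid,
assign it and its neighbours to a new cluster, and remove them.  Every
member is therefore within the cutoff of its centroid.

Two cutoffs matter downstream: 10 Å for the primary decoy clustering and
3 Å for sub-clustering locally re-sampled ("enrichment") poses, of which the
ten largest sub-clusters contribute one representative each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structures import ComplexModel

__all__ = [
    "DistanceMatrix",
    "Cluster",
    "pairwise_lrmsd_matrix",
    "gromos_cluster",
    "apply_size_cutoff",
    "select_enrichment_representatives",
    "attach_enrichment",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise ligand RMSDs (Å) between models."""

    model_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.model_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match model count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0) or not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric and non-negative")
        np.fill_diagonal(self.d, 0.0)


@dataclass
class Cluster:
    """A set of models grouped by pose similarity, seeded by its centroid."""

    cluster_id: int
    member_ids: list[str]
    centroid_id: str
    enrichment_ids: list[str] = field(default_factory=list)
    min_lrmsd_to_reference: float | None = None

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a cluster member")

    @property
    def size(self) -> int:
        """Number of original decoys (enrichment poses not counted)."""
        return len(self.member_ids)

    @property
    def all_member_ids(self) -> list[str]:
        """Members used for descriptor aggregation: decoys + enrichment."""
        return self.member_ids + self.enrichment_ids


def _model_ca_frames(models: list[ComplexModel]) -> tuple[np.ndarray, np.ndarray]:
    """Receptor and ligand Cα coordinate stacks in a common residue order."""
    ref_rec = models[0].receptor.ca_coords_by_key()
    ref_lig = models[0].ligand.ca_coords_by_key()
    rec_keys = list(ref_rec)
    lig_keys = list(ref_lig)
    recs = np.empty((len(models), len(rec_keys), 3))
    ligs = np.empty((len(models), len(lig_keys), 3))
    for i, m in enumerate(models):
        rmap = m.receptor.ca_coords_by_key()
        lmap = m.ligand.ca_coords_by_key()
        try:
            recs[i] = [rmap[k] for k in rec_keys]
            ligs[i] = [lmap[k] for k in lig_keys]
        except KeyError as exc:
            raise ValueError(
                f"model {m.model_id!r} lacks Cα for residue {exc.args[0]!r}; "
                "truncate models to shared residues first"
            ) from exc
    return recs, ligs


def pairwise_lrmsd_matrix(models: list[ComplexModel]) -> DistanceMatrix:
    """All-vs-all ligand-Cα RMSD after receptor-Cα superposition.

    For each unordered model pair, one model's receptor Cα set is
    superposed onto the other's (Kabsch) and the RMSD between the two
    ligand Cα sets is recorded; the measure is symmetric.  Models must
    already share residue sets.
    """
    if not models:
        raise ValueError("no models")
    recs, ligs = _model_ca_frames(models)
    if recs.shape[1] < 3:
        raise ValueError("need at least 3 shared receptor Cα atoms")
    n = len(models)
    rec_cent = recs.mean(axis=1, keepdims=True)
    recs_c = recs - rec_cent
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # Kabsch of model i's receptor onto model j's (both pre-centred)
            h = recs_c[i].T @ recs_c[j]
            u, s, vt = np.linalg.svd(h)
            sign = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
            moved = (ligs[i] - rec_cent[i]) @ rot.T + rec_cent[j]
            d[i, j] = d[j, i] = np.sqrt(np.mean(np.sum((moved - ligs[j]) ** 2, axis=1)))
    return DistanceMatrix(model_ids=[m.model_id for m in models], d=d)


def gromos_cluster(dm: DistanceMatrix, cutoff: float) -> list[Cluster]:
    """Iterative neighbour-count clustering.

    Among unassigned models, the one with the most unassigned neighbours
    within ``cutoff`` (inclusive) seeds a cluster containing itself and
    those neighbours; repeat until all models are assigned.  Equal
    neighbour counts are broken by the lexicographically smallest model ID,
    which makes the partition independent of input order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ids = dm.model_ids
    n = len(ids)
    adj = dm.d <= cutoff
    np.fill_diagonal(adj, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (adj & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        # lexicographic tie-break: smallest id among max-count candidates
        candidates = np.flatnonzero(counts == counts.max())
        best = int(min(candidates, key=lambda i: ids[i]))
        member_idx = [best] + [
            int(j) for j in np.flatnonzero(adj[best] & unassigned) if j != best
        ]
        member_idx.sort()
        clusters.append(
            Cluster(
                cluster_id=len(clusters) + 1,
                member_ids=[ids[i] for i in member_idx],
                centroid_id=ids[best],
            )
        )
        unassigned[member_idx] = False
    return clusters


def apply_size_cutoff(
    clusters: list[Cluster],
    min_size_exclusive: int = 5,
    always_include: set[int] | None = None,
) -> list[Cluster]:
    """Keep clusters with size strictly greater than the cutoff.

    Clusters listed in ``always_include`` (by cluster_id) are kept
    regardless of size — the escape hatch for small near-native clusters
    that would otherwise be lost.  Order is preserved.
    """
    always = always_include or set()
    return [
        c for c in clusters if c.size > min_size_exclusive or c.cluster_id in always
    ]


def select_enrichment_representatives(
    enrichment_models: list[ComplexModel],
    sub_cutoff: float = 3.0,
    top_n: int = 10,
) -> list[ComplexModel]:
    """Pick representative poses from locally re-sampled enrichment models.

    The poses are sub-clustered at ``sub_cutoff``; sub-clusters are ranked
    by descending size and, for each of the largest ``top_n``, the member
    closest to the sub-cluster centroid (the centroid itself, at distance
    zero) is returned.  Fewer sub-clusters yield fewer representatives.
    """
    if not enrichment_models:
        return []
    if len(enrichment_models) == 1:
        return list(enrichment_models)
    dm = pairwise_lrmsd_matrix(enrichment_models)
    subs = gromos_cluster(dm, sub_cutoff)
    subs = sorted(subs, key=lambda c: -c.size)  # stable: formation order on ties
    by_id = {m.model_id: m for m in enrichment_models}
    idx = {mid: i for i, mid in enumerate(dm.model_ids)}
    reps: list[ComplexModel] = []
    for sub in subs[:top_n]:
        ci = idx[sub.centroid_id]
        closest = min(sub.member_ids, key=lambda mid: (dm.d[idx[mid], ci], mid))
        reps.append(by_id[closest])
    return reps


def attach_enrichment(
    cluster: Cluster, representatives: list[ComplexModel]
) -> Cluster:
    """Attach enrichment representatives to a cluster.

    The representatives join the member list for descriptor aggregation
    only; the size feature and any minimum-LRMSD labelling keep counting
    original decoys alone.
    """
    rep_ids = [m.model_id for m in representatives]
    combined = cluster.member_ids + cluster.enrichment_ids + rep_ids
    if len(set(combined)) != len(combined):
        raise ValueError("duplicate model id when attaching enrichment")
    return replace(cluster, enrichment_ids=cluster.enrichment_ids + rep_ids)
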