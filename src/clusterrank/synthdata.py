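"""Synthetic multi-target decoy benchmarks with known ground truth.

Real decoy sets for this problem are large and external; this module
generates miniature but structurally faithful stand-ins so every pipeline
stage can be exercised and validated end-to-end:

* a rigid toy receptor and ligand (compact ~30-residue Cα pseudo-chains,
  enough geometry for meaningful superpositions);
* rigid ligand poses grouped into well-separated clusters whose sizes
  follow a heavy-tailed (power-law-like) distribution — a few big clusters,
  many small ones — mirroring how docked decoys distribute over binding
  regions;
* exactly one (or zero) planted near-native cluster sitting at the
  reference ligand position;
* descriptor columns whose correlation with LRMSD is configurable per
  descriptor category, contaminated by a heavy-tailed outlier mixture that
  emulates the spurious low-energy poses which plague real scoring
  functions.

The configured ``rho`` is the *realized* descriptor-LRMSD Pearson
correlation including the outlier mixture: the clean-noise variance is
solved from ``rho`` and the outlier variance, so generated data honour the
requested correlation even with outliers switched on.

Geometry and descriptors use separate seed streams, so descriptor noise
can be varied with the pose geometry held fixed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .descriptors import CATEGORIES, DescriptorMeta, DescriptorTable
from .structures import AtomRecord, AtomTable, ComplexModel

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "TargetData",
    "generate_target",
    "generate_benchmark",
    "generate_enrichment_poses",
    "write_models_pdb",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    n_targets: int = 11
    models_per_target: int = 160
    n_clusters: int = 10
    powerlaw_exponent: float = 1.5
    size_floor: int = 6  # smallest cluster; > 5 keeps every cluster rankable
    p_near_native: float = 1.0  # probability a target has a planted NN cluster
    descriptor_count: int = 16
    rho: float | dict[str, float] = 0.9  # descriptor-LRMSD correlation
    outlier_fraction: float = 0.05
    outlier_scale: float = 1.5  # Laplace scale of the outlier component
    n_residues: int = 30
    scaffold_radius: float = 8.0  # Å, compact pseudo-protein extent
    placement_radius: float = 40.0  # Å, cluster centres from receptor centroid
    rotation_sigma_deg: float = 5.0
    translation_sigma: float = 1.2  # Å
    clustering_cutoff: float = 10.0  # Å, the cutoff clusters must respect
    n_holdout: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.descriptor_count < 1:
            raise ValueError("need at least one descriptor")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier fraction must be in [0, 1)")
        for r in self._rho_values():
            if not (-1.0 <= r <= 1.0):
                raise ValueError("rho must lie in [-1, 1]")
        if 3.0 * self.translation_sigma > self.clustering_cutoff / 2.0:
            raise ValueError(
                "infeasible geometry: intra-cluster spread exceeds half the "
                "clustering cutoff"
            )

    def _rho_values(self) -> list[float]:
        if isinstance(self.rho, dict):
            return list(self.rho.values())
        return [self.rho]

    def rho_for_category(self, category: str) -> float:
        if isinstance(self.rho, dict):
            return float(self.rho.get(category, 0.0))
        return float(self.rho)

    def descriptor_metadata(self) -> list[DescriptorMeta]:
        return [
            DescriptorMeta(
                name=f"N_SYN_{CATEGORIES[i % len(CATEGORIES)].upper()}{i:03d}",
                category=CATEGORIES[i % len(CATEGORIES)],
            )
            for i in range(self.descriptor_count)
        ]


@dataclass
class SynthTruth:
    """Generator-side ground truth for one target."""

    target_id: str
    assignment: dict[str, int]  # model_id -> generated cluster label
    lrmsd: dict[str, float]  # model_id -> LRMSD to the planted reference
    planted_cluster: int | None  # label of the near-native cluster, if any
    best_cluster: int  # label attaining the target's minimum LRMSD

    def min_lrmsd_per_cluster(self) -> dict[int, float]:
        mins: dict[int, float] = {}
        for mid, c in self.assignment.items():
            v = self.lrmsd[mid]
            if c not in mins or v < mins[c]:
                mins[c] = v
        return mins


@dataclass
class TargetData:
    target_id: str
    models: list[ComplexModel]
    reference: ComplexModel
    descriptors: DescriptorTable
    truth: SynthTruth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _small_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, sigma_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _pseudo_chain(
    rng: np.random.Generator, n_residues: int, radius: float, chain_id: str
) -> AtomTable:
    """Compact Cα-only pseudo-chain centred at the origin."""
    coords = rng.normal(size=(n_residues, 3))
    coords *= radius / np.abs(coords).max()
    coords -= coords.mean(axis=0)
    records = [
        AtomRecord(
            chain_id=chain_id,
            residue_index=i + 1,
            residue_name="ALA",
            atom_name="CA",
            element="C",
            coords=coords[i],
            vdw_radius=1.7,
        )
        for i in range(n_residues)
    ]
    return AtomTable.from_records(records)


def _cluster_sizes(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed sizes: Zipf weights over a per-cluster floor."""
    k = config.n_clusters
    budget = config.models_per_target - config.size_floor * k
    if budget < 0:
        raise ValueError("models_per_target too small for the cluster count/floor")
    weights = np.arange(1, k + 1, dtype=float) ** (-config.powerlaw_exponent)
    weights /= weights.sum()
    extra = np.floor(weights * budget).astype(int)
    extra[0] += budget - extra.sum()
    sizes = config.size_floor + extra
    return rng.permutation(sizes)


def _descriptor_values(
    config: SynthConfig, lrmsd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """rho-correlated, outlier-contaminated descriptor columns."""
    n = len(lrmsd)
    z = (lrmsd - lrmsd.mean()) / lrmsd.std()
    f = config.outlier_fraction
    scale = config.outlier_scale
    outlier_var = f * 2.0 * scale**2  # Laplace variance is 2*scale^2
    columns = []
    for meta in config.descriptor_metadata():
        rho = config.rho_for_category(meta.category)
        sigma2 = 1.0 + outlier_var
        a = rho * np.sqrt(sigma2)
        b2 = sigma2 * (1.0 - rho**2) - outlier_var
        if b2 < 0:
            warnings.warn(
                f"rho={rho} unattainable with the configured outlier mixture; "
                "clean noise clamped to zero"
            )
            b2 = 0.0
        noise = np.sqrt(b2) * rng.normal(size=n)
        outliers = np.where(
            rng.random(n) < f, rng.laplace(0.0, scale, size=n), 0.0
        )
        columns.append(a * z + noise + outliers)
    return np.column_stack(columns)


def generate_target(config: SynthConfig, target_seed: int, target_id: str) -> TargetData:
    """Generate one target: poses, reference, descriptors and ground truth.

    Deterministic given ``(config, target_seed)``; geometry and descriptors
    draw from separate child streams of the target seed.
    """
    geom_rng = np.random.default_rng([int(target_seed), 1])
    desc_rng = np.random.default_rng([int(target_seed), 2])

    receptor = _pseudo_chain(geom_rng, config.n_residues, config.scaffold_radius, "A")
    ligand_template = _pseudo_chain(
        geom_rng, config.n_residues, config.scaffold_radius, "B"
    )

    directions = _fibonacci_sphere(config.n_clusters + 1) @ _random_rotation(geom_rng).T
    planted = bool(geom_rng.random() < config.p_near_native)
    # direction 0 hosts the reference; cluster centres use directions 0..K-1
    # when a near-native cluster is planted, else 1..K (reference unoccupied)
    offset = 0 if planted else 1
    centre_dirs = directions[offset : offset + config.n_clusters]
    reference_dir = directions[0]

    centre_rotations = [_random_rotation(geom_rng) for _ in range(config.n_clusters)]
    ref_rotation = centre_rotations[0] if planted else _random_rotation(geom_rng)
    ref_coords = (
        ligand_template.coords @ ref_rotation.T
        + reference_dir * config.placement_radius
    )
    reference = ComplexModel(
        model_id="reference",
        target_id=target_id,
        receptor=receptor,
        ligand=_with_coords(ligand_template, ref_coords),
    )

    sizes = _cluster_sizes(config, geom_rng)
    models: list[ComplexModel] = []
    assignment: dict[str, int] = {}
    lrmsd_truth: dict[str, float] = {}
    k_model = 0
    for c in range(config.n_clusters):
        centre = centre_dirs[c] * config.placement_radius
        base = ligand_template.coords @ centre_rotations[c].T
        for _ in range(int(sizes[c])):
            k_model += 1
            mid = f"models_m{k_model}"
            rot = _small_rotation(geom_rng, config.rotation_sigma_deg)
            shift = geom_rng.normal(0.0, config.translation_sigma, size=3)
            coords = (base - base.mean(axis=0)) @ rot.T + base.mean(axis=0)
            coords = coords + centre + shift
            models.append(
                ComplexModel(
                    model_id=mid,
                    target_id=target_id,
                    receptor=receptor,
                    ligand=_with_coords(ligand_template, coords),
                )
            )
            assignment[mid] = c + 1
            # receptors are identical, so LRMSD reduces to ligand-Cα RMSD
            lrmsd_truth[mid] = float(
                np.sqrt(np.mean(np.sum((coords - ref_coords) ** 2, axis=1)))
            )

    best_cluster = min(
        assignment.values(),
        key=lambda c: min(
            lrmsd_truth[m] for m, cc in assignment.items() if cc == c
        ),
    )
    truth = SynthTruth(
        target_id=target_id,
        assignment=assignment,
        lrmsd=lrmsd_truth,
        planted_cluster=1 if planted else None,
        best_cluster=best_cluster,
    )

    lrmsd_arr = np.array([lrmsd_truth[m.model_id] for m in models])
    table = DescriptorTable(
        target_id=target_id,
        model_ids=[m.model_id for m in models],
        descriptor_names=[m.name for m in config.descriptor_metadata()],
        values=_descriptor_values(config, lrmsd_arr, desc_rng),
    )
    return TargetData(
        target_id=target_id,
        models=models,
        reference=reference,
        descriptors=table,
        truth=truth,
    )


def _with_coords(table: AtomTable, coords: np.ndarray) -> AtomTable:
    new = AtomTable(
        chain_id=table.chain_id.copy(),
        residue_index=table.residue_index.copy(),
        icode=table.icode.copy(),
        residue_name=table.residue_name.copy(),
        atom_name=table.atom_name.copy(),
        element=table.element.copy(),
        coords=np.asarray(coords, dtype=float).copy(),
        vdw_radius=table.vdw_radius.copy(),
    )
    return new


def generate_enrichment_poses(
    base: ComplexModel,
    n_subclusters: int,
    poses_per_subcluster: int,
    centre_spread: float = 6.0,
    jitter_sigma: float = 0.15,
    seed: int = 0,
) -> list[ComplexModel]:
    """Locally re-sampled poses forming well-separated tight sub-clusters.

    Sub-cluster centres sit on a sphere of radius ``centre_spread`` around
    the base ligand position (pairwise separation comfortably above the
    3 Å sub-clustering cutoff at the default); members jitter by
    ``jitter_sigma`` per coordinate.  Returned poses carry
    ``source="enrichment"``.
    """
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_subclusters) @ _random_rotation(rng).T
    poses: list[ComplexModel] = []
    k = 0
    for s in range(n_subclusters):
        centre = base.ligand.coords + dirs[s] * centre_spread
        for _ in range(poses_per_subcluster):
            k += 1
            coords = centre + rng.normal(0.0, jitter_sigma, size=centre.shape)
            poses.append(
                ComplexModel(
                    model_id=f"{base.model_id}_e{k}",
                    target_id=base.target_id,
                    receptor=base.receptor,
                    ligand=_with_coords(base.ligand, coords),
                    source="enrichment",
                )
            )
    return poses


def _to_bio_structure(models: list[ComplexModel], name: str):
    builder = StructureBuilder()
    builder.init_structure(name)
    for k, model in enumerate(models):
        builder.init_model(k, k)
        serial = 1
        for table in (model.receptor, model.ligand):
            for cid in dict.fromkeys(table.chain_id):
                builder.init_chain(cid)
                builder.init_seg("    ")
                sub = table.subset(table.chain_id == cid)
                current = None
                for i in range(len(sub)):
                    key = (int(sub.residue_index[i]), sub.icode[i])
                    if key != current:
                        builder.init_residue(
                            sub.residue_name[i], " ", key[0], key[1] or " "
                        )
                        current = key
                    builder.init_atom(
                        sub.atom_name[i],
                        sub.coords[i],
                        0.0,
                        1.0,
                        " ",
                        sub.atom_name[i].center(4),
                        serial,
                        sub.element[i],
                    )
                    serial += 1
    return builder.get_structure()


def write_models_pdb(models: list[ComplexModel], path: str | Path) -> None:
    """Write models as a (multi-MODEL) PDB file."""
    io = PDBIO()
    io.set_structure(_to_bio_structure(models, Path(path).stem))
    io.save(str(path), write_end=True)


def generate_benchmark(config: SynthConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Write a benchmark directory tree consumable by the pipeline.

    Layout: one sub-directory per target with ``models.pdb`` (multi-MODEL),
    ``reference.pdb``, ``descriptors.csv`` and ``truth.json``, plus a
    top-level ``manifest.yaml`` recording the config, per-target seeds and
    the training/hold-out split (the last ``n_holdout`` targets are held
    out).  Returns the manifest.
    """
    if config.n_targets < 2:
        raise ValueError("a benchmark needs at least two targets")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    seeds = [
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(
            config.n_targets
        ) % (2**31)
    ]
    target_ids = [f"T{i + 1:02d}" for i in range(config.n_targets)]
    holdout = target_ids[len(target_ids) - config.n_holdout :] if config.n_holdout else []
    for target_id, target_seed in zip(target_ids, seeds):
        data = generate_target(config, target_seed, target_id)
        tdir = out / target_id
        tdir.mkdir(exist_ok=True)
        write_models_pdb(data.models, tdir / "models.pdb")
        write_models_pdb([data.reference], tdir / "reference.pdb")
        data.descriptors.to_frame().to_csv(tdir / "descriptors.csv", index=False)
        (tdir / "truth.json").write_text(
            json.dumps(
                {
                    "target_id": target_id,
                    "planted_cluster": data.truth.planted_cluster,
                    "best_cluster": data.truth.best_cluster,
                    "assignment": data.truth.assignment,
                    "lrmsd": data.truth.lrmsd,
                },
                indent=1,
            )
        )
    manifest = {
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in asdict(config).items()
        },
        "target_seeds": dict(zip(target_ids, seeds)),
        "targets": target_ids,
        "train_targets": [t for t in target_ids if t not in holdout],
        "holdout_targets": holdout,
        "receptor_chains": ["A"],
        "ligand_chains": ["B"],
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
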