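"""CAPRI-style quality measures for docked models against a reference.

Three measures quantify how close a docked pose is to the bound (reference)
structure:

* **LRMSD** — superpose the model's receptor Cα atoms onto the reference
  receptor Cα atoms, then report the RMSD of the model's ligand Cα atoms to
  the reference ligand Cα atoms.  Note this is Cα-only for both the
  superposition and the deviation (the common community variant uses all
  backbone atoms; that is available via ``atom_mode="backbone"``).
* **IRMSD** — RMSD over backbone atoms of interface residues (residues with
  any heavy atom within ``interface_cutoff`` of the partner chain in the
  reference), after superposing on exactly those atoms.
* **FNAT** — the fraction of reference interface residue--residue contacts
  (any heavy-atom pair within ``contact_cutoff``) that the model preserves.

A model is then binned into high / medium / acceptable / incorrect by a
configurable threshold table on (fnat, lrmsd, irmsd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .structures import AtomTable, ComplexModel, ResidueKey

__all__ = [
    "RigidSuperposition",
    "ModelQuality",
    "kabsch_superpose",
    "lrmsd",
    "fnat",
    "irmsd",
    "capri_class",
    "load_capri_thresholds",
    "evaluate_model",
    "quality_report",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class RigidSuperposition:
    """Least-squares rigid-body fit of one coordinate set onto another."""

    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Å
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class ModelQuality:
    model_id: str
    lrmsd: float
    irmsd: float
    fnat: float
    capri_class: str = "incorrect"


def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray) -> RigidSuperposition:
    """Optimal rigid superposition of ``mov`` onto ``ref`` (Kabsch, SVD form).

    Rows correspond 1:1.  Returns the proper rotation R and translation t
    minimising RMSD(R·mov + t, ref), together with that minimum RMSD.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3 with matching N")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for a rigid fit, got {n}")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        warnings.warn("degenerate (collinear) coordinates: rotation may be ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_c - rotation @ mov_c
    moved = mov @ rotation.T + translation
    fit_rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return RigidSuperposition(rotation=rotation, translation=translation, fit_rmsd=fit_rmsd)


def _matched_coords(
    model_table: AtomTable,
    ref_table: AtomTable,
    atom_names: tuple[str, ...] | None,
    keys: list[ResidueKey] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates matched by (residue key, atom name) in reference order."""
    wanted = set(atom_names) if atom_names is not None else None

    def index(table: AtomTable) -> dict[tuple[ResidueKey, str], np.ndarray]:
        out = {}
        tkeys = table.residue_keys()
        for i in range(len(table)):
            if wanted is not None and table.atom_name[i] not in wanted:
                continue
            out.setdefault((tkeys[i], table.atom_name[i]), table.coords[i])
        return out

    ref_idx = index(ref_table)
    mod_idx = index(model_table)
    selected = [
        k for k in ref_idx
        if (keys is None or k[0] in keys)
    ]
    missing = [k for k in selected if k not in mod_idx]
    if missing:
        shown = ", ".join(f"{k[0]}/{k[1]}" for k in missing[:5])
        raise ValueError(
            f"{len(missing)} reference atom(s) unmatched in model (e.g. {shown})"
        )
    ref_xyz = np.array([ref_idx[k] for k in selected])
    mod_xyz = np.array([mod_idx[k] for k in selected])
    return ref_xyz, mod_xyz


def lrmsd(
    model: ComplexModel, reference: ComplexModel, atom_mode: str = "ca"
) -> float:
    """Ligand RMSD after receptor superposition.

    ``atom_mode="ca"`` (default) uses Cα atoms for both the receptor
    superposition and the ligand deviation; ``"backbone"`` uses N/CA/C/O.
    """
    names = ("CA",) if atom_mode == "ca" else BACKBONE_ATOMS
    ref_rec, mod_rec = _matched_coords(model.receptor, reference.receptor, names)
    ref_lig, mod_lig = _matched_coords(model.ligand, reference.ligand, names)
    if len(ref_rec) < 3:
        raise ValueError("fewer than 3 matched receptor atoms for superposition")
    if len(ref_lig) == 0:
        raise ValueError("no matched ligand atoms")
    sup = kabsch_superpose(ref_rec, mod_rec)
    moved = sup.apply(mod_lig)
    return float(np.sqrt(np.mean(np.sum((moved - ref_lig) ** 2, axis=1))))


def _residue_contacts(model: ComplexModel, cutoff: float) -> set[tuple[ResidueKey, ResidueKey]]:
    """Receptor--ligand residue pairs with any heavy-atom pair <= cutoff."""
    rec = model.receptor.heavy()
    lig = model.ligand.heavy()
    dist = cdist(rec.coords, lig.coords)
    rkeys = rec.residue_keys()
    lkeys = lig.residue_keys()
    ii, jj = np.nonzero(dist <= cutoff)
    return {(rkeys[i], lkeys[j]) for i, j in zip(ii, jj)}


def fnat(model: ComplexModel, reference: ComplexModel, contact_cutoff: float = 5.0) -> float:
    """Fraction of the reference's interface contacts preserved by the model."""
    native = _residue_contacts(reference, contact_cutoff)
    if not native:
        raise ValueError("reference has no receptor-ligand contacts (no interface)")
    model_contacts = _residue_contacts(model, contact_cutoff)
    return len(native & model_contacts) / len(native)


def _interface_residues(reference: ComplexModel, cutoff: float) -> list[ResidueKey]:
    rec = reference.receptor.heavy()
    lig = reference.ligand.heavy()
    dist = cdist(rec.coords, lig.coords)
    rkeys = rec.residue_keys()
    lkeys = lig.residue_keys()
    near = dist <= cutoff
    keys: dict[ResidueKey, None] = {}
    for i in np.flatnonzero(near.any(axis=1)):
        keys.setdefault(rkeys[i], None)
    for j in np.flatnonzero(near.any(axis=0)):
        keys.setdefault(lkeys[j], None)
    return list(keys)


def irmsd(
    model: ComplexModel,
    reference: ComplexModel,
    interface_cutoff: float = 10.0,
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """Backbone RMSD over reference-defined interface residues.

    Interface residues are those of the reference with any heavy atom within
    ``interface_cutoff`` of the partner chain; the model is superposed onto
    the reference on the backbone atoms of those residues and the fit RMSD
    is returned.
    """
    keys = _interface_residues(reference, interface_cutoff)
    if not keys:
        raise ValueError("no interface residues within cutoff")
    keyset = set(keys)
    ref_r, mod_r = _matched_coords(model.receptor, reference.receptor, atom_names, keys=keyset)
    ref_l, mod_l = _matched_coords(model.ligand, reference.ligand, atom_names, keys=keyset)
    ref_xyz = np.vstack([ref_r, ref_l]) if len(ref_l) else ref_r
    mod_xyz = np.vstack([mod_r, mod_l]) if len(mod_l) else mod_r
    if len(ref_xyz) < 3:
        raise ValueError("fewer than 3 interface atoms for superposition")
    return kabsch_superpose(ref_xyz, mod_xyz).fit_rmsd


def load_capri_thresholds(path: str | Path | None = None) -> list[dict]:
    """Quality-class threshold rows, best class first."""
    if path is None:
        src = resources.files("clusterrank.data").joinpath("capri_thresholds.yaml")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)["classes"]


def capri_class(q: ModelQuality, thresholds: list[dict] | None = None) -> str:
    """Assign high/medium/acceptable/incorrect from the threshold table.

    A model gets the first (best) class whose row it satisfies:
    fnat >= fnat_min and (lrmsd <= lrmsd_max or irmsd <= irmsd_max).
    """
    rows = thresholds if thresholds is not None else load_capri_thresholds()
    for row in rows:
        if q.fnat >= row["fnat_min"] and (
            q.lrmsd <= row["lrmsd_max"] or q.irmsd <= row["irmsd_max"]
        ):
            return row["name"]
    return "incorrect"


def evaluate_model(
    model: ComplexModel,
    reference: ComplexModel,
    thresholds: list[dict] | None = None,
    contact_cutoff: float = 5.0,
    interface_cutoff: float = 10.0,
) -> ModelQuality:
    q = ModelQuality(
        model_id=model.model_id,
        lrmsd=lrmsd(model, reference),
        irmsd=irmsd(model, reference, interface_cutoff=interface_cutoff),
        fnat=fnat(model, reference, contact_cutoff=contact_cutoff),
    )
    q.capri_class = capri_class(q, thresholds)
    return q


def quality_report(
    models: list[ComplexModel],
    reference: ComplexModel,
    thresholds: list[dict] | None = None,
) -> pd.DataFrame:
    """Quality table (model_id, lrmsd, irmsd, fnat, capri_class)."""
    rows = [evaluate_model(m, reference, thresholds) for m in models]
    return pd.DataFrame(
        {
            "model_id": [q.model_id for q in rows],
            "lrmsd": [q.lrmsd for q in rows],
            "irmsd": [q.irmsd for q in rows],
            "fnat": [q.fnat for q in rows],
            "capri_class": [q.capri_class for q in rows],
        }
    )
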