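"""Reading, normalising and clash-filtering docked protein--protein models.

A docked pose ("decoy") is a rigid arrangement of a ligand protein relative
to a receptor protein.  Models arrive as (possibly multi-MODEL) PDB files in
which receptor and ligand are identified by chain ID.  Before any geometric
comparison, all models of a target are truncated to the residues they share,
and poses in which receptor and ligand atoms inter-penetrate (steric clash:
two atoms closer than the sum of their van der Waals radii) are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "AtomTable",
    "ComplexModel",
    "load_radii_table",
    "read_models",
    "truncate_to_shared_residues",
    "has_clash",
    "filter_clashed",
]

DEFAULT_UNKNOWN_RADIUS = 1.7  # carbon-like fallback, Å

#: Residue identity key: (chain_id, author residue number, insertion code).
ResidueKey = tuple[str, int, str]


def load_radii_table(path: str | Path | None = None) -> dict[str, float]:
    """Element -> van der Waals radius (Å) mapping.

    Reads the packaged table by default; a user table (TSV with ``element``
    and ``radius`` columns) may be supplied to override it.
    """
    if path is None:
        src = resources.files("clusterrank.data").joinpath("vdw_radii.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        element, radius = line.split("\t")
        table[element.strip().upper()] = float(radius)
    return table


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of a docked model."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    vdw_radius: float
    icode: str = ""

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index, self.icode)


@dataclass
class AtomTable:
    """Column-oriented atom store for one chain set (receptor or ligand)."""

    chain_id: np.ndarray
    residue_index: np.ndarray
    icode: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    vdw_radius: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if np.any(self.vdw_radius <= 0):
            raise ValueError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return len(self.atom_name)

    @classmethod
    def from_records(cls, records: list[AtomRecord]) -> "AtomTable":
        return cls(
            chain_id=np.array([r.chain_id for r in records], dtype=object),
            residue_index=np.array([r.residue_index for r in records], dtype=int),
            icode=np.array([r.icode for r in records], dtype=object),
            residue_name=np.array([r.residue_name for r in records], dtype=object),
            atom_name=np.array([r.atom_name for r in records], dtype=object),
            element=np.array([r.element for r in records], dtype=object),
            coords=np.array([r.coords for r in records], dtype=float),
            vdw_radius=np.array([r.vdw_radius for r in records], dtype=float),
        )

    def records(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                chain_id=self.chain_id[i],
                residue_index=int(self.residue_index[i]),
                residue_name=self.residue_name[i],
                atom_name=self.atom_name[i],
                element=self.element[i],
                coords=self.coords[i].copy(),
                vdw_radius=float(self.vdw_radius[i]),
                icode=self.icode[i],
            )
            for i in range(len(self))
        ]

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue keys as a 1-D object array of tuples."""
        out = np.empty(len(self), dtype=object)
        for i in range(len(self)):
            out[i] = (self.chain_id[i], int(self.residue_index[i]), self.icode[i])
        return out

    def unique_residue_keys(self) -> list[ResidueKey]:
        """Residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for key in self.residue_keys():
            seen.setdefault(key, None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "AtomTable":
        return AtomTable(
            chain_id=self.chain_id[mask],
            residue_index=self.residue_index[mask],
            icode=self.icode[mask],
            residue_name=self.residue_name[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            coords=self.coords[mask],
            vdw_radius=self.vdw_radius[mask],
        )

    def heavy(self) -> "AtomTable":
        return self.subset(self.element != "H")

    def ca_coords_by_key(self) -> dict[ResidueKey, np.ndarray]:
        """Residue key -> Cα coordinate (first CA atom of the residue)."""
        out: dict[ResidueKey, np.ndarray] = {}
        keys = self.residue_keys()
        for i in np.flatnonzero(self.atom_name == "CA"):
            out.setdefault(keys[i], self.coords[i])
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomTable":
        new = replace(self)
        new.coords = self.coords @ rotation.T + translation
        return new


@dataclass
class ComplexModel:
    """One docked pose: receptor and ligand atoms of a single target."""

    model_id: str
    target_id: str
    receptor: AtomTable
    ligand: AtomTable
    source: str = "scoreset"  # "scoreset" (original decoy) or "enrichment"

    def __post_init__(self) -> None:
        if len(self.receptor) == 0 or len(self.ligand) == 0:
            raise ValueError(
                f"model {self.model_id!r}: receptor and ligand must be non-empty"
            )
        if self.source not in ("scoreset", "enrichment"):
            raise ValueError(f"unknown source {self.source!r}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexModel":
        return replace(
            self,
            receptor=self.receptor.transformed(rotation, translation),
            ligand=self.ligand.transformed(rotation, translation),
        )


def _element_of(atom) -> str:
    element = (atom.element or "").strip().upper()
    if not element:
        # fall back to the first alphabetic character of the atom name
        element = next((c for c in atom.get_name() if c.isalpha()), "C").upper()
    return element


def _pick_altloc(atom):
    """Resolve a (possibly disordered) atom to one conformer.

    Highest occupancy wins; ties go to altloc 'A' then alphabetical.
    """
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc() != "A", a.get_altloc()),
    )
    return children[0]


def read_models(
    pdb_source: str | Path,
    receptor_chains: set[str],
    ligand_chains: set[str],
    target_id: str,
    radii: dict[str, float] | None = None,
) -> list[ComplexModel]:
    """Read docked models from a (multi-MODEL) PDB file.

    Every MODEL block yields one :class:`ComplexModel`; atoms are partitioned
    into receptor and ligand by chain ID.  Alternate locations are resolved
    to the highest-occupancy conformer; hydrogens are retained when present.
    """
    path = Path(pdb_source)
    radii = radii if radii is not None else load_radii_table()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    bio_models = list(structure)
    if not bio_models:
        raise ValueError(f"{path}: no models found (empty or unparseable file)")

    warned_elements: set[str] = set()
    out: list[ComplexModel] = []
    multi = len(bio_models) > 1
    for k, bio_model in enumerate(bio_models, start=1):
        chains = {c.id: c for c in bio_model}
        for wanted in sorted(receptor_chains | ligand_chains):
            if wanted not in chains:
                raise ValueError(f"{path}: chain {wanted!r} not found in MODEL {k}")
        parts: dict[str, list[AtomRecord]] = {"receptor": [], "ligand": []}
        for part, chain_set in (("receptor", receptor_chains), ("ligand", ligand_chains)):
            for cid in sorted(chain_set):
                for residue in chains[cid]:
                    hetflag, resseq, icode = residue.get_id()
                    for atom in residue:
                        atom = _pick_altloc(atom)
                        element = _element_of(atom)
                        radius = radii.get(element)
                        if radius is None:
                            if element not in warned_elements:
                                warnings.warn(
                                    f"unknown element {element!r}: using default "
                                    f"radius {DEFAULT_UNKNOWN_RADIUS} Å"
                                )
                                warned_elements.add(element)
                            radius = DEFAULT_UNKNOWN_RADIUS
                        parts[part].append(
                            AtomRecord(
                                chain_id=cid,
                                residue_index=int(resseq),
                                residue_name=residue.get_resname().strip(),
                                atom_name=atom.get_name().strip(),
                                element=element,
                                coords=np.asarray(atom.get_coord(), dtype=float),
                                vdw_radius=float(radius),
                                icode=icode.strip(),
                            )
                        )
        model_id = f"{path.stem}_m{k}" if multi else path.stem
        out.append(
            ComplexModel(
                model_id=model_id,
                target_id=target_id,
                receptor=AtomTable.from_records(parts["receptor"]),
                ligand=AtomTable.from_records(parts["ligand"]),
            )
        )
    return out


def _truncate_part(models: list[ComplexModel], part: str) -> list[AtomTable]:
    tables = [getattr(m, part) for m in models]
    key_sets = [set(t.unique_residue_keys()) for t in tables]
    shared = set.intersection(*key_sets)
    if not shared:
        raise ValueError(f"no {part} residues shared by all models")

    # Residue-name agreement at shared keys; on mismatch, keep only atom
    # names common to every model at that key.
    names_at_key: dict[ResidueKey, set[str]] = {}
    atomnames_at_key: dict[ResidueKey, set[str]] = {}
    for t in tables:
        keys = t.residue_keys()
        for i in range(len(t)):
            key = keys[i]
            if key in shared:
                names_at_key.setdefault(key, set()).add(t.residue_name[i])
    mismatched = {k for k, names in names_at_key.items() if len(names) > 1}
    if mismatched:
        warnings.warn(
            f"{len(mismatched)} shared {part} residue(s) disagree on residue "
            "name; keeping atoms common to all models at those positions"
        )
        for t in tables:
            keys = t.residue_keys()
            per_model: dict[ResidueKey, set[str]] = {}
            for i in range(len(t)):
                if keys[i] in mismatched:
                    per_model.setdefault(keys[i], set()).add(t.atom_name[i])
            for key, names in per_model.items():
                if key in atomnames_at_key:
                    atomnames_at_key[key] &= names
                else:
                    atomnames_at_key[key] = set(names)

    out = []
    for t in tables:
        keys = t.residue_keys()
        mask = np.array(
            [
                keys[i] in shared
                and (
                    keys[i] not in mismatched
                    or t.atom_name[i] in atomnames_at_key[keys[i]]
                )
                for i in range(len(t))
            ],
            dtype=bool,
        )
        out.append(t.subset(mask))
    return out


def truncate_to_shared_residues(models: list[ComplexModel]) -> list[ComplexModel]:
    """Restrict every model to the residues present in all models.

    Residues are identified by (chain ID, author residue number, insertion
    code); atom order within each model is preserved and no model gains
    atoms.  Raises if the receptor or ligand intersection is empty.
    """
    if not models:
        raise ValueError("no models given")
    receptors = _truncate_part(models, "receptor")
    ligands = _truncate_part(models, "ligand")
    return [
        replace(m, receptor=r, ligand=l)
        for m, r, l in zip(models, receptors, ligands)
    ]


def has_clash(
    model: ComplexModel, include_hydrogens: bool = False
) -> tuple[bool, list[tuple[int, int, float]]]:
    """Detect steric clashes between receptor and ligand.

    A clash is two atoms across the interface strictly closer than the sum
    of their van der Waals radii (touching spheres are legal).  Intra-chain
    contacts are never counted.  Returns ``(clashed, pairs)`` where pairs
    are ``(receptor_atom_index, ligand_atom_index, distance)`` in the
    (possibly hydrogen-filtered) atom tables.
    """
    rec = model.receptor if include_hydrogens else model.receptor.heavy()
    lig = model.ligand if include_hydrogens else model.ligand.heavy()
    if len(rec) == 0 or len(lig) == 0:
        return False, []
    dist = cdist(rec.coords, lig.coords)
    limit = rec.vdw_radius[:, None] + lig.vdw_radius[None, :]
    ii, jj = np.nonzero(dist < limit)  # strict inequality
    pairs = [(int(i), int(j), float(dist[i, j])) for i, j in zip(ii, jj)]
    return len(pairs) > 0, pairs


def filter_clashed(
    models: list[ComplexModel], include_hydrogens: bool = False
) -> tuple[list[ComplexModel], list[ComplexModel], list[tuple[str, int]]]:
    """Split models into clash-free and clashed, preserving order.

    Returns ``(kept, removed, report)`` with the report listing
    ``(model_id, n_clashes)`` for every removed model.
    """
    kept: list[ComplexModel] = []
    removed: list[ComplexModel] = []
    report: list[tuple[str, int]] = []
    for m in models:
        clashed, pairs = has_clash(m, include_hydrogens=include_hydrogens)
        if clashed:
            removed.append(m)
            report.append((m.model_id, len(pairs)))
        else:
            kept.append(m)
    return kept, removed, report
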