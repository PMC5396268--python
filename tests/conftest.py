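"""Shared fixtures: programmatic toy complexes and PDB files."""

from __future__ import annotations

import numpy as np
import pytest

from clusterrank.structures import AtomRecord, AtomTable, ComplexModel


def build_model(
    model_id: str,
    rec_coords,
    lig_coords,
    target_id: str = "T",
    rec_chain: str = "A",
    lig_chain: str = "B",
    atom_name: str = "CA",
    element: str = "C",
    radius: float = 1.7,
    source: str = "scoreset",
) -> ComplexModel:
    """One pseudo-atom per residue; residue numbering follows row order."""

    def table(coords, chain):
        coords = np.asarray(coords, dtype=float)
        records = [
            AtomRecord(
                chain_id=chain,
                residue_index=i + 1,
                residue_name="ALA",
                atom_name=atom_name,
                element=element,
                coords=coords[i],
                vdw_radius=radius,
            )
            for i in range(len(coords))
        ]
        return AtomTable.from_records(records)

    return ComplexModel(
        model_id=model_id,
        target_id=target_id,
        receptor=table(rec_coords, rec_chain),
        ligand=table(lig_coords, lig_chain),
        source=source,
    )


def build_model_from_atoms(model_id, rec_atoms, lig_atoms, target_id="T"):
    """Atoms given as (chain, resi, resname, atomname, element, xyz[, radius])."""

    def rec(entry):
        radius = entry[6] if len(entry) > 6 else 1.7
        return AtomRecord(
            chain_id=entry[0],
            residue_index=entry[1],
            residue_name=entry[2],
            atom_name=entry[3],
            element=entry[4],
            coords=np.asarray(entry[5], dtype=float),
            vdw_radius=radius,
        )

    return ComplexModel(
        model_id=model_id,
        target_id=target_id,
        receptor=AtomTable.from_records([rec(s) for s in rec_atoms]),
        ligand=AtomTable.from_records([rec(s) for s in lig_atoms]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_decoys(rng):
    """Five random rigid decoys sharing one receptor (10 residues each)."""
    receptor = rng.normal(scale=5.0, size=(10, 3))
    ligand = rng.normal(scale=5.0, size=(10, 3))
    models = []
    for k in range(5):
        shift = rng.normal(scale=8.0, size=3)
        theta = rng.uniform(0, np.pi)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        kmat = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(theta) * kmat + (1 - np.cos(theta)) * (kmat @ kmat)
        models.append(
            build_model(f"d{k}", receptor, ligand @ rot.T + shift + [20.0, 0, 0])
        )
    return models


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


TINY_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      4  CA  LEU B   1      20.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  VAL B   2      23.800   0.000   0.000  1.00  0.00           C
ENDMDL
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def four_model_pdb(tmp_path):
    blocks = []
    for k in range(1, 5):
        body = TINY_PDB.replace("MODEL        1", f"MODEL        {k}")
        body = body.replace("0.000   0.000   0.000", f"0.000   0.000   {k:.3f}")
        blocks.append(body)
    path = tmp_path / "four.pdb"
    path.write_text("".join(blocks) + "END\n")
    return path


ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  CA  LEU B   1      20.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  VAL B   2      23.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
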