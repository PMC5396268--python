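"""Per-model molecular descriptor tables and per-target standardisation.

Descriptors are scalar scores of a docked pose — contact potentials,
solvation terms, composite scoring functions and so on.  The pipeline is
descriptor-agnostic: any numeric CSV keyed by model ID can be ingested, and
two built-in exemplars (an inter-chain residue contact potential and an
atomic contact count) allow a full run from PDB files alone.

Before aggregation, each target's descriptor columns are standardised to
zero mean and unit variance over all of that target's models (decoys plus
enrichment poses); standardisation is strictly per target, never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structures import ComplexModel

__all__ = [
    "DescriptorTable",
    "DescriptorMeta",
    "CATEGORIES",
    "read_descriptor_table",
    "residue_contact_potential",
    "atomic_contact_count",
    "compute_builtin_descriptors",
    "standardize_per_target",
]

#: Descriptor categories: residue contact (rc), atomic contact (ac),
#: statistical-potential terms (sp), composite scores (cs), solvation (se),
#: hydrogen bonding (hb), van der Waals / electrostatics (ve), misc (mi).
CATEGORIES = ("rc", "ac", "sp", "cs", "se", "hb", "ve", "mi")


@dataclass(frozen=True)
class DescriptorMeta:
    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown descriptor category {self.category!r}")


@dataclass
class DescriptorTable:
    """Models x descriptors value matrix for one target."""

    target_id: str
    model_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.model_ids), len(self.descriptor_names)):
            raise ValueError("value matrix shape mismatch")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor table contains missing/non-finite values")

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def row(self, model_id: str) -> np.ndarray:
        try:
            return self.values[self.model_ids.index(model_id)]
        except ValueError:
            raise KeyError(f"model {model_id!r} not in descriptor table") from None

    def rows(self, model_ids: list[str]) -> np.ndarray:
        index = {mid: i for i, mid in enumerate(self.model_ids)}
        missing = [m for m in model_ids if m not in index]
        if missing:
            raise KeyError(f"models missing from descriptor table: {missing[:5]}")
        return self.values[[index[m] for m in model_ids]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "model_id", self.model_ids)
        return df

    def zero_variance_descriptors(self) -> list[str]:
        sd = self.values.std(axis=0)
        return [n for n, s in zip(self.descriptor_names, sd) if s == 0.0]


def read_descriptor_table(
    csv_path: str | Path,
    target_id: str,
    known_model_ids: list[str] | None = None,
    missing_policy: str = "drop",
) -> DescriptorTable:
    """Ingest a per-model descriptor CSV (first column ``model_id``).

    Rows for models not in ``known_model_ids`` (when given) are dropped with
    a warning.  Known models absent from the CSV are handled by
    ``missing_policy``: ``"drop"`` leaves them out (downstream stages drop
    the model), ``"impute"`` fills each descriptor with the column median.
    """
    df = pd.read_csv(csv_path)
    if df.shape[1] < 2:
        raise ValueError(f"{csv_path}: need a model_id column plus >=1 descriptor")
    id_col = df.columns[0]
    model_ids = df[id_col].astype(str).tolist()
    if len(set(model_ids)) != len(model_ids):
        dupes = sorted({m for m in model_ids if model_ids.count(m) > 1})
        raise ValueError(f"{csv_path}: duplicate model_id(s): {dupes[:5]}")
    value_df = df.drop(columns=[id_col])
    for col in value_df.columns:
        coerced = pd.to_numeric(value_df[col], errors="coerce")
        bad = coerced.isna() & value_df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{csv_path}: non-numeric value at row {row} "
                f"(model {model_ids[row]!r}), column {col!r}"
            )
        value_df[col] = coerced

    if known_model_ids is not None:
        known = set(known_model_ids)
        unknown = [m for m in model_ids if m not in known]
        if unknown:
            warnings.warn(
                f"{len(unknown)} descriptor row(s) for unknown models dropped "
                f"(e.g. {unknown[:3]})"
            )
            keep = [i for i, m in enumerate(model_ids) if m in known]
            value_df = value_df.iloc[keep]
            model_ids = [model_ids[i] for i in keep]
        absent = [m in set(model_ids) for m in known_model_ids]
        n_absent = absent.count(False)
        if n_absent:
            warnings.warn(
                f"{n_absent} model(s) lack descriptor rows; policy={missing_policy!r}"
            )
            if missing_policy == "impute":
                medians = value_df.median(axis=0)
                extra = pd.DataFrame(
                    [medians] * n_absent, columns=value_df.columns
                )
                value_df = pd.concat([value_df, extra], ignore_index=True)
                model_ids = model_ids + [
                    m for m, present in zip(known_model_ids, absent) if not present
                ]
            elif missing_policy != "drop":
                raise ValueError(f"unknown missing policy {missing_policy!r}")

    values = value_df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{csv_path}: missing values remain after ingestion")
    table = DescriptorTable(
        target_id=target_id,
        model_ids=model_ids,
        descriptor_names=list(value_df.columns),
        values=values,
    )
    zv = table.zero_variance_descriptors()
    if zv:
        warnings.warn(f"zero-variance descriptor column(s): {zv[:5]}")
    return table


def residue_contact_potential(
    model: ComplexModel,
    pair_scores: pd.DataFrame,
    contact_cutoff: float,
    unknown_residue: str = "skip",
) -> float:
    """Coarse-grained inter-chain residue contact potential.

    Sums ``pair_scores[receptor_residue_type, ligand_residue_type]`` over
    receptor--ligand residue pairs with any heavy-atom pair within
    ``contact_cutoff``; each residue pair counts once.  ``pair_scores`` is a
    symmetric table indexed by residue type (e.g. 3-letter codes).
    """
    if contact_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = model.receptor.heavy()
    lig = model.ligand.heavy()
    dist = cdist(rec.coords, lig.coords)
    rkeys = rec.residue_keys()
    lkeys = lig.residue_keys()
    rnames = dict(zip(rkeys, rec.residue_name))
    lnames = dict(zip(lkeys, lig.residue_name))
    ii, jj = np.nonzero(dist <= contact_cutoff)
    pairs = {(rkeys[i], lkeys[j]) for i, j in zip(ii, jj)}
    total = 0.0
    for rkey, lkey in pairs:
        rtype, ltype = rnames[rkey], lnames[lkey]
        if rtype not in pair_scores.index or ltype not in pair_scores.columns:
            if unknown_residue == "skip":
                warnings.warn(f"unknown residue type in pair ({rtype}, {ltype}); skipped")
                continue
            raise ValueError(f"unknown residue type in pair ({rtype}, {ltype})")
        total += float(pair_scores.loc[rtype, ltype])
    return total


def atomic_contact_count(model: ComplexModel, cutoff: float) -> int:
    """Number of receptor--ligand heavy-atom pairs within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = model.receptor.heavy()
    lig = model.ligand.heavy()
    if len(rec) == 0 or len(lig) == 0:
        return 0
    tree = cKDTree(lig.coords)
    counts = tree.query_ball_point(rec.coords, r=cutoff, return_length=True)
    return int(counts.sum())


def compute_builtin_descriptors(
    models: list[ComplexModel],
    target_id: str,
    contact_cutoff: float = 5.0,
    pair_scores: pd.DataFrame | None = None,
) -> DescriptorTable:
    """Exemplar descriptor table computed from structure alone.

    Provides an inter-chain residue contact count (uniform contact
    potential, ``N_CP_CNT``) and an atomic contact count (``N_AC_CNT``) so
    the full pipeline can run end-to-end without an external descriptor
    server.  A custom residue ``pair_scores`` table replaces the uniform
    potential when given.
    """
    if pair_scores is None:
        restypes = sorted(
            {n for m in models for n in m.receptor.residue_name}
            | {n for m in models for n in m.ligand.residue_name}
        )
        pair_scores = pd.DataFrame(1.0, index=restypes, columns=restypes)
    rows = [
        [
            residue_contact_potential(m, pair_scores, contact_cutoff),
            float(atomic_contact_count(m, contact_cutoff)),
        ]
        for m in models
    ]
    return DescriptorTable(
        target_id=target_id,
        model_ids=[m.model_id for m in models],
        descriptor_names=["N_CP_CNT", "N_AC_CNT"],
        values=np.array(rows, dtype=float),
    )


def standardize_per_target(table: DescriptorTable) -> DescriptorTable:
    """Scale each descriptor to zero mean and unit variance within a target.

    Statistics are taken over all of the target's models (decoys and
    enrichment poses together), using the population standard deviation.
    Zero-variance columns become all zeros.
    """
    if table.standardized:
        raise ValueError("table already standardized")
    if len(table.model_ids) < 2:
        raise ValueError("cannot standardize a single-model table (sd undefined)")
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0)  # population sd
    centred = table.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    return replace(table, values=scaled, standardized=True)
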