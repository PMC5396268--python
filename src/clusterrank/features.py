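"""Cluster feature vectors: five-point descriptor summaries plus size.

Each cluster's distribution of every (standardised) descriptor is reduced
to five points — minimum, first quartile, median, third quartile, maximum —
and the cluster size is appended, giving ``5*D + 1`` features per cluster
(546 when D = 109 descriptors).

Feature names follow the ``{slot}_{stat}_{descriptor}`` convention used in
pairwise comparisons: ``C2_Q1_N_CP_TB`` is the first quartile (Q1) of the
normalised (N) TOBI potential (CP_TB) of the second cluster (C2) in a pair.
The median's stat token is ``AVG`` for historical reasons; the value is the
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Cluster
from .descriptors import DescriptorTable

__all__ = [
    "STATS",
    "FivePointSummary",
    "ClusterFeatureVector",
    "five_point_summary",
    "build_cluster_features",
    "feature_name",
    "cluster_feature_frame",
]

#: Stat tokens in feature order; AVG denotes the median.
STATS = ("MIN", "Q1", "AVG", "Q3", "MAX")


@dataclass(frozen=True)
class FivePointSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(a > b + 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("five-point summary must be non-decreasing")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.min, self.q1, self.median, self.q3, self.max)


@dataclass
class ClusterFeatureVector:
    """``5*D + 1`` summary features describing one cluster."""

    cluster_id: int
    feature_names: list[str]
    values: np.ndarray
    min_lrmsd: float | None = None  # training label ingredient, decoys only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.feature_names) != len(self.values):
            raise ValueError("feature names and values differ in length")


def five_point_summary(values) -> FivePointSummary:
    """Min / Q1 / median / Q3 / max with linear quantile interpolation.

    Quartiles interpolate order statistics at positions ``(n-1)*p`` (the
    common default in scientific software); min and max are exact.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty value list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FivePointSummary(*[float(v) for v in q])


def feature_name(slot: str, stat: str, descriptor: str | None = None) -> str:
    """Compose a comparison feature name, e.g. ``C2_Q1_N_CP_TB``."""
    if slot not in ("C1", "C2"):
        raise ValueError(f"slot must be C1 or C2, got {slot!r}")
    if stat == "SIZE":
        return f"{slot}_SIZE"
    if stat not in STATS:
        raise ValueError(f"unknown stat {stat!r}")
    if not descriptor:
        raise ValueError("descriptor name required for distribution stats")
    return f"{slot}_{stat}_{descriptor}"


def build_cluster_features(
    cluster: Cluster,
    table: DescriptorTable,
    size_counts_enrichment: bool = False,
) -> ClusterFeatureVector:
    """Five-point summaries of every descriptor over the cluster's members.

    Summaries aggregate original decoys and enrichment poses; the trailing
    SIZE feature counts original decoys only unless
    ``size_counts_enrichment`` is set.  Feature order is descriptor-major,
    stat-minor (MIN, Q1, AVG, Q3, MAX), with SIZE last.
    """
    if not table.standardized:
        raise ValueError("descriptor table must be standardized first")
    members = cluster.all_member_ids
    rows = table.rows(members)  # raises naming the model on a miss
    names: list[str] = []
    values: list[float] = []
    for j, desc in enumerate(table.descriptor_names):
        summary = five_point_summary(rows[:, j])
        for stat, val in zip(STATS, summary.as_tuple()):
            names.append(f"{stat}_{desc}")
            values.append(val)
    names.append("SIZE")
    values.append(float(len(members) if size_counts_enrichment else cluster.size))
    return ClusterFeatureVector(
        cluster_id=cluster.cluster_id,
        feature_names=names,
        values=np.array(values),
        min_lrmsd=cluster.min_lrmsd_to_reference,
    )


def cluster_feature_frame(vectors: list[ClusterFeatureVector]) -> pd.DataFrame:
    """Per-target cluster-feature table (one row per cluster)."""
    if not vectors:
        return pd.DataFrame()
    names = vectors[0].feature_names
    for v in vectors:
        if v.feature_names != names:
            raise ValueError("inconsistent feature names across clusters")
    df = pd.DataFrame([v.values for v in vectors], columns=names)
    df.insert(0, "cluster_id", [v.cluster_id for v in vectors])
    return df
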