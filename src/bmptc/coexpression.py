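"""Synexpression-group discovery by correlation-based hierarchical clustering.

Probes surviving the general filter are clustered with UPGMA (agglomerative,
average linkage) on the correlation distance d = 1 - Pearson(x, y) across all
events of one ligand. Tight clusters — connected components below a cut
height whose members are large enough and mutually well correlated — are the
operational stand-in for the visually delineated co-expression blocks, and
the intersection of one tight cluster per ligand yields the shared
synexpression group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io_model import ExpressionMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("profiles must be equal-length 1-D vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance profile has undefined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


@dataclass
class Dendrogram:
    """UPGMA merge tree over probe profiles.

    ``merges`` is the scipy linkage matrix: row i merges nodes Z[i,0] and
    Z[i,1] (< n = leaves, >= n = earlier merges) at height Z[i,2].
    """

    leaves: list[str]
    merges: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.merges.shape != (n - 1, 4):
            raise ValidationError("merge list must have exactly n-1 rows")

    def cut(self, height: float) -> dict[int, list[str]]:
        """Connected components strictly below the cut height."""
        labels = hierarchy.fcluster(self.merges, t=height, criterion="distance")
        groups: dict[int, list[str]] = {}
        for leaf, lab in zip(self.leaves, labels):
            groups.setdefault(int(lab), []).append(leaf)
        return groups

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.merges, rd=False)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaves[node.id]
            # branch length = parent height - child height
            left = rec(node.left)
            right = rec(node.right)
            bl_l = node.dist - (0.0 if node.left.is_leaf() else node.left.dist)
            bl_r = node.dist - (0.0 if node.right.is_leaf() else node.right.dist)
            if node.left.is_leaf():
                bl_l = node.dist
            if node.right.is_leaf():
                bl_r = node.dist
            return f"({left}:{bl_l:.10g},{right}:{bl_r:.10g})"

        return rec(tree) + ";"

    def to_json(self) -> str:
        return json.dumps(
            {"leaves": self.leaves,
             "merges": [[int(a), int(b), float(h), int(c)] for a, b, h, c in self.merges]},
            separators=(",", ":"),
        )

    def write(self, newick_path: str | Path | None = None, json_path: str | Path | None = None) -> None:
        if newick_path is not None:
            Path(newick_path).write_text(self.to_newick() + "\n")
        if json_path is not None:
            Path(json_path).write_text(self.to_json() + "\n")


def average_linkage_cluster(matrix: ExpressionMatrix, drop_constant: bool = True) -> Dendrogram:
    """UPGMA on the correlation-distance matrix of probe profiles."""
    data = matrix.data.dropna(axis=0)
    variances = data.var(axis=1, ddof=0)
    if drop_constant and (variances == 0).any():
        dropped = data.index[variances == 0].tolist()
        logger.warning("dropping %d zero-variance probes before clustering", len(dropped))
        data = data[variances > 0]
    elif (variances == 0).any():
        raise ValidationError("zero-variance probe profiles present")
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 probes to cluster")
    dists = pdist(data.to_numpy(dtype=float), metric="correlation")
    merges = hierarchy.linkage(dists, method="average")
    return Dendrogram(leaves=list(data.index), merges=merges)


def sample_cluster(matrix: ExpressionMatrix) -> Dendrogram:
    """Cluster the event columns (samples) with the same metric/linkage."""
    data = matrix.data.dropna(axis=0).T
    dists = pdist(data.to_numpy(dtype=float), metric="correlation")
    merges = hierarchy.linkage(dists, method="average")
    return Dendrogram(leaves=list(data.index), merges=merges)


@dataclass
class TightCluster:
    members: list[str]
    mean_correlation: float
    cut_height: float

    @property
    def size(self) -> int:
        return len(self.members)


def mean_pairwise_correlation(matrix: ExpressionMatrix, probe_ids: list[str]) -> float:
    rows = matrix.data.loc[probe_ids].to_numpy(dtype=float)
    d = pdist(rows, metric="correlation")
    return float(1.0 - d.mean())


def extract_tight_clusters(
    dendrogram: Dendrogram,
    matrix: ExpressionMatrix,
    cut_height: float = 0.3,
    min_size: int = 20,
    tightness: float = 0.8,
) -> list[TightCluster]:
    """Clusters below ``cut_height`` with >= ``min_size`` members and mean
    pairwise Pearson correlation >= ``tightness``, sorted by size descending."""
    if cut_height < 0 or min_size < 2 or not (0 < tightness <= 1):
        raise ValidationError("invalid extraction parameters")
    out: list[TightCluster] = []
    for members in dendrogram.cut(cut_height).values():
        if len(members) < min_size:
            continue
        r = mean_pairwise_correlation(matrix, members)
        if r >= tightness:
            out.append(TightCluster(sorted(members), r, cut_height))
    out.sort(key=lambda c: (-c.size, c.members[0]))
    return out


@dataclass
class SynexpressionGroup:
    shared_probes: list[str]
    size_a: int
    size_b: int
    unique_genes: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.shared_probes)


def intersect_clusters(
    a: TightCluster, b: TightCluster,
    annotations: dict[str, ProbeAnnotation] | None = None,
) -> SynexpressionGroup:
    """Probes present in both ligands' tight clusters; the shared group.

    The unique-gene subset keeps one entry per gene among shared probes whose
    annotation status is 'unique'.
    """
    if not a.members or not b.members:
        raise ValidationError("both clusters must be non-empty")
    shared = sorted(set(a.members) & set(b.members))
    genes: list[str] = []
    if annotations is not None:
        seen: set[str] = set()
        for p in shared:
            ann = annotations.get(p)
            if ann is not None and ann.status == "unique" and ann.gene_ids[0] not in seen:
                seen.add(ann.gene_ids[0])
                genes.append(ann.gene_ids[0])
    return SynexpressionGroup(shared, size_a=a.size, size_b=b.size, unique_genes=genes)


def clusters_to_frame(clusters: list[TightCluster]) -> pd.DataFrame:
    rows = [
        {"cluster_id": i + 1, "probe_id": p, "size": c.size,
         "mean_correlation": c.mean_correlation}
        for i, c in enumerate(clusters) for p in c.members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "probe_id", "size", "mean_correlation"])
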