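"""Hierarchical clustering of taxa on their RSCU vectors.

Each taxon is represented by the RSCU vector of its concatenated
protein-coding genes (59 dimensions under the standard layout). The
merge tree is built with scipy's agglomerative linkage; defaults are
Euclidean distance with average linkage, recorded in the result metadata
for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .codes import GeneticCode, STANDARD
from .codon_stats import CodonCountTable, count_codons, rscu
from .genome_io import MitogenomeRecord, extract_gene_sequence


@dataclass
class ClusterResult:
    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy linkage encoding of the n-1 merges
    leaf_order: tuple[int, ...]
    cophenetic: np.ndarray  # square symmetric matrix
    metric: str
    linkage: str

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """(node, node, height) triples; leaves are 0..n-1, internal nodes follow."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    def flat_clusters(self, k: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(x) for x in assign)))

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def build_rscu_matrix(
    records: list[MitogenomeRecord], code: GeneticCode = STANDARD
) -> pd.DataFrame:
    """Taxa x codons RSCU matrix from each genome's concatenated PCGs.

    Codon columns are alphabetical; taxa lacking PCGs are excluded with a
    warning.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    rows = {}
    for rec in records:
        pcgs = rec.pcgs
        if not pcgs:
            warnings.warn(f"{rec.accession}: no protein-coding genes; excluded")
            continue
        pooled = CodonCountTable(source=rec.accession, code=code)
        for feat in sorted(pcgs, key=lambda f: f.name):
            pooled = pooled.merged(
                count_codons(extract_gene_sequence(rec, feat.name), code),
                source=rec.accession,
            )
        vec = rscu(pooled)
        rows[rec.accession] = [vec.values[c] for c in code.rscu_codons]
    if len(rows) < 2:
        raise ValueError("fewer than 2 records with protein-coding genes")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(code.rscu_codons))


def agglomerative_cluster(
    matrix: pd.DataFrame, metric: str = "euclidean", linkage: str = "average"
) -> ClusterResult:
    """Deterministic hierarchical clustering of the taxa rows."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    # sort rows by label so equal inputs yield identical merge order
    order = np.argsort(matrix.index.to_numpy())
    values = values[order]
    labels = tuple(matrix.index[order])
    dists = pdist(values, metric=metric)
    Z = hierarchy.linkage(dists, method=linkage)
    coph_condensed = hierarchy.cophenet(Z)
    return ClusterResult(
        labels=labels,
        linkage_matrix=Z,
        leaf_order=tuple(int(i) for i in hierarchy.leaves_list(Z)),
        cophenetic=squareform(coph_condensed),
        metric=metric,
        linkage=linkage,
    )
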