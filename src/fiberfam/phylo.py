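"""Pairwise distances, neighbor-joining trees, and subgroup assignment.

Distances are uncorrected p-distances on a pre-computed repeat-domain
alignment (alignment itself is an input, not computed here).  Trees are
built with the Saitou-Nei neighbor-joining agglomeration; on any additive
matrix NJ provably recovers the generating topology and path lengths.
Subgroup labels (the S-number categories defined on Arabidopsis references,
e.g. S9/MIXTA, S15/GLABRA1) are transferred from the nearest labeled
reference, falling back to a lineage-specific "G-S" label beyond a distance
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skbio
from skbio.tree import TreeNode, nj as _skbio_nj

__all__ = [
    "DistanceMatrix",
    "SubgroupAssignment",
    "p_distance",
    "nj_tree",
    "assign_subgroup",
]

_EXCLUDED = {"-", "X", "x", ".", "?"}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa count")
        if np.any(self.d < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @classmethod
    def from_alignment(cls, records: dict[str, str]) -> "DistanceMatrix":
        """All-pairs p-distance matrix from an id -> aligned-sequence map."""
        taxa = list(records)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(records[taxa[i]], records[taxa[j]])
        return cls(taxa, d)


@dataclass(frozen=True)
class SubgroupAssignment:
    query_id: str
    subgroup_label: str
    nearest_reference_id: str
    distance: float


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatched columns between two aligned sequences.

    Columns where either sequence has a gap or ambiguity character
    (``- X . ?``) are excluded pairwise.  Raises if the strings differ in
    length or no comparable columns remain.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ ({len(a)} vs {len(b)})")
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _EXCLUDED or y in _EXCLUDED:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable columns between the two sequences")
    return mismatches / compared


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; root trifurcation) from a distance matrix.

    For two taxa the single edge is split evenly.  Negative branch-length
    estimates are clamped to zero.  The returned tree serializes to Newick
    via ``str(tree)`` / ``tree.write``.
    """
    if len(dm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(dm.taxa) == 2:
        half = dm.d[0, 1] / 2.0
        return TreeNode.read([f"({dm.taxa[0]}:{half},{dm.taxa[1]}:{half});"])
    sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.taxa)
    return _skbio_nj(sk_dm, neg_as_zero=True)


def assign_subgroup(
    query_id: str,
    distances: dict[str, float],
    reference_labels: dict[str, str],
    cutoff: float = 0.6,
    lineage_label: str = "G-S",
) -> SubgroupAssignment:
    """Assign a query to the subgroup of its nearest labeled reference.

    *distances* maps reference id -> distance to the query.  The nearest
    reference's label is copied when its distance is <= *cutoff*; otherwise
    the query is called lineage-specific (*lineage_label*).  Ties are broken
    by lexicographically smaller reference id.
    """
    if not distances:
        raise ValueError("empty reference set")
    unlabeled = set(distances) - set(reference_labels)
    if unlabeled:
        raise ValueError(f"references without labels: {sorted(unlabeled)}")
    nearest = min(distances, key=lambda ref: (distances[ref], ref))
    dist = distances[nearest]
    label = reference_labels[nearest] if dist <= cutoff else lineage_label
    return SubgroupAssignment(query_id, label, nearest, dist)
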