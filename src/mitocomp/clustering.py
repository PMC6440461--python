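"""Compositional clustering of genomes (UPGMA on feature vectors).

Genomes are embedded as numeric feature vectors (A+T content, skews,
selected CDspT entries), optionally z-scored, and clustered by average
linkage on Euclidean distances.  UPGMA produces a rooted ultrametric tree
whose newick export carries branch lengths; merge ties are broken by
lexicographic label order so the result is independent of input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    labels: list[str]
    feature_names: list[str]
    values: np.ndarray          # genomes x features

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("matrix shape does not match labels/features")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing cells")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.feature_names)


def feature_matrix(
    features_by_genome: dict[str, dict[str, float]],
    feature_names: Sequence[str],
    standardize: bool = True,
) -> FeatureMatrix:
    """Assemble a genomes x features matrix in the stated feature order.

    With ``standardize`` each column is z-scored (constant columns are set
    to zero with a warning).  A genome missing a requested feature is an
    error naming both.
    """
    labels = list(features_by_genome)
    rows = []
    for label in labels:
        row = []
        for name in feature_names:
            if name not in features_by_genome[label] or features_by_genome[label][name] is None:
                raise ValueError(f"genome {label!r} lacks feature {name!r}")
            row.append(features_by_genome[label][name])
        rows.append(row)
    values = np.array(rows, dtype=float)
    if standardize and len(labels) > 1:
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"constant feature column(s) {[feature_names[i] for i in np.flatnonzero(flat)]}"
                " set to zero"
            )
        sd[flat] = 1.0
        values = (values - mean) / sd
    return FeatureMatrix(labels, list(feature_names), values)


def distance_matrix(m: FeatureMatrix) -> np.ndarray:
    """Euclidean distance matrix between genome feature vectors."""
    if len(m.labels) < 2:
        raise ValueError("need at least two genomes")
    diff = m.values[:, None, :] - m.values[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class ClusterNode:
    """A node of the rooted ultrametric cluster tree."""

    height: float
    label: Optional[str] = None                 # leaves only
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [leaf for c in self.children for leaf in c.leaves()]

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.label
        parts = ",".join(
            f"{c._newick_inner()}:{self.height - c.height:.6g}" for c in self.children
        )
        return f"({parts})"


@dataclass
class ClusterTree:
    root: ClusterNode
    linkage: str

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick()

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node."""
        out = []

        def walk(node: ClusterNode) -> None:
            if not node.is_leaf:
                out.append(frozenset(node.leaves()))
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


def upgma(
    d: np.ndarray, labels: Sequence[str], linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of a distance matrix.

    ``average`` linkage (UPGMA, size-weighted mean of member distances) is
    the default; ``single`` and ``complete`` are also available.  The
    closest pair is merged at node height = distance / 2; ties are broken
    by the lexicographically smallest pair of cluster labels, where a
    cluster is labelled by its smallest leaf.
    """
    d = np.asarray(d, dtype=float)
    k = len(labels)
    if d.shape != (k, k):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")

    nodes = {i: ClusterNode(height=0.0, label=labels[i]) for i in range(k)}
    sizes = {i: 1 for i in range(k)}
    names = {i: labels[i] for i in range(k)}   # tie-break key: smallest leaf
    dist = {(i, j): d[i, j] for i in range(k) for j in range(i + 1, k)}
    next_id = k
    active = set(range(k))
    while len(active) > 1:
        best = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda ij: (
                dist[ij],
                min(names[ij[0]], names[ij[1]]),
                max(names[ij[0]], names[ij[1]]),
            ),
        )
        i, j = best
        h = dist[best] / 2
        children = sorted((nodes[i], nodes[j]), key=lambda nd: min(nd.leaves()))
        merged = ClusterNode(height=h, children=tuple(children))
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        names[next_id] = min(names[i], names[j])
        active -= {i, j}
        for other in active:
            dij = dist[tuple(sorted((i, other)))]
            djj = dist[tuple(sorted((j, other)))]
            if linkage == "average":
                new = (sizes[i] * dij + sizes[j] * djj) / (sizes[i] + sizes[j])
            elif linkage == "single":
                new = min(dij, djj)
            else:
                new = max(dij, djj)
            dist[tuple(sorted((other, next_id)))] = new
        active.add(next_id)
        next_id += 1
    return ClusterTree(root=nodes[next_id - 1], linkage=linkage)
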