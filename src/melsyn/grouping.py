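"""Phenotype grouping of cell lines from cytotoxicity response profiles.

Cell lines are clustered on their joint single-drug and combination
cytotoxicity profiles with the Pearson correlation distance
(``d = 1 - r``) and average linkage (UPGMA).  Cutting the dendrogram at
a height or at a fixed number of clusters yields cytotoxicity groups
(labelled ``CGA``, ``CGB``, ... in dendrogram leaf order).  Branch
stability is assessed by an ordinary row bootstrap: conditions are
resampled with replacement, the clustering is repeated, and each branch
of the full-data tree is scored by the fraction of replicate trees that
contain the same set of leaves under some node.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "correlation_distance",
    "average_linkage_cluster",
    "cut_tree",
    "bootstrap_stability",
    "cluster_lines",
    "Dendrogram",
    "GroupAssignment",
]


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation distance between columns.

    ``d(x, y) = 1 - r(x, y)``; symmetric with zero diagonal, range [0, 2].
    A zero-variance column has no defined correlation and is rejected.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least two columns")
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = profiles.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance (degenerate) profiles: {bad}")
    r = np.corrcoef(arr, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled leaves.

    ``linkage`` is a scipy linkage matrix; ``labels[i]`` names leaf i.
    """

    linkage: np.ndarray
    labels: list[str]
    method: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def clades(self) -> list[frozenset]:
        """Leaf set under each internal node, in merge order."""
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(self.n_leaves)}
        out = []
        for step, (a, b, _, _) in enumerate(self.linkage):
            node = self.n_leaves + step
            members[node] = members[int(a)] | members[int(b)]
            out.append(members[node])
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def average_linkage_cluster(dissim: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a symmetric dissimilarity matrix.

    Inter-cluster distance is the unweighted mean over all cross-pair
    dissimilarities.
    """
    arr = np.asarray(dissim, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    labels = list(dissim.columns) if isinstance(dissim, pd.DataFrame) else [str(i) for i in range(arr.shape[0])]
    condensed = squareform(np.ascontiguousarray((arr + arr.T) / 2.0), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=labels)


_GROUP_LETTERS = string.ascii_uppercase


def _group_name(i: int) -> str:
    return f"CG{_GROUP_LETTERS[i]}" if i < 26 else f"CG{i + 1}"


@dataclass
class GroupAssignment:
    """Partition of cell lines into phenotype groups.

    ``groups`` maps line -> group label; ``supports`` maps each internal
    clade (frozenset of lines) of the dendrogram to its bootstrap
    stability fraction.
    """

    groups: pd.Series
    dendrogram: Dendrogram | None = None
    supports: dict[frozenset, float] | None = None
    cut: dict = field(default_factory=dict)

    @property
    def lines(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def multi_member_groups(self, min_lines: int = 2) -> list[str]:
        sizes = self.sizes()
        return [g for g in self.group_names if sizes[g] >= min_lines]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"line": self.groups.index, "group": self.groups.values})
        if self.supports is not None and self.dendrogram is not None:
            parent = []
            clades = self.dendrogram.clades()
            for line in out["line"]:
                # support of the smallest internal clade containing the line
                holding = [c for c in clades if line in c]
                smallest = min(holding, key=len) if holding else None
                parent.append(self.supports.get(smallest, np.nan) if smallest else np.nan)
            out["parent_branch_support"] = parent
        return out


def cut_tree(dend: Dendrogram, height: float | None = None, k: int | None = None) -> GroupAssignment:
    """Cut a dendrogram into groups at a height or into ``k`` clusters.

    Exactly one of ``height``/``k`` must be given.  Group labels are
    assigned in dendrogram leaf order (left-to-right), so the leftmost
    group is ``CGA``.
    """
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    if k is not None:
        if k > dend.n_leaves:
            raise ValueError(f"k={k} exceeds number of leaves ({dend.n_leaves})")
        flat = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    else:
        flat = hierarchy.fcluster(dend.linkage, t=height, criterion="distance")
    raw = pd.Series(flat, index=dend.labels)
    order = dend.leaf_order()
    relabel: dict[int, str] = {}
    for leaf in order:
        c = raw[leaf]
        if c not in relabel:
            relabel[c] = _group_name(len(relabel))
    groups = raw.map(relabel)
    cut = {"height": height} if height is not None else {"k": k}
    return GroupAssignment(groups=groups, dendrogram=dend, cut=cut)


def _bootstrap_distance(arr: np.ndarray, labels, rng: np.random.Generator) -> pd.DataFrame | None:
    idx = rng.integers(0, arr.shape[0], size=arr.shape[0])
    sub = arr[idx]
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        return None  # degenerate resample; skipped
    r = np.corrcoef(sub, rowvar=False)
    d = np.clip(1.0 - (r + r.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def bootstrap_stability(
    profiles: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[frozenset, float]:
    """Row-bootstrap branch supports for the full-data dendrogram.

    Conditions (rows) are resampled with replacement ``n_iter`` times;
    each internal clade of the full-data tree is scored by the fraction
    of replicate trees containing the same leaf set.  Degenerate
    resamples (a line left with zero variance) are redrawn.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 condition rows to bootstrap")
    full = average_linkage_cluster(correlation_distance(profiles))
    clades = [c for c in full.clades() if len(c) < full.n_leaves]  # root always present
    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    arr = profiles.to_numpy(dtype=float)
    done = 0
    while done < n_iter:
        d = _bootstrap_distance(arr, profiles.columns, rng)
        if d is None:
            continue
        rep = average_linkage_cluster(d)
        rep_clades = set(rep.clades())
        for c in clades:
            if c in rep_clades:
                counts[c] += 1
        done += 1
    supports = {c: counts[c] / n_iter for c in clades}
    supports[frozenset(full.labels)] = 1.0
    return supports


def cluster_lines(
    profiles: pd.DataFrame,
    height: float | None = None,
    k: int | None = None,
    n_bootstrap: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> GroupAssignment:
    """Convenience wrapper: distance -> UPGMA -> cut -> optional bootstrap."""
    dend = average_linkage_cluster(correlation_distance(profiles))
    assignment = cut_tree(dend, height=height, k=k)
    if n_bootstrap:
        assignment.supports = bootstrap_stability(profiles, n_iter=n_bootstrap, seed=seed)
    return assignment
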