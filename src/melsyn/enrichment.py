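"""Gene-set / motif over-representation and focal-group rank aggregation.

Over-representation analysis (ORA) scores a query gene list against a
collection of annotated sets (e.g. transcription-factor motif target
sets) with the one-sided hypergeometric upper tail, within a stated gene
universe.  On top of per-group ORA tables the module implements a
focal-group comparison for motifs that are enriched in more than one
group: the aggregate score of a shared motif is

    rank_in_focal_group + (100 - mean rank over the other groups)

so that a low score marks a motif that is highly ranked in the focal
group but poorly ranked elsewhere.  The constant 100 reflects ranking
within top-100 enrichment lists; ranks beyond 100 are permitted but
produce negative contributions and trigger a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .basal import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_overlap",
    "ora",
    "unique_motifs",
    "aggregate_focal_rank",
    "tf_gene_matrix",
    "cluster_overlap_test",
    "OverlapResult",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a scoring universe."""

    sets: dict[str, frozenset]
    universe: frozenset
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        restricted = {}
        for name, members in self.sets.items():
            kept = frozenset(members) & self.universe
            if kept:
                restricted[name] = kept
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(dict(self.sets), frozenset(universe), dict(self.descriptions))


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
            desc[parts[0]] = parts[1]
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe), desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts the overlap between a query of size ``n`` and a set of
    size ``K`` drawn from a universe of size ``N``.
    """
    if not (0 <= k <= min(n, K) <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # survival function evaluated via the log pmf for stability in deep tails
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def ora(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against every set.

    Query genes outside the universe are dropped (count logged).  The
    table is ranked by ascending p with ties broken by descending
    overlap ``k`` then by set id, so ranks are a gap-free 1..m.
    """
    q = frozenset(query)
    dropped = len(q - collection.universe)
    if dropped:
        log.info("ora: dropped %d query genes outside the universe", dropped)
    q &= collection.universe
    if not q:
        raise ValueError("query empty after restriction to the universe")
    N, n = len(collection.universe), len(q)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(q & members)
        rows.append({"set_id": name, "k": k, "K": K, "n": n, "N": N, "p": hypergeometric_overlap(k, n, K, N)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    out = out.sort_values(["p", "k", "set_id"], ascending=[True, False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("set_id")


def _significant(table: pd.DataFrame, cutoff: float, adjusted: bool) -> set[str]:
    col = "q" if adjusted else "p"
    return set(table.index[table[col] <= cutoff])


def unique_motifs(
    tables: Mapping[str, pd.DataFrame],
    focal: str,
    significance_cutoff: float = 0.05,
    adjusted: bool = True,
) -> set[str]:
    """Motifs significant in the focal group's table and in no other group."""
    if focal not in tables:
        raise KeyError(f"focal group {focal!r} has no enrichment table")
    hits = _significant(tables[focal], significance_cutoff, adjusted)
    for group, table in tables.items():
        if group == focal:
            continue
        hits -= _significant(table, significance_cutoff, adjusted)
    return hits


def aggregate_focal_rank(ranks: Mapping[str, Mapping[str, int] | pd.Series], focal: str) -> pd.Series:
    """Aggregate focal-vs-other rank score for motifs shared across groups.

    ``score = rank_focal + (100 - mean(rank_other over the other groups
    containing the motif))``; lower means more focally enriched.  Only
    motifs present in the focal ranking and in at least one other group
    are scored.  The returned Series is sorted ascending by score.
    """
    if focal not in ranks:
        raise KeyError(f"focal group {focal!r} has no rank table")
    focal_ranks = pd.Series(ranks[focal], dtype=float)
    other_tables = {g: pd.Series(r, dtype=float) for g, r in ranks.items() if g != focal}
    scores = {}
    for motif, r_focal in focal_ranks.items():
        others = [tab[motif] for tab in other_tables.values() if motif in tab.index]
        if not others:
            continue
        if r_focal > 100 or any(r > 100 for r in others):
            warnings.warn(f"motif {motif!r}: rank exceeds 100; aggregate contribution is negative", stacklevel=2)
        scores[motif] = float(r_focal + (100.0 - float(np.mean(others))))
    return pd.Series(scores, name="aggregate_score").sort_values(kind="mergesort")


def tf_gene_matrix(
    motif_sets: GeneSetCollection,
    pathway_genes: Iterable[str],
    gene_order: list[str] | None = None,
    motif_order: list[str] | None = None,
) -> pd.DataFrame:
    """Binary genes x motifs membership matrix.

    Entry ``(g, m)`` is 1 iff gene ``g`` belongs to motif target set
    ``m``.  Row/column order can be supplied to match an externally
    clustered fold-change matrix.
    """
    genes = list(gene_order) if gene_order is not None else sorted(set(pathway_genes))
    motifs = list(motif_order) if motif_order is not None else sorted(motif_sets.sets)
    data = np.zeros((len(genes), len(motifs)), dtype=int)
    for j, m in enumerate(motifs):
        members = motif_sets.sets.get(m, frozenset())
        for i, g in enumerate(genes):
            if g in members:
                data[i, j] = 1
    return pd.DataFrame(data, index=genes, columns=motifs)


@dataclass
class OverlapResult:
    k: int
    fraction_pct: float
    p: float


def cluster_overlap_test(cluster_genes: Iterable[str], target_genes: Iterable[str], universe: Iterable[str]) -> OverlapResult:
    """Hypergeometric overlap of a gene cluster with an external target list.

    Returns the overlap count, the overlap as a percentage of the
    cluster, and the upper-tail hypergeometric p-value against the
    supplied universe.
    """
    uni = frozenset(universe)
    cluster = frozenset(cluster_genes) & uni
    targets = frozenset(target_genes) & uni
    k = len(cluster & targets)
    if not cluster:
        raise ValueError("empty cluster after restriction to universe")
    p = hypergeometric_overlap(k, len(cluster), len(targets), len(uni))
    return OverlapResult(k=k, fraction_pct=100.0 * k / len(cluster), p=p)
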