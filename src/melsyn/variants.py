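"""Exome variant filtering and resistance-modifier identification.

The variant workflow mirrors a standard driver-hunting funnel:

1. drop variants already catalogued in dbSNP or 1000 Genomes (keep
   ``novel`` only), then keep nonsynonymous consequences (missense or
   nonsense);
2. intersect with a list of known cancer driver genes;
3. search for genes mutated in every line of exactly one cytotoxicity
   group and nowhere else (group-unique), and genes mutated in exactly
   one line (line-unique).

"Mutated in a line" is defined at the gene level: the line carries any
qualifying variant in the gene.

The module also implements the permutation t-test that asks whether
BRAF-V600E homozygous lines are more drug-sensitive (lower IC50) than
heterozygous lines: a Welch t statistic whose null distribution comes
from random relabelling (exhaustive over all labelings when feasible).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grouping import GroupAssignment

__all__ = [
    "CONSEQUENCES",
    "KNOWN_FLAGS",
    "VARIANT_COLUMNS",
    "validate_variants",
    "filter_novel_nonsynonymous",
    "intersect_driver_genes",
    "group_unique_variants",
    "line_unique_variants",
    "zygosity_permutation_test",
    "PermutationResult",
]

CONSEQUENCES = frozenset({"missense", "nonsense", "synonymous", "splice", "other"})
KNOWN_FLAGS = frozenset({"dbSNP", "1000G", "novel"})
NONSYNONYMOUS = frozenset({"missense", "nonsense"})

VARIANT_COLUMNS = [
    "line", "gene", "chrom", "pos", "ref", "alt",
    "consequence", "known_flag", "damaging", "zygosity",
]


def validate_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and closed vocabularies of a variant table."""
    missing = set(VARIANT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    bad = set(table["consequence"]) - CONSEQUENCES
    if bad:
        raise ValueError(f"unknown consequence values: {sorted(bad)}")
    bad = set(table["known_flag"]) - KNOWN_FLAGS
    if bad:
        raise ValueError(f"unknown known_flag values: {sorted(bad)}")
    if table.duplicated(subset=["line", "chrom", "pos", "alt"]).any():
        raise ValueError("duplicate (line, chrom, pos, alt) records")
    return table


def filter_novel_nonsynonymous(table: pd.DataFrame) -> pd.DataFrame:
    """Keep novel (not dbSNP / 1000 Genomes) missense and nonsense variants."""
    validate_variants(table)
    keep = (table["known_flag"] == "novel") & table["consequence"].isin(NONSYNONYMOUS)
    return table[keep].reset_index(drop=True)


def intersect_driver_genes(table: pd.DataFrame, drivers: Iterable[str]) -> pd.DataFrame:
    """Restrict to variants in known cancer driver genes.

    The result carries ``attrs['n_variants']`` and ``attrs['n_genes']``
    summarizing the funnel stage.
    """
    driver_set = frozenset(drivers)
    out = table[table["gene"].isin(driver_set)].reset_index(drop=True)
    out.attrs["n_variants"] = len(out)
    out.attrs["n_genes"] = int(out["gene"].nunique())
    return out


def _gene_line_incidence(table: pd.DataFrame) -> dict[str, frozenset]:
    return {g: frozenset(sub["line"]) for g, sub in table.groupby("gene")}


def group_unique_variants(table: pd.DataFrame, groups: GroupAssignment) -> dict[str, list[str]]:
    """Genes mutated in every member of one group and in no outside line."""
    incidence = _gene_line_incidence(table)
    out: dict[str, list[str]] = {}
    for group in groups.group_names:
        members = frozenset(groups.members(group))
        if not members:
            raise ValueError(f"group {group!r} has no member lines")
        out[group] = sorted(g for g, lines in incidence.items() if lines == members)
    return out


def line_unique_variants(table: pd.DataFrame) -> dict[str, list[str]]:
    """Genes mutated in exactly one cell line, keyed by that line."""
    incidence = _gene_line_incidence(table)
    out: dict[str, list[str]] = {ln: [] for ln in sorted(table["line"].unique())}
    for gene, lines in sorted(incidence.items()):
        if len(lines) == 1:
            out[next(iter(lines))].append(gene)
    return out


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(vx / len(x) + vy / len(y))
    if denom == 0:
        return 0.0 if mx == my else np.sign(mx - my) * np.inf
    return float((mx - my) / denom)


@dataclass
class PermutationResult:
    t_obs: float
    p: float
    n_hom: int
    n_het: int
    exact: bool
    n_perm: int


def zygosity_permutation_test(
    panel: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    exclude: Iterable[str] = (),
    exhaustive_limit: int = 10000,
) -> PermutationResult:
    """Permutation-based Welch t-test of IC50: homozygous vs heterozygous.

    ``panel`` is indexed by line with columns ``ic50`` and ``zygosity``
    (``hom`` / ``het`` / ``wt``; wild-type lines are not compared).
    Labels are permuted over the pooled lines; when the number of
    distinct labelings is at most ``exhaustive_limit`` the null is
    enumerated exactly (two-sided p = fraction of labelings with
    \\|t\\| >= \\|t_obs\\|), otherwise ``n_perm`` random relabellings are
    drawn and p = (1 + #{\\|t_perm\\| >= \\|t_obs\\|}) / (1 + n_perm).
    """
    sub = panel.drop(index=[ln for ln in exclude if ln in panel.index])
    hom = sub.loc[sub["zygosity"] == "hom", "ic50"].to_numpy(dtype=float)
    het = sub.loc[sub["zygosity"] == "het", "ic50"].to_numpy(dtype=float)
    if len(hom) < 2 or len(het) < 2:
        raise ValueError("need >=2 lines per zygosity class after exclusions")
    pooled = np.concatenate([hom, het])
    n, n_hom = len(pooled), len(hom)
    t_obs = _welch_t(hom, het)
    total = comb(n, n_hom)
    if total <= exhaustive_limit:
        count = 0
        idx = np.arange(n)
        for hom_idx in combinations(idx, n_hom):
            mask = np.zeros(n, dtype=bool)
            mask[list(hom_idx)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= abs(t_obs) - 1e-12:
                count += 1
        return PermutationResult(t_obs, count / total, n_hom, len(het), True, total)
    rng = np.random.default_rng(seed)
    # vectorized random relabellings: first n_hom entries of each shuffled row
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[order]
    xs, ys = perm[:, :n_hom], perm[:, n_hom:]
    mx, my = xs.mean(axis=1), ys.mean(axis=1)
    vx, vy = xs.var(axis=1, ddof=1), ys.var(axis=1, ddof=1)
    denom = np.sqrt(vx / n_hom + vy / (n - n_hom))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = (mx - my) / denom
    t_perm = np.where(denom == 0, 0.0, t_perm)
    count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(t_obs, p, n_hom, len(het), False, n_perm)
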