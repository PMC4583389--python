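"""Basal (untreated) transcriptome screening, clustering and PCA.

The basal analysis asks which genes vary across cell lines before any
treatment, and whether the dominant axes of basal variation align with
drug-response phenotypes:

* a per-probe one-way ANOVA across lines with Benjamini-Hochberg FDR
  control (default 0.1% FDR) selects significantly varying probes;
* the selected probes and the lines are hierarchically clustered with
  the correlation distance / average linkage primitives from
  :mod:`melsyn.grouping`;
* PCA over line-averaged basal profiles decomposes the panel, and
  gene profiles / phenotype scores are screened against component
  scores with Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionExperiment
from .grouping import Dendrogram, average_linkage_cluster, correlation_distance, cut_tree

__all__ = [
    "bh_adjust",
    "oneway_anova_screen",
    "cluster_screened_genes",
    "pca_basal",
    "correlate_genes_with_component",
    "correlate_component_with_phenotype",
    "ComponentDecomposition",
]

log = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    ``q_(i) = min_{j >= i} p_(j) * m / j``, order-preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def oneway_anova_screen(expr: ExpressionExperiment, q_cutoff: float = 0.001) -> pd.DataFrame:
    """Per-probe one-way ANOVA of basal expression across cell lines.

    Returns a DataFrame indexed by probe with columns ``F``, ``p``, ``q``
    and ``selected`` (q <= ``q_cutoff``).  Zero-variance probes are
    excluded before testing (their F statistic is undefined); the count
    is recorded in ``result.attrs['n_zero_variance']``.
    """
    basal = expr.basal()
    meta = basal.samples.loc[list(basal.values.columns)]
    lines = meta["line"].unique()
    if len(lines) < 2:
        raise ValueError("need >=2 cell lines")
    groups = [basal.values[meta.index[meta["line"] == ln]].to_numpy() for ln in lines]
    n_within_df = sum(g.shape[1] for g in groups) - len(lines)
    if n_within_df < 1:
        raise ValueError("no within-line degrees of freedom (need replicates)")
    mat = basal.values.to_numpy()
    keep = mat.var(axis=1) > 0
    n_zero = int((~keep).sum())
    if n_zero:
        log.info("excluding %d zero-variance probes from ANOVA", n_zero)
    F, p = stats.f_oneway(*[g[keep] for g in groups], axis=1)
    out = pd.DataFrame({"F": F, "p": p}, index=basal.values.index[keep])
    # identical values in all samples inside the tested subset produce nan
    out["p"] = out["p"].fillna(1.0)
    out["F"] = out["F"].fillna(0.0)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["selected"] = out["q"] <= q_cutoff
    if expr.feature_to_gene is not None:
        out.insert(0, "gene", expr.feature_to_gene.reindex(out.index))
    out.attrs["n_zero_variance"] = n_zero
    out.attrs["q_cutoff"] = q_cutoff
    return out


def cluster_screened_genes(
    expr: ExpressionExperiment,
    screen: pd.DataFrame,
    height_cutoff: float = 0.41,
) -> tuple[pd.Series, Dendrogram, Dendrogram]:
    """Cluster ANOVA-selected genes and the cell lines.

    Genes (selected probes) are clustered on their line-averaged basal
    profiles with correlation distance and average linkage, then cut at
    ``height_cutoff`` into gene clusters.  Returns
    ``(gene_clusters, gene_dendrogram, line_dendrogram)`` where
    ``gene_clusters`` maps probe -> integer cluster id (1-based, in leaf
    order).
    """
    selected = screen.index[screen["selected"]]
    if len(selected) < 2:
        raise ValueError("need >=2 selected probes to cluster")
    mat = expr.line_means("control").loc[selected]
    gene_dend = average_linkage_cluster(correlation_distance(mat.T))
    line_dend = average_linkage_cluster(correlation_distance(mat))
    assignment = cut_tree(gene_dend, height=height_cutoff)
    # numeric ids in leaf order rather than CG letters (these are gene clusters)
    names = {g: i + 1 for i, g in enumerate(assignment.group_names)}
    clusters = assignment.groups.map(names)
    return clusters, gene_dend, line_dend


@dataclass
class ComponentDecomposition:
    """PCA of the line-averaged basal expression matrix.

    ``scores`` is lines x components, ``loadings`` features x components,
    ``variance_ratio`` the fraction of variance captured per component.
    Component sign is fixed so the largest-magnitude score entry of each
    component is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray

    def score(self, component: int) -> pd.Series:
        """Per-line scores of a 1-based component (PC1 = 1)."""
        return self.scores[f"PC{component}"]


def pca_basal(
    expr: ExpressionExperiment,
    probes: str = "all",
    screen: pd.DataFrame | None = None,
    n_components: int | None = None,
) -> ComponentDecomposition:
    """Centered, unscaled PCA over line-averaged basal expression.

    ``probes='screened'`` restricts the matrix to ANOVA-selected probes
    (``screen`` then required); the default uses every probe.  Values are
    centered per probe but not rescaled: expression is already on a
    common log2 scale.
    """
    mat = expr.line_means("control")
    if probes == "screened":
        if screen is None:
            raise ValueError("probes='screened' requires the screen result")
        mat = mat.loc[screen.index[screen["selected"]]]
    elif probes != "all":
        raise ValueError("probes must be 'all' or 'screened'")
    n_lines = mat.shape[1]
    max_comp = n_lines - 1
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"at most {max_comp} components for {n_lines} lines")
    X = mat.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)  # center per probe across lines
    # columns (lines) are the observations
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = (s[:, None] * Vt).T[:, :n_components]  # lines x comps
    loadings = U[:, :n_components]
    # deterministic sign: largest-|score| entry positive
    for j in range(n_components):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
            loadings[:, j] *= -1
    var = s**2
    names = [f"PC{j + 1}" for j in range(n_components)]
    return ComponentDecomposition(
        scores=pd.DataFrame(scores, index=mat.columns, columns=names),
        loadings=pd.DataFrame(loadings, index=mat.index, columns=names),
        variance_ratio=(var / var.sum())[:n_components],
    )


def correlate_genes_with_component(
    expr: ExpressionExperiment,
    decomp: ComponentDecomposition,
    component: int = 2,
    cutoff: float = 0.8,
) -> tuple[list[str], list[str]]:
    """Genes whose basal profile correlates with a PC beyond +-cutoff.

    Returns ``(positive, negative)`` lists of features with Pearson
    correlation > cutoff and < -cutoff respectively.  Zero-variance
    features cannot be correlated and are skipped (count logged).
    """
    score = decomp.score(component)
    mat = expr.line_means("control")[score.index]
    arr = mat.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    skipped = int((sd == 0).sum())
    if skipped:
        log.info("skipping %d zero-variance genes in PC correlation screen", skipped)
    keep = sd > 0
    centered = arr[keep] - arr[keep].mean(axis=1, keepdims=True)
    z = score.to_numpy() - score.to_numpy().mean()
    r = centered @ z / (np.linalg.norm(centered, axis=1) * np.linalg.norm(z))
    feats = mat.index[keep]
    positive = list(feats[r > cutoff])
    negative = list(feats[r < -cutoff])
    return positive, negative


def correlate_component_with_phenotype(decomp: ComponentDecomposition, phenotype: pd.Series, component: int) -> float:
    """Pearson correlation between a component's scores and a per-line phenotype."""
    score = decomp.score(component)
    missing = set(score.index) - set(phenotype.index)
    if missing:
        raise ValueError(f"phenotype missing lines: {sorted(missing)}")
    pheno = phenotype.loc[score.index].to_numpy(dtype=float)
    return float(np.corrcoef(score.to_numpy(), pheno)[0, 1])
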