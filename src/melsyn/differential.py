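"""Group-wise paired differential response to drug treatment.

Within each cytotoxicity group, every treated sample is matched to its
untreated control (same line, same replicate index) and the
treated-minus-control log2 differences are pooled across the group's
lines.  A one-sample t test of mean difference = 0 per feature, with
Benjamini-Hochberg adjustment across features within the group, yields
per-group differential tables (1% FDR for expression, 5% for RPPA in
the standard configuration).  Probe-level tables are collapsed to gene
level by keeping each gene's minimum-FDR probe.

The module also hosts the RPPA fold-change vs. cytotoxicity screen:
per-epitope Spearman correlations against single-drug cytotoxicity at
each dose, averaged across the doses and ranked ascending (most
anticorrelated epitope first).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .basal import bh_adjust
from .containers import ExpressionExperiment
from .grouping import GroupAssignment

__all__ = [
    "paired_group_ttest",
    "collapse_probes",
    "foldchange_matrix",
    "line_fold_changes",
    "protein_cytotox_correlation",
    "spearman",
]

log = logging.getLogger(__name__)

#: smallest representable positive double; assigned to degenerate
#: zero-variance nonzero differences so they sort first but stay flagged
_MIN_P = float(np.nextafter(0, 1))


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-sample t of rows of a features x pairs matrix."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0
    t = np.zeros(diffs.shape[0])
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # zero-variance rows: no spread at all -> p collapses to its limit
    t[degenerate & (mean != 0)] = np.sign(mean[degenerate & (mean != 0)]) * np.inf
    p[degenerate & (mean != 0)] = _MIN_P
    p[degenerate & (mean == 0)] = 1.0
    return t, p, degenerate


def paired_group_ttest(
    expr: ExpressionExperiment,
    groups: GroupAssignment,
    q_cutoff: float = 0.01,
    min_lines: int = 2,
) -> pd.DataFrame:
    """Paired t-tests of treatment response within each phenotype group.

    Groups with fewer than ``min_lines`` member lines are excluded from
    testing (a single line cannot support a group-level claim; mirrors
    the exclusion of the singleton group from group analyses).  BH
    adjustment is applied across features *within* each group.

    Returns a long DataFrame with columns ``group``, ``feature``,
    ``fold_change`` (mean paired log2 difference), ``t``, ``df``, ``p``,
    ``q``, ``significant``, ``degenerate``.
    """
    tables = []
    analyzed = groups.multi_member_groups(min_lines)
    skipped = [g for g in groups.group_names if g not in analyzed]
    if skipped:
        log.info("groups excluded from paired testing (fewer than %d lines): %s", min_lines, skipped)
    for group in analyzed:
        diffs = expr.paired_differences(lines=groups.members(group))
        if diffs.shape[1] < 2:
            raise ValueError(f"group {group!r} has fewer than 2 treated/control pairs")
        arr = diffs.to_numpy(dtype=float)
        t, p, degenerate = _paired_t(arr)
        if degenerate.any() and (arr.mean(axis=1)[degenerate] != 0).any():
            log.warning(
                "group %s: %d features with zero-variance nonzero differences; "
                "p set to the smallest representable value and flagged degenerate",
                group,
                int(degenerate.sum()),
            )
        tab = pd.DataFrame(
            {
                "group": group,
                "feature": diffs.index,
                "fold_change": arr.mean(axis=1),
                "t": t,
                "df": diffs.shape[1] - 1,
                "p": p,
                "degenerate": degenerate,
            }
        )
        tab["q"] = bh_adjust(tab["p"].to_numpy())
        tab["significant"] = tab["q"] <= q_cutoff
        tables.append(tab)
    out = pd.concat(tables, ignore_index=True)
    out.attrs["q_cutoff"] = q_cutoff
    return out


def collapse_probes(table: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level differential table to gene level.

    For genes with multiple probes the minimum-q probe row is kept; ties
    are broken by larger \\|fold change\\|, then by probe label.  Probes
    absent from the mapping are retained under their own label (count
    logged).
    """
    tab = table.copy()
    genes = probe_to_gene.reindex(tab["feature"])
    unmapped = int(genes.isna().sum())
    if unmapped:
        log.info("collapse_probes: %d probes not in mapping kept under probe labels", unmapped)
    tab["gene"] = np.where(genes.isna(), tab["feature"], genes)
    tab["_absfc"] = -tab["fold_change"].abs()
    tab = tab.sort_values(["group", "gene", "q", "_absfc", "feature"], kind="mergesort")
    out = tab.groupby(["group", "gene"], sort=True).head(1).drop(columns="_absfc")
    out = out.rename(columns={"feature": "probe"}).reset_index(drop=True)
    out.attrs.update(table.attrs)
    return out


def foldchange_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features x groups fold-change matrix for features significant somewhere.

    Returns ``(fold_changes, significant)``: the second frame carries the
    per-cell significance flags used as star annotations.
    """
    key = "gene" if "gene" in table.columns else "feature"
    fc = table.pivot_table(index=key, columns="group", values="fold_change")
    sig = table.pivot_table(index=key, columns="group", values="significant", aggfunc="any").fillna(False)
    keep = sig.any(axis=1)
    fc, sig = fc.loc[keep].sort_index(), sig.loc[keep].sort_index()
    fc = fc.sort_index(axis=1)
    sig = sig[fc.columns]
    return fc, sig.astype(bool)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def line_fold_changes(expr: ExpressionExperiment) -> pd.DataFrame:
    """Per-line mean treated-minus-control log2 fold change (features x lines)."""
    treated = expr.line_means("treated")
    control = expr.line_means("control")
    return (treated - control)[sorted(treated.columns)]


def protein_cytotox_correlation(rppa_fc: pd.DataFrame, cytotox: pd.DataFrame) -> pd.DataFrame:
    """Average Spearman correlation of epitope fold changes with cytotoxicity.

    ``rppa_fc`` is epitopes x lines (log2 fold change under treatment);
    ``cytotox`` is lines x doses of the primary drug (three dose columns
    in the standard design).  Each epitope is correlated with the
    cytotoxicity at every dose separately and the correlations are
    averaged; the table is ranked ascending so the most anticorrelated
    epitope has rank 1.  Epitopes with constant fold change across lines
    have no defined rank correlation: their value is reported as 0 and
    flagged ``degenerate``.
    """
    if cytotox.shape[1] < 1:
        raise ValueError("cytotoxicity table has no dose columns")
    lines = [ln for ln in rppa_fc.columns if ln in cytotox.index]
    if len(lines) < 4:
        raise ValueError("need >=4 lines with both fold-change and cytotoxicity data")
    fc = rppa_fc[lines]
    rows = []
    for epitope, values in fc.iterrows():
        v = values.to_numpy(dtype=float)
        rec: dict = {"epitope": epitope}
        if np.all(v == v[0]):
            for dose in cytotox.columns:
                rec[f"rho@{dose}"] = 0.0
            rec.update(mean_rho=0.0, degenerate=True)
        else:
            rhos = [spearman(v, cytotox.loc[lines, dose].to_numpy()) for dose in cytotox.columns]
            for dose, rho in zip(cytotox.columns, rhos):
                rec[f"rho@{dose}"] = rho
            rec.update(mean_rho=float(np.mean(rhos)), degenerate=False)
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values(["mean_rho", "epitope"], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("epitope")
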