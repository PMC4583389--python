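"""End-to-end orchestration: config, stage sequencing, report bundle.

The pipeline runs the full systems analysis in dependency order:

    synergy -> phenotype grouping -> basal transcriptome ->
    differential response (expression + RPPA) -> motif enrichment ->
    variant analysis / zygosity test

driven by a single YAML-able configuration that either points at input
files or describes a synthetic panel to generate.  All stage thresholds
default to the study's stated values (basal ANOVA 0.1% FDR, expression
paired t 1% FDR, RPPA 5% FDR, gene-cluster height 0.41, PC correlation
cutoff 0.8, 1000 bootstrap iterations).  Every output is a plain-text
table, accompanied by a manifest (config hash, seed, version) that
suffices to reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import basal as basal_mod
from . import differential, enrichment, grouping, io, synergy, synthetic, variants

__version__ = "0.1.0"

log = logging.getLogger(__name__)

STAGES = ("synergy", "grouping", "basal", "differential", "enrichment", "variants")


@dataclass
class StageParams:
    """Analysis thresholds; defaults are the study's stated values."""

    fdr_basal: float = 0.001
    fdr_expression: float = 0.01
    fdr_rppa: float = 0.05
    gene_cluster_height: float = 0.41
    n_groups: int = 5
    group_height: float | None = None  # overrides n_groups when set
    pc_corr_cutoff: float = 0.8
    synergy_component: int = 2
    n_bootstrap: int = 1000
    n_perm: int = 10000
    focal_group: str = "CGC"
    min_group_lines: int = 2
    enrichment_alpha: float = 0.05

    def validate(self) -> None:
        for name in ("fdr_basal", "fdr_expression", "fdr_rppa", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0 < self.pc_corr_cutoff <= 1:
            raise ValueError("pc_corr_cutoff must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Input source (files or synthetic block), stage parameters, output dir."""

    seed: int = 0
    outdir: str | None = None
    inputs: dict | None = None  # paths: expression/metadata/dose_response/...
    synthetic: dict | None = None  # kwargs of synthetic.generate_bundle
    params: StageParams = field(default_factory=StageParams)

    def validate(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' and 'synthetic' must be given")
        self.params.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        params = StageParams(**doc.pop("params", {}))
        return cls(params=params, **doc)

    def to_yaml(self) -> str:
        doc = asdict(self)
        return yaml.safe_dump(doc, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of the scientific content (the output location is excluded)."""
        doc = asdict(self)
        doc.pop("outdir", None)
        return hashlib.sha256(yaml.safe_dump(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Every table the pipeline produces, plus the run manifest."""

    synergy_summary: pd.DataFrame
    synergy_matrices: dict[str, pd.DataFrame]
    groups: grouping.GroupAssignment
    basal_screen: pd.DataFrame
    gene_clusters: pd.Series
    pca: basal_mod.ComponentDecomposition
    pc_gene_lists: tuple[list[str], list[str]]
    pc_synergy_corr: float
    expr_differential: pd.DataFrame
    expr_differential_genes: pd.DataFrame
    foldchange: pd.DataFrame
    foldchange_sig: pd.DataFrame
    rppa_differential: pd.DataFrame
    rppa_cytotox: pd.DataFrame
    enrichment_tables: dict[str, pd.DataFrame]
    unique_motifs: set[str]
    aggregate_scores: pd.Series
    tf_gene: pd.DataFrame
    variant_funnel: dict[str, int]
    group_unique_genes: dict[str, list[str]]
    line_unique_genes: dict[str, list[str]]
    zygosity: variants.PermutationResult | None
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.synergy_summary.to_csv(out / "synergy_summary.tsv", sep="\t")
        for line, mat in self.synergy_matrices.items():
            mat.to_csv(out / f"synergy_matrix_{line}.csv")
        io.write_groups(self.groups, out / "groups.tsv")
        if self.groups.dendrogram is not None:
            io.write_newick(self.groups.dendrogram, out / "groups.nwk")
        self.basal_screen.to_csv(out / "basal_screen.tsv", sep="\t", index_label="probe")
        self.gene_clusters.rename("cluster").to_csv(out / "basal_gene_clusters.tsv", sep="\t", index_label="probe")
        self.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="line")
        self.pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", index_label="probe")
        pos, neg = self.pc_gene_lists
        (out / "pc_genes_positive.txt").write_text("\n".join(pos) + "\n")
        (out / "pc_genes_negative.txt").write_text("\n".join(neg) + "\n")
        self.expr_differential.to_csv(out / "differential_probes.tsv", sep="\t", index=False)
        self.expr_differential_genes.to_csv(out / "differential_genes.tsv", sep="\t", index=False)
        self.foldchange.to_csv(out / "foldchange_matrix.tsv", sep="\t")
        self.foldchange_sig.astype(int).to_csv(out / "foldchange_significant.tsv", sep="\t")
        self.rppa_differential.to_csv(out / "rppa_differential.tsv", sep="\t", index=False)
        self.rppa_cytotox.to_csv(out / "rppa_cytotox_correlation.tsv", sep="\t")
        for group, table in self.enrichment_tables.items():
            table.to_csv(out / f"enrichment_{group}.tsv", sep="\t")
        (out / "unique_motifs.txt").write_text("\n".join(sorted(self.unique_motifs)) + "\n")
        self.aggregate_scores.to_csv(out / "aggregate_motif_scores.tsv", sep="\t", index_label="motif")
        self.tf_gene.to_csv(out / "tf_gene_matrix.tsv", sep="\t")
        with open(out / "variant_gene_lists.json", "w") as fh:
            json.dump(
                {
                    "funnel": self.variant_funnel,
                    "group_unique": self.group_unique_genes,
                    "line_unique": self.line_unique_genes,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        if self.zygosity is not None:
            with open(out / "zygosity_test.json", "w") as fh:
                json.dump(asdict(self.zygosity), fh, indent=2, sort_keys=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    expr = io.read_expression(paths["expression"], paths["expression_metadata"], paths.get("probe_map"))
    panel = io.read_dose_response(paths["dose_response"])
    rppa = io.read_expression(paths["rppa"], paths["rppa_metadata"]) if "rppa" in paths else None
    var = io.read_variants_tsv(paths["variants"]) if "variants" in paths else None
    sets = enrichment.read_gmt(paths["gene_sets"], universe=expr.feature_to_gene) if "gene_sets" in paths else None
    ic50 = io.read_ic50(paths["ic50"]) if "ic50" in paths else None
    drivers = None
    if "drivers" in paths:
        drivers = [g.strip() for g in Path(paths["drivers"]).read_text().splitlines() if g.strip()]
    return expr, panel, rppa, var, sets, ic50, drivers


def validate_inputs(paths: dict) -> list[str]:
    """Schema and consistency diagnostics for a set of input files.

    Returns a list of human-readable problems (empty = clean).
    """
    diagnostics: list[str] = []
    try:
        expr = io.read_expression(paths["expression"], paths["expression_metadata"], paths.get("probe_map"))
        try:
            expr.paired_differences()
        except Exception as exc:  # pairing completeness
            diagnostics.append(f"expression pairing: {exc}")
    except Exception as exc:
        diagnostics.append(f"expression: {exc}")
    try:
        panel = io.read_dose_response(paths["dose_response"])
        panel.profile_matrix()
    except Exception as exc:
        diagnostics.append(f"dose_response: {exc}")
    for key, reader in (("variants", io.read_variants_tsv), ("ic50", io.read_ic50)):
        if key in paths:
            try:
                reader(paths[key])
            except Exception as exc:
                diagnostics.append(f"{key}: {exc}")
    if "rppa" in paths:
        try:
            io.read_expression(paths["rppa"], paths["rppa_metadata"]).paired_differences()
        except Exception as exc:
            diagnostics.append(f"rppa: {exc}")
    return diagnostics


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in dependency order and return the report bundle."""
    config.validate()
    p = config.params
    ss = np.random.SeedSequence(config.seed)
    s_synth, s_boot, s_perm = ss.spawn(3)

    truth = None
    if config.synthetic is not None:
        bundle = synthetic.generate_bundle(seed=s_synth, **config.synthetic)
        truth = bundle.truth
        expr, panel, rppa = bundle.expression, bundle.dose_response, bundle.rppa
        var, sets, ic50, drivers = bundle.variants, bundle.gene_sets, bundle.ic50, bundle.drivers
    else:
        expr, panel, rppa, var, sets, ic50, drivers = _load_inputs(config)

    # --- synergy ---------------------------------------------------------
    matrices = {line: synergy.synergy_matrix(panel, line).scores for line in panel.lines}
    summary = synergy.panel_summary(panel)
    log.info("synergy: scored %d lines", len(matrices))

    # --- phenotype grouping ---------------------------------------------
    profiles = panel.profile_matrix()
    assignment = grouping.cluster_lines(
        profiles,
        height=p.group_height,
        k=None if p.group_height is not None else p.n_groups,
        n_bootstrap=p.n_bootstrap,
        seed=s_boot,
    )
    log.info("grouping: %d lines -> %d groups", len(assignment.lines), len(assignment.group_names))

    # --- basal transcriptome --------------------------------------------
    screen = basal_mod.oneway_anova_screen(expr, q_cutoff=p.fdr_basal)
    log.info("basal screen: %d/%d probes selected at %g FDR", int(screen["selected"].sum()), len(screen), p.fdr_basal)
    gene_clusters, _, _ = basal_mod.cluster_screened_genes(expr, screen, height_cutoff=p.gene_cluster_height)
    pca = basal_mod.pca_basal(expr)
    pc_lists = basal_mod.correlate_genes_with_component(expr, pca, component=p.synergy_component, cutoff=p.pc_corr_cutoff)
    pc_syn = basal_mod.correlate_component_with_phenotype(pca, summary["summary_score"], component=p.synergy_component)

    # --- differential response ------------------------------------------
    diff = differential.paired_group_ttest(expr, assignment, q_cutoff=p.fdr_expression, min_lines=p.min_group_lines)
    genes_table = (
        differential.collapse_probes(diff, expr.feature_to_gene) if expr.feature_to_gene is not None else diff.copy()
    )
    fc, fc_sig = differential.foldchange_matrix(genes_table)
    rppa_diff = differential.paired_group_ttest(rppa, assignment, q_cutoff=p.fdr_rppa, min_lines=p.min_group_lines)
    rppa_fc = differential.line_fold_changes(rppa)
    plx_cyto = pd.DataFrame(
        {f"{panel.drug_a}@{d:g}": {ln: panel.single_means(ln, panel.drug_a)[d] for ln in panel.lines} for d in panel.doses_a}
    )
    rppa_corr = differential.protein_cytotox_correlation(rppa_fc, plx_cyto)
    for group, n in diff.groupby("group")["significant"].sum().items():
        log.info("differential (%s): %d significant probes", group, int(n))

    # --- enrichment ------------------------------------------------------
    key = "gene" if "gene" in genes_table.columns else "feature"
    collection = sets.restrict(expr.feature_to_gene.unique() if expr.feature_to_gene is not None else expr.features)
    tables = {}
    for group in sorted(genes_table["group"].unique()):
        query = genes_table.loc[(genes_table["group"] == group) & genes_table["significant"], key]
        if len(query) == 0:
            continue
        tables[group] = enrichment.ora(query, collection)
    uniq = enrichment.unique_motifs(tables, focal=p.focal_group, significance_cutoff=p.enrichment_alpha)
    # a motif is "present" in a group when it makes that group's significant list
    ranks = {g: t.loc[t["q"] <= p.enrichment_alpha, "rank"] for g, t in tables.items()}
    agg = enrichment.aggregate_focal_rank(ranks, focal=p.focal_group)
    tf_gene = enrichment.tf_gene_matrix(collection, fc.index, motif_order=sorted(collection.sets))
    log.info("enrichment: %d motifs unique to %s, %d shared motifs scored", len(uniq), p.focal_group, len(agg))

    # --- variants --------------------------------------------------------
    funnel = {"input_variants": len(var)}
    novel = variants.filter_novel_nonsynonymous(var)
    funnel["novel_nonsynonymous"] = len(novel)
    in_drivers = variants.intersect_driver_genes(novel, drivers)
    funnel["driver_variants"] = in_drivers.attrs["n_variants"]
    funnel["driver_genes"] = in_drivers.attrs["n_genes"]
    group_unique = variants.group_unique_variants(in_drivers, assignment)
    line_unique = variants.line_unique_variants(in_drivers)
    log.info("variants: funnel %s", funnel)
    zyg = None
    if ic50 is not None:
        exclude = [ln for g in assignment.group_names if len(assignment.members(g)) < p.min_group_lines for ln in assignment.members(g)]
        zyg = variants.zygosity_permutation_test(ic50, n_perm=p.n_perm, seed=s_perm, exclude=exclude)
        log.info("zygosity test: t=%.3f p=%.4f (%s)", zyg.t_obs, zyg.p, "exact" if zyg.exact else "monte-carlo")

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": list(STAGES),
        "synthetic": config.synthetic is not None,
    }
    report = ReportBundle(
        synergy_summary=summary,
        synergy_matrices=matrices,
        groups=assignment,
        basal_screen=screen,
        gene_clusters=gene_clusters,
        pca=pca,
        pc_gene_lists=pc_lists,
        pc_synergy_corr=pc_syn,
        expr_differential=diff,
        expr_differential_genes=genes_table,
        foldchange=fc,
        foldchange_sig=fc_sig,
        rppa_differential=rppa_diff,
        rppa_cytotox=rppa_corr,
        enrichment_tables=tables,
        unique_motifs=uniq,
        aggregate_scores=agg,
        tf_gene=tf_gene,
        variant_funnel=funnel,
        group_unique_genes=group_unique,
        line_unique_genes=line_unique,
        zygosity=zyg,
        manifest=manifest,
    )
    if config.outdir is not None:
        report.write(config.outdir)
    if truth is not None:
        report.manifest["truth_attached"] = True
        report.truth = truth  # type: ignore[attr-defined]
    return report
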