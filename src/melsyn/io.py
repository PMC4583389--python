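"""Plain-text readers and writers for every pipeline format.

Formats (all uncompressed text):

* expression TSV: genes x samples with a header row of sample ids, plus
  a sidecar sample-metadata TSV (``sample``, ``line``, ``treatment``,
  ``replicate``) and an optional probe-map TSV (``probe``, ``gene``);
* dose-response CSV: ``line, dose_a, dose_b, replicate, cytotoxicity``
  (single-drug rows carry 0 for the other dose);
* groups TSV: ``line, group`` plus optional branch support;
* variant TSV with the closed vocabularies of :mod:`melsyn.variants`,
  or a minimal VCF with per-record INFO keys;
* GMT gene sets (see :mod:`melsyn.enrichment`);
* IC50 TSV: ``line, ic50, zygosity``;
* Newick dendrogram export;
* truth YAML for synthetic panels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DOSE_COLUMNS, DoseResponsePanel, ExpressionExperiment
from .grouping import Dendrogram, GroupAssignment
from .synthetic import SyntheticPanelTruth
from .variants import VARIANT_COLUMNS, validate_variants

__all__ = [
    "write_expression", "read_expression",
    "write_dose_response", "read_dose_response",
    "write_groups", "read_groups",
    "write_variants_tsv", "read_variants_tsv",
    "write_variants_vcf", "read_variants_vcf",
    "write_ic50", "read_ic50",
    "write_newick",
    "write_truth", "read_truth",
]


def write_expression(expr: ExpressionExperiment, matrix_path, metadata_path, probe_map_path=None) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="feature")
    meta = expr.samples.loc[list(expr.values.columns)]
    meta.to_csv(metadata_path, sep="\t", index_label="sample")
    if probe_map_path is not None and expr.feature_to_gene is not None:
        expr.feature_to_gene.rename("gene").to_csv(probe_map_path, sep="\t", index_label="probe")


def read_expression(matrix_path, metadata_path, probe_map_path=None) -> ExpressionExperiment:
    values = pd.read_csv(matrix_path, sep="\t", index_col="feature")
    values.index.name = None
    samples = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    samples.index.name = None
    mapping = None
    if probe_map_path is not None and Path(probe_map_path).exists():
        mapping = pd.read_csv(probe_map_path, sep="\t", index_col="probe")["gene"]
        mapping.index.name = None
    return ExpressionExperiment(values=values, samples=samples, feature_to_gene=mapping)


def write_dose_response(panel: DoseResponsePanel, path) -> None:
    panel.data[DOSE_COLUMNS].to_csv(path, index=False)


def read_dose_response(path, drug_a: str = "PLX4720", drug_b: str = "lapatinib") -> DoseResponsePanel:
    data = pd.read_csv(path)
    return DoseResponsePanel(data=data, drug_a=drug_a, drug_b=drug_b)


def write_groups(assignment: GroupAssignment, path) -> None:
    assignment.to_frame().to_csv(path, sep="\t", index=False)


def read_groups(path) -> GroupAssignment:
    frame = pd.read_csv(path, sep="\t")
    groups = pd.Series(frame["group"].to_numpy(), index=frame["line"])
    return GroupAssignment(groups=groups)


def write_variants_tsv(table: pd.DataFrame, path) -> None:
    validate_variants(table)[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return validate_variants(pd.read_csv(path, sep="\t", keep_default_na=False))


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=LINE,Number=1,Type=String,Description="Cell line">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=KNOWN,Number=1,Type=String,Description="Known-variant flag (dbSNP/1000G/novel)">
##INFO=<ID=DMG,Number=1,Type=String,Description="Damaging prediction">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity (hom/het)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(table: pd.DataFrame, path) -> None:
    """Minimal single-column VCF carrying the variant annotations in INFO."""
    validate_variants(table)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for rec in table.itertuples(index=False):
            info = (
                f"LINE={rec.line};GENE={rec.gene};CSQ={rec.consequence};"
                f"KNOWN={rec.known_flag};DMG={rec.damaging};ZYG={rec.zygosity}"
            )
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n")


def read_variants_vcf(path) -> pd.DataFrame:
    """Read the minimal VCF back into the canonical variant table.

    Unknown INFO keys are ignored; records lacking the required keys are
    rejected.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            try:
                rows.append(
                    (
                        info["LINE"], info["GENE"], rec.chrom, rec.pos, rec.ref,
                        rec.alts[0] if rec.alts else ".",
                        info["CSQ"], info["KNOWN"], info["DMG"], info["ZYG"],
                    )
                )
            except KeyError as exc:
                raise ValueError(f"VCF record at {rec.chrom}:{rec.pos} lacks INFO key {exc}") from exc
    return validate_variants(pd.DataFrame(rows, columns=VARIANT_COLUMNS))


def write_ic50(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index_label="line")


def read_ic50(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line")


def write_newick(dend: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(dend.to_newick() + "\n")


def write_truth(truth: SyntheticPanelTruth, path) -> None:
    doc = {
        "line_ids": list(truth.line_ids),
        "true_groups": dict(truth.true_groups),
        "true_synergy": {k: float(v) for k, v in truth.true_synergy.items()},
        "de_genes": {g: {k: int(v) for k, v in d.items()} for g, d in truth.de_genes.items()},
        "hub_gene": truth.hub_gene,
        "hub_targets": list(truth.hub_targets),
        "synergy_genes": list(truth.synergy_genes),
        "enriched_sets": {g: list(v) for g, v in truth.enriched_sets.items()},
        "shared_sets": list(truth.shared_sets),
        "planted_variants": {f"{scope}:{name}": list(v) for (scope, name), v in truth.planted_variants.items()},
        "zygosity": dict(truth.zygosity),
        "true_ic50_shift": float(truth.true_ic50_shift),
        "gene_universe": list(truth.gene_universe),
        "anti_epitope": truth.anti_epitope,
        "rppa_de_epitopes": {g: list(v) for g, v in truth.rppa_de_epitopes.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth(path) -> SyntheticPanelTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    planted = {}
    for key, val in doc["planted_variants"].items():
        scope, name = key.split(":", 1)
        planted[(scope, name)] = tuple(val)
    return SyntheticPanelTruth(
        line_ids=list(doc["line_ids"]),
        true_groups=dict(doc["true_groups"]),
        true_synergy={k: float(v) for k, v in doc["true_synergy"].items()},
        de_genes={g: {k: int(v) for k, v in d.items()} for g, d in doc["de_genes"].items()},
        hub_gene=doc["hub_gene"],
        hub_targets=tuple(doc["hub_targets"]),
        synergy_genes=tuple(doc["synergy_genes"]),
        enriched_sets={g: tuple(v) for g, v in doc["enriched_sets"].items()},
        shared_sets=tuple(doc["shared_sets"]),
        planted_variants=planted,
        zygosity=dict(doc["zygosity"]),
        true_ic50_shift=float(doc["true_ic50_shift"]),
        gene_universe=tuple(doc["gene_universe"]),
        anti_epitope=doc["anti_epitope"],
        rppa_de_epitopes={g: tuple(v) for g, v in doc.get("rppa_de_epitopes", {}).items()},
    )
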