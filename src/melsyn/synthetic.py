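"""Synthetic study panel with planted ground truth.

Every pipeline input can be generated here with known truth, so each
downstream stage is testable without any external download:

* a 12-line cell panel in five cytotoxicity groups (sizes 3/1/4/2/2);
* single-drug dose responses from per-group 4-parameter logistic curves
  (used purely as a generator, never fitted), with combination cells
  built as the Bliss expectation of the singles plus each line's planted
  synergy excess;
* a log2 expression matrix with a paired control/treated design,
  planted group-wise treatment effects, a basal regulatory-hub gene
  cluster (one latent factor) and a second basal factor proportional to
  the planted synergy so one principal component tracks synergy;
* an RPPA-like epitope panel with one epitope whose treatment fold
  change is anticorrelated with single-drug cytotoxicity across lines;
* a variant table with planted group-unique and line-unique driver-gene
  variants over a randomized background;
* GMT-style motif target sets with planted per-group enrichments;
* an IC50 table with BRAF zygosity labels and a planted homozygous
  sensitivity shift.

All generators are deterministic given (parameters, seed); a bundle
draws per-generator child seeds from one integer via
``numpy.random.SeedSequence`` spawning.

Cytotoxicity may be negative: the CGD/CGE groups grow under low-dose
lapatinib, which the grouping stage must resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DoseResponsePanel, ExpressionExperiment
from .synergy import bliss_expected

__all__ = [
    "SyntheticPanelTruth",
    "default_truth",
    "single_drug_effect",
    "generate_dose_response",
    "generate_expression",
    "generate_rppa",
    "generate_variant_table",
    "generate_gene_sets",
    "generate_ic50_table",
    "driver_gene_list",
    "SyntheticBundle",
    "generate_bundle",
    "PLX_DOSES",
    "LAP_DOSES",
]

PLX_DOSES = (125.0, 625.0, 1250.0)
LAP_DOSES = (1000.0, 2000.0, 4000.0)

#: group -> ordered member count of the default panel
GROUP_SIZES = (("CGA", 3), ("CGB", 1), ("CGC", 4), ("CGD", 2), ("CGE", 2))

#: per (group, drug) 4PL parameters (bottom, top, ec50 nM, hill).
#: CGA: strong PLX dose dependence, flat moderate lapatinib.
#: CGB: near-complete PLX resistance (the DM331-like singleton).
#: CGC: resistant to each single agent (synergy carried by the combo).
#: CGD/CGE: net growth under low-dose lapatinib (negative cytotoxicity).
_FOUR_PL = {
    ("CGA", "PLX4720"): (0.05, 0.90, 400.0, 1.5),
    ("CGA", "lapatinib"): (0.14, 0.18, 2000.0, 1.0),
    ("CGB", "PLX4720"): (0.00, 0.08, 800.0, 1.0),
    ("CGB", "lapatinib"): (0.05, 0.10, 3000.0, 1.0),
    ("CGC", "PLX4720"): (0.05, 0.28, 900.0, 1.2),
    ("CGC", "lapatinib"): (0.02, 0.20, 3500.0, 1.2),
    ("CGD", "PLX4720"): (0.10, 0.45, 700.0, 1.3),
    ("CGD", "lapatinib"): (-0.20, 0.15, 3000.0, 2.0),
    ("CGE", "PLX4720"): (0.08, 0.30, 900.0, 1.0),
    ("CGE", "lapatinib"): (-0.28, 0.05, 3500.0, 2.5),
}

#: per-line planted Bliss excess.  CGA/CGB are the non-synergistic lines
#: (exactly 0); CGC carries strong synergy, CGD mild synergy, CGE mild
#: antagonism, so line ranking by synergy is well defined.
_SYNERGY = {
    "CGA": (0.0, 0.0, 0.0),
    "CGB": (0.0,),
    "CGC": (0.30, 0.26, 0.22, 0.18),
    "CGD": (0.08, 0.06),
    "CGE": (-0.06, -0.04),
}

#: BRAF V600E zygosity of the default panel (4/12 homozygous; the
#: CGB singleton is the homozygous-but-resistant outlier).
_ZYGOSITY_HOM = ("MEL01", "MEL04", "MEL06", "MEL07")


@dataclass
class SyntheticPanelTruth:
    """Planted ground truth of a synthetic study panel."""

    line_ids: list[str]
    true_groups: dict[str, str]
    true_synergy: dict[str, float]
    de_genes: dict[str, dict[str, int]]  # group -> gene -> effect sign
    hub_gene: str
    hub_targets: tuple[str, ...]
    synergy_genes: tuple[str, ...]
    enriched_sets: dict[str, tuple[str, ...]]
    shared_sets: tuple[str, ...]
    planted_variants: dict[tuple[str, str], tuple[str, str, str]]  # (scope, name) -> (gene, consequence, damaging)
    zygosity: dict[str, str]
    true_ic50_shift: float
    gene_universe: tuple[str, ...]
    anti_epitope: str = "EP001"
    rppa_de_epitopes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for line in self.line_ids:
            if line not in self.true_groups:
                raise ValueError(f"line {line!r} has no group")
            seen.append(line)
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate line ids")
        for line, s in self.true_synergy.items():
            if self.true_groups[line] in ("CGA", "CGB") and s != 0.0:
                raise ValueError("non-synergistic lines must have planted excess 0")

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for g in self.true_groups.values():
            if g not in out:
                out.append(g)
        return out

    def members(self, group: str) -> list[str]:
        return [ln for ln in self.line_ids if self.true_groups[ln] == group]

    @property
    def analyzed_groups(self) -> list[str]:
        """Groups with at least two lines (the singleton is excluded)."""
        return [g for g in self.groups if len(self.members(g)) >= 2]


def _gene_names(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def default_truth(
    n_genes: int = 2000,
    de_per_group: int = 150,
    n_hub_targets: int = 72,
    n_synergy_genes: int = 40,
) -> SyntheticPanelTruth:
    """The default 12-line / 5-group study panel with planted signal.

    The hub cluster has 73 genes (hub + 72 targets), mirroring the size
    of the regulatory-hub gene cluster the basal analysis should find.
    """
    lines, groups = [], {}
    i = 1
    for group, size in GROUP_SIZES:
        for _ in range(size):
            ln = f"MEL{i:02d}"
            lines.append(ln)
            groups[ln] = group
            i += 1
    synergy = {}
    for group, values in _SYNERGY.items():
        for ln, s in zip([l for l in lines if groups[l] == group], values):
            synergy[ln] = float(s)

    genes = _gene_names(n_genes)
    hub_gene = genes[0]
    hub_targets = tuple(genes[1 : 1 + n_hub_targets])
    syn_genes = tuple(genes[1 + n_hub_targets : 1 + n_hub_targets + n_synergy_genes])
    cursor = 1 + n_hub_targets + n_synergy_genes
    de: dict[str, dict[str, int]] = {}
    for group, size in GROUP_SIZES:
        if size < 2:
            continue  # the singleton group is excluded from group testing
        block = genes[cursor : cursor + de_per_group]
        if len(block) < de_per_group:
            raise ValueError("n_genes too small for the planted signal genes")
        de[group] = {g: (1 if j % 2 == 0 else -1) for j, g in enumerate(block)}
        cursor += de_per_group

    planted_variants = {
        ("group", "CGD"): ("ALK", "missense", "damaging"),
        ("group", "CGE"): ("EZH1", "missense", "damaging"),
    }
    for ln in lines:
        cons = "nonsense" if int(ln[-2:]) % 3 == 0 else "missense"
        planted_variants[("line", ln)] = (f"UNIQ_{ln}", cons, "possibly")

    zygosity = {ln: ("hom" if ln in _ZYGOSITY_HOM else "het") for ln in lines}
    analyzed = [g for g, size in GROUP_SIZES if size >= 2]
    return SyntheticPanelTruth(
        line_ids=lines,
        true_groups=groups,
        true_synergy=synergy,
        de_genes=de,
        hub_gene=hub_gene,
        hub_targets=hub_targets,
        synergy_genes=syn_genes,
        enriched_sets={g: (f"MOTIF_{g}",) for g in analyzed},
        shared_sets=("MOTIF_SHARED_CGA", "MOTIF_SHARED_CGD"),
        planted_variants=planted_variants,
        zygosity=zygosity,
        true_ic50_shift=0.6,
        gene_universe=tuple(genes),
        rppa_de_epitopes={},
    )


def single_drug_effect(truth: SyntheticPanelTruth, line: str, drug: str, dose: float) -> float:
    """Noise-free single-drug cytotoxicity from the line's group 4PL curve."""
    bottom, top, ec50, hill = _FOUR_PL[(truth.true_groups[line], drug)]
    return float(bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill))


def generate_dose_response(
    truth: SyntheticPanelTruth,
    noise_sd: float = 0.03,
    n_reps: int = 2,
    seed: int | np.random.SeedSequence = 0,
    doses_a: tuple[float, ...] = PLX_DOSES,
    doses_b: tuple[float, ...] = LAP_DOSES,
) -> DoseResponsePanel:
    """Cytotoxicity panel: 3+3 single doses and the 3x3 combination grid.

    Combination cell (i, j) is the Bliss expectation of the two
    noise-free singles plus the line's planted excess, plus Gaussian
    noise; replicates differ only by noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    if np.any(np.diff(doses_a) <= 0) or np.any(np.diff(doses_b) <= 0):
        raise ValueError("dose vectors must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for line in truth.line_ids:
        sa = {d: single_drug_effect(truth, line, "PLX4720", d) for d in doses_a}
        sb = {d: single_drug_effect(truth, line, "lapatinib", d) for d in doses_b}
        excess = truth.true_synergy[line]
        for rep in range(1, n_reps + 1):
            for d in doses_a:
                rows.append((line, d, 0.0, rep, sa[d] + rng.normal(0, noise_sd)))
            for d in doses_b:
                rows.append((line, 0.0, d, rep, sb[d] + rng.normal(0, noise_sd)))
            for da in doses_a:
                for db in doses_b:
                    base = bliss_expected(sa[da], sb[db]) + excess
                    rows.append((line, da, db, rep, base + rng.normal(0, noise_sd)))
    data = pd.DataFrame(rows, columns=["line", "dose_a", "dose_b", "replicate", "cytotoxicity"])
    return DoseResponsePanel(data=data)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _latent_factors(truth: SyntheticPanelTruth, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-line basal factors: hub factor (orthogonal to synergy) and synergy factor."""
    syn = np.array([truth.true_synergy[ln] for ln in truth.line_ids])
    f2 = _standardize(syn) if syn.std() > 0 else np.zeros_like(syn)
    raw = rng.normal(size=len(truth.line_ids))
    if syn.std() > 0:
        raw = raw - (raw @ f2) / (f2 @ f2) * f2  # keep the factors identifiable
    f1 = _standardize(raw)
    return f1, f2


def generate_expression(
    truth: SyntheticPanelTruth,
    n_genes: int | None = None,
    effect_size: float = 2.0,
    within_sd: float = 0.12,
    n_reps: int = 2,
    seed: int | np.random.SeedSequence = 0,
    hub_strength: float = 1.0,
    synergy_strength: float = 0.8,
) -> ExpressionExperiment:
    """Paired control/treated log2 expression with planted structure.

    Control samples scatter around per-line baselines built from two
    latent factors (hub cluster, synergy); treated samples add the
    planted signed ``effect_size`` to the line's group DE genes.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_reps < 2:
        raise ValueError("need >=2 replicates per line and condition")
    genes = list(truth.gene_universe)
    if n_genes is not None:
        if n_genes < len(genes):
            planted = (
                {truth.hub_gene}
                | set(truth.hub_targets)
                | set(truth.synergy_genes)
                | {g for d in truth.de_genes.values() for g in d}
            )
            if n_genes < len(planted):
                raise ValueError("fewer genes requested than planted signal genes")
        genes = _gene_names(n_genes) if n_genes > len(genes) else genes[:n_genes]
    rng = np.random.default_rng(seed)
    f1, f2 = _latent_factors(truth, rng)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    mu = rng.normal(8.0, 1.0, size=n)
    l1 = np.zeros(n)
    for g in (truth.hub_gene, *truth.hub_targets):
        if g in idx:
            l1[idx[g]] = hub_strength
    l2 = np.zeros(n)
    for j, g in enumerate(truth.synergy_genes):
        if g in idx:
            l2[idx[g]] = synergy_strength * (1 if j % 2 == 0 else -1)
    effect = np.zeros((n, len(truth.line_ids)))
    for group in truth.groups:
        signs = truth.de_genes.get(group, {})
        for g, sign in signs.items():
            if g in idx:
                for li, ln in enumerate(truth.line_ids):
                    if truth.true_groups[ln] == group:
                        effect[idx[g], li] = sign * effect_size

    columns, meta = [], []
    blocks = []
    for li, line in enumerate(truth.line_ids):
        base = mu + l1 * f1[li] + l2 * f2[li]
        for treatment in ("control", "treated"):
            shift = effect[:, li] if treatment == "treated" else 0.0
            for rep in range(1, n_reps + 1):
                columns.append(f"{line}_{treatment}_{rep}")
                meta.append((line, treatment, rep))
                blocks.append(base + shift + rng.normal(0, within_sd, size=n))
    values = pd.DataFrame(np.column_stack(blocks), index=genes, columns=columns)
    samples = pd.DataFrame(meta, columns=["line", "treatment", "replicate"], index=columns)
    probe_map = pd.Series(genes, index=genes, name="gene")
    return ExpressionExperiment(values=values, samples=samples, feature_to_gene=probe_map)


def generate_rppa(
    truth: SyntheticPanelTruth,
    n_epitopes: int = 132,
    n_reps: int = 2,
    within_sd: float = 0.10,
    de_effect: float = 0.8,
    de_per_group: int = 8,
    anti_strength: float = 1.2,
    seed: int | np.random.SeedSequence = 0,
) -> ExpressionExperiment:
    """RPPA-like log2 epitope panel with a planted anticorrelated epitope.

    Epitope ``truth.anti_epitope`` responds to treatment with a per-line
    fold change proportional to minus the line's (noise-free) average
    single-drug cytotoxicity of the primary drug, so it is recovered as
    the most anticorrelated epitope by the fold-change screen.  Each
    analyzed group additionally gets ``de_per_group`` planted
    differential epitopes (mostly down-regulated).
    """
    epitopes = [f"EP{i:03d}" for i in range(1, n_epitopes + 1)]
    needed = 1 + de_per_group * len(truth.analyzed_groups)
    if n_epitopes < needed:
        raise ValueError("fewer epitopes requested than planted signal epitopes")
    rng = np.random.default_rng(seed)
    cyto = np.array(
        [np.mean([single_drug_effect(truth, ln, "PLX4720", d) for d in PLX_DOSES]) for ln in truth.line_ids]
    )
    anti_fc = -anti_strength * _standardize(cyto)
    mu = rng.normal(0.0, 0.5, size=n_epitopes)

    idx = {e: i for i, e in enumerate(epitopes)}
    de_map: dict[str, tuple[str, ...]] = {}
    cursor = 1  # EP001 is the anticorrelated epitope
    fc = np.zeros((n_epitopes, len(truth.line_ids)))
    fc[idx[truth.anti_epitope]] = anti_fc
    for group in truth.analyzed_groups:
        block = epitopes[cursor : cursor + de_per_group]
        de_map[group] = tuple(block)
        cursor += de_per_group
        members = [li for li, ln in enumerate(truth.line_ids) if truth.true_groups[ln] == group]
        for j, e in enumerate(block):
            sign = 1.0 if j % 4 == 3 else -1.0  # majority down-regulated
            for li in members:
                fc[idx[e], li] = sign * de_effect
    truth.rppa_de_epitopes = de_map

    columns, meta, blocks = [], [], []
    for li, line in enumerate(truth.line_ids):
        for treatment in ("control", "treated"):
            shift = fc[:, li] if treatment == "treated" else 0.0
            for rep in range(1, n_reps + 1):
                columns.append(f"{line}_{treatment}_{rep}")
                meta.append((line, treatment, rep))
                blocks.append(mu + shift + rng.normal(0, within_sd, size=n_epitopes))
    values = pd.DataFrame(np.column_stack(blocks), index=epitopes, columns=columns)
    samples = pd.DataFrame(meta, columns=["line", "treatment", "replicate"], index=columns)
    return ExpressionExperiment(values=values, samples=samples, feature_to_gene=None)


def driver_gene_list(truth: SyntheticPanelTruth, n_decoys: int = 40) -> list[str]:
    """Known-driver gene list: planted resistance modifiers plus decoys."""
    planted = sorted({gene for gene, _, _ in truth.planted_variants.values()})
    decoys = [f"DRV{i:03d}" for i in range(1, n_decoys + 1)]
    return sorted(set(planted) | set(decoys) | {"BRAF"})


def generate_variant_table(
    truth: SyntheticPanelTruth,
    n_background_variants: int = 2000,
    n_background_genes: int = 300,
    n_driver_background: int = 150,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Variant table with planted group-/line-unique driver variants.

    Background variants scatter over non-driver genes with randomized
    known-variant flags and consequence classes.  Background variants
    inside driver-list genes are always dbSNP/1000G-flagged (drivers are
    well-catalogued genes), so the novel-nonsynonymous driver funnel
    retains exactly the planted variants.
    """
    rng = np.random.default_rng(seed)
    lines = truth.line_ids
    bg_genes = [f"BG{i:04d}" for i in range(1, n_background_genes + 1)]
    decoy_drivers = [g for g in driver_gene_list(truth) if g.startswith("DRV")]
    rows = []
    pos = 10_000  # globally unique position counter keeps records distinct

    def add(line, gene, consequence, known_flag, damaging, zygosity):
        nonlocal pos
        pos += 7
        chrom = f"chr{1 + (pos % 22)}"
        ref, alt = "A", "T"
        rows.append((line, gene, chrom, pos, ref, alt, consequence, known_flag, damaging, zygosity))

    # BRAF V600E-like record for every line (catalogued variant)
    for line in lines:
        add(line, "BRAF", "missense", "dbSNP", "damaging", truth.zygosity[line])

    # planted group-unique variants: same gene mutated in every member line
    for (scope, name), (gene, consequence, damaging) in sorted(truth.planted_variants.items()):
        if scope == "group":
            for line in truth.members(name):
                add(line, gene, consequence, "novel", damaging, "het")
        else:
            add(name, gene, consequence, "novel", damaging, "het")

    flags = np.array(["dbSNP", "1000G", "novel"])
    consequences = np.array(["missense", "synonymous", "nonsense", "splice", "other"])
    damaging_vals = np.array(["damaging", "possibly", "benign", "NA"])
    for _ in range(n_background_variants):
        add(
            lines[rng.integers(len(lines))],
            bg_genes[rng.integers(len(bg_genes))],
            consequences[rng.integers(len(consequences))],
            flags[np.searchsorted([0.55, 0.70, 1.0], rng.random())],
            damaging_vals[rng.integers(len(damaging_vals))],
            "hom" if rng.random() < 0.2 else "het",
        )
    for _ in range(n_driver_background):
        add(
            lines[rng.integers(len(lines))],
            decoy_drivers[rng.integers(len(decoy_drivers))],
            consequences[rng.integers(len(consequences))],
            "dbSNP" if rng.random() < 0.8 else "1000G",
            damaging_vals[rng.integers(len(damaging_vals))],
            "hom" if rng.random() < 0.2 else "het",
        )
    from .variants import VARIANT_COLUMNS, validate_variants

    return validate_variants(pd.DataFrame(rows, columns=VARIANT_COLUMNS))


def generate_gene_sets(
    truth: SyntheticPanelTruth,
    n_sets: int = 100,
    set_size_range: tuple[int, int] = (25, 60),
    seed: int | np.random.SeedSequence = 0,
    overlap_size: int = 25,
) -> "GeneSetCollection":
    """Motif-target style gene sets with planted per-group enrichments.

    One planted set per analyzed group overlaps that group's DE genes
    far above chance; two shared sets overlap the focal group's DE genes
    *and* one other group's; remaining decoy sets are uniform draws from
    the universe.
    """
    from .enrichment import GeneSetCollection

    universe = list(truth.gene_universe)
    if not universe:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}

    def planted_set(name: str, source_genes: list[str], n_source: int) -> None:
        size = int(rng.integers(lo, hi + 1))
        core = list(rng.choice(source_genes, size=min(n_source, len(source_genes)), replace=False))
        fill = [g for g in rng.choice(universe, size=size + len(core), replace=False) if g not in core]
        sets[name] = frozenset(core + fill[: max(size - len(core), 0)])
        desc[name] = "planted"

    for group in truth.analyzed_groups:
        planted_set(f"MOTIF_{group}", sorted(truth.de_genes[group]), overlap_size)
    focal_de = sorted(truth.de_genes.get("CGC", {}))
    for name, other in zip(truth.shared_sets, ("CGA", "CGD")):
        both = list(rng.choice(focal_de, size=overlap_size // 2, replace=False)) + list(
            rng.choice(sorted(truth.de_genes[other]), size=overlap_size // 2, replace=False)
        )
        size = int(rng.integers(lo, hi + 1))
        fill = [g for g in rng.choice(universe, size=size + len(both), replace=False) if g not in both]
        sets[name] = frozenset(both + fill[: max(size - len(both), 0)])
        desc[name] = "planted-shared"

    i = 1
    while len(sets) < n_sets:
        name = f"M{i:04d}"
        i += 1
        if name in sets:
            continue
        size = int(rng.integers(lo, hi + 1))
        sets[name] = frozenset(rng.choice(universe, size=size, replace=False))
        desc[name] = "decoy"
    return GeneSetCollection(sets=sets, universe=frozenset(universe), descriptions=desc)


def generate_ic50_table(
    truth: SyntheticPanelTruth,
    noise_sd: float = 0.15,
    base_log10: float = 2.2,
    outlier_shift: float = 1.5,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """IC50 (nM) table with zygosity labels and a planted hom/het shift.

    Heterozygous lines sit ``truth.true_ic50_shift`` log10 units above
    homozygous lines; the CGB singleton is the homozygous-but-resistant
    outlier (excluded from the zygosity test by default downstream).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for line in truth.line_ids:
        z = truth.zygosity[line]
        log10 = base_log10 + (truth.true_ic50_shift if z == "het" else 0.0)
        if truth.true_groups[line] == "CGB":
            log10 += outlier_shift
        rows.append((line, float(10 ** (log10 + rng.normal(0, noise_sd))), z))
    return pd.DataFrame(rows, columns=["line", "ic50", "zygosity"]).set_index("line")


@dataclass
class SyntheticBundle:
    """Every pipeline input generated from one truth and one seed."""

    truth: SyntheticPanelTruth
    dose_response: DoseResponsePanel
    expression: ExpressionExperiment
    rppa: ExpressionExperiment
    variants: pd.DataFrame
    gene_sets: "GeneSetCollection"
    ic50: pd.DataFrame
    drivers: list[str]


def generate_bundle(
    seed: int | np.random.SeedSequence = 0,
    truth: SyntheticPanelTruth | None = None,
    noise_sd: float = 0.03,
    n_reps: int = 2,
    expression_params: dict | None = None,
    rppa_params: dict | None = None,
    variant_params: dict | None = None,
    gene_set_params: dict | None = None,
    ic50_params: dict | None = None,
) -> SyntheticBundle:
    """Generate all six inputs with child seeds split from one integer."""
    if truth is None:
        truth = default_truth()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_dose, s_expr, s_rppa, s_var, s_sets, s_ic50 = ss.spawn(6)
    return SyntheticBundle(
        truth=truth,
        dose_response=generate_dose_response(truth, noise_sd=noise_sd, n_reps=n_reps, seed=s_dose),
        expression=generate_expression(truth, n_reps=n_reps, seed=s_expr, **(expression_params or {})),
        rppa=generate_rppa(truth, n_reps=n_reps, seed=s_rppa, **(rppa_params or {})),
        variants=generate_variant_table(truth, seed=s_var, **(variant_params or {})),
        gene_sets=generate_gene_sets(truth, seed=s_sets, **(gene_set_params or {})),
        ic50=generate_ic50_table(truth, seed=s_ic50, **(ic50_params or {})),
        drivers=driver_gene_list(truth),
    )
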