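# Methods

This note documents the statistical procedures, the synthetic study
panel the package ships as its test bed, the numerical conventions, and
the design choices that were genuinely open.

## Bliss synergy

Cytotoxicity is the fractional reduction in viable signal against
vehicle control; negative values mean net growth under drug.  For two
drugs with single-agent cytotoxicities `c_a`, `c_b`, Bliss independence
predicts a combination effect `1 − (1 − c_a)(1 − c_b)` — the two "kill"
events treated as independent probabilities.  The synergy score of an
observed combination cell is the observed cytotoxicity minus this
expectation.

Conventions: single-agent values are clamped to `[0, 1]` before
entering the expectation, because the Bliss formula is defined on
probabilities; the observed combination value enters the score
unclamped, because combination kill beyond the single-agent bounds is
signal, not a model violation.  Replicates are averaged before scoring.
The per-line scalar synergy score is the arithmetic mean over the 3×3
grid — the simplest summary consistent with treating all nine dose
pairs as exchangeable; a maximum or a dose-weighted mean would
emphasize different regions of the surface and is easy to substitute.

IC50 estimation (used only for synthetic panels; real-panel IC50s are
consumed as inputs) is linear interpolation in log10 dose between the
two doses bracketing cytotoxicity 0.5; if 0.5 is never bracketed the
estimate is refused rather than extrapolated.

## Phenotype grouping

Lines are clustered on their 15-condition cytotoxicity profiles
(3 doses × 2 single drugs + 3×3 combinations) with Pearson correlation
distance `d = 1 − r` (range `[0, 2]`) and unweighted average linkage
(UPGMA).  Correlation distance compares response *shapes*, so a
uniformly more sensitive line can still cluster with lines sharing its
dose-response pattern — the behaviour the grouping is meant to capture.
The tree can be cut at a height or into `k` groups; group labels are
assigned left-to-right in dendrogram leaf order (`CGA`, `CGB`, ...), so
labels are reproducible but are in general a *permutation* of any
externally defined names — downstream comparisons should match
partitions, not label strings.

Branch stability is an ordinary single-scale row bootstrap: conditions
are resampled with replacement, the clustering is repeated, and each
internal clade of the full-data tree is scored by the fraction of
replicate trees containing the same leaf set (default 1000 iterations).
This is a deliberate simplification of multiscale bootstrap machinery:
it answers the same qualitative question (which branches survive
perturbation of the conditions) with a directly testable estimator.
Degenerate resamples that leave a line with zero variance are redrawn.

## Basal transcriptome

The ANOVA screen runs a per-probe one-way F test of basal (untreated)
expression across lines, with replicates as within-line observations,
and BH step-up control at 0.1% FDR.  Zero-variance probes have an
undefined F and are excluded up front.  BH adjustment is implemented
literally — `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1 — and is checked
against an independent loop oracle in the tests.

Gene clustering reuses the grouping primitives on line-averaged
profiles of the selected probes, with a default height cut of 0.41.

PCA operates on the line-averaged basal matrix, centered per probe and
*not* rescaled (log2 expression is already on a common scale).
Components are computed by SVD; each component's sign is fixed so its
largest-magnitude score is positive.  By default all probes enter the
PCA; restricting to screen-selected probes is exposed as an option
since either convention is defensible.  Gene-vs-component and
phenotype-vs-component screens use Pearson correlation (the natural
companion of a linear decomposition); Spearman is reserved for the
RPPA–cytotoxicity analysis where rank robustness matters.

## Differential response

Pairing key: (line, replicate index).  Within each phenotype group the
treated-minus-control log2 differences are pooled over all pairs of all
member lines and each feature gets a one-sample t test of mean
difference 0; BH is applied across features *within* each group, at 1%
FDR for expression and 5% for RPPA.  Groups with fewer than two member
lines are excluded from group-wise testing — a single line cannot
support a group-level claim (the default panel's singleton group plays
the role of the resistant outlier line).  Zero-variance nonzero
difference rows are t = ±∞ in the limit; they are assigned the smallest
representable positive p, flagged `degenerate`, and logged.  The plain
paired t is used rather than a variance-moderated (empirical-Bayes)
statistic; moderation is a documented extension point, and with the
replicate numbers in scope the plain test is well calibrated (the
acceptance suite verifies a 5% type-I error at α = 0.05).

Probe collapse keeps, per gene, the probe with the smallest FDR; ties
break by larger |fold change|, then probe label.  The fold-change
matrix shows every feature significant in at least one group, with all
groups' fold changes and per-cell significance flags.

The RPPA screen correlates each epitope's per-line fold change with
single-drug cytotoxicity at each of the three doses separately
(Spearman mid-rank correlation), reports the arithmetic mean of the
three coefficients, and ranks ascending so the most anticorrelated
epitope — the candidate adaptive-response marker — is rank 1.  Constant
fold-change vectors have no defined rank correlation and are reported
as 0 with a degenerate flag.

## Motif enrichment

Over-representation uses the one-sided hypergeometric upper tail
`P(X ≥ k)` for an overlap of `k` between a query of `n` and a set of
`K` in a universe of `N`, evaluated through the log survival function.
The universe is a free parameter with no verifiable default — the
package uses all genes scoreable on the platform (every gene in the
expression matrix), restricted per collection, and exposes it in
configuration.  Sets are ranked by ascending p, ties broken by
descending overlap then set id, giving gap-free ranks.

Focal-group aggregation scores motifs enriched in the focal group *and*
at least one other group as
`rank_focal + (100 − mean(rank_other))`, lower = more focally enriched.
The constant 100 reflects ranking within top-100 enrichment lists;
ranks above 100 are permitted (negative contribution) with a warning.
"Present in a group" means present in that group's significant list
(BH q ≤ 0.05 by default), not merely ranked.  The rule converting
aggregate scores to a final motif shortlist is not uniquely determined;
the package reports the full ascending score table rather than
hard-coding a cutoff.

## Variant analysis

The funnel is: keep `novel` (absent from dbSNP and 1000 Genomes)
variants with `missense`/`nonsense` consequence; intersect with a
driver-gene list; then search for genes mutated in every line of
exactly one group and no other line (group-unique) and genes mutated in
exactly one line (line-unique).  "Mutated in a line" is gene-level
presence of any qualifying variant, since the outputs are gene lists.
The two filters commute, and counts are reported at every stage so the
funnel is auditable.

The zygosity test compares IC50 values of homozygous vs heterozygous
BRAF-V600E lines with a Welch t statistic (robust to unequal class
sizes and variances) whose null is generated by relabelling: exhaustive
enumeration when the number of distinct labelings is ≤ 10,000 (p =
fraction of labelings with |t| at least the observed), otherwise
Monte Carlo with the add-one correction `p = (1 + #{|t*| ≥ |t|})/(1 + B)`,
so p is never 0 and never exceeds 1.  The resistant outlier line is
excluded by default.

## The synthetic study panel

The generator is first-class code: it defines the conditions under
which every claim of the test suite holds.

* **Panel**: 12 lines in five groups of sizes 3/1/4/2/2.  Group
  phenotypes follow the biology the grouping must resolve: group A is
  PLX4720-dose-dependent with flat moderate lapatinib response; B is
  the near-totally resistant singleton; C resists both single agents
  and responds only to the combination; D and E *grow* under low-dose
  lapatinib (negative cytotoxicity), D with moderate PLX response.
* **Dose response**: per-group 4-parameter logistic curves in log dose
  (a generator only, never fitted) at the standard doses (125/625/1250
  nM primary drug, 1000/2000/4000 nM secondary); combination cells are
  the Bliss expectation of the noise-free singles plus the line's
  planted excess; Gaussian noise sd 0.03 (recovery claims are made for
  sd ≤ 0.05); duplicate replicates.
* **Planted synergy**: group C lines 0.18–0.30, D mildly positive
  (0.06–0.08), E mildly antagonistic (−0.04 to −0.06), A and B exactly
  0.  Giving D and E small nonzero excesses keeps the planted ranking
  well defined: with 8 of 12 lines tied at exactly zero, the maximum
  achievable rank correlation of any estimator is √(101/143) ≈ 0.84,
  so a rank-recovery criterion of ρ ≥ 0.9 would be structurally
  unattainable rather than informative.
* **Expression**: 2000 genes, log2 scale, baseline N(8, 1); two basal
  line-level latent factors — a hub factor loading on a planted 73-gene
  regulatory-hub cluster (hub + 72 targets, loading 1.0) and a synergy
  factor equal to the standardized planted synergy vector loading (±0.8)
  on 40 genes, orthogonalized so the two axes are identifiable; 150
  DE genes per multi-line group with signed effect 2.0 log2 units added
  in treated samples; replicate noise sd 0.12; duplicate arrays
  (matching a two-replicate design).  The effect-to-noise ratio was
  chosen at design time so that even the 4-pair groups (2 lines ×
  2 replicates, df 3) detect planted genes with per-gene sensitivity
  > 0.99 at the group-level 1% FDR threshold, and 150 planted genes per
  group keep the pooled empirical-FDR estimate stable (≈ 600 true
  discoveries, so the Poisson fluctuation of ~6 expected false
  discoveries stays well under an empirical FDR of 0.02).
* **RPPA**: 132 epitopes; one epitope's per-line fold change is
  −1.2 × the standardized noise-free mean PLX4720 cytotoxicity, making
  it the most anticorrelated epitope by construction; 8 planted
  differential epitopes per analyzed group, three-quarters
  down-regulated, effect 0.8, noise sd 0.10.
* **Variants**: ~2000 background variants over 300 non-driver genes
  with randomized catalog flags (55% dbSNP, 15% 1000G, 30% novel) and
  consequence classes; background variants inside driver-list genes
  are always catalog-flagged (drivers are well-characterized genes
  whose common variation is in dbSNP), so the novel-nonsynonymous
  driver funnel recovers exactly the planted group-unique genes (one
  damaging missense per member line of groups D and E) and the planted
  per-line private genes.
* **IC50 / zygosity**: 4 of 12 lines homozygous; heterozygous lines sit
  0.6 log10 units above homozygous (lognormal noise sd 0.15); the
  singleton line is homozygous-but-resistant (+1.5 log10) and excluded
  from the test, mirroring the outlier exclusion convention.
* **Gene sets**: 100 motif-style sets of 25–60 genes; one planted set
  per analyzed group containing 25 of that group's DE genes; two shared
  sets straddling the focal group and one other; decoys uniform.

All generators flow from a single integer seed through
`numpy.random.SeedSequence` spawning, so a bundle is bit-reproducible
and its parts are independently reproducible.

**What the synthetic panel does not emulate** — probe-level microarray
intensity structure, probe-to-gene multiplicity (the probe map is
1:1; collapse logic is exercised on constructed tables), batch and
plate effects, correlated gene-gene noise, linkage between variants,
and dose-response curve misspecification.  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
the stated generative model, not performance on raw instrument data.

## Numerical conventions

* BH: exact step-up `p·m/rank` with reverse cumulative minimum.
* Hypergeometric tail: `exp(logsf(k−1))`, checked to 1e−12 against
  exact rational enumeration for all instances with N ≤ 12.
* UPGMA: scipy linkage on the condensed matrix, checked against a
  naive O(n³) merge oracle on random matrices (n ≤ 5).
* Permutation p: add-one correction in Monte-Carlo mode; plain
  count/total in exhaustive mode; |t| comparisons use a 1e−12 slack so
  the observed labeling always counts itself.
* Degenerate inputs: zero-variance profiles are rejected in distance
  computations, excluded in the ANOVA screen, skipped (with a count) in
  correlation screens, flagged in differential tables, and reported as
  rho 0 in the RPPA screen.
* Tie-breaks are deterministic everywhere (mergesort ordering; ORA ties
  by descending overlap then set id; probe collapse by |fold change|
  then label).

## Problem sizes

The shipped defaults — 2000 genes, 132 epitopes, ~2200 variants,
100 gene sets, 12 lines — are the scale at which the full pipeline runs
in seconds and the complete test suite in well under a minute, while
keeping every planted-recovery margin wide.  Calibration checks use
10,000 features (type-I error) and 500 replicates × 999 permutations
(null uniformity).

## Known limitations

* The bootstrap support is a single-scale estimator; it is biased
  relative to multiscale extrapolation for small condition counts.
* The paired t-test is unmoderated; with two replicates per condition
  per line, groups of two lines rest on 3 degrees of freedom.
* The ORA universe choice dominates enrichment p-values and cannot be
  validated internally; it is configuration, not inference.
* Group labels depend on dendrogram leaf order; cross-run comparisons
  must match partitions rather than label strings.
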