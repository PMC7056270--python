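# Methods

## Copy-number estimation with the histone ruler

The estimator assumes (i) summed label-free MS intensity of a protein is
proportional to its mass in the sample, with one unknown global factor per
sample; and (ii) histone mass per cell equals the mass of the cell's DNA,
because core histones package DNA at fixed stoichiometry. Under those
assumptions, anchoring the summed histone intensity of sample *s* to

    m_hist = ploidy x genome_size_bp x bp_molar_mass / N_A

turns every intensity into grams per cell, and molecular weight converts
grams to copies. Constants live in `RulerConfig` with defaults for a
diploid mouse cell: ploidy 2, haploid genome 2.73e9 bp, 615.8771 g/mol per
base pair, N_A = 6.02214076e23 /mol, giving m_hist ≈ 5.58e-12 g. All are
overridable (including a direct `histone_mass_override_g`), since the
genome-size constant appropriate to a dataset depends on organism and
annotation release. The per-sample factor cancels exactly in the
intensity ratio; this scale invariance is property-tested.

Histones are recognised by case-insensitive gene-name globs
(`H1*, H2A*, H2B*, H3*, H4*, Hist*`), covering both old clustered-histone
names and current nomenclature, rather than a hard-coded accession list;
the matched set is logged per run. The default list includes linker
histone H1 alongside the core histones — H1 is chromatin-bound in
near-stoichiometric amounts and its intensity share is small, so either
choice perturbs the anchor by far less than measurement noise; the
pattern list is configuration if a core-only anchor is wanted.

Not-detected intensities (absent, zero or non-numeric cells) produce zero
copies with a separate `detected` flag, and condition means include those
zeros. This matches how mean copy numbers are reported for proteins absent
in some conditions (e.g. transporters at a few hundred copies in naive
cells); detection is tracked independently because the filters, not the
means, consume it. No imputation is performed anywhere.

### Filters and quality categories

Rows flagged contaminant, reversed decoy or identified-only-by-site are
removed first. A protein is kept iff at least one condition has detected
intensity in ≥2 biological replicates (`min_detected_replicates`,
default 2). Quantification accuracy is categorised from peptide counts:
high = ≥8 razor+unique peptides of which ≥75% unique, medium = ≥3 with
≥50% unique, low otherwise; thresholds sit in `RulerConfig` and the
categorisation is tested by exhaustive enumeration against a literal
restatement of the rule.

## Differential statistics

Tests are per protein on log2 copies per cell: the two-tailed Welch
unequal-variance *t*-test with Satterthwaite degrees of freedom,
implemented directly (scipy supplies only the *t* distribution) and
verified against `scipy.stats.ttest_ind` to 1e-12. Zero copies have no
log2 value, so only detected replicates enter a test; a condition with
fewer than two detected replicates yields an undefined p (NaN), which
propagates — it never silently becomes 0 or 1. Degenerate variance is
handled without fabricated statistics: both groups constant and equal →
t = 0, p = 1; both constant and unequal → p undefined. A consequence worth
knowing: on exactly noise-free data every within-condition replicate set
is constant, so p-values are undefined by construction; fold changes are
still exact. Welch at n = 3 per group is conservative (true size ≈ 0.035
at nominal 0.05, a documented property of the Satterthwaite
approximation), which the calibration test on planted-null proteins
reflects.

Fold change is the ratio of untransformed condition means (zeros
included), not a mean of per-replicate log-ratios. Regulation rules use
raw p-values: activation-regulated iff p < 0.05 regardless of fold;
genotype-regulated iff fold > 2 or < 0.5 with p < 0.05 (both thresholds
strict inequalities, configurable). A Benjamini–Hochberg `q_value` column
is emitted for modern reuse but never consulted by these rules, keeping
the classification faithful to the raw-p convention while making the
correction available.

## Proteome structure

**Mass ranking.** Proteins are sorted by descending condition-mean mass
per cell, stable with ties broken by group id; cumulative mass fractions
and the protein counts reaching 25/50/75/100% of total mass follow by
prefix scan (smallest prefix whose cumulative fraction reaches the
quantile, with a 1e-12 absolute tolerance against float accumulation).
The implementation is checked against a brute-force sort-and-scan oracle
on random instances.

**Pathway mass.** Gene-set aggregation matches names case-insensitively,
reports µg per million cells (grams/cell × 1e12) and percent of total
mass per condition, and returns unmatched names; an empty intersection
warns rather than errors, since user-supplied gene lists routinely carry
aliases absent from a given annotation.

**Heatmap matrix.** Inclusion requires, within the reference cell type's
conditions, at least one condition with mean ≥500 copies per cell *and* at
least one condition with ≥2 detected replicates. (The inclusion wording
could also be read as "the average over all reference conditions ≥500";
the per-condition reading was chosen because it keeps proteins expressed
only in one state — precisely the interesting ones in an
activation-versus-naive comparison — while still excluding uniformly rare
proteins.) Rows are min-max scaled to [0, 1] on condition means; constant
rows, for which Pearson correlation is undefined, map to 0.5 and append
after the clustered block in id order. Row order comes from average-linkage
agglomerative clustering on 1 − Pearson distance with rows pre-sorted by
group id, making the leaf order deterministic; "nearest-neighbour"
grouping in visualisation tools is conventionally this agglomerative
scheme, and linkage/metric are arguments if another variant is wanted.
Columns keep the design's condition order.

## Synthetic data generator

The generator emulates a two-genotype (optionally three) activation study:
per cell type, naive wild-type plus TCR-activated samples of each
genotype, three biological replicates each. Planted effect classes:
Myc-dependent induced (induced on activation in wild type only),
Myc-independent induced (induced in all genotypes), down-regulated on
activation, unchanged (the null class), and histones
(condition-invariant). Default class fractions 6/6/6/81/1% give a few
hundred regulated proteins per thousand, the order observed in activation
proteomes. Induced/repressed folds are drawn log-uniformly from [4, 100]
per protein — activation induces transporters from hundreds of copies by
up to two orders of magnitude. An optional Slc7a5-knockout genotype fails
to induce 80% of Myc-dependent and 20% of Myc-independent induced
proteins, producing the overlapping-regulation structure that motivates
knockout-overlap (Venn) analyses.

Baseline abundances are log-uniform over 10^2–10^6 copies; histone
baselines are near-equimolar (relative abundance uniform in [0.5, 1.5]),
because core histones are DNA-stoichiometric rather than spread over
decades, and their total mass is calibrated exactly to the ruler's m_hist
so that noise-free data are recovered bit-near-exactly. Non-histone
baselines are rescaled so histones carry ~4% of naive cell mass.

Measurement: intensity = per-sample scale × copies × MW × 2^ε with
ε ~ N(0, σ), σ = 0.25 log2 units by default (typical label-free replicate
scatter); the per-sample scale is drawn over a decade and must be
cancelled by the ruler. Missingness is completely at random at rate 0.05
by default — real label-free missingness is intensity-dependent, which the
generator deliberately does not model because the downstream pipeline
applies only a detection-count filter, never imputation; passing tests
therefore demonstrate correctness of the estimator and statistics under
MCAR, not robustness to censoring-type missingness. Other un-modelled
features of real data: peptide-level variation (intensities are drawn at
the protein level), shared-peptide ambiguity between groups, and
batch/run-order drift beyond a single global factor per sample.

## Pipeline and determinism

`run_pipeline` chains simulate → quantify → differential → structure from
one `RunConfig`; one seed fans out to stages by fixed offsets (truth at
`seed`, measurement noise at `seed+1`) so the planted truth is invariant
to re-drawing noise. All tables serialise with pandas' shortest
round-trip float representation and `NA` for undefined values, so reruns
are byte-identical and the manifest of SHA-256 hashes is the determinism
certificate. Stage errors abort with the stage name and leave a `FAILED`
marker beside any partial outputs.

## Problem sizes

The validation suite and the reproduction script run on synthetic studies
of 400–2500 proteins × 18–24 samples: large enough that class counts,
rejection rates and mass-dominance statistics are stable, while keeping
any single check to seconds. Statistical checks (type-I calibration,
4-fold effect recovery) use ≥2000 null proteins and fixed seeds; exact
checks (ruler closed form, noise-free recovery, scale invariance) are at
1e-9 relative tolerance or better.
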