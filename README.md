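# proteoruler

Absolute quantitative proteomics for immunology-scale label-free
experiments: estimate **protein copies and mass per cell** from a
protein-groups intensity table with the histone "proteomic ruler", apply
the standard filtering and quality rules, run Welch differential
statistics with fold-change regulation calls, and derive proteome-structure
analytics — cumulative mass-dominance ranking, gene-set mass fractions and
clustered heatmap matrices.

The package targets analyses like T-cell activation studies: naive versus
receptor-activated cells across wild-type and conditional-knockout
genotypes, in biological triplicate, asking which parts of the proteome a
transcription factor or transporter selectively controls. A synthetic-data
generator with planted ground truth (effect classes, noise, missing
values, decoys) makes every stage verifiable end to end.

## The model

Histones are stoichiometrically bound to DNA, so total histone mass per
cell is fixed by genome size. The ruler sets, per sample *s* with summed
histone intensity *H<sub>s</sub>*,

```
m_hist   = ploidy x genome_size_bp x bp_molar_mass / N_A   (~5.6 pg, diploid mouse)
mass_i,s = (I_i,s / H_s) x m_hist
c_i,s    = mass_i,s x N_A / MW_i
```

giving copies per cell *c<sub>i,s</sub>* for every protein *i* from raw
intensities *I<sub>i,s</sub>*; any per-sample global intensity factor
cancels in the ratio. Downstream:

* **Filters** — drop contaminant / reversed-decoy / identified-only-by-site
  rows; keep proteins detected in ≥2 replicates of at least one condition.
* **Quality** — "high" ≥8 razor+unique peptides with ≥75% unique;
  "medium" ≥3 with ≥50%; otherwise "low".
* **Statistics** — two-tailed Welch *t*-test (Satterthwaite df) on log2
  copies; fold change = ratio of untransformed condition means. A protein
  is *activation-regulated* at p < 0.05 (any fold) and
  *genotype-regulated* at >2-fold with p < 0.05.
* **Structure** — proteins ranked by mean mass per cell with cumulative
  mass fractions and quartile counts (e.g. the smallest set covering 75% of
  cell mass); pathway mass as µg per million cells and percent of total;
  heatmap rows filtered at ≥500 mean copies and ≥2 detected replicates in
  the reference cell type, min-max scaled, ordered by average-linkage
  clustering under 1 − Pearson distance.

## Worked example

```python
import proteoruler as pr

groups, design, truth = pr.simulate_dataset(n_proteins=1000, seed=42)
filtered = pr.detection_filter(pr.filter_groups(groups), design)
result = pr.estimate_copy_numbers(filtered, design)
print(pr.total_protein_content(result).round(1))
```

prints the total protein content per condition in µg per million cells:

```
WT.CD4.naive       138.9
WT.CD4.TCR         428.5
Myc_cKO.CD4.TCR    267.3
WT.CD8.naive       141.2
WT.CD8.TCR         439.1
Myc_cKO.CD8.TCR    319.2
```

— activated wild-type cells roughly triple their protein mass while the
Myc-knockout increase is blunted, exactly as planted in the synthetic
ground truth. Continuing,

```python
prof = pr.mass_rank_profile(result, "WT.CD8.TCR")
print(prof.quartile_counts)          # (2, 6, 37, 1000)
```

says 2, 6 and 37 proteins already cover 25%, 50% and 75% of activated-cell
mass: proteome mass is dominated by a small abundant minority. The
`examples/` directory has one narrative script per capability
(simulation, quantification, differential regulation and knockout overlap,
proteome structure, full pipeline); each prints its numbers with a line on
what they mean.

The same stages are available from a shell:

```sh
proteoruler simulate --n-proteins 1000 --seed 42 --out-dir sim/
proteoruler quantify --protein-groups sim/protein_groups.tsv --design sim/design.tsv --out copies.tsv
proteoruler run --config cfg.yaml     # simulate -> quantify -> differential -> structure
```

`run` consumes a YAML file mirroring `proteoruler.RunConfig` (paths,
ruler constants, contrast list, thresholds, seed) and writes every result
table plus a JSON manifest of SHA-256 hashes; identical config and seed
reproduce identical bytes. Real MaxQuant-style `proteinGroups.txt` tables
are read directly (`pr.read_protein_groups`); header strings are a
configurable dialect.

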