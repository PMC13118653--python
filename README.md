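# rivasm

Community-assembly analysis for river microbiomes fragmented by cascade
dams — and a synthetic metacommunity generator that makes every stage of
the analysis verifiable against planted ground truth.

## The scientific problem

Serial hydropower dams partition a river into ordered reaches. For
host-associated microbiomes sampled along such a cascade (here: fish gut
bacterial communities from 10 reaches × 2 seasons × 4 replicate hosts),
the central ecological question is which assembly processes structure
the communities — deterministic selection by the environment, dispersal
shaped by the dam barriers, or neutral drift — and how their balance
shifts between hydrological seasons.

`rivasm` implements the complete statistical core of such a study:

- **Data handling** — OTU count tables (TSV), Newick phylogenies,
  sample/environment/taxonomy/dam-geometry metadata; singleton and
  prevalence filtering; TSS normalization; rarefaction without
  replacement (hypergeometric).
- **Diversity** — Shannon, Chao1, Faith's PD on rarefied counts;
  rarefaction curves; Bray–Curtis on TSS relative abundances; PCoA;
  one-way PERMANOVA (Anderson's pseudo-F, optional exhaustive
  enumeration and stratified permutations); multivariate dispersion
  (betadisper, centroid variant); two-way ANOVA with partial η²;
  Spearman trends (exact p for n ≤ 9).
- **Spatial & environmental matrix statistics** — dam-count distance
  matrices (path-additive along the reach order), distance–decay
  regression with Mantel permutation inference, per-season Mantel
  families over z-scored environmental distances with Benjamini–Hochberg
  FDR, and multiple regression on distance matrices (MRM).
- **Null-model process partitioning** — abundance-weighted βMNTD and
  βNTI (z-score against tip-shuffle nulls over the regional phylogeny),
  abundance-weighted Raup–Crick on Bray–Curtis (RC_Bray), and the
  standard five-way partition: βNTI > +2 heterogeneous selection,
  βNTI < −2 homogeneous selection, otherwise RC > +0.95 dispersal
  limitation, RC < −0.95 homogenizing dispersal, else undominated
  ("drift").
- **Sloan neutral community model** — fits the immigration parameter m
  to the occurrence-frequency vs mean-relative-abundance relationship
  through the Beta law `freq(p) = 1 − BetaCDF(d; Nmp, Nm(1−p))`,
  reports R² and Nm, and partitions OTUs against Wilson 95% envelopes.
- **SPEC–OCCU** — per-group specificity and occupancy, specialist
  classification (Spec ≥ 0.7 and Occ ≥ 0.7), within-season core OTU
  sets (Occ ≥ 0.7), detected-set and core-set Venn arithmetic, and
  phylum composition summaries.
- **Synthetic metacommunities** — a generator that emulates the survey
  design and plants known regimes of selection (Gaussian trait–
  environment match on phylogenetically conserved traits), dispersal
  (dam-permeability mixing kernel) and drift (Dirichlet-multinomial
  host noise), so that each inferential stage can be validated by
  parameter recovery and directional contrasts.

## Worked example

Simulate a scaled-down survey (400 taxa, 2 hosts per reach) and ask the
three headline questions from the shell:

```bash
rivasm simulate --preset study --seed 7 --taxa 400 --replicates 2 --out demo/

rivasm permanova --table demo/table.tsv --meta demo/metadata.tsv \
    --group season --perms 999 --seed 7
# F = 36.4131  R2 = 0.4893  p = 0.0010

rivasm ddr --table demo/table.tsv --meta demo/metadata.tsv \
    --geometry demo/dam_geometry.tsv --season winter --perms 999 --seed 7
# slope = 0.08131  r = 0.9152  R2 = 0.8375  p = 0.0010

rivasm ncm --table demo/table.tsv --meta demo/metadata.tsv \
    --season winter -o demo/ncm.tsv
# m = 0.00197  Nm = 60.4  R2 = 0.6594  above/neutral/below = 28/157/22
```

Reading the output: season separates community structure strongly
(PERMANOVA pseudo-F = 36.4 explaining 49% of the Bray–Curtis variance,
permutation p = 0.001); within winter, dissimilarity climbs by ≈ 0.081
per intervening dam (Mantel p = 0.001) — the planted dispersal
limitation; and the winter occurrence-frequency/abundance relationship
is only moderately neutral (R² = 0.66) because the winter regime also
plants strong selection. The full pipeline — alpha diversity through
process fractions, neutral fits and core-set overlaps — runs with
`rivasm run --preset study --seed 7 --out results/`, or from Python via
`rivasm.pipeline.run_full`.

## Layout

```
src/rivasm/
  tables.py     count tables, I/O, filtering, TSS, rarefaction, DIN
  trees.py      Newick I/O, pruning, patristic distances
  diversity.py  alpha/beta diversity, PERMANOVA, betadisper, ANOVA, trends
  spatial.py    dam distances, DDR, Mantel, MRM, BH-FDR
  assembly.py   betaMNTD/betaNTI, RC_Bray, process partitioning
  neutral.py    Sloan neutral community model
  specocc.py    SPEC-OCCU, specialists, core/detected sets
  simulate.py   synthetic surveys and the explicit neutral simulator
  pipeline.py   run_full orchestration, input validation, reports
  cli.py        the `rivasm` command
docs/methods.md the model and design notes
```
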