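# Methods and design notes

This note records the statistical models `rivasm` implements, the
conventions chosen where the literature leaves latitude, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer should know about. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data conventions

OTU tables are integer count matrices (taxa × samples) read from TSV
with taxa as rows by default; orientation can be forced or
auto-detected. Filtering removes singletons (total count 1 across all
samples) and, optionally, OTUs below a prevalence fraction. Relative
abundances are total-sum scaled (TSS; per-sample totals divide the
counts). Rarefaction subsamples without replacement (multivariate
hypergeometric), per-sample streams keyed by sample id so results do
not depend on column order; it is applied only to alpha diversity — all
abundance-based community analyses run on the filtered, non-rarefied
table with TSS. Dissolved inorganic nitrogen is the sum of ammonium,
nitrate and nitrite nitrogen. Phylogenies are rooted Newick trees with
non-negative branch lengths; support values are parsed but ignored by
all distance mathematics; pruning collapses unary nodes with lengths
summed so patristic distances among retained leaves are conserved
exactly.

## Diversity and group tests

Shannon entropy is reported in nats. Chao1 uses the classic
`S + F1²/(2·F2)` with the bias-corrected `S + F1(F1−1)/2` branch when no
doubletons exist. Faith's PD is the branch length of the minimal
subtree spanning a sample's taxa, anchored at the root (a single
present taxon contributes its full root-to-tip path); an unrooted
variant is available.

PERMANOVA implements Anderson's pseudo-F from the squared-distance
partition with free label permutation (an exhaustive-enumeration mode
exists for small designs, and `strata` restricts permutations within
blocks, e.g. within seasons). Permutation p-values use the standard
`(count + 1)/(B + 1)` correction. The dispersion test (betadisper)
embeds samples by PCoA keeping negative-eigenvalue axes; squared
distance to the group centroid is the real-part distance minus the
imaginary-part distance, floored at zero; the centroid (not spatial
median) variant was chosen for determinism; significance permutes the
per-sample dispersions. Two-way ANOVA uses type-II sums of squares
(statsmodels), with a nested-OLS fallback for saturated designs, and
partial η² = SS_effect/(SS_effect + SS_residual); sums of squares at
floating-point noise level are snapped to zero so degenerate designs
report clean 0/1 effect sizes. Spearman trends use exact enumeration
p-values for n ≤ 9 and the t approximation otherwise.

## Spatial and environmental matrix statistics

Spatial separation is the number of dams between reaches, accumulated
along the reach order (path-additive; 9 dams end-to-end in the default
10-reach design). Distance–decay regresses unfolded upper-triangle
Bray–Curtis on dam counts (OLS slope/intercept/R²) with significance
from the Mantel permutation scheme — simultaneous row+column
permutation of one matrix; two-sided by default with a one-sided
option, 999 permutations by default. Environmental distances z-score
each variable within season using the population SD (ddof = 0; the
choice only rescales distances and cannot affect Mantel correlations),
then take Euclidean distances; multivariate environmental distance is
Euclidean over the z-scored vector. Mantel families (one per season
across environmental variables) are Benjamini–Hochberg adjusted as one
family. MRM regresses the unfolded response triangle on any number of
predictor matrices, permuting the response's rows and columns jointly
and reporting two-sided per-coefficient p-values; a condition-number
guard warns on collinear predictors.

## Null-model process partitioning

βMNTD between two communities is the abundance-weighted mean distance
from each present taxon to its phylogenetically nearest taxon in the
partner community (shared taxa contribute zero); an unweighted variant
exists. βNTI standardizes the observed βMNTD against nulls that shuffle
taxa across the tips of the phylogeny — implemented as joint
row+column permutations of the patristic matrix, with one shuffle
evaluated against all sample pairs (the per-pair z-scores therefore
share null draws, which leaves each pair's marginal null distribution
unchanged). Null standard deviations use ddof = 1; zero-variance nulls
(e.g. star phylogenies, or exactly identical communities, whose shared
taxa pin every null draw at zero) yield NaN with an explanatory note
rather than a fabricated score.

**The taxon registry defines the randomization pool.** βNTI asks
whether a pair's phylogenetic turnover is unusual relative to taxa
placed anywhere on the *regional* phylogeny. The pipeline therefore
keeps the full filtered table's OTU registry (and its pruned tree) when
computing within-season pairs, rather than re-pruning to the taxa
detected in that season. Pruning to the season's own taxa would make
the null universe coincide with the very clades selection has confined
the communities to, and homogeneous selection would become almost
undetectable. This mirrors standard practice with real data, where the
tree spans the whole study's OTU table.

RC_Bray rebuilds each community of a pair 99–999 times, preserving its
observed richness and total count: occurrences are a weighted sample
without replacement (metacommunity occupancy weights; Gumbel top-k),
and remaining individuals follow a multinomial over the drawn taxa
weighted by metacommunity relative abundance (equiprobable variants
exposed). RC is the fraction of null Bray–Curtis values below the
observed value, ties at half weight, rescaled to [−1, 1]. Metacommunity
weights default to the analyzed (within-season) table; external weights
can be supplied. Per-pair child seeds derive from the sorted sample-id
pair, so results are bit-identical regardless of evaluation order; both
null models also canonicalize taxon order internally, making them
invariant to relabeling.

Processes follow the conventional thresholds, exposed as parameters:
|βNTI| > 2 selection (sign separates heterogeneous from homogeneous),
otherwise |RC| > 0.95 dispersal (sign separates limitation from
homogenization), remainder undominated (displayed as "drift"). Pairs
are partitioned within season; fractions are reported over non-NA pairs
with the NA count alongside.

## Sloan neutral community model

Per OTU the model relates occurrence frequency across samples to mean
TSS relative abundance p̄ through the stationary Beta law of a local
community of size N with per-birth immigration probability m:
`freq(p̄) = 1 − BetaCDF(d; Nmp̄, Nm(1−p̄))`. N is the mean library size
of the analyzed table. Detection in count data means at least one read
out of N, so the default detection limit applies a continuity
correction, `d = 0.5/N` — fitting the continuous law at the raw
single-read abundance `1/N` systematically overestimates m (verified
against exact Dirichlet-multinomial absence probabilities, where the
`1/N` convention inflates m̂ by 20–100%); `1/N` remains available via
`detection_limit`. m is fitted by bounded scalar least squares on
log m; R² is computed about the mean observed frequency and may be
negative. The 95% envelope uses Wilson binomial prediction bounds at
the realized sample count around the fitted curve, and OTUs are
partitioned above/neutral/below. Nm = N·m, so reported Nm values scale
with the library-size convention.

The explicit neutral simulator implements the matching source–sink
process: every replaced individual is an immigrant with probability m,
otherwise a local birth. Its exact stationary law is
Dirichlet-multinomial with concentration `m(N−1)/(1−m)` times the pool
(the classical urn result), so by default samples are drawn from that
law directly and burn-in is unnecessary; explicit batched Moran
generations (batches of N/10 replacements) are available for
relaxation studies or pool-initialized runs.

## The synthetic metacommunity generator

Defaults reproduce the survey design: 10 reaches in downstream order
separated by one dam each, two seasons, four replicate hosts per
reach/season (80 samples), lognormal library sizes around 30k truncated
at 15k, and a 2000-taxon regional pool with lognormal abundances
(σ_log = 2.5), giving per-sample detected richness that is a realistic
fraction of the pool. The generative model composes:

- **Phylogeny.** A pure-birth tree with an episodic rate — slow while
  the first ~10 backbone lineages arise, 8× faster thereafter —
  yielding a deep backbone capped by dense radiations, the shape of
  97%-OTU 16S trees. A Kingman coalescent alternative exists but
  concentrates trait variance into two clades.
- **Conserved niche traits.** Brownian motion along branches, with the
  rate attenuated (×0.1) on branches subtending fewer than 30 tips:
  niche optima are conserved at backbone-clade level while close
  relatives share nearly the same optimum. Without deep conservation a
  selection "band" of trait space is a slice across every clade and
  phylogenetic turnover metrics cannot see the selection that is
  genuinely present.
- **Selection.** Reach expected composition multiplies the pool by a
  super-Gaussian trait–environment match
  `exp(−½(|z − e_r|/σ_sel)^4)` plus a small floor (0.002) representing
  transient taxa that escape filtering; e_r is a monotone longitudinal
  gradient whose amplitude differs by season. The sharpened edge keeps
  membership turnover inside the selected clades; the floor keeps rare
  out-of-band taxa in the regional registry.
- **Dispersal.** A fraction `mix_frac` of each reach's expectation is
  immigrant, sourced from other reaches with weight `rho^dams`: `rho`
  shapes the distance decay per dam crossed, `mix_frac` the overall
  connectivity. (A single ρ-driven kernel over-homogenizes: with
  row-normalization the home reach would retain ~20% weight even at
  moderate permeability.)
- **Reach noise and drift.** Reach-level lognormal compositional noise
  (priority effects / unmeasured factors) differentiates reaches even
  without selection, and each host is a Dirichlet-multinomial draw
  around its reach expectation, the concentration parameter setting
  drift strength.

The two seasonal parameter sets embody the inferred process contrast:
*winter-like* = strong, deeply conserved selection (σ_sel 0.35),
stronger gradient (amplitude 0.45), weak mixing (mix 0.1, ρ 0.5);
*summer-like* = weak selection (σ_sel 2.0), weak gradient (0.25), high
mixing (mix 0.6, ρ 0.9), stronger host drift. The "study" preset runs
both in one survey, and the seasonal contrast — higher deterministic
and homogeneous-selection fractions, steeper dam-count distance decay,
higher reach PERMANOVA R² in winter — is evaluated between the two
seasons of such a run: each season carries exactly one regime's
parameters, and the shared survey provides the broad regional taxon
registry the null models reference, just as the real study's two
seasons share one OTU table. Additional presets give pure controls:
`neutral` (no selection, full mixing), `selection` (strong selection,
flat environment), `dispersal-limited` (no selection, weak mixing).

What the generator does **not** emulate: sequencing error and chimeras;
taxonomic realism (phylum labels are clade-contiguous placeholders);
any attempt to match the study's taxon composition or absolute
diversity. One known divergence from the study narrative: the simulated
winter, being the strongly filtered season, detects *fewer* taxa than
summer, whereas the real survey found winter richer in OTUs, so
specialist and core-set counts lean toward summer in simulations. The
generator is calibrated to reproduce the *process* contrast, not the
richness contrast; passing tests demonstrate that the pipeline detects
planted assembly processes at the study's design scale, not that the
generator matches the ecosystem in all marginals.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; composite analyses
derive per-stage and per-item child seeds by stable SHA-256 hashing of
the parent seed with string tokens, so outputs are bit-identical across
reruns, pair orderings and worker counts, and below 2³¹ everywhere.

The test suite exercises reduced designs (600–1500 taxa, 2 replicates,
~1.5–3k reads) chosen so each directional effect is decisive at that
scale; null-model calibrations use 100 taxa × 20 samples with 999
nulls; neutral-model recovery uses the full 80-sample, 500-taxon,
N = 10,000 setting. `scripts/acceptance.py` runs the full 80-sample
default design with 999 permutations for matrix tests, 299 βNTI
shuffles and 99 RC rebuilds per pair.

## Known limitations

- βNTI's homogeneous-selection sensitivity depends on richness and on
  the breadth of the taxon registry; at very small fixture scales the
  attainable |z| for clade-confined pairs is modest (≈2–5).
- RC_Bray conflates host-level overdispersion with dispersal
  limitation, a known property of the framework: strong per-host drift
  raises observed dissimilarity above the richness/abundance-preserving
  null and is read as dispersal limitation, not drift.
- The Wilson envelope treats the fitted curve as known; it does not
  propagate uncertainty in m̂.
- MRM assumes unfolded-triangle observations are exchangeable under the
  Mantel permutation scheme; as usual, p-values are approximate for
  strongly structured predictors.
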