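# Methods

This note documents the models, parameter choices and numerical decisions
behind `qmpdecomp`, and what the synthetic cohort does and does not
establish about real data.

## The measurement model

Amplicon sequencing reports proportions: each sample's reads sum to a
depth chosen by the instrument, not by the community. When total microbial
load moves by orders of magnitude — as it does in decomposing tissue —
relative microbiome profiling (RMP) conflates a taxon's own dynamics with
everyone else's. Quantitative microbiome profiling (QMP) removes the
constant-sum constraint with synthetic internal standards: spike-in
sequences of known copy number are added to each quantified DNA extract
before amplification, and for each sample we fit

    log10(R_s) = a * log10(C_s) + b

by ordinary least squares over the spikes, where `R_s` is a spike's read
count and `C_s` its input copies. Inverting the curve converts any taxon's
reads to absolute copies; dividing by the documented extract mass gives
copies per gram. Conventions: log base 10 (the copies are base-invariant,
the reported intercept is not); zero reads map to zero copies (the curve is
undefined at zero, and absence of evidence maps to absence); spikes with
zero reads are dropped from the fit and fewer than two surviving spikes is
a calibration failure — the sample is flagged and excluded from QMP rather
than imputed. Fits with R² < 0.8 are kept but flagged (configurable).
Ribosomal operon copy-number variation across taxa is deliberately not
corrected; copies per gram is a load proxy, not a cell count.

The RMP arm removes spike rows and rarefies to a common depth (default:
the minimum retained sample total) by multivariate hypergeometric
subsampling, so every retained column sums exactly to the depth and the
draw is reproducible from the seed.

## The synthetic cohort

The generator emulates a buried-carcass succession study: 42 carcasses
exhumed over days 1–35 (7 time points × 6 replicates) with grave soil and
abdominal tissue sampled at each exhumation and regular soil from day 0 —
132 samples; bacteria (default 300 genus-level taxa) and fungi (150)
profiled separately at a mean depth of 5×10⁴ reads.

Each taxon follows a piecewise log-linear trajectory of true copies per
gram: baseline log10 load, a growth rate to day 14 (the putrefaction
peak), and a second rate after. Defaults encode the study conditions:
regular soil stable (net change < 0.5 log10 over the window), grave soil
transiently enriched then declining, and tissue undergoing a nutrient-flush
bloom — every taxon's rate drawn around +0.15 log10/day (bacteria) or
+0.13 (fungi) so the tissue totals expand ≥ 2 orders of magnitude by day
14, with bacteria plateauing and fungi declining afterwards. Fourteen
bacterial and ten fungal genera are flagged as planted decomposers — the
strongest monotone risers, named after genera repeatedly reported from
carrion (e.g. *Sporosarcina*, *Vagococcus*, *Scopulariopsis*). Replicate
noise is multiplicative lognormal, σ = 0.2 log10 units; reads are
multinomial in (copies/g × extract mass) jointly with the spike copies.
Masses are uniform on [0.3, 0.7] g (soil) and [0.15, 0.25] g (tissue),
matching ~0.5 g / ~0.2 g extraction inputs.

Spike-ins: three per domain, dosed per extract at 0.2%, 2% and 20% of the
fluorometrically measured total copies (measurement noise 0.1 log10). This
mirrors how standards are added to quantified extracts and keeps all three
spikes on-scale across a two-order load range; the true capture slope is 1
by construction, so calibration accuracy is measurable.

Metabolome: 300 lognormal intensity features on the 42 tissue samples. A
quarter trend up with PMI (lipid-enriched superclasses — recalcitrant
lipids accumulate late), 30% trend down (organic-acid- and
nucleoside-enriched — labile substrates consumed early), and within the
remainder a configurable subset is linear in a designated taxon's
standardized log10 load (20 bacterial-driven vs 8 fungal-driven features by
default). Superclass labels are input metadata; no annotation database is
queried.

Scenario presets isolate specific claims:

- **Compositional trap** (`trap_dynamics`): background taxa grow at a
  single shared rate (composition constant, total up ~100×) while focal
  taxa hold constant absolute copies. Under RMP the focal taxa show a
  strong spurious decline; under QMP they are flat. With several focal
  taxa, RMP additionally invents positive edges among them.
- **Guild structure** (`guild_dynamics`): decomposer guilds share a
  per-sample latent factor (0.45 log10) over a moderate trend, planting
  co-occurrence modules. This is deliberately separate from the default
  cohort: in a nutrient flush *everything* is monotone in PMI, so all
  abundant taxa correlate and a single giant component is the correct
  network answer there; module recovery is only a testable claim when
  block structure actually exists.
- **Compositional signal** (`signal_dynamics`): five low-abundance marker
  taxa trend with PMI over a stable total, so QMP carries no information
  beyond composition — the background for the QMP-vs-RMP prediction
  comparison.
- **Stable background** (`stable_dynamics`): no temporal trend at all, so
  microbe–metabolite concordance can only flow through the planted driver
  map.

What the synthetic cohort does **not** emulate: taxonomic misassignment,
chimeras, PCR efficiency differences between spikes and genomic templates,
operon copy-number variation, batch effects, and inter-animal covariance
beyond the per-sample noise. Passing tests establish that the estimators
recover known structure under the stated noise model, not that real
decomposition data will be as clean.

## Analysis conventions

- **Diversity**: Shannon index with natural log; Bray–Curtis
  dissimilarity; PCoA by eigendecomposition of the double-centred −d²/2
  matrix (relative eigenvalues against the positive-eigenvalue sum).
- **Group tests**: two-sided Wilcoxon rank-sum (two groups) or
  Kruskal–Wallis, Benjamini–Hochberg corrected within the feature batch
  being tested.
- **Key decomposers**: genus-level Spearman r > 0.6 and P < 0.001 against
  PMI day on tissue copies per gram. P values use the t approximation for
  n > 20 and a seeded 10,000-draw permutation otherwise. Note that in the
  default nutrient-flush cohort most taxa genuinely rise, so the criterion
  selects far more genera than the planted decomposers; the planted flags
  are the sensitivity reference, not an exclusivity claim.
- **Trend discordance**: the top 100 genera by mean QMP abundance
  (lexicographic tie-break), early = days {1,3,7} vs late = {14,21,28,35}
  (both boundaries read inclusively; configurable), Wilcoxon + BH within
  the top set separately per mode, direction from the median difference.
  Classification is QMP-referenced: a significant RMP trend that QMP does
  not confirm in the same direction is *contrasting* (a compositional
  artifact — the relative signal asserts a change the absolute data do not
  support), a significant QMP trend invisible to RMP is *qmp_only*
  (RMP blindness), agreement is *concordant*. The scheme is intentionally
  asymmetric; swapping the inputs exchanges the contrasting/qmp_only
  labels.
- **Time decay**: OLS of similarity (1 − Bray–Curtis) on |Δday| over all
  within-type pairs; slope = succession rate; a log-similarity option
  exists but the linear form is the default.
- **Networks**: Spearman |r| > 0.6 and raw P < 0.001 (no multiplicity
  correction, matching common practice for these thresholds; a BH switch
  exists) among the top 100 genera per domain; the combined network
  concatenates each domain's top set on shared samples. Modules by greedy
  (CLM) modularity maximisation on the unsigned edge set — deterministic,
  with Q reported but treated as algorithm-dependent; module eigengene =
  first principal component of the z-scored module submatrix, sign-aligned
  with mean module abundance; module–metabolite grids use class sums of
  sum-normalised intensities at P < 0.05.
- **Metabolomics**: sum-normalise columns then Pareto-scale features
  (centre, divide by √SD). PLS-DA regresses one-hot day groups on features
  (2 components by default); VIP_j = √(p·Σ_a SSY_a w_ja² / Σ_a SSY_a),
  which guarantees Σ VIP² = p. The "P < 0.05" companion to VIP > 1.5 is a
  BH-adjusted Kruskal–Wallis across day groups (the nonparametric toolkit
  used everywhere else here). PMI-correlated metabolites (|r| > 0.6,
  P < 0.001) are split by Ward clustering of z-scored per-day mean
  trajectories into k = 2 clusters, signed by mean correlation.
- **Integration**: Procrustes on the first two ordination axes of each
  block (both configurations centred, unit trace; rotation by SVD;
  M² = 1 − (Σσ)²; permutation P over row permutations). Mantel/partial
  Mantel on upper triangles, Pearson by default with a Spearman option,
  first-order partial correlation, one-sided P by simultaneous row/column
  permutation of the first matrix, 999 permutations seeded. RDA as PCA of
  the fitted values of the multivariate regression on standardized
  explanatory variables (total copies/g per domain, Shannon, top phylum
  abundances); per-variable marginal contributions with permutation P;
  collinearity handled by pseudo-inverse with a warning. The random-forest
  association uses log10 total copies per gram as each domain's summary
  response (an ordination-axis alternative is available) and ranks
  metabolites by out-of-bag IncMSE.
- **PMI regression**: stratified 2:1 split within each day (exact counts,
  seeded); 1000-tree forests by default; IncMSE = mean out-of-bag MSE
  increase per permuted feature (per-tree bootstrap complements, averaged
  over trees and repeats; a held-out variant exists); biomarker
  optimisation ranks by IncMSE and scans a log-spaced k-grid
  {1,2,3,5,8,10,15,20,30,50,p} with repeated 10-fold CV, returning the
  MAE-minimising subset; evaluation refits 100 fresh-seeded forests on the
  fixed split and reports MAE/R² mean ± SD. Multi-omics concatenation
  z-scores each block so no block dominates split choices by scale; ASV
  features are prevalence-filtered (≥ 3 samples) before modelling.

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks run at deliberately chosen desk scales: the
acceptance script and replicate-based tests use 200-tree forests, 5- or
10-fold CV with 2 repeats, 25 evaluation reseeds, 100-taxon scenario
cohorts, and 25–100 scenario replicates; library defaults remain the
full-size settings above. The methods' conclusions (recovery, blindness,
discordance, equivalence) are scale-robust in the regimes tested.

## Known limitations

- Copies per gram inherits every amplicon bias upstream of the spike
  (extraction efficiency, primer bias, operon counts); only
  compositionality is corrected.
- Greedy modularity Q is algorithm- and resolution-dependent; Q values are
  descriptive, not reproducibility targets.
- The "P ≈ uniform under the null" calibration of permutation tests is
  checked by Monte Carlo at modest replicate counts; tail behaviour beyond
  that is asserted only asymptotically.
- Partial-Mantel contrasts between domains are only meaningful when the
  shared temporal trend is controlled or absent; on the default cohort
  both domains ride the same PMI trend and their partial correlations are
  small and unstable by design.
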