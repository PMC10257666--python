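# Methods

## The problem

Amplicon surveys estimate community composition from 16S rRNA read counts,
but genomes carry between 1 and ~15 copies of the 16S gene (the gene copy
number, GCN), so read counts over-represent taxa with many copies.
Correcting for GCN requires predicting the copy number of taxa that have
never been sequenced, from their position in a reference phylogeny — and the
prediction carries irreducible uncertainty that grows with the distance to
the nearest sequenced relative (NSTD).  `pulsegcn` models that uncertainty
explicitly, attaches a calibrated confidence to every integer prediction,
and propagates it into corrected relative abundances as Monte-Carlo
confidence intervals and support values.

## Trait model

Copy-number evolution is modelled as **pulsed evolution** (PE): along a
branch of length `t` (substitutions/site) the latent trait changes by
`sum_{j<=N} J_j` with `N ~ Poisson(lambda * t)` and `J_j ~ Normal(0,
sigma2_jump)` — stasis punctuated by jumps.  Each observed tip additionally
carries **time-independent variation** `Normal(0, sigma2_eps)` (intraspecific
variation plus measurement error; it does not accumulate with branch
length).  The heterogeneous variant splits branches into a slowly- and a
regularly-evolving group that share one jump-size variance but differ in
jump frequency (`lambda_slow <= lambda_regular`) and white-noise variance.
Nested simplifications — Brownian motion with and without white noise, and
homogeneous PE — are fitted for AIC comparison.

### Likelihood

The likelihood is evaluated over phylogenetically independent contrasts.
The Felsenstein recursion runs in variance space: a node with children whose
messages carry variances `u_i = rate_i * l_i + s_i` (process rate
`lambda_i * sigma2_jump` on the branch plus carried Gaussian uncertainty
`s_i`, which at tips is `sigma2_eps`) produces

* a contrast `d = x_1 - x_2` scored by the compound-Poisson mixture with
  total jump intensity `lambda_1 l_1 + lambda_2 l_2` (Poisson additivity,
  which also resolves mixed-group sister branches) plus Gaussian variance
  `s_1 + s_2`;
* the precision-weighted node value and the carried variance
  `u_1 u_2 / (u_1 + u_2)`.

This is exact for Brownian motion (verified against an independent
matrix-GLS restricted likelihood to 1e-10) and moment-matched for PE: the
jump mixture is applied within each contrast, while deeper uncertainty is
propagated as Gaussian.  In the high-intensity limit the mixture converges
to the Gaussian likelihood (checked at `lambda = 1e4` against the matrix
oracle to within 0.1 log-units).

**Integer-trait scoring convention.**  Observed copy numbers are integers,
so exactly-zero contrasts are common and carry the stasis signal.  A zero
contrast is scored by the *probability* that the increment falls within the
unit rounding bin (the stasis atom `exp(-intensity)` plus the bin mass of
the continuous mixture); nonzero contrasts are scored by the mixture
density.  Mixing an atom *mass* with *densities* — the naive alternative —
makes stasis evidence incommensurable across parameter regimes and lets the
two-group classification collapse (every zero contrast gains an unbounded
advantage for the slow group).  The same bin convention is applied to the
BM likelihood so AICs remain comparable across families.  On continuous
data exact zeros have measure zero and the convention changes nothing.

### Fitting

Parameters are estimated by bounded L-BFGS-B on log-transformed parameters
(bounds `e^-30 .. e^15`), with a screened multi-start (default 8 starts):
a moment-based centre, deterministic displacements along the weakly
identified `(lambda, sigma2_jump)` ridge (the process rate
`lambda * sigma2_jump` is well constrained long before the
frequency-vs-size split is), and random log-space perturbations; the best
two screened starts are polished to `ftol = 1e-10`.  Pure BM has a closed
form (contrast weights are rate-free) used directly on continuous data and
as the start otherwise.  After optimisation each parameter is shrunk to its
lower bound when the likelihood is indifferent, so flat ridges resolve to
the parsimonious boundary.  Poisson sums are truncated at cumulative mass
`1 - 1e-12`; above total intensity 2000 the mixture is evaluated as its
Gaussian limit (excess kurtosis `3/mu < 2e-3`).  AIC ties within 2 units
resolve to the simpler model.

### Rate-group classification

1. Per-node local rates are computed as mean squared standardised contrasts
   over the smallest enclosing subtree with >= 10 tips (the same size floor
   as genus-level rate screens).
2. The log10 rate distribution of the *minimal* decision nodes (the
   genus-like layer; nested ancestors mix groups and blur the modes) is
   split at the antimode, operationalised as the between-class-variance
   (Otsu) split with at least 8% of the sample on each side, accepted only
   when the class means are >= 1 decade apart — the two-group frequency
   ratios of interest are orders of magnitude, while the sampling spread of
   local-rate estimates under a homogeneous model is a fraction of a
   decade.  If no qualifying split exists the distribution is unimodal and
   the heterogeneous model is rejected outright — without bimodality there
   is no structure to initialise from.
3. Group labels live on *decision nodes* (internal nodes with >= 10
   descendant tips; smaller subtrees inherit the nearest labelled
   ancestor).  Classification alternates 5-parameter refits with label
   sweeps, accepting a flip only when it raises the total log-likelihood by
   more than 2 (an AIC-equivalent per-label cost; each label is a binary
   model choice, and unpenalised greedy flips would harvest noise and let
   the two-group model always win on homogeneous data).  Iteration stops at
   a joint fixed point (cap 50).
4. The heterogeneous model is accepted only if its AIC (5 parameters, the
   assignment treated as fixed) beats the homogeneous PE fit by more than
   the tie margin.

Finer-grained per-contrast reassignment was evaluated and rejected: a
single stasis contrast always prefers the slow group by a bounded Bayes
factor, so maximum likelihood fragments clade-structured truth (~70%
assignment accuracy at a simulated frequency ratio of 100, versus ~90-95%
for the clade-granular scheme).

## Hidden-state prediction

A query attached to the reference tree (jplace placement, or a held-out tip)
is predicted in three steps:

1. **Ancestral reconstruction** at the attachment point by two-pass Gaussian
   belief propagation, each branch contributing variance at its group's
   process rate.  Observed reference values are treated as exact; the
   white-noise term enters once, on the query's side.  This mirrors the
   construction in which time-independent variation is represented as a
   small branch added to the insertion branch, and caps the attainable
   confidence of the regularly-evolving group at 85% (for
   `sigma_eps = 0.3473`) even for a query identical to a reference.
   The cost is a modest overconfidence at near-zero NSTD (the reference's
   own noise is not filtered); the symmetric alternative would cap
   confidence near 69% instead and break the stated behaviour.
2. **Pendant mixture**: the query's predictive distribution is the
   compound-Poisson mixture over the pendant branch (group-specific
   intensity) plus the group's white noise.  In hold-out mode with
   NSTD-thinned references, the pendant runs from the query to the junction
   with the first informative lineage, accumulating each traversed branch's
   own jump intensity — the placement the query would receive on the
   actually pruned tree.  This keeps the stasis atom and heavy tails of the
   jump process on the whole unobserved path instead of Gaussianising it.
3. **Integer PMF**: the continuous mixture is integrated over unit bins
   centred on the integers, with all mass below 1.5 folded into copy number
   1 (GCN >= 1).  The point estimate is the rounded (half-up) continuous
   mean clamped to >= 1; its PMF mass is the confidence; predictions under
   95% confidence are flagged unreliable.  The PMF argmax is reported as a
   diagnostic.

Adjusted NSTD is the query's minimum patristic distance to any reference on
the rescaled tree (slowly-evolving branch lengths multiplied by
`lambda_slow / lambda_regular`); adjusted NSTI is the read-abundance-
weighted mean over a community.

## Copy-number correction

Per community sample, 1000 copy-number vectors are drawn independently from
the per-OTU integer PMFs; corrected cell counts are `reads / GCN`,
normalised within each draw.  The point estimate is the per-OTU median
corrected count renormalised across OTUs; the 95% CI the 2.5/97.5%
quantiles of the per-draw relative abundances; the support value of the
most-abundant OTU the fraction of draws in which it ranks first (exact ties
split equally).  A single seeded generator drives each run.

### Known limitations of the CI construction

The draws are independent across OTUs, but prediction errors are not: OTUs
in the same thinned region share ancestral uncertainty, and the reads-
weighted sum of `1/GCN` (the normalising denominator) is a convex
functional, so calibrated-but-dispersed marginal posteriors bias it upward
relative to the truth.  Both effects shrink below the per-OTU CI width only
when community members are phylogenetically sparse on the reference and
their individual GCN uncertainty dominates.  When many members have
near-certain predictions (dense references, strong stasis) the CIs of those
members are driven by the shared denominator and can systematically miss;
read-sampling (multinomial) noise is likewise outside the CI.  The
`ci_coverage_experiment` driver measures exactly this, and the acceptance
analysis reports the resulting under-coverage honestly rather than
widening the intervals beyond their definition.

## Synthetic data (study conditions)

The generators define the conditions every calibration claim is tested
under:

* **Tree**: pure-birth tree, branch lengths rescaled to mean root-to-tip
  depth 0.4 substitutions/site (a typical 16S scale); exact-zero edges from
  the birth-death start floored at `1e-6 * depth`.
* **Groups**: disjoint clades of 10-60 tips labelled slow until ~48% of
  tips are covered (the reported fraction of slowly-evolving branches).
* **PE parameters**: regular-group white-noise sd 0.3473 (the value that
  caps unit-interval confidence at 85%); shared jump sd `0.3473 / 0.4 =
  0.868` (time-independent variation ~40% of a jump, read on the sd scale —
  the variance-scale reading would make the noise larger than a jump and
  contradict the 85% cap); `lambda_regular = 20` per substitution/site
  (chosen once so tip copy numbers span ~1-12 from a root value of 4 over
  depth 0.4); `lambda_slow = lambda_regular / 145` (the reported
  jump-frequency ratio); no slow-group white noise.
* **Traits**: tip values rounded half-up and clamped to >= 1.  The
  rounding adds ~1/12 of unmodelled variance that the fitted white noise
  absorbs; parameter-recovery experiments therefore use the continuous
  (`discretize=False`) process, which is the model the estimator actually
  targets.
* **SC1 communities**: default 200 OTUs per community, log-normal(0, 1)
  cell abundances, multinomial gene reads at depth 1e5 (optionally
  noise-free expected counts); per NSTD threshold, reference tips within
  the threshold of any community member are removed.
* **SC2 communities**: two environments sharing a 2000-OTU pool (scaled
  down in tests), 1% disjoint signature OTUs per environment enriched
  4-fold at home, 20% of the non-signature core replaced per sample
  ("turnover"), 20 samples per environment, depth 1e5.  Fold, depth and
  abundance law are reconstructions and overridable.

What these generators do **not** emulate: real 16S alignment/placement
error, compositional sequencing artefacts (extraction and PCR bias), tree
estimation error, or the taxonomic correlation structure of real reference
databases.  Passing calibration here shows the machinery is self-consistent
under its own model, not that real-data predictions are this well behaved.

## Validation machinery

* **Cross-validation**: per NSTD bin, 2% of tips held out (disjoint test
  sets within a bin), references thinned at the bin threshold, each test
  tip predicted and scored: R^2 of the point predictions, exact-integer
  accuracy, precision (correct among reliable) and recall (reliable among
  correct); repeat-level means with normal-theory 95% CIs (repeats are
  weighted equally).  Bins whose thinning leaves fewer than 2 references
  are skipped with a warning.  Default thresholds: 0, 0.002, 0.005, 0.010,
  0.022, 0.046, 0.100, 0.215, 0.464 substitutions/site; 50 repeats.
* **Beta diversity**: Bray-Curtis, normalised weighted UniFrac
  (scikit-bio) and Aitchison distance (CLR/Euclidean; zeros replaced by
  0.5x the smallest nonzero relative abundance in the table, then
  re-closed), classical-scaling PCoA (axes with eigenvalue <= 1e-8
  dropped, negative eigenvalues reported), and a seeded one-way PERMANOVA
  (Anderson's pseudo-F; `p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`;
  PVE = SS_between/SS_total).
* **Ordination shift**: the true, gene and corrected versions of every
  sample are embedded in one joint PCoA; a version's shift is its Euclidean
  distance to the true point over all retained axes, and the reduction is
  `1 - mean shift(corrected) / mean shift(gene)`.  A joint embedding is
  used because distances "in all dimensions" are only defined in a common
  space (the alternative — Procrustes between separate ordinations — adds a
  fitted rotation).

## Numerical choices

* Path-length floor `1e-9` for degenerate (zero-length, equal-trait)
  contrasts; zero-length unequal pairs are flagged and dropped from rate
  estimation but retained (via the white-noise term) in likelihood fitting.
* Polytomies resolved to zero-length bifurcations, ordered by smallest tip
  label for reproducibility.
* Quantiles of Monte-Carlo draws use linear interpolation (numpy default);
  text outputs print 12 significant digits.
* Problem sizes in the shipped experiments (500-1000-tip references, 100
  communities, 20 cross-validation repeats per bin) are the package's
  default desk-scale study conditions; all are parameters.

## Known limitations

* `lambda_slow` is estimated from a handful of jump events at desk scale
  and carries multi-fold uncertainty; only the process rate
  `lambda * sigma2_jump` is well identified on integer data.
* Regular-group confidence is mildly overstated at near-zero NSTD (see the
  85%-cap discussion above).
* The CI construction inherits the independence and convexity caveats
  described under copy-number correction; coverage of true cell abundances
  degrades when communities are dense on the reference tree.
* Group count is fixed at two; jump sizes are homoscedastic; no
  Ornstein-Uhlenbeck or trend components.
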