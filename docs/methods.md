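# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `divlen`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Diversity profiling

Per-site nucleotide diversity is

    π = 2 · Σ_{i<j} f_i f_j / (N(N−1))

over the four base counts f_i at a column, N = Σ f_i — identically the mean
of the "bases differ" indicator over all N(N−1)/2 sequence pairs.  Gap and N
characters are removed before counting (N is treated as missing everywhere:
it can neither be a consensus base nor contribute to π); columns with fewer
than two ungapped bases are skipped.

Column eligibility for the silent profile:

* columns with more than 70% gaps are excluded (`max_gap_frac = 0.7`);
* a consensus base requires the modal base to reach 60% of *all* rows
  (`consensus_threshold = 0.6`); gaps count in the denominator, so the gap
  rule above is the only mechanism by which gappy columns survive or die —
  a deliberately conservative choice;
* degeneracy is read from the standard genetic code applied to the consensus
  codon (the 4-fold families are identical under the bacterial code, so no
  table switch is needed); codons with any no-consensus position yield no
  degeneracy call;
* consensus ties are broken in fixed A<C<G<T order; ties are rare at
  realistic polymorphism levels and a deterministic rule keeps runs
  reproducible.

Positions are indexed by **silent-site rank**: the 0-based order of eligible
4-fold columns from the start codon, with excluded columns occupying no
rank.  This matches the Effect Length semantics (L_e counts silent sites,
not bp) and keeps profiles dense.  A `position_mode="bp"` switch reports the
bp offset of the column instead, for comparison with bp-indexed analyses —
the simulator, which has no codon structure, reports bp offsets.

The species profile is the unweighted mean of per-gene diversities at each
rank; the gene count w(l) is carried as the regression weight only.  Strain
dereplication (Jaccard distance ≥ 0.01 between protein-id sets, greedy in
input order) and ortholog filtering (single-copy, present in ≥ 75% of
strains) mirror standard multi-strain panel practice.

## Asymptotic regression

π̄(l) = d_max + (d_min − d_max)·e^(−cl), fitted by weighted nonlinear least
squares in the (d_min, d_max, K = ln c) parameterization, which enforces
c > 0 and makes the delta-method transfer to L_e a function of σ_K alone.
The optimizer is Levenberg–Marquardt (damped Gauss–Newton,
`scipy.optimize.least_squares(method="lm")`) with analytic Jacobian and
tolerances of 1e−12; the decay exponent is clipped at 700 so that extreme
trial values of K degrade gracefully instead of overflowing.  Start values:
d_max from the mean of the upper quartile of observed means, d_min from the
observation nearest l = 0, and c from the slope of a weighted linear fit of
ln(1.001·d_max_init − π̄) on l.  A flat profile has no positive decay and is
rejected at this stage — the pipeline records such species in its exclusion
log, as it does species whose fitted Effect Size is not positive.

Parameter covariance is σ̂²(JᵀWJ)⁻¹ with σ̂² the weighted residual mean
square.  Effect metrics:

* S_e = log2(d_max/d_min); se(S_e) = (1/ln 2)·sqrt(var(d_max)/d_max² +
  var(d_min)/d_min² − 2cov(d_max,d_min)/(d_max·d_min)).  The radical is the
  standard first-order delta form; a `sqrt_se_S=False` toggle reproduces the
  variant without it.
* L_e = ln2/c; se(L_e) = (ln 2)·σ_K·e^(−K)·(1 − σ_K²/4).  The (1 − σ_K²/4)
  factor is a small curvature correction of uncertain provenance; it is
  applied as given, and the plain first-order value is reported alongside
  (`se_L_e_first_order`).  For σ_K < 0.05 the two differ by < 0.1%.
* saturation = 4·L_e, the conservative point at which the profile is treated
  as flat (≈ 94% of the way to the plateau).

Weights enter as residual variance σ²/w, so integer weights are exactly
equivalent to replicated observations and any positive rescaling of the
weight vector leaves the estimates unchanged.

## Wright–Fisher simulator

Haploid population of constant size N, non-overlapping generations, one
linear chromosome held as a dense N×L matrix of 2-bit bases.  Per
generation: parents are drawn multinomially with probabilities proportional
to fitness; fitness is multiplicative, (1+s) per non-reference base inside
the 5′ selection region of each gene (back-mutation restores neutrality);
each offspring receives Poisson(μL) mutations at uniform positions with the
new base uniform over the three alternatives (finite-sites, Jukes–Cantor
style, matching how π is computed from base counts); recombination initiates
Poisson(rL) donor tracts per offspring generation, each copying a
geometric-length segment (mean `mean_tract`) from a uniformly chosen member
of the parental generation, truncated at the chromosome end (one-way gene
conversion — no reciprocal exchange).

Gene lengths are log-normal with location ln 1000 and scale 0.405 — the
mean of ln(1000/450)/1.96 and ln(2200/1000)/1.96 — giving a median of
~1000 bp with ~95% of draws in [450, 2200] bp.  Genes pack left-to-right
with a fixed 50 bp spacing (an arbitrary, recorded constant); per-gene
selection-region lengths are Normal(L_s_mean, L_s_sd) truncated to
[1, gene length].

**Desk scaling.**  Full-scale runs (N = 5000, 20000 generations, 50 kb) are
expensive; the package's presets shrink N while holding θ = 2Nμ, R = 2Nr
and S = 2Ns fixed and running 4N generations, which preserves
diffusion-scale diversity patterns.  The test suite uses N = 500 (neutral
equilibrium checks, 20 kb) and N = 150 with 10 replicates per parameter
combination (selection studies, 50 kb, 20 combinations); the acceptance
script's targets need no simulation beyond drawing gene lengths.  Replicates
of a combination evolve the same randomly generated chromosome under
different seeds; profiles are pooled across replicates before fitting and
per-gene diversities averaged before the diversity–length correlation.
Diversity is measured only at the final generation; the generation count
includes equilibration.

Closed forms: neutral plateau d_max = 2N_eμ; heterozygosity reduction under
scaled selection S = 2N_e s,

    H_T/H_T,0 = 2(S − 1 + e^(−S)) / (S(1 − e^(−S))),

evaluated in an overflow-safe rearrangement for S < 0, with the Taylor limit
1 at S → 0 and asymptote 2/|S| for strong selection.  `invert_selection`
recovers s from a d_min/d_max ratio by root bracketing to 1e−12.

**Default parameter grid.**  When no empirical trait table is supplied,
`default_parameter_table` draws π_S log-uniform in [4e−3, 2e−2], r/m
log-uniform in [0.1, 5], tract means uniform in [200, 1000] bp, L_s uniform
in [40, 200] bp, and |S| log-uniform in [2.5, 10] — the range implied by an
observed 30–80% loss of diversity at gene starts under the reduction
formula above.  These are plausible stand-ins, not canonical species values.

## Structure profiles

Per-gene unpaired probabilities over −100..+200 (produced upstream by any
partition-function folder; never computed here) are averaged across genes
first; the averaged profile is z-scored against a baseline estimated from
the pooled flanks −90..−51 and +151..+190 (80 positions, population sd).
One z-profile per species.  S_ss is the maximum z over the window; L_ss is
the first integer position ≥ +5 with z ≤ 0 (no interpolation), undefined if
z stays positive through +200.  Genes with incomplete windows should be
dropped upstream; the reader rejects them.

## Comparative statistics

Spearman correlations use average ranks with the t-approximation p-value.
Box–Cox λ is chosen on a grid over [−2, 2] in steps of 0.05 by profile
log-likelihood.  VIF is 1/(1−R²) per predictor, with perfectly collinear
columns reported as +inf.  Regressions are on z-scored variables so
coefficients are comparable; p-values are two-sided with no multiplicity
correction.  Backward elimination drops, at each level, the predictor whose
removal minimizes mean out-of-fold RMSE under repeated k-fold CV
(fold-level RMSE averaged across all folds of all repeats; folds by random
shuffling under a fixed seed), reporting RMSE/MAE (response scale) and
in-sample R² per predictor-count level.

**Pagel's-λ GLS.**  The Brownian-motion covariance C has entries equal to
shared root-to-MRCA path length (valid for non-ultrametric trees); λ scales
the off-diagonal entries.  β and σ² are profiled out analytically, and λ is
estimated by maximizing the profile likelihood over
[λ_min/2, 1.0]: λ_min is the most negative λ keeping C(λ) positive definite
(so mildly negative λ — "anti-signal" — is admissible), and the halving
keeps the search away from the singular edge, where the log-determinant
diverges and produces a spurious likelihood spike.  The ceiling is 1.0, the
Brownian case, because for ultrametric trees C(λ) loses positive
definiteness almost immediately above 1 and the same boundary pathology
appears there; this is also the convention of the standard R
implementations.  A coarse grid precedes local refinement (the profile can
be multimodal), and the 95% CI is the profile-likelihood set
{λ : logL ≥ logL_max − χ²₁(0.95)/2}, clipped to the search box.  Star
phylogenies (all off-diagonals zero) are flagged unidentifiable rather than
fitted.  Missing trait values are handled upstream by listwise deletion.

## Synthetic data

Every generator is deterministic under its seed and records its generating
parameters ("truth") in a sidecar.

* **Alignments.**  All codons after ATG come from 4-fold families, so silent
  rank l is codon l+1.  Sites are biallelic: the minor-allele count m is the
  solution of π(m) = 2m(N−m)/(N(N−1)) = π̄(l), randomized between the two
  bracketing integers with probabilities that make E[π] exact.  Biallelic
  sites suffice because target diversities are far below the triallelic
  regime, and the closed-form inversion is then exact.  Columns are
  independent across sites and genes — adequate because the downstream fit
  consumes only per-rank means and gene counts; coalescent-realistic linkage
  is the simulator's job, not this generator's.
* **Accessibility profiles.**  The species-level curve is a 0.5 baseline
  plus a truncated-Gaussian bump that reaches the baseline exactly at the
  edge of its support (peak + 2.5 widths), giving a well-defined truth zero
  crossing, plus a fixed positional flank pattern drawn once per species and
  standardized to the requested flank sd (zero inside the bump support).
  Per-gene noise rides on top and averages out across genes.  The split
  matters: if all flank variability were independent per gene, averaging
  genes would annihilate the baseline sd and the z-score denominator would
  be an artifact of gene count; a species-level pattern models
  sequence-driven pairing propensity shared across the genome and keeps
  S_ss ≈ height/flank_sd well-defined.
* **Trees and traits.**  Pure-birth trees (dendropy) with all tip edges
  extended by the waiting time to the next unrealized speciation — the
  sampler otherwise stops exactly at the n-th event, leaving zero-length
  cherries and a singular covariance.  Response = Xβ + noise with covariance
  σ²·C(λ_true); predictors are iid normal per tip.

## What passing tests do and do not show

The synthetic alignments have independent columns and no strain relatedness,
so recovery there validates the estimator chain, not robustness to linkage
or population structure; the Wright–Fisher tests supply linkage but at desk
scale (N = 150–500), where drift noise is larger than in the full-scale
regime the presets mirror.  The structure generator's flank pattern is an
idealization of shared positional variability.  Real-data concerns that the
suite cannot exercise: alignment error, annotation error in start codons,
unequal strain relatedness distorting π, and selection models beyond uniform
(1+s) within a fixed 5′ region.

## Degenerate inputs and tie-breaks

Alignments need ≥ 2 rows and length divisible by 3; sites with < 2 ungapped
bases are skipped with a debug log; genes with zero eligible silent sites
contribute an empty profile; a species whose genes are all empty is an
error.  π̄(0) = 0 makes the model-free effect size infinite (flagged, not
raised).  Fits that fail to converge return `converged=False`; a singular
Jacobian raises.  `invert_selection` rejects ratios above 1 (diversity
excess is not purifying selection).  All CLI errors exit non-zero with a
message on stderr.
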