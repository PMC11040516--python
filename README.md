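# divlen

Tools for quantifying the reduction of synonymous nucleotide diversity near
bacterial translation initiation sites (TIS), and for asking what shapes that
reduction across species.

## The problem

Nucleotide diversity π at a site — the average pairwise difference among
sampled sequences — is the workhorse for estimating effective population
size (under neutrality π equilibrates near 2·N_e·μ for haploids).  4-fold
degenerate ("silent") third codon positions are the usual stand-in for
neutral sites.  But silent sites near the start of a gene are not neutral:
purifying selection on translation initiation (mRNA accessibility around the
start codon, and whatever else acts on 5′ gene regions) depresses their
diversity, and linkage spreads the deficit into flanking sites.  One visible
consequence is a positive correlation between a gene's length and its mean
silent-site diversity: short genes are dominated by the depressed 5′ region.

`divlen` profiles mean silent diversity by position, fits the recovery curve,
simulates the process forward in time, and relates the fitted quantities to
species traits with phylogenetic comparative statistics.

## The model

Mean diversity at silent-site rank *l* from the start codon is fitted with an
asymptotic regression (negative exponential),

    π̄(l) = d_max + (d_min − d_max) · e^(−c·l) + ε,     ε ~ N(0, σ²/w(l))

weighted by the number of genes w(l) contributing at each position.  Two
summary statistics follow:

* **Effect Size** `S_e = log2(d_max / d_min)` — log-2 fold reduction at the
  TIS relative to the plateau;
* **Effect Length** `L_e = ln 2 / c` — the position at which the curve is
  halfway between d_min and d_max; saturation is taken conservatively at
  4·L_e.

Standard errors come from the delta method on the (d_min, d_max, K = ln c)
covariance.  The companion components are:

* a Wright–Fisher forward simulator (haploid, finite sites, donor-tract
  recombination, multiplicative (1+s) fitness confined to 5′ gene regions)
  with the closed-form conversions `d_max = 2·N_e·μ` and
  `H_T/H_T,0 = 2(S−1+e^(−S)) / (S(1−e^(−S)))`, S = 2·N_e·s;
* z-score profiles of per-base unpaired probabilities over −100..+200 around
  the TIS (baseline from the −90..−51 and +151..+190 flanks), summarized as
  `S_ss` (max z) and `L_ss` (first position ≥ +5 with z ≤ 0);
* cross-species statistics: Spearman correlations, Box–Cox transforms, VIF,
  standardized regression, backward elimination under repeated 10-fold CV,
  and GLS with Pagel's λ on a species tree;
* synthetic-data generators with recorded ground truth for every input the
  pipeline consumes.

## Worked example

Generate alignments for a synthetic species whose silent diversity follows a
known curve, profile them, and fit:

```python
from divlen import synth, diversity, asr

spec = synth.SynthSpec(n_strains=30, n_genes=400,
                       d_min=0.002, d_max=0.010, c=0.01, seed=1)
alignments, truth = synth.synth_alignment_set(spec)
profiles = [diversity.gene_silent_profile(a) for a in alignments]
profile = diversity.species_mean_profile(profiles, max_sites=500)
fit = asr.fit_asr(profile)
m = asr.effect_metrics(fit)
print(f"d_min = {fit.d_min:.5f}   d_max = {fit.d_max:.5f}   c = {fit.c:.5f}")
print(f"Effect Size  S_e = {m.S_e:.2f} +/- {m.se_S_e:.2f}")
print(f"Effect Length L_e = {m.L_e:.1f} +/- {m.se_L_e:.1f} silent sites")
print(f"saturation ~ 4 L_e = {m.saturation:.0f} silent sites")
```

prints

```
d_min = 0.00204   d_max = 0.01010   c = 0.00935
Effect Size  S_e = 2.31 +/- 0.16
Effect Length L_e = 74.1 +/- 5.6 silent sites
saturation ~ 4 L_e = 296 silent sites
```

The generating curve had L_e = ln2/0.01 ≈ 69.3 and S_e = log2(5) ≈ 2.32:
with 400 genes the fit recovers both within one standard error.  An S_e of
2.3 means diversity at the start codon is about 5-fold below the plateau,
and the profile is effectively saturated ~300 silent sites into the gene.

The same flow is available from the shell:

```bash
divlen synth alignments --n-genes 400 --seed 1 --out-dir sp1/
divlen profile --species-dir sp1/ --out profile.tsv
divlen fit --profile profile.tsv --out asr.tsv
divlen simulate --n-combinations 5 --replicates 3 --out-dir runs/
```

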