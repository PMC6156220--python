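# Methods

This note documents the models, parameter choices and numerical
decisions behind `homeopop`, and what the synthetic study does and does
not establish about real data.

## The synthetic allotetraploid study

The generator (`homeopop.simulate`) builds a desk-scale allotetraploid
resequencing experiment with complete truth tables. Its defaults are the
study conditions the downstream analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_accessions` | 25 | selfing accessions, one haplotype per subgenome (disomic inheritance, residual heterozygosity only via the `het_rate` knob) |
| `parental_divergence` | 0.03 /site | Jukes–Cantor divergence between the two parental references |
| `outgroup_divergence_factor` | 3 | outgroup branch length relative to `parental_divergence`; the outgroup's true divergence is not independently known, so it is a free parameter |
| `theta_syn` | 0.005 /site | scaled synonymous mutation rate (4Nμ) |
| `dfe_shape`, `dfe_mean` | 0.3, 100 | gamma DFE of Ne·s against new nonsynonymous mutations (leptokurtic, as typically estimated in plants) |
| `alpha_true` | 0.25 | adaptive fraction of nonsynonymous divergence, injected into a flagged 10% of genes |
| `read_length`, insert, `coverage` | 100 bp, 200–500 bp, 12× | paired-end read geometry of the emulated resequencing design |
| `error_rate` | 0.01 | per-base sequencing error |
| `impact_rate`, singleton prob. | 0.2, 0.85 | per-gene probability of one injected loss-of-function variant; carrier count 1 with probability 0.85, else uniform 2–5 |

Polymorphism is placed per gene: synonymous variants come from a
single Hudson-coalescent genealogy per gene (so synonymous sites within
a gene are linked), while nonsynonymous variants are drawn
independently per site from the Poisson-random-field (PRF) expected
spectrum under a per-gene selection strength γ drawn from the gamma
DFE — **independently for the two homeologs of a pair**, which is what
decorrelates homeolog diversity statistics while leaving their marginal
distributions identical. To keep the two site classes demographically
consistent, the PRF class expectations are multiplied by the
demography's per-class distortion factors, estimated once from the
coalescent itself (8,000 loci, fixed internal seed, cached); this is
exactly the shared-nuisance structure the DFE model assumes.

The default demography is a bottleneck: a normal-sized recent epoch
over a 50×-smaller ancestral population (sizes 1 → 0.02 at time 0.4 in
units of 2N generations). Lineages surviving into the ancestral epoch
coalesce almost instantly, giving star-like genealogies, an excess of
rare variants, and strongly negative Tajima's D — the signature of a
recently founded selfing polyploid.

Parental and outgroup divergence are neutral Jukes–Cantor
substitutions (stop codons avoided inside CDS, first and last codons
protected), so realised CDS divergence tracks the nominal rate;
purifying selection shapes polymorphism, and the abstract
selected-counts generator (`simulate_selected_counts`) additionally
thins nonadaptive divergence by the DFE-averaged relative fixation rate
and adds adaptive divergence so its expected fraction equals
`alpha_true`.

What the generator does **not** emulate: chromosome-scale genome
structure, gene conversion and homeologous exchange, indel realism
beyond injected frameshifts, base-quality variation, mapping biases of
real aligners, and linkage between the nonsynonymous sites of a gene.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artefact of
real resequencing data.

## Poisson random field machinery

For a deleterious strength γ = Ne·s ≥ 0 the expected unfolded class-i
contribution is

    B_i(γ) = C(n,i) ∫₀¹ H(γ,x) x^i (1−x)^{n−i} dx,
    H(γ,x) = (e^{−2γx} − e^{−2γ}) / ((1 − e^{−2γ}) x (1−x)),

normalised so B_i(0) = 1/i. This has the closed form
B_i(γ) = C(n,i)·B(i, n−i)·(₁F₁(i; n; −2γ) − e^{−2γ})/(1 − e^{−2γ})
in terms of Kummer's confluent hypergeometric function, evaluated
directly via `scipy.special.hyp1f1`; below γ = 0.05 a 14-term power
series avoids the cancellation between numerator terms. Expectations
over the gamma DFE use composite Simpson quadrature on a fixed
logarithmic γ-grid (2049 points spanning 10⁻⁶–10⁸) with the mass below
the grid treated as exactly neutral; the kernel matrix is precomputed
once per sample size, so a DFE expectation inside MCMC costs one
density evaluation and a mat-vec. Against independent nested adaptive
quadrature the class means agree to ~4×10⁻⁹ relative. The relative
fixation rate of a deleterious mutation is 2γ/(e^{2γ} − 1).

## DFE + α model and MCMC

Folded synonymous classes are θ_s·r_j·c_j (c_j the folded neutral
shape) and nonsynonymous classes θ_n·r_j·F_j(β, m̄), with shared
per-class nuisance multipliers r_j (r_1 ≡ 1) absorbing demography and
ascertainment; counts are independent Poissons. Parameters are sampled
on log scale by Metropolis–Hastings with Gaussian proposals, scale
adapted during burn-in toward 20–40% acceptance, under log-uniform
priors (β ∈ [0.05, 5], m̄ ∈ [10⁻³, 10⁵], θ ∈ [10⁻⁸, 10⁸],
r_j ∈ [10⁻³, 10³]). The desk-scale schedule is 10⁵ replicates, thinned
every 100 after a burn-in of max(reps/10, 20 000); the full-scale
schedule (10⁶/1000/10⁵) is available through the same arguments.

Two identifiability points matter and are deliberate design choices:

1. **Tied mutation scales.** With θ_n free, the folded SFS shape leaves
   (β, m̄) on a near-flat ridge — e.g. (0.32, 36) fits data generated at
   (0.3, 100) within ~1 log-likelihood unit at 5×10⁴ SNPs — because
   strongly deleterious mass is invisible in polymorphism. `run_mcmc`
   therefore accepts `site_ratio` = Ln/Ls and ties θ_n = θ_s·(Ln/Ls)
   (equal per-site mutation rates), so the genome-wide *deficit* of
   nonsynonymous polymorphism identifies the invisible tail. All
   pipeline fits pass the ratio.
2. **Data scale.** Category recovery to a few percentage points needs
   genome-scale site counts; the recovery analyses use Ls = 3×10⁶,
   Ln = 10⁷ (the coding-site budget of a ~21k-gene plant genome), where
   the four Ne·s category proportions are recovered within 1–2 points
   and α within ~0.02 of its true 0.25.

α is computed per posterior sample as
(Dn − Ds·(Ln/Ls)·E_DFE[2γ/(e^{2γ}−1)])/Dn with a central 95% interval.
On fully neutral data the posterior piles up at negligible selection
only after the chain has had time to descend the m̄ prior range; the
neutral-sanity check runs 2.5×10⁵ replicates for that reason. A small
positive α bias on weak data is inherent: fixation probability falls
roughly ten times faster in γ than the SFS distorts, so slightly
deleterious posterior mass depresses the predicted nonadaptive
divergence before it is detectable in polymorphism.

## Neutrality statistics

Tajima's D uses the 1989 variance constants; Fu & Li's D*/F* use the
published corrected constants with within-sample singletons (derived
count 1 or n−1); Fay & Wu's H is the unnormalised π − θ_H and requires
outgroup polarisation. Statistics are reported as absent (None) when
S = 0. Missing data are handled by per-site pairwise deletion for π;
SFS construction uses complete columns only, with hypergeometric
projection available for down-sampling.

One calibration subtlety, measured here and worth stating: the
*per-locus mean* of Tajima's D under strict neutrality at n = 25,
θ = 5 is ≈ −0.086 (20 000 replicates; independent genealogies from
msprime give −0.073 ± 0.015), because the variance-normalised statistic
is not mean-centred at finite S. The unbiased calibration is the pooled
form — D computed from summed S and π over the replicate loci — which
sits within ±0.01 of zero; the acceptance script reports both. The
same effect puts the neutral mean of Fu & Li's D* near −0.067.

Site counting is Nei–Gojobori-style enumeration of the nine single-base
changes per codon (mutations creating stops count as nonsynonymous);
polymorphic and fixed sites are classified per site in the context of
the ingroup major codon. Multi-hit codons are not resolved by averaging
over mutational pathways; at desk-scale divergence this affects a
negligible fraction of codons and is a known limitation relative to
path-counting methods.

## Read sorting and polishing

Placement is ungapped, seeded by exact 21-mers at the read's start,
middle and end, minimising mismatch count with ties to the smallest
offset; reads above a 10% mismatch-rate ceiling (a flag) are
unclassified, and equal mismatch counts on both references — including
0/0 — are `common`. Polishing substitutes the majority non-reference
base only where coverage is within [20%, 200%] of the library average
and a Phred-scaled binomial variant quality (error rate /3 per specific
base) reaches 30. Indel-containing reads fall to unclassified by
construction. Equivalence with probabilistic classifiers of
homeolog-sorting pipelines is not claimed; the mismatch rule is the
simplest classifier consistent with quantifying mismatches to either
parent.

## Other numerical choices

* Fisher's exact test is two-sided by the probability-mass rule
  (summing tables with probability ≤ observed), matching exhaustive
  hypergeometric enumeration.
* The MK/DoS classifier uses marginal p < 0.05 and a DoS dead band of
  ±0.01 by default (both flags), with no multiple-testing correction.
* LD "confidence bands" are central empirical quantiles of pairwise r²
  within each 50-bp bin (50% = interquartile, 90% = 5–95%); accessions
  are haploid genotype vectors, so genotype r² equals haplotype r².
  Unpaired region contrasts use the two-sample rank-sum test; the
  signed-rank test is reserved for homeolog-paired data (a
  compatibility flag forces the signed-rank naming only).
* Reciprocal best hits use a global aligner (match +1, mismatch −1,
  gap −2/−0.5) with a score floor of 100 and minimum aligned length of
  200 bp standing in for an E-value cutoff; the score matrix is
  symmetric, so one all-vs-all pass serves both directions.
* Coordinates are 0-based half-open internally; GFF3 and VCF writers/
  readers are the only 1-based crossing points.
* All generator randomness derives from one seed with sub-streams keyed
  by module name (CRC32 of the name), so adding a component never
  reshuffles another's draws; identical configurations produce
  byte-identical output files.

## Problem sizes

The shipped analyses run at desk scale by choice: 60-gene studies for
the pipeline drivers, 160 genes / ~10⁵ reads for read-sorting accuracy,
2000 loci for neutral calibration, 400 gene pairs for the
homeolog-decorrelation pattern, and 10⁵-replicate MCMC chains. Each
stage scales linearly in genes and reads if larger studies are needed.
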