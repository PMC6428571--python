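# Methods

This note documents the statistical model behind `polyadapt`, the
conventions and defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## The drift model and the Qx / latitude nulls

Allele frequencies in M populations are modelled as drifting from an
ancestral frequency `p̄_l` with covariance proportional to a shared M×M
kernel `F`:

    p_l· = p̄_l + ε,   ε ~ MVN(0, p̄_l(1 − p̄_l) F).

`F` is dimensionless, symmetric, positive semidefinite; its diagonal plays
the role of per-population F_ST-like drift magnitudes and its off-diagonal
encodes shared history.  A population polygenic score is the effect-
weighted frequency sum `Z_m = Σ_l β_l p_lm`.  Conditional on the effects,
neutral drift therefore gives

    Var(Z̃) = V_A · T F Tᵀ,   V_A = Σ_l β_l² p̄_l(1 − p̄_l),

where `Z̃ = TZ` are mean-centered scores and `T = I − 11ᵀ/M`.  The Qx
statistic is the Mahalanobis norm of `Z̃` under this null, computed with a
pseudo-inverse restricted to the kernel's numerical rank (M − 1 for a
full-rank `F̂`), and is chi-square with that rank as degrees of freedom.
The latitude statistic contrasts scores along a mean-centered latitude
vector `Y`: `t = YᵀZ/√(V_A·YᵀF̂Y)`, standard normal under drift.

A note on scale conventions: the same test is often written with a kernel
`2·V_A·F` — that form belongs to diploid-coded scores (`Z = 2Σβp` with
`V_A = 2Σβ²p̄(1−p̄)`) and is algebraically identical to the form above
after the change of scale.  Because this package computes scores and
`V_A` on the allele-frequency (haplotype) scale, only the `V_A·F` kernel
is internally consistent; using `2·V_A·F` with frequency-scale scores
halves Qx and destroys the chi-square calibration that the null tests in
the suite verify (replicate mean ≈ M − 1, KS-uniform P values).

`F̂` is estimated from putatively neutral SNPs — never from the
trait-ascertained set — as the average over SNPs of
`outer(p − p̄)/ (p̄(1−p̄))`, symmetrized and PSD-projected.  With `p̄` taken
as the across-population mean (the only option for real data) the
estimator converges to `T F Tᵀ`, which is exactly the part of `F` the Qx
and latitude statistics use; when the ancestral frequencies are known
(simulation ground truth) they can be supplied and the estimator is then
unbiased for `F` itself, which is how the recovery checks are run.

## The stratification mechanism

The generator's GWAS model is

    β̂_l = β_l + a·δ_l + N(0, se_l²),    δ_l = Σ_m axis_m p_lm,

with `axis` a mean-zero vector over populations (e.g. centered latitudes,
or a two-population contrast).  This is the signature of uncorrected
stratification: any variant differentiated along the structure axis
acquires an effect-size bias proportional to its frequency contrast.  The
bias coefficient used in the calibrated experiments is chosen so that
`E|a·δ| ≈ se` — a bias of the same order as the per-SNP sampling noise,
individually invisible but devastating in aggregate: with 1000 ascertained
SNPs it drives the Qx rejection rate from ~5% to ~100%.

SDS-like scores carry the analogous confound plus a true-selection term:

    SDS_l = c·δ_l + s·1[l ∈ selection set]·sign(β_l) + N(0, noise_sd²),

reported with respect to the derived allele, which the simulator defines
as the effect allele.  With `c > 0` and `a > 0` the trait-aligned trend
reproduces the confounded-GWAS regime (strongly positive Spearman ρ);
with `a = 0` the same SDS data yield a null trend.  With `s > 0` and no
confounding, only the shift test at genome-wide-significant SNPs fires
while the frequency-contrast probe stays null — the dissociation that
distinguishes true within-population selection from cline artifacts.

## Scores, standardization, credible intervals

`p̄_l` is the *unweighted* mean frequency across the analyzed populations,
not a sample-size-weighted mean — deliberate, because ancient groups have
very different sample sizes.  Credible intervals update a Uniform prior
with allele counts `x of n` per locus and population, giving a
Beta(1 + x, 1 + n − x) posterior; the score variance
`V_Z(m) = Σ β_l²·Var_posterior` treats loci and populations as independent
(no LD correction, matching the ascertainment of independent SNPs), and
the 95% half-width is `1.96·√V_Z`, reported both in trait units and
divided by `√V_A`.  Coverage checks center the band at the posterior-mean
score `Σ β_l (x+1)/(n+2)`, the Bayesian-calibrated center; measured
coverage at n = 50 haploids is ~94–95%.

## Ascertainment

- *Lowest-P per LD block*: blocks are read from BED-like files (0-based
  half-open, converted to the package's 1-based inclusive positions at the
  boundary); ties break by (position, id).
- *Clumping*: greedy PLINK-style — index candidates below `p1` processed
  by ascending (P, position, id); each index absorbs unassigned SNPs below
  `p2` within the window whose genotypic r² with the index is strictly
  above the threshold ("above an r² threshold"); each SNP joins at most
  one clump.  Window is measured index-to-candidate.
- *Pruning*: position-order greedy; a SNP is removed when an already-kept
  SNP within the window has r² ≥ the threshold (the earlier-position SNP
  is kept).
- r² is genotypic (squared Pearson correlation of 0/1/2 counts), so
  unphased panels suffice; a monomorphic SNP has undefined correlation and
  is treated as r² = 0 with a warning.

Both clumping and pruning are verified against naive brute-force
transcriptions of their definitions on hundreds of randomized ≤12-SNP
instances.

## tSDS analysis

Raw SDS are normalized to mean 0, unit sample variance (n − 1 denominator)
within each 1% derived-allele-frequency bin after excluding the MHC
(chromosome 6, 25–35 Mb — the region is named in the literature, the
bounds are this package's convention).  Alignment flips the sign so that
positive tSDS means the trait-increasing allele carries the
recent-selection-like signal; SNPs whose derived allele matches neither
GWAS allele, or whose β is exactly 0, are dropped and tallied.

The trend statistic is the Spearman correlation between the score and the
significance order (ranks of −P), so positive ρ = selection-like.  Errors
come from a delete-one-block jackknife over B contiguous blocks in genomic
order (default B = 100, i.e. 1% of SNPs per block);
`SE = √((B−1)/B·Σ(θ_i − θ̄)²)`, which on singleton blocks for the mean
reduces exactly to the classical standard error.  A regression slope of
the score on the [0, 1]-scaled significance rank is reported with its
analytic P, and binned means (default 1000 SNPs per bin, the final
smaller bin flagged) provide the familiar staircase curve.  The shift
test at independent genome-wide-significant SNPs uses
`z = mean(tSDS)·√n` against the standard normal null that normalization
imposes.

## Stratification diagnostics

PCA uses centered allele counts scaled by `1/√(2p(1−p))` (unit-variance
convention, toggleable — external tools differ and the choice is not
standardized), after a MAF > 5% floor, optional exclusion intervals and
optional r² < 0.2 pruning; missing genotypes are mean-imputed only here,
never in frequency computation.  PC signs are fixed deterministically
(largest-magnitude score positive).  Per-SNP loadings are the allele-count
coefficients from least squares of each PC score on (intercept, sex,
count), computed by Frisch–Waugh residualization so they are available
for SNPs beyond the PCA input set; SNPs whose residual count variance is
at round-off scale (monomorphic or sex-collinear) get missing loadings.

Loading–effect correlations use a contiguous-block jackknife in genomic
order (default 1000 blocks, reduced with a warning when SNPs are fewer)
with two flags per PC: nominal (P < 0.05) and Bonferroni over 20 PCs
(P < 0.0025).  Frequency contrasts report `p_A − p_B` for the
trait-increasing allele (the A1 contrast negated when β < 0).  Heat maps
bin SNPs by minor-allele frequency in each population (0.05-wide bins)
and mask cells with fewer than 300 SNPs.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: MVN drift
with an arbitrary covariance (matching the Qx null exactly, so
calibration tests are clean — a Balding–Nichols Beta model would not),
frequency-proportional stratification bias, cline-confounded and
selection-shifted SDS, and binomial diploid panels with an optional
block-latent-variable LD scheme (shared within-block haplotype indicator)
sufficient to exercise clumping and pruning.  It does **not** emulate
coalescent genealogies, recombination maps, realistic site-frequency
spectra, linked selection, or the singleton-density machinery that
produces real SDS — so passing tests demonstrate correctness and the
confounding mechanism, not realism of any particular human dataset.
Frequencies are clipped to [0.001, 0.999]; with the default drift scales
the clipped mass is negligible (the variance checks in the suite pass at
5% tolerance).

## Study conditions used by the acceptance experiments

Chosen once as a desk-scale analogue of a continental cline and stated
here as the package's own design: M = 6 populations at latitudes 40–65°,
F = 0.02·I + 0.01, ancestral frequencies Uniform(0.05, 0.95), 1000
ascertained + 2000 null SNPs per replicate, per-SNP GWAS se = 0.02, true
effects N(0, 0.05²); bias calibrated to `E|a·δ| = se` on a dedicated
replicate.  The tSDS experiments use a two-population cline (F = 0.02·I,
10 000 SNPs, cline coefficient c = 5 against unit SDS noise, chosen so the
cline explains ~8% of SDS variance); the selection experiments put
s = 0.3 on 300 strongly associated SNPs (|β| = 0.5, genome-wide
significant by construction) so the shift test operates at the scale the
z = mean·√n null makes interpretable.  Replicate counts (300 for null
calibration and rejection rates, 100 for trend and shift power, 2000 for
coverage, 500 randomized oracle instances) balance statistical resolution
against a single-CPU run of a few minutes; `scripts/acceptance.py` uses
the same conditions with some counts halved.

## Known limitations

- The empirical Qx null re-ascertains random SNP sets with optional
  decile frequency matching; it does not model ascertainment through the
  P value itself (winner's curse), which the paper-scale analyses handle
  by matching on frequency only.
- Harmonization drops palindromic A/T and C/G SNPs outright rather than
  resolving them by frequency; conservative, and the simulator never
  generates them.
- Jackknife P values use the normal approximation; for very small SNP
  sets the block bootstrap would be preferable.
- The pipeline's "block" ascertainment on simulated data uses fixed-span
  position blocks, a stand-in for empirically derived LD blocks, which
  the block reader accepts from real BED-like files.
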