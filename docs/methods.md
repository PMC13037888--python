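# Methods

## Setting and scope

The package models the analysis of leaf boron accumulation in a young,
severely bottlenecked, selfing island population: inbred accessions are
effectively homozygous and are treated throughout as one haplotype each
(calls coded 0/1, never 0/1/2). Associations are mapped with a
kinship-corrected linear mixed model; tandem duplications of a transporter
locus are genotyped from read depth and their breakpoint junctions
classified; and population-genetic summaries prepare inputs for genealogy
inference. Genealogy/ARG inference itself, Bayesian sparse LMM chip
heritability, de novo assembly and split-read SV calling are out of scope:
the pipeline stops at verified input files or uses light-weight stand-ins
(the depth-changepoint helper) that are labelled as such.

## Phenotype QC, BLUEs and H²

Contaminated plants are removed by a z-score filter: z uses the mean and
sample SD (n−1) of each channel (B, plus the soil sentinels Cr and Ti)
computed once over all rows, and a row is dropped if |z| > 3 on any
channel. The filter is deliberately single-pass — iterative re-filtering
would change the retained set and is not part of the procedure. Accessions
with fewer than 3 surviving replicates are dropped entirely.

BLUEs fit `value = accession (fixed) + block (random) + residual` by REML.
With a single variance component the REML criterion is profiled to one
dimension and optimized over log γ, γ = σ²_block/σ²_e ∈ [1e−6, 1e6], with
bounded Brent search (xatol 1e−10); the Woodbury identity keeps the cost
proportional to the number of blocks. If block effects are not estimable
(one block, or complete accession–block confounding detected by a rank
check) the fit falls back, with a warning, to OLS with sum-to-zero fixed
block contrasts, which keeps accession estimates on the original µg/g
scale. Broad-sense heritability uses the same machinery with accession as
the single random effect: H² = σ̂²_line/(σ̂²_line + σ̂²_e), components
truncated at zero (a ratio pinned at the search floor reports a zero line
component). H² is invariant to affine rescaling of the element values.

## The association scan

Genotype calls failing DP > 3 or GQ > 20 (strict inequalities) are set
missing; non-biallelic records are dropped; variants are then filtered to
MAF ≥ 5% (computed on non-missing calls, before imputation) and
missingness < 10%. The kinship matrix is the centered estimator
K = WWᵀ/p with mean-imputed, mean-centered variant columns.

Each marker is tested in `y = intercept + covariates + xβ + u + ε`,
`u ~ N(0, σ²_g K)`, `ε ~ N(0, σ²_e I)`. On the eigenbasis of K the
covariance is diagonal, so the REML log-likelihood for the variance ratio
δ = σ²_e/σ²_g is cheap to evaluate; δ is optimized per marker (not frozen
at the null model) by Brent on log δ ∈ [log 1e−5, log 1e5] with tolerance
1e−8 — exact per-marker REML is affordable at these sample sizes and
removes any ambiguity about approximation error. The Wald statistic
(β̂/se)² is referred to χ²₁, the large-sample mixed-model convention; at
n ≈ 100 this is mildly anticonservative relative to an F reference (the
χ²₁-vs-F(1, n−q) median ratio is ≈ 1.01), which is visible as a small
upward shift in genomic-control λ and is accepted as documented behaviour.
Markers collinear with the covariates report missing statistics. Effect
sizes are per allele copy; because lines are homozygous, reported
homozygote contrasts are 2β. Conditional scans append the mean-imputed
lead-marker genotypes as fixed covariates and exclude those markers from
the output.

Scan-level statistics: Bonferroni cut α/m with α = 0.05; Benjamini–
Hochberg step-up cut at q = 0.10 (None when nothing qualifies); genomic
control λ = median(χ²_obs)/median(χ²₁), the denominator computed by
inverse CDF (0.4549 to four decimals, never hard-coded). Group contrasts
(e.g. B by haplotype class) use the Mann–Whitney–Wilcoxon test, exact when
both groups have n ≤ 20 without ties, otherwise the normal approximation
with mid-ranks and tie-corrected variance.

## Copy number and junctions

Depth is averaged in 800 bp windows every 400 bp. Window starts advance
while a full window fits; an uncovered tail shorter than half a window
extends the last window, a longer tail becomes its own truncated window.
Ratios divide each window mean by the pooled per-base mean of the two 3 kb
flanks immediately outside the breakpoints (pooling the flanks is a
choice — the mean over both sides is the default, a median is available);
flanks running past the profile are clipped with a warning. Only windows
fully inside the duplicated span enter the copy-number median, because
breakpoint-straddling windows dilute the signal; the integer call per
haplotype rounds half-up, so ratios in [1.5, 2.5) give CN 2. All ratios
and calls are invariant to rescaling the profile by any positive constant.
The changepoint helper (runs of ≥ 3 consecutive windows above 1.5× the
global median) is a deliberately simple stand-in that seeds breakpoint
refinement; it is not a structural-variant caller.

Junction classification anchors 50 bp of reference context — the sequence
ending at the duplication end (copy-1 terminus) and starting at the
duplication start (copy-2 head) — in the junction-spanning read by exact
match (case-insensitive; 'N' never matches). Overlapping anchors share the
microhomology motif; separated anchors bound a novel insertion; adjacent
anchors are blunt unless the reference itself carries identical sequence
at both breakpoint ends, in which case the longest zero-insert
microhomology explanation is preferred (a blunt join and a k-bp
microhomology junction produce literally identical sequence there, so the
tie-break is a convention, applied consistently by constructor and
classifier). The synthetic constructor edits the reference to install a
requested motif and then actively breaks accidental homology beyond the
requested length, so its recorded truth is exactly what the sequence
shows.

## Population-genetic summaries

Watterson's θ_w = S/(a_n·L) counts sites segregating among the sampled
haplotypes, with n = number of accessions (one haplotype each, matching
the haploid genealogy model downstream). The missingness-corrected
mutation rate is μ₀(1 − missing/total) per 10 Mb window every 50 kb with
μ₀ = 7×10⁻⁹ per bp per generation: `total` counts biallelic SNPs with
≤ 10% genotype missingness and `missing` counts those among them where any
called genotype fails DP > 3 and GQ > 25 — i.e. sites a
missing-data-intolerant genealogy method must drop. Which sites count as
"missing" is genuinely underspecified in this procedure; counting
completeness failures is the reading adopted here. Windows are truncated
at chromosome ends rather than dropped, so ends are never rateless.
Genetic map distances are multiplied by the outcrossing fraction
(5% ⇒ division by twenty), generalizing the correction to any rate in
(0, 1]. The genealogy-input GQ cutoff (25) is intentionally different
from the GWAS cutoff (20); they are separate configuration keys. The
haps/sample/map bundle writes one haplotype row per line, inserts TD
breakpoints as biallelic pseudo-variants in position order (collisions
with existing sites are an error), and parses back exactly.

## The synthetic generator

The generator reproduces the statistical structure the pipeline must
handle, not the biology of any real population. Genotypes follow a
finite-island Balding–Nichols construction: an island-wide derived-allele
frequency is drawn from a neutral SFS (mass ∝ 1/i), each subpopulation's
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F_ST = 0.3 by default
(two subpopulations), and haploid calls are Bernoulli draws. When a
per-site θ target is given, the site count is Poisson(θ·a_n·L) and each
site is redrawn until it segregates (and clears any MAF floor), which
makes the realized Watterson estimator exactly unbiased for the target —
this is the property the calibration tests check. The generator does not
simulate a coalescent, linkage disequilibrium decay along the chromosome,
selection, or read-level data, so passing tests say nothing about those
aspects of real data.

The trait is `B = intercept + genetic value + block + residual` with one
row per accession × 4 blocks (the replicated randomized-block design).
The residual scale is derived from the target H²: σ²_env = var(g)(1−h²)/h²,
split 30%/70% between block and plant-level residual, so the realized
broad-sense heritability matches the target by construction, with
H² = 0.75 as the default regime of interest. Defaults place the causal
SNP effect at 11.4 µg/g per allele (homozygote contrast ≈ 22.8 µg/g, the
scale of the strong transporter signal), baseline leaf B at 40 µg/g DW.
Soil-contamination outliers hit 2% of plants jointly on Cr and Ti with an
8× multiplicative shift — far beyond the z = 3 filter — plus a B
inflation, so QC has unambiguous targets. Depth profiles are negative
binomial with mean depth × copies inside the duplicated span (Poisson at
dispersion 0, 30× by default). All generators derive child seeds
deterministically from one integer seed.

## Test design choices and problem sizes

The statistical acceptance checks run at deliberately reduced sizes chosen
to keep the full suite fast while leaving the tested properties intact:
null calibration uses 50 scans of 100 samples × 250 markers; oracle
equivalence uses 20 instances at n ≤ 10 against a dense-grid GLS oracle;
copy-number recovery uses 500 regions of 20 kb at 30×; heritability
recovery uses 100 simulations at 150 accessions × 4 replicates; the
end-to-end check runs 100 seeded pipelines of 200 samples × 300 markers.

The "structured null" for calibration is a polygenic background drawn over
the genotyped panel (u = Σ w_j x_j, scaled to half the phenotypic
variance) plus i.i.d. noise. This is the infinitesimal model whose
covariance is exactly proportional to the kinship matrix, i.e. the
confounding the LMM is designed to absorb, and the standard design for
this experiment; measured median λ is ≈ 1.07 for the LMM versus ≈ 2.4 for
naive OLS. A fixed per-subpopulation mean shift is a harder, mis-specified
confounder: at these scaled-down sizes the LMM removes most but not all of
it (median λ ≈ 1.12–1.17). That residual inflation under mean-shift
confounding, and the mild small-n anticonservatism of the χ²₁ Wald
reference, are known limitations and are documented rather than corrected.

## Numerical conventions

Coordinates are 0-based half-open internally; VCF and map positions
(1-based) are converted at I/O boundaries. Kinship symmetry is required to
1e−10 and eigenvalues to ≥ −1e−8 (clipped to zero afterwards). Wald
p-values are floored at 1e−300 so degenerate zero-noise constructions
still satisfy p ∈ (0, 1]. Ties in copy-number rounding go half-up. The
variance-ratio searches are bounded ([1e−6, 1e6] for the phenotype models,
[1e−5, 1e5] for the scan) so degenerate fits pin at a bound instead of
diverging. Pipeline outputs are byte-identical for identical config + seed,
and the manifest records the hash of the scientific configuration (output
paths excluded).
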