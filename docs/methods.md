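# Methods

This note documents the statistical procedures implemented in `sweepscan`,
the tunable parameters and their defaults, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## Input model and QC

Genotypes are diploid biallelic SNPs for samples partitioned into breeds
(optionally grouped). Internally a dataset holds a variant table (1-based
positions, strictly increasing per chromosome), an alt-allele dosage
matrix `G ∈ {0,1,2,MISSING}`, and — when the source VCF is fully phased and
called — a binary haplotype matrix `H` whose column pairs sum to `G`. `H`
never contains missing entries; any missing or unphased genotype demotes
the dataset to genotype-only, and the haplotype-based statistics then
refuse to run rather than silently imputing.

QC follows the standard array workflow, in this order: restriction to the
configured autosome set (a coordinate restriction, applied first), removal
of samples with > 5% missing genotypes, removal of loci missing in > 1% of
the remaining samples, and removal of loci with MAF < 0.05. The report
records counts removed per step so alternative orders can be audited. MAF
is computed on the dataset being filtered, so per-group scans should apply
QC after subsetting to the analysis unit.

## The five per-breed statistics

All statistics live on one variant-aligned grid; window statistics are
anchored at the window's centre SNP (the window is 25 SNPs, step 1, and
the first/last 12 SNPs of each chromosome are undefined). Anchoring at
the centre keeps all five statistics joinable per SNP, which the composite
requires.

* **H1, H12** — haplotype-frequency spectra over exact 25-SNP haplotype
  strings (windows containing any missing entry are undefined rather than
  imputed); H1 = Σpᵢ², H12 = H1 + 2p₁p₂.
* **Tajima's D** — computed on the same 25-SNP windows from the breed's
  haplotypes with the standard variance constants (a₁, a₂, b₁, b₂, c₁, c₂,
  e₁, e₂); monomorphic windows are undefined. Computing D on the same
  windows as H1/H12 (rather than some coarser segmentation) keeps the
  statistics comparable per SNP.
* **F_ST** — per-SNP Weir–Cockerham (1984) two-population estimator
  θ̂ = a/(a+b+c), focal breed versus the pooled remaining breeds, missing
  genotypes excluded per SNP; negative estimates truncated to 0, then
  smoothed.
* **π** — per-site nucleotide diversity n_ref·n_alt/C(n,2), smoothed.
* **Smoothing** — running median per chromosome, k = 31, with the
  "constant" end rule (verified against R's `runmed` in the tests);
  undefined values are excluded and reinserted.

## The DCMS composite

Each statistic is converted to genome-wide one-tailed rank p-values,
p = (#{values at least as extreme})/(n+1): right-tailed for H1, H12, F_ST,
left-tailed for π and Tajima's D. The n+1 denominator keeps p strictly
inside (0,1) so the log-odds transform stays finite; ties count every
value at least as extreme (midranks are not used).

The correlation among the k statistics is estimated by the minimum
covariance determinant (support fraction α = 0.75) on up to 300,000
complete SNP rows sampled without replacement under a recorded seed, per
breed (the statistics are per-breed quantities, so the model is too). The
weights are sᵢ = Σⱼ|r_ij| ∈ [1, k], and

DCMS_l = Σᵢ log((1 − p_{l,i})/p_{l,i}) / sᵢ .

Duplicating a statistic doubles its s-weights and leaves the composite
unchanged — the de-correlation property the tests verify algebraically.

**Degenerate statistics.** A statistic whose genome-wide median absolute
deviation is zero is constant at the method's resolution: its rank
p-values form one giant tie, and the log-odds transform converts the few
off-tie windows into ±log n discrete jumps rather than graded evidence,
making the composite's null bimodal and unfittable. Such statistics are
excluded from the composite for that breed (with a warning). On real
LD-rich data all five statistics vary continuously and the guard never
fires; it matters on linkage-equilibrium simulations, where background
H1/H12 collapse to 1/n_hap.

The genome-wide composite is fitted with an intercept-only Huber
M-estimator (tuning constant 1.345, MAD-anchored scale, tolerance 1e-8,
≤ 50 iterations) so that the outlying selected regions themselves do not
inflate the null scale; fitted μ, σ give upper-tail normal p-values, and
Storey q-values (π₀ from the λ-grid 0.05…0.95 with a cubic smoother,
clamped to (0,1]; < 100 p-values falls back to Benjamini–Hochberg).

## FLK

Population allele frequencies feed the Reynolds coancestry distance
(uncorrected form). Two properties matter:

* the Reynolds distance between populations a and b estimates the *mean*
  of their drifts, (F_a + F_b)/2, so the additive patristic matrix of the
  drift tree is **2·D_R**; neighbour joining runs on the doubled matrix
  and branch lengths are then drift amounts directly;
* computed from sample frequencies, the uncorrected estimator inflates
  distances by the binomial sampling variance (~1/(2n) per population),
  which the tree absorbs into leaf branches. This is a feature: the FLK
  statistic computed with this kinship on the same sample is χ²-calibrated
  (measured type-I ≈ 0.044 at nominal 0.05 with 20 diploids per breed),
  whereas the noise-free "true" drift matrix is not (≈ 0.145).

When the tree itself is the quantity of interest (comparison against a
known generating tree), `bias_correction=True` subtracts the per-locus
sampling variance p̂q̂/(m−1), giving an unbiased drift estimate; the
recovery tests use this form.

The tree is midpoint-rooted (an optional outgroup can be supplied by
rooting externally and passing the tree to `kinship_from_tree`), negative
NJ branches are clamped to zero with a warning, and the kinship is
F_ij = drift shared by the root paths of i and j. The single-SNP statistic
uses the generalised-least-squares ancestral frequency p̂₀ and the
quadratic form above; SNPs with p̂₀ ∈ {0,1} are undefined. The χ²(k−1)
reference is computed, but region calling uses the same robust-normal →
q-value post-processing as DCMS, which applies unchanged to externally
computed hapFLK tracks (the haplotype-cluster likelihood itself is out of
scope for this package; its output is ingested by position matching).

## Region calling and candidate genes

A region is a maximal run of consecutive same-chromosome SNPs with
q ≤ 0.1 containing at least one SNP with q < 0.01 ("adjusted p-value" is
read as the q-value); its bounds are the first/last SNP positions of the
run, so a single-SNP run is a 1-bp region. Both thresholds are
configurable. The peak is the SNP with the largest statistic in the run.
Genes are collected from the plateau — the contiguous SNP run around the
peak where the statistic stays within one robust σ (the Huber scale of
the genome-wide fit; multiplier configurable) of the peak value, never
extending beyond the region — and ranked by bp distance from the peak SNP
(0 if the gene spans it; ties broken by gene start, then identifier).
Overlap between region sets is 1-based inclusive bp arithmetic; BED output
converts to 0-based half-open only at serialisation. Runs of ≥ 3
rank-consecutive genes sharing a letter prefix are abbreviated
`PREFIX@ (i–j)` in the region tables.

## Synthetic data

The generator draws ancestral frequencies p₀ ~ Uniform(0.05, 0.95), then
per-breed frequencies from the Balding–Nichols Beta with mean p₀ and
variance F·p₀(1−p₀) — either one F per breed (star) or compounded along a
rooted tree whose branch lengths are drift amounts in [0, 0.5). Haplotypes
are independent Bernoulli draws per site; positions are cumulative
geometric gaps (mean 4 kb, the density of a ~600K ovine array). Defaults:
4 breeds × 20 diploids (40 autosomes per breed, the minimum the scan
design targets), 20,000 SNPs, drift F = 0.1 — a typical one-vs-rest
differentiation level for livestock breed panels.

Hard sweeps are injected by copying one randomly chosen carrier haplotype
onto random haplotypes of the affected breeds until its frequency reaches
`final_freq` within a chosen SNP window; nothing changes outside the
window, and exact truth records (window, breeds) are kept for matching.
Missingness is i.i.d. per genotype and drops the haplotype matrix. Toy
annotations place non-overlapping genes with at least one inside every
sweep window, plus optional same-prefix gene triples to exercise cluster
shorthand.

**What this does and does not emulate.** The baseline is linkage
equilibrium between sites, so background haplotype homozygosity is far
lower than in real SNP data (H1 ≈ 1/n_hap; the degeneracy guard above
exists for exactly this regime) and sweep detection power on this
background flows mainly through π, Tajima's D and F_ST. The site frequency
spectrum is Beta/Uniform, not coalescent: neutral Tajima's D is centred
near +1.7 here, which is why the D-neutrality check in the tests uses
msprime coalescent windows instead. Passing tests therefore demonstrate
correctness of the statistics and calibration of the testing machinery,
not realistic power estimates for LD-rich array data. At much weaker
differentiation (F ≈ 0.05) a sizable fraction of smoothed F_ST values sits
exactly at the zero truncation boundary; the resulting rank-p tie atom
widens the composite's null and costs power — a genuine limitation of the
rank-based composite for weakly differentiated panels.

## Numerical choices

* Missing dosage sentinel −1; undefined track values NaN, serialised "NA".
* Window haplotypes are bit-packed into uint64 rolling codes (windows ≤ 64
  SNPs) so the H1/H12 scan is linear in SNPs.
* MCD seed, sample size and α are recorded in the serialised correlation
  model; identical inputs and seed reproduce bit-identical models, q-value
  tracks and regions.
* p-values from the normal tail are floored at the smallest positive
  float so the q-value machinery never sees 0.
* Degenerate-variance guard threshold: MAD² ≤ 1e-12.
* Negative W&C denominators/monomorphic SNPs: θ̂ defined as 0 when a+b+c
  = 0, undefined when a pool has no called genotypes.
* NJ on ≥ 3 populations; 2 populations split their distance at the
  midpoint by construction.

## Problem sizes used in validation

Calibration and recovery experiments run at 20,000 SNPs (4 breeds × 20
diploids; FLK type-I, neutral DCMS false-call fraction, F_ST recovery
against a 10-replicate oracle) and 50,000 SNPs (kinship recovery from
tree-structured drift); sweep recovery injects 10 hard sweeps of 50 SNPs
at final frequency 0.95 across 4 breeds in a 20,000-SNP panel. These sizes
give stable stochastic outcomes across seeds while keeping the whole
validation suite around half a minute.

## Known limitations

* Single-SNP FLK only; the haplotype-cluster (hapFLK) likelihood is
  ingested from the external program, not recomputed.
* No LD-aware null for the rank-based composite: q-values are marginal.
* The generator produces hard sweeps by haplotype copying — a caricature
  with exact truth windows, not a selection trajectory; soft sweeps and
  recombination-map realism are out of scope.
* Unphased real data restricts the scan to the genotype-based statistics;
  phasing is expected upstream.
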