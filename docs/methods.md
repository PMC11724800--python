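# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `phenoblup`, in enough detail to judge what
the package's tests do and do not establish.

## Prediction models

All prediction models are linear mixed models with a single intercept
and a list of random effects, each carrying its own relationship
kernel over its levels:

    y = X β + Σ_k Z_k u_k + ε,   u_k ~ N(0, C_k σ²_k),  ε ~ N(0, I σ²_ε).

For hybrid prediction the effects are the dent GCA (levels = dent
parents), the flint GCA (levels = flint parents) and, where the kernel
source allows it, the SCA (levels = crosses). A model may stack
several kernel sources (e.g. spectra from two trials), giving up to
ten random effects; sources missing one pool contribute only the
effects they support.

### Kernels

* **VanRaden GCA kinship** (genomic): computed within one heterotic
  pool, with allele frequencies estimated on that pool's lines.
  Markers monomorphic within the pool are excluded from that pool's
  kernel (their centered terms carry no information and would break
  the `0 < f < 1` requirement of the denominator). Heterozygous calls
  (0.5) are retained.
* **Spectral H matrix**: wavelength columns of the pretreated spectra
  are centered and scaled to unit sample variance (ddof = 1) across
  genotypes, then `H = S*S*ᵀ/L`. Zero-variance columns are dropped
  with a warning and `L` decremented.
* **Pedigree**: a two-level expected-relationship matrix (diagonal
  1.0, same biparental family 0.5, different family 0.25). Its
  defining property — every cross-family coefficient equal — is what
  makes pedigree prediction degenerate in the across-family scenario.
* **SCA kernels** are entrywise products of the parental kernels over
  the crosses in the design, for every source.

All genomic and spectral kernels are scaled so the sample variance
(ddof = 1) of all n² entries is 1, read literally; the alternative
mean-diagonal normalization was considered and not used. Kernels whose
smallest eigenvalue falls below −1e−8 after construction get
`|λ_min| + 1e−6` added to the diagonal, recorded in the kernel's
`jitter` field; REML needs invertible covariances and the SCA products
of near-singular parental kernels are the usual offenders.

### Marker quality control

Markers are dropped when missingness exceeds 20 % within either pool,
when the heterozygous-call rate exceeds 5 % among dent or 10 % among
flint lines, or when the minor-allele frequency is below 5 % in *both*
pools (a marker polymorphic in at least one pool is kept; the per-pool
kernels then subset to the markers polymorphic within their own pool).
Missing calls are imputed by the within-pool allele frequency of the
marker.

## REML

`fit_reml` maximizes the restricted likelihood of
`V = Σ_k σ²_k Z_k C_k Z_kᵀ + σ²_ε I` by average-information updates
with safeguards:

* **Score/AI**: score_k = −½(tr(P G_k) − yᵀP G_k P y),
  AI_kl = ½ yᵀP G_k P G_l P y, with P the REML projection matrix.
* **Active set**: components pinned at the variance floor whose score
  points further down are frozen out of the AI solve; without this the
  boundary component ill-conditions the step and the remaining
  parameters crawl along a flat ridge.
* **Fallback**: if the AI step does not increase the likelihood it is
  halved repeatedly, then replaced by an EM-like step
  σ²_new = σ² + σ⁴(yᵀP G P y − tr(P G))/n, likewise halved. Accepted
  iterates are therefore monotone in log-REML.
* **Floor and convergence**: variances are floored at
  max(1e−10 · var(y), 1e−12); convergence requires
  |Δ log-REML| < 1e−8 together with either a relative parameter change
  below 1e−6 or three consecutive sub-tolerance likelihood changes
  (the flat-ridge case, where the criterion is numerically maximized
  while a free parameter still drifts).
* Constant responses short-circuit: all variances 0, μ̂ = the constant.
* Observations with missing phenotype are dropped row-wise.

BLUPs are û_k = σ̂²_k C_k Z_kᵀ V̂⁻¹(y − Xβ̂); out-of-sample prediction
replaces the leading C_k block by the covariance between new and
training levels, so a new hybrid with zero kernel covariance to the
training set is predicted at μ̂. Predictions for training observations
reproduce the stored BLUP combination exactly, and interpolate the
data as σ̂²_ε → 0.

### Bivariate across-trial model

The per-wavelength decomposition uses a two-trial model with fixed
trial means, genetic covariance `Σ_g ⊗ K` and heteroscedastic
independent residuals. `Σ_g` is parameterized by its Cholesky factor
(log-diagonal), so the estimate is PSD by construction — whether
boundary estimates should be allowed is genuinely open; this choice
trades a possible boundary fit for unconstrained optimization. The
five parameters are optimized by Nelder–Mead from moment-based starts
(two starts, deterministic). When both trials observe the same
genotype list, the likelihood is evaluated in the eigenbasis of K,
where V block-diagonalizes into 2×2 blocks per eigenvalue; this makes
a 150-wavelength scan of 60 genotypes run in seconds and is exactly
equal (verified to 1e−6) to the dense evaluation. The Yamada mapping
to across-trial components is
σ²_G = σ_u12, σ²_GxE = (σ²_u1+σ²_u2)/2 − σ_u12,
σ²_e = (σ²_e1+σ²_e2)/2; a negative estimated genetic covariance is
reported as-is, not clipped. Wavelengths where the fit fails are
flagged unconverged and left missing — scan averages are over
converged wavelengths with counts reported, never interpolated.

## Spectra pretreatment

The chain is raw plot spectra → technical-replicate mean per microplot
→ wavelength-wise spatially adjusted genotype means → per-spectrum SNV
normalization → Savitzky–Golay first derivative (window 37, order 2 by
default), enforced by state tags so stages cannot be skipped or
reordered.

* The spatial model per wavelength is `y = genotype + row + column +
  error` with row and column as i.i.d. random effects fitted by the
  same REML engine — a deliberate simplification of tensor-P-spline
  spatial surfaces to the quoted random row/column structure; a smooth
  surface term is out of scope. Genotype is taken fixed for the
  adjusted means and random for broad-sense heritability
  `H² = σ²_g / (σ²_g + σ²_e / n̄_rep)` (classical repeatability form;
  effective-dimension variants are not reproduced). Fully unreplicated
  trials make both the adjustment and H² unidentifiable: observations
  pass through unchanged with a warning and H² is reported missing.
* Normalization is per spectrum (SNV), the chemometrics default
  reading of "centered and scaled"; the per-wavelength standardization
  that the H matrix needs happens inside the kernel construction, so
  the two operations are not conflated.
* The SG derivative drops the `window − 1` edge points rather than
  padding (padding invents data); it requires a uniform grid and
  instructs resampling (linear interpolation is provided) otherwise.
  Technical replicates are averaged before, not after, the spatial
  adjustment.

## Synthetic data

The generator emulates the structure of a two-pool maize hybrid study
and is the basis of every end-to-end test:

* **Genomes**: 4 founders per pool, homozygous, per-marker founder
  allele frequencies uniform on (0.2, 0.8); markers evenly spaced on
  10 chromosomes of 100 cM (40/chromosome by default — enough for the
  kernel structure; the real arrays are denser but add nothing at this
  scale). Meiosis uses the Haldane map function without interference
  (closed-form testable; recombinant fractions are checked against
  `r = (1−e^{−2d/100})/2`). The 6 families per pool are the half-
  diallel of the founders; dent lines are doubled haploids (one
  meiosis, then doubling), flint lines come from 6 selfing generations
  by single-seed descent, leaving residual heterozygosity.
* **Design**: a configuration-model pairing of parent slots with swap
  repair of duplicate crosses; with equal pools and a feasible degree
  every parent gets exactly `hybrids_per_parent` (default 4) crosses,
  ~360 hybrids.
* **Phenotypes**: GCA values are polygenic scores with i.i.d. normal
  marker effects, rescaled so the realized per-pool GCA variance
  equals its target exactly; SCA is drawn directly from
  `N(0, K_SCA σ²_SCA)` with the genomic SCA kernel (matching the
  fitted model's own distribution — an exact-rescale variant was
  tried and degraded the recovery calibration); error is i.i.d.
  normal. Defaults: GCA variances 1.0 per pool, SCA 0.25, error 1.0.
  Realized components and their cross-covariances are recorded and sum
  to the total variance exactly.
* **Spectra**: per wavelength, a shared polygenic score (marker
  loadings smoothed along the wavelength axis with a moving average,
  width 9), an independent per-trial polygenic score (the G×E part)
  and smooth correlated noise are mixed as
  `√h2 · A + √gxe · B_t + √(1−h2−gxe) · E_t` after per-wavelength
  standardization, so the variance shares across genotypes match the
  configured profiles. The default profiles vary smoothly between ~0
  and 0.9 (genetic) and up to ~0.25 (G×E). An optional field layout
  plants each genotype in replicate plots on a row × column grid with
  additive random row/column effects, moving the residual share to the
  plot level.

What the generator does **not** emulate: linkage disequilibrium decay
calibrated to real maize, selection during line derivation, instrument
physics (scatter, baseline drift, detector-region artifacts), or any
particular real heritability profile — the profiles are emulation
targets, not estimates. Tests passing on this generator therefore
establish that the estimators recover the structure they assume, not
that real spectra carry that structure.

## Cross-validation

* `CV_SparseTesting`: per repeat, a seeded shuffle splits hybrids into
  k folds differing in size by at most one (remainders to the
  lowest-index folds); each fold is predicted once.
* `CV_newDentFlint`: one partition per (dent family, flint family)
  pair — predicted = hybrids with both parents in the pair,
  calibration = hybrids with *neither* parent in the pair (two-sided
  exclusion); partitions with fewer than 10 predicted hybrids are
  dropped. Grouped multi-family holdouts would be a straightforward
  extension but are not implemented.
* Partitions are created once per dataset and reused by every model
  and trait; the results log carries a partition hash so the reuse is
  auditable. Undefined correlations (constant predictions, detected at
  relative tolerance 1e−6 to absorb floating-point noise in genuinely
  constant predictions) are reported missing with the reason, never
  coerced to 0; summary means are over defined folds with counts.

## Problem sizes used in tests and the acceptance script

The recovery experiment runs 20 simulated studies at the default scale
(90+90 parents, ~360 hybrids) with 4 simulated traits each, averaging
all 80 REML fits: the SCA estimate has a per-dataset standard
deviation of roughly 0.17 around its small true value (0.25), so
averaging over traits as well as seeds is needed for the mean to be a
sharp measure of bias rather than of Monte Carlo noise. Heritability
scans use 150 wavelengths and 60 genotypes over two trials; scenario
comparisons use 5 simulated studies with one repeat of 5-fold sparse
testing and up to 12 across-family partitions each. Grid-search
oracles for the REML engine use n ≤ 28 with 200×200 (one kernel) and
30³ (two kernels) grids.

## Known limitations

* The REML engine is dense (O(n³) per iteration) and intended for the
  hundreds-of-hybrids scale of sparse factorials, not for tens of
  thousands of observations.
* The bivariate model covers exactly two trials; more trials would
  need a general multi-trait parameterization.
* The spatial adjustment ignores smooth field surfaces beyond additive
  row and column effects.
* Scenario results on synthetic data reproduce qualitative orderings
  (sparse testing easier than across-family prediction; pedigree
  uninformative across families); the relative ranking of spectral vs
  genomic kernels is data-dependent and deliberately not asserted.
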