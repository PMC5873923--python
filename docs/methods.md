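# Methods

## Data model and notation

The unit of analysis is a multi-environment trial: `N` records
`(line i, environment j, phenotype y_ij)`, with `n` lines, `m` environments,
and arbitrary unbalance (a line need not appear in every environment; at most
one record per cell). Phenotypes are assumed to be stage-1 adjusted means
(BLUEs) on a single trait scale; producing them from raw plot data is outside
the package's scope. Records are canonicalized environment-major,
line-minor; all matrices share that ordering, which makes the block
structure of the covariances visible (the (j, j′) block of `Z_g K Z_g′`
holds kernel entries for lines observed in j × lines observed in j′) and
makes record order irrelevant to every result.

## Kernels

Marker QC removes markers by missing rate, then by minor-allele frequency
(default threshold 0.05, the conventional cutoff), and mean-imputes what
remains; standardization uses the n−1 sample variance and drops monomorphic
columns before `p` is counted, keeping `K = XX′/p` on the VanRaden scale
(mean diagonal ≈ 1). The Gaussian kernel uses squared Euclidean marker
distances scaled by their median over strictly off-diagonal pairs — the
diagonal zeros would deflate the scale — so the pair at the median distance
always maps to `exp(−h)`; the bandwidth default `h = 1` is fixed, not
estimated. Numerical PSD is enforced as eigenvalues ≥ −1e−8·λmax; anything
below that fails validation rather than being clipped silently.

A practical note: in high marker dimension the off-diagonal squared
distances concentrate around their median, and the Gaussian kernel becomes
nearly an affine function of the linear kernel. Non-additive signal is
therefore easiest to demonstrate at a few hundred markers; with tens of
thousands the two kernels largely coincide on simulated (LD-free) panels.

## Gibbs sampler (Hadamard family)

Each model is `y = μ1 + Z_E β_E + Σ_k effect_k + ε` with
`effect_k ~ N(0, σ²_k C_k)` and `ε ~ N(0, σ² I)`. The sampler rotates each
pattern `C_k = U_k D_k U_k′` and samples coefficients `b_k` with diagonal
prior `N(0, σ²_k D_k)`; because `U_k′U_k = I`, every full conditional of
`b_k` is diagonal and one sweep costs a few matrix–vector products.
Rotations use structure-aware fast paths: a thin SVD of the low-rank factor
for the main-effect (`Z_g V√Λ`) and intercept (`Z_g`) patterns, and
per-environment block eigendecompositions for the G×E patterns. Eigenvalues
below `1e−10·λmax` are dropped.

Fixed effects are parameterized as per-environment means
`η_j = μ + β_E,j` with flat priors; `μ` is reported as their average and
`β_E` as sum-to-zero deviations, keeping `μ` identifiable.

Variance components carry scaled-inverse-χ²(ν, S) priors with ν = 5 and S
set so the prior mode equals `var(y)·R²/k` (R² = 0.5 split equally over the
k non-residual components) and `var(y)·(1−R²)` for the residual — the
standard Bayesian-GBLUP default, overridable per component. Chain defaults
are 12,000 iterations, 2,000 burn-in, thinning 5; the tests and the
acceptance script use shorter chains (800–1,500 iterations) chosen so the
Monte-Carlo error of posterior means is small relative to the tolerances
being checked.

**Missing and held-out records.** Both engines treat masked (test) records
by data augmentation: the masked phenotype is never read; each sweep imputes
it from the current model state. This is an exact Gibbs scheme on the joint
of parameters and missing data, keeps the rotated algebra balanced, and
gives a sharp guarantee used by the tests: replacing test phenotypes by
arbitrary constants leaves every chain bit-identical under the same seed.
Predictions are posterior means of `μ + Z_E β_E + Σ random effects`
(residual excluded), for observed and masked records alike; point
predictions rather than posterior-predictive draws because Pearson accuracy
is invariant to zero-mean residual noise in expectation.

Determinism: a single `numpy` Generator seeded from the config drives every
draw in a fixed order, so identical configs replay bit-identically.

## Kronecker engine (MUC, MUCf)

On the wide n × m matrix, `u ~ N(0, U_E ⊗ K)`, optionally `f ~ N(0, F_E ⊗ I)`,
and `ε ~ N(0, Σ ⊗ I)` with diagonal heterogeneous Σ. Rotating line space by
the eigenvectors of `K` decouples rows: each retained eigen-row of the
rotated `u` has an m-variate normal full conditional. The update
eigendecomposes the current `U_E` rather than inverting it, so pinned
singular choices — e.g. `U_E = c·J`, which reduces MUC to the main-effect
model and is used as a bridge test against the closed-form BLUP — run
through the same code path. `U_E` and `F_E` get inverse-Wishart full
conditionals (priors: df = m + 2, scale = 0.5·diag of per-environment
phenotypic variance — weakly informative, overridable); each Σ_jj a
scaled-inverse-χ². Non-PD draws are jittered with a logged count (none
observed in practice; inverse-Wishart draws are PD by construction). Empty
and masked cells are data-augmented exactly as above. With one environment
the unstructured model is undefined and the fit refuses.

The scientific point of the family: the Hadamard models force the
between-environment genetic covariance to be `σ²_g·K_ii` (plus `σ²_l`),
which is nonnegative; `U_E` is free, so negatively correlated environments
(the wheat-like regime) are representable only here.

## Cross-validation

CV1 sends 20% of *lines* (all their records) to test — newly developed,
never-evaluated lines; CV2 sends 20% of *records* — sparse testing, where a
line's other environments remain in training. Default protocol is repeated
random sub-sampling (50 partitions in the reference protocol; the tests use
10 or fewer), with disjoint k-fold available behind a flag and an optional
environment-stratified CV2. Partitions violating a per-environment floor
(≥ 2 test records, ≥ 1 training record) are resampled with a logged count.
Accuracy is Pearson r between observed and predicted test phenotypes per
environment, reported mean (SD) over partitions; environments with degenerate
test sets in a partition are skipped and counted. All models share the same
partitions, and because masking does not alter covariance patterns under
data augmentation, each model's rotations are computed once and reused
across partitions.

## Synthetic data

The generator draws effects in the kernel eigenbasis, so `Var(g) = σ²_g K`
holds by construction rather than on average over marker effects. Markers
are independent Binomial(2, q) dosages with q uniform in the MAF range — no
linkage disequilibrium, no map. An *epistasis fraction* routes part of each
genetic variance through a component with covariance `K ∘ K` (normalized to
unit mean diagonal), the covariance of pairwise marker-product effects; the
Gaussian kernel can partially represent this component, the linear kernel
cannot, which reproduces the GK-over-GB accuracy ordering. Environment
means default to an even spread over ±0.5 trait units. Unbalance is applied
by per-environment line counts (cells deleted at random) or an
observed-cell probability.

Four presets mirror the reference trials in structure: `HEL_like` (maize:
5 sites, 452 lines, per-site counts 247/330/452/367/330, positive
correlations, dominant G×E), `USP_like` (maize: 4 artificial environments,
739 lines, near-balanced, sizable iid intercept variance), `WHE1_like`
(wheat: 4 mega-environments, 599 lines, one environment negatively
correlated with the rest — generative model MUC), and `WHE5_like` (wheat:
5 environments, 807 lines, balanced, G×E variance dominating the main
effect). Preset variance magnitudes are borrowed scales for realism, not
reproduction targets. What passing tests on these simulations do **not**
show: behavior under LD, allele-frequency structure, non-Gaussian residuals,
or stage-1 design effects — real-data accuracy levels are outside what the
generator can certify.

## Numerical and design choices

* Eigenvalue truncation `1e−10·λmax`; PSD tolerance `−1e−8·λmax`; kernel
  CSVs round-trip bit-exactly at 17 significant digits (readers use
  round-trip float parsing).
* Degenerate inputs fail loudly: all markers removed by QC, monomorphic
  panels (zero median distance names the identical pairs), kernels missing
  trial lines (listed), duplicate (line, environment) cells, environments
  with no observed records.
* With a variance component pinned at zero the corresponding effect is
  exactly zero rather than sampled from a degenerate conditional.
* The CV2 sampler is uniform over records by default (stratification is a
  flag) and the 80/20 repeated sub-sampling protocol is the default, with
  k-fold behind a flag; the SDs in accuracy tables are across partitions.

## Known limitations

* **Weak identification of variance splits.** The main-effect vs intercept
  split (σ²_g vs σ²_l) and the G×E vs residual split are only weakly
  identified when the kernel is close to the identity (many markers, no LD).
  The exact likelihood peaks near the truth, but posterior *means* of small
  components sit above their generative values (right-skewed marginals
  bounded at zero) — at n = 400 a truth of σ²_l = 0.3 yields a posterior
  mean near 0.38 while the (σ²_g + σ²_l) sum is recovered within 1%.
  Recovery checks therefore use an absolute band for small components and a
  relative band only where components are large enough for it to be
  meaningful.
* MUC with many environments would be better served by a factor-analytic
  covariance; not implemented.
* No pedigree kernels, no VCF/PLINK ingestion, no multi-trait models, no
  variable-selection priors; bandwidth `h` is fixed.
* Runtime scales as the dense eigendecompositions of the per-environment
  kernel blocks and the per-sweep matrix–vector products; the package is
  sized for desk-scale studies (hundreds of lines), not biobank data.
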