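# Methods

## The problem being modelled

In large population cohorts, allele frequencies vary smoothly in space
(residual ancestry structure) and many health and social traits are also
geographically patterned. When both hold, a polygenic score (PS) — a
weighted sum of trait-associated allele dosages — is correlated with
birth location, and a PS–trait regression absorbs the shared geography as
association that is not a within-person genetic effect. The package
provides (i) a generator for cohorts in which the strength of this
coincident structure is known and controllable, and (ii) the analysis
battery used to detect it (per-variant location GWAS and genomic
inflation, PS–geography smooth models), to quantify it (tiered
adjustment and percent attenuation), and to isolate it (geography-matched
null traits, ancestry-mixture regional means).

## Synthetic cohorts (simpop)

**Allele frequencies.** M ancestral frequencies are drawn uniform on
(0.05, 0.95). Each of K source populations diverges by the
Balding–Nichols model: `f_kj ~ Beta(p_j(1-F)/F, (1-p_j)(1-F)/F)`, so
`E[f_kj] = p_j` and `Var[f_kj] = F p_j (1-p_j)` with F the fixation
index. Draws are clipped to [0.001, 0.999] to avoid monomorphic
variants. Defaults: K = 3, F in the 0.05–0.1 range typical of within-
continent differentiation at the upper end (chosen so that desk-scale
cohorts of a few thousand individuals show detectable structure, where a
biobank shows it at F two orders of magnitude smaller with two orders of
magnitude more samples).

**Geography and admixture.** Birth coordinates are uniform on a square
`grid_extent` km grid (default 1000 km) with the origin at the
south-west corner; a converter to the metre scale used by biobank fields
is provided. Individual i's admixture row is the softmax of affine
functions of the projection of position on `gradient_axis`: source k has
logit `gradient_strength * u_k * z_i`, with slopes `u_k` evenly spaced
on [-1, 1] and `z_i` the standardized projection. Rows are strictly
positive and sum to one by construction, and vary smoothly in space.
`gradient_strength` (default 3, the logit change per SD of projection)
sets how sharply source composition turns over across the map; 0 gives a
panmictic cohort, 3 gives strong but overlapping clines. Dosages are
`Binomial(2, q_i · f_.j)`; variants are placed 500 kb apart across 22
chromosomes (independent draws — linkage is emulated only positionally,
for clumping).

**Traits.** `trait = gw·Z(score) + geow·Z(surface) + N(0, sd)` where
`Z` standardizes, `score` is the true PS over a `causal_fraction`
(default 10%) of variants, and `surface` is a fixed smooth nonlinear
function of the gradient projection (`t + sin(2t)/2`, standardized).
Because both components are standardized, `gw²` and `geow²` are variance
contributions directly. `cline_coupling` in [0, 1] correlates causal
effect sizes with each variant's frequency cline along the gradient
(slope-weighted source frequencies): at 0, effects have random signs and
the net geographic cline of the true score varies by chance from seed to
seed; at 1, effects align with the cline, emulating polygenic
differentiation along the gradient. The designed-confounding experiments
use coupling 0.9 so that the PS reliably carries geography; neutral
traits use 0.

**Sampling.** Individuals are assigned to the nearest assessment centre
(Euclidean distance, ties to the lowest centre index). Participation is
optionally a logistic function of standardized trait value and distance
to the nearest centre — off by default; it exists to demonstrate
selection/collider phenomena qualitatively, not to estimate their
real-world magnitude.

**What the generator does not emulate.** Linkage disequilibrium,
haplotypes, realistic UK cartography, family structure, measurement
error in self-reported location, and the very-high-dimensional residual
structure of real biobanks. The last point matters for interpretation:
here ancestry is exactly K-dimensional, so K-1 principal components can
capture it almost fully and tier-3 adjustment already removes most
confounding; in real data adjustment attenuates but does not extinguish
geographic structure. Passing tests therefore validate the machinery and
the direction/ordering of effects, not the residual-confounding
magnitudes seen in real cohorts.

## Quality control (qc)

The graded INFO filter applies band-wise minimum imputation-quality
thresholds: INFO > 0.3 for MAF > 3%, > 0.6 for 1–3%, > 0.8 for 0.5–1%,
> 0.9 for 0.1–0.5%; MAF below the lowest band fails outright
(conservative; the convention is silent there). Hardy–Weinberg uses the
exact test conditional on allele counts — the p-value sums the
probabilities of all heterozygote counts no more probable than the one
observed, with `P(h) ∝ n!/(n_AA! h! n_aa!)·2^h` — applied to hard calls
(dosage rounded to nearest integer). Relatedness pruning iteratively
removes the individual with the most remaining above-threshold (default
kinship 0.125) pairs, ties broken by lowest id, until none remain.
Income categories recode to the published pounds-sterling values
{1: 11505, 2: 22495, 3: 41499, 4: 76000, 5: 124000} used as a verbatim
lookup (the printed values for the open-ended bands extend the boundary
by half the adjacent band's width; categories 1–2 do not equal naive
band midpoints, and the lookup, not the rule, is authoritative).
Sibling counts sum brothers and sisters and are missing if either is;
negative coordinates are missing.

## Polygenic scores (scores)

Weighted scores are `Σ_j β_j d_ij` over variants below the discovery
p-value threshold; unweighted scores use `sign(β_j)` only (`sign(0)=0`).
Weight-table alleles are harmonized to genotype effect alleles (dosage
`2-d` when effect/other are swapped); strand-ambiguous A/T and C/G
variants are dropped with a warning. Individuals missing some
contributing dosages get their observed-variant score rescaled by
total/observed count (proportional rescaling ≈ mean imputation; the
convention for this case is not standardized, and this choice keeps the
score scale comparable across individuals). Clumping is greedy and
distance-based (default window 250 kb): variants are taken in ascending
p order (ties by position, then id) and accepted when no accepted
variant on the chromosome is within the window — a deterministic
stand-in for LD-r² clumping, appropriate because the simulator has no
LD. Scores are z-transformed after all sample exclusions; transforming
before subsetting is deliberately not equivalent and the "after
exclusions" order is the contract.

## Penalized spline engine (smoothfit)

Each smooth term is a cubic B-spline basis of dimension k (default 10)
with interior knots at quantiles of the data and a sum-to-zero constraint
(one dimension absorbed) for identifiability next to an intercept. The
penalty is an order-2 divided-difference penalty at the Greville
abscissae: because the B-spline coefficients of a polynomial are that
polynomial at the Greville sites, the penalty null space is exactly
{constant, linear}, so infinite smoothing collapses the term to a
straight line (edf → 1). The penalty matrix is Frobenius-normalized,
which makes fits exactly invariant to affine rescaling of the smoothed
variable and gives the smoothing-parameter grid a scale-free meaning.

Fitting minimizes `‖y−Xβ‖² + Σ_s λ_s β_sᵀP_sβ_s`. Each λ_s is selected
on a 41-point log grid (log10 λ in [-4, 6]) by generalized
cross-validation `GCV = n·RSS/(n − γ·edf)²`; with one or two smooths the
grid (product) is searched exhaustively, otherwise by cyclic coordinate
descent. Plain GCV (γ = 1) is known to undersmooth pure noise, which
makes downstream significance tests anti-conservative; the default
γ = 4 prices effective degrees of freedom strongly enough that the
smooth-term test's empirical type-I error sits near the nominal 5%
(measured at ≈0.05–0.065 over 1000-replicate null batches) while strong
signals are fitted identically. Continuous-optimizer GAM software uses
smaller γ (≈1.4); a discrete grid selects more aggressively and needs a
larger price.

Effective degrees of freedom are `tr((XᵀX+S)⁻¹XᵀX)` restricted to each
term's block. The smooth-term test is an F-test of the full penalized
fit against the fit with the term removed (other terms' λ held fixed),
with numerator df the rounded edf of the term and denominator df
`n − edf_total`. It is approximate by construction — λ is treated as
fixed and the edf as known — so its contract is calibration (type-I
error, power), not agreement with any particular GAM implementation; a
cross-check test confirms the fitted curves agree closely with an
independent GAM engine. If a smooth's penalty null space is already
spanned by unpenalized columns (e.g. `s(x)` alongside linear `x`), the
null direction is dropped from the smooth, making it fully penalized;
collinearity among unpenalized columns is an error naming the columns.
Coefficient covariance is `σ²(XᵀX+S)⁻¹` with `σ² = RSS/(n−edf)`.

## Geographic association battery (geo_assoc)

PCs: dosages are thinned positionally (default 100 kb), mean-imputed for
missingness, standardized, and decomposed by truncated SVD; scores are
scaled to unit variance with a deterministic sign convention.
Per-variant GWAS of a birth-coordinate axis on dosage uses
Frisch–Waugh–Lovell residualization against the tier covariates, which
reproduces full multiple-regression estimates, SEs and p-values exactly
at a fraction of the cost; constant or covariate-collinear dosages are
skipped and logged. Coordinates are used in km — p-values are invariant
to the unit. The genomic inflation factor is the median association χ²
divided by 0.4549. Tiers: 1 none, 2 array, 3 array + PCs + centre,
4 array + more PCs + centre; requested PC counts (defaults 10/40) are
capped at availability with a warning since synthetic cohorts are far
smaller than biobanks. The PS-geography battery fits
`ps ~ s(coordinate) + tier covariates` per score, axis and tier and
tabulates smooth-term p-values (the tier-table layout).

## Attenuation and the matched null (attenuation)

PS–trait models are linear in the PS throughout: tier 1 `t ~ ps`, tier 2
adds array, tier 3 adds PCs (default 40 where available) and centre,
tier 4 adds `s(north) + s(east)` penalized smooths (axes enter
additively, matching the per-axis modelling convention; no 2-D tensor
smooth). Percent attenuation between tiers a and b is
`100·(1 − β_b/β_a)` using the signed ratio — negative values mean
amplification, values above 100 a sign flip — and is flagged as unstable
when `|β_a| < 2·SE_a`. Rescaling divides each tier's coefficient and
95% CI by the tier-1 coefficient (tier 1 ≡ 1; interval endpoints are
re-ordered after division by a negative baseline).

Geography-matched null traits: individuals with the trait and both
coordinates non-missing are ranked by northing (ties by id) and split
into `n_bins` (default 100) contiguous bins, the first `N mod n_bins`
bins taking one extra member. Within each bin, replacement values are
drawn `Normal(μ̂, σ̂)` (σ̂ with n−1 denominator; bins of one are rejected
by precondition). The procedure repeats along the easting and the final
value is the arithmetic mean of the two draws ("equal weighting" read
literally). The result preserves coarse geographic structure while being
conditionally independent of genotype within bins — the null against
which PS–trait associations that survive are attributable to geography.

## Admixture mapping (admixmap)

Reference panels are per-region mean feature profiles (mean dosages in
the synthetic setting; haplotype-painting copying vectors fit the same
TSV shape). Individual mixture weights solve non-negative least squares
(Lawson–Hanson active set) and are renormalized to sum to one
(post-hoc renormalization of the unconstrained-scale solution; an
augmented constraint row is an alternative but not the default). An
all-zero NNLS solution returns the uniform mixture with a warning.
Regional phenotype means solve `AB = C` by least squares
(`B = (AᵀA)⁻¹AᵀC` when full rank, pseudoinverse with a warning
otherwise — individual-level mixtures may be unidentifiable for
near-collinear panels while regional averages remain valid). Confidence
intervals are percentile bootstrap over individuals (default 1000
replicates; singular replicates fall back to the pseudoinverse and are
counted). The selective-migration demonstration retains distant
individuals only when their trait exceeds a threshold and shows the
distant regions' inferred means biased upward relative to the full-
sample solve — the mechanism by which a single-site cohort can paint
distant ancestries with misleading trait averages.

## Pipeline (pipeline_cli)

A YAML config mirrors the dataclass field names exactly and unknown keys
are rejected before any stage runs. Stages execute in dependency order;
requesting a stage without its upstream stages is an explicit error
naming the stage. Outputs are write-once per run directory; the manifest
records the package version, seed, per-stage row counts and SHA-256
digests of every artifact, and identical config+seed reproduces
identical digests. All randomness in a run derives from the single
config seed via labelled substreams. Genotypes are written as a TSV
dosage matrix with a variant-metadata sidecar (a VCF-with-DS writer was
considered and not included; TSV keeps artifacts plainly diffable at
desk scale).

## Problem sizes used in validation

Simulation-based checks use cohorts of 1500–5000 individuals and
200–2000 variants: large enough that clinal structure is unambiguous
(tier-1 genomic λ far above 1.2; PC1–gradient correlation > 0.5) and
small enough that the full suite and the acceptance script each run in a
few minutes on one CPU. Monte-Carlo rates use 10–50 seeds per claim
(50 for the central confounding-removal rate, 1000 replicates for
smooth-test calibration, 200 datasets for bootstrap coverage). These
sizes are the package's validation conditions; the statistical
machinery itself has no scale assumptions beyond memory.

## Known limitations

- No LD: clumping is positional; LD-aware methods cannot be validated.
- Adjustment "works" here: low-rank simulated ancestry means PCs remove
  most confounding, unlike the persistent residual structure of real
  cohorts; the package demonstrates ordering and direction, not
  real-world residual magnitudes.
- The smooth-term p-value is approximate (post-selection λ treated as
  fixed); calibration is enforced empirically at n = 500, k = 10 and may
  drift for very small n or very large k.
- Education-style ordinal phenotypes are treated as numeric in the
  regional-means machinery, following the convention of the analyses it
  mirrors, without endorsing ordinality-blind means.
- Participation modelling is qualitative (logistic in trait and
  distance); it is not a fitted model of any real cohort's recruitment.
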