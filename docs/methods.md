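# Methods

This note documents the models and procedures skelevol implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where more than one
defensible option existed.

## Measurement model and trait table

Each specimen contributes two landmark configurations (pectoral and pelvic
girdle, 18 anatomical landmarks each, 3D coordinates in mm) and up to 15
limb-bone maximum lengths (humerus, ulna, five fore-digit elements; femur,
tibia, six hind-digit elements — the digit splits follow anole digit-IV
phalangeal counts and are configurable). Right-sided girdles (digitized
when the left side is damaged) are mirrored onto the left by negating one
coordinate axis; the axis is a per-dataset setting (default `x`) because
the midsagittal plane of a digitization protocol is a property of that
protocol, not of the method.

Generalized Procrustes analysis removes translation, scale (unit centroid
size), and rotation by iterative superimposition onto the updating mean
shape; reflections are disallowed (the optimal rotation is constrained to
determinant +1). Convergence: change in the mean shape < 1e-8, at most
100 iterations. The per-iteration sum of squared residuals is recorded and
is non-increasing. Degenerate configurations (zero centroid size) are
rejected naming the specimen.

Missing limb lengths are filled by iterative low-rank (PPCA-style)
imputation: fit a rank-k principal-component model to the current
completion, replace missing cells by the reconstruction, repeat to
convergence (tolerance 1e-8 relative to the data scale, 200 iterations;
non-convergence returns the last iterate with a warning). The default
rank is the broken-stick count of the complete-case correlation matrix —
a conservative, automatic choice; any rank can be forced. Observed cells
are returned bit-identical.

The species-level table divides limb lengths by the specimen's pelvic
centroid size (relative limb length; pelvic centroid size doubles as the
body-size proxy), averages specimens within species (males only by
default, because pelvic shape is sexually dimorphic and the downstream
analyses cannot condition on sex), and z-standardizes each of the 124
columns. Analyses that need original trait variances (disparity) instead
use mean-centered raw blocks; the disparity function refuses standardized
input.

Sex assignment for unsexed specimens uses LDA on pelvic shape, fit on
specimens of known sex, with PCA reduction to 95% variance first (raw
54-dimensional Procrustes coordinates are singular with museum-scale
sample sizes). A call is made only when the winning posterior reaches the
threshold (default 0.8); posteriors are clipped away from exact 0/1, so a
threshold of 1.0 assigns nothing and 0 assigns everything. Validation
accuracy comes from a random 60/40 split of the labeled specimens (not
stratified by species; the split fraction and seed are parameters).

## Phylogenetic machinery

All comparative statistics run through the Brownian-motion tip covariance
`C` (shared root-to-MRCA path lengths) and its *symmetric* inverse square
root `P = U Λ^(-1/2) Uᵀ`. The symmetric root — rather than a Cholesky or
plain eigenvector whitener — matters: it satisfies `P C Pᵀ = I` while
keeping each row of the whitened data associated with its species, which
per-group statistics (group rates, disparity of whitened data) require.
Eigenvalues below 1e-10 of the largest indicate effectively duplicated
tips and raise an error naming the near-duplicate pairs.

Polytomies in input trees are resolved into zero-length bifurcations with
a warning. Grafting attaches a new tip on the sister lineage's subtending
edge at a requested stem age and preserves ultrametricity; grafted branch
lengths are user inputs, not inferences.

Discrete ancestral states (used to label branches with biogeographic
groups) use an equal-rates continuous-time Markov model with the rate
found by bounded 1-D maximum likelihood and marginal node probabilities
from an up–down pass; each branch takes the modal state of its child node
(tip branches take the tip state; ties break toward the parent's modal
state). Continuous ancestral estimates are the joint-normal conditional
means of internal nodes given the tips under Brownian motion with the root
at its GLS estimate; the test suite verifies them against an independent
rerooted-GLS route.

## Comparative statistics

`K_mult` is the multivariate phylogenetic-signal ratio: observed summed
squared deviation from the GLS mean, over its phylogenetically whitened
counterpart, divided by the Brownian expectation
`(tr C − N (1ᵀC⁻¹1)⁻¹)/(N − 1)`. It equals exactly 1 on a star tree for
any data, and 1 in expectation under Brownian motion on any tree.
Significance: permutation of species across tips; all permutation
p-values in the package are `(b + 1)/(n_perm + 1)` counting the observed
arrangement.

Group rates: `σ²_g` is the mean squared whitened deviation of the group's
species, summed over traits and divided by the trait count; the max/min
ratio is tested against Brownian simulations under the pooled common rate
(999 by default). Disparity: Procrustes variance
`PV_g = Σᵢ ||yᵢ − ȳ_g||²/n_g` on raw-variance blocks; pairwise absolute PV
differences tested by group-label permutation (absolute differences, not
ratios, as the permutation statistic). Phylogenetic ANOVA: GLS fit of the
whitened data on factor dummies, R² as explained/total whitened sum of
squares, p by residual-randomization permutation of the reduced model.
Broken-stick retention keeps leading components while the variance
proportion exceeds `b_k = (1/p) Σ_{i=k..p} 1/i`, stopping at the first
failure (strict sequential rule).

## Modularity and integration

The covariance ratio for a module pair is
`CR(A,B) = √( tr(S_AB S_ABᵀ) / √( tr(S*_AA S*_AAᵀ) tr(S*_BB S*_BBᵀ) ) )`
with within-module diagonals zeroed; multi-module CR is the mean over
pairs. The size trait is excluded from every partition — the five
hypotheses concern girdles and limbs. CR and PLS always operate on
phylogenetically whitened data, so they measure evolutionary covariation.

Effect sizes standardize the observed statistic against a permutation
null. Two design choices here differ from the most literal reading of the
original statistic and were made after measuring the alternatives:

- **Permutation unit = single trait columns** (per-module variable counts
  preserved). Moving landmark x/y/z triplets as indivisible units is
  appealing, but when modules mix 3-variable triplets with 1-variable limb
  columns, unit-preserving permutations change per-module *variable*
  counts, the null stops being exchangeable with the observed assignment,
  and the test's type-I error collapses toward zero (0/60 null datasets
  significant at α = 0.05 in our calibration). Column permutation restores
  exchangeability (type-I ≈ 0.03–0.05 over 500 null simulations) and is
  what a flat combined trait matrix gets in standard practice. The triplet
  scheme remains available via `permute_unit="triplet"` for pure-shape
  analyses, where all units are triplets and the issue does not arise.
- **Effect sizes on log CR** (`log_transform=True` by default). The CR
  permutation null is right-skewed, and raw-scale z-scores are not
  comparable across partitions with different module counts: in recovery
  simulations under an H1 generator, the two-module hypothesis H2
  out-ranked the true three-module H1 on about half the datasets with raw
  z, versus 92–100% correct recovery with log-scale z. The p-value is
  computed on the raw CR scale either way.

Two-block PLS: SVD of the whitened cross-covariance; `r_PLS` is the
correlation of the first score pair; its null permutes the rows of one
whitened block. Pairwise comparisons of effect sizes between datasets or
hypotheses use `(z₁ − z₂)/√(se₁² + se₂²)` with each se the standard
deviation of the standardized null (1 by construction), i.e. `Δz/√2`,
against a two-tailed normal. Within one dataset, hypotheses share a common
permutation stream (same seed) for variance reduction.

Rarefied comparisons equalize sampling effort: per iteration each group is
subsampled without replacement to a target fraction (default 0.39), the
tree pruned, the statistic recomputed, and the percent of iterations with
a significant pairwise difference reported. The ML module-correlation
comparison models the Fisher-z transformed pairwise correlations as
normals with variance 1/(n_eff − 3), one ρ per within-module class plus
one between-module ρ; models are ranked by AICc with exp(−ΔAICc/2)
weights. The effective n for phylogenetically whitened data is taken as
the number of species (no further correction).

## Variable-rates model

Traits (orthogonal PCs; the sampler warns if column correlations exceed
0.01) evolve as independent Brownian motions on a tree whose branch
lengths are multiplied by effective rates: the product of all scalars
whose scope covers the branch. A scalar is either branch-kind (one edge)
or node-kind (every edge of the subtended clade, stem branch included).
Per-trait likelihoods use Felsenstein pruning with the root profiled at
its GLS value, so one pass yields `log|C|` and the per-trait GLS sums of
squares.

Priors and kernels (declared defaults, all configurable): scalar count ~
Poisson(λ = 1) with locations uniform among unoccupied positions; scalar
values log-uniform on [1/100, 100]; per-trait base rates inverse-gamma
(α = 2, β set so the prior mean equals the empirical per-trait rate) and
updated by exact conjugate Gibbs steps. Reversible-jump moves: add/remove
a scalar (independent prior draw; acceptance simplifies to λ/(k+1) and
k/λ times the likelihood ratio), log-normal perturbation (sd 0.35, bounds
enforced), relocation to a uniformly chosen free position, and a
merge/split pair exchanging one clade scalar for covering scalars on its
two daughter clades (log-space geometric mean with a Gaussian
half-difference auxiliary, sd 0.5). The merge/split move exists because
without it the sampler can freeze a single planted clade shift into
several nested sub-clade scalars and never consolidate them. Correctness
of the full move set was verified by running the sampler at likelihood
power 0 and recovering the Poisson(1) prior on the scalar count to within
Monte-Carlo error.

Default desk-scale chain: 500k iterations, 20% burn-in, thinning 100
(pipeline stages default to 200k). Acceptance-rate warnings fire outside
[5%, 80%] on the perturbation move. A non-finite likelihood aborts with a
state dump. Posterior summaries: per-branch mean log relative rate
(averaged over chains when several are given), shift locations present in
more than the threshold (default 0.5) of samples with their posterior
median magnitude, and ESS per branch-rate series from a Geyer
initial-positive-sequence autocorrelation estimator (warning below 200).

Stepping-stone marginal likelihoods use power posteriors at
`β_k = (k/K)^(1/0.3)` (Beta(0.3, 1) quantiles, K = 16 stones by default),
each stone estimated as the mean of `lik^(β_{k+1}−β_k)` over samples at
`β_k`; Bayes factors are `2·Δ(log ML)`. For the equal-rates model with the
inverse-gamma rate prior the marginal likelihood has a closed conjugate
form, which the test suite uses as the oracle (agreement within 0.2 log
units, typically 0.03).

Group tests on branch rates: Brown–Forsythe (one-way ANOVA on absolute
deviations from group medians; Tukey HSD on the same deviations when
significant) and Kruskal–Wallis with tie correction plus pairwise
mean-rank comparisons against the normal-approximation critical difference
at family α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a three-group island/mainland
radiation study: a dated tree with Primary Mainland sister to (Greater
Antilles, Secondary Mainland), pure-birth clades scaled to fixed crown
ages (defaults 50 / 40 / 30 time units for root, inner split, and crowns);
group sizes defaulting to 110 / 29 / 107 species; ~2–3 specimens per
species; trait covariance following any of H1–H5 with two knobs
(`r_within = 0.7`, `r_between = 0.1` — declared test conditions, since no
empirical effect sizes exist for them); planted per-group rate scalars;
landmark configurations under rigid transforms with ~3.5% right-sided
specimens; pelvic sexual dimorphism as a fixed mean-shift direction; and
0.45% missing limb cells, completely at random. Everything is
bit-reproducible from (config, seed).

It does not emulate: digitization error beyond isotropic landmark noise,
allometric shape–size relationships, ecomorph-specific selection regimes,
non-Brownian trait dynamics (OU, early bursts), or missingness that
correlates with specimen quality. Passing tests on these data therefore
demonstrate statistical correctness and calibration of the machinery, not
robustness to every real-data pathology.

The desk-scale validation studies (`skelevol.validation`) size the
simulations to minutes on one CPU: 60 species and 12/12/6/7-trait blocks
(preserving the study's girdle:limb proportions) for calibration and
recovery; 100-tip trees for signal calibration; 50 species per group and
3 traits for rate-ratio recovery — three traits because the σ² ratio is
unbiased at any trait count but only concentrates inside a ±1 window
around a 3× truth with at least three independent traits; and a 40-tip
tree (12-tip scaled clade, 6 traits, 200k iterations) for shift detection.

## Known limitations

- The rjMCMC explores scalar configurations by local moves; for strong,
  finely structured rate heterogeneity the posterior can distribute
  support across nested clade configurations, and the planted-location
  detection frequency is then conservative.
- Cross-hypothesis CR comparisons rely on permutation z-scores being
  comparable across partitions; the log transform makes this reliable in
  our simulations but it remains an approximation, and raw CR ranking is
  reported alongside.
- The equal-rates Markov model for group labels ignores asymmetric
  dispersal; with strongly monophyletic groups (the intended use) the
  labeling is insensitive to this.
- EMMLi-style model comparison treats pairwise correlations as
  independent, which overstates certainty for large trait blocks; it is
  used for model ranking, not for inference on ρ.
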