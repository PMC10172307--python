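# Methods

This note records the models, conventions, and numerical choices behind each
pipeline stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Measurements, size and shape

Inputs are specimen-level tables of p strictly positive linear measurements
(mm). Trait count is taken from the CSV header; the default label set has 14
cranial measurements held in a fixed alphabetical order so coefficient
vectors are comparable everywhere downstream. Specimens with a missing or
non-positive value are rejected outright rather than imputed: the geometric
mean requires a complete vector, and silent imputation would distort the
size variable for every trait at once.

Size is the log geometric mean x = (1/p) Σ ln mⱼ; shape is the vector of
log-shape ratios yⱼ = ln mⱼ − x. Natural logarithms are used throughout;
allometric slopes are invariant to the base. Because Σⱼ yⱼ = 0 for every
specimen, the per-species OLS slope and intercept vectors of y on x sum to
zero exactly — an identity the tests assert at 1e-10 — and species
trajectories live in a (p−1)-dimensional subspace.

Species pass to trajectory estimation only with at least 15 specimens
(default), i.e. more specimens than shape variables; smaller series give
unstable multivariate regressions.

## SMA and homogeneity-of-slopes inference

Bivariate scaling tests use the standardised major axis: b =
sign(sₓᵧ)√(sᵧᵧ/sₓₓ), symmetric in x and y. Inference is built on the
residual–fitted correlation r(b) = corr(y − bx, y + bx):

* slope-vs-b₀ test: F = r²(n−2)/(1−r²) against F(1, n−2);
* common slope across g groups: b̂ minimises LR(b) = Σ₉ −n₉ ln(1−r₉(b)²);
  LR(b̂) ~ χ²₍g−1₎. LR is zero iff all group slopes coincide, because each
  group's own SMA slope zeroes its residual–fitted correlation. The
  optimisation is a bounded golden-section/Brent search on ln|b| over a
  bracket spanning one third to three times the group slopes (tolerance
  1e-10), falling back to a search on b itself when group slopes differ in
  sign;
* elevation: Wald statistic on the g−1 intercept contrasts at b̂, with
  var(b̂) taken from the observed information — the inverse numerical second
  derivative of LR(b)/2 at b̂ (central differences, step 1e-5·|b̂|) — and
  intercept covariances coupled through var(b̂).

The multivariate response is reduced to a composite shape score for these
bivariate tests: PC1 of the log-shape-ratio matrix over exactly the
specimens in the comparison, sign-aligned with size. A single printed
statistic per comparison implies a single response variable; the composite
keeps the dominant multivariate signal. Pairwise families (species, orders,
diets, partition × diet) are Šidák-corrected, p_adj = 1 − (1−p)^m, with m
the number of comparisons in the family; elevation tests are run only where
the pair's slopes are homogeneous at α = 0.05, and are corrected as their
own family. α = 0.05 throughout.

Calibration: on equal-slope/equal-intercept data (two groups of 30), the
empirical size of both the LR and the Wald test at α = 0.05 falls inside
[0.03, 0.07] over 2000 simulated datasets (asserted in the acceptance
suite). The LR test runs slightly liberal (~0.06) at these sample sizes,
a known property of the uncorrected statistic.

## Allometric space

Covariance PCA (no unit-variance scaling — all coefficients are log-log
slopes on one scale) of the species × p slope matrix. The origin is the mean
trajectory, so a positive/negative loading reads as faster/slower than
average growth of that trait. Axis signs are fixed by making each loading
column's largest-magnitude element positive. Axis retention: broken-stick
rule, bsᵢ = (1/p) Σⱼ₌ᵢ..p 1/j, keeping the leading run of axes whose
variance fraction strictly exceeds bsᵢ; downstream stages use
min(broken-stick k*, cap), cap 4 by default, at least 1.

Intercepts are deliberately excluded from the PCA input: the space is about
growth *patterns* (slopes), and a 50 × 14 slope matrix is what the
coefficient count implies.

## Disparity

Procrustes variance of a group is the trace of its covariance matrix with
divisor n₉ — the mean squared distance to the centroid — making unequal
group sizes comparable. Computed on the full coefficient vectors by
default: PV is rotation-invariant, so this equals the value on all PC
scores and avoids an arbitrary axis cut (an `axes` option reproduces
truncated variants). Pairwise group differences use |PV₉ − PVₕ| with
label permutations over the species in the comparison;
p = (1 + #{null ≥ obs})/(1 + N) so p is never exactly zero; 10,000
iterations by default, seeded and recorded. Allometry-corrected residual
disparity is the mean squared specimen-level residual from the group's
common-slope SMA line on the composite score.

## Convergence

Positions are species' scores on the first k* axes (default cap 4),
centred at the grand mean (the origin of allometric space).

C1–C4: for each focal pair, Dtip is the tip phenotypic distance and Dmax
the maximum distance between reconstructed states on the two root-ward
paths from the MRCA, tips included among the candidates. C1 = 1 −
Dtip/Dmax ∈ [0,1]; C2 = Dmax − Dtip; C3 divides C2 by the summed
branch-wise phenotypic change along both paths; C4 by the change over the
whole clade rooted at the MRCA. Ancestral states are ML reconstructions
under Brownian motion (the GLS solution with a GLS root), implemented as a
single linear map from tip values so that simulated datasets are
reconstructed by one matrix product. Significance: the BM rate matrix is
estimated from the observed tips by independent contrasts (non-PD
estimates repaired by eigenvalue clipping), 300 BM datasets are simulated
on the tree, and pᵢ is the fraction of simulations whose index reaches the
observed one. Because the rate is estimated from the same data, the test
runs slightly conservative under the null — the acceptance suite checks
that null p-values average near 1/2 with few small values rather than
exact uniformity. For diet-level questions the focal set is all species
with that diet and pair enumeration is restricted to cross-partition pairs
(the convergence question is between the two sides of the tree); an
all-pairs option exists. Diets present in only one partition are excluded
by validation, and angle tests additionally require at least two species
per partition — both overridable.

Angle tests: θ = arccos of the cosine between two species' centred
phenotype vectors (degrees); ang.state is the mean over the state's
cross-partition pairs and ang.state.time the mean of θ divided by the
pair's patristic separation (degrees/Myr). The null permutes state labels
across tips; small angles indicate convergence, so p is the fraction of
null means at or below the observed mean, with the (1+hits)/(1+valid)
convention.

## Evolutionary models

Twelve models are fitted to the species × k score matrix, stacked
trait-major, on an ultrametric tree:

| model | covariance | mean | free parameters (k traits, m regimes) |
|---|---|---|---|
| BM1 | t_shared · R | root vector | k(k+1)/2 + k |
| EB | R·(e^{r·t} − 1)/r, r ≤ 0 | root vector | k(k+1)/2 + k + 1 |
| BMMs/d/sd | Σ_r R_r · t_shared^(r) | root vector | m·k(k+1)/2 + k |
| BMMsm/dm/sdm | t_shared · R | regime mean per tip state | k(k+1)/2 + k·m |
| OU1/s/d/sd | blocks R_tu/(α_t+α_u)·(e^{−s(T−t_a)} − e^{−sT}) | Hansen regime weights · θ | k(k+1)/2 + k + k·m |

Conventions, chosen where the model names alone do not pin a
parameterisation:

* multi-rate BM uses a full rate matrix per regime ("branch-segment rate
  matrices"), accumulated along shared paths from stochastic-map regime
  times. A proportional-rate profile (R_r = s_r·R, Kronecker-factorable so
  R profiles out analytically) seeds the optimiser; the full fit then uses
  an analytic gradient (envelope theorem over the GLS mean, with the
  Cholesky chain rule collapsing to (S − Q)·L per regime);
* "multiple ancestral states" BM variants keep the BM1 covariance and give
  each tip the GLS-estimated mean of its regime — closed form;
* OU uses a diagonal attraction matrix (one α per trait) with a full R, a
  fixed root equal to the root regime's optimum (the root's Hansen weight
  e^{−αT} is folded into that regime's column), and optima profiled by
  GLS. α → 0 recovers BM1 exactly, which the tests assert;
* rate matrices are optimised through Cholesky factors with log diagonals
  (positive semi-definiteness by construction), bounded L-BFGS-B,
  multi-start (≥ 3 starts: α ∈ {0.1, 1, 5}/tree-height; BM-moment rate
  seeds);
* regime models are fitted on each of n_maps stochastic character maps
  (equal-rates Mk, ML rate, Nielsen/Bollback node-conditional sampling
  with rejection-sampled branch histories; seeded) and logL/AICc averaged
  across maps. The pipeline default is 10 maps;
* AICc = −2logL + 2p + 2p(p+1)/(n_eff − p − 1) with n_eff = n_tips × k,
  logged in the output. ΔAICc < 2 marks the best-supported set.

Model selection at n ≈ 50 tips is noisy by nature: with 12 candidate
models, a richer model occasionally beats the generating one on AICc by
sampling fluctuation alone. The model-recovery checks therefore assert
high-frequency (not certain) recovery, at the replicate counts below.

## Synthetic data

The generator emulates the structure of a museum ontogenetic-series
compilation at survey scale: a pure-birth tree scaled to 70 Myr height
(the divergence frame of the target clade), conditioned on a root split
with at least ~18% of tips on the smaller side to mirror the two-partition
structure of the emulated fauna; 62 species of which 50 carry
15–64 specimens and 12 carry 5–14 (exercising the pruning rule; ~2000
specimens in total); a four-state diet character under an equal-rates
Markov process (expected ≈ a dozen transitions per tree); per-species
log-linear growth ln mᵢⱼ = cⱼ + (1 + β_sj)xᵢ + ε, x uniform over a
three-fold growth range, measurement noise σ = 0.04 on the log scale
(~4% of a measurement, a realistic calliper/observer error); slope
deviations β evolving under single-optimum OU (half-life = half the tree
height, stationary per-trait SD 0.12) with a structured stationary
covariance — a dominant first axis and a geometrically decaying tail inside
the zero-sum subspace — because real trajectory covariances are strongly
anisotropic. The "forced convergence" option additionally pulls one diet's
tips toward a shared optimum along their terminal branches (OU pull with a
2–3.5 Myr half-life), planting a true convergence signal; the pull only
has material effect on tips whose terminal branches are at least a few
Myr long.

What the generator does *not* emulate: real cranial geometry and
inter-trait allometric structure beyond the planted covariance; ontogenetic
nonlinearity (growth is exactly log-linear); unequal specimen age sampling;
measurement error correlated across traits; fossil calibration uncertainty
in the tree. Passing tests therefore demonstrate the *inferential
machinery* — estimation, calibration, recovery — not the biological claims
one would make from real data.

## Problem sizes in the test suite

Monte-Carlo sizes are package choices balancing statistical resolution
against a single-CPU run: SMA/Wald calibration 2000 datasets; disparity
permutation size 2000 datasets × 299 permutations; convergence null 50
replicates × 300 simulations and power 12 replicates at 50 tips; model
recovery 15 BM1 replicates (1 stochastic map per regime model) and 10 OUd
replicates (2 maps) at 50 tips, k = 4; the full pipeline test runs the
complete survey-scale preset with its production defaults. The recovery
experiments draw trees conditioned on a root split of at least 10 tips on
the smaller side and a conserved diet character (ER rate 0.004/Myr,
roughly a dozen transitions per tree) — the partition and dietary
structure of the system the generator emulates; extreme 1-versus-49
splits or a diet flipping every few Myr are conditions neither the real
clade nor the regime models' asymptotics contemplate. All seeds are
fixed.

## Limitations

* The composite-score reduction for pooled HOS tests is one defensible
  choice among several; per-trait testing with Šidák correction across
  traits is available but not the default.
* OU fits assume an ultrametric tree and a fixed (non-random) root; very
  small α values are indistinguishable from BM at these sample sizes.
* The Wald elevation test relies on a numerical observed-information
  variance for the common slope; with tiny groups (< 10) it can run
  slightly anticonservative.
* Stochastic-map branch histories use rejection sampling with a
  forced-transition fallback for pathological endpoint combinations; at
  plausible Mk rates the fallback essentially never triggers.
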