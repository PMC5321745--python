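# Methods

## The model

The package analyses presence/absence dynamics of a species in a highly
fragmented landscape with a stochastic patch occupancy model (SPOM).
State is a binary occupancy vector over patches, updated annually and
synchronously:

- an occupied patch i goes extinct with probability
  `P_ext,i = 1 − exp(−E_i)`, `E_i = e · A_i^−ex · exp(−y·Q̃_i)`;
- an empty patch is colonized with probability
  `P_col,i = 1 − exp(−c·S_i)`, with connectivity
  `S_i = A_i^im · Σ_{j≠i} p_j · A_j^em · exp(−α·d_ij)` computed from the
  previous year's occupancy.

Areas `A` are in hectares, distances `d` in kilometres, `α` in 1/km.
`ex`, `im`, `em` scale extinction, immigration and emigration by patch
area; `Q̃_i ∈ [−1, 1]` is a composite habitat-quality index and `y` its
effect on the extinction rate. A patch changes state at most once per
year and extinction does not depend on current connectivity (no
within-year rescue); the monotone threshold coupling of the random draws
makes elementwise-larger states produce elementwise-larger successors
under shared seeds, which the dominance tests rely on.

Three landscape-level constructs follow. The **landscape matrix** has
`m_ii = 0` and `m_ij = A_i^x · exp(y·Q̃_i) · A_j^em · exp(−α·d_ij)` with
`x = ex + im`; its Perron root `λ_M` is the **metapopulation capacity**,
and the products of left and right Perron eigenvector entries (normalised
to unit sum) are the patch occupancy weights behind the weighted
metapopulation size `p_λ`. The **extinction threshold** `δ = e/c` is a
species property; the deterministic equilibrium satisfies
`p*_λ = 1 − δ/λ_M`, so a network is viable iff `λ_M > δ`. For a fully
homogeneous network this identity is exact: with identical patches the
mean-field fixed point `p = C/(C+E)` solves to `p = 1 − δ/λ_M` in closed
form, which is why the simulation checks use vertex-transitive ring
landscapes. On heterogeneous landscapes the identity is the weighted
linearised approximation; the fixed-point check allows |error| ≤ 0.05
for λ_M/δ in [1.2, 5].

The **equilibrium incidence model** restates the same balance per patch:
`p̄_i = V_i/(V_i + δ)` with `V_i = A_i^x · exp(y·Q̃_i) · R_i`, where
`R_i = S_i/A_i^im` is the target-area-free connectivity computed from
observed multi-year mean occupancies (held fixed during fitting, the
incidence-function tradition). Stage 1 fits (δ, x) with y = 0; stage 2
frees y. Estimation is nonlinear least squares on the probability scale
(the loss scale is a genuine design freedom; a logit-scale option was
considered and rejected because p̄ = 0 and 1 occur in the data), with
asymptotic 95% CIs from the Gauss–Newton covariance; δ is fitted on the
log scale and its CI delta-method transformed.

The **genotype layer** tracks the pooled frequency `f_disp` of a
dispersal-associated SNP's AC and CC genotypes (dominance model; an
additive C-allele option exists and is the default for the reference SNP
panel). Dispersive genotypes emigrate Δ = 2 times faster, so their
frequency among emigrants is `f̃ = Δf/(Δf + 1 − f)` and among the
immigrants reaching patch i it is the connectivity-share weighted average
`f^S_i = Σ_j w_ij·f̃_j`, `w_ij ∝ p_j·A_j^em·e^(−α·d_ij)`.

## Parameters

| parameter | meaning | unit | default | origin of default |
|---|---|---|---|---|
| α | dispersal-kernel decay | 1/km | 1.0 (0.93 in the turnover set) | field-calibrated for a mobile checkerspot |
| e | extinction rate at A = 1 ha, Q̃ = 0 | 1/yr | 0.38 | turnover estimates |
| c | colonization rate per connectivity unit | 1/yr | e/δ | ties δ to the incidence fit |
| ex, im, em | area exponents | – | 0.23, 0.44 (0.2 in structural runs), 0.2 | turnover estimates / structural convention |
| x | ex + im in the incidence model | – | 0.428 | incidence fit |
| y | quality effect | – | 1.71 (incidence) / 1.40 (turnover) | respective fits |
| δ | extinction threshold e/c | – | 5.47 (incidence) / 3.45 (turnover) | respective fits |
| Δ | emigration ratio of dispersive genotypes | – | 2 | mark–release estimates |

The two δ values are not a contradiction: the incidence and turnover
estimators weight the data differently and the package keeps both,
deriving δ from the joint posterior draws of e/c in the turnover route
(never from the ratio of posterior means — the ratio of means of 0.38 and
0.11 is not the mean of the ratio).

## Inference machinery

`estimate_rates` samples the 7-parameter posterior (uniform priors on the
positive reals, the Bernoulli transition likelihood, connectivity
recomputed from each year's occupancy) with an ensemble sampler using
differential-evolution moves; stretch moves mix poorly on the strongly
correlated (e, c, ex, im) directions. Split-R̂ and ESS are reported and a
warning (error in strict mode) fires above R̂ = 1.01.

`fit_turnover_glmm` fits the varying-intercepts logistic model
`logit p = α₀ + α_{n,t} + α_{i,n} + β·X` (annual network effects
`α_{n,t} ~ N(0, τ)`, patch effects `α_{i,n} ~ N(0, ρ)`, covariates
standardized, area entering as A^0.2) with a purpose-built blocked
Metropolis–within–Gibbs sampler: all random effects of a block are
updated simultaneously by vectorised elementwise Metropolis (per-group
log-likelihood differences via bincount), τ and ρ by exact Gibbs through
the inverse-gamma mixture representation of their half-Cauchy(2.5)
priors, fixed effects jointly with the plain-GLM Fisher covariance as
proposal shape, plus η-invariant location swaps between the intercept
and each random-effect block that remove the dominant posterior
correlation. Adaptation (Robbins–Monro on acceptance rates) runs during
warm-up only. statsmodels' variational Bayes mixed GLM serves as an
independent cross-check in the test suite, not as the implementation.

The three control-survey detection GLMs (binomial group detection,
Bernoulli patch non-detection, Poisson population size; Student-t(4)
priors, scale 10/2.5) use the same ensemble sampler with a vectorised
posterior; their convergence contract is R̂ < 1.005, which the default
chain lengths meet to within ~0.001 (a warning reports any excess).

All samplers are pure functions of their `seed` argument (the ensemble
sampler's internal state is seeded explicitly; it otherwise falls back to
numpy's global generator).

## Synthetic data: what it emulates and what it does not

`generate_study` produces a clustered landscape (uniform parent points,
Gaussian offspring spread 0.55 km, 900 patches in 30 clusters over
30 × 30 km), log-normal areas solved from (median 0.06 ha,
P(A > 2 ha) = 0.01 ⇒ σ ≈ 1.507), ordinal host scores and Beta-distributed
percentage covers; SPOM dynamics at the turnover parameter set with a
10-year burn-in from random occupancy; a survey layer in which the first
6 of 22 years cover a random third of patches and detection operates at
the larval-group level (zero-truncated negative-binomial group counts
with area-scaled mean, per-group logistic detection), so patch-level
non-detection emerges when every group is missed (~10% of occupied
patch-years; missed populations are predominantly single-group, and the
detected-population mean is ≈ 8 groups); and network genotype samples of
one candidate SNP whose frequency follows
`f = 0.25 + 0.7·turnover − 0.2·(log₁₀ pooled area − mean) + N(0, 0.04)`
(clipped to [0.02, 0.98], Hardy–Weinberg counts at the
dominance-consistent allele frequency, 20 family groups × 3 larvae per
network) plus 18 neutral SNPs drawn independently of the dynamics.
These settings were fixed once, against the descriptive statistics a
long-term fragmented-landscape survey reports (fraction of viable
networks ≈ ¼, association R² ≈ 0.4, non-detection ≈ 10–15%).

Deliberately not emulated: real geography and barriers, observation-era
changes in patch delineation, regionally correlated environmental
stochasticity (years are conditionally independent), within-patch
population dynamics beyond group counts, linkage between SNPs, and
family structure within genotype samples (triplet sampling inflates
effective sample size; a family-collapse mode exists but is off by
default). Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions and realistic sampling
noise — not robustness to synchrony, barrier effects or cryptic
population structure.

## Numerical choices and degenerate inputs

- Eigen-decomposition via dense `numpy.linalg.eig` with the Perron pair
  selected by largest real part; power iteration is the independent
  oracle (agreement to 1e-10 relative on random 50-patch landscapes).
  Disconnected matrices keep the global Perron root; weights concentrate
  on the dominant component with a warning.
- Boundary λ_M = δ classifies as non-viable (strict inequality);
  λ_M = 0 yields p*_λ = −∞, flagged.
- Min–max rescaling of quality maps constant columns to 0; a
  single-patch landscape gets all-zero components with a warning. The
  two host-species scores combine by max by default (`sum` available):
  the larva needs at least one host.
- Incidence fitting drops patches never surveyed; a fit with all patches
  permanently occupied aborts (δ at the zero boundary). Transitions
  spanning an unsurveyed year are discarded, never imputed.
- Cluster merging breaks similarity ties deterministically toward the
  lowest patch index; the damping exponent `min(n₁,n₂)^(1−q)` with
  q = 1.5 reproduces pure geometric-mean linkage at q = 1. The exact
  linkage semantics of the original clustering software are not
  recoverable from public sources; this rule is the package's own and is
  exposed (b, q, cut) in `ClusterParams`, and a user-supplied
  `networks.csv` bypasses clustering entirely.
- The genotype propagation layer in the simulator (colonizers inherit
  the immigrant-pool frequency; residents relax toward it at a mixing
  rate, default 0.1/yr) is a deliberately simple frequency model, off by
  default.

## Problem sizes

The test and acceptance runs use the sizes at which the estimators'
sampling behaviour was characterised: 200 patches × 20 years × 20
replicates for rate recovery; 50 networks × 15 years × 20 patches × 20
replicates for the hierarchical model; 60-patch ring networks × 200
replicates × 100 years for the equilibrium identity; 350–900 patches for
incidence fitting and the network reanalysis.

## Known limitations

- Frequentist coverage of the 95% equal-tailed credible intervals under
  the improper uniform-positive priors is slightly below nominal
  (≈ 85–90%) for the colonization-rate parameter c at the 200-patch ×
  20-year study size: c is only weakly identified jointly with α, im and
  em at that scale, and the flat prior's mass at large values skews the
  posterior. The recovery tests document this honestly rather than
  widening the bands; with informative priors or longer series the
  intervals calibrate.
- The hierarchical-model sampler is tuned for crossed random intercepts
  with thousands of groups; random slopes are out of scope.
- `p_λ` renormalises eigenvector weights over the observed patch subset
  each year, which is exact only when missingness is unrelated to the
  weights (true for the generator's random early-year coverage).
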