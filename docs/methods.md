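# Methods

## The model

`occabund` estimates macroscale species abundance from spatially replicated
detection–nondetection data. The study region is divided into grid cells
(index *j*), each containing suitable habitat of known area *A_j* (km²) and
*K_j ≥ 0* non-overlapping sampling plots of recorded area *a_jk* (m²). For
each species *i* and plot the datum is binary: detected (1) or not (0).

Individuals of each species are assumed to follow a homogeneous Poisson
point process with conditional density *d_ij* (per km² of habitat), so the
plot count is Poisson with mean *d_ij a_jk* and the probability of detecting
at least one individual is

    p_ijk = 1 − exp(−z_ij · d_ij · a_jk),

where *z_ij* ∈ {0, 1} indicates whether the species occurs in the cell at
all (zero inflation). The hierarchical structure is

    y_ijk ~ Bernoulli(p_ijk)
    z_ij  ~ Bernoulli(ψ_ij)
    log d_ij    = μ + β₁x₁ⱼ + β₂x₂ⱼ + β₃x₁ⱼx₂ⱼ + e⁽¹⁾_i + e⁽²⁾_j + e⁽³⁾_ij
    logit ψ_ij  = η + γ₁x₁ⱼ + γ₂x₂ⱼ + γ₃x₁ⱼx₂ⱼ + u⁽¹⁾_i + u⁽²⁾_j

with covariates x₁ (actual evapotranspiration) and x₂ (human influence
index) standardised to mean 0, variance 1 over cells. Random effects are
zero-mean Gaussian: species effects (e⁽¹⁾, u⁽¹⁾) with SDs σ₁, τ₁
(independent of each other), cell effects (e⁽²⁾, u⁽²⁾) bivariate with SDs
σ₂, τ₂ and correlation ρ, and a species×cell interaction e⁽³⁾ with SD σ₃.

Auxiliary occurrence information (specimens, range maps, checklists) fixes
*z_ij* where available (*m_ij* = 1). Presence evidence takes priority over
absence evidence when sources conflict, because absences are hard to verify;
a recorded detection combined with an auxiliary absence is treated as a data
contradiction and rejected at validation rather than silently re-prioritised.
Without the density part, dropping zero inflation and auxiliary data reduces
the model to a Bernoulli GLMM with a complementary log–log link and
log-area offset, which is the cross-check oracle used in the tests (lme4 /
statsmodels).

## Inference

The latent occupancy *z_ij* is marginalised analytically: for a pair with
unknown state and all plots empty the contribution is
log[ψ·exp(−Σ_k d a_k) + (1 − ψ)]; a detection forces the presence branch.
The Gaussian random effects are then integrated out by a joint Laplace
approximation. The joint mode is found by damped Newton iteration; because
the e⁽³⁾ block of the negative Hessian is diagonal, it is eliminated by a
Schur complement, leaving a dense system of dimension 2I + 2J. The
log-determinant splits accordingly, so an evaluation at the recovery-study
scale (I = 30, J = 50, K = 10) costs a few milliseconds.

When e⁽³⁾ is the only active random effect, the marginal factorises over
(species, cell) pairs into one-dimensional integrals and the implementation
switches to adaptive Gauss–Hermite quadrature (31 nodes, centred and scaled
at each conditional mode) — the same escalation lme4 performs through nAGQ.
With no active random effects the likelihood is evaluated exactly. Fully
Bayesian sampling (MCMC) would be a valid alternative inference route; it is
not implemented here.

The outer maximisation over (μ, β, η, γ, log σ, log τ, atanh ρ) uses
L-BFGS-B with finite-difference gradients (step 1e−5), warm-starting the
inner Newton solve across evaluations. SDs are optimised on the log scale
and ρ through atanh, so the optimum is interior. Starting values are
moment-based (intercepts from the pooled detection frequency and observed
occupancy fraction; SDs at 0.5). Convergence and the terminal gradient norm
are reported; a non-positive-definite Hessian at the mode raises rather than
passing silently. Standard errors come from the observed information —
a central finite-difference Hessian of the negative log marginal likelihood
(relative step 1e−3) — inverted on the transformed scale.

Known accuracy limits: the joint Laplace approximation for binary data
mildly shrinks variance components (the occupancy-side cell SD τ₂ most of
all, since each cell's occupancy is informed by few effective observations),
which makes Wald ±2 SE intervals for fixed effects slightly anti-conservative
at moderate designs. This is the standard behaviour of Laplace-based GLMM
estimators for binary crossed designs; the recovery test in the suite
measures the empirical coverage at I = 30, J = 50, K = 10. Profile or
bootstrap intervals are preferable when occupancy-side coefficients are the
quantity of interest.

### Units

Plot areas are m², habitat areas km², densities per km² of habitat; the
conversion constant 1e−6 is applied once inside the likelihood. Reported
abundances are individuals; areas of occupancy are km².

## Derived estimators

All estimators use the occupancy weight w_ij = m_ij z_ij + (1 − m_ij) ψ̂_ij:

- richness Ŝ_j = Σ_i w_ij
- cell abundance N̂_ij = d̂_ij A_j w_ij, regional abundance by summing cells
- area of occupancy R̂_i = Σ_j A_j w_ij
- Shannon entropy H = −Σ q log q with natural logarithms (0·log 0 = 0),
  computed from the abundance vector.

Uncertainty comes from a parametric bootstrap: each replicate resimulates
random effects, occupancy and detections from the fitted parameters with the
same survey design, holding the auxiliary records (and hence the z values
they fix) constant; the model is refit starting at the original estimates to
cut cost, and SEs are SDs over successful replicates (failures are counted
and a warning is raised below an 80% success rate). The published analysis
used B = 100 replicates; the test suite uses B = 30 with smaller simulated
designs to keep runtimes in minutes.

Validation metrics compare predicted and observed density per km²: RMSE and
bias on the arithmetic scale, Pearson correlation of log densities over
pairs where both are positive (zeros are excluded before logging). Pairs
whose absence is indicated by auxiliary data are excluded upstream. The
red-list summary excludes introduced species, tabulates log abundance and
area of occupancy per category (NC, NT, VU, EN, CR), and flags unlisted
(NC) native species whose area of occupancy falls below the IUCN D2
threshold of 20 km².

## Neutral-theory (UNTB) suite

Metacommunity species-abundance distributions (SADs) are compared across
three speciation modes and one statistical baseline:

- **Point mutation (PMS).** The metacommunity SAD likelihood is the Ewens
  sampling formula, evaluated entirely in log-gamma form so it is stable at
  J_M ~ 1e10. The MLE of θ solves S = θ[ψ₀(θ + J_M) − ψ₀(θ)] (digamma);
  the expected SAD is E[S_n] = (θ/n)·J!/(J−n)!·Γ(θ+J−n)/Γ(θ+J).
- **Random fission (RFS).** The equilibrium distribution of the abundance
  vector in a fixed-size metacommunity factorises as a species-count law
  P(S|θ) ∝ θ^{2(S−1)}/(S!(S−1)!) (normalised over S ≤ J_M; the birth–death
  balance of fission events at rate ∝ θ² against extinctions of singleton
  species) times a uniform (broken-stick) distribution over compositions.
  Only the first factor involves θ, so the fit is one-dimensional and the
  optimum sits at θ̂ ≈ S − 1/4 for large J_M. Brute-force enumeration over
  all partitions at J_M ≤ 8 confirms normalisation.
- **Protracted speciation (PS).** The expected SAD is the difference
  logseries E[S_n] = (θ/n)[(1−μ)ⁿ − (τ/(1+τ))ⁿ] with μ = θ/(J_M−1+θ) and
  τ = (J_M−1)/β − 1: logseries at large abundance, a rare-species deficit
  below n ≈ τ, and exact reduction to the logseries as τ → 0. The model is
  fit by equally weighted least squares on Preston octaves (octave *j*
  contains abundances 2^(j−1) ≤ n < 2^j; continuous estimates are binned by
  the same half-open boundaries without rounding), with multi-start
  Nelder–Mead over (log θ, log β); boundary solutions are flagged. Octave
  expectations are summed exactly below 2¹⁶ and by midpoint-corrected
  integrals (exponential-integral or log-Simpson) above, accurate to ~1e−6
  relative.
- **Poisson-lognormal (PLN).** A zero-truncated Poisson-lognormal fitted by
  maximum composite likelihood; its pmf is evaluated with adaptive
  Gauss–Hermite quadrature in log intensity, centred at the per-count mode
  so it remains accurate from n = 0 to n ~ 1e8.

Model comparison uses the composite likelihood that treats each species'
abundance as an independent draw from the normalised expected SAD
(Σ_s log E[S_{n_s}] − S log Σ_n E[S_n]); a per-species multinomial
construction rather than per-octave Poisson counts. AIC = −2 logL_c + 2k
with k = 1 (PMS, RFS) or 2 (PS, PLN), and Akaike weights
w_m ∝ exp(−ΔAIC_m/2). The AIC ranking is invariant to rescaling all
expected SADs by a constant. For the PS model the composite likelihood is
evaluated post hoc at the least-squares optimum, treating that estimate as
the maximum-likelihood value.

Macroevolutionary conversions (natural logs throughout):

| model | θ–ν relation | lifetime L (generations) |
|---|---|---|
| PMS | θ = ν/(1−ν)·(J_M−1) | −log ν |
| RFS | θ = √ν·J_M | ν^(−1/2) |
| PS | θ = μ/(1−μ)·(J_M−1), μ = (1+τ)ν, τ = (J_M−1)/β − 1 | −τ·log(τμ) |

These follow from the general relation L = (equilibrium species number) /
(rate of production of new species).

## Synthetic data

The generator draws every quantity from exactly the distributions the model
assumes, so parameter-recovery tests are well specified. Defaults emulate a
vegetation-survey design: plot areas log-uniform on [10, 1000] m² (surveys
of this kind report plots from 0.01 m² to 1.8 ha with ~100 m² typical),
habitat areas lognormal with median ≈ 30 km² per cell, and density intercept
μ = log 2000 per km² conditional on presence, giving realistic detection
probabilities of 0.05–0.5 at typical plot sizes. Occupancy defaults centre
ψ at 0.5 with species SD 1.0 and cell SD 0.5, correlation ρ = 0.5 with the
density cell effect. Auxiliary coverage defaults register 50% of true
presences and 30% of true absences; real coverages are unknown, and both are
configurable. Plots are represented by areas only (the likelihood depends on
nothing else, given non-overlap); spatially autocorrelated covariates,
clustered point patterns and temporal dynamics are deliberately not
emulated, so passing tests say nothing about robustness to those
violations. The Ewens urn provides exact point-mutation SADs; random-fission
and protracted metacommunities have no comparable exact sampler, so fitter
tests for those models use expected-SAD-based draws instead.

## Problem sizes in the test suite

Parameter recovery runs 20 replicates at I = 30 species, J = 50 cells,
K = 10 plots per cell; bootstrap coverage runs 20 replicates at I = 8,
J = 15, K = 10 with B = 30; cross-validation examples use 3–4 folds on
small simulated designs. These sizes keep the full suite to roughly ten
minutes on one CPU while leaving each check statistically meaningful; all
are package choices and scale up linearly.

## Known limitations

- Laplace-based variance components shrink slightly for binary data (see
  above); profile or bootstrap intervals are preferable for τ₂-like
  parameters in small designs.
- The detection model identifies density only while d·a is moderate; as
  d·a grows the detection probability saturates and density information
  vanishes (abundant species in large plots).
- Continuous "abundances" produced by the estimators are binned into
  octaves and treated by the composite likelihood as if integer; for
  J_M ≫ S the effect is negligible.
- The RFS equilibrium law and the PS difference-logseries expectation are
  implemented from their defining processes (fission birth–death balance;
  protracted-lineage survival) and validated by enumeration, limiting
  behaviour and self-consistency tests rather than against an external
  reference implementation.
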