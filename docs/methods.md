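# Methods

`ecodiff` implements a hierarchical spatiotemporal model for a population
recolonizing a patchy nearshore domain from multiple release sites, together
with the survey observation process and Bayesian inference. This note
records the model, the numerical choices, and the reasoning behind the
design decisions; nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Process model

The population intensity λ(s, t) follows logistic ecological diffusion

∂λ/∂t = ∇²(δ(s) λ) + γ λ (1 − λ/K(s)),

where δ(s) is motility (m²/yr; inversely proportional to residence time —
animals linger where δ is low), γ the intrinsic growth rate (per year) and
K(s) the local density dependence. Note the operator is ∇²(δλ), not Fickian
∇·(δ∇λ): ecological diffusion arises from random walks with spatially
variable movement probabilities and concentrates individuals in low-δ
habitat at equilibrium (λ ∝ 1/δ under pure diffusion).

Both coefficient fields are log-linear in landscape covariates:

- log δ = β₀ + β₁·depth + β₂·dist_shore + β₃·(slope×depth) + β₄·shoreline
  complexity + β₅·town distance + β₆·protected bay + β₇·fisheries closures;
- log K = α₀ + α₁·protected bay + α₂·fisheries closures.

Non-indicator covariates are standardized to mean 0, sd 1 over water cells.
The initial condition is a sum of J Gaussian kernels centred on the release
epicenters, each normalized over the water domain so that the initial total
abundance is exactly Σθⱼ; κⱼ sets each kernel's spatial spread. The kernel
normalizer integrates over the water domain (not the whole plane), so θⱼ is
the abundance actually placed in the domain; near coastlines this differs
from a free-plane normalization, which we consider the more faithful reading
of "initial abundance at the release site".

### Units

λ and K are per fine grid cell (the 400 m cell is the areal integration
unit): a cell intensity is directly the expected count in that cell, and the
regional nominal carrying capacity is ΣK over water cells. δ carries m²/yr:
with the reference coefficient magnitudes (β₀ ≈ 16.4) this puts the minimum
wave speed 2√(δγ) in the observed km/yr range. Times are years internally;
solver steps are specified in days and converted by /365.

## Numerics

### Discretization and homogenization

The solver works in the substituted state c = δλ on the water cells of a
grid coarsened by a factor 1/ε (default ε = 1/5 for the desk-scale domain;
the reference configuration is ε = 1/10 on a much larger domain). Each
coarse cell carries

- δ̄ = harmonic mean of δ over its fine water cells, and
- r̄ = arithmetic mean of 1/(δK),

and the coarse reaction–diffusion system is dc/dt = (δ̄/A)Σⱼ(cⱼ − cᵢ)/a² +
γc(1 − r̄c), a finite-volume flux form with A the coarse cell's water area.
This reduces exactly to δ̄∇²c on fully-water coarse cells and keeps fluxes
antisymmetric, so with γ = 0 total abundance is conserved to rounding even
when coarse cells are partially land. For ecological diffusion the harmonic
mean is the exact effective coefficient in the scale-separation limit
(substituting c = δλ moves the coefficient out of the divergence, so no
cell-problem correction appears); the averaging choices are validated
against a direct fine-scale solve in the test suite. The fine solution is
recovered as λ = c/δ(s) at fine resolution, which restores the 1/δ
within-cell microstructure.

Boundary conditions are zero-flux (reflective) at every water/non-water
interface, implemented by mirror ghost cells — absent neighbours simply
contribute no flux. The domain boundary includes offshore cells beyond the
configured distance-to-shore and depth limits, mirroring the nearshore
system's outer edge.

Homogenization is accurate when δ varies on a scale finer than the coarse
cells and the solution varies on a coarser one. It degrades (i) immediately
after initialization if the kernels are narrower than a coarse cell, and
(ii) near local saturation, where the true field approaches the constant K
while the downscaled field keeps its 1/δ microstructure. The homogenization
oracle test therefore uses a coarse-resolved initial kernel and a
growth-phase horizon — which is also the regime the recolonization analysis
itself occupies.

### Time stepping

Each step is operator-split: backward-Euler diffusion (unconditionally
stable; the system matrix is an M-matrix, so its inverse is nonnegative and
the state cannot undershoot), followed by an exact per-cell logistic update
c ← c·g / (1 + r̄c(g − 1)) with g = exp(γΔt). The exact reaction step was
chosen over the forward-Euler update because it is positivity-preserving and
removes the reaction's time-stepping error entirely (a forward-Euler scheme
is retained as `scheme="euler"`; an order-of-accuracy test uses it). The
default step is Δt = 1 d; the desk-scale simulation studies use Δt = 3–5 d
for both truth generation and fitting, so the generating process and the
fitted likelihood share one discretization. On small coarse grids the
backward-Euler propagator is precomputed as a dense matrix and the stepping
loop is numba-compiled; above ~1500 coarse cells the solver switches to a
sparse LU factorization reused across steps.

## Observation model

True abundance is negative binomial around the cell intensity,
N ~ NB(mean λ, size τ) with Var = λ + λ²/τ; observed counts are binomially
thinned, y ~ Binomial(N, p_t), with one detection probability per year
shared across survey types. The mean/size parameterization was chosen
because the reference dispersion (τ ≈ 0.03 under a Uniform(0,1) prior)
implies heavy overdispersion — clustered rafts of animals — whereas a
Var = λ(1+τ) convention would force near-Poisson counts on (0,1).

Two exact identities drive both testing and inference:

- thinning: marginally y ~ NB(pλ, τ);
- latent conditional: N − y | y ~ NB(size τ + y, success prob 1 − q') with
  q' = (1 − p)λ/(λ + τ),

both verified against brute-force enumeration. Intensive search units
(ISUs) — groups recounted exhaustively while circling — contribute
Binomial(initial | final, p_t) terms, with the circling count treated as the
true abundance of the cell (so ISU cells enter the process likelihood as
known-N observations and never double as thinned counts). Photographic
survey years get the informative moment-matched Beta(44.04937, 13.40566)
detection prior; other years Beta(1,1).

## Inference

Metropolis-within-Gibbs over (γ, β, α, θ, κ, τ), the latent N at
count-observed cells, and the yearly p_t:

- random-walk Metropolis on log scale for γ and (θ, κ) jointly, natural
  scale for β and α, logit scale for τ; every process-parameter proposal
  triggers one homogenized PDE solve, and λ is cached across blocks that do
  not touch process parameters (τ, which needs no solve, gets several cheap
  sub-updates per sweep);
- latent N by its exact shifted-NB conditional (a direct Gibbs draw);
- p_t by its conjugate Beta conditional given N, y and the ISU records.

Proposal scales adapt in batches toward 0.30 acceptance during burn-in and
are frozen afterwards; the vector blocks additionally learn a Haario-style
empirical-covariance proposal shape from the burn-in history, which matters
because the motility intercept and the indicator coefficients are strongly
correlated (the depth indicator is unstandardized, so β₀ and β₁ form a
ridge identified mainly through the sparse deep-water observations). Chains
initialize at the prior means except the motility intercept, which starts
at log(one homogenized cell area per year) — the natural dynamic scale of
the solver — because exp(0) m²/yr is dynamically frozen and wastes burn-in.
The growth-rate prior is truncated to (0, ∞) (negligible mass change at the
reference hyperparameters) so the log posterior is finite exactly on the
support the PDE accepts. The analytically marginalized count likelihood
(y ~ NB(pλ, τ)) is implemented alongside the augmented one and serves as a
cross-check oracle in the tests.

Sampler correctness is checked three ways: a priors-only run reproduces the
prior marginals; identical seeds give bit-identical chains; and a
Geweke-style successive-conditional simulation (alternating one sampler
transition with data re-simulated from the current parameters) preserves the
prior marginals on a small model.

## Synthetic studies

The generator emulates the structure of a multi-decade aerial monitoring
program on a desk-scale domain: 40×40 cells of 400 m (16×16 km), a
connected fjord-like water domain carved from anisotropically smoothed
noise, depth increasing away from shore with the shallow (<40 m) fraction
pinned at 0.40, offshore cells beyond 5 km from shore or 100 m depth
removed from the domain, three coastal towns, and two disjoint rectangular
management areas (protected bay, fisheries closures). Covariates are
computed exactly as the model consumes them (shoreline complexity in a
1000 m disc; cumulative shortest swimmable path to towns by 8-connected
Dijkstra with √2 diagonal costs).

Default truth parameters are the reference posterior means (β, α, γ = 0.29,
τ = 0.03) with the release scales adapted to the small domain: θ scaled by
0.1 (the reference Σθ ≈ 471 would exceed the small domain's nominal
capacity; the real region is an order of magnitude larger) and κ set to
0.8–3 km (the reference values, up to ~29, do not fit a 16 km domain).
Twenty years are simulated with 8 surveyed: distribution surveys of all
shallow cells in years 1–2, stratified design transects with ISUs in years
4, 7, 10, 13, 16 (columns flown with probability 0.5; shallow-stratum cells
surveyed at 3× the rate of deep cells; ISUs triggered at rate 0.3 on groups
of 1–20), and a photographic survey in year 19 with p drawn from the
informative Beta prior.

What the generator does *not* emulate: spatially correlated detection,
group-size-dependent availability, observer effects, subsistence-harvest
removals, within-year survey timing, or real bathymetry. Passing tests
therefore demonstrate internal consistency of the method under its own
assumptions at desk scale — not field validity on real survey data.

### Priors for the simulation studies

`PriorSpec()` defaults reproduce the reference analysis' priors exactly
(γ ~ N(0.25, 0.01²), β, α ~ N(0, 10²), release-record positive-normals for
θ and κ, τ ~ U(0,1)) and are what the priors-only sampler check uses.
`PriorSpec.for_study` builds priors for a synthetic study: θ and κ
hyperparameters centred on the study's release records with relative sds
matching the shape of the reference translocation priors (20% on release
scales, 40% on dispersals), and a γ prior with the same centre but sd 0.05. The rationale: the
reference γ prior's precision encodes previous-study information
commensurate with a dataset of ~42,000 counts; a desk-scale study carries
γ likelihood information of roughly sd 0.04–0.05, and a recovery experiment
is only meaningful when the posterior is data-dominated. With the reference
sd of 0.01 the desk posterior is the prior, and no recovery experiment at
this scale could assess the method.

Recovery-experiment scale: 20 replicate studies, one chain of 3600
iterations (1800 burn-in) each at Δt = 5 d — sizes chosen so the whole
experiment runs in minutes on a laptop core while keeping enough effective
samples for stable 90% intervals.

## Derived quantities

Front regime and spread rates follow traveling-wave theory for the logistic
model: steep initial fronts (steepness 1/κ² ≥ √(γ/δ̄)) converge to the
minimum speed 2√(δ̄γ); flatter fronts keep their shape and travel at
δ̄/κ² + γκ². As printed, the steepness comparison is not dimensionally
homogeneous; we adopt the kilometre as the reference length (κ in km, δ̄ in
km²/yr, 1/κ² read as the exponential tail steepness per km) and report
rates in km/yr. The regime inequality mixes a per-epicenter κ with the
spatial δ̄ field; we evaluate it at the δ̄ of the coarse cell containing each
epicenter and report the per-epicenter regimes rather than asserting one.
Spread-rate maps use the single global γ with the local δ̄ on the
homogenized grid; summaries (min/median/max) are taken over coarse water
cells at fixed (posterior-mean) parameters.

Total abundance per posterior draw sums (i) known true abundances (ISU
recounts), (ii) the draw's latent N at count-observed cells, and (iii)
fresh NB draws around the draw's intensity surface at unsurveyed cells —
re-solving the PDE per retained draw rather than storing intensity surfaces
(CPU traded for storage). Posterior predictive checks simulate replicate
counts through the full observation layer and report the fraction of
observations outside their equal-tailed 95% predictive intervals; with
heavy overdispersion the discrete intervals are conservative, so the
self-simulated outside fraction sits at or below the nominal 5%.

## Degenerate inputs and tie-breaks

- Standardization rejects zero-variance covariates by name; indicators are
  exempt and returned bit-identical.
- Towns on land snap to the nearest water cell; water cells unreachable
  from a town take that town's maximum finite in-domain distance so
  standardization stays finite.
- Shoreline is defined as a water cell 4-adjacent to land (configurable
  reading; the array edge is not land). The complexity radius must be at
  least one cell.
- Epicenters must sit on water; a kernel that sums to zero over water is
  rejected.
- λ = 0 with a positive latent N has likelihood −∞; proposals that overflow
  exp or break the solver are treated as −∞ and rejected (logged by the
  acceptance-rate warnings if chronic).
- Equality in the front-steepness condition counts as steep (the two rate
  formulas coincide there).

## Known limitations

- In the desk-scale recovery experiment the growth-rate marginal posterior
  is systematically attracted below the generating value: the weakly
  identified density-dependence and release-scale directions (their
  likelihood is nearly flat upward) drag the γ marginal down when
  integrated over, an effect that persists in long chains and with the
  exact marginalized likelihood, and therefore reflects the posterior
  itself rather than the sampler. Credible-interval coverage of γ is
  nonetheless close to nominal because the intervals are wide; the
  replicated experiment in the test suite and `scripts/acceptance.py`
  quantifies both the coverage and the posterior-mean bias. Resolving the
  bias requires substantially more survey information than the desk-scale
  study carries.

- The homogenized fine-scale reconstruction carries the 1/δ microstructure;
  near local saturation it cannot represent the flat λ ≈ K profile, so
  late-saturation intensity maps are coarse-scale accurate only.
- Detection probabilities in years without ISUs are identified mainly
  through the prior and the shared process model.
- The sampler treats the PDE as a black box (no gradients); mixing along
  the β₀/β₁ ridge is the practical bottleneck, mitigated but not removed by
  the adaptive-covariance proposals.
- Desk-scale simulation studies use one chain per replicate; multi-chain
  convergence diagnostics (rank-normalized split R̂, ESS) are available via
  the chains' parameter table and arviz but are not part of the automated
  experiment.
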