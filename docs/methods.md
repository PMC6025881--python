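# Methods

This note records the models, conventions and numerical choices behind
`oncotoc`, and what the synthetic experiments do and do not demonstrate.

## Fields, grids and quadrature

All fields live on a regular 3D voxel lattice (cell-centered, 0-based
indices, physical units mm).  Temporal fields add a uniformly spaced time
axis (hours).  Every spatial integral is the midpoint rule
`ε³ Σ_voxels`, every time integral the rectangle rule `Δt Σ_frames`; a frame
value represents the interval `[t_k, t_k + Δt)`.  No other quadrature is
used anywhere, so discrete identities (e.g. that the integrated log-kill
equals the inner product of the sampled fields) hold exactly rather than
approximately.  Units are fixed package-wide: mm, h, molecules/mm³;
diffusion coefficients in mm²/h.

## Random-field ensembles

* **Gaussian** — mean (constant or field) plus either a stationary
  squared-exponential covariance `σ² exp(−|r−r′|²/2ℓ²)` or an explicit
  symmetric matrix over voxels.  Stationary sampling uses circulant
  embedding: the kernel is placed on a torus padded by at least six
  correlation lengths per axis, its FFT spectrum clipped at zero, and a
  complex white-noise draw filtered back; the retained block then has the
  target covariance to within the (negligible) wrap-around term.  Explicit
  covariances are sampled by dense eigendecomposition, refused above
  20 000 voxels; eigenvalues below `−10⁻¹⁰·trace` raise an error, small
  negative ones are clipped to zero.
* **Lumpy background** — baseline b₀ plus `K ~ Poisson(K̄)` isotropic
  Gaussian blobs `a₀ exp(−|r−r_k|²/2s²)` with centers uniform over the
  field of view.  Because this is a filtered Poisson point process its
  characteristic functional is known exactly; the implementation evaluates
  it by convolving the test function with the lump kernel (full-width FFT
  convolution, so the discrete sum is exact) and midpoint-quadrating over
  the center coordinate.  `mean_value` gives the idealized spatial mean
  (infinite-domain lump integral); `mean_field` gives the exact
  finite-volume expectation, which is lower near edges because lumps
  centered close to the boundary leave part of their mass outside.
* **Lognormal** — `exp` of a Gaussian field; strictly positive, used for
  cell densities.  No analytic CF is exposed; requesting one raises a
  capability error directing to the empirical route.
* **Spatiotemporal Poisson point process** — mean function s̄(r, t) ≥ 0;
  events per draw `J ~ Poisson(∫∫ s̄)`, bins proportional to s̄, positions
  uniform within the voxel and times uniform within the frame.  Its CF is
  `exp(∫∫ s̄ (e^{−2πiφ} − 1))` by the same quadrature, which is consistent
  with the sampler by construction (the test functions are bin-wise
  constant).

The Fourier convention is fixed throughout: characteristic
function/functional with kernel `e^{−2πi(...)}`, inversion with
`e^{+2πi(...)}`, no angular-frequency variants.

## Growth and response

Growth laws are expressed as `d ln N/dt = Φ(N)` with Φ exponential (β),
logistic, Gompertz (`−μ ln(N/N_max)`) or von Bertalanffy
(`μ((N/N_max)^{−1/3} − 1)`); all saturating forms vanish at the carrying
capacity.  The drug enters as the linear log-kill term `−α C(t)`.  The
spatial version integrates every voxel independently with its own μ(r),
n_max(r), α(r) and exposure c(r, t) — a random differential equation solved
realization-by-realization, not a stochastic (Itô) one, and deliberately
without diffusive or chemotactic coupling between voxels.

Integration is fixed-step explicit RK4 in ln n (16 substeps per output
interval by default), which preserves positivity identically and keeps the
Gompertz closed-form error below 10⁻⁶ for rates of order 1/h on the time
spans used here; the suite verifies fourth-order step-halving behavior.
Initial densities must be strictly positive: growth proceeds from
pre-existing clonogenic cells, so a zero-density voxel can never seed a
tumor.

The "evolving tumor volume" over which cells are counted has no dynamical
rule in this framework; `density_threshold_mask` is a documented stand-in
(default: the whole grid), not a boundary-evolution model.

## Log-kill statistics and Fourier inversion

`ψ_{Y|c}(ξ) = Ψ_α[−ξ·AUC]` is evaluated analytically for Gaussian and lumpy
sensitivity ensembles (the lumpy path is the showcase non-Gaussian case:
the Poisson-point CF of lump centers composed with the lump-smoothed
exposure).  The PDF of Y is recovered on a symmetric ξ grid of power-of-two
length (default 4096) via a single inverse FFT; with both grids symmetric
and reciprocal (`ΔY = 1/(2ξ_max)`), the double sum reduces exactly to an
FFT with alternating-sign twiddles.

Grid policy: the mean and standard deviation of Y are first estimated from
log ψ near the origin (central differences, step adapted so the probe phase
sits between 0.02 and 0.5 radians — large enough to beat roundoff, small
enough for the quadratic cumulant expansion).  ξ_max starts near 1/(2πσ)
and doubles until |ψ| < 10⁻⁸ at the grid edge, then is enlarged so that
ΔY ≤ σ/64 (pure zero-padding; ψ is already negligible there), and the grid
length grows if the Y window would not cover 30σ.  The inversion is
centered on the estimated mean by modulating ψ, which also makes the
degenerate case exact: a (near-)deterministic Y (σ below 10⁻⁵ of scale)
collapses to a single-bin delta rather than a truncation-artifact sinc.
Negative ripple is clipped at zero and the PDF renormalized; clipped mass
above 10⁻⁴ is an error (raise ξ_max), below it is recorded on the result.
If |ψ| refuses to decay — which genuinely happens when the sensitivity
distribution has an almost-atom, e.g. a lumpy model whose blobs rarely
overlap the exposure — the code raises a resolution error instead of
silently returning a distorted PDF.

TCP is the lower tail `Pr(Y < Y_c)` of the inverted PDF (strict inequality;
the distributions handled are continuous).  A threshold of Y_c = −3
corresponds to an e³ ≈ 20-fold cell reduction.  Mass sweeps use the linear
delivery model `AUC = M·auc`; TCP(M) is then nondecreasing for nonnegative
sensitivity and exposure.  Nonlocal response (dose deposited at a distance,
as in targeted radionuclide therapy) is a purely spatial smoothing of the
time-integrated exposure before the CF evaluation — exposure is already
time-integrated, so there is nothing for the kernel to act on in time; an
identity kernel reproduces the local result exactly.

## Microscale delivery cascade

The drug decomposes into capillary, diffusing, bound and internalized
components.  Extravasation is a Poisson point source with mean
`s̄ = c_cap·v`; diffusion uses a symmetric finite-volume discretization of
`−∇·D∇` (arithmetic-mean face diffusivities, zero-flux boundaries, zero
rows sums, PSD), advanced by backward Euler with a single sparse
factorization per run.  Zero-flux plus zero row sums make mass conservation
exact to solver precision, which the suite checks at 10⁻⁸.  Point events
deposit `1/ε³` into their containing voxel at the nearest step.

Because the discretization is symmetric, the diffusion operator is
self-adjoint and the adjoint semigroup in the CF propagation rule equals
the forward one — stated explicitly since the continuous theory
distinguishes them.  The propagation rule evaluates the source CF at the
effective test function `e^{(t′−t)A}φ`, computed by dense eigendecomposition
(capacity-capped at 2500 unknowns) at the *midpoints* of the source time
bins: event times are uniform within a bin, and midpoint evaluation is the
O(Δt²)-consistent choice (left-endpoint evaluation biases the comparison
with simulation noticeably when the fastest modes decay within one bin).
The evaluation time t should be a bin boundary.

Binding is Michaelis–Menten at local dynamic equilibrium,
`c_bound = n·N_rec·c_diff/(K_d + c_diff)`, with per-cell receptor numbers
optionally Poisson (tumor cells are near-clonal, making a Poisson count the
natural model) and a configurable receptors-to-concentration conversion
constant, since `n·N_rec` mixes per-cell counts with volume densities.  The
weak-binding linearization divides by K_d only; its relative error is
bounded by `max(c_diff)/K_d`, which the suite verifies field-wise.
Internalization is the running rectangle-rule integral scaled by the
endocytotic rate K_e.  Intravasation is treated as a reduction of the
extravasation rate, and catabolism is not modeled.

## Imaging chain

The toy ECT system is a separable Gaussian blur (configurable FWHM) with
optional block downsampling, as an explicit sparse matrix — the low-pass-
plus-sampling essence of emission tomography without attenuation, scatter
or detector physics.  Data are independent Poisson draws per bin; dynamic
sequences image each frame independently with the same operator.

MLEM uses the standard multiplicative update with a fixed iteration count
(default 50) — stopping is a bias/variance knob, not a convergence
criterion, and early-stopped MLEM is slightly biased; the digital-patient
experiments therefore measure the residual bias rather than assuming it
away.  The classical properties (nonnegativity, monotone log-likelihood,
total projected counts equal total observed counts after the first
iteration) are verified on every tested operator/phantom pair.
Reconstruction covariance is a Monte-Carlo sample covariance over
independent noise realizations at fixed truth; a Fisher-information (CRB)
approximation is available but explicitly non-reference.

## Patient-specific estimation and the TOC curve

Plugging the reconstructions into the log-kill quadrature gives
`Ŷ = −ε³ Σ_n α̂_n (Δt Σ_m ĉ_{nm})`.  Two variance propagations ship:

* **as-printed** — the literal double sum `ε³Δt ΣΣ K_α K_c`, kept verbatim
  as the cited form;
* **quadrature-consistent** — the exact variance of the discrete quadrature
  for independent α̂ and ĉ estimates:
  `ε⁶ [Σ K_α∘K_AUC + α̂ᵀK_AUC α̂ + AUCᵀK_α AUC]` with `K_AUC = Δt² Σ_m K_c^{(m)}`.

Dimensional analysis of the quadrature supports the second form, and the
Monte-Carlo experiment arbitrates: at the default study geometry the
quadrature-consistent value lands within ~10% of the variance of Ŷ over
2000 simulated noise pairs, while the as-printed value differs by orders of
magnitude.  Both are always computed and reported; no intent is guessed.
The two ECT studies (sensitivity and drug) use independent seeds,
implementing their statistical independence.

The TCP estimate is the Gaussian lower tail at Y_c (an error function),
justified by the asymptotic normality of ML functionals and verified
empirically (voxelwise and Ŷ skewness < 0.3 at high counts; 95% intervals
achieve 92–97% coverage over 500 simulated patients).

NTCP has no mechanistic model here — whole-body dose-complication data are
scarce — so a conventional probit in ln M (NTCP(M50) = ½, slope σ in
log-mass units) serves as a configurable stand-in; it is a shape, not a
calibration.  The TOC curve plots TCP against NTCP over the mass sweep; the
area AUTOC is computed by the trapezoid rule after extending the curve to
the endpoints NTCP = 0 and 1 with the M → 0 and M → ∞ TCP limits (by
default the first/last sampled values, carried out flat).  With the true
limits supplied, the degenerate identities AUTOC = 1 (perfect therapy) and
AUTOC = ½ (TCP ≡ NTCP) hold exactly.

## The digital patient (synthetic-data generator)

`workbench.generate_patient` wires the chain end-to-end: lumpy sensitivity
and exposure truths (lumpy fields are nonnegative by construction, which
the Poisson forward model requires), a separable drug truth
`c = M·shape(r)·k e^{−kt}` (linear in mass, so the unit exposure is well
defined), two independent ECT studies, per-frame MLEM, Monte-Carlo
covariances, and the Ŷ/Var/TCP/TOC report.  Every stochastic stage has its
own named seed; identical configs give bit-identical outputs, and the
manifest records the config hash.

What the generator emulates: spatial heterogeneity with controllable
correlation structure, Poisson counting noise, resolution loss, and the
propagation of both through a nonlinear reconstruction.  What it does not:
vascular anatomy (capillary trees are supplied as random-field models, not
grown constructively), attenuation/scatter/detector physics, pharmacology
beyond linear log-kill, catabolism, migration, and real population
variability in any parameter.  Passing tests therefore demonstrate the
correctness and internal consistency of the statistical machinery on these
idealized ensembles — not clinical validity of any particular parameter
value.

## Problem sizes and defaults

Closed-form checks run on 32³ voxels; Monte-Carlo cross-checks use 10⁴
field or event samples where a distributional distance is asserted and
2–5·10³ where only a CF value is compared.  The variance/coverage studies
use an 8×8×1 grid with 4 frames at ~10³ counts per bin, 40 MLEM iterations,
2000 noise-pair realizations for the variance ratio and 500 for coverage,
with covariances from 500-realization Monte Carlo — sizes chosen so the
Monte-Carlo error is comfortably below the 10–15% bands being tested while
the whole suite stays fast on a single CPU.  The demo configuration is
32×32×1 with 6 frames.

## Known limitations

* The characteristic-function inversion assumes ψ decays at the chosen
  ξ_max; distributions with near-atoms are refused rather than distorted.
* `variance_Y` treats reconstruction estimates as unbiased; early-stopped
  MLEM bias is measured by the experiments, not folded into the variance.
* The lumpy CF quadrature over lump centers uses voxel midpoints while the
  sampler draws continuous centers; the residual discrepancy is far below
  the asserted KS tolerance at the shipped lump widths (≥ 2 voxels) but
  would grow for sub-voxel lumps.
* Dense eigendecomposition caps (20 000 voxels for covariances, 2500 for
  the diffusion semigroup) bound the exact analytic routes; beyond them,
  use the samplers and empirical CFs.
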