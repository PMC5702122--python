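# Methods

`stokesbd` simulates the transport of drug-delivery nanoparticles through the
interstitial space of a two-dimensional tissue section. The model couples a
static creeping-flow solve (Method of Regularized Stokeslets, MRS) with a
three-tier time-adaptive Brownian dynamics (BD) engine in which cell
boundaries act as sticky walls that capture colliding particles with a
per-contact probability ρ. This note records the model, its assumptions, the
numerical choices, and what the validation suite does and does not
demonstrate.

## Tissue domain and cell packing

The domain is a rectangle of width W (tissue depth, default 1000 μm) and
height H (default 500 μm), origin at the bottom-left corner. The left edge is
a porous capillary wall (the inlet) where particles enter at uniform-random
heights and where fluid is driven in at speed `v_in`; the bottom and top
edges are stationary no-slip walls; the right edge is open and is assumed far
enough away that particles do not reach it within the horizon (violations are
recorded per particle as `exited_right` and reported).

Cells are stationary discs of common radius r = 10 μm packed by random
sequential addition (RSA): uniform center proposals, rejected on overlap or
on protrusion outside the rectangle. The cell count is fixed up front as
n = round(α_cell · W·H / (πr²)) for a target cell-area fraction α_cell
(default 0.40, i.e. porosity 0.60), so the achieved fraction matches the
target up to one-disc quantization (637 cells and 40.02% on the default
domain). A clear margin of one cell radius is kept between the inlet and the
nearest cell surface so the entry edge stays porous; cells may touch the
top/bottom walls tangentially. RSA of discs jams near area fraction 0.55, so
target fractions are restricted to [0, 0.55) and a stall raises an explicit
error naming the achieved fraction.

## Interstitial flow: regularized Stokeslets

Creeping flow past the cells is represented by point forces regularized over
the blob

φ_ε(r) = 2ε⁴ / (π (r² + ε²)³),  ∫_{ℝ²} φ_ε = 1,

with ε = 0.5 μm. The velocity at **x** due to a regularized force **f** at
**x**_k is

**u**(**x**) = −**f**/(8πμ) · (ln(r²+ε²) − 2ε²/(r²+ε²))
             + (**f**·**d**)**d** / (4πμ (r²+ε²)),  **d** = **x**−**x**_k,

finite at the force point itself. All solid boundaries (three edges and every
cell rim) are discretized into N collocation points (default 6,700),
allocated to segments proportionally to their length with largest-remainder
rounding; edge points sit at midpoints of equal subintervals and cell points
are equispaced in angle. Prescribing (v_in, 0) at inlet points and zero
elsewhere yields a dense 2N×2N system solved directly (LU); the relative
residual is checked (≤ 1e−8) and an ill-conditioned system raises with a
condition estimate. Units are μm, s, and centipoise converted to Pa·s through
a single constant; the solved forces only re-enter through the same kernel,
so their absolute unit never matters downstream.

Two properties of this formulation deserve emphasis:

* **Flux, not plug flow.** In a cell-free channel the converged interior
  solution is the developed parabolic profile (centerline ≈ 1.5 v_in), while
  the cross-sectional mean of v_x equals v_in at every depth (mass
  conservation). Validation therefore checks flux conservation and flow
  direction, not pointwise equality with (v_in, 0).
* **Refinement regime.** The first-kind integral equation behind MRS is
  regularized by the discretization itself: refinement is self-convergent
  while the collocation spacing h stays well above ε (the default operating
  point is h ≈ 6ε), but per-point forces grow and interior values drift once
  h approaches ε, especially for dense packings with narrow inter-cell
  channels. The refinement test therefore runs on a single-cell geometry over
  h/ε ≈ 9 → 2.3, where probe velocities converge monotonically; very fine
  discretizations at fixed ε are outside the validated regime.

Because the cells are stationary the field is static; it is precomputed on a
regular grid (default node spacing 0.25 μm, where bilinear interpolation
agrees with exact summation to ~1% of v_in; 0.5 μm was measured marginally
above the 2% default tolerance) and queried in O(1) inside the particle loop.
Exact summation remains available. The field is smooth across cell rims, so
grid nodes inside cells hold the (near-zero) analytic continuation and
interpolation near a rim is well behaved; fluid-side queries through the
public API flag in-cell positions as invalid.

## Particle motion: three-tier adaptive Brownian dynamics

Each particle is an independent circle of radius a (default 100 nm) with
Einstein–Stokes diffusivity D = k_B T/(6πμa) (0.908 μm²/s at 310 K, 2.5 cP).
A BD jump over Δt is **S** = **v**Δt + √(4DΔt)·**e** with **e** a uniformly
random unit vector: the diffusive magnitude is deterministic, only its
direction random, so ⟨|**S**_d|²⟩ = 4DΔt per step and ensembles obey the 2D
MSD law exactly in distribution at multi-step times. The step size adapts to
R, the distance from the particle center to the nearest solid feature
(inlet, walls, cell rims; ties break to the lowest feature index):

1. propose at Δt_max (default 0.1 s); accept iff |**S**| < R − a;
2. otherwise solve |**v**|Δt_a + √(4DΔt_a) = R − a (unique positive root of
   a quadratic in √Δt_a, so the proposal cannot cross the nearest boundary)
   and accept iff the realized |**S**| > 4a;
3. otherwise step at the finest δt (default 1e−3 s), resolving wall
   reflection and cell contact. The clock advances by δt whether the fine
   move is accepted, reflected, or rejected, so elapsed time is well defined.

The tier-2 gate uses the realized |**S**| > 4a comparison literally; at δt
the diffusive jump of a 100 nm particle (≈ 0.06 μm) is smaller than its
radius, fine enough to resolve particle–cell contact.

Contact handling: a fine move ending with the center within r + a of a cell
center is a collision. The first crossing of the contact circle along the
move segment defines the contact point (with a radial-projection fallback for
degenerate geometry). With probability ρ the particle is captured there
(center parked at distance r + a, capturing cell and contact count recorded);
otherwise the penetrating remainder of the displacement is mirrored about the
local tangent — the rim is treated as flat at the contact scale, since
a/r ≈ 0.01 — and the move is rejected outright if the mirrored position is
itself invalid. Contacts at an isolated wall are therefore i.i.d. Bernoulli
trials and the number of contacts before capture is geometric with mean 1/ρ,
which the suite verifies against a closed single-cell box. Domain edges
reflect specularly about lines offset by one particle radius (the particle is
a finite circle); the inlet reflects too, so every injected particle remains
in the tissue — an absorbing capillary wall would be a one-line change in the
kernel but is not the default. A particle whose center passes the open right
edge is retired as `exited_right`.

Reproducibility: the master seed spawns named child streams (packing, entry
sampling, and one stream per particle), so results are independent of
simulation order and of how many particles run. Two engines exist: the
readable pure-Python per-step functions (unit-tested directly, including a
trajectory-level no-interpenetration guard) and numba-compiled whole-
trajectory kernels used for ensembles. They cannot share random streams, so
their equivalence is enforced statistically (matching MSD and capture
statistics), not draw by draw.

### Fixed-step reference engine

For sensitivity comparisons a non-adaptive engine advances particles with a
constant Δt, rejects moves that would overlap a cell interior, and attempts
capture with probability ρ when the particle circle arrives within an
interaction layer (default 0.25 μm) of a rim. Because a fixed step of 0.1 s
jumps ≈ 0.6 μm — past the layer — this engine under-captures and
over-penetrates as Δt grows, which is precisely the artifact the adaptive
scheme removes: the adaptive engine's mean penetration depth moves by ~1%
across Δt_max ∈ [1e−3, 0.1] s while the fixed-step depth rises monotonically
with Δt.

## Closed-form references (cell-free limits)

With neither cells nor flow, the depth coordinate of a particle released at
the inlet is reflected Brownian motion, with density
G(x,t) = (πDt)^{−1/2} exp(−x²/4Dt) on x ≥ 0 — a Gaussian folded at the
origin, peak height twice the free-space value, unit mass on the half line.
With a small uniform drift v the package also provides the translated form
G(x,t) = (πDt)^{−1/2} exp(−(x−vt)²/4Dt). The translated form is an
*approximation*: the exact reflected-drift solution carries a wall correction
whose mean excess over vt is ≈ D/v (≈ 18 μm at v = 0.05 μm/s) and which does
not vanish with time. The validation suite therefore checks the drift case
two ways: the distribution peak sits at vt to within a quarter of the profile
width √(2Dt) (the qualitative claim), and the ensemble mean matches an
independent conservative finite-volume Crank–Nicolson solution of the
reflecting half-line advection–diffusion problem at the 3-standard-error
scale (the quantitative check). The pure-diffusion case is checked by a
Kolmogorov–Smirnov distance ≤ 0.03 against the exact folded Gaussian at
n = 5000.

## Capture-probability response and size effects

With cells present, penetration is controlled by particle–cell interaction
rather than by D. Near a rim the engine takes many δt contacts per encounter,
so the per-encounter capture probability saturates: mean depth decreases
steeply with ρ below 0.1 and plateaus for ρ ∈ [0.1, 1] (the suite checks
non-increasing depth over ρ ∈ {0.001, 0.01, 0.1, 1} and a < 5% difference
between ρ = 0.1 and 1, using common random numbers across ρ so the paired
comparison is not noise-dominated).

Size effects depend on the transport regime. Under pure diffusion with cells
(ρ = 0.01), 10 nm and 100 nm particles pile up at the first cell row — modes
within one 10 μm bin — while the 10 nm distribution carries more mass in the
deep right tail. Under advection (solved MRS field, v_in = 1 μm/s) the modes
align exactly but the tail ordering reverses in this implementation: high-D
particles migrate off streamlines into cell contact sooner (diffusional
deposition, as in classical filtration theory), while low-D particles ride
the inter-cell channels deeper. The size-effect test asserts the
diffusion-regime behavior; the advection-regime reversal is noted here as a
model property worth bearing in mind when comparing against fluorescence
profiles.

## Scaled-down validation sizes

The production configuration (16,000 particles, 1e4 s horizon, N = 6,700
collocation points) is the package default. The validation suite runs the
same code at reduced sizes chosen for ensemble standard errors comfortably
inside each tolerance: 2,000–5,000 particles and 100–5,000 s horizons for
cell-free checks; a 400×200 μm tissue (~102 cells) with 2,000–3,000 particles
and 100–1,000 s horizons for capture and step-size checks; N = 1,000
collocation points for boundary-condition recovery. These choices are stated
in the tests themselves; standard errors are quoted alongside every ensemble
mean.

## What the synthetic geometry does and does not emulate

The generator reproduces the stated tissue statistics — monodisperse 10 μm
discs at 40% area, porous inlet, no-slip walls — but real tissue has
polydisperse, deformable, non-circular cells, three-dimensional pore
connectivity, heterogeneous interstitial viscosity, and reversible particle
binding; none of these are modeled (ρ lumps all adhesion/uptake biophysics
into one number, with no dissociation). Passing tests therefore demonstrate
the correctness and internal consistency of the transport algorithm under
the stated idealization, not quantitative agreement with any particular
tissue. Particle–particle interactions are neglected on dosing grounds: with
~1% of an intravenous dose reaching tissue, 1 ml at 1e8 particles/ml delivers
~1e6 particles, a volume fraction of order 1e−9 in 1 cm³ — far too dilute
for crowding.

## Known limitations

* 2D only; the Stokeslet kernel, packing and capture geometry are planar.
* The MRS system is dense; N is practically limited to ~10⁴ on one CPU, and
  refinement at fixed ε is only meaningful while h ≫ ε (above).
* The velocity cache interpolates across rims from the smooth continuation;
  particles advected within ~one node spacing of a rim see an O(1%) velocity
  error, which is negligible against the no-slip decay of the field there.
* Tier-3 time always advances by δt, so a particle trapped in a dead-end pore
  costs real simulation time; there is no first-passage shortcut.
* The fixed-step engine exists to demonstrate step-size sensitivity, not as a
  production integrator.
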