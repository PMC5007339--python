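# Methods

This note documents the models, conventions, parameter choices and
numerical decisions behind `actogel`, and what the synthetic-data tests do
and do not establish about real data.

## Conventions and units

Lengths in µm, times in s, velocities in µm/s, forces in pN (agent-based
model), stresses in units of the gel modulus (continuum model). Two
package-wide sign conventions, chosen to match how contraction data are
usually plotted and stated prominently because most libraries default to
the opposite:

- the radial velocity `v_r` is **inward-positive** (positive toward the
  activation center);
- strain is **contraction-positive**: ε(t) = −⟨∇·u⟩ over the activation
  disc, with u the cumulative time integral of the velocity field.

Because the time integral, the divergence stencil and the disc average
are all linear and commute on a uniform grid, ε(t) equals the integral of
the mean divergence of velocity to round-off; `strain_timecourse`
asserts this internally on every call.

## Field analysis

Derivatives are second-order central differences (one-sided at grid
edges); no smoothing is applied by default. Missing PIV vectors are
flagged and infilled by the iterated median of valid 3×3 neighbours
before any differentiation, and the per-frame gap fraction is retained so
heavily gapped frames can be audited. At nodes within half a grid
spacing of the activation center the radial/tangential decomposition is
undefined and both components are set to zero.

Phase boundaries default to t₁ = 100 s and t₂ = 300 s. The lag phase is
excluded from rate estimates because its flow carries a substantial
tangential component; the per-frame tangential fraction
⟨|v_t|⟩/(⟨|v_r|⟩+⟨|v_t|⟩) is attached to every strain timecourse so the
exclusion is auditable, and the same quantity (threshold 0.25) gates the
stress inversion's radial-symmetry assumption.

## Stress inversion

With overdamped dynamics, substrate friction ζ and radial symmetry, the
force balance ζ v_out = dσ/dr integrates directly under the closure
σ_rr ≈ σ_θθ, giving σ(r) = ζ ∫_r^R v_r dr′ with σ(R) = 0. The closure is
the minimal assumption that lets the 1-D balance close from the radial
velocity alone — the full anisotropic inversion is under-determined from
v_r — and on gel-model flows it reproduces the expected center-peaked,
outward-decaying stress. The geometric (σ_rr − σ_θθ)/r term it drops is
exactly zero for an isotropic in-plane stress and modest for the flows
the gate admits; profiles near the activation boundary should still be
read as approximate. ζ defaults to 1 (friction-normalized stress units).

## Hill fit

The transition ε_max(ρ) = ε_sat / (1 + (ρ_half/ρ)^n) is fit by bounded
nonlinear least squares restarted from exponents {1, 2, 5, 10, 20}
(steep Hill fits are multimodal in (ρ_half, n)), with n ∈ [0.5, 30],
ε_sat ∈ (0, 10], ρ_half within the data range ± 50%; standard errors come
from the Jacobian at the optimum. Degenerate inputs (flat response, or a
fitted ρ_half outside the sampled range) set `converged=False` with a
message instead of returning a silently bad fit. ρ_half is identified
with the critical density ρ_c: at n ≈ 11 the curve is steep enough that
the half-saturation point and any reasonable "onset" definition coincide
within the sampling resolution.

## Active gel model

An overdamped, substrate-coupled Kelvin–Voigt solid in radial symmetry:

    ζ ∂u/∂t = ∂σ_rr/∂r + (σ_rr − σ_θθ)/r
    σ_rr = Ē (u′ + ν u/r) + η ∂t u′  + σ_a(r,t)
    σ_θθ = Ē (u/r + ν u′) + η ∂t(u/r) + σ_a(r,t)

with Ē = E/(1−ν²) (plane stress; a plane-strain variant applies the
standard E → E/(1−ν²), ν → ν/(1−ν) substitution) and isotropic active
tension σ_a = σ₀ (1 − e^(−t/τ_a)) for r ≤ ξ. Because σ_a is isotropic
the right side collapses to (Ē + η ∂t) L[u] + ∂σ_a/∂r with
L[u] = u″ + u′/r − u/r², discretized by central differences and stepped
with Crank–Nicolson; the viscous flux coupling makes each step a
tridiagonal solve. The outer edge is clamped at R = 10 ξ by default
(quiescent far field); a stress-free edge is provided and agrees with the
clamped case on ε_max to within ~1.4% at the default domain.

The t → ∞ limit has the closed form u = A r inside, u = B r + C/r
outside, with A, B, C fixed by continuity of u and total σ_rr at ξ and
the outer condition; it is exposed as `steady_state` and is the solver's
oracle (relative L2 error 0.07% at N = 800, halving under refinement).
Across the interface the total hoop stress jumps by −(1−ν) σ₀.
Note u has a kink at ξ, so pointwise quantities at the interface (hence
ε_max) converge first order even though the scheme is second order in
smooth regions.

Defaults: E = σ₀ = 1 (the balanced regime E/σ_a ≈ 1 in which the model
reproduces the observed dynamics), ν = 0.5, η = 10 Pa·s, ζ = 0.01
Pa·s/µm², τ_a = 120 s, ξ = 10 µm, T = 600 s, Δt = 1 s, N = 800. The
friction is chosen weak enough that the frictional relaxation time
ζ ξ²/Ē stays below τ_a even at ξ = 40 µm — equivalently, the screening
length exceeds the largest activation zone — because boundary velocity
observed to scale with size up to tens of µm implies exactly that regime;
τ_a is set so the stress ramp spans the 100–300 s linear phase and the
strain plateaus within 600 s. With these defaults the sweep over
ξ ∈ {5, 10, 20, 40} µm gives a near-linear v_max(ξ) (R² ≈ 0.997) whose
slope drops when E/σ₀ doubles, while ε_max (CV < 1%) and strain rate
(CV ≈ 2%) are nearly size-invariant. One subtlety: the *maximum* strain
rate decreases nominally with ξ (lag smearing), whereas the OLS slope on
the fixed 100–300 s window ticks up by ~3% because a more-lagged curve is
"younger" inside a fixed late window; the sweep table reports both.

## Agent-based model

Filaments are bead-spring chains of 280 nm segments with fixed polarity
(bead order pointed → barbed) and linearized worm-like-chain bending of
rigidity κ = l_p k_BT. Motors are four-bead backbones (3 × 42 nm,
stiffly straightened) with two arms per joint (eight per motor). Arms
bind to sites every 7 nm on filaments within a 20 nm capture radius at
k_on = 40 s⁻¹, walk toward the barbed end with v(F) = v₀ max(0, 1−F/F_s)
(v₀ = 140 nm/s, F_s = 4 pN), **dwell at the barbed end** when they reach
it, and unbind with load-dependent kinetics: inside the activation disc a
catch bond k(F) = k₀ e^(−F/F₀) (k₀ = 0.35 s⁻¹, F₀ = 4 pN) with a slip
cutoff (forced release above 10 pN ≈ 2.5 F_s); outside the disc a
constant fast rate k_off = 20 s⁻¹ **and no stepping**, representing
ATPase-inhibited myosin that decorates but cannot contract the network.
All connectivity is motor-mediated; there are no passive crosslinkers and
no excluded volume (quasi-2D crowded film; the dominant couplings are
motor crosslinks). Thermal noise is off (motor forces dominate).

End dwelling deserves emphasis: without it, walking motors polarity-sort
to barbed ends and detach, which biases the network *extensile* (the
interior of the activation disc measurably expands); end-dwelling motors
act as polar crosslinks and tip the system to net contraction, the
behaviour the disordered-network experiments show. The outside-the-disc
stepping ban matters equally: motors that keep walking outside contract
the whole box and destroy the activation contrast.

Motor count: `r_m` is a myosin:actin molecular ratio; with ~104 monomers
per 280 nm segment and 64 myosins per thick filament (each of the eight
arms standing in for a small head ensemble), thick filaments per actin
segment = r_m·104/64. At the reduced scale (20 µm box, actin length
density 2.5 µm⁻¹) r_m = 0.04 gives ≈ 230 motors. At substantially higher
force densities both stiff and floppy networks collapse collectively and
the persistence-length effect washes out; at this density the floppy
(l_p = 20 µm) network contracts markedly faster than the stiff
(l_p = 2.6 mm) one, as buckling-mediated contraction predicts.

**Integration.** Overdamped, athermal, Δt = 0.5 ms, bead drag
γ = 0.2 pN·s/µm, IMEX: the stiff linear operators of every chain — the
zero-rest-length part of the extensional springs (β D₁ᵀD₁,
β = Δt k_seg/γ) and the linearized curvature (α D₂ᵀD₂,
α = Δt κ/(γ l₀³)) — are inverted implicitly via per-chain banded Cholesky
factors computed once at build time; only the bounded nonlinear spring
remainder is explicit. This is what keeps l_p = 2.6 mm stable at the
same Δt as l_p = 20 µm. Point springs (motor linkers k = 30 pN/µm,
rim pinning k = 50 pN/µm) are integrated with a per-bead backward-Euler
diagonal drag γ_i = γ + Δt Σk, recomputed whenever binding changes, so
arbitrarily many arms crowding one bead cannot destabilize the step.
Rare fast local events (a segment folding under strong motor load) are
caught by a step-displacement trigger and the 10 ms block is redone at
Δt/5 with matching implicit factors; a move exceeding one segment length
even then aborts with a diagnostic. Extensional stiffness is softened to
k_seg = 100 pN/µm; under typical (≤ 4 pN) loads segment strain stays
≤ 4%. Kinetics (binding via a cell-list neighbour search, stepping,
unbinding) run every 10 ms with random numbers drawn from a single seeded
generator, so trajectories are bit-reproducible given (parameters, seed).

**Boundary condition.** Beads initially within 1 µm of the box edge are
pinned to their initial positions by stiff springs (soft anchoring rather
than hard immobilization, so the implicit chain factors never need
rebuilding); this mimics the quiescent surrounding network.

**Measurements.** Strain uses the field-pipeline convention: filament
bead displacements since t = 0 are binned onto a 1 µm grid by initial
position, empty cells median-infilled, and ε(t) = −⟨∇·u⟩ over the disc.
The boundary velocity is the mean inward radial speed of unpinned
filament beads in a ±1 µm annulus about ξ, re-selected per interval.
For the activation-size comparison over radii {3, 6, 9} µm three
adjustments keep the measurement about the network rather than the
setup: the box is widened to 24 µm (the smallest in which the 9 µm
disc's annulus stays clear of the pinned rim — in a 20 µm box it
overlaps the anchoring); the motor density is raised above the
cooperative onset for all sizes (size scaling is a property of
supercritical contraction, and a 3 µm disc at the comparison density
used elsewhere is subcritical); and the boundary-velocity mean excludes
the first ~25 s, for the same reason the strain-rate analysis excludes
the lag phase — the early flow reflects motor sorting and loading, not
contraction.

## Synthetic data

The PIV generator emulates the acquisition the analysis assumes: frames
every 10 s, grid pitch 1 µm, i.i.d. Gaussian component noise
(default sd 0.005 µm/s, a few percent of peak gel speeds), and 5% of
vectors dropped then median-infilled so the gap logic is exercised by
default. The Hill-dataset generator uses half-saturation 0.56 µm⁻² and
exponent 11 with saturation strain 1.4 (a choice consistent with strongly
contracting networks exceeding ε = 1; the true saturation strain is not
separately constrained) and multiplicative lognormal noise, because
strains span an order of magnitude across the transition and additive
noise would distort the low-density branch. Filament lengths are
truncated-exponential on [0.56, 25] µm with the scale solved numerically
so the *truncated* mean is 7.1 µm.

What passing tests show — and don't. The generators produce radially
organized, noise- and gap-corrupted fields with the stated statistics;
they do not emulate PIV's spatially correlated errors, interrogation-
window smoothing, aggregation-stage flows after the plateau, or
non-circular activation geometries. Recovery results on synthetic data
therefore validate the pipeline's correctness and calibration, not its
robustness to every artifact of real microscopy.

## Problem sizes

Default test and acceptance runs use the reduced agent-based scale
(20–24 µm box, 100 s, ≈ 5–7 × 10³ beads) and gel grids of N = 400–1600;
these sizes resolve every phenomenon tested while keeping the full suite
in the tens of minutes. The full-scale geometry (40 µm box, 400 s) is
available via `ABMParams()` but is an order of magnitude slower.

## Known limitations

- The stress inversion's isotropy closure ignores shear and geometric
  terms; it is qualitative near the activation boundary.
- The gel model is linear: ε scales exactly with σ₀/E and cannot capture
  strain-stiffening, density-dependent moduli, or the aggregation stage.
- The ABM omits excluded volume, actin turnover, explicit crosslinkers
  and 3-D effects; its kinetic constants are standard modelling values,
  not measurements of this system; the end-dwell and slip-cutoff rules
  are explicit mechanistic stand-ins where single-molecule detail is
  unavailable.
- ε_max from the gel solver converges first-order in grid spacing due to
  the displacement kink at the activation interface.
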