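# actogel

Analysis pipeline and model suite for **light-activated contraction of
disordered actomyosin networks** — quasi-2D actin/myosin-II films in which
motor activity is switched on inside a circular region and the network's
contractile response is read out from microscopy-derived flow fields.

It is written for biophysicists studying cytoskeletal active matter who
need to turn PIV velocity fields into contraction metrics, compare them
with continuum and agent-based models, and quantify the cooperativity of
the contractile transition.

## What it computes

**Analysis chain** (`actogel.fields`, `.contraction`, `.stress`): from a
time series of 2-D velocity fields *v*(x, y, t) on a regular grid,

- strain rate = ∇·*v*; network strain ε(t) = −⟨∇·*u*⟩ over the activation
  disc, where *u* is the time-integrated displacement field
  (contraction-positive; strains can exceed 1 as material flows into the
  disc);
- phase segmentation of ε(t) into a lag phase P1 (0–100 s), a linear phase
  P2 (100–300 s) whose OLS slope is the strain rate dε/dt, and a plateau
  P3 (> 300 s) whose mean is the maximum strain ε_max;
- boundary velocity: mean inward radial velocity in a 2.65 µm annulus
  about the activation radius ξ (inward-positive throughout);
- radial stress from overdamped force balance with substrate friction ζ:
  σ(r) = ζ ∫_r^R v_r dr′, valid once tangential flows are suppressed
  (an applicability gate checks this frame by frame).

**Cooperativity** (`actogel.cooperativity`): the switch-like dependence of
ε_max on myosin thick-filament density ρ is fit with the Hill equation

    ε_max(ρ) = ε_sat / (1 + (ρ_c / ρ)^n_H)

by bounded multi-start nonlinear least squares; n_H quantifies
cooperativity and ρ_c is the critical density.

**Active-gel model** (`actogel.gel`): axisymmetric overdamped Kelvin–Voigt
solid with isotropic contractile active stress
σ_a = σ₀(1 − e^(−t/τ_a)) inside a disc of radius ξ, friction-coupled to
the substrate; Crank–Nicolson tridiagonal solver with a closed-form
disc-inclusion steady state as its oracle. Reproduces telescopic
contractility: boundary velocity grows nearly linearly with ξ while ε_max
and strain rate stay nearly constant.

**Agent-based model** (`actogel.abm`): bead-spring semiflexible filaments
(280 nm segments, worm-like-chain bending with persistence length l_p)
plus bipolar motor thick filaments (3 × 42 nm backbone, eight arms)
with binding, linear force–velocity stepping toward barbed ends,
end-dwelling, and catch-like load-dependent unbinding gated by the
activation disc. Numba-accelerated IMEX integration keeps l_p up to
millimetres stable.

**Synthetic data** (`actogel.synthetic`): seeded generators for PIV-like
series (noise + dropped vectors), Hill-transition datasets, and disordered
filament sets (truncated-exponential lengths, uniform orientations) with
the apolar nematic order parameter q.

## Worked example

```python
import numpy as np
from actogel import (GelParameters, solve_gel, SynthConfig, gen_piv_series,
                     ActivationRegion, strain_timecourse, strain_rate,
                     max_strain, gen_hill_dataset, fit_hill)

# continuum model -> synthetic acquisition -> analysis
p = GelParameters()                       # E/sigma0 = 1, xi = 10 um
sol = solve_gel(p)
series = gen_piv_series(SynthConfig(scenario="gel-derived", seed=7), sol)
tc = strain_timecourse(series, ActivationRegion((0.0, 0.0), p.xi))
print(f"strain rate {strain_rate(tc):.5f} 1/s, eps_max {max_strain(tc):.3f}")

# cooperativity of the contractile transition
df = gen_hill_dataset(n=50, noise=0.05, seed=7)
fit = fit_hill(df.rho_per_um2.values, df.epsilon_max.values)
print(f"n_H = {fit.n:.1f}, rho_c = {fit.rho_half:.3f} um^-2")
```

Output:

```
strain rate 0.00131 1/s, eps_max 0.683
n_H = 11.8, rho_c = 0.557 um^-2
```

The first line is the linear-phase contraction rate and the plateau strain
recovered from a noisy synthetic acquisition of the gel model's flow (the
solver's own plateau is 0.714; the acquisition adds noise and 5% dropped
vectors). The second line shows the Hill refit recovering the generating
cooperativity (exponent 11, half-saturation 0.56 µm⁻²) from 50 noisy
points.

A CLI mirrors these flows: `actogel synth | simulate-gel | simulate-abm |
analyze | fit-hill | sweep | compare | report` (see `actogel --help`).

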