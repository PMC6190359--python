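# Methods

## Physical model

### Small-particle radiation force

A bio-particle suspended in a standing ultrasound field experiences a
time-averaged radiation force from the scattering of the incident wave at
its boundary.  When the particle is much smaller than the wavelength it
acts as a weak point scatterer and the force derives from the radiation
potential

    U_rad = V_BP ( f1 · β_f/2 · ⟨p_in²⟩ − f2 · 3ρ_f0/4 · ⟨v_in²⟩ ),
    F_s   = −∇U_rad,

with the ideal-fluid monopole and dipole scattering coefficients

    f1 = 1 − β_p/β_f,        f2 = 2(ρ_p0 − ρ_f0) / (2ρ_p0 + ρ_f0).

The ideal-fluid coefficients are appropriate at high actuation frequency:
the viscous and thermal boundary layers scale as f^(−1/2) (δ_v = √(2ν/ω),
δ_t = √(2D_th/ω), the standard penetration-depth forms) and at tens of MHz
are tens of nanometres, far below a micron-scale cell radius.
`materials.validity_summary` reports these diagnostics so a user can check
the regime for their own parameters.  Viscous/thermoviscous coefficient
corrections are deliberately out of scope; the `ScatteringCoefficients`
container stores possibly-complex values and exposes `real_f1`/`real_f2`
so such extensions would not change the API.

### Finite-size correction

When the diameter D_p approaches the wavelength, different volume elements
of the particle sit at different phases of the standing field; their
point-scatterer forces partially cancel and the net force falls below the
small-particle prediction.  Because bio-particles are nearly
impedance-matched to water (Z_p/Z_f ≈ 1.12 for the reference cell), the
field transmitted into the particle is close to the incident field, and
the force is well approximated by averaging F_s over the particle volume:

    F = (1/V_BP) ∫_V F_s dv.

For a one-directional wave p = p_ac·cos(ky) the small-particle force is
the closed form F_1D^s = 4πΦa³kE_ac·sin(2kh), with contrast factor
Φ = f1/3 + f2/2, energy density E_ac = β_f·p_ac²/4, and h the signed axial
offset from the particle centre to the nearest pressure node.  The volume
average then has the exact closed form

    F_1D = F_1D^s · f_m(χ),
    f_m(χ) = 3[sin(2χ) − 2χ·cos(2χ)] / (2χ)³,     χ = ka.

f_m decreases from 1 and first crosses zero where tan x = x (x = 2χ) on
(π, 3π/2), i.e. at D_p/λ = 0.7151: a particle of that size feels no net 1D
radiation force at all.  For the 10 µm reference cell in a 60 µm field,
f_m = 0.8945.

In multidirectional fields no constant factor relates F to F_s (the ratio
map has a coefficient of variation of ~0.5 for D_p/λ = 0.4), so the volume
average must be computed by quadrature.

### Sign conventions

Each standing-wave component is p_j·cos(k·r·e_j − φ_j), with the origin at
a pressure antinode (φ = 0) and all components sharing a single cos(ωt)
temporal factor (mutually in phase).  A per-component temporal phase of
zero is assumed for the perpendicular two-wave lattice, which produces the
checkerboard node/antinode pattern.  The first-order velocity follows
from the linearised momentum balance, giving the closed-form time
averages ⟨p²⟩ = A²/2 and ⟨v²⟩ = |∇A|²/(2ρ²ω²) used throughout — no
numerical time averaging is done in the force path (a trapezoid average
over one period is kept in the test suite as an oracle).

`closed_form_1d(h, …)` defines h as the signed offset **from the particle
to the nearest node**: with that reading the returned value is exactly the
axial component of −∇U_rad, and positive contrast pushes toward the node.
The alternative reading (offset from node to particle) flips the sign and
contradicts the gradient of the potential.

## Numerical choices

* **Volume-average quadrature.** Gauss–Legendre product rule in spherical
  coordinates (radial × polar Gauss nodes, equispaced azimuthal nodes,
  which are spectrally accurate on the periodic angle).  Orders 8, 12, 18,
  27, 40 are tried in turn until two successive refinements agree to a
  relative 10⁻⁶ in max norm; exceeding the budget raises a diagnostic
  error.  Convergence is measured relative to the larger of the result and
  the volume-mean force magnitude, so that near symmetry points (where the
  average vanishes but the integrand does not) the criterion remains
  meaningful.
* **2D maps.** For fields invariant along the out-of-plane direction the
  sphere average reduces to a disk integral with the chord weight
  2√(a² − r²).  The substitution r = a·sin ψ removes the square-root
  endpoint singularity; without it Gauss–Legendre converges only
  algebraically and misses the 10⁻⁶ target.  Both routes are implemented
  and agree to ~10⁻¹³ relative in tests.
* **Modifying factor.** Below χ = 10⁻³ the Taylor series
  1 − (2χ)²/10 + (2χ)⁴/280 replaces the exact expression to avoid
  catastrophic cancellation in sin(2χ) − 2χ·cos(2χ).
* **Zero crossing.** Brent root find of f_m on the bracket χ ∈ [2.0, 2.3]
  (the first sign change), xtol 10⁻¹⁴.
* **Tracing.** Quasi-static force balance dr/dt = u_flow + F/(6πμa),
  integrated with adaptive RK45 (rtol 10⁻⁸, atol 10⁻⁶λ by default).  A
  fixed-step classical RK4 mode (`fixed_dt`) produces bit-reproducible
  trajectories for regression pinning.  In a single-component field the
  finite-size force closure uses the exact f_m scaling; multi-component
  fields evaluate the quadrature at every step.  An optional inertial mode
  was considered and dropped: at the simulated scales the Stokes number is
  ~10⁻⁶ and the quasi-static limit is exact to far better than integrator
  tolerance.
* **Equilibria.** Seeded overdamped relaxation (the same quasi-static
  dynamics without flow), accepting points whose residual force is below
  10⁻⁸ of the trap stiffness scale and whose force Jacobian (central
  differences, step 10⁻⁴λ) has eigenvalues with negative real parts;
  duplicates within 10⁻³λ are merged.

## Material data

The built-in registry stores the reference property table verbatim: water
at 25 °C and an NIH/3T3 fibroblast (ρ_p0 = 1079 kg·m⁻³,
β_p = 3.78×10⁻¹⁰ Pa⁻¹, G = 1.67 kPa, default radius 5 µm).  Derived
quantities follow the table's own defining formulas: β = 1/(ρc²), Poisson
ratio υ = (3κ − 2G)/(2(3κ + G)) with κ = 1/β, longitudinal speed
c = √([3(1 − υ)/(1 + υ)]/(ρβ)), shear speed c_s = √(G/ρ).

Two notes on that table:

* The printed transverse wave speed is 1.244×10³ m/s, but √(G/ρ0) with the
  printed G = 1.67×10³ Pa gives 1.244 m/s.  The significand matches and
  the exponent cannot: kPa-scale shear moduli give m/s-scale shear speeds.
  The formula is authoritative in this package; the printed cell is kept
  verbatim in the registry constant for reference.
* The tabulated β_f = 4.433×10⁻¹⁰ Pa⁻¹ is 1/(ρc²) rounded to four
  significant figures.  Identities that hold only when β = 1/(ρc²) exactly
  (the E_ac factorisation of the 1D force, equipartition) are therefore
  exact with a derived-β fluid and agree to ~10⁻⁴ relative with the
  tabulated one; the strict-tolerance tests use the derived-β variant.

The registry also carries order-of-magnitude density/speed presets for
cells, liposomes, microvesicles and viruses, labelled approximate; they
exist to illustrate that common bio-particles stay impedance-matched to
water within ~25%, not to be authoritative inputs.

## Scenario defaults

The pinned scenarios use the study conditions throughout: λ = 60 µm,
p_ac = 200 kPa (E_ac = 4.433 J·m⁻³), water host, NIH/3T3 particle,
particle released λ/8 from a node for force curves.

The separation scenario is under-specified in its source (the axial
distance is explicitly not to scale and the inflow speed is not stated),
so it is pinned constructively: a 240 µm wide channel (4λ) with plug flow
at 0.8 mm/s, a 20 µm centre-outlet band at mid-channel, and three release
positions 112, 118 and 127 µm straddling the band.  The channel length
(12.528 µm) is set from a transit time 5% above the slowest
small-particle capture.  Because the finite-size force is exactly
f_m = 0.894 times the small-particle force in a 1D field, every capture
takes 1/f_m = 1.118 times longer under the finite-size model, so the
slowest particle (released at 118 µm) misses the sheath stream and
changes outlet class — the qualitative outcome the scenario exists to
show.  The outlet change is robust to integrator tolerances (the margins
are 5% and 6% against a 10⁻⁴λ tolerance sensitivity) but the geometry is
a constructed fixture, not a reproduction of a specific published device.

## What the scenarios do and do not show

Everything here is closed-form or quadrature physics on idealised fields:
perfect standing plane waves, no attenuation, no acoustic streaming, no
walls or boundary scattering, no particle–particle (secondary Bjerknes)
forces, independent point particles in the tracer.  Passing tests show the
implementation is internally consistent and matches the analytic
finite-size theory; they do not validate the impedance-matching
approximation against a coupled acoustic–solid simulation or experiment,
which is outside this package's scope (the difference metric
Ɗ = Σ|F − F_ref| / Σ|F_ref| is provided as a generic curve comparison for
users who have such a reference; its default sampling grid is 20 uniform
points on D_p/λ ∈ (0.05, 1.0], a choice the user can override since no
canonical grid exists).

## Known limitations

* Ideal-fluid scattering coefficients only; no thermoviscous corrections,
  so results at low frequency (boundary layers comparable to the particle
  radius) are outside the validity envelope — check
  `validity_summary` diagnostics.
* The finite-size average assumes the internal field equals the incident
  field; for particles far from impedance-matched (dense minerals, gas
  bubbles) the model degrades, and the negative-contrast examples in the
  tests exercise the sign structure only.
* Channel flow is unidirectional plug or plane-Poiseuille; no 3D flow
  profiles, lift forces or wall interactions.
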