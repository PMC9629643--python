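# Methods

## Physical model and assumptions

The package computes the steady-state oxygen partial-pressure field
φ(r, z) [mmHg] in one cylindrical well of a multi-well plate containing
culture media of depth H and a disc of liver tissue (a precision-cut liver
slice) of radius r_T and thickness h₂ − h₁, suspended with its base at
height h₁ above the well floor.  The model is axisymmetric.  Governing
equations:

* media: ∇²φ = 0 (pure diffusion, diffusivity D₁);
* tissue: D₂∇²φ − Vφ = 0 (diffusion with first-order consumption at rate
  V [1/s], diffusivity D₂).

Boundary conditions: Dirichlet φ = φ₀ at the media surface z = H (the
incubator clamps the surface value), zero normal flux at the well wall
r = r_o and floor z = 0, symmetry at the axis.  At every tissue–media
interface both φ and the diffusive normal flux D ∂φ/∂n are continuous.

Assumptions worth stating explicitly:

* **Linear uptake.**  Consumption is proportional to local φ.  Liver
  tissue kinetics are closer to Michaelis–Menten; the linear law
  overstates uptake at high φ and understates it near anoxia.  It makes
  the whole problem linear in φ₀, which the implementation exploits and
  tests (doubling the surface pressure exactly doubles the field).
* **Steady state.**  No transients; results describe the long-time
  equilibrium of a static, unstirred well.  No rocking/agitation, and any
  support insert is assumed not to impede diffusion.
* **Concentration as partial pressure.**  φ carries mmHg throughout; no
  Henry's-law solubility conversion is applied anywhere, and the surface
  value is the incubator partial pressure directly.

## Default parameters

| quantity | symbol | default | units |
|---|---|---|---|
| media diffusivity | D₁ | 4.85e-9 | m²/s |
| tissue diffusivity | D₂ | 1.6e-9 | m²/s |
| uptake rate | V | 0.057 | 1/s |
| absorption wavenumber | k = √(V/D₂) | 5968.7 | 1/m |
| well radius (12-well plate) | r_o | 11.05 | mm |
| media depth (1.3 ml) | H | 3.4 | mm |
| slice thickness | h₂ − h₁ | 250 | µm |
| slice radius | r_T | 2.5 or 4.0 | mm |
| surface oxygen at 21% | φ₀ | 160 | mmHg |

Surface oxygen for other incubator fractions f scales linearly:
φ₀ = 160·f/0.21.  The three named placements are "bottom" (h₁ = 0),
"middle" (slice centred at H/2) and "top" (slice top face 1 µm below the
media surface).  The media depth can be given directly or derived from a
volume, H = volume/(π r_o²); 1.3 ml in the 22.1 mm-diameter well gives
H ≈ 3.39 mm, and the default preset uses the rounded 3.4 mm with the
volume-derived option available.

## Solution method

### Baseline column profile

With the radial dependence suppressed, the layered fluid–tissue–fluid
column has the closed-form profile U(z): constant D₁φ₀/θ below the slice,
(D₁φ₀/θ)·cosh(k(z−h₁)) inside it, linear in the media above, with
θ = D₁cosh(kΔ) + D₂k(H−h₂)sinh(kΔ), Δ = h₂−h₁.  U satisfies every vertical
boundary and interface condition and is the exact solution whenever the
slice spans the whole well cross-section (r_T = r_o) or V = 0 — both
degeneracies the solver short-circuits.

### Inner eigensystem

The correction φ − U in the cylinder r < r_T separates into radial factors
I₀(λr) and vertical modes Z(z) solving Z'' + λ²Z = 0 in the fluid bands and
Z'' + (λ²−k²)Z = 0 in the tissue, with Z'(0) = 0, Z(H) = 0, value
continuity and D-weighted flux continuity (D₁Z' = D₂Z') at h₁ and h₂.
Written as (DZ')' + (λ²D − V·1_tissue)Z = 0 this is self-adjoint with
weight D(z): eigenvalues are real, positive and simple, and modes are
orthogonal under D — asserted in the tests but deliberately *not* used in
the matching projection, which is unweighted (see below).

Eigenvalues are roots of a single **pole-free dispersion function** built
directly from the interface determinant at h₂, using the analytic pair
C(x; s), S(x; s) (cos/cosh and sin/sinh normalised so the pair is jointly
analytic in s = λ²−k²).  One expression therefore covers both the trapped
branch (λ < k, hyperbolic in the tissue) and the free branch (λ > k);
multiplying the textbook tangent-form relations through by their cosine
denominators gives the same roots without tangent poles.  Root finding is
a dense uniform scan (2000 samples per asymptotic spacing π/H) with
sign-change bracketing and Brent polishing near machine precision; the
window is sized by a WKB mode count and widened geometrically if needed.
For the default parameters there are 6 trapped modes
(k·(H−Δ)/π ≈ 6), verified against an independent 10⁵-sample scan.

The closure coefficient of the top fluid piece (ρ) is computed from
whichever of the two equivalent interface conditions has the
better-conditioned denominator — important for the "top" placement, where
sin(λ(h₂−H)) is O(λ·1 µm).

### Outer annulus and matching

The annulus modes are cos(ωₙz), ωₙ = (n−½)π/H, with radial factor
fₙ(r) = K₀'(ωₙr_o)I₀(ωₙr) − I₀'(ωₙr_o)K₀(ωₙr), which has zero slope at the
wall.  Value and flux continuity at r = r_T are projected (unweighted) onto
the inner modes Z_m.  The flux condition is D-weighted only across the
tissue band; dividing that band's equation by D₁ before summing the
band-wise projections yields the system

    T α − R A = g,   S A = W α

with R_mn = fₙ(r_T)·O_mn, S_mn = fₙ'(r_T)·O_mn (O the inner–outer overlap
integrals), T carrying the unweighted inner Gram, W the Gram with a D₂/D₁
weight on the tissue band times λⱼI₀'(λⱼr_T), and
g_m = ∫(φ₀−U)Z_m dz.  Both elimination routes,
α = (T − RS⁻¹W)⁻¹g and A = (TW⁻¹S − R)⁻¹g, are computed via LU solves and
compared (they agree to ~1e-15 relative); residuals of both matching
equations are reported on every solve.

Numerical safeguards:

* **Scaled Bessel basis.**  Every radial factor is evaluated with
  exponentially scaled I/K functions, with the exponents combined
  analytically so only ratios bounded on the domain appear.  The stored
  coefficients are rescaled (α̂_m = α_m I₀(λ_m r_T), Â_n = A_n·I₁(ωₙr_o)K₀(ωₙr_T));
  conversion helpers recover the literal values.  This keeps M = 40 and
  beyond fully usable (ωₙr_o ≈ 400 would overflow naive I₀).
* **Quadrature.**  Overlap, Gram and load integrals are evaluated by
  piecewise Gauss–Legendre panels with breakpoints at h₁ and h₂ and node
  counts proportional to the integrand's total phase (error at machine
  level); an independent adaptive-quadrature path (scipy `quad` with the
  same breakpoints) is kept for cross-checks and agrees to 1e-10.
* **Conditioning.**  The reduced matrix's condition number is monitored; a
  numerically singular system raises an error advising a lower M.

### Truncation

The default working truncation is M = 7 with a single common order for
both regions (a square matching system); M = 40 is used where converged
values are wanted, and a `converge` utility reports field changes between
successive orders.  Convergence is strongly non-uniform in space: on the
centre line and anywhere with r ≲ 0.8 r_T the field changes by under 0.3%
of φ₀ between M = 7 and M = 40, while the slice rim carries a
boundary-layer error (the slice corner makes the exact field weakly
singular) of order 10% of φ₀ at M = 7, shrinking to ~0.3% at M = 40.
Consequences adopted here: interior quantities (placement search, centre
profiles, depth/volume sweeps) are reliable at M = 7, but rim-sensitive
quantities — the mid-plane maximum, which sits at the rim — are reported
at M = 40.  The rim concentration jump between the inner and outer
representations decreases monotonically with M (6.1 → 0.10 mmHg RMS over
M = 5…40 for the reference scenario) and is 0.34% of φ₀ at M = 40.

### Which extremum the placement analysis tracks

The physiological-window analysis (placement table, depth and volume
sweeps) uses the extrema of the **through-thickness profile at the slice
centre** (r = 0): the centre line is the least-oxygenated radius, its
maximum sits on the top face and its minimum in the interior, and it is
the quantity the through-thickness comparisons plot.  The tissue-wide grid
extremum is also available (`tissue_extrema(..., scope="slice")`); note its
maximum lives at the rim corner and is substantially higher (e.g. ~102 vs
65 mmHg for the 5 mm slice at its "max = 65" placement), so the two scopes
answer different questions.  The placement search brackets the extremum
over h₁ ∈ [0, H − Δ − 1 µm] — both extrema are monotone in h₁ — and
Brent-bisects to 1e-7 m in h₁, verifying the achieved extremum to
0.01 mmHg.

## Finite-volume validation oracle

A deliberately independent solver discretises the same problem with
cell-centred finite volumes on a tensor mesh whose cell edges are pinned
to r_T, h₁ and h₂ (every cell entirely one material), harmonic-mean
two-resistor face conductances (flux continuity without explicit interface
equations), half-cell Dirichlet coupling at the surface, and a sparse
direct factorisation.  The scheme is conservative — the discrete surface
influx balances total tissue uptake to <1% on a 200² mesh — and obeys a
discrete maximum principle.  On a 400²-cell mesh the converged series
solution agrees with it to ≤0.36% of φ₀ (L∞ over the tissue) in all
eighteen scenario/placement combinations, and both reproduce the
closed-form column profile to ≤0.5% of φ₀ when the slice spans the whole
well.

## Design choices made where the design was open

* **Unweighted projection.**  The matching projects onto Z_m without the
  D(z) orthogonality weight; the D-weighted Gram is kept as a property
  test only.  With the correct Gram matrices in T and W the projection is
  a consistent Petrov–Galerkin scheme, and the FD oracle confirms
  convergence to the true field.
* **Single square truncation** rather than mixed orders per region: a
  rectangular pairing requires least-squares solves and was measurably
  less accurate at equal cost.
* **Rim reporting convention.**  At exactly r = r_T the inner
  representation is returned; inner and outer values there differ only by
  the truncation mismatch quantified above.
* **H = 3.4 mm exactly** in the default preset (the rounded value), with
  volume-derived depth available via configuration.

## Limitations

Linear uptake kinetics; steady state only; perfectly cylindrical geometry
and axisymmetry; no media convection; the insert or support holding the
slice at height h₁ is assumed diffusively transparent; oxygen levels are
partial pressures with no solubility modelling.  Results for plate formats
other than the 12-well default are obtained simply by changing the well
dimensions, which assumes the same unstirred-film physics applies.
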