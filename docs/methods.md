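# Methods

## Model

`nanobead` computes mechanical equilibria of a membrane nanotube whose
composition and material properties vary along its length.  The
membrane is a thin, areally incompressible elastic surface with free
energy per unit area

    W = κ(m) [H − C(σ)]² + κ_G(m) K − α σ² + β (∇σ)²  (+ entropic term)

where H and K are the mean and Gaussian curvatures, κ and κ_G the
bending and Gaussian moduli, σ the surface density of cone-shaped
membrane proteins, and C(σ) = μφσ the protein-induced spontaneous
curvature (φ ≤ 0, so proteins bend the membrane away from the tube's
own curvature).  The aggregation term −ασ² and the gradient penalty
β(∇σ)² form a Cahn–Hilliard-like protein energy; the dilute-limit
entropic term k_BT σ(log(σ/σ_s) − 1) is retained behind a flag but off
by default, since k_BT σ ≪ 1 for every density considered.

Normal force balance gives the shape equation; tangential force balance
gives the spatial variation of the tension field λ (the Lagrange
multiplier of local area incompressibility),

    λ' = 2[κμφ(H − C) + ασ]σ' − 2βσ'σ'' − κ'(H − C)² − κ_G' K .

The coefficients of the σ'-terms follow from the variational derivation
(λ' = −∂W/∂s at fixed curvatures); they are also the only dimensionally
consistent choice.

## Axisymmetric reduction and solver

On a surface of revolution parameterized by arclength s the equations
close into seven first-order ODEs for (r, z, ψ, H, L, Λ, m):

    r' = cos ψ,  z' = sin ψ,  ψ' = 2H − sin ψ / r
    H' = (L/r − κ'(H − C))/κ + C'
    L' = r [p + 2ΛH + 2κH(H−C)² − 2κ(H−C)(2H² − K) − G]
    Λ' = 2κ(H − C)C' − κ'(H − C)² − κ_G' K
    m' = r / R_c

with L = r d/ds[κ(H−C)] the moment flux,
G = (1/r) d/ds[κ_G' sin ψ] the heterogeneous-Gaussian-modulus source,
and Λ = λ − ασ² + β(σ')² the *net* tension.  Two consequences of this
exact reduction are worth stating:

* α and β drop out of the mechanics entirely whenever σ vanishes at the
  boundary: they shift the tension field and the energy bookkeeping but
  not the equilibrium shape.  (Varying α indeed leaves bead shapes
  unchanged.)
* the tether force 2π√(κΛ) is a first integral on homogeneous
  segments; two joined tube segments with rigidities κ₁, κ₂ therefore
  satisfy R₂ = (κ₂/κ₁)R₁, which the solver reproduces exactly and which
  serves as an independent algebra check.

The heterogeneity fields are *material* fields: they are prescribed on
the reference arclength m of the undeformed tube, with local area
incompressibility mapping 2πr ds of deformed surface onto 2πR_c dm of
reference surface (the m' equation).  A protein domain of reference
length 8 μm therefore wraps a bead compactly instead of stretching over
8 μm of deformed meridian.  The material origin is anchored at the tube
midpoint; membrane is free to flow in through the tube ends, and the
total deformed arclength is held at L_c.

The sign of the Gaussian source G and every other algebraic choice are
pinned by two oracles rather than by convention: the homogeneous
cylinder must be an exact fixed point (R = ½√(κ/λ), tension constant),
and every converged shape must pass an energy first-variation test
(below).

The system is nondimensionalized (lengths by R_c, tensions by κ/R_c²,
moment flux by κ/R_c) and solved with `scipy.integrate.solve_bvp`
(4th-order collocation) under six mechanical boundary conditions —
r = R_c, ψ = π/2 clamped at both ends, z(0) = 0, Λ(S) = λ₀ at one end —
plus the material anchor.  Mirror-symmetric inputs are solved on half
the domain with symmetry conditions (z = 0, ψ = π/2, L = 0) at the
midpoint, which halves the cost; the returned shape is always the full
tube.  Heterogeneity is always introduced by parameter continuation
from the homogeneous cylinder, each solve seeded by the previous
solution; failed steps are bisected.  Collocation meshes that the
solver refined are re-equidistributed (density following the variation
of r, ψ and H) before seeding the next solve, otherwise meshes grow
monotonically along a branch.

## Stationarity oracle

`verify_stationarity` is independent of the ODE right-hand side.  It
evaluates the discrete functional E = ∫(W + λ) dA − ∫λ dA₀ on the
solved shape and on normally perturbed copies (compact Gaussian bumps,
amplitude ±ε = 0.5 nm), with the material fields riding on the nodes
and the solved multiplier held fixed, using only finite-difference
surface geometry.  For equilibria the symmetric difference quotient
|dE/dε|·R_c/E_bend sits at ~1e-5–1e-6 (quadrature floor); deliberately
perturbed shapes score orders of magnitude higher.  The threshold used
in tests is 1e-4.

## Synthetic heterogeneity profiles

Domains are hyperbolic-tangent plateaus: a domain of length L centered
at c contributes amplitude·[tanh((s−c+L/2)/w) − tanh((s−c−L/2)/w)] /
(2 tanh(L/2w)), which makes the plateau value exact at the center.  The
transition half-width w defaults to 10 R_c = 350 nm: well below the
8 μm domain length, well above the mesh scale.  Computed bead radii are
insensitive to w (±1% for w between 175 and 700 nm).  Profiles carry
analytic first and second derivatives; the solver never differentiates
sampled fields numerically.  Defaults follow the documented parameter
set: R_c = 35 nm, L_c = 20 μm, κ = 320 pN·nm, α = 1.28e7 pN·nm³,
μ = 200 nm, φ = −1, λ₀ = 0.064 pN/nm, protein densities up to
3.75e-4 nm⁻², rigidity ratios up to 30, p = 0.  β is not part of the
tabulated set; it defaults to 0, and because of the exact cancellation
noted above a nonzero β (e.g. 1e11 pN·nm⁴, keeping the gradient energy
below 10% of the aggregation energy for default profiles) changes only
the energy bookkeeping.  The Gaussian modulus baseline is set to
−0.9 κ, a typical lipid value; it only matters when it varies along the
tube.

What the generator does *not* emulate: protein diffusion or any
feedback of shape on σ (the fields are prescribed, not evolved),
thermal fluctuations, anisotropic (BAR-type) curvature inducers, and
non-axisymmetric modes.  Passing tests therefore validate the
equilibrium mechanics of prescribed heterogeneity, not the dynamics of
domain formation.

## Bead measurement and classification

A bead is a maximal region with r > 1.1 R_c around a radius peak; peaks
whose connecting saddle stays above 95% of the smaller peak count as
one bead.  Classes: *cylindrical* if the radius varies by less than 1%
over the central half of the bead; *unduloid* if the (Savitzky–Golay
smoothed) radius has an interior dip deeper than 1% between two bulges
near the bead top — the geometric signature of the curvature criterion,
since the second arclength derivative of H flips sign at such a neck;
*ellipsoidal* otherwise.  Direct sign-testing of smoothed H''(s) cannot
separate the classes (every smooth curvature dip has flanking
inflections at every smoothing scale we tested), which is why the
radius-based reading is used.

## Two-domain studies

`merge_study` sweeps the end-to-end separation of two identical domains
downward by continuation from a warm-started two-bead state, and (for
bidirectional studies) independently warms up the merged state at the
smallest separation and sweeps upward.  The critical separation is the
largest one at which a downward quasi-static sweep yields one bead; if
the two-bead branch terminates at a fold while the merged branch
persists, the transition is recorded as a snap-through at the fold.
Disagreement of bead counts between the two branches, or a
discontinuous shape jump along a single branch, likewise marks
snap-through; a state with no bead at all is never counted as merged.

## Numerical choices and problem sizes

Default collocation mesh 601 points (half domain), residual tolerance
1e-6, node budget 60k; bead radii change by <0.2% under mesh halving
and are identical at tolerance 1e-8.  Continuation paths use 11–21
steps per parameter leg with up to 4 bisections per failed step.
Separation sweeps use 21 points over [0, 4 μm]; phase diagrams default
to a 6×6 grid.  These sizes keep a full experiment suite in minutes on
one CPU while all reported quantities are mesh-converged.

## Known limitations

* The model's equilibria cease to exist beyond a fold in parameter
  space (near σ₀ ≈ 2.6e-5 at κ_ratio = 11, σ₀ ≈ 2.4e-4 at uniform
  rigidity): beyond it the transition-region tension drop exceeds what
  the domain can balance and the bead grows without bound.  Fine-step,
  bisected continuation, orthogonal parameter paths, homotopies in
  domain length and tension, and fold tracing with the axial extent as
  the continuation parameter all terminate at the same boundary, so it
  is a property of the equations as implemented, not of the numerics.
  Morphology studies therefore operate in the pre-fold window; the
  ellipsoid → flat-top → unduloid sequence appears there, compressed
  toward lower densities.
* Merging of well-developed beads is strongly hysteretic in this
  system: the merged single-bead branch persists to large separations.
  Stability of branches is not assessed (no second-variation analysis);
  continuation tracks stationary points, and which branch a physical
  tube selects near a fold is outside the model.
* The cylindrical-bead closed-form estimates (energy matching at the
  domain center) agree with the solver only for small deformations
  (r_b ≲ 60 nm, σ₀ ≲ 2e-5 at uniform rigidity); beyond that they
  underestimate the computed radii.
* No self-contact handling: at very small two-domain separations
  opposing membrane faces may approach within bilayer thickness, where
  the continuum model is silent.
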