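# Methods

This note records the model, the assumptions behind it, the parameter
choices built into the canonical fixtures, and the numerical decisions made
where the design was genuinely open.  No empirical claim is made here that
the test suite or `scripts/acceptance.py` does not itself compute.

## Physical model

**Geometry.** A labyrinth is a set of duct sections joined at confluence
nodes.  Each section is a straight segment or a polyline chain of straight
sub-segments with a circular cross section (area A = πr²); curved ducts are
polyline approximations.  Flow is treated as one-dimensional along the duct
axis (laminar Poiseuille flow, rigid walls, no secondary flow in the
cross-sectional plane).  The plane through three corner points of a duct
triangle is computed from 2×2 determinants of coordinate differences,
equivalent to the cross product of two edge vectors.

**Stimulus.** The canonical stimulus is the pseudo-impulse stop: the head
rotates at constant **ω** for much longer than the slowest time constant and
is stopped instantaneously at t = 0.  In that protocol all coordinate
frames coincide at the stop, the centripetal and Coriolis contributions to
the fluid acceleration vanish, and integrating the tangential acceleration
over the (vanishing) stop interval leaves the endolymph moving at
**ω** × **r** relative to the walls.  Because the implementation works
directly with momenta (time-integrated forces), the stop duration Δt never
appears; tests verify that scaling all impulses by a common factor scales
all velocities by the same factor.

**External impulses.** Each section carries an external impulse
I_sex = ρA_s l_s (**ω**×**h**_s)·**t̂** (sign)_s, where **h**_s is the
perpendicular from the rotation centre to the segment's supporting line.
The projection (**ω**×**h**)·**t̂** is invariant to sliding the arm along
the segment, so the segment start point serves as the arm; polyline
sections sum over sub-segments.  A property test compares the result with a
1000-point numerical integration of (**ω**×**r**)·**t̂** along the section.

**Initial flow distribution.** Right after the stop, friction and
elasticity have had no time to act, so the velocities follow from momentum
balance per section, m_s v_s − A_s(P_from − P_to) = I_sex (P is the
pressure impulse at a node), plus volume continuity at all nodes but one.
The pressure gauge is anchored at the lexicographically first node; a test
confirms the velocities are gauge-independent.  Continuity rows are
assembled from the topology rather than transcribed from the historical
5×5 matrix; for the canonical five-section, three-node labyrinth a test
shows the assembly reproduces that matrix (whose published fifth row
contains a typesetting slip in the utriculus column — node-A continuity
fixes the entry to zero) to 1e−10 on random impulse vectors.

**Coupled dynamics.** Each section obeys M ẍ + F ẋ + S x = A Δp with
M = ρAl, F = 8πηl and lumped cupular stiffness S on the ampullary ducts
only (S is a user input; information about real cupular stiffness is
scarce, so fixtures back-solve S = F/T₁ from a prescribed slow constant).
On volumetric displacement V = A x the coefficients become
L = ρl/A, R = 8πηl/A², C = S/A²; continuity restricts V to the cycle space
of the network, computed as the null space of the reduced node-section
incidence matrix.  The loop-coordinate system (BᵀLB) z̈ + (BᵀRB) ż +
(BᵀCB) z = 0 is reduced to first order and eigen-decomposed.  This replaces
the historical 18×18 symbolic solution; equivalence is demonstrated by
reconstruction tests against an independent stiff ODE integration (Radau,
rtol 1e−10) to better than 1e−6 relative, by volume-continuity and by
confluence-pressure consistency checks along the solution.  Complex or
non-decaying eigenvalues raise a regime error: the model is valid only for
the heavily overdamped labyrinth (ζ = ½√(T₁/T₂) ≈ 30 for human-like
dimensions).

## Canonical fixtures (study conditions)

All fixtures use water-like endolymph (ρ = 1000 kg/m³, η = 1 mPa·s,
ν = 10⁻⁶ m²/s) and strict SI units internally.

- **`two_duct_fig4`** — two congruent right-isosceles triangular circuits
  sharing one leg (the common part, length s; default s = 10 mm).  Each
  duct traverses the other leg plus the hypotenuse, so
  λ = l_c/l_d = 1/(1+√2) ≈ 0.4142 and γ = 1.  This reconstruction is the
  unique one simultaneously consistent with the two published benchmark
  values it must reproduce: the single-duct-excitation coupling coefficient
  0.29 = λ/(γ²+λ) and the 73° null-flow angle.
- **`flat_three_duct`** — the folded-out flat three-duct layout: three
  confluence nodes on a line, the crus commune and utriculus as short wide
  straight sections between them, the three ampullary ducts as triangular
  circuits.  Proportions (in units of the default scale s = 4 mm) follow
  real labyrinth anatomy: equal duct radii r_d = 0.05 s (0.2 mm), vertical
  ducts of length 6 s, horizontal duct 3 s — about half, the anatomical
  fact that makes one slow constant about half the other two — common
  parts of length 0.75 s with the crus commune 2.2× and the utriculus 4×
  the duct radius (wide, low-resistance common parts, which is why the
  three fast constants stay within a few per cent of r²/8ν).  These
  proportions were fixed from a slow-limit eigen-analysis of the loop
  system before the tests were frozen.
- **`human_like`** — a single duct circuit with r = 0.2 mm (T₂ = r²/8ν =
  5 ms, inside the published human 5–10 ms range), duct length 20 mm and a
  wide utricular return path; S from T₁ = 20 s.

What the fixtures do *not* emulate: real ducts are tori with non-uniform
cross sections, the utriculus is a sac rather than a duct, cupular
mechanics is a distributed elastic membrane rather than a lumped spring,
and duct planes are not exactly orthogonal.  Passing tests therefore show
the coupled-network theory is implemented correctly under its own
assumptions, not that those assumptions exhaust real labyrinth behaviour.

## Two-duct closed forms

The closed-form initial velocities contain an I_cex term whose sign is
inconsistent across the published formulas (and one formula lacks an
operator altogether).  The implementation adopts +I_cex in duct a's
velocity and −I_cex in duct p's — the unique choice under which the
velocity-form maximal excursions (via the two fast constants) equal the
impulse-form expressions identically.  That identity is asserted inside
`max_excursions_2duct` at 1e−12 relative and exercised by a derandomised
property test; the closed forms are also checked against the generic
network solver to 1e−10 on random impulse triples.

The λ-scan normalizes I_aex by ρ|ω|·(total duct volume) so curves from
different shape families are comparable, and takes the rotation centre at
the midpoint of the common part with the axis normal to the labyrinth
plane (for open sections the external impulse depends on the rotation
centre, so a convention is required; the common-part midpoint is the
natural centre of the labyrinth).  The dip family (two triangles sharing a
leg, duct length fixed) shows an interior maximum in λ; the smooth family
(a circle split by a chord) is monotone — the scan asserts shapes, not
published curve values, because the published normalizer is not printed.

## Transducer

Corner frequencies use the inverse-time-constant convention f = 1/T, which
reproduces the published lower corner 0.05 Hz for T₁ = 20 s exactly.  The
published corner pair (0.05 Hz, 30 Hz) cannot be reproduced by any single
1/T vs 1/2πT convention given T₂ = 5–10 ms; the 1/T convention is used and
the discrepancy left as such.  Consequently the ±3 dB plateau property of
the velocity view is asserted at the corner *rates* ω ∈ [2/T₁, 1/(2T₂)],
where the plateau of u|H(ju)| actually lives.

The subcupular fast constant treats the duct + subcupular space as a
composite circuit on volumetric flow: M_q = ρΣlᵢ/Aᵢ, F_q = 8πηΣlᵢ/Aᵢ²,
T₂ = M_q/F_q, normalized by the uniform-duct value ρA_d/8πη.  This reduces
to r²/8ν for a uniform duct (tested) and produces the interior optimum of
x*_max = ẋ*(0)·T₂* in A_s/A_d.  The utricular part is omitted from the
subcupular circuit, the standard simplification.

## Brownian noise

The bundle is a stiff slender rod, elastically anchored at the base,
overdamped in endolymph.  The transverse drag uses the slender-body form
γ = 4πηL/(ln(L/r) + 0.84), isolated in `rod_friction` so alternative drag
laws can be swapped; downstream quantities take γ as a parameter.
Temperature defaults to 310 K and k_BT is computed, never hard-coded.

The mean-square tip excursion obeys τλ̇ + λ = 4Dτ (D = k_BT/γ,
τ = γ/2κ), solved in closed form.  The "exact" amplitude spectrum is
defined as X*(f) = (1/2π)√(λ(t_f)) with observation window t_f = 1/(8f) —
the unique scaling-plus-substitution that reproduces both published
anchors: the plateau √(k_BT/κ)/(π√2) at f → 0 and the free-diffusion tail
√(D/2f)/(2π) at f → ∞.  The classical two-term closed form (constants
A + B = 1, a, b) is fitted to this spectrum by least squares followed by a
derivative-free minimax polish over fT_c ∈ [10⁻³, 10] (four decades
spanning the plateau and roll-off); the worst-case deviation is about 4 %
and is reported in the fit result.  The stationary mean square 2k_BT/κ and
the spectral plateau differ by the 1/2π spectral normalization — they are
related, not equal, and both relations are asserted.

The published 70 nm rms noise figure is treated as an order-of-magnitude
anchor only (the diffusion constant and evaluation frequency behind it are
not printed); the round trip plateau → κ → plateau is exact by
construction and tested at 1e−12.

## Scaling and allometry

Design metrics T₂ = r²/8ν, x_max = |ω|R·T₂ and Re = |ω|R·r/ν are evaluated
on log-spaced (r, R) grids; isolines are emitted from the closed-form
rearrangements (T₂ vertical in r, x_max along R ∝ 1/r², Re along R ∝ 1/r).
The reference ω defaults to 1 rad/s and is a required CLI flag for
absolute numbers.  Allometric laws use R in mm and m in kg — the only unit
assignment that reproduces the published 0.2 mm circuit radius of a 13 mg
fish larva; at 35 kg the fish law gives 12.7 mm against a published
"about 15 mm" (rounded upward in the source; left as is).  The two laws
cross near 4 g, so the fish-exceeds-mammal inequality is asserted only
above 5 g.

## Numerical choices

- Linear systems are solved with LAPACK via numpy; singularity surfaces as
  a topology error (a loop-free network cannot carry divergence-free flow).
- The cycle basis is the orthonormal null space of the incidence matrix;
  the basis choice is immaterial (only the span enters) and is covered by
  the reconstruction tests.
- Eigenvalues with relative imaginary part above 1e−9 raise a regime
  error rather than being silently truncated.
- "Approximately equal" in the mode-structure tests is fixed at 5 %
  (fast constants, slow pair) and 0.5 ± 20 % (the halved slow constant);
  these are test configuration constants reflecting qualitative published
  statements, not physics.
- Problem sizes: mode reconstruction is checked on 120–200 time points
  over five slow constants; agreement sweeps use 100 random impulse
  vectors; design grids default to 40–50 points per axis.  These sizes
  keep the full suite under a few seconds while leaving the tolerances
  meaningful.
- Scalar outputs are serialized at 12 significant digits, making repeated
  runs byte-identical.

## Known limitations

- No secondary flow, wall compliance, or non-circular cross sections.
- No sustained-rotation or sinusoidal forcing of the full 3-D network; the
  frequency-domain treatment applies to the single-duct standard form.
- No neuronal/afferent processing ("velocity storage" is downstream of the
  mechanics and out of scope), and no cupula elastodynamics beyond the
  lumped stiffness.
- The λ-optimum is a numeric scan, not a closed-form derivation.
- Mode amplitudes for the three-duct network are solver outputs constrained
  by the reconstruction/continuity/pressure invariants; no published table
  exists to compare them against.
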