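# Methods

## Scope and model chain

`elfxs` implements the linear-response dielectric route to electron
inelastic scattering observables on analytically controllable model
systems. The chain is:

1. a periodic Kohn-Sham-like model (band energies, occupations, plane-wave
   coefficients on a reciprocal-lattice basis) or a parametric Drude
   surface;
2. the non-interacting density-density response `chi0_GG'(E, q)` summed
   over electron-hole pairs;
3. the RPA Dyson equation with the bare Coulomb kernel
   `v_G(q) = 4 pi / |q+G|^2` — electron interactions enter only through
   Hartree screening, no exchange-correlation kernel;
4. the macroscopic energy loss function
   `ELF(E, q) = -(4 pi / q^2) Im chi_00`, with local-field effects (LFE)
   carried by the off-diagonal reciprocal-lattice components, or the
   head-only variant `Im[-1/(1 - v_0 chi0_00)]` (NLFE);
5. additive decompositions of the ELF (pairs, occupied-energy DELF,
   Mulliken species / angular momentum / species pairs, molecular-orbital
   channels);
6. first-Born cross-section quadratures: SDCS, total inelastic cross
   section / IMFP, electronic stopping power, per-channel SDCS.

## Units and conventions

All internal arithmetic is in Hartree atomic units; public interfaces take
energies in eV and momentum transfer in atomic units, with the single
conversion constant 1 hartree = 27.211386 eV defined once in
`elfxs.constants`. Cross-section outputs are converted at the boundary to
track-structure units: total cross section per unit path length in 1/nm,
IMFP in nm, stopping power in eV/nm, SDCS in 1/(eV nm).

Occupations carry the spin factor explicitly: `f in [0, 2]`. States are
normalized to the unit cell, which makes the plane-wave matrix elements
`U^G_{nm,k}(q)` dimensionless overlaps; the per-volume normalization of
`chi0` then reads `1/(N_k V_uc)` in front of the pair sum. This convention
is fixed by requiring that jellium reproduce the closed-form Lindhard
function (per unit volume) exactly in the mesh-refinement limit.

Momentum transfers must connect k-mesh points: `q` is accepted only if
`q a n_k / (2 pi)` is an integer vector (an informative error names the
nearest commensurate magnitude otherwise), and a `q` equal to a
reciprocal-lattice vector is rejected — it is Gamma-equivalent and its
Coulomb kernel diverges. The optical limit is represented by the smallest
commensurate `q` of the model, exactly as periodic-cell response
calculations approximate `q -> 0` by their smallest representable
momentum. Public entry points accept a magnitude plus a cubic-axis
direction and can average over the three axes (`average_directions`), the
inexpensive isotropy proxy appropriate for a disordered liquid.

The broadening `eta` must be positive (the response has poles on the real
axis otherwise) and should be at least twice the energy-grid spacing; a
warning is issued below that. Defaults: `dE = 0.15 eV`, `eta = 0.3 eV`,
tabulated `q` in [0.1, 2.0] a.u. For coarse-mesh jellium oracle
comparisons a larger `eta` (1-1.5 eV) is used, commensurate with the
discrete transition-energy spacing of the k-mesh, and the analytic
reference is always evaluated at the *same* complex energy `E + i eta` so
that only the mesh discretization is being measured.

## Model systems (what the generators emulate, and what not)

**Jellium.** Plane-wave eigenstates `E = |k+G|^2 / 2` in a cubic box whose
size fixes the electron count per cell (default 2), occupations filled to
the Fermi level of the requested density. Every state is a one-hot
plane-wave coefficient vector, so the matrix elements are exact Kronecker
overlaps and `chi0` is diagonal in G — jellium is the homogeneous limit in
which local fields vanish identically. Its role is the analytic oracle:
the discrete pair sum must converge to the complex-frequency Lindhard
function, the RPA ELF must peak at `omega_p = sqrt(4 pi n)`, and the f-sum
rule `int E ELF dE = (pi/2) omega_p^2` must hold at small q.

**Water-like LCAO toy.** One "molecule" per cubic cell at the molecular
volume of liquid water (a = 5.87 bohr, so the valence density and hence
the plasmon scale are those of water), four occupied bands with centres at
the photoemission binding energies of the liquid-water molecular orbitals
(2a1 30.90, 1b2 17.34, 3a1 13.50, 1b1 11.16 eV below vacuum) and small
cosine dispersion (default half-width 0.5 eV) so the bands are resolvable
but never overlap; one empty band a configurable gap (default 8.7 eV, the
experimental optical gap of water) above the highest occupied band, which
puts the mid-gap Fermi level near -6.8 eV. Bands are fixed linear
combinations of labelled Gaussian atomic orbitals (O s/p at the cell
centre, H s/p at the two proton sites, C2v geometry) expanded exactly in
plane waves; the Bloch orbital basis is Lowdin-orthonormalized per
k-point, and the band template vectors are Lowdin-orthonormalized once, so
states are exactly orthonormal and Mulliken weights are plain `|C|^2`.
Template compositions are symmetry-adapted (b2-like bands use the in-plane
antisymmetric combinations, the 1b1 the out-of-plane O p) so that
orthonormalization barely moves the requested species weights. The 1b1
template carries a small antisymmetric H-s admixture: a mathematically
pure out-of-plane lone pair would be *exactly dark* along the cubic axes
by parity — an artifact of the single-molecule toy that no disordered
liquid band shares.

What the toys do **not** emulate: real self-consistent band structures,
orbital relaxation, the quantitative height/shape of the measured water
ELF, disorder broadening, or multi-molecule local-field structure. Passing
tests therefore demonstrate the correctness of the response, partition and
integration machinery and the qualitative water-like phenomenology (single
dominant loss peak between 15 and 30 eV, four DELF windows,
HOMO-dominated threshold losses), not a quantitative prediction for real
water.

**Drude surfaces.** `ELF(E, q) = sum_i A_i gamma_i E / [(E^2 - E_i(q)^2)^2
+ gamma_i^2 E^2]` with optional free-electron-recoil dispersion
`E_i(q) = E_i + q^2/2`. The weight `A_i` (eV^2) is the squared plasmon
energy carried by the peak: each term integrates to `(pi/2) A_i` under the
f-sum exactly, independent of position and width, which is what makes
these surfaces useful cross-section references. The water-like reference
uses a single peak at 21 eV, width 10 eV, weight `4 pi n_val` with
`n_val = 8 / (202.2 bohr^3)` — the valence-electron plasmon energy
(19.2 eV) of liquid water.

All generators are deterministic; nothing in the model construction is
random.

## Partition conventions

The ELF is assembled by applying `chi0` to the effective potential
`V_eff = [1 - v chi0]^(-1) V_ext`, `V_ext = delta_G0`; this route is
algebraically identical to the direct Dyson solve (asserted to 1e-10) and
linear in the pair index, so every decomposition closes exactly. Three
conventions the decomposition needs that are otherwise underdetermined:

- **Pair-term normalization.** The pair term is defined as the `(n, m, k)`
  summand of `chi0 V_eff` including the `1/(N_k V_uc)` prefactor, so the
  pair sum reproduces the total ELF identically (closure is the defining
  property).
- **Occupied-state attribution.** Each pair term involves one occupied and
  one empty state; labels (energy bin, Mulliken weights, channel window)
  are always taken from the **occupied** state, for both the resonant and
  antiresonant term of a pair. Species-pair weights are the symmetrized
  product of the occupied state's two species weights.
- **Delta functions as histograms.** The occupied-energy DELF realizes its
  delta functions as histogram bins (default width = the energy
  resolution), which keeps closure exact; Gaussian broadening would trade
  closure for smoothness.

Individual components may legitimately be negative (screening cross
terms); only the total ELF is sign-constrained. Molecular-orbital channel
windows default to boundaries midway between adjacent occupied bands and
must jointly cover all occupied states.

## Cross-section quadratures

SDCS: trapezoid in `ln q` on 200 points between the kinematic limits,
evaluated on a bilinear interpolant of the tabulated surface. `q_min` is
computed in the rationalized form `2mE / q_max` — the same closed form as
`sqrt(2m)(sqrt(T) - sqrt(T-E))` but immune to subtractive cancellation, so
`q_min q_max = 2mE` holds to round-off. Energy integrals (total cross
section, stopping) run on the surface's native energy grid restricted to
`[E_min, E_max]`, with `E_max = min[(T + E_gap)/2, T - E_F]` and
`E_min = 0` by default (`emin_mode='gap'` applies the threshold instead).
Energy-grid points above `T` are excluded with a warning count. Halving
the quadrature step moves sigma and S_e by < 0.2% on the reference
surface.

Out-of-grid momentum transfers follow an explicit, logged policy: below
the tabulated range the optical column is used (periodic-cell data cannot
reach smaller q, and the surface is flattest there); above it two policies
are available. `'loglog'` extrapolates linearly in (ln ELF, ln q) from the
last two columns with a floor at zero — the physically sensible decay for
a total ELF, used by default for IMFP/stopping pipelines. `'hold'` clamps
to the last column; it is the **value-linear** policy, which is the only
way per-channel SDCS curves can sum *exactly* to the curve of the summed
surface (log extrapolation is nonlinear in the values and undefined for
signed channel components), so channel cross sections default to it.
Every SDCS reports the fraction of its integral obtained beyond the
tabulated q range; for the reference surfaces this fraction is below 1e-6,
so the policy choice is immaterial there.

## Numerical choices and degenerate inputs

- Dyson and effective-potential systems are solved with LAPACK partial
  pivoting, never by explicit inversion; a condition-number check rejects
  systems singular to `1/cond < 1e-12` with a message pointing at the
  plasmon-pole-with-too-small-eta failure mode.
- `eta = 0` is rejected rather than special-cased; with `eta > 0` no
  denominator can vanish.
- Fully occupied models yield exactly zero response (pairs with equal
  occupations are skipped, not computed-and-cancelled).
- A jellium whose retained bands are all occupied is rejected at
  construction (no excitations representable).
- Toy-water occupied bands whose energy windows would overlap are rejected
  (channel windows would be ill-defined), as is a gap small enough to
  overlap the empty band.

## Problem sizes

The test suite and the acceptance script run the jellium oracle on 16^3
k-points (about 190k electron-hole pairs per q), convergence trends on
6/8/12^3, and the toy-water pipeline on the 3^3 mesh with a 0.15 eV energy
grid to 60 eV; Drude reference surfaces are tabulated to 2 keV at 0.25-0.5
eV resolution with 20-80 q columns. These sizes keep every check at
machine-or-better-than-percent precision; the full suite completes in
under a minute on one CPU.

## Known limitations

- RPA only: no exchange-correlation kernel, no excitonic effects; the
  known RPA biases of loss spectra carry over by construction.
- First Born approximation only: no exchange (Mott) or Coulomb-field
  corrections at low T, no relativistic kinematics above ~10 keV — the
  Bethe asymptote check stops at 100 keV where these are still small for
  the shape property being tested.
- The LCAO toys use fixed band templates, not self-consistent eigenstates;
  their k-dispersion is prescribed, not derived from the orbital overlap.
- Channel decompositions are exact for the model, but their negative
  screening cross terms mean single channels should not be interpreted as
  standalone cross sections far from their resonances.
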