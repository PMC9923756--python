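# Methods

This note records the models implemented in `x2cxas`, the numerical choices
behind them, and what the built-in fixtures do and do not probe.

## Four-component reference

The reference theory is Dirac–Coulomb Kohn–Sham (or Hartree–Fock) for closed
shells.  Operators are represented over a restricted-kinetic-balance (RKB)
basis in the "modified Dirac" matrix form: with scalar overlap `S`, kinetic
`T`, nuclear attraction `V`, and `W_uv = <d_u chi| V |d_v chi>`,

```
h4c = [[ V,            T      ]       M4c = [[ S,  0         ]
       [ T,  W/(4c^2) - T     ]]             [ 0,  T/(2c^2)  ]]
```

where the rest-mass energy is removed and `W` carries the one-electron
spin–orbit coupling through its Pauli structure.  Every two-electron and xc
contribution is evaluated by expanding the small component in an auxiliary
scalar basis Φ that spans all Cartesian derivatives of the large-component
functions (shells of angular momentum l±1 with the same exponents), so the
4c Fock build reduces to three scalar ERI classes, (LL|LL), (LL|ΦΦ), and
(ΦΦ|ΦΦ), contracted with sparse derivative maps and Pauli algebra.  Gaunt and
Breit two-electron terms are not included; the reference is Dirac–Coulomb
throughout.

Integrals are McMurchie–Davidson recursions over uncontracted Cartesian
Gaussians of arbitrary angular momentum, written in this package and
numba-compiled.  Nuclei are Gaussian charge distributions with the standard
isotope-mass parameterization `r_rms = 0.836 A^(1/3) + 0.570 fm` (a
point-nucleus option exists for tests against the hydrogenic closed form).
The gauge origin of the electric dipole operator defaults to the center of
nuclear charge.

Linear dependence is removed by canonical orthogonalization with an
eigenvalue cutoff of 1e-9 applied to the *diagonally normalized* metric.
Normalizing first matters: the RKB small-component metric `T/(2c^2)` spans
ten or more decades for steep-plus-diffuse even-tempered sets, and an
unnormalized relative cutoff would discard kinetically balanced partners and
reintroduce variational collapse (we observed millihartree errors in the
hydrogen 4c ground state before adopting this convention).

SCF runs in the orthonormal basis with DIIS (subspace 8), an optional level
shift, and a density-damping retry for the fractional-occupation atomic
solver.  Convergence thresholds: 1e-9 Eh on the energy and 1e-7 on the RMS
density change.

### Configuration-averaged atoms

Atomic mean-field corrections need spherically symmetric atomic references.
Atoms are solved Kramers-restricted with fractional occupations: eigenvalues
of the positive branch are clustered by a combined relative/absolute energy
gap (2 % / 0.02 Eh, wide enough to merge spin–orbit partners of one (n, l)
shell and narrow enough to separate shells), filled in order, and the last
partially filled cluster shares its electrons evenly (e.g. oxygen: 4/6 per
2p spinor).  This averaging scheme is a documented choice of this package;
it produces densities whose dipole moments vanish below 1e-8.

## Exchange–correlation

The functional family is LDA-based: Slater exchange and VWN5 correlation,
hybridized with an exact-exchange weight ζ (`hfx`); the DFT exchange is
scaled by (1−ζ) and correlation is kept in full.  `functional` may be `hf`
(pure exact exchange), `slater`, or `svwn5`.  GGA enhancement factors are not
implemented; every Hamiltonian-model and response expression is
functional-agnostic, so the picture-change machinery is exercised identically
to a GGA-based setup, but absolute energies and edge positions are those of
the LDA hybrid.

The noncollinear potential uses the locally collinear variables (ρ, s=|m|);
at closed shells all spin channels vanish and only the charge potential
survives.  The adiabatic closed-shell kernel has a charge channel f_ρρ and a
spin channel f_ss (transverse = longitudinal at s = 0); both are obtained by
central finite differences of the analytic potential with a relative step of
1e-4, which agrees with the analytic second derivative to ~1e-8 and, more
importantly, is used identically in the iterative actions and the dense
oracles.

Quadrature is a per-atom product grid (Gauss–Chebyshev radial with the Becke
mapping × Gauss–Legendre θ × uniform φ) under Becke partitioning with
atomic-size adjustment.  The default (35, 10, 20) grid reproduces the He
SVWN5 energy to 2e-8 Eh against a (70, 18, 32) grid and sulfur 2p levels to
1e-4 eV; it is a fixed specification, so all paths that must agree (SCF,
response action, dense kernel oracle) integrate on identical points.

## X2C decoupling and picture change

One-step decoupling builds U from the positive-energy eigenvectors of a
parent 4c operator: `R = C+^S (C+^L)^-1` followed by symmetric (Löwdin-style)
renormalization.  U is exactly unitary in the orthonormal basis, reproduces
the parent's positive spectrum to ~1e-10 Eh, and is computed once, field-free
(adiabatic X2C); no field-dependent U appears anywhere.  The picture-change
transform of an operator is the upper-left 2c block of U†OU, with the norm of
the discarded off-diagonal block recorded for diagnostics.

## Hamiltonian models

All four models share the 2c Fock form
`F = h̃2c + G2c[D] + Vxc2c[D] + ΔF̃`, with untransformed 2c integrals and
overlap distributions contracted with the picture-change-transformed density:

* **1eX2C** — U from `h4c` alone, ΔF̃ = 0.
* **amfX2C** — U from the parent `h4c + F⊕(4c,2e)`, where F⊕ is the full
  two-electron-plus-xc 4c mean field of the superposed static atomic
  densities (whether xc belongs in the parent is a convention; we include
  it).  ΔF̃ is assembled per atom in the atom's own orthonormal basis as
  (transformed atomic 2e/xc Fock) − (untransformed-integral Fock at the
  transformed atomic density), mapped to the raw AO basis, placed on the
  atomic diagonal blocks, and re-orthonormalized with the molecular map.
* **eamfX2C** — same U; the superposed 4c molecular density and its
  per-atom-transformed 2c counterpart are built first and the correction is
  formed in the full molecular basis, giving nonzero interatomic blocks.
  For a single atom it coincides with amfX2C to round-off.
* **mmfX2C** — U from a converged molecular 4c Fock matrix; the transformed
  Fock reproduces the positive-energy 4c spectrum to ~1e-10 Eh and ΔF̃ is its
  exact 2e/xc picture-change difference.

Time- and perturbation-dependent atomic density corrections are not
implemented; all corrections are static and perturbation-independent, which
is also the production path for electric-field response.

The model total energy adds the static correction with weight 1/2,
`E += 1/2 Tr(D ΔF̃)`, because ΔF̃ corrects the (double-counted) two-electron
part of the Fock matrix; with this convention the amf total energy of the
H2O fixture lands within ~1e-5 Eh of the 4c energy and mmf within ~1e-6 Eh.
A `nonrel` tag provides the Schrödinger 2-spinor reference used by the
c → ∞ limit tests through the identical 2c SCF code path.

## Linear response

On top of any converged closed-shell 2c or 4c result, the orbital Hessian
acts on trial matrices T (N_v × N_o):

```
(A T)_ai = (eps_a - eps_i) T_ai + [C_v' g(C_v T C_o') C_o]_ai
(B T)_ai =                        [C_v' g(C_o T^T C_v') C_o]_ai
g(rho)   = J(rho) - zeta K(rho) + f_xc(rho)
```

Core–valence separation is a restriction of the occupied index set (pair-
space projection), selected either by explicit indices or by a selector such
as `"S:2p"` resolved through Löwdin populations per (atom, l) group plus
energy ordering for the principal quantum number.

**Damped response** solves
`([[A,B],[B*,A*]] − (ω+iγ)[[1,0],[0,−1]]) (X;Y) = −(P;P̃*)` for batches of
frequencies in one growing preconditioned subspace; projected (Galerkin)
systems are solved per frequency with incremental updates, true residuals
are evaluated against the stored matrix–vector products, and at most 72
preconditioned residuals (worst first) expand the space per iteration.  The
result is independent of frequency batching to the solver tolerance
(default 1e-10; pipeline runs use 1e-6, ample for spectra on a 0.1 eV grid).

**Eigenvalue response** finds the lowest roots of
`[[A,B],[−B*,−A*]]` with a Davidson-type subspace kept closed under the
(X,Y) ↔ (Y*,X*) pairing; seeds are unit vectors on the smallest orbital-energy
differences, ties broken by index.  Roots are normalized to X†X − Y†Y = 1.
On dense near-degenerate core manifolds (hundreds of pair functions) the
damped solver is the recommended production route — exactly the regime it is
designed for — while the eigensolver is best for stick spectra of moderate
root counts.

Conventions are pinned operationally: transition moments
`t_u = P_u†X + P_u^T Y`, polarizability `α_uv = −(P_u†X_v + P_u^T Y_v)`
(damped) or the ±ω Lorentzian sum over states (eigenvalue route), and the
dipole strength `S(ω) = 4πω/(3c) · Im Tr α(ω)`.  A single isolated root
produces an exact Lorentzian of FWHM 2γ; the damped and sum-over-states
spectra agree to ~1e-12 relative on the full-root H2 fixture, which fixes
every sign and phase choice at once.  Spectra default to γ = 0.15 eV on a
0.1 eV grid, in atomic units (or normalized to unity on request).

## Fixtures and what they show

The built-in study conditions are light main-group systems with uncontracted
even-tempered bases (one fixed choice per element; e.g. S: 11s8p spanning
α = 0.08–3e4 for s and 0.06–385 for p), where the full 4c reference runs in
minutes on one CPU:

* H2 (3s per H): full-root response identities and solver oracles.
* H2O (O 8s4p, H 4s): mmf exactness at the Dirac–HF level; the c×100
  nonrelativistic-limit study.
* H2S (S 11s8p, H 4s): the spin–orbit workhorse.  The sulfur 2p splitting
  comes out at ≈1.29 eV (experiment ≈1.2 eV); 1eX2C overestimates it by
  ≈12 %, while amf, eamf, and mmf agree with the 4c value to ≤1e-4 eV —
  the qualitative and quantitative pattern expected of the model family.
* Synthetic paired-Hessian problems (seeded, dimension ≤ 50) with prescribed
  Hermitian/complex-symmetric structure and guaranteed stability, for
  solver/oracle equivalence sweeps.

These fixtures exercise every code path (spin–orbit coupling, picture-change
corrections, CVS, both solvers, 4c response) but not heavy-element edge
positions: transition-metal L/M edges in DZ-quality bases are hours-to-days
of single-CPU work with in-package integrals and are therefore out of
desk-scale; the code paths are size-agnostic.  Passing fixtures demonstrate
internal exactness relations and limits, not agreement with experimental
heavy-element spectra, whose absolute positions also depend on the GGA
hybrid functional family not implemented here.

## Known limitations

* LDA-based functionals only (no GGA gradient terms, hence no PBE0-xHF
  calibration of absolute keV-range edge positions).
* Dirac–Coulomb only (no Gaunt/Breit), closed shells only, electric-dipole
  coupling in the length gauge only.
* The amf picture-change correction retains a genuine O(c^-2) remainder at
  scaled c; at 100× c its largest matrix element on the H2O fixture is
  ≈1.1e-6 Eh (and ≈7e-10 on H2), scaling cleanly as c^-2.
* The eigensolver can saturate its subspace on very dense manifolds; it
  reports diagnostics and the damped route is preferred there.
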