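# x2cxas

Relativistic two-component (X2C) Hamiltonians with two-electron and
exchange–correlation picture-change corrections, and linear-response TDDFT
(damped and eigenvalue variants) for simulating X-ray absorption spectra
near L- and M-edges — validated against a built-in four-component
Dirac–Coulomb reference.

## The problem

Core-level (XAS) spectra of molecules containing heavier elements are shaped
by spin–orbit coupling: a 2p core hole splits into j = 1/2 and j = 3/2
levels (the L2/L3 edges, separation ΔSO).  Fully relativistic
four-component (4c) Dirac–Kohn–Sham response theory describes this
correctly but is expensive.  Exact two-component (X2C) theory
block-diagonalizes the 4c problem with a unitary U built from positive-energy
solutions,

    U† F⁴ᶜ U = diag(F̃²ᶜ₊, F̃²ᶜ₋),   U from R = C₊ˢ (C₊ᴸ)⁻¹ + renormalization,

but operators must be *picture-change* transformed consistently.  The widely
used one-electron X2C (1eX2C) transforms only h⁴ᶜ and systematically
**overestimates** core spin–orbit splittings.  This package implements the
family of corrected models in which a static Hermitian correction ΔF̃ fixes
the two-electron/xc picture change at 2c cost:

| model   | decoupling parent          | ΔF̃                                     |
|---------|----------------------------|------------------------------------------|
| 1eX2C   | h⁴ᶜ                        | 0                                        |
| amfX2C  | h⁴ᶜ + superposed atomic mean field | per-atom blocks from atomic 4c solutions |
| eamfX2C | same                       | molecular-basis correction from superposed atomic densities |
| mmfX2C  | converged molecular 4c Fock | exact (2c spectrum = 4c positive branch) |

On top of any converged 2c (or 4c) reference, spectra come from linear
response with core–valence separation (CVS): the damped route solves

    ([[A,B],[B*,A*]] − (ω+iγ)[[1,0],[0,−1]]) (X;Y) = −(P̃;P̃*)

for the complex polarizability α(ω) directly, and the eigenvalue (Casida)
route diagonalizes [[A,B],[−B*,−A*]] for roots ω_N and transition moments;
both give the identical dipole strength S(ω) = 4πω/(3c)·Im Tr α(ω) for the
same γ.

Everything underneath — McMurchie–Davidson integrals over uncontracted
Cartesian Gaussians, restricted kinetic balance, Gaussian finite nuclei,
4c/2c SCF, Becke-grid LDA (Slater/VWN5) with a hybrid exact-exchange weight —
is implemented in the package; see `docs/methods.md` for the complete model
description and numerical conventions.

## Worked example

Sulfur L2,3-edge of H2S with the atomic-mean-field model (library API):

```python
import numpy as np
import x2cxas as x

mol, basis, rkb, ints = x.load_fixture("h2s")
xc = x.XCSpec(functional="svwn5", hfx=0.25)

refs = {el: x.solve_atomic_scf_4c(
            el, x.GaussianBasis(shells={el: basis.for_element(el)}), xc)
        for el in ("S", "H")}
model = x.build_hamiltonian("amfx2c", rkb, ints, xc, atomic_refs=refs)
scf = x.solve_scf_2c(model)

print(x.so_splitting_2p(scf.mo_energy))     # 1.28805  (eV, 2p1/2-2p3/2)

res4 = x.solve_scf_4c(rkb, ints, xc)        # 4c reference
m1e = x.build_hamiltonian("1ex2c", rkb, ints, xc)
print(x.so_splitting_2p(x.solve_scf_2c(m1e).mo_energy))   # 1.44759
print(x.so_splitting_2p(res4.mo_energy[res4.n_positive_start:]))  # 1.28794
```

The amf model reproduces the 4c sulfur 2p spin–orbit splitting to
1.1e-4 eV, while 1eX2C overestimates it by 12 % — the signature error the
picture-change corrections remove.  A spectrum over the edge:

```python
cvs = x.select_core_spinors(scf, rkb, ints, "S:2p")
hess = x.HessianOperator(scf, cvs=cvs)
P = model.dipole_2c()
props = {u: hess.property_mo(P[u]) for u in range(3)}
spec = x.ResponseSpec.window_ev(164.0, 171.0, 0.1, gamma_ev=0.15, cvs=cvs)
sol = x.solve_damped_response(hess, props, spec)
spectrum = x.assemble_spectra(sol, spec)
spectrum.to_tsv("h2s_l_edge.tsv")
```

The two strongest maxima land at 167.6 and 168.8 eV; their 1.2 eV separation
is the L2–L3 splitting read off the spectrum itself.

The same pipeline is available as a shell tool:

```bash
x2cxas run --geometry h2s.xyz --basis basis.yml --hamiltonian amfx2c \
           --functional svwn5 --hfx 0.25 --method dr \
           --window 164:171:0.1 --gamma 0.15 --cvs "S:2p" --out spec.tsv
x2cxas roots --geometry h2s.xyz --basis basis.yml --hamiltonian amfx2c \
             --functional svwn5 --cvs "S:2p" --nroots 50 --out sticks.json
x2cxas selftest
```

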