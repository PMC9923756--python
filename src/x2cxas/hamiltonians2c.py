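"""Two-component Hamiltonian models and the 2c SCF.

Four models are assembled here, differing in the decoupling parent and in the
static two-electron/xc picture-change correction Delta-F added to the 2c Fock

    F2c = h2c(tilde) + G2c[D] + Vxc2c[D] + Delta-F,

where G2c/Vxc2c are built from *untransformed* 2c integrals and overlap
distributions but the picture-change-transformed density:

* 1eX2C  — U from the one-electron Dirac Hamiltonian alone; Delta-F = 0.
* amfX2C — U from the parent (h4c + F_sup^{4c,2e}) with the superposed-atomic
  mean field; Delta-F is a superposition of per-atom corrections placed on
  the atomic diagonal blocks.
* eamfX2C — same U; Delta-F built in the full molecular basis from superposed
  atomic densities (nonzero interatomic blocks).
* mmfX2C — U and Delta-F from a converged molecular 4c SCF (exact positive-
  energy spectrum).

A 'nonrel' tag provides the nonrelativistic (Schroedinger) 2-spinor reference
used by limit tests; it shares the 2c machinery but bypasses the decoupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._xc import MolecularGrid
from .dirac4c import (
    AtomicReference,
    DiracFockBuilder,
    SCFConvergenceError,
    SCFResult4c,
    XCSpec,
    _DIIS,
    _k_contract,
    _occupations_aufbau,
    _xc_eval,
    from_pauli,
    pauli_components,
)
from .integrals_rkb import IntegralSet, Molecule, RKBSpace
from .x2c_transform import DecouplingU, one_step_decoupling, pc_density

MODEL_TAGS = ("1ex2c", "amfx2c", "eamfx2c", "mmfx2c", "nonrel")


@dataclass
class PCCorrection:
    """Static Hermitian 2c picture-change correction Delta-F."""

    matrix: np.ndarray  # orthonormal molecular 2c basis
    model: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        nrm = np.linalg.norm(self.matrix)
        if nrm > 0 and np.linalg.norm(self.matrix - self.matrix.conj().T) > 1e-8 * nrm:
            raise ValueError("picture-change correction must be Hermitian")


@dataclass
class HamiltonianModel:
    tag: str
    h2c: np.ndarray  # orthonormal-basis one-electron 2c Hamiltonian
    correction: PCCorrection
    U: DecouplingU = None
    builder2c: "TwoCompFockBuilder" = field(repr=False, default=None)
    builder4c: DiracFockBuilder = field(repr=False, default=None)

    def dipole_2c(self) -> np.ndarray:
        """Picture-change-transformed dipole components (3, n2c, n2c)."""
        dip4 = self.builder4c.dipole_raw()
        out = []
        for u in range(3):
            d_orth = self.builder4c.to_orth(dip4[u])
            if self.U is None:  # nonrelativistic reference: bare 2c dipole
                n = self.h2c.shape[0]
                out.append(d_orth[:n, :n])
            else:
                out.append(self.U.pc(d_orth).matrix)
        return np.array(out)


@dataclass
class SCFResult2c:
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    occupations: np.ndarray
    density: np.ndarray
    fock: np.ndarray
    energy: float
    converged: bool
    model: HamiltonianModel = field(repr=False, default=None)

    @property
    def n_positive_start(self) -> int:  # uniform interface with SCFResult4c
        return 0

    @property
    def occupied_positive(self):
        return np.nonzero(self.occupations > 1e-8)[0]


class TwoCompFockBuilder:
    """Untransformed 2c two-electron/xc machinery over the large-component basis."""

    def __init__(self, rkb: RKBSpace, ints: IntegralSet, xc: XCSpec, grid=None):
        self.rkb = rkb
        self.ints = ints
        self.xc = xc
        self.nL = rkb.nL
        self.X2 = np.kron(np.eye(2), rkb.X_L).astype(complex)
        self.S2 = np.kron(np.eye(2), ints.S_L).astype(complex)
        self._grid = grid

    @property
    def n2(self) -> int:
        return self.X2.shape[1]

    @property
    def grid(self) -> MolecularGrid:
        if self._grid is None:
            self._grid = MolecularGrid(self.ints.mol, *self.xc.grid)
        return self._grid

    def density_to_raw(self, D_orth):
        return self.X2 @ D_orth @ self.X2.conj().T

    def to_orth(self, A_raw):
        return self.X2.conj().T @ A_raw @ self.X2

    def operator_to_raw(self, A_orth):
        """Inverse transform for operators: A_raw = S X A_orth X' S."""
        SX = self.S2 @ self.X2
        return SX @ A_orth @ SX.conj().T

    def density_to_orth(self, D_raw):
        XS = self.X2.conj().T @ self.S2
        return XS @ D_raw @ XS.conj().T

    def coulomb_exchange(self, D_raw, hermitian=True):
        """J - zeta*K over the raw 2c basis for a (possibly complex) density."""
        nL = self.nL
        q = pauli_components(D_raw, nL)[0]
        if hermitian:
            q = q.real
        Gm = self.ints.eri_LLLL.reshape(nL * nL, nL * nL)
        if np.iscomplexobj(q):
            J = (Gm @ q.real.ravel() + 1j * (Gm @ q.imag.ravel())).reshape(nL, nL)
        else:
            J = (Gm @ q.ravel()).reshape(nL, nL)
        K = _k_contract(self.ints.k_matrix("LL"), D_raw, nL, nL)
        return np.kron(np.eye(2), J) - self.xc.hfx * K

    def densities_on_grid(self, D_raw):
        dL = pauli_components(D_raw, self.nL)
        ao = self.grid.ao_values(self.rkb.shells_L)
        rho = np.empty((4, len(self.grid.weights)))
        for k in range(4):
            rho[k] = np.einsum("mp,mp->p", ao, dL[k].real @ ao)
        return rho

    def vxc(self, D_raw):
        if not self.xc.needs_grid:
            return np.zeros_like(D_raw), 0.0
        rho = self.densities_on_grid(D_raw)
        e, v = _xc_eval(rho, self.xc)
        w = self.grid.weights
        ao = self.grid.ao_values(self.rkb.shells_L)
        V = np.zeros((4, self.nL, self.nL))
        for k in range(4):
            if np.max(np.abs(v[k])) < 1e-14:
                continue
            V[k] = (ao * (w * v[k])) @ ao.T
        return from_pauli(V), float(np.dot(w, e))

    def two_electron_xc(self, D_orth):
        """Orthonormal-basis 2e+xc Fock contribution and (e2, exc)."""
        D_raw = self.density_to_raw(D_orth)
        F2e = self.coulomb_exchange(D_raw)
        e2 = 0.5 * np.real(np.trace(F2e @ D_raw))
        Fxc, exc = self.vxc(D_raw)
        return self.to_orth(F2e + Fxc), (e2, exc)


# ---------------------------------------------------------------------------
# Atomic block embedding
# ---------------------------------------------------------------------------


def _atom_ranges(rkb: RKBSpace, mol: Molecule):
    fa = rkb.shells_L.function_atom()
    out = []
    for ia in range(mol.natoms):
        idx = np.nonzero(fa == ia)[0]
        out.append((int(idx[0]), int(idx[-1]) + 1))
    return out


def _embed_spin_block(target, block, rng_r, rng_c, n_r, n_c):
    """Add an atomic 2-spinor block into a molecular 2-spinor matrix."""
    nKr = block.shape[0] // 2
    nKc = block.shape[1] // 2
    for t in range(2):
        for s in range(2):
            target[t * n_r + rng_r[0]: t * n_r + rng_r[1],
                   s * n_c + rng_c[0]: s * n_c + rng_c[1]] += \
                block[t * nKr:(t + 1) * nKr, s * nKc:(s + 1) * nKc]
    return target


def _atomic_dF(ref: AtomicReference, xc: XCSpec):
    """Per-atom 2c picture-change correction in the atomic orthonormal basis."""
    b4 = ref.scf.builder
    U_K = one_step_decoupling(ref.scf.fock, b4.c, b4.n2L_orth, parent_tag="amf-parent")
    D_t = pc_density(U_K, ref.scf.density)
    D_raw = b4.density_to_raw(ref.scf.density)
    F2e, _ = b4.coulomb_exchange(D_raw)
    Fxc, _ = b4.vxc(D_raw)
    tilde = U_K.pc(b4.to_orth(F2e + Fxc)).matrix
    b2 = TwoCompFockBuilder(ref.rkb, ref.ints, xc, grid=b4._grid)
    untilde, _ = b2.two_electron_xc(D_t)
    dF = tilde - untilde
    return 0.5 * (dF + dF.conj().T), U_K, D_t, b2


def _superposed_density_raw4c(atomic_refs, mol, rkb):
    """Molecular raw-basis 4c density superposed from atomic blocks."""
    nL = rkb.nL
    ranges = _atom_ranges(rkb, mol)
    D = np.zeros((4 * nL, 4 * nL), dtype=complex)
    for ia, (sym, _z, _pos) in enumerate(mol.atoms):
        ref = atomic_refs[sym]
        bK = ref.scf.builder
        DK = bK.density_to_raw(ref.scf.density)
        nK = bK.nL
        rng = ranges[ia]
        comp = {
            "LL": DK[: 2 * nK, : 2 * nK], "LS": DK[: 2 * nK, 2 * nK:],
            "SL": DK[2 * nK:, : 2 * nK], "SS": DK[2 * nK:, 2 * nK:],
        }
        views = {
            "LL": D[: 2 * nL, : 2 * nL], "LS": D[: 2 * nL, 2 * nL:],
            "SL": D[2 * nL:, : 2 * nL], "SS": D[2 * nL:, 2 * nL:],
        }
        for key, blk in comp.items():
            _embed_spin_block(views[key], blk, rng, rng, nL, nL)
    return D


def _check_atomic_refs(atomic_refs, mol, xc):
    for sym, _z, _pos in mol.atoms:
        if sym not in atomic_refs:
            raise ValueError(f"missing atomic reference for element {sym}")
        ref = atomic_refs[sym]
        if ref.xc.key() != xc.key():
            raise ValueError(f"atomic reference for {sym} uses a different functional")


def amf_correction(atomic_refs: dict, mol: Molecule, rkb: RKBSpace,
                   ints: IntegralSet, xc: XCSpec) -> PCCorrection:
    """Superposition of per-atom 2c picture-change corrections (Eq.-24 style).

    Each unique element is computed once in its own atomic orthonormal basis,
    mapped back to the raw AO basis, placed on the atomic diagonal block of
    the molecular matrix, and finally transformed by the molecular
    orthonormalization map.
    """
    _check_atomic_refs(atomic_refs, mol, xc)
    ranges = _atom_ranges(rkb, mol)
    nL = rkb.nL
    per_element = {}
    F_raw = np.zeros((2 * nL, 2 * nL), dtype=complex)
    for ia, (sym, _z, _pos) in enumerate(mol.atoms):
        if sym not in per_element:
            ref = atomic_refs[sym]
            if [tuple(s) for s in _basis_signature(ref.rkb)] != \
               [tuple(s) for s in _basis_signature(rkb, ranges[ia])]:
                raise ValueError(f"basis mismatch between atomic reference and "
                                 f"molecule for element {sym}")
            dF_orth, _U, _Dt, b2 = _atomic_dF(ref, xc)
            per_element[sym] = b2.operator_to_raw(dF_orth)
        _embed_spin_block(F_raw, per_element[sym], ranges[ia], ranges[ia], nL, nL)
    X2 = np.kron(np.eye(2), rkb.X_L)
    dF = X2.conj().T @ F_raw @ X2
    return PCCorrection(matrix=0.5 * (dF + dF.conj().T), model="amfx2c",
                        provenance={"atoms": sorted(per_element)})


def _basis_signature(rkb, rng=None):
    sh = rkb.shells_L
    sig = []
    for ish in range(len(sh.exps)):
        if rng is not None:
            o = sh.offs[ish]
            if not (rng[0] <= o < rng[1]):
                continue
        sig.append((int(sh.ls[ish]), float(sh.exps[ish])))
    return sig


def eamf_correction(atomic_refs: dict, mol: Molecule, rkb: RKBSpace,
                    ints: IntegralSet, xc: XCSpec,
                    _cache: dict = None) -> PCCorrection:
    """Extended atomic mean-field correction in the full molecular basis.

    The molecular 4c density and its 2c counterpart are superposed from
    atomic blocks; the transformed molecular 2e+xc Fock of the former minus
    the untransformed-integral Fock of the latter gives Delta-F with nonzero
    interatomic blocks.
    """
    _check_atomic_refs(atomic_refs, mol, xc)
    b4 = DiracFockBuilder(rkb, ints, xc)
    D_sup = _superposed_density_raw4c(atomic_refs, mol, rkb)
    F2e, _ = b4.coulomb_exchange(D_sup)
    Fxc, _ = b4.vxc(D_sup)
    F2exc_orth = b4.to_orth(F2e + Fxc)
    U = one_step_decoupling(b4.to_orth(b4.h4c_raw()) + F2exc_orth, b4.c,
                            b4.n2L_orth, parent_tag="amf-parent")
    if _cache is not None:
        _cache["U"] = U
        _cache["builder4c"] = b4
    tilde = U.pc(F2exc_orth).matrix
    # superposed *transformed* 2c density, from per-atom decouplings
    nL = rkb.nL
    ranges = _atom_ranges(rkb, mol)
    D_raw2c = np.zeros((2 * nL, 2 * nL), dtype=complex)
    per_element = {}
    for ia, (sym, _z, _pos) in enumerate(mol.atoms):
        if sym not in per_element:
            ref = atomic_refs[sym]
            bK = ref.scf.builder
            U_K = one_step_decoupling(ref.scf.fock, bK.c, bK.n2L_orth,
                                      parent_tag="amf-parent")
            Dt = pc_density(U_K, ref.scf.density)
            per_element[sym] = np.kron(np.eye(2), ref.rkb.X_L) @ Dt @ \
                np.kron(np.eye(2), ref.rkb.X_L).conj().T
        _embed_spin_block(D_raw2c, per_element[sym], ranges[ia], ranges[ia], nL, nL)
    b2 = TwoCompFockBuilder(rkb, ints, xc, grid=b4._grid)
    D_t_orth = b2.density_to_orth(D_raw2c)
    untilde, _ = b2.two_electron_xc(D_t_orth)
    dF = tilde - untilde
    return PCCorrection(matrix=0.5 * (dF + dF.conj().T), model="eamfx2c",
                        provenance={"atoms": sorted(per_element)})


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def build_hamiltonian(tag: str, rkb: RKBSpace, ints: IntegralSet, xc: XCSpec,
                      atomic_refs: dict = None, scf4c: SCFResult4c = None,
                      grid=None) -> HamiltonianModel:
    """Assemble a HamiltonianModel for one of MODEL_TAGS."""
    tag = tag.lower()
    if tag not in MODEL_TAGS:
        raise ValueError(f"unknown Hamiltonian model {tag!r}")
    b4 = scf4c.builder if (tag == "mmfx2c" and scf4c is not None) else \
        DiracFockBuilder(rkb, ints, xc)
    if grid is not None:
        b4._grid = grid
    b2 = TwoCompFockBuilder(rkb, ints, xc, grid=b4._grid if xc.needs_grid else None)
    n2L = b4.n2L_orth
    h4c_orth = b4.to_orth(b4.h4c_raw())
    zero = PCCorrection(matrix=np.zeros((n2L, n2L), dtype=complex), model=tag)

    if tag == "nonrel":
        hnr = np.kron(np.eye(2), ints.T_L + ints.V_L).astype(complex)
        h2c = b2.to_orth(hnr)
        return HamiltonianModel(tag=tag, h2c=h2c, correction=zero, U=None,
                                builder2c=b2, builder4c=b4)
    if tag == "1ex2c":
        U = one_step_decoupling(h4c_orth, b4.c, n2L, parent_tag="1e")
        return HamiltonianModel(tag=tag, h2c=U.pc(h4c_orth).matrix,
                                correction=zero, U=U, builder2c=b2, builder4c=b4)
    if tag == "mmfx2c":
        if scf4c is None or not scf4c.converged:
            raise ValueError("mmfX2C requires a converged 4c SCF result")
        from .x2c_transform import mmf_reduce

        U, _F2c, dF, _C = mmf_reduce(scf4c, xc)
        return HamiltonianModel(
            tag=tag, h2c=U.pc(h4c_orth).matrix,
            correction=PCCorrection(matrix=dF, model=tag), U=U,
            builder2c=b2, builder4c=b4,
        )
    # amf / eamf share the superposed-atomic-parent decoupling
    if not atomic_refs:
        raise ValueError(f"{tag} requires atomic references")
    cache = {}
    eamf = eamf_correction(atomic_refs, ints.mol, rkb, ints, xc, _cache=cache)
    U = cache["U"]
    if tag == "eamfx2c":
        corr = eamf
    else:
        corr = amf_correction(atomic_refs, ints.mol, rkb, ints, xc)
    return HamiltonianModel(tag=tag, h2c=U.pc(h4c_orth).matrix, correction=corr,
                            U=U, builder2c=b2, builder4c=cache["builder4c"])


def fock_2c(model: HamiltonianModel, D_orth: np.ndarray):
    """F = h2c + G2c[D] + Vxc2c[D] + Delta-F and the model total energy.

    The static correction enters the energy with weight 1/2, consistent with
    its role as a correction to the two-electron part of the Fock matrix.
    """
    G, (e2, exc) = model.builder2c.two_electron_xc(D_orth)
    dF = model.correction.matrix
    F = model.h2c + G + dF
    e1 = np.real(np.trace(model.h2c @ D_orth))
    ecorr = 0.5 * np.real(np.trace(dF @ D_orth))
    etot = e1 + e2 + exc + ecorr + model.builder2c.ints.mol.nuclear_repulsion()
    return F, etot


def solve_scf_2c(model: HamiltonianModel, n_electrons: int = None,
                 guess: np.ndarray = None, conv_energy: float = 1e-9,
                 conv_dens: float = 1e-7, maxiter: int = 150,
                 average_open_shell: bool = False, diis_size: int = 8) -> SCFResult2c:
    """2c SCF for the given Hamiltonian model (orthonormal basis, DIIS)."""
    mol = model.builder2c.ints.mol
    if n_electrons is None:
        n_electrons = mol.n_electrons
    if not average_open_shell and n_electrons % 2:
        raise ValueError("closed-shell SCF requires an even electron count")
    dim = model.h2c.shape[0]

    def diag_occupy(F):
        eps, C = np.linalg.eigh(F)
        occ = _occupations_aufbau(eps, n_electrons, 0, average_open_shell)
        return eps, C, occ, (C * occ) @ C.conj().T

    if guess is None:
        _, _, _, D = diag_occupy(model.h2c + model.correction.matrix)
    else:
        D = guess
    diis = _DIIS(diis_size)
    e_last = np.inf
    history = []
    for it in range(1, maxiter + 1):
        F, etot = fock_2c(model, D)
        err = F @ D - D @ F
        F = diis.update(F, err)
        eps, C, occ, D_new = diag_occupy(F)
        d_rms = np.linalg.norm(D_new - D) / dim
        de = etot - e_last
        history.append((it, etot, de, d_rms))
        converged = abs(de) < conv_energy and d_rms < conv_dens
        D = D_new
        e_last = etot
        if converged:
            F_final, etot = fock_2c(model, D)
            return SCFResult2c(mo_coeff=C, mo_energy=eps, occupations=occ,
                               density=D, fock=F_final, energy=etot,
                               converged=True, model=model)
    raise SCFConvergenceError(
        f"2c SCF ({model.tag}) not converged in {maxiter} iterations; "
        f"residual history tail: {history[-3:]}", history)


def so_splitting_2p(energies: np.ndarray, occ_start: int = 0) -> float:
    """2p(1/2)-2p(3/2) orbital-energy splitting (eV) from sorted spinor energies.

    Identifies the six 2p core spinors as entries [4:10] of the sorted spinor
    energies (after the 1s and 2s Kramers pairs); the two lowest of them form
    the j=1/2 pair.  Returns eps(2p3/2) - eps(2p1/2) averaged over each
    multiplet.
    """
    from .dirac4c import HARTREE_EV

    core = energies[occ_start + 4: occ_start + 10]
    if len(core) < 6:
        raise ValueError("need at least ten occupied spinors for a 2p shell")
    e12 = np.mean(core[:2])
    e32 = np.mean(core[2:6])
    return (e32 - e12) * HARTREE_EV
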