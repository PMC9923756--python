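"""Four-component Dirac-Kohn-Sham machinery.

Matrix representation
---------------------
All 4c operators are stored over the "modified Dirac" RKB basis: the
large-component 2-spinor space L (dimension 2*nL, spin index slow) stacked on
the RKB small-component space S (also 2*nL in the raw basis; its functions are
(1/2c) sigma.p chi_mu).  In this representation the one-electron Dirac
operator (rest mass removed) and the metric read

    h4c = [[ V,            T          ],        M4c = [[ S, 0          ],
           [ T,  W/(4c^2) - T        ]]                [ 0, T/(2c^2)   ]]

with W_{mu nu} = <sigma.p chi_mu| V |sigma.p chi_nu> carrying the one-electron
spin-orbit coupling.  Two-electron and xc contributions are evaluated by
expanding the small component in the auxiliary scalar basis Phi through the
derivative maps of :class:`~x2cxas.integrals_rkb.RKBSpace`, so that every
Fock contribution reduces to scalar ERI classes (LL|LL), (LL|PhiPhi),
(PhiPhi|PhiPhi) and scalar xc matrices contracted with Pauli algebra.

SCF is performed in the canonically orthonormalized basis; densities are
mapped to the raw basis for Fock builds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from ._xc import MolecularGrid, closed_shell_kernel, noncollinear_potential
from .integrals_rkb import (
    GaussianBasis,
    IntegralSet,
    Molecule,
    RKBSpace,
    build_rkb_integrals,
    pauli_matrices,
)

HARTREE_EV = 27.211386245988


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


# ---------------------------------------------------------------------------
# Spinor / Pauli algebra helpers
# ---------------------------------------------------------------------------

_SIGMA = pauli_matrices()


def pauli_components(A: np.ndarray, n: int) -> np.ndarray:
    """Scalar Pauli components a_k of a 2-spinor matrix A (spin index slow).

    a_k[mu, nu] = sum_{tau sigma} (sigma_k)_{tau sigma} A[(sigma mu), (tau nu)]
    so that a_0 is the charge component and a_1..a_3 the spin components of
    the associated density/overlap distribution.
    """
    A4 = A.reshape(2, n, 2, n)
    return np.stack([np.einsum("ts,smtn->mn", _SIGMA[k], A4) for k in range(4)])


def from_pauli(comps: np.ndarray) -> np.ndarray:
    """Spinor matrix sum_k sigma_k (x) V_k from scalar Pauli components."""
    return sum(np.kron(_SIGMA[k], comps[k]) for k in range(4))


def time_reversal(A: np.ndarray, n: int) -> np.ndarray:
    """K A K^-1 with the spinor time-reversal operation K = (i sigma_y) K_0.

    ``A`` is a single spin (x) scalar block of scalar dimension ``n`` (a 2c
    operator); 4c operators should use :func:`time_reversal_4c`.
    """
    isy = np.kron(1j * np.asarray(_SIGMA[2]), np.eye(n))
    return isy @ A.conj() @ isy.conj().T


def time_reversal_4c(A: np.ndarray, nL: int, nS: int) -> np.ndarray:
    """Time reversal of a 4c operator with L/S scalar dimensions (nL, nS)."""
    isy = sla.block_diag(np.kron(1j * np.asarray(_SIGMA[2]), np.eye(nL)),
                         np.kron(1j * np.asarray(_SIGMA[2]), np.eye(nS)))
    return isy @ A.conj() @ isy.conj().T


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class XCSpec:
    """Exchange-correlation specification.

    ``functional``: 'hf' (pure exact exchange), 'slater', or 'svwn5' (LDA
    exchange + VWN5 correlation).  ``hfx`` is the exact-exchange weight zeta;
    the density-functional exchange is scaled by (1 - zeta).  ``grid`` is the
    (n_radial, n_theta, n_phi) per-atom quadrature specification.
    """

    functional: str = "svwn5"
    hfx: float = 0.25
    grid: tuple = (35, 10, 20)

    def __post_init__(self):
        if not 0.0 <= self.hfx <= 1.0:
            raise ValueError("hfx weight must lie in [0, 1]")
        if self.functional == "hf":
            self.hfx = 1.0
        if self.functional not in ("hf", "slater", "svwn5"):
            raise ValueError(f"unknown functional {self.functional!r}")

    @property
    def needs_grid(self) -> bool:
        return self.functional != "hf"

    @property
    def x_scale(self) -> float:
        return 1.0 - self.hfx

    def key(self) -> tuple:
        return (self.functional, round(self.hfx, 10), tuple(self.grid))


class Operator4c:
    """Complex matrix over flattened 4c indices with L/S block views."""

    def __init__(self, matrix: np.ndarray, n2L: int, hermitian: bool = True):
        self.matrix = np.asarray(matrix, dtype=complex)
        self.n2L = n2L
        self.hermitian = hermitian
        if hermitian:
            nrm = np.linalg.norm(self.matrix)
            if nrm > 0 and np.linalg.norm(self.matrix - self.matrix.conj().T) > 1e-10 * nrm:
                raise ValueError("operator flagged Hermitian is not")

    @property
    def LL(self):
        return self.matrix[: self.n2L, : self.n2L]

    @property
    def LS(self):
        return self.matrix[: self.n2L, self.n2L:]

    @property
    def SL(self):
        return self.matrix[self.n2L:, : self.n2L]

    @property
    def SS(self):
        return self.matrix[self.n2L:, self.n2L:]


@dataclass
class Density4c:
    """4c one-particle reduced density matrix plus its electron count."""

    matrix: np.ndarray
    n_electrons: float

    def trace_error(self, metric: np.ndarray) -> float:
        return abs(np.real(np.trace(metric @ self.matrix)) - self.n_electrons)


@dataclass
class SCFResult4c:
    mo_coeff: np.ndarray  # orthonormal-basis MO coefficients, all branches
    mo_energy: np.ndarray
    occupations: np.ndarray  # per-MO occupation numbers (fractional allowed)
    density: np.ndarray  # orthonormal-basis density
    fock: np.ndarray  # orthonormal-basis converged Fock
    energy: float
    converged: bool
    n_positive_start: int  # index of the first positive-energy MO
    builder: "DiracFockBuilder" = field(repr=False, default=None)

    @property
    def positive_energies(self):
        return self.mo_energy[self.n_positive_start:]

    @property
    def occupied_positive(self):
        occ = self.occupations[self.n_positive_start:]
        return np.nonzero(occ > 1e-8)[0]


@dataclass
class AtomicReference:
    """Configuration-averaged spherical atomic 4c solution."""

    element: str
    scf: SCFResult4c
    rkb: RKBSpace
    ints: IntegralSet
    xc: XCSpec


# ---------------------------------------------------------------------------
# Fock builder
# ---------------------------------------------------------------------------


class DiracFockBuilder:
    """Assembles 4c Fock matrices and energies for a fixed (rkb, ints, xc)."""

    def __init__(self, rkb: RKBSpace, ints: IntegralSet, xc: XCSpec):
        self.rkb = rkb
        self.ints = ints
        self.xc = xc
        self.nL = rkb.nL
        self.nP = rkb.nP
        self.c = rkb.c
        self.M = rkb.small_map()  # raw RKB small -> Phi (x) spin
        self._grid = None
        self._h_raw = None
        self._X4 = None

    # -- one-electron pieces -------------------------------------------------

    @property
    def grid(self) -> MolecularGrid:
        if self._grid is None:
            self._grid = MolecularGrid(self.ints.mol, *self.xc.grid)
        return self._grid

    def h4c_raw(self) -> np.ndarray:
        if self._h_raw is None:
            n = self.nL
            I2 = np.eye(2)
            W = np.zeros((2 * n, 2 * n), dtype=complex)
            for u in range(3):
                for v in range(3):
                    m = self.rkb.Du[u].T @ self.ints.V_P @ self.rkb.Du[v]
                    W += np.kron(_SIGMA[u + 1] @ _SIGMA[v + 1], m)
            T2 = np.kron(I2, self.ints.T_L).astype(complex)
            h = np.zeros((4 * n, 4 * n), dtype=complex)
            h[: 2 * n, : 2 * n] = np.kron(I2, self.ints.V_L)
            h[: 2 * n, 2 * n:] = T2
            h[2 * n:, : 2 * n] = T2
            h[2 * n:, 2 * n:] = W / (4.0 * self.c**2) - T2
            self._h_raw = h
        return self._h_raw

    def metric_raw(self) -> np.ndarray:
        I2 = np.eye(2)
        return sla.block_diag(
            np.kron(I2, self.ints.S_L),
            np.kron(I2, self.ints.T_L / (2.0 * self.c**2)),
        ).astype(complex)

    def X4(self) -> np.ndarray:
        """Raw -> orthonormal transformation (canonical, per component)."""
        if self._X4 is None:
            I2 = np.eye(2)
            self._X4 = sla.block_diag(
                np.kron(I2, self.rkb.X_L), np.kron(I2, self.rkb.X_S)
            ).astype(complex)
        return self._X4

    @property
    def n2L_orth(self) -> int:
        return self.rkb.n2L

    def to_orth(self, A_raw: np.ndarray) -> np.ndarray:
        X = self.X4()
        return X.conj().T @ A_raw @ X

    def density_to_raw(self, D_orth: np.ndarray) -> np.ndarray:
        X = self.X4()
        return X @ D_orth @ X.conj().T

    # -- dipole operator -----------------------------------------------------

    def dipole_raw(self) -> np.ndarray:
        """P_u = -(r - R) over the 4c basis; shape (3, 4nL, 4nL)."""
        n = self.nL
        I2 = np.eye(2)
        out = np.zeros((3, 4 * n, 4 * n), dtype=complex)
        for u in range(3):
            out[u, : 2 * n, : 2 * n] = np.kron(I2, -self.ints.dip_L[u])
            dP = np.kron(I2, -self.ints.dip_P[u]).astype(complex)
            out[u, 2 * n:, 2 * n:] = self.M.conj().T @ dP @ self.M
        return out

    # -- density expansion ---------------------------------------------------

    def expand_density(self, D_raw: np.ndarray):
        """(D_LL, D_PP, D_LP): spinor densities over L, Phi and cross spaces."""
        n2 = 2 * self.nL
        D_LL = D_raw[:n2, :n2]
        D_LS = D_raw[:n2, n2:]
        D_SS = D_raw[n2:, n2:]
        D_PP = self.M @ D_SS @ self.M.conj().T
        D_LP = D_LS @ self.M.conj().T
        return D_LL, D_PP, D_LP

    # -- two-electron contribution -------------------------------------------

    def coulomb_exchange(self, D_raw: np.ndarray, hermitian: bool = True):
        """J - zeta*K over the raw 4c basis, plus the 2e energy.

        ``hermitian=False`` supports complex transition densities (response).
        """
        nL, nP = self.nL, self.nP
        zeta = self.xc.hfx
        ints = self.ints
        D_LL, D_PP, D_LP = self.expand_density(D_raw)
        qL = pauli_components(D_LL, nL)[0]
        qP = pauli_components(D_PP, nP)[0]
        if hermitian:
            qL = qL.real
            qP = qP.real

        G_LL = ints.eri_LLLL
        G_LP = ints.eri_LLPP
        G_PP = ints.eri_PPPP

        def _jc(Gm, q):
            if np.iscomplexobj(q):
                return Gm @ q.real.ravel() + 1j * (Gm @ q.imag.ravel())
            return Gm @ q.ravel()

        JL = (_jc(G_LL.reshape(nL * nL, -1), qL)
              + _jc(G_LP.reshape(nL * nL, -1), qP)).reshape(nL, nL)
        JP = (_jc(G_LP.reshape(nL * nL, -1).T, qL)
              + _jc(G_PP.reshape(nP * nP, -1), qP)).reshape(nP, nP)

        K_LL = _k_contract(ints.k_matrix("LL"), D_LL, nL, nL)
        K_PP = _k_contract(ints.k_matrix("PP"), D_PP, nP, nP)
        K_LP = _k_contract(ints.k_matrix("LP"), D_LP, nL, nP)

        F = np.zeros_like(D_raw)
        n2 = 2 * nL
        F[:n2, :n2] = np.kron(np.eye(2), JL) - zeta * K_LL
        F[n2:, n2:] = self.M.conj().T @ (np.kron(np.eye(2), JP) - zeta * K_PP) @ self.M
        F[:n2, n2:] = -zeta * (K_LP @ self.M)
        F[n2:, :n2] = F[:n2, n2:].conj().T
        e2 = 0.5 * np.real(np.trace(F @ D_raw))
        return F, e2

    # -- exchange-correlation contribution -------------------------------------

    def densities_on_grid(self, D_raw: np.ndarray):
        """Charge and spin densities rho_k(r) on the molecular grid."""
        nL, nP = self.nL, self.nP
        D_LL, D_PP, _ = self.expand_density(D_raw)
        dL = pauli_components(D_LL, nL)
        dP = pauli_components(D_PP, nP)
        aoL = self.grid.ao_values(self.rkb.shells_L)
        aoP = self.grid.ao_values(self.rkb.shells_P)
        rho = np.empty((4, len(self.grid.weights)))
        for k in range(4):
            rho[k] = np.einsum("mp,mp->p", aoL, dL[k].real @ aoL) + np.einsum(
                "mp,mp->p", aoP, dP[k].real @ aoP
            )
        return rho

    def vxc(self, D_raw: np.ndarray):
        """Noncollinear xc Fock contribution (raw basis) and xc energy."""
        if not self.xc.needs_grid:
            return np.zeros_like(D_raw), 0.0
        nL, nP = self.nL, self.nP
        rho = self.densities_on_grid(D_raw)
        e, v = _xc_eval(rho, self.xc)
        w = self.grid.weights
        exc = float(np.dot(w, e))
        aoL = self.grid.ao_values(self.rkb.shells_L)
        aoP = self.grid.ao_values(self.rkb.shells_P)
        VL = np.zeros((4, nL, nL))
        VP = np.zeros((4, nP, nP))
        for k in range(4):
            if np.max(np.abs(v[k])) < 1e-14:
                continue
            wv = w * v[k]
            VL[k] = (aoL * wv) @ aoL.T
            VP[k] = (aoP * wv) @ aoP.T
        F = np.zeros_like(D_raw)
        n2 = 2 * nL
        F[:n2, :n2] = from_pauli(VL)
        F[n2:, n2:] = self.M.conj().T @ from_pauli(VP) @ self.M
        return F, exc

    # -- total Fock ------------------------------------------------------------

    def fock_raw(self, D_raw: np.ndarray):
        F2e, e2 = self.coulomb_exchange(D_raw)
        Fxc, exc = self.vxc(D_raw)
        h = self.h4c_raw()
        F = h + F2e + Fxc
        e1 = np.real(np.trace(h @ D_raw))
        etot = e1 + e2 + exc + self.ints.mol.nuclear_repulsion()
        return F, etot


def _k_contract(Kmat: np.ndarray, D: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Spinor exchange K[(t m),(s v)] = sum_{kl} (mk|lv) D[(t k),(s l)].

    ``Kmat`` is the exchange-ordered real ERI matrix; the four complex spin
    blocks are contracted in one real GEMM.
    """
    D4 = D.reshape(2, n1, 2, n2)
    rhs = np.empty((n1 * n2, 8))
    for i, (t, s) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        blk = D4[t, :, s, :].ravel()
        rhs[:, 2 * i] = blk.real
        rhs[:, 2 * i + 1] = blk.imag
    out = Kmat @ rhs
    K = np.empty((2, n1, 2, n2), dtype=complex)
    for i, (t, s) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        K[t, :, s, :] = (out[:, 2 * i] + 1j * out[:, 2 * i + 1]).reshape(n1, n2)
    return K.reshape(2 * n1, 2 * n2)


def _xc_eval(rho, xc: XCSpec):
    """Energy density and Pauli-component potentials with hybrid scaling."""
    from ._xc import lda_energy_potential

    ex_scale = xc.x_scale
    if xc.functional == "slater":
        e, v = noncollinear_potential(rho[0], rho[1:], "slater")
        return ex_scale * e, ex_scale * v
    # svwn5: scale only the exchange part
    e_x, v_x = noncollinear_potential(rho[0], rho[1:], "slater")
    e_full, v_full = noncollinear_potential(rho[0], rho[1:], "svwn5")
    e = ex_scale * e_x + (e_full - e_x)
    v = ex_scale * v_x + (v_full - v_x)
    return e, v


def density_from_mos(coeffs: np.ndarray, occupations=None) -> np.ndarray:
    """D = sum_i f_i C_i C_i^dagger over the given (orthonormal-basis) MOs."""
    if coeffs.ndim != 2:
        raise ValueError("expected a (nbasis, nocc) coefficient matrix")
    if coeffs.shape[1] > coeffs.shape[0]:
        raise ValueError("more occupied orbitals than basis functions")
    if occupations is None:
        occupations = np.ones(coeffs.shape[1])
    return (coeffs * occupations) @ coeffs.conj().T


# ---------------------------------------------------------------------------
# SCF drivers
# ---------------------------------------------------------------------------


class _DIIS:
    def __init__(self, size=8):
        self.size = size
        self.focks = []
        self.errors = []

    def update(self, F, err):
        self.focks.append(F.copy())
        self.errors.append(err.ravel().copy())
        if len(self.focks) > self.size:
            self.focks.pop(0)
            self.errors.pop(0)
        n = len(self.focks)
        if n < 2:
            return F
        B = -np.ones((n + 1, n + 1), dtype=complex)
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = np.vdot(self.errors[i], self.errors[j])
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            coef = np.linalg.solve(B, rhs)
        except np.linalg.LinAlgError:
            return F
        out = np.zeros_like(F)
        for i in range(n):
            out += coef[i] * self.focks[i]
        return out


def _occupations_aufbau(energies, n_elec, branch_start, average_open_shell,
                        cluster_tol=(0.02, 0.02)):
    """Occupation vector over all MOs; fractional averaging over the open shell.

    Shells are identified by clustering positive-branch eigenvalues with a
    combined relative/absolute gap tolerance; if the electron count exhausts
    inside a cluster the remaining electrons are spread evenly over it
    (Kramers-restricted configuration average).
    """
    occ = np.zeros(len(energies))
    pos = energies[branch_start:]
    if n_elec > len(pos):
        raise SCFConvergenceError("electron count exceeds positive-branch dimension")
    if not average_open_shell:
        occ[branch_start: branch_start + n_elec] = 1.0
        return occ
    rel, absr = cluster_tol
    clusters = []
    start = 0
    for i in range(1, len(pos) + 1):
        if i == len(pos) or (pos[i] - pos[i - 1]) > max(rel * abs(pos[i - 1]), absr):
            clusters.append((start, i))
            start = i
        if start > 0 and sum(c[1] - c[0] for c in clusters) >= n_elec:
            break
    left = float(n_elec)
    for c0, c1 in clusters:
        g = c1 - c0
        if left >= g:
            occ[branch_start + c0: branch_start + c1] = 1.0
            left -= g
        elif left > 0:
            occ[branch_start + c0: branch_start + c1] = left / g
            left = 0.0
    return occ


def solve_scf_4c(rkb: RKBSpace, ints: IntegralSet, xc: XCSpec,
                 guess: np.ndarray = None, n_electrons: int = None,
                 conv_energy: float = 1e-9, conv_dens: float = 1e-7,
                 maxiter: int = 150, average_open_shell: bool = False,
                 diis_size: int = 8, level_shift: float = 0.0,
                 damping: float = 0.0) -> SCFResult4c:
    """Static 4c SCF in the orthonormal basis (DIIS-accelerated).

    ``guess`` is an orthonormal-basis density; the default is the bare-nucleus
    (h4c) guess.  Closed-shell molecules require an even electron count;
    atoms may use ``average_open_shell`` for the Kramers-restricted
    configuration average.
    """
    builder = DiracFockBuilder(rkb, ints, xc)
    mol = ints.mol
    if n_electrons is None:
        n_electrons = mol.n_electrons
    if not average_open_shell and n_electrons % 2:
        raise ValueError("closed-shell SCF requires an even electron count")
    h_orth = builder.to_orth(builder.h4c_raw())
    dim = h_orth.shape[0]
    c2 = rkb.c**2

    def diag_occupy(F):
        eps, C = np.linalg.eigh(F)
        branch_start = int(np.searchsorted(eps, -c2))
        occ = _occupations_aufbau(eps, n_electrons, branch_start, average_open_shell)
        D = (C * occ) @ C.conj().T
        return eps, C, occ, D, branch_start

    if guess is None:
        _, _, _, D, _ = diag_occupy(h_orth)
    else:
        D = guess
    diis = _DIIS(diis_size)
    e_last = np.inf
    history = []
    for it in range(1, maxiter + 1):
        D_raw = builder.density_to_raw(D)
        F_raw, etot = builder.fock_raw(D_raw)
        F = builder.to_orth(F_raw)
        err = F @ D - D @ F
        err_norm = np.linalg.norm(err) / dim
        F = diis.update(F, err)
        if level_shift > 0.0:
            F = F + level_shift * (np.eye(dim) - D)
        eps, C, occ, D_new, branch_start = diag_occupy(F)
        if damping > 0.0:
            D_new = (1.0 - damping) * D_new + damping * D
        d_rms = np.linalg.norm(D_new - D) / dim
        de = etot - e_last
        history.append((it, etot, de, d_rms, err_norm))
        converged = abs(de) < conv_energy and d_rms < conv_dens
        D = D_new
        e_last = etot
        if converged:
            return SCFResult4c(
                mo_coeff=C, mo_energy=eps, occupations=occ, density=D,
                fock=F, energy=etot, converged=True,
                n_positive_start=branch_start, builder=builder,
            )
    raise SCFConvergenceError(
        f"4c SCF not converged in {maxiter} iterations "
        f"(last dE={history[-1][2]:.3e}, dD={history[-1][3]:.3e})",
        history,
    )


def fock_4c(density: Density4c, builder: DiracFockBuilder) -> Operator4c:
    """F = h4c + G[D] + Vxc[D] over the raw 4c basis."""
    D = density.matrix
    nrm = np.linalg.norm(D)
    if nrm > 0 and np.linalg.norm(D - D.conj().T) > 1e-8 * nrm:
        raise ValueError("density must be Hermitian")
    F, _ = builder.fock_raw(D)
    return Operator4c(F, n2L=2 * builder.nL, hermitian=True)


def solve_atomic_scf_4c(element: str, basis: GaussianBasis, xc: XCSpec,
                        c: float = None, finite_nucleus: bool = True,
                        **scf_kw) -> AtomicReference:
    """Kramers-restricted, configuration-averaged spherical atomic solution."""
    from .integrals_rkb import SPEED_OF_LIGHT, Z_OF

    z = Z_OF.get(element)
    if z is None:
        raise ValueError(f"unknown element {element!r}")
    mol = Molecule(atoms=[(element, z, np.zeros(3))], finite_nucleus=finite_nucleus)
    rkb, ints = build_rkb_integrals(mol, basis, c=c or SPEED_OF_LIGHT)
    try:
        scf = solve_scf_4c(rkb, ints, xc, average_open_shell=True, **scf_kw)
    except SCFConvergenceError:
        # fractional-occupation limit cycles: retry with density damping
        try:
            scf = solve_scf_4c(rkb, ints, xc, average_open_shell=True,
                               damping=0.35, maxiter=300, **scf_kw)
        except SCFConvergenceError as exc:
            raise SCFConvergenceError(f"atomic SCF failed for {element}: {exc}",
                                      exc.history) from exc
    return AtomicReference(element=element, scf=scf, rkb=rkb, ints=ints, xc=xc)
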