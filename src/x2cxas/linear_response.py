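"""Linear-response TDDFT on 2c or 4c references.

Orbital-Hessian blocks (complex spinor reference, chemists' notation,
zeta-scaled exact exchange, adiabatic closed-shell LDA kernel):

    A_{ai,bj} = delta_ab delta_ij (eps_a - eps_i) + (ai|jb) - zeta (ab|ji) + f_{ai,jb}
    B_{ai,bj} = (ai|bj) - zeta (aj|bi) + f-term

Both are realized as *actions* on trial matrices T (N_v x N_o) through one
generalized Fock build per action,

    (A T)_{ai} = omega_ai T_ai + [C_v' g(C_v T C_o') C_o]_{ai},
    (B T)_{ai} =               [C_v' g(C_o T^T C_v') C_o]_{ai},

where g(rho) = J(rho) - zeta K(rho) + f_xc(rho).  The damped-response
equation and the eigenvalue (Casida) equation

    ([[A, B], [B*, A*]] - (omega + i gamma) [[1, 0], [0, -1]]) (X; Y) = -(P; P*)
    [[A, B], [-B*, -A*]] (X_N; Y_N) = omega_N (X_N; Y_N)

are solved by preconditioned iterative subspace methods; the complex
polarizability follows as alpha_uv = -(P_u' X_v + P_u^T Y_v) (damped route)
or from transition moments t_u = P_u' X_N + P_u^T Y_N with Lorentzian
damping (sum-over-states route).  Both routes yield identical spectra for
the same gamma.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._xc import closed_shell_kernel
from .dirac4c import HARTREE_EV, SCFResult4c, XCSpec, from_pauli, pauli_components
from .hamiltonians2c import SCFResult2c


class ResponseError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Specifications and result containers
# ---------------------------------------------------------------------------


@dataclass
class ResponseSpec:
    """Damped-response / spectrum parameters (atomic units internally)."""

    frequencies: np.ndarray  # au
    gamma: float = 0.15 / HARTREE_EV  # au; 0.15 eV default
    components: tuple = (0, 1, 2)
    cvs: tuple = None  # occupied-orbital indices (within the occupied set)
    batch_size: int = 100
    solver_tol: float = 1e-10
    max_iter: int = 200

    def __post_init__(self):
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, float))
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if self.gamma <= 0:
            raise ValueError("damping gamma must be positive for damped response")

    @classmethod
    def window_ev(cls, lo: float, hi: float, step: float = 0.1,
                  gamma_ev: float = 0.15, **kw) -> "ResponseSpec":
        om = np.arange(lo, hi + 0.5 * step, step) / HARTREE_EV
        return cls(frequencies=om, gamma=gamma_ev / HARTREE_EV, **kw)


@dataclass
class ResponseSolution:
    """Damped response vectors per Cartesian component and frequency."""

    frequencies: np.ndarray
    gamma: float
    X: dict  # u -> array (n_freq, Nv, No)
    Y: dict
    property_mo: dict  # u -> (Nv, No)
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ExcitationSet:
    """Casida roots with transition vectors and dipoles."""

    omegas: np.ndarray  # ascending, au
    X: np.ndarray  # (N, Nv, No)
    Y: np.ndarray
    tdip: np.ndarray  # (3, N) transition dipole moments
    diagnostics: dict = field(default_factory=dict)

    @property
    def oscillator_strengths(self) -> np.ndarray:
        return (2.0 / 3.0) * self.omegas * np.sum(np.abs(self.tdip) ** 2, axis=0)


@dataclass
class Spectrum:
    """Dipole strength function S(omega) and complex polarizability."""

    omega_ev: np.ndarray
    strength: np.ndarray
    alpha: np.ndarray  # (3, 3, n_freq) complex
    gamma_ev: float
    normalized: bool = False

    def normalize(self) -> "Spectrum":
        mx = np.max(np.abs(self.strength))
        return Spectrum(self.omega_ev, self.strength / mx if mx > 0 else self.strength,
                        self.alpha, self.gamma_ev, normalized=True)

    def to_tsv(self, path):
        header = ["omega_eV", "S"]
        cols = [self.omega_ev, self.strength]
        for u in range(3):
            for v in range(3):
                header += [f"Re_alpha_{'xyz'[u]}{'xyz'[v]}", f"Im_alpha_{'xyz'[u]}{'xyz'[v]}"]
                cols += [self.alpha[u, v].real, self.alpha[u, v].imag]
        data = np.column_stack(cols)
        np.savetxt(path, data, header="\t".join(header),
                   fmt="%.17e", delimiter="\t", comments="# ")

    @classmethod
    def from_tsv(cls, path, gamma_ev=0.0):
        data = np.atleast_2d(np.loadtxt(path))
        alpha = np.empty((3, 3, data.shape[0]), dtype=complex)
        k = 2
        for u in range(3):
            for v in range(3):
                alpha[u, v] = data[:, k] + 1j * data[:, k + 1]
                k += 2
        return cls(omega_ev=data[:, 0], strength=data[:, 1], alpha=alpha,
                   gamma_ev=gamma_ev)


def sticks_to_json(exc: ExcitationSet, path):
    recs = []
    for n in range(len(exc.omegas)):
        recs.append({
            "omega_eV": exc.omegas[n] * HARTREE_EV,
            "f": float(exc.oscillator_strengths[n]),
            "t2_xyz": [float(np.abs(exc.tdip[u, n]) ** 2) for u in range(3)],
        })
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)


def sticks_from_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Orbital Hessian
# ---------------------------------------------------------------------------


class HessianOperator:
    """Implicit action of A and B on (Nv x No) trial matrices.

    Works on a converged 2c (model) or 4c (reference) SCF result.  With a
    nonempty CVS index set the occupied space is restricted to the listed
    core spinors.  ``coupling=False`` reduces A to the bare orbital-energy
    differences and B to zero (test mode).
    """

    def __init__(self, scf, cvs=None, coupling=True, kernel="alda"):
        self.scf = scf
        self.coupling = coupling
        self.is4c = isinstance(scf, SCFResult4c)
        if self.is4c:
            self.builder = scf.builder
        else:
            self.builder = scf.model.builder2c
        self.xc: XCSpec = self.builder.xc
        start = scf.n_positive_start
        occ_all = scf.occupied_positive
        if np.any(np.abs(scf.occupations[start + occ_all] - 1.0) > 1e-8):
            raise ResponseError("response requires an integer-occupied closed shell")
        if cvs is not None and len(cvs):
            cvs = np.asarray(sorted(cvs), dtype=int)
            if np.any(cvs < 0) or np.any(cvs >= len(occ_all)):
                raise ResponseError("CVS indices outside the occupied set")
            occ_sel = occ_all[cvs]
        else:
            occ_sel = occ_all
        virt_sel = np.array([i for i in range(len(scf.mo_energy) - start)
                             if i not in set(occ_all)], dtype=int)
        if len(virt_sel) == 0 or len(occ_sel) == 0:
            raise ResponseError("empty CVS-restricted particle-hole space")
        self.C_o = scf.mo_coeff[:, start + occ_sel]
        self.C_v = scf.mo_coeff[:, start + virt_sel]
        self.eps_o = scf.mo_energy[start + occ_sel]
        self.eps_v = scf.mo_energy[start + virt_sel]
        self.omega_ai = self.eps_v[:, None] - self.eps_o[None, :]
        self.No = len(occ_sel)
        self.Nv = len(virt_sel)
        self._kernel_ready = False
        self.kernel = kernel

    @property
    def dim(self) -> int:
        return self.Nv * self.No

    # -- xc kernel ------------------------------------------------------------

    def _prepare_kernel(self):
        if self._kernel_ready:
            return
        self._kernel_ready = True
        self.f00 = self.fss = None
        if not (self.coupling and self.xc.needs_grid):
            return
        b = self.builder
        rho0 = b.densities_on_grid(b.density_to_raw(self.scf.density))[0]
        fx0, fxs = closed_shell_kernel(rho0, "slater")
        if self.xc.functional == "slater":
            f00 = self.xc.x_scale * fx0
            fss = self.xc.x_scale * fxs
        else:
            ff0, ffs = closed_shell_kernel(rho0, "svwn5")
            f00 = self.xc.x_scale * fx0 + (ff0 - fx0)
            fss = self.xc.x_scale * fxs + (ffs - fxs)
        self.f00, self.fss = f00, fss

    def _kernel_matrices(self, D_raw):
        """f_xc-induced potential matrices for a complex transition density."""
        if self.f00 is None:
            return None
        b = self.builder
        w = b.grid.weights
        out = []
        if self.is4c:
            spaces = ((b.rkb.shells_L, b.nL), (b.rkb.shells_P, b.nP))
            D_LL, D_PP, _ = b.expand_density(D_raw)
            dens = (D_LL, D_PP)
        else:
            spaces = ((b.rkb.shells_L, b.nL),)
            dens = (D_raw,)
        # transition densities on grid (complex), all Pauli components; the
        # four components are stacked into single GEMMs
        npts = len(w)
        drho = np.zeros((4, npts), dtype=complex)
        aos = []
        for (shells, n), D in zip(spaces, dens):
            ao = b.grid.ao_values(shells)
            aos.append(ao)
            comps = pauli_components(D, n).reshape(4 * n, n)
            Tr = (comps.real @ ao).reshape(4, n, npts)
            Ti = (comps.imag @ ao).reshape(4, n, npts)
            drho += np.einsum("mp,kmp->kp", ao, Tr) + 1j * np.einsum(
                "mp,kmp->kp", ao, Ti)
        dv = np.empty_like(drho)
        dv[0] = self.f00 * drho[0]
        for k in range(1, 4):
            dv[k] = self.fss * drho[k]
        wv = w * dv  # (4, npts)
        for (shells, n), ao in zip(spaces, aos):
            rows_r = (ao[None, :, :] * wv.real[:, None, :]).reshape(4 * n, npts)
            rows_i = (ao[None, :, :] * wv.imag[:, None, :]).reshape(4 * n, npts)
            V = ((rows_r @ ao.T) + 1j * (rows_i @ ao.T)).reshape(4, n, n)
            out.append(from_pauli(V))
        return out

    # -- generalized Fock -------------------------------------------------------

    def _gfock(self, rho_orth: np.ndarray) -> np.ndarray:
        """g(rho) = J - zeta K + f_xc over the orthonormal basis."""
        self._prepare_kernel()
        b = self.builder
        D_raw = b.density_to_raw(rho_orth)
        if self.is4c:
            F, _ = b.coulomb_exchange(D_raw, hermitian=False)
        else:
            F = b.coulomb_exchange(D_raw, hermitian=False)
        Vk = self._kernel_matrices(D_raw)
        if Vk is not None:
            if self.is4c:
                n2 = 2 * b.nL
                F[:n2, :n2] += Vk[0]
                F[n2:, n2:] += b.M.conj().T @ Vk[1] @ b.M
            else:
                F += Vk[0]
        return b.to_orth(F)

    def apply_A(self, T: np.ndarray) -> np.ndarray:
        out = self.omega_ai * T
        if self.coupling:
            rho = self.C_v @ T @ self.C_o.conj().T
            out = out + self.C_v.conj().T @ self._gfock(rho) @ self.C_o
        return out

    def apply_B(self, T: np.ndarray) -> np.ndarray:
        if not self.coupling:
            return np.zeros_like(T)
        rho = self.C_o @ T.T @ self.C_v.conj().T
        return self.C_v.conj().T @ self._gfock(rho) @ self.C_o

    def apply_AB(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """A X + B Y with a single generalized Fock build (g is linear)."""
        out = self.omega_ai * X
        if self.coupling:
            rho = self.C_v @ X @ self.C_o.conj().T + self.C_o @ Y.T @ self.C_v.conj().T
            out = out + self.C_v.conj().T @ self._gfock(rho) @ self.C_o
        return out

    def apply_paired(self, z: np.ndarray, sign_lower: float = 1.0) -> np.ndarray:
        """[[A,B],[s B*, s A*]] acting on a stacked supervector [X; Y]."""
        n = self.dim
        X = z[:n].reshape(self.Nv, self.No)
        Y = z[n:].reshape(self.Nv, self.No)
        top = self.apply_AB(X, Y)
        bot = np.conj(self.apply_AB(np.conj(Y), np.conj(X)))
        return np.concatenate([top.ravel(), sign_lower * bot.ravel()])

    def apply_paired_block(self, Z: np.ndarray, sign_lower: float = 1.0) -> np.ndarray:
        """apply_paired on each column of ``Z`` (2n x K), with batched g-builds."""
        n = self.dim
        K = Z.shape[1]
        if not self.coupling or K == 1:
            return np.column_stack([self.apply_paired(Z[:, i], sign_lower)
                                    for i in range(K)])
        X = Z[:n].reshape(self.Nv, self.No, K)
        Y = Z[n:].reshape(self.Nv, self.No, K)
        # 2K trial densities: K for the top row, K (conjugated) for the bottom
        rhos = np.empty((2 * K, self.C_v.shape[0], self.C_v.shape[0]), complex)
        for i in range(K):
            rhos[i] = (self.C_v @ X[:, :, i] @ self.C_o.conj().T
                       + self.C_o @ Y[:, :, i].T @ self.C_v.conj().T)
            rhos[K + i] = (self.C_v @ np.conj(Y[:, :, i]) @ self.C_o.conj().T
                           + self.C_o @ np.conj(X[:, :, i]).T @ self.C_v.conj().T)
        g = self._gfock_block(rhos)
        out = np.empty_like(Z)
        for i in range(K):
            top = self.omega_ai * X[:, :, i] + self.C_v.conj().T @ g[i] @ self.C_o
            bot = np.conj(self.omega_ai * np.conj(Y[:, :, i])
                          + self.C_v.conj().T @ g[K + i] @ self.C_o)
            out[:n, i] = top.ravel()
            out[n:, i] = sign_lower * bot.ravel()
        return out

    def _gfock_block(self, rhos: np.ndarray) -> np.ndarray:
        """Batched generalized Fock builds for a stack of transition densities."""
        self._prepare_kernel()
        b = self.builder
        K = rhos.shape[0]
        if self.is4c:
            return np.array([self._gfock(r) for r in rhos])
        nL = b.nL
        raws = np.array([b.density_to_raw(r) for r in rhos])
        # Coulomb: one real GEMM over all densities
        q = np.array([pauli_components(r, nL)[0] for r in raws])  # (K, nL, nL)
        Gm = b.ints.eri_LLLL.reshape(nL * nL, nL * nL)
        qcols = np.concatenate([q.real.reshape(K, -1).T, q.imag.reshape(K, -1).T],
                               axis=1)
        Jall = Gm @ qcols  # (nL^2, 2K)
        # exchange: one real GEMM over all spin blocks of all densities
        Kmat = b.ints.k_matrix("LL")
        rhs = np.empty((nL * nL, 8 * K))
        pat = ((0, 0), (0, 1), (1, 0), (1, 1))
        for i in range(K):
            D4 = raws[i].reshape(2, nL, 2, nL)
            for j, (t, s) in enumerate(pat):
                blk = D4[t, :, s, :].ravel()
                rhs[:, 8 * i + 2 * j] = blk.real
                rhs[:, 8 * i + 2 * j + 1] = blk.imag
        Kall = Kmat @ rhs
        F = np.empty_like(raws)
        for i in range(K):
            J = (Jall[:, i] + 1j * Jall[:, K + i]).reshape(nL, nL)
            Kx = np.empty((2, nL, 2, nL), complex)
            for j, (t, s) in enumerate(pat):
                Kx[t, :, s, :] = (Kall[:, 8 * i + 2 * j]
                                  + 1j * Kall[:, 8 * i + 2 * j + 1]).reshape(nL, nL)
            F[i] = np.kron(np.eye(2), J) - self.xc.hfx * Kx.reshape(2 * nL, 2 * nL)
        if self.f00 is not None:
            F += self._kernel_block_2c(raws)
        X2 = b.X2
        return np.array([X2.conj().T @ f @ X2 for f in F])

    def _kernel_block_2c(self, raws: np.ndarray, chunk: int = 8) -> np.ndarray:
        """Batched f_xc potentials for 2c transition densities."""
        b = self.builder
        nL = b.nL
        ao = b.grid.ao_values(b.rkb.shells_L)
        w = b.grid.weights
        npts = len(w)
        K = raws.shape[0]
        out = np.empty((K, 2 * nL, 2 * nL), complex)
        for c0 in range(0, K, chunk):
            sub = raws[c0: c0 + chunk]
            k = sub.shape[0]
            comps = np.array([pauli_components(r, nL) for r in sub])
            comps = comps.reshape(k * 4 * nL, nL)
            Tr = (comps.real @ ao).reshape(k, 4, nL, npts)
            Ti = (comps.imag @ ao).reshape(k, 4, nL, npts)
            drho = (np.einsum("mp,ckmp->ckp", ao, Tr)
                    + 1j * np.einsum("mp,ckmp->ckp", ao, Ti))
            fk = np.array([self.f00, self.fss, self.fss, self.fss])
            wv = (w * fk)[None, :, :] * drho  # (k, 4, npts)
            rows_r = (ao[None, None, :, :] * wv.real[:, :, None, :]).reshape(
                k * 4 * nL, npts)
            rows_i = (ao[None, None, :, :] * wv.imag[:, :, None, :]).reshape(
                k * 4 * nL, npts)
            V = ((rows_r @ ao.T) + 1j * (rows_i @ ao.T)).reshape(k, 4, nL, nL)
            for i in range(k):
                out[c0 + i] = from_pauli(V[i])
        return out

    def property_mo(self, P_ao: np.ndarray) -> np.ndarray:
        """Transform an (orthonormal-basis) one-electron operator to (Nv x No)."""
        return self.C_v.conj().T @ P_ao @ self.C_o


def hessian_action(scf, xc_unused=None, cvs=None, coupling=True) -> HessianOperator:
    """Build the orbital-Hessian action for a converged SCF result."""
    return HessianOperator(scf, cvs=cvs, coupling=coupling)


# ---------------------------------------------------------------------------
# Damped-response solver
# ---------------------------------------------------------------------------


def _orthonormalize_against(V, vec, drop_tol=1e-10):
    """Modified Gram-Schmidt of ``vec`` against columns of V (may return None)."""
    nrm0 = np.linalg.norm(vec)
    if nrm0 == 0:
        return None
    vec = vec / nrm0
    for _ in range(2):
        for j in range(V.shape[1]):
            vec = vec - V[:, j] * (V[:, j].conj() @ vec)
    nrm = np.linalg.norm(vec)
    if nrm < drop_tol:
        return None
    return vec / nrm


def solve_damped_response(hess: HessianOperator, property_matrices: dict,
                          spec: ResponseSpec) -> ResponseSolution:
    """Multifrequency preconditioned subspace solution of the damped equation.

    ``property_matrices``: u -> MO-space perturbation (Nv x No).  All
    requested frequencies of a batch share one growing subspace; results are
    independent of the batching.
    """
    n = hess.dim
    freqs = spec.frequencies
    sols_X = {u: np.zeros((len(freqs), hess.Nv, hess.No), complex)
              for u in property_matrices}
    sols_Y = {u: np.zeros((len(freqs), hess.Nv, hess.No), complex)
              for u in property_matrices}
    iters_total = 0
    sub_max = 0
    for b0 in range(0, len(freqs), spec.batch_size):
        batch = list(range(b0, min(b0 + spec.batch_size, len(freqs))))
        out = _solve_batch(hess, property_matrices, freqs[batch], spec)
        for u in property_matrices:
            sols_X[u][batch] = out[0][u]
            sols_Y[u][batch] = out[1][u]
        iters_total += out[2]
        sub_max = max(sub_max, out[3])
    return ResponseSolution(frequencies=freqs, gamma=spec.gamma, X=sols_X, Y=sols_Y,
                            property_mo=dict(property_matrices),
                            diagnostics={"iterations": iters_total,
                                         "max_subspace": sub_max})


def _solve_batch(hess, props, freqs, spec, max_new=72):
    """One multifrequency batch: shared subspace, projected (Galerkin) solves.

    Per iteration the projected k x k systems (G0 - z G1) alpha = V' rhs are
    solved for every live (component, frequency) task; true residuals are
    evaluated batched through the stored W = L(V) columns, and at most
    ``max_new`` preconditioned residuals (worst first) expand the subspace.
    """
    n = hess.dim
    omg = hess.omega_ai.ravel()
    rhs = {}
    for u, P in props.items():
        p = P.ravel()
        rhs[u] = -np.concatenate([p, np.conj(p)])
    live = [(u, iw) for u in props for iw in range(len(freqs))
            if np.linalg.norm(rhs[u]) > 0]
    X_out = {u: np.zeros((len(freqs), hess.Nv, hess.No), complex) for u in props}
    Y_out = {u: np.zeros((len(freqs), hess.Nv, hess.No), complex) for u in props}
    if not live:
        return X_out, Y_out, 0, 0

    def precond(vec, z):
        return np.concatenate([vec[:n] / (omg - z), vec[n:] / (omg + z)])

    V = np.zeros((2 * n, 0), complex)
    W = np.zeros((2 * n, 0), complex)
    JV = np.zeros((2 * n, 0), complex)
    G0 = np.zeros((0, 0), complex)
    G1 = np.zeros((0, 0), complex)
    rhs_p = {u: np.zeros(0, complex) for u in props}
    # seed: preconditioned right-hand sides at three shifts across the batch
    seeds = sorted({0, len(freqs) // 2, len(freqs) - 1})
    new_vecs = [precond(rhs[u], freqs[iw] + 1j * spec.gamma)
                for u in props if np.linalg.norm(rhs[u]) > 0 for iw in seeds]
    converged = {}
    it = 0
    while it < spec.max_iter:
        it += 1
        block = []
        for vec in new_vecs:
            q = _orthonormalize_against(np.column_stack([V] + block) if block else V,
                                        vec)
            if q is not None:
                block.append(q)
        if not block and it > 1:
            raise ResponseError(
                f"damped-response subspace stagnated with "
                f"{len(live) - len(converged)} unconverged systems")
        if block:
            Vnew = np.column_stack(block)
            Wnew = hess.apply_paired_block(Vnew)
            JVnew = Vnew.copy()
            JVnew[n:] *= -1.0
            # incremental Galerkin updates
            G0 = np.block([[G0, V.conj().T @ Wnew],
                           [Vnew.conj().T @ W, Vnew.conj().T @ Wnew]])
            G1 = np.block([[G1, V.conj().T @ JVnew],
                           [Vnew.conj().T @ JV, Vnew.conj().T @ JVnew]])
            for u in props:
                rhs_p[u] = np.concatenate([rhs_p[u], Vnew.conj().T @ rhs[u]])
            V = np.column_stack([V, Vnew])
            W = np.column_stack([W, Wnew])
            JV = np.column_stack([JV, JVnew])
        new_vecs = []
        # projected solves grouped by frequency (shared factorization)
        todo = [t for t in live if t not in converged]
        alphas = {}
        for iw in sorted({iw for _u, iw in todo}):
            z = freqs[iw] + 1j * spec.gamma
            us = [u for (u, jw) in todo if jw == iw]
            sol = np.linalg.solve(G0 - z * G1,
                                  np.column_stack([rhs_p[u] for u in us]))
            for j, u in enumerate(us):
                alphas[(u, iw)] = sol[:, j]
        # batched residuals
        Amat = np.column_stack([alphas[t] for t in todo])
        WA = W @ Amat
        JVA = JV @ Amat
        VA = V @ Amat
        done_all = True
        residuals = []
        for j, (u, iw) in enumerate(todo):
            z = freqs[iw] + 1j * spec.gamma
            r = WA[:, j] - z * JVA[:, j] - rhs[u]
            rn = np.linalg.norm(r) / np.linalg.norm(rhs[u])
            sol = VA[:, j]
            X_out[u][iw] = sol[:n].reshape(hess.Nv, hess.No)
            Y_out[u][iw] = sol[n:].reshape(hess.Nv, hess.No)
            if rn < spec.solver_tol:
                converged[(u, iw)] = it
            else:
                done_all = False
                residuals.append((rn, r, z))
        if done_all:
            break
        residuals.sort(key=lambda t: -t[0])
        new_vecs = [precond(r, z) for _rn, r, z in residuals[:max_new]]
    else:
        raise ResponseError(
            f"damped response not converged after {spec.max_iter} iterations; "
            f"{len(live) - len(converged)} systems remain")
    return X_out, Y_out, it, V.shape[1]


# ---------------------------------------------------------------------------
# Eigenvalue (Casida) solver
# ---------------------------------------------------------------------------


def _pair_partner(z, n):
    return np.concatenate([np.conj(z[n:]), np.conj(z[:n])])


def solve_eigen(hess: HessianOperator, n_roots: int, tol: float = 1e-9,
                max_iter: int = 120, property_matrices: dict = None) -> ExcitationSet:
    """Lowest ``n_roots`` of the paired eigenproblem by a Davidson-type method.

    Initial guesses are unit vectors on the smallest orbital-energy
    differences (ties broken by index order); the subspace is kept closed
    under the (X,Y) pairing so that the projected problem inherits the +/-
    pairing of the full spectrum.
    """
    n = hess.dim
    if n_roots > n:
        raise ResponseError("more roots requested than particle-hole dimension")
    omg = hess.omega_ai.ravel()
    order = np.lexsort((np.arange(n), omg))
    nseed = min(n, n_roots + min(n_roots, 10))
    V = np.zeros((2 * n, 0), complex)
    W = np.zeros((2 * n, 0), complex)
    new_vecs = []
    for k in order[:nseed]:
        e = np.zeros(2 * n, complex)
        e[k] = 1.0
        new_vecs.append(e)

    roots = None
    for it in range(1, max_iter + 1):
        block = []
        for vec in new_vecs:
            for cand in (vec, _pair_partner(vec, n)):
                q = _orthonormalize_against(
                    np.column_stack([V] + block) if block else V, cand)
                if q is not None:
                    block.append(q)
        if block:
            Vnew = np.column_stack(block)
            Wnew = hess.apply_paired_block(Vnew, sign_lower=-1.0)
            V = np.column_stack([V, Vnew])
            W = np.column_stack([W, Wnew])
        new_vecs = []
        M = V.conj().T @ W
        theta, yv = np.linalg.eig(M)
        pos = np.where(theta.real > 1e-12)[0]
        pos = pos[np.argsort(theta.real[pos])][:n_roots]
        roots = []
        done_all = True
        for idx in pos:
            th = theta[idx].real
            z = V @ yv[:, idx]
            r = W @ yv[:, idx] - theta[idx] * z
            rn = np.linalg.norm(r)
            roots.append((th, z, rn))
            if rn > tol:
                done_all = False
                dx = omg - th
                dy = omg + th
                dx = np.where(np.abs(dx) < 1e-8, 1e-8, dx)
                dy = np.where(np.abs(dy) < 1e-8, 1e-8, dy)
                new_vecs.append(np.concatenate([r[:n] / dx, r[n:] / dy]))
        if done_all and len(roots) == n_roots:
            break
        if V.shape[1] >= 2 * n:
            # subspace saturated the full space: the projected solve is exact
            break
    else:
        warnings.warn("Davidson did not reach tolerance on all roots; "
                      "consider a larger subspace", RuntimeWarning)

    omegas = []
    Xs, Ys = [], []
    for th, z, _rn in sorted(roots, key=lambda t: t[0]):
        X = z[:n].reshape(hess.Nv, hess.No)
        Y = z[n:].reshape(hess.Nv, hess.No)
        nrm = np.real(np.vdot(X, X) - np.vdot(Y, Y))
        if nrm <= 0:
            warnings.warn(f"root at {th:.6f} au has non-positive metric norm",
                          RuntimeWarning)
            nrm = abs(nrm) or 1.0
        X /= np.sqrt(nrm)
        Y /= np.sqrt(nrm)
        omegas.append(th)
        Xs.append(X)
        Ys.append(Y)
    omegas = np.array(omegas)
    Xs = np.array(Xs)
    Ys = np.array(Ys)
    tdip = np.zeros((3, len(omegas)), complex)
    if property_matrices is not None:
        for u, P in property_matrices.items():
            for N in range(len(omegas)):
                tdip[u, N] = np.vdot(P, Xs[N]) + np.sum(P * Ys[N])
    return ExcitationSet(omegas=omegas, X=Xs, Y=Ys, tdip=tdip,
                         diagnostics={"iterations": it, "subspace": V.shape[1]})


# ---------------------------------------------------------------------------
# Spectrum assembly
# ---------------------------------------------------------------------------


def polarizability_dr(sol: ResponseSolution) -> np.ndarray:
    """alpha_uv(omega) = -(P_u' X_v + P_u^T Y_v) from damped response vectors."""
    nw = len(sol.frequencies)
    alpha = np.zeros((3, 3, nw), complex)
    for u, Pu in sol.property_mo.items():
        for v in sol.X:
            for iw in range(nw):
                alpha[u, v, iw] = -(np.vdot(Pu, sol.X[v][iw])
                                    + np.sum(Pu * sol.Y[v][iw]))
    return alpha


def polarizability_sos(exc: ExcitationSet, freqs: np.ndarray, gamma: float) -> np.ndarray:
    """Sum-over-states alpha with Lorentzian damping (Casida route)."""
    z = freqs + 1j * gamma
    alpha = np.zeros((3, 3, len(freqs)), complex)
    for u in range(3):
        for v in range(3):
            tu = exc.tdip[u]
            tv = exc.tdip[v]
            alpha[u, v] = np.sum(
                tu[:, None] * tv.conj()[:, None] / (exc.omegas[:, None] - z[None, :])
                + tu.conj()[:, None] * tv[:, None] / (exc.omegas[:, None] + z[None, :]),
                axis=0,
            )
    return alpha


def assemble_spectra(source, spec: ResponseSpec, mode: str = None,
                     normalized: bool = False) -> Spectrum:
    """Dipole strength S(omega) = (4 pi omega)/(3 c) Im Tr alpha(omega)."""
    from .integrals_rkb import SPEED_OF_LIGHT

    if isinstance(source, ResponseSolution):
        if abs(source.gamma - spec.gamma) > 1e-12:
            raise ValueError("gamma mismatch between response solution and spectrum")
        if len(source.frequencies) != len(spec.frequencies) or np.any(
                np.abs(source.frequencies - spec.frequencies) > 1e-12):
            raise ValueError("frequency grid mismatch")
        alpha = polarizability_dr(source)
    elif isinstance(source, ExcitationSet):
        alpha = polarizability_sos(source, spec.frequencies, spec.gamma)
    else:
        raise TypeError("source must be a ResponseSolution or ExcitationSet")
    om = spec.frequencies
    S = (4.0 * np.pi * om) / (3.0 * SPEED_OF_LIGHT) * np.imag(
        alpha[0, 0] + alpha[1, 1] + alpha[2, 2])
    out = Spectrum(omega_ev=om * HARTREE_EV, strength=S, alpha=alpha,
                   gamma_ev=spec.gamma * HARTREE_EV)
    return out.normalize() if normalized else out
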