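"""One-step X2C decoupling and picture-change transformations.

The unitary U that block-diagonalizes a parent 4c operator is built from its
positive-energy eigenvectors: with C+ = (C+^L; C+^S) the coupling matrix is
R = C+^S (C+^L)^-1, and U follows by symmetric (Loewdin-style)
renormalization,

    U = [[ (1+R'R)^(-1/2),  -R' (1+RR')^(-1/2) ],
         [ R (1+R'R)^(-1/2),   (1+RR')^(-1/2)  ]]   (R' = R^dagger).

All operators here live in the canonically orthonormalized 4c basis, where U
is exactly unitary.  U is computed once, field-free, and reused for all
response work (adiabatic X2C); the upper-left block of U' O U is the
picture-change-transformed 2c form of an operator O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .dirac4c import SCFResult4c, XCSpec


class DecouplingError(RuntimeError):
    pass


@dataclass
class DecouplingU:
    """Unitary 4c -> (2c + 2c) decoupling, tagged by its parent Hamiltonian."""

    U: np.ndarray
    parent: str  # '1e', 'amf-parent', 'converged-4c', ...
    n2L: int  # dimension of the decoupled (upper-left) 2c block
    offdiag_residual: float = 0.0

    def __post_init__(self):
        dim = self.U.shape[0]
        uni = np.linalg.norm(self.U.conj().T @ self.U - np.eye(dim))
        if uni > 1e-9:
            raise DecouplingError(f"U not unitary (deviation {uni:.2e})")

    def pc(self, source: np.ndarray) -> "PCTransformed2c":
        return picture_change_transform(self, source)


@dataclass
class PCTransformed2c:
    """Upper-left 2c block of U' O U, with provenance diagnostics."""

    matrix: np.ndarray
    parent: str
    neglected_block_norm: float


def one_step_decoupling(parent: np.ndarray, c: float, n2L: int,
                        parent_tag: str = "1e") -> DecouplingU:
    """One-step X2C decoupling of a Hermitian parent 4c matrix.

    ``parent`` is given in the orthonormal 4c basis with ``n2L`` large-
    component rows first; the branch boundary sits at -c^2 (rest-mass-shifted
    spectrum).  The positive-branch eigenvalue count must equal ``n2L``.
    """
    nrm = np.linalg.norm(parent)
    if np.linalg.norm(parent - parent.conj().T) > 1e-9 * max(nrm, 1.0):
        raise DecouplingError("parent operator must be Hermitian")
    eps, C = np.linalg.eigh(parent)
    c2 = c * c
    start = int(np.searchsorted(eps, -c2))
    npos = len(eps) - start
    if npos != n2L:
        raise DecouplingError(
            f"branch identification failed: {npos} positive-energy solutions "
            f"for a 2c dimension of {n2L}"
        )
    CL = C[:n2L, start:]
    CS = C[n2L:, start:]
    try:
        R = CS @ np.linalg.inv(CL)
    except np.linalg.LinAlgError as exc:
        raise DecouplingError("singular large-component block (basis pathology)") from exc
    RR = R.conj().T @ R
    NL = _inv_sqrt(np.eye(n2L) + RR)
    NS = _inv_sqrt(np.eye(R.shape[0]) + R @ R.conj().T)
    dim = parent.shape[0]
    U = np.zeros((dim, dim), dtype=complex)
    U[:n2L, :n2L] = NL
    U[n2L:, :n2L] = R @ NL
    U[:n2L, n2L:] = -R.conj().T @ NS
    U[n2L:, n2L:] = NS
    Ft = U.conj().T @ parent @ U
    off = np.linalg.norm(Ft[:n2L, n2L:])
    out = DecouplingU(U=U, parent=parent_tag, n2L=n2L,
                      offdiag_residual=off / max(nrm, 1e-300))
    if out.offdiag_residual > 1e-9:
        raise DecouplingError(
            f"decoupling residual {out.offdiag_residual:.2e} exceeds 1e-9"
        )
    return out


def _inv_sqrt(A: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(A)
    if w.min() <= 0:
        raise DecouplingError("renormalization matrix not positive definite")
    return (v / np.sqrt(w)) @ v.conj().T


def picture_change_transform(U: DecouplingU, source: np.ndarray) -> PCTransformed2c:
    """2c picture-change transform of a 4c operator (upper-left block)."""
    if source.shape != U.U.shape:
        raise ValueError("operator/decoupling dimension mismatch")
    t = U.U.conj().T @ source @ U.U
    n = U.n2L
    return PCTransformed2c(
        matrix=t[:n, :n],
        parent=U.parent,
        neglected_block_norm=float(np.linalg.norm(t[:n, n:])),
    )


def pc_density(U: DecouplingU, D_orth4c: np.ndarray) -> np.ndarray:
    """Picture-change-transformed 2c density (upper block of U' D U)."""
    t = U.U.conj().T @ D_orth4c @ U.U
    return t[: U.n2L, : U.n2L]


def mmf_reduce(scf: SCFResult4c, xc: XCSpec = None):
    """Molecular mean-field reduction of a converged 4c solution.

    Returns (DecouplingU, 2c Fock, PCCorrection matrix, 2c occupied MOs), all
    in the orthonormal 2c basis.  The transformed Fock reproduces the 4c
    positive-energy spectrum to machine precision; the static correction
    Delta-F(mmf) is the transformed minus untransformed-integral 2e/xc Fock
    evaluated at the transformed density.
    """
    from .hamiltonians2c import TwoCompFockBuilder

    if not scf.converged:
        raise ValueError("mmf reduction requires a converged 4c result")
    b4 = scf.builder
    xc = xc or b4.xc
    n2L = b4.n2L_orth
    U = one_step_decoupling(scf.fock, b4.c, n2L, parent_tag="converged-4c")
    F2c = U.pc(scf.fock).matrix
    D2c = pc_density(U, scf.density)
    h2c = U.pc(b4.to_orth(b4.h4c_raw())).matrix
    b2 = TwoCompFockBuilder(b4.rkb, b4.ints, xc, grid=b4._grid)
    G2c, _ = b2.two_electron_xc(D2c)
    dF = F2c - h2c - G2c
    dF = 0.5 * (dF + dF.conj().T)
    occ_idx = scf.occupied_positive + scf.n_positive_start
    C2c = (U.U.conj().T @ scf.mo_coeff[:, occ_idx])[:n2L]
    return U, F2c, dF, C2c
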