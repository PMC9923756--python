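"""Numerical exchange-correlation machinery: Becke grids and LDA functionals.

The functional family implemented here is LDA-based: Slater exchange and
VWN5 correlation, optionally hybridized with a fraction zeta of exact
exchange handled by the Fock builders.  Potentials are analytic; the
adiabatic kernel (charge and spin channels, evaluated at the closed-shell
reference) is obtained by central finite differences of the potential.

Noncollinear open-shell densities enter through the locally collinear
variables (rho, s=|m|); at a closed-shell reference all spin channels
vanish and only the charge potential survives.
"""

from __future__ import annotations

import numpy as np

from . import _mcmurchie as md

# Bragg-Slater radii (Angstrom) for the Becke radial mapping.
_BRAGG = {
    1: 0.35, 2: 0.93, 3: 1.45, 4: 1.05, 5: 0.85, 6: 0.70, 7: 0.65, 8: 0.60,
    9: 0.50, 10: 0.38, 11: 1.80, 12: 1.50, 13: 1.25, 14: 1.10, 15: 1.00,
    16: 1.00, 17: 1.00, 18: 0.71, 19: 2.20, 20: 1.80, 21: 1.60, 22: 1.40,
    23: 1.35, 24: 1.40, 25: 1.40, 26: 1.40, 27: 1.35, 28: 1.35, 29: 1.35,
    30: 1.35, 34: 1.15, 35: 1.15, 36: 0.88, 53: 1.40,
}
_ANG = 1.0 / 0.529177210903


# ---------------------------------------------------------------------------
# Molecular quadrature grid (Becke partitioning)
# ---------------------------------------------------------------------------


def atomic_grid(center, rb, n_rad, n_theta, n_phi):
    """Product grid: Gauss-Chebyshev(2) radial x Gauss-Legendre(theta) x uniform(phi)."""
    i = np.arange(1, n_rad + 1)
    th = i * np.pi / (n_rad + 1)
    x = np.cos(th)
    # integral over x in (-1,1) with GC2 nodes
    w_x = (np.pi / (n_rad + 1)) * np.sin(th) ** 2 / np.sqrt(1.0 - x**2)
    r = rb * (1.0 + x) / (1.0 - x)
    drdx = 2.0 * rb / (1.0 - x) ** 2
    w_rad = w_x * drdx * r**2

    ct, w_ct = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct**2)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    w_phi = 2.0 * np.pi / n_phi

    pts = []
    wts = []
    for ir in range(n_rad):
        for it in range(n_theta):
            for ip in range(n_phi):
                pts.append((r[ir] * st[it] * np.cos(phi[ip]),
                            r[ir] * st[it] * np.sin(phi[ip]),
                            r[ir] * ct[it]))
                wts.append(w_rad[ir] * w_ct[it] * w_phi)
    return np.asarray(pts) + np.asarray(center), np.asarray(wts)


def _becke_weights(points, centers, rbs, k=3):
    natom = len(centers)
    if natom == 1:
        return np.ones(len(points))
    dist = np.stack([np.linalg.norm(points - c, axis=1) for c in centers])
    P = np.ones((natom, len(points)))
    for i in range(natom):
        for j in range(natom):
            if i == j:
                continue
            rij = np.linalg.norm(centers[i] - centers[j])
            mu = (dist[i] - dist[j]) / rij
            # Becke atomic-size adjustment
            chi = rbs[i] / rbs[j]
            uij = (chi - 1.0) / (chi + 1.0)
            aij = np.clip(uij / (uij**2 - 1.0), -0.5, 0.5)
            nu = mu + aij * (1.0 - mu**2)
            f = nu
            for _ in range(k):
                f = 1.5 * f - 0.5 * f**3
            P[i] *= 0.5 * (1.0 - f)
    return P / P.sum(axis=0)


class MolecularGrid:
    """Becke-partitioned molecular integration grid with cached AO values."""

    def __init__(self, mol, n_rad=55, n_theta=14, n_phi=26):
        self.spec = (n_rad, n_theta, n_phi)
        centers = mol.coords
        rbs = np.array([
            0.5 * _BRAGG.get(z, 1.45) * _ANG if z > 1 else _BRAGG[1] * _ANG
            for _s, z, _p in mol.atoms
        ])
        pts, wts = [], []
        for ia in range(mol.natoms):
            p, w = atomic_grid(centers[ia], rbs[ia], n_rad, n_theta, n_phi)
            becke = _becke_weights(p, centers, rbs)
            pts.append(p)
            wts.append(w * becke[ia])
        self.points = np.concatenate(pts)
        self.weights = np.concatenate(wts)
        self._ao_cache = {}

    def ao_values(self, shells) -> np.ndarray:
        """(nbf, npts) values of normalized Cartesian Gaussians."""
        key = id(shells)
        if key in self._ao_cache:
            return self._ao_cache[key]
        npts = len(self.points)
        out = np.empty((shells.nbf, npts))
        for ish in range(len(shells.exps)):
            l = int(shells.ls[ish])
            a = float(shells.exps[ish])
            d = self.points - shells.centers[ish]
            r2 = np.einsum("pi,pi->p", d, d)
            g = np.exp(-a * r2)
            comps = np.asarray(md._cart_comps(l))
            norms = md.cart_norms(l, a)
            for ic, (lx, ly, lz) in enumerate(comps):
                out[shells.offs[ish] + ic] = (
                    norms[ic] * d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz * g
                )
        self._ao_cache[key] = out
        return out


# ---------------------------------------------------------------------------
# LDA functionals (spin-resolved energy density and potential)
# ---------------------------------------------------------------------------

_CX = 0.75 * (6.0 / np.pi) ** (1.0 / 3.0)  # Slater exchange constant

# VWN5 parameterizations: paramagnetic, ferromagnetic, spin stiffness
_VWN = {
    "P": (0.0310907, -0.10498, 3.72744, 12.9352),
    "F": (0.01554535, -0.32500, 7.06042, 18.0578),
    "A": (-1.0 / (6.0 * np.pi**2), -0.0047584, 1.13107, 13.0045),
}


def _vwn_eps(rs, tag):
    """VWN fit epsilon(rs) and its derivative d eps/d rs."""
    A, x0, b, c = _VWN[tag]
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = np.sqrt(4.0 * c - b * b)
    atn = np.arctan(Q / (2.0 * x + b))
    eps = A * (
        np.log(x * x / X) + 2.0 * b / Q * atn
        - b * x0 / X0 * (np.log((x - x0) ** 2 / X) + 2.0 * (b + 2.0 * x0) / Q * atn)
    )
    # d/dx
    dX = 2.0 * x + b
    datn = -2.0 * Q / (Q * Q + dX * dX)
    deps_dx = A * (
        2.0 / x - dX / X + 2.0 * b / Q * datn
        - b * x0 / X0 * (2.0 / (x - x0) - dX / X + 2.0 * (b + 2.0 * x0) / Q * datn)
    )
    deps_drs = deps_dx / (2.0 * x)
    return eps, deps_drs


def _fzeta(z):
    return (np.power(1.0 + z, 4.0 / 3.0) + np.power(1.0 - z, 4.0 / 3.0) - 2.0) / (
        2.0 ** (4.0 / 3.0) - 2.0
    )


def _dfzeta(z):
    return (4.0 / 3.0) * (np.power(1.0 + z, 1.0 / 3.0) - np.power(1.0 - z, 1.0 / 3.0)) / (
        2.0 ** (4.0 / 3.0) - 2.0
    )


_FPP0 = 8.0 / (9.0 * (2.0 ** (4.0 / 3.0) - 2.0))  # f''(0)


def lda_energy_potential(rho_up, rho_dn, functional="svwn5"):
    """(e, v_up, v_dn): energy density per volume and spin potentials.

    ``functional``: 'hf' (no density functional part), 'slater', 'svwn5'.
    """
    rho_up = np.maximum(rho_up, 0.0)
    rho_dn = np.maximum(rho_dn, 0.0)
    e = np.zeros_like(rho_up)
    vu = np.zeros_like(rho_up)
    vd = np.zeros_like(rho_up)
    if functional == "hf":
        return e, vu, vd
    # Slater exchange, separable in the spin densities
    e += -_CX * (rho_up ** (4.0 / 3.0) + rho_dn ** (4.0 / 3.0))
    vu += -(4.0 / 3.0) * _CX * rho_up ** (1.0 / 3.0)
    vd += -(4.0 / 3.0) * _CX * rho_dn ** (1.0 / 3.0)
    if functional == "slater":
        return e, vu, vd
    if functional != "svwn5":
        raise ValueError(f"unknown functional {functional!r}")
    rho = rho_up + rho_dn
    ok = rho > 1e-14
    rs = np.empty_like(rho)
    rs[ok] = (3.0 / (4.0 * np.pi * rho[ok])) ** (1.0 / 3.0)
    rs[~ok] = 1e10
    z = np.zeros_like(rho)
    z[ok] = (rho_up[ok] - rho_dn[ok]) / rho[ok]
    z = np.clip(z, -1.0 + 1e-15, 1.0 - 1e-15)
    epsP, depsP = _vwn_eps(rs, "P")
    epsF, depsF = _vwn_eps(rs, "F")
    epsA, depsA = _vwn_eps(rs, "A")
    fz = _fzeta(z)
    dfz = _dfzeta(z)
    z3 = z**3
    z4 = z**4
    eps = epsP + epsA * fz / _FPP0 * (1.0 - z4) + (epsF - epsP) * fz * z4
    deps_drs = depsP + depsA * fz / _FPP0 * (1.0 - z4) + (depsF - depsP) * fz * z4
    deps_dz = (
        epsA / _FPP0 * (dfz * (1.0 - z4) - 4.0 * z3 * fz)
        + (epsF - epsP) * (dfz * z4 + 4.0 * z3 * fz)
    )
    # v_sigma = eps + rho d eps/d rho_sigma
    common = eps - (rs / 3.0) * deps_drs
    vc_u = common + deps_dz * (1.0 - z)
    vc_d = common - deps_dz * (1.0 + z)
    e[ok] += (rho * eps)[ok]
    vu[ok] += vc_u[ok]
    vd[ok] += vc_d[ok]
    return e, vu, vd


def noncollinear_potential(rho, m, functional="svwn5"):
    """Charge/spin potentials (v0, v1, v2, v3) from (rho, magnetization m).

    Locally collinear variables: s = |m|; v_w = (dE/ds) m_w / s.
    """
    s = np.sqrt(m[0] ** 2 + m[1] ** 2 + m[2] ** 2)
    s = np.minimum(s, np.maximum(rho, 0.0))
    e, vu, vd = lda_energy_potential(0.5 * (rho + s), 0.5 * (rho - s), functional)
    v0 = 0.5 * (vu + vd)
    vs = 0.5 * (vu - vd)
    out = np.zeros((4,) + rho.shape)
    out[0] = v0
    ok = s > 1e-12
    for w in range(3):
        out[w + 1][ok] = vs[ok] * m[w][ok] / s[ok]
    return e, out


def closed_shell_kernel(rho, functional="svwn5", step=1e-4):
    """Adiabatic LDA kernel at a closed-shell reference.

    Returns (f00, fss): second derivatives of the energy density with respect
    to the charge density and to the spin density s (transverse = longitudinal
    at s = 0), by central finite differences of the analytic potential.
    """
    rho = np.maximum(rho, 0.0)
    h = np.maximum(step * rho, 1e-10)
    _, vu_p, _ = lda_energy_potential(0.5 * (rho + h), 0.5 * (rho + h), functional)
    _, vu_m, _ = lda_energy_potential(0.5 * (rho - h), 0.5 * (rho - h), functional)
    f00 = (vu_p - vu_m) / (2.0 * h)
    # spin channel: vs(rho, s)/s as s -> 0; vs is odd in s
    _, vu_s, vd_s = lda_energy_potential(0.5 * (rho + h), 0.5 * (rho - h), functional)
    fss = (0.5 * (vu_s - vd_s)) / h
    small = rho < 1e-12
    f00[small] = 0.0
    fss[small] = 0.0
    return f00, fss
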