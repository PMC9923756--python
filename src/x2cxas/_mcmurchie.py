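"""Low-level Gaussian integral engine (McMurchie-Davidson recursions).

All routines work on *uncontracted* Cartesian Gaussian shells described by
flat numpy arrays (centers, exponents, angular momenta, function offsets).
Integrals are returned over unnormalized Cartesian primitives; per-function
normalization is applied by the callers in :mod:`x2cxas.integrals_rkb`.

Everything here is numba-jitted; the first call in a process pays the
compilation cost (cached on disk afterwards).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Cartesian component bookkeeping
# ---------------------------------------------------------------------------


def ncart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


@njit(cache=True)
def _ncart(l):
    return (l + 1) * (l + 2) // 2


@njit(cache=True)
def _cart_comps(l):
    """Cartesian powers (lx, ly, lz) in canonical (lx desc, ly desc) order."""
    n = _ncart(l)
    out = np.empty((n, 3), dtype=np.int64)
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out[k, 0] = lx
            out[k, 1] = ly
            out[k, 2] = l - lx - ly
            k += 1
    return out


def cart_norms(l: int, alpha: float) -> np.ndarray:
    """Normalization constants of the Cartesian components of a shell."""
    comps = np.asarray(_cart_comps(l))
    out = np.empty(len(comps))
    for i, (lx, ly, lz) in enumerate(comps):
        df = _dfact(2 * lx - 1) * _dfact(2 * ly - 1) * _dfact(2 * lz - 1)
        out[i] = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (0.5 * l) / np.sqrt(df)
    return out


def _dfact(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boys(mmax, x, out):
    """Fill out[0..mmax] with Boys functions F_m(x)."""
    if x < 1e-14:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x < 35.0:
        # series for F_mmax, then downward recursion
        s = 0.0
        term = 1.0 / (2 * mmax + 1)
        k = 0
        while True:
            s += term
            k += 1
            term *= 2.0 * x / (2 * mmax + 2 * k + 1)
            if term < 1e-17 * s or k > 300:
                break
        ex = np.exp(-x)
        out[mmax] = s * ex
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * x * out[m + 1] + ex) / (2 * m + 1)
    else:
        out[0] = 0.5 * np.sqrt(np.pi / x)
        ex = np.exp(-x)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - ex) / (2.0 * x)


# ---------------------------------------------------------------------------
# Hermite expansion coefficients and Hermite Coulomb tensor
# ---------------------------------------------------------------------------


@njit(cache=True)
def _etable(la, lb, a, b, AB):
    """E[i, j, t] Hermite expansion coefficients for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    xpa = -b / p * AB
    xpb = a / p * AB
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    for i in range(la):
        for t in range(i + 2):
            v = xpa * E[i, 0, t]
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = xpb * E[i, j, t]
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v
    return E


@njit(cache=True)
def _rtensor(L, alpha, X, Y, Z):
    """Hermite Coulomb integrals R_{tuv}(alpha, (X,Y,Z)) for t+u+v <= L."""
    F = np.empty(L + 1)
    _boys(L, alpha * (X * X + Y * Y + Z * Z), F)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))  # [n, t, u, v]
    m2a = 1.0
    for n in range(L + 1):
        R[n, 0, 0, 0] = m2a * F[n]
        m2a *= -2.0 * alpha
    for t in range(L):
        for n in range(L - t - 1, -1, -1):
            v = X * R[n + 1, t, 0, 0]
            if t > 0:
                v += t * R[n + 1, t - 1, 0, 0]
            R[n, t + 1, 0, 0] = v
    for t in range(L + 1):
        for u in range(L - t):
            for n in range(L - t - u - 1, -1, -1):
                v = Y * R[n + 1, t, u, 0]
                if u > 0:
                    v += u * R[n + 1, t, u - 1, 0]
                R[n, t, u + 1, 0] = v
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for w in range(L - t - u):
                for n in range(L - t - u - w - 1, -1, -1):
                    v = Z * R[n + 1, t, u, w]
                    if w > 0:
                        v += w * R[n + 1, t, u, w - 1]
                    R[n, t, u, w + 1] = v
    return R[0]


# ---------------------------------------------------------------------------
# One-electron integrals
# ---------------------------------------------------------------------------


@njit(cache=True)
def _overlap_kinetic_pair(la, lb, a, b, A, B, S, T):
    """Overlap and kinetic blocks for one shell pair (unnormalized)."""
    p = a + b
    pref = (np.pi / p) ** 0.5
    # 1D overlap tables with lb extended by 2 for the kinetic recursion
    s1 = np.zeros((3, la + 1, lb + 3))
    for d in range(3):
        E = _etable(la, lb + 2, a, b, A[d] - B[d])
        for i in range(la + 1):
            for j in range(lb + 3):
                s1[d, i, j] = E[i, j, 0] * pref
    ca = _cart_comps(la)
    cb = _cart_comps(lb)
    for ia in range(ca.shape[0]):
        for ib in range(cb.shape[0]):
            sv = 1.0
            for d in range(3):
                sv *= s1[d, ca[ia, d], cb[ib, d]]
            S[ia, ib] = sv
            tv = 0.0
            for d in range(3):
                i = ca[ia, d]
                j = cb[ib, d]
                kd = b * (2 * j + 1) * s1[d, i, j] - 2.0 * b * b * s1[d, i, j + 2]
                if j >= 2:
                    kd -= 0.5 * j * (j - 1) * s1[d, i, j - 2]
                rest = 1.0
                for e in range(3):
                    if e != d:
                        rest *= s1[e, ca[ia, e], cb[ib, e]]
                tv += kd * rest
            T[ia, ib] = tv


@njit(cache=True)
def _dipole_pair(la, lb, a, b, A, B, origin, D):
    """Electric dipole blocks <a|(r-origin)_u|b>, D shape (3, nca, ncb)."""
    p = a + b
    pref = (np.pi / p) ** 0.5
    s1 = np.zeros((3, la + 1, lb + 2))
    for d in range(3):
        E = _etable(la, lb + 1, a, b, A[d] - B[d])
        for i in range(la + 1):
            for j in range(lb + 2):
                s1[d, i, j] = E[i, j, 0] * pref
    ca = _cart_comps(la)
    cb = _cart_comps(lb)
    for ia in range(ca.shape[0]):
        for ib in range(cb.shape[0]):
            for u in range(3):
                v = 1.0
                for d in range(3):
                    i = ca[ia, d]
                    j = cb[ib, d]
                    if d == u:
                        # (x - C) = (x - B) + (B - C)
                        v *= s1[d, i, j + 1] + (B[d] - origin[d]) * s1[d, i, j]
                    else:
                        v *= s1[d, i, j]
                D[u, ia, ib] = v


@njit(cache=True)
def _nuclear_pair(la, lb, a, b, A, B, charges, centers, nucexp, V):
    """Nuclear attraction block; nucexp[k] <= 0 means a point nucleus."""
    p = a + b
    L = la + lb
    Ex = _etable(la, lb, a, b, A[0] - B[0])
    Ey = _etable(la, lb, a, b, A[1] - B[1])
    Ez = _etable(la, lb, a, b, A[2] - B[2])
    P = (a * A + b * B) / p
    ca = _cart_comps(la)
    cb = _cart_comps(lb)
    for k in range(charges.shape[0]):
        xi = nucexp[k]
        if xi > 0.0:
            alpha = p * xi / (p + xi)
            pref = -charges[k] * (2.0 * np.pi / p) * np.sqrt(xi / (p + xi))
        else:
            alpha = p
            pref = -charges[k] * (2.0 * np.pi / p)
        R = _rtensor(L, alpha, P[0] - centers[k, 0], P[1] - centers[k, 1],
                     P[2] - centers[k, 2])
        for ia in range(ca.shape[0]):
            for ib in range(cb.shape[0]):
                acc = 0.0
                for t in range(ca[ia, 0] + cb[ib, 0] + 1):
                    ex = Ex[ca[ia, 0], cb[ib, 0], t]
                    if ex == 0.0:
                        continue
                    for u in range(ca[ia, 1] + cb[ib, 1] + 1):
                        ey = Ey[ca[ia, 1], cb[ib, 1], u]
                        if ey == 0.0:
                            continue
                        for w in range(ca[ia, 2] + cb[ib, 2] + 1):
                            ez = Ez[ca[ia, 2], cb[ib, 2], w]
                            if ez == 0.0:
                                continue
                            acc += ex * ey * ez * R[t, u, w]
                V[ia, ib] += pref * acc


@njit(cache=True)
def one_electron(ctr, exps, ls, offs, nbf, charges, nuccen, nucexp, origin):
    """All one-electron matrices over a shell list.

    Returns (S, T, V, Dx3) over unnormalized Cartesian functions.
    """
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    Dip = np.zeros((3, nbf, nbf))
    nsh = exps.shape[0]
    for ish in range(nsh):
        la = ls[ish]
        na = _ncart(la)
        for jsh in range(ish + 1):
            lb = ls[jsh]
            nb = _ncart(lb)
            sblk = np.zeros((na, nb))
            tblk = np.zeros((na, nb))
            vblk = np.zeros((na, nb))
            dblk = np.zeros((3, na, nb))
            _overlap_kinetic_pair(la, lb, exps[ish], exps[jsh], ctr[ish], ctr[jsh],
                                  sblk, tblk)
            _nuclear_pair(la, lb, exps[ish], exps[jsh], ctr[ish], ctr[jsh],
                          charges, nuccen, nucexp, vblk)
            _dipole_pair(la, lb, exps[ish], exps[jsh], ctr[ish], ctr[jsh],
                         origin, dblk)
            for ia in range(na):
                for ib in range(nb):
                    mu = offs[ish] + ia
                    nu = offs[jsh] + ib
                    S[mu, nu] = sblk[ia, ib]
                    S[nu, mu] = sblk[ia, ib]
                    T[mu, nu] = tblk[ia, ib]
                    T[nu, mu] = tblk[ia, ib]
                    V[mu, nu] = vblk[ia, ib]
                    V[nu, mu] = vblk[ia, ib]
                    for u in range(3):
                        Dip[u, mu, nu] = dblk[u, ia, ib]
                        Dip[u, nu, mu] = dblk[u, ia, ib]
    return S, T, V, Dip


# ---------------------------------------------------------------------------
# Electron repulsion integrals (class tensors)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _eri_quartet(la, lb, lc, ld, a, b, c, d, A, B, C, D, out):
    """(ab|cd) over unnormalized Cartesians; out shape (nca,ncb,ncc,ncd)."""
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    Lab = la + lb
    Lcd = lc + ld
    L = Lab + Lcd
    E1x = _etable(la, lb, a, b, A[0] - B[0])
    E1y = _etable(la, lb, a, b, A[1] - B[1])
    E1z = _etable(la, lb, a, b, A[2] - B[2])
    E2x = _etable(lc, ld, c, d, C[0] - D[0])
    E2y = _etable(lc, ld, c, d, C[1] - D[1])
    E2z = _etable(lc, ld, c, d, C[2] - D[2])
    R = _rtensor(L, alpha, P[0] - Q[0], P[1] - Q[1], P[2] - Q[2])
    pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
    ca = _cart_comps(la)
    cb = _cart_comps(lb)
    cc = _cart_comps(lc)
    cd_ = _cart_comps(ld)
    nc = cc.shape[0]
    nd = cd_.shape[0]
    # step 1: contract ket Hermite with R for every ket component pair
    mid = np.zeros((Lab + 1, Lab + 1, Lab + 1, nc, nd))
    for ic in range(nc):
        for idd in range(nd):
            for tau in range(cc[ic, 0] + cd_[idd, 0] + 1):
                e2x = E2x[cc[ic, 0], cd_[idd, 0], tau]
                if e2x == 0.0:
                    continue
                for nu in range(cc[ic, 1] + cd_[idd, 1] + 1):
                    e2y = E2y[cc[ic, 1], cd_[idd, 1], nu]
                    if e2y == 0.0:
                        continue
                    for ph in range(cc[ic, 2] + cd_[idd, 2] + 1):
                        e2z = E2z[cc[ic, 2], cd_[idd, 2], ph]
                        if e2z == 0.0:
                            continue
                        sgn = -1.0 if (tau + nu + ph) % 2 else 1.0
                        w = sgn * e2x * e2y * e2z
                        for t in range(Lab + 1):
                            for u in range(Lab + 1 - t):
                                for v in range(Lab + 1 - t - u):
                                    mid[t, u, v, ic, idd] += w * R[t + tau, u + nu, v + ph]
    # step 2: contract bra Hermite
    for ia in range(ca.shape[0]):
        for ib in range(cb.shape[0]):
            for t in range(ca[ia, 0] + cb[ib, 0] + 1):
                e1x = E1x[ca[ia, 0], cb[ib, 0], t]
                if e1x == 0.0:
                    continue
                for u in range(ca[ia, 1] + cb[ib, 1] + 1):
                    e1y = E1y[ca[ia, 1], cb[ib, 1], u]
                    if e1y == 0.0:
                        continue
                    for v in range(ca[ia, 2] + cb[ib, 2] + 1):
                        e1z = E1z[ca[ia, 2], cb[ib, 2], v]
                        if e1z == 0.0:
                            continue
                        w = pref * e1x * e1y * e1z
                        for ic in range(nc):
                            for idd in range(nd):
                                out[ia, ib, ic, idd] += w * mid[t, u, v, ic, idd]


@njit(cache=True)
def eri_class(ctrA, expA, lA, offA, nA, ctrB, expB, lB, offB, nB, same):
    """Full (AA|BB) ERI tensor over two shell lists.

    ``same`` signals that the two lists are identical so bra/ket symmetry can
    be exploited on top of the in-pair symmetry.
    """
    G = np.zeros((nA, nA, nB, nB))
    nshA = expA.shape[0]
    nshB = expB.shape[0]
    for ish in range(nshA):
        for jsh in range(ish + 1):
            for ksh in range(nshB):
                if same and ksh > ish:
                    continue
                lmax = ksh + 1
                if same and ksh == ish:
                    lmax = jsh + 1
                for lsh in range(lmax):
                    na = _ncart(lA[ish])
                    nb = _ncart(lA[jsh])
                    nc = _ncart(lB[ksh])
                    nd = _ncart(lB[lsh])
                    blk = np.zeros((na, nb, nc, nd))
                    _eri_quartet(lA[ish], lA[jsh], lB[ksh], lB[lsh],
                                 expA[ish], expA[jsh], expB[ksh], expB[lsh],
                                 ctrA[ish], ctrA[jsh], ctrB[ksh], ctrB[lsh], blk)
                    for ia in range(na):
                        mu = offA[ish] + ia
                        for ib in range(nb):
                            nu = offA[jsh] + ib
                            for ic in range(nc):
                                ka = offB[ksh] + ic
                                for idd in range(nd):
                                    laa = offB[lsh] + idd
                                    v = blk[ia, ib, ic, idd]
                                    G[mu, nu, ka, laa] = v
                                    G[nu, mu, ka, laa] = v
                                    G[mu, nu, laa, ka] = v
                                    G[nu, mu, laa, ka] = v
                                    if same:
                                        G[ka, laa, mu, nu] = v
                                        G[laa, ka, mu, nu] = v
                                        G[ka, laa, nu, mu] = v
                                        G[laa, ka, nu, mu] = v
    return G
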