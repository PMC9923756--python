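"""Integral engine and RKB-space checks against closed forms and derivatives."""

import numpy as np
import pytest

import x2cxas as x
from x2cxas import _mcmurchie as md
from x2cxas.integrals_rkb import InputError, gaussian_nucleus_exponent


def _one_el(shells, charges=None, centers=None, nucexp=None, origin=None):
    """Normalized one-electron matrices for a list of (center, l, exp)."""
    ctr = np.array([s[0] for s in shells], float).reshape(-1, 3)
    ls = np.array([s[1] for s in shells], dtype=np.int64)
    exps = np.array([s[2] for s in shells], float)
    offs = np.cumsum([0] + [md.ncart(int(l)) for l in ls])[:-1].astype(np.int64)
    nbf = int(offs[-1] + md.ncart(int(ls[-1])))
    if charges is None:
        charges = np.array([1.0])
        centers = np.zeros((1, 3))
        nucexp = np.array([-1.0])
    if origin is None:
        origin = np.zeros(3)
    S, T, V, D = md.one_electron(ctr, exps, ls, offs, nbf, charges,
                                 centers, nucexp, origin)
    norms = np.concatenate([md.cart_norms(int(l), a) for l, a in zip(ls, exps)])
    N = np.outer(norms, norms)
    return S * N, T * N, V * N, D * N[None], norms


class TestDerivativeIdentities:
    """Higher angular momenta vs finite differences of s-type integrals.

    d/dA_x <s_A|O|s_B> = 2a <p_x,A|O|s_B> for unnormalized primitives, so
    every p-class integral is a central difference of s-class ones; a second
    difference reaches the d class through
    d2/dA_x2 (ss|ss) = 4a^2 (d_xx s|ss) - 2a (ss|ss).
    """

    A = np.array([0.1, -0.2, 0.3])
    B = np.array([0.4, 0.1, -0.2])
    a, b = 0.9, 1.4
    h = 1e-5

    def _s_pair(self, A):
        return _one_el([(A, 0, self.a), (self.B, 0, self.b)])

    @pytest.mark.parametrize("which", ["overlap", "nuclear", "dipole_z"])
    def test_p_class_one_electron(self, which):
        idx = {"overlap": 0, "nuclear": 2}.get(which)
        for u in range(3):
            Ap = self.A.copy()
            Ap[u] += self.h
            Am = self.A.copy()
            Am[u] -= self.h
            if which == "dipole_z":
                up_ = self._s_pair(Ap)[3][2][0, 1]
                dn_ = self._s_pair(Am)[3][2][0, 1]
            else:
                up_ = self._s_pair(Ap)[idx][0, 1]
                dn_ = self._s_pair(Am)[idx][0, 1]
            norm_s = md.cart_norms(0, self.a)[0]
            fd = (up_ - dn_) / (2 * self.h) / norm_s  # unnormalized derivative
            mats = _one_el([(self.A, 1, self.a), (self.B, 0, self.b)])
            norms_p = md.cart_norms(1, self.a)
            if which == "dipole_z":
                direct = mats[3][2][u, 3] / norms_p[u]
            else:
                direct = mats[idx][u, 3] / norms_p[u]
            assert abs(2 * self.a * direct - fd) < 5e-9

    def test_p_and_d_class_eri(self):
        a, b = self.a, self.b

        # quartet where only the bra's first center carries A:
        # (s_A s_B | s_B s_B) so d/dA_x differentiates a single function
        def eri_sb(A):
            ctr = np.array([A, self.B])
            G = md.eri_class(ctr, np.array([a, b]), np.zeros(2, np.int64),
                             np.array([0, 1], np.int64), 2,
                             np.array([self.B]), np.array([b]),
                             np.zeros(1, np.int64), np.zeros(1, np.int64), 1,
                             False)
            return G[0, 1, 0, 0]

        Ap, Am = self.A.copy(), self.A.copy()
        Ap[0] += self.h
        Am[0] -= self.h
        fd1 = (eri_sb(Ap) - eri_sb(Am)) / (2 * self.h)
        ctr = np.array([self.A, self.B])
        Gp = md.eri_class(ctr, np.array([a, b]), np.array([1, 0], np.int64),
                          np.array([0, 3], np.int64), 4,
                          np.array([self.B]), np.array([b]),
                          np.zeros(1, np.int64), np.zeros(1, np.int64), 1, False)
        assert abs(2 * a * Gp[0, 3, 0, 0] - fd1) < 5e-8

        # second derivative reaches the d class:
        # d2/dA_x2 (s_A s_B|s_B s_B) = 4a^2 (d_xx s|s s) - 2a (s s|s s)
        fd2 = (eri_sb(Ap) - 2 * eri_sb(self.A) + eri_sb(Am)) / self.h**2
        Gd = md.eri_class(ctr, np.array([a, b]), np.array([2, 0], np.int64),
                          np.array([0, 6], np.int64), 7,
                          np.array([self.B]), np.array([b]),
                          np.zeros(1, np.int64), np.zeros(1, np.int64), 1, False)
        d_xx = Gd[0, 6, 0, 0]
        s_val = eri_sb(self.A)
        assert abs(4 * a * a * d_xx - 2 * a * s_val - fd2) < 1e-4 * max(abs(fd2), 1)


class TestRKBSpace:
    def test_orthonormal_metric_and_hermiticity(self, h2o_hf):
        rkb, ints = h2o_hf["rkb"], h2o_hf["ints"]
        Id = rkb.X_L.T @ ints.S_L @ rkb.X_L
        assert np.abs(Id - np.eye(Id.shape[0])).max() < 1e-10
        c = rkb.c
        Id_s = rkb.X_S.T @ (ints.T_L / (2 * c * c)) @ rkb.X_S
        assert np.abs(Id_s - np.eye(Id_s.shape[0])).max() < 1e-10
        for M in (ints.S_L, ints.T_L, ints.V_L, ints.S_P, ints.V_P):
            assert np.linalg.norm(M - M.T) < 1e-12 * max(np.linalg.norm(M), 1)

    def test_kinetic_matches_rkb_derivative_maps(self, h2o_hf):
        # 2T = sum_u Du' S_Phi Du ties the derivative maps to the analytic T
        rkb, ints = h2o_hf["rkb"], h2o_hf["ints"]
        T2 = 0.5 * sum(rkb.Du[u].T @ ints.S_P @ rkb.Du[u] for u in range(3))
        assert np.abs(T2 - ints.T_L).max() < 1e-7 * np.abs(ints.T_L).max()

    def test_dipole_gauge_shift_identity(self):
        mol, basis, rkb, ints = x.load_fixture("h2")
        d = np.array([0.3, -0.1, 0.2])
        rkb2, ints2 = x.build_rkb_integrals(mol, basis,
                                            gauge_origin=ints.gauge_origin + d)
        for u in range(3):
            diff = ints.dip_L[u] - ints2.dip_L[u]
            assert np.abs(diff - d[u] * ints.S_L).max() < 1e-12

    def test_dirac_hydrogen_closed_form(self):
        """One-electron 4c ground state approaches the point-nucleus closed form."""
        exact = x.dirac_point_nucleus_energy(1.0)
        errs = []
        for n in (14, 18, 24):
            basis = x.basis_from_dict(
                {"H": {"even_tempered": {"s": [n, 0.01, 2.6]}}})
            mol = x.Molecule(atoms=[("H", 1, np.zeros(3))], finite_nucleus=False)
            rkb, ints = x.build_rkb_integrals(mol, basis)
            from x2cxas.dirac4c import DiracFockBuilder

            b = DiracFockBuilder(rkb, ints, x.XCSpec(functional="hf"))
            w = np.linalg.eigvalsh(b.to_orth(b.h4c_raw()))
            e0 = w[w > -rkb.c**2][0]
            errs.append(e0 - exact)
        assert all(e > 0 for e in errs)  # RKB approaches from above
        assert errs[0] > errs[1] > errs[2]  # monotone with basis growth
        assert errs[-1] < 1e-5

    def test_finite_nucleus_raises_energy(self):
        basis = x.basis_from_dict({"H": {"even_tempered": {"s": [18, 0.01, 2.6]}}})
        res = {}
        for fin in (False, True):
            mol = x.Molecule(atoms=[("H", 1, np.zeros(3))], finite_nucleus=fin)
            rkb, ints = x.build_rkb_integrals(mol, basis)
            from x2cxas.dirac4c import DiracFockBuilder

            b = DiracFockBuilder(rkb, ints, x.XCSpec(functional="hf"))
            w = np.linalg.eigvalsh(b.to_orth(b.h4c_raw()))
            res[fin] = w[w > -rkb.c**2][0]
        assert res[True] > res[False]
        assert res[True] - res[False] < 1e-6  # tiny for Z = 1

    def test_gaussian_nucleus_exponent_scale(self):
        # heavier nuclei are larger: exponents decrease with Z
        assert gaussian_nucleus_exponent(1) > gaussian_nucleus_exponent(16) > \
            gaussian_nucleus_exponent(74)


class TestParsers:
    def test_xyz_units_and_errors(self):
        mol = x.parse_xyz("1\ncomment bohr\nH 1.0 0 0\n")
        assert np.allclose(mol.atoms[0][2], [1.0, 0, 0])
        mol2 = x.parse_xyz("1\n\nH 1.0 0 0\n")
        assert np.allclose(mol2.atoms[0][2], [1.0 / 0.529177210903, 0, 0])
        with pytest.raises(InputError, match="Xx"):
            x.parse_xyz("1\n\nXx 0 0 0\n")
        with pytest.raises(InputError, match="line 3"):
            x.parse_xyz("1\n\nH 0 0\n")
        with pytest.raises(InputError):
            x.parse_xyz("nonsense\n")

    def test_nwchem_basis_parser(self):
        text = """
BASIS "ao basis" PRINT
O  s
  9000.0  1.0
  1300.0  1.0
O  p
  34.0    1.0
H  s
  13.0    1.0
END
"""
        basis = x.parse_nwchem_basis(text)
        assert basis.for_element("O") == [(0, 9000.0), (0, 1300.0), (1, 34.0)]
        assert basis.for_element("H") == [(0, 13.0)]

    def test_load_system_missing_element_basis(self):
        with pytest.raises(InputError, match="S"):
            x.load_system("1\n\nS 0 0 0\n", {"H": {"s": [1.0]}})

    def test_basis_exponent_validation(self):
        with pytest.raises(InputError):
            x.basis_from_dict({"H": {"s": [-1.0]}})
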