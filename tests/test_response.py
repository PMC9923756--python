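"""Linear response: Hessian action, solvers, spectra, conventions."""

import numpy as np
import pytest

import x2cxas as x
from x2cxas.dirac4c import HARTREE_EV
from x2cxas.linear_response import (
    ResponseError,
    polarizability_sos,
    sticks_from_json,
    sticks_to_json,
)

from conftest import dense_from_action


class TestHessian:
    def test_dense_action_matches_mo_eri_oracle(self, h2_hessian):
        """Fock-contraction action vs brute-force MO-transformed integrals."""
        hess, _ = h2_hessian
        A, B = dense_from_action(hess)
        Ad, Bd = x.dense_molecular_ab(hess)
        assert np.abs(A - Ad).max() < 1e-12
        assert np.abs(B - Bd).max() < 1e-12
        assert np.linalg.norm(A - A.conj().T) < 1e-12
        assert np.linalg.norm(B - B.T) < 1e-12

    def test_coupling_off_reduces_to_orbital_differences(self, h2):
        hess = x.HessianOperator(h2["scf"], coupling=False)
        exc = x.solve_eigen(hess, 4)
        om = np.sort(hess.omega_ai.ravel())[:4]
        assert np.abs(exc.omegas - om).max() < 1e-12

    def test_vacuous_cvs_equals_full(self, h2):
        hess_full = x.HessianOperator(h2["scf"])
        hess_cvs = x.HessianOperator(h2["scf"],
                                     cvs=list(range(hess_full.No)))
        e1 = x.solve_eigen(hess_full, 4)
        e2 = x.solve_eigen(hess_cvs, 4)
        assert np.abs(e1.omegas - e2.omegas).max() < 1e-10

    def test_cvs_restricts_occupied_space(self, h2):
        hess = x.HessianOperator(h2["scf"], cvs=[0])
        assert hess.No == 1
        with pytest.raises(ResponseError):
            x.HessianOperator(h2["scf"], cvs=[99])


class TestSolvers:
    def test_damped_solver_vs_dense(self, h2_hessian):
        hess, props = h2_hessian
        spec = x.ResponseSpec(frequencies=[0.35, 0.6], gamma=0.15 / HARTREE_EV)
        sol = x.solve_damped_response(hess, props, spec)
        A, B = dense_from_action(hess)
        n = hess.dim
        Lam = np.block([[A, B], [B.conj(), A.conj()]])
        Jm = np.diag(np.concatenate([np.ones(n), -np.ones(n)]))
        for iw, w in enumerate(spec.frequencies):
            z = w + 1j * spec.gamma
            for u in range(3):
                rhs = -np.concatenate([props[u].ravel(), props[u].ravel().conj()])
                ref = np.linalg.solve(Lam - z * Jm, rhs)
                it = np.concatenate([sol.X[u][iw].ravel(), sol.Y[u][iw].ravel()])
                assert np.linalg.norm(it - ref) < 1e-9

    def test_eigen_solver_vs_dense(self, h2_hessian):
        hess, props = h2_hessian
        exc = x.solve_eigen(hess, hess.dim, property_matrices=props)
        A, B = dense_from_action(hess)
        Om = np.block([[A, B], [-B.conj(), -A.conj()]])
        ev = np.linalg.eigvals(Om)
        ref = np.sort(ev.real[ev.real > 1e-10])
        assert np.abs(exc.omegas - ref[: hess.dim]).max() < 1e-9

    def test_zero_property_gives_zero_solution(self, h2_hessian):
        hess, _ = h2_hessian
        spec = x.ResponseSpec(frequencies=[0.5], gamma=0.01)
        sol = x.solve_damped_response(
            hess, {0: np.zeros((hess.Nv, hess.No), complex)}, spec)
        assert np.abs(sol.X[0]).max() == 0.0
        assert np.abs(sol.Y[0]).max() == 0.0

    def test_batch_partitioning_invariance(self, h2_hessian):
        hess, props = h2_hessian
        freqs = np.linspace(0.3, 1.4, 23)
        full = x.solve_damped_response(
            hess, props, x.ResponseSpec(frequencies=freqs, gamma=0.006))
        split = x.solve_damped_response(
            hess, props, x.ResponseSpec(frequencies=freqs, gamma=0.006,
                                        batch_size=5))
        dev = max(np.abs(full.X[u] - split.X[u]).max() for u in range(3))
        assert dev < 1e-8

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            x.ResponseSpec(frequencies=[0.5], gamma=0.0)
        with pytest.raises(ValueError):
            x.ResponseSpec(frequencies=[-0.5], gamma=0.1)


class TestSpectra:
    def test_dr_equals_ev_sum_over_states(self, h2_hessian):
        """The module's master convention check: both routes, same spectrum."""
        hess, props = h2_hessian
        exc = x.solve_eigen(hess, hess.dim, property_matrices=props)
        spec = x.ResponseSpec.window_ev(8.0, 40.0, 0.25, gamma_ev=0.15)
        sol = x.solve_damped_response(hess, props, spec)
        sp_dr = x.assemble_spectra(sol, spec)
        sp_ev = x.assemble_spectra(exc, spec)
        scale = np.abs(sp_ev.strength).max()
        assert np.abs(sp_dr.strength - sp_ev.strength).max() < 1e-6 * scale
        assert np.abs(sp_dr.alpha - sp_ev.alpha).max() < 1e-6 * np.abs(
            sp_ev.alpha).max()

    def test_positivity_and_symmetry(self, h2_hessian):
        hess, props = h2_hessian
        spec = x.ResponseSpec.window_ev(5.0, 45.0, 0.5, gamma_ev=0.15)
        sol = x.solve_damped_response(hess, props, spec)
        sp = x.assemble_spectra(sol, spec)
        tr = np.imag(sp.alpha[0, 0] + sp.alpha[1, 1] + sp.alpha[2, 2])
        assert tr.min() > -1e-10
        assert np.abs(sp.alpha - np.transpose(sp.alpha, (1, 0, 2))).max() < 1e-8

    def test_single_pole_lorentzian_width(self):
        """Im alpha of an isolated root is a Lorentzian of FWHM exactly 2 gamma."""
        om0, g = 0.5, 0.15 / HARTREE_EV
        t = np.zeros((3, 1), complex)
        t[0, 0] = 1.0
        exc = x.ExcitationSet(omegas=np.array([om0]), X=np.zeros((1, 1, 1)),
                              Y=np.zeros((1, 1, 1)), tdip=t)
        w = np.linspace(om0 - 12 * g, om0 + 12 * g, 4801)
        alpha = polarizability_sos(exc, w, g)
        im = alpha[0, 0].imag
        assert im.max() == pytest.approx(1.0 / g - g / (4 * om0**2 + g**2),
                                         rel=1e-9)
        # FWHM by linear interpolation of the half-maximum crossings
        half = im.max() / 2
        above = im >= half
        i0 = np.argmax(above)
        i1 = len(w) - 1 - np.argmax(above[::-1])
        wl = np.interp(half, [im[i0 - 1], im[i0]], [w[i0 - 1], w[i0]])
        wr = np.interp(half, [im[i1 + 1], im[i1]], [w[i1 + 1], w[i1]])
        assert (wr - wl) == pytest.approx(2 * g, rel=1e-4)

    def test_zero_moments_zero_strength(self):
        exc = x.ExcitationSet(omegas=np.array([0.4]), X=np.zeros((1, 1, 1)),
                              Y=np.zeros((1, 1, 1)), tdip=np.zeros((3, 1)))
        spec = x.ResponseSpec(frequencies=[0.3, 0.4], gamma=0.01)
        sp = x.assemble_spectra(exc, spec)
        assert np.abs(sp.strength).max() == 0.0

    def test_gamma_mismatch_rejected(self, h2_hessian):
        hess, props = h2_hessian
        spec = x.ResponseSpec(frequencies=[0.5], gamma=0.01)
        sol = x.solve_damped_response(hess, props, spec)
        other = x.ResponseSpec(frequencies=[0.5], gamma=0.02)
        with pytest.raises(ValueError):
            x.assemble_spectra(sol, other)

    def test_writers_round_trip(self, tmp_path, h2_hessian):
        hess, props = h2_hessian
        spec = x.ResponseSpec(frequencies=np.linspace(0.3, 0.6, 5), gamma=0.01)
        sol = x.solve_damped_response(hess, props, spec)
        sp = x.assemble_spectra(sol, spec)
        p = tmp_path / "spec.tsv"
        sp.to_tsv(p)
        sp2 = x.Spectrum.from_tsv(p)
        assert np.abs(sp2.strength - sp.strength).max() < 1e-12
        assert np.abs(sp2.alpha - sp.alpha).max() < 1e-12
        exc = x.solve_eigen(hess, 4, property_matrices=props)
        q = tmp_path / "sticks.json"
        sticks_to_json(exc, q)
        recs = sticks_from_json(q)
        assert len(recs) == 4
        assert recs[0]["omega_eV"] == pytest.approx(exc.omegas[0] * HARTREE_EV)


class TestFourComponentResponse:
    def test_4c_reference_spectrum_matches_mmf(self, h2o_hf):
        """The 4c response and the mmfX2C response see the same physics."""
        res4 = h2o_hf["scf4c"]
        h4 = x.HessianOperator(res4, cvs=[0, 1])  # O 1s core
        e4 = x.solve_eigen(h4, 4)
        r2 = h2o_hf["scfs"]["mmfx2c"]
        h2c = x.HessianOperator(r2, cvs=[0, 1])
        e2 = x.solve_eigen(h2c, 4)
        # small residual difference: the mmf 2c model re-solves its own SCF
        assert np.abs(e4.omegas - e2.omegas).max() < 5e-4
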