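"""Two-component Hamiltonian models: corrections, SCF, spin-orbit ordering."""

import numpy as np
import pytest

import x2cxas as x
from x2cxas.dirac4c import time_reversal
from x2cxas.hamiltonians2c import fock_2c, so_splitting_2p


def test_fock_2c_construction(h2o_hf):
    """F(model) - h - G2c[D] equals the static correction; zero-density case."""
    m = h2o_hf["models"]["amfx2c"]
    scf = h2o_hf["scfs"]["amfx2c"]
    F, _ = fock_2c(m, scf.density)
    G, _ = m.builder2c.two_electron_xc(scf.density)
    assert np.abs(F - m.h2c - G - m.correction.matrix).max() < 1e-12
    D0 = np.zeros_like(scf.density)
    F0, e0 = fock_2c(m, D0)
    assert np.abs(F0 - m.h2c - m.correction.matrix).max() < 1e-12


def test_1e_model_has_zero_correction(h2o_hf):
    assert np.abs(h2o_hf["models"]["1ex2c"].correction.matrix).max() == 0.0


def test_corrections_hermitian_time_reversal(h2s_suite):
    for tag in ("amfx2c", "eamfx2c", "mmfx2c"):
        dF = h2s_suite["models"][tag].correction.matrix
        assert np.linalg.norm(dF - dF.conj().T) < 1e-10 * max(np.linalg.norm(dF), 1)
        n = dF.shape[0] // 2
        assert np.linalg.norm(dF - time_reversal(dF, n)) < 1e-6 * max(
            np.linalg.norm(dF), 1)


def test_single_atom_eamf_equals_amf():
    """For a one-atom system the molecular and atomic superpositions coincide."""
    basis = x.basis_from_dict({"He": {"even_tempered": {"s": [8, 0.1, 3.0]}}})
    xc = x.XCSpec(functional="svwn5", hfx=0.25)
    ref = x.solve_atomic_scf_4c("He", basis, xc)
    mol = x.Molecule(atoms=[("He", 2, np.zeros(3))])
    rkb, ints = x.build_rkb_integrals(mol, basis)
    amf = x.amf_correction({"He": ref}, mol, rkb, ints, xc)
    eamf = x.eamf_correction({"He": ref}, mol, rkb, ints, xc)
    scale = max(np.abs(amf.matrix).max(), 1e-30)
    assert np.abs(amf.matrix - eamf.matrix).max() < 1e-8 * scale


def test_eamf_long_range_charge_cancellation():
    """The superposed-density Coulomb potential screens the nuclear tail.

    For a stretched neutral diatomic, the electrostatic potential of the
    superposed atomic electron density cancels the electron-nucleus
    attraction at probe points far from both centers (the stated motivation
    of the molecular-basis correction): checked against the bare multipole
    expectation that the residual is far below either term alone.
    """
    from x2cxas import _mcmurchie as md
    from x2cxas.dirac4c import DiracFockBuilder, pauli_components
    from x2cxas.hamiltonians2c import _superposed_density_raw4c

    basis = x.basis_from_dict({"He": {"even_tempered": {"s": [8, 0.1, 3.0]}}})
    xc = x.XCSpec(functional="hf")
    ref = x.solve_atomic_scf_4c("He", basis, xc)
    mol = x.parse_xyz("2\ncomment bohr\nHe 0 0 0\nHe 0 0 20.0\n")
    rkb, ints = x.build_rkb_integrals(mol, basis)
    D = _superposed_density_raw4c({"He": ref}, mol, rkb)
    b = DiracFockBuilder(rkb, ints, xc)
    D_LL, D_PP, _ = b.expand_density(D)
    qL = pauli_components(D_LL, b.nL)[0].real
    qP = pauli_components(D_PP, b.nP)[0].real
    probes = np.array([[8.0, 0.0, 10.0], [0.0, -9.0, 25.0], [12.0, 0.0, -5.0]])
    for r0 in probes:
        v_nuc = sum(z / np.linalg.norm(r0 - pos) for _s, z, pos in mol.atoms)
        v_el = 0.0
        for sh, q in ((rkb.shells_L, qL), (rkb.shells_P, qP)):
            # 1/|r - r0| matrix via a unit point charge at the probe
            _S, _T, V, _D = md.one_electron(
                sh.centers, sh.exps, sh.ls, sh.offs, sh.nbf,
                np.array([-1.0]), r0.reshape(1, 3), np.array([-1.0]),
                np.zeros(3))
            v_el += np.sum(V * np.outer(sh.norms, sh.norms) * q)
        assert abs(v_nuc - v_el) < 1e-6 * v_nuc


def test_amf_requires_matching_references(h2o_hf):
    xc_other = x.XCSpec(functional="svwn5", hfx=0.5)
    with pytest.raises(ValueError):
        x.amf_correction(h2o_hf["refs"], h2o_hf["mol"], h2o_hf["rkb"],
                         h2o_hf["ints"], xc_other)
    with pytest.raises(ValueError, match="missing atomic reference"):
        x.amf_correction({"O": h2o_hf["refs"]["O"]}, h2o_hf["mol"],
                         h2o_hf["rkb"], h2o_hf["ints"], h2o_hf["xc"])


def test_amf_beats_1e_on_orbital_energies(h2o_hf):
    """amf picture-change correction shrinks 1eX2C orbital-energy errors >10x."""
    res4 = h2o_hf["scf4c"]
    occ4 = res4.mo_energy[res4.n_positive_start: res4.n_positive_start + 10]
    dev = {}
    for tag in ("1ex2c", "amfx2c"):
        dev[tag] = np.abs(h2o_hf["scfs"][tag].mo_energy[:10] - occ4).max()
    assert dev["amfx2c"] < 0.1 * dev["1ex2c"]


def test_amf_total_energy_close_to_4c(h2o_hf):
    assert abs(h2o_hf["scfs"]["amfx2c"].energy - h2o_hf["scf4c"].energy) < 2e-5


def test_mmf_energies_match_4c(h2s_suite):
    res4 = h2s_suite["scf4c"]
    r = h2s_suite["scfs"]["mmfx2c"]
    occ4 = res4.mo_energy[res4.n_positive_start: res4.n_positive_start + 18]
    assert np.abs(r.mo_energy[:18] - occ4).max() < 1e-7


def test_model_ordering_of_so_splittings(h2s_suite):
    """1eX2C overestimates the S 2p spin-orbit splitting; amf/eamf/mmf track 4c."""
    res4 = h2s_suite["scf4c"]
    s = {tag: so_splitting_2p(h2s_suite["scfs"][tag].mo_energy)
         for tag in ("1ex2c", "amfx2c", "eamfx2c", "mmfx2c")}
    s["4c"] = so_splitting_2p(res4.mo_energy[res4.n_positive_start:])
    assert s["1ex2c"] > s["amfx2c"]
    assert s["1ex2c"] / s["amfx2c"] > 1.03  # > 3% overestimation
    assert abs(s["amfx2c"] - s["mmfx2c"]) < 0.05
    assert abs(s["amfx2c"] - s["eamfx2c"]) < 0.05
    assert abs(s["mmfx2c"] - s["4c"]) < 1e-6


def test_2c_restart_from_converged(h2s_suite):
    m = h2s_suite["models"]["amfx2c"]
    r = h2s_suite["scfs"]["amfx2c"]
    r2 = x.solve_scf_2c(m, guess=r.density, maxiter=3)
    assert r2.converged
    assert abs(r2.energy - r.energy) < 1e-9


def test_2c_scf_never_builds_small_component_eris():
    """The 1eX2C path touches no (SS|LL)/(SS|SS)-class integral tensors."""
    mol, basis, rkb, ints = x.load_fixture("h2")
    xc = x.XCSpec(functional="svwn5", hfx=0.25)
    model = x.build_hamiltonian("1ex2c", rkb, ints, xc)
    scf = x.solve_scf_2c(model)
    assert scf.converged
    assert ints.audit["LP"] == 0
    assert ints.audit["PP"] == 0


def test_amf_setup_assembles_small_eris_only_once(h2s_suite):
    """amf/eamf setup cost is one-time; 2c SCF iterations reuse nothing heavy."""
    ints = h2s_suite["ints"]
    before = dict(ints.audit)
    m = h2s_suite["models"]["amfx2c"]
    x.solve_scf_2c(m)
    assert dict(ints.audit) == before


def test_nonrel_limit_pc_corrections_vanish(nonrel_limit):
    """Picture-change corrections scale as 1/c^2: tiny at 100x c."""
    for key in ("m_amf", "m_eamf"):
        dF = nonrel_limit[key].correction.matrix
        assert np.abs(dF).max() < 5e-6
    # scf energies agree with the Schroedinger reference
    assert abs(nonrel_limit["r_amf"].energy
               - nonrel_limit["r_nr"].energy) < 1e-4
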