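"""Shared (session-scoped) fixtures: the expensive SCF references."""

import numpy as np
import pytest

import x2cxas as x


def element_basis(basis, el):
    return x.GaussianBasis(shells={el: basis.for_element(el)})


@pytest.fixture(scope="session")
def h2():
    """Minimal-basis H2 with the hybrid LDA functional (response workhorse)."""
    mol, basis, rkb, ints = x.load_fixture("h2")
    xc = x.XCSpec(functional="svwn5", hfx=0.25)
    model = x.build_hamiltonian("1ex2c", rkb, ints, xc)
    scf = x.solve_scf_2c(model)
    return dict(mol=mol, basis=basis, rkb=rkb, ints=ints, xc=xc,
                model=model, scf=scf)


@pytest.fixture(scope="session")
def h2_hessian(h2):
    hess = x.HessianOperator(h2["scf"])
    P = h2["model"].dipole_2c()
    props = {u: hess.property_mo(P[u]) for u in range(3)}
    return hess, props


@pytest.fixture(scope="session")
def h2o_hf():
    """H2O at the Dirac-Hartree-Fock level: 4c SCF plus all 2c models."""
    mol, basis, rkb, ints = x.load_fixture("h2o")
    xc = x.XCSpec(functional="hf")
    res4 = x.solve_scf_4c(rkb, ints, xc)
    refs = {el: x.solve_atomic_scf_4c(el, element_basis(basis, el), xc)
            for el in ("O", "H")}
    models = {}
    scfs = {}
    for tag in ("1ex2c", "amfx2c", "eamfx2c", "mmfx2c"):
        models[tag] = x.build_hamiltonian(tag, rkb, ints, xc,
                                          atomic_refs=refs, scf4c=res4)
        scfs[tag] = x.solve_scf_2c(models[tag])
    # memory hygiene: the big small-component ERI tensors are no longer
    # needed (they are rebuilt lazily if a test wants them)
    ints.release_small_component()
    for ref in refs.values():
        ref.ints.release_small_component()
    return dict(mol=mol, basis=basis, rkb=rkb, ints=ints, xc=xc, scf4c=res4,
                refs=refs, models=models, scfs=scfs)


@pytest.fixture(scope="session")
def h2s_suite():
    """H2S with the 25%-exact-exchange hybrid: the spin-orbit study fixture."""
    mol, basis, rkb, ints = x.load_fixture("h2s")
    xc = x.XCSpec(functional="svwn5", hfx=0.25)
    res4 = x.solve_scf_4c(rkb, ints, xc)
    refs = {el: x.solve_atomic_scf_4c(el, element_basis(basis, el), xc)
            for el in ("S", "H")}
    models = {}
    scfs = {}
    for tag in ("1ex2c", "amfx2c", "eamfx2c", "mmfx2c"):
        models[tag] = x.build_hamiltonian(tag, rkb, ints, xc,
                                          atomic_refs=refs, scf4c=res4)
        scfs[tag] = x.solve_scf_2c(models[tag])
    # memory hygiene: the big small-component ERI tensors are no longer
    # needed (they are rebuilt lazily if a test wants them)
    ints.release_small_component()
    for ref in refs.values():
        ref.ints.release_small_component()
    return dict(mol=mol, basis=basis, rkb=rkb, ints=ints, xc=xc, scf4c=res4,
                refs=refs, models=models, scfs=scfs)


@pytest.fixture(scope="session")
def nonrel_limit():
    """H2O with the speed of light scaled by 100 plus its Schroedinger twin."""
    c = 100.0 * x.SPEED_OF_LIGHT
    mol, basis, rkb, ints = x.load_fixture("h2o", c=c)
    xc = x.XCSpec(functional="svwn5", hfx=0.25)
    refs = {el: x.solve_atomic_scf_4c(el, element_basis(basis, el), xc, c=c)
            for el in ("O", "H")}
    m_amf = x.build_hamiltonian("amfx2c", rkb, ints, xc, atomic_refs=refs)
    m_eamf = x.build_hamiltonian("eamfx2c", rkb, ints, xc, atomic_refs=refs)
    m_nr = x.build_hamiltonian("nonrel", rkb, ints, xc)
    r_amf = x.solve_scf_2c(m_amf)
    r_nr = x.solve_scf_2c(m_nr)
    ints.release_small_component()
    for ref in refs.values():
        ref.ints.release_small_component()
    return dict(mol=mol, basis=basis, rkb=rkb, ints=ints, xc=xc, c=c,
                refs=refs, m_amf=m_amf, m_eamf=m_eamf, m_nr=m_nr,
                r_amf=r_amf, r_nr=r_nr)


def dense_from_action(hess):
    """Dense A, B by applying the Hessian action to unit trial vectors."""
    n = hess.dim
    A = np.zeros((n, n), complex)
    B = np.zeros((n, n), complex)
    for k in range(n):
        T = np.zeros(n, complex)
        T[k] = 1.0
        T = T.reshape(hess.Nv, hess.No)
        A[:, k] = hess.apply_A(T).ravel()
        B[:, k] = hess.apply_B(T).ravel()
    return A, B
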