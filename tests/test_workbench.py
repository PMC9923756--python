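"""Workbench: synthetic problems, dense oracles, pipeline, determinism."""

import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import x2cxas as x
from x2cxas.workbench import (
    _ELEMENT_BASES,
    _GEOMETRIES,
    core_window_guess,
    dense_oracle_solve,
    main_line_positions,
    make_model_response_problem,
    model_hessian,
)


class TestModelProblems:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(dim=st.integers(1, 12), seed=st.integers(0, 40))
    def test_generator_is_stable_and_deterministic(self, dim, seed):
        p1 = make_model_response_problem(dim, seed)
        p2 = make_model_response_problem(dim, seed)
        assert np.array_equal(p1.A, p2.A) and np.array_equal(p1.B, p2.B)
        stab = np.block([[p1.A, p1.B], [p1.B.conj(), p1.A.conj()]])
        assert np.linalg.norm(stab - stab.conj().T) < 1e-12
        assert np.linalg.eigvalsh(stab).min() > 0

    def test_dimension_one_uncoupled(self):
        p = make_model_response_problem(1, seed=0, coupling=0.0)
        ref = dense_oracle_solve(p, n_roots=1)
        assert ref["omegas"][0] == pytest.approx(np.real(p.A[0, 0]))

    def test_seeded_ensemble_iterative_vs_dense(self):
        """Twenty seeded problems (dim <= 50): solvers match oracles to 1e-10."""
        worst_dr = worst_ev = 0.0
        for seed in range(20):
            dim = 10 + (seed * 7) % 41  # deterministic spread, <= 50
            prob = make_model_response_problem(dim, seed=seed)
            hess = model_hessian(prob)
            spec = x.ResponseSpec(frequencies=[0.7], gamma=0.02,
                                  solver_tol=1e-12)
            sol = x.solve_damped_response(hess, {0: prob.P.reshape(-1, 1)}, spec)
            ref = dense_oracle_solve(prob, omega=0.7, gamma=0.02)["XY"][0]
            it = np.concatenate([sol.X[0][0].ravel(), sol.Y[0][0].ravel()])
            worst_dr = max(worst_dr, np.linalg.norm(it - ref))
            nr = min(5, dim)
            exc = x.solve_eigen(hess, nr, tol=1e-12)
            refo = dense_oracle_solve(prob, n_roots=nr)["omegas"]
            worst_ev = max(worst_ev, np.abs(exc.omegas - refo).max())
        assert worst_dr < 1e-10
        assert worst_ev < 1e-10

    def test_dense_oracle_refuses_large(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((2001, 2001))
        with pytest.raises(ValueError):
            dense_oracle_solve((A, A * 0), n_roots=1)

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            make_model_response_problem(0, seed=1)


class TestCVSSelection:
    def test_core_selector_h2o(self, h2o_hf):
        sel = x.select_core_spinors(h2o_hf["scfs"]["amfx2c"], h2o_hf["rkb"],
                                    h2o_hf["ints"], "O:1s")
        assert sel == [0, 1]
        with pytest.raises(ValueError):
            x.select_core_spinors(h2o_hf["scfs"]["amfx2c"], h2o_hf["rkb"],
                                  h2o_hf["ints"], "S:2p")

    def test_core_selector_s2p(self, h2s_suite):
        sel = x.select_core_spinors(h2s_suite["scfs"]["amfx2c"],
                                    h2s_suite["rkb"], h2s_suite["ints"], "S:2p")
        assert sel == [4, 5, 6, 7, 8, 9]

    def test_window_guess_brackets_core_levels(self, h2s_suite):
        scf = h2s_suite["scfs"]["amfx2c"]
        lo, hi = core_window_guess(scf, [4, 5, 6, 7, 8, 9])
        eps_2p = -scf.mo_energy[4] * x.HARTREE_EV
        assert lo < eps_2p < hi + 30.0


@pytest.fixture(scope="module")
def run_files(tmp_path_factory):
    d = tmp_path_factory.mktemp("run")
    geo = d / "h2.xyz"
    geo.write_text(_GEOMETRIES["h2"])
    bas = d / "basis.yml"
    bas.write_text("H:\n  even_tempered:\n    s: [3, 0.15, 3.0]\n")
    return d, str(geo), str(bas)


class TestPipeline:
    def test_run_xas_deterministic_outputs(self, run_files):
        d, geo, bas = run_files
        outs = []
        for i in (1, 2):
            cfg = x.RunConfig(geometry=geo, basis=bas, hamiltonian="1ex2c",
                              functional="hf", method="ev", n_roots=6,
                              window_ev=(10.0, 45.0, 0.5),
                              out_spectrum=str(d / f"s{i}.tsv"),
                              out_sticks=str(d / f"j{i}.json"))
            res = x.run_xas(cfg)
            outs.append(res)
        b1 = open(d / "s1.tsv", "rb").read()
        b2 = open(d / "s2.tsv", "rb").read()
        assert b1 == b2
        assert open(d / "j1.json").read() == open(d / "j2.json").read()
        assert outs[0]["provenance"]["scf_energy"] == pytest.approx(
            outs[1]["provenance"]["scf_energy"], abs=1e-12)

    def test_run_xas_dr_mode_and_line_readout(self, run_files):
        d, geo, bas = run_files
        cfg = x.RunConfig(geometry=geo, basis=bas, hamiltonian="1ex2c",
                          functional="hf", method="dr",
                          window_ev=(14.0, 30.0, 0.25), gamma_ev=0.5)
        res = x.run_xas(cfg)
        sp = res["spectrum"]
        assert sp.strength.min() > -1e-12
        lines = main_line_positions(sp, n_lines=2)
        assert len(lines) >= 1
        assert 14.0 <= lines[0] <= 30.0

    def test_invalid_configs_rejected_before_compute(self, run_files):
        _d, geo, bas = run_files
        with pytest.raises(ValueError):
            x.run_xas(x.RunConfig(geometry=geo, basis=bas, method="dr",
                                  gamma_ev=0.0))
        with pytest.raises(ValueError):
            x.run_xas(x.RunConfig(geometry=geo, basis=bas, method="bogus"))
        with pytest.raises(ValueError):
            x.run_xas(x.RunConfig(geometry=geo, basis=bas,
                                  hamiltonian="dkh2"))

    def test_runconfig_yaml_round_trip(self, run_files):
        d, geo, bas = run_files
        cfgf = d / "cfg.yml"
        cfgf.write_text(
            f"geometry: {geo}\nbasis: {bas}\nhamiltonian: 1ex2c\n"
            "functional: hf\nmethod: ev\nn_roots: 4\n"
            "window_ev: [10.0, 45.0, 0.5]\n")
        cfg = x.RunConfig.from_yaml(str(cfgf))
        assert cfg.hamiltonian == "1ex2c"
        assert cfg.n_roots == 4


class TestCLI:
    def test_run_command_writes_spectrum(self, run_files):
        from click.testing import CliRunner

        from x2cxas.cli import main as cli_main

        d, geo, bas = run_files
        out = str(d / "cli_spec.tsv")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "run", "--geometry", geo, "--basis", bas, "--hamiltonian", "1ex2c",
            "--functional", "hf", "--method", "ev", "--nroots", "4",
            "--window", "10:45:0.5", "--out", out,
        ])
        assert res.exit_code == 0, res.output
        assert "SCF energy" in res.output
        assert os.path.exists(out)

    def test_roots_command_lists_oscillator_strengths(self, run_files):
        from click.testing import CliRunner

        from x2cxas.cli import main as cli_main

        d, geo, bas = run_files
        out = str(d / "cli_sticks.json")
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "roots", "--geometry", geo, "--basis", bas, "--hamiltonian",
            "1ex2c", "--functional", "hf", "--nroots", "3",
            "--window", "10:45:0.5", "--out", out,
        ])
        assert res.exit_code == 0, res.output
        assert "omega/eV" in res.output
        assert os.path.exists(out)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 30))
def test_spectrum_tsv_round_trip(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    n = 7
    sp = x.Spectrum(omega_ev=np.sort(rng.random(n)) * 100,
                    strength=rng.random(n),
                    alpha=(rng.standard_normal((3, 3, n))
                           + 1j * rng.standard_normal((3, 3, n))),
                    gamma_ev=0.15)
    p = tmp_path_factory.mktemp("io") / "s.tsv"
    sp.to_tsv(p)
    sp2 = x.Spectrum.from_tsv(p)
    assert np.abs(sp2.omega_ev - sp.omega_ev).max() < 1e-12
    assert np.abs(sp2.alpha - sp.alpha).max() < 1e-12
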