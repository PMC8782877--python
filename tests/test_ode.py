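"""Rate-term models, the three-phase protocol and settling-time measurement."""

import warnings

import numpy as np
import pytest
import sympy as sp

from petrisens import (
    ModelError,
    ODEModel,
    RateTerm,
    SimulationProtocol,
    Trajectory,
    evaluate_rhs,
    load_model,
    reduced_fixture_model,
    settling_time,
    simulate_protocol,
)


def p53_balance_oracle():
    """Independent symbolic reconstruction of the phosphorylated-p53 balance:
    (spontaneous + saturating ATM + saturating Chk2 activation)·p53_n
    − Wip1 inactivation − (spontaneous + quadratic-Mdm2 degradation)·p53_pn."""
    s = sp.symbols("p53_n p53_pn ATM_an CHK2_pn WIP1_n MDM2_pn")
    p53_n, p53_pn, atm, chk2, wip1, mdm2 = s
    a1, a2, a3, k1, k2, c1, d4, d5 = sp.symbols(
        "act_spont act_atm_max act_chk2_max km_atm km_chk2 inact_wip1 "
        "deg_spont deg_mdm2"
    )
    expr = (
        (a1 + a2 * atm / (atm + k1) + a3 * chk2 / (chk2 + k2)) * p53_n
        - c1 * p53_pn * wip1
        - (d4 + d5 * mdm2**2) * p53_pn
    )
    return sp.lambdify((*s, a1, a2, a3, k1, k2, c1, d4, d5), expr, "numpy")


def decay_model(p=0.5, x0=2.0):
    return ODEModel(["x"], {"p": p}, [RateTerm("x", -1, "p * x", "decay")],
                    initial_state=[x0])


SHORT_PROTOCOL = SimulationProtocol(
    phase1_duration=0.01, phase2_duration=1.0, phase3_duration=10.0,
    tnf_level=0.0, ir_dose=0.0, step=0.05,
)


def quiet_simulate(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_protocol(*args, **kwargs)


class TestEvaluateRhs:
    def test_zero_state_zero_basal_rates(self):
        model = ODEModel(
            ["x", "y"], {"k": 1.0},
            [RateTerm("x", -1, "k * x", "decay"),
             RateTerm("y", +1, "k * x * y", "cross")],
        )
        assert np.allclose(evaluate_rhs(model, [0.0, 0.0]), 0.0)

    def test_michaelis_menten_saturation_limit(self, fixture_model):
        p = fixture_model.parameters
        state = {s: 0.0 for s in fixture_model.species}
        state.update({"p53_n": 2.0, "ATM_an": 1e9})
        dx = evaluate_rhs(fixture_model, [state[s] for s in fixture_model.species])
        d_p53pn = dx[fixture_model.species.index("p53_pn")]
        saturated = (p["act_spont"] + p["act_atm_max"]) * 2.0
        assert d_p53pn == pytest.approx(saturated, rel=1e-6)

    def test_all_symbols_one_closed_form(self, fixture_model):
        p = fixture_model.parameters
        dx = evaluate_rhs(fixture_model, np.ones(6))
        expected = (
            p["act_spont"]
            + p["act_atm_max"] / (1 + p["km_atm"])
            + p["act_chk2_max"] / (1 + p["km_chk2"])
            - p["inact_wip1"]
            - (p["deg_spont"] + p["deg_mdm2"])
        )
        assert dx[fixture_model.species.index("p53_pn")] == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_symbolic_oracle_at_random_states(self, fixture_model):
        oracle = p53_balance_oracle()
        p = fixture_model.parameters
        pars = [p["act_spont"], p["act_atm_max"], p["act_chk2_max"],
                p["km_atm"], p["km_chk2"], p["inact_wip1"], p["deg_spont"],
                p["deg_mdm2"]]
        rng = np.random.default_rng(42)
        j = fixture_model.species.index("p53_pn")
        for _ in range(100):
            state = rng.uniform(0.0, 5.0, size=6)
            got = evaluate_rhs(fixture_model, state)[j]
            want = oracle(*state, *pars)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

    def test_nan_state_rejected(self, fixture_model):
        with pytest.raises(ModelError, match="NaN"):
            evaluate_rhs(fixture_model, [np.nan] + [0.0] * 5)

    def test_wrong_length_rejected(self, fixture_model):
        with pytest.raises(ModelError, match="length"):
            evaluate_rhs(fixture_model, [1.0, 2.0])

    def test_undeclared_symbol_rejected(self):
        with pytest.raises(ModelError, match="mystery"):
            ODEModel(["x"], {"k": 1.0}, [RateTerm("x", -1, "k * mystery", "bad")])

    def test_unused_parameter_warns(self):
        with pytest.warns(UserWarning, match="never used"):
            ODEModel(["x"], {"k": 1.0, "inert": 2.0},
                     [RateTerm("x", -1, "k * x", "decay")])


class TestFixtureModel:
    def test_six_species(self, fixture_model):
        assert len(fixture_model.species) == 6
        assert set(fixture_model.species) == {
            "p53_n", "p53_pn", "ATM_an", "CHK2_pn", "WIP1_n", "MDM2_pn"
        }

    def test_each_balance_parameter_in_expected_terms(self, fixture_model):
        by_species = fixture_model.parameters_of_species()
        for param in ("act_spont", "act_atm_max", "act_chk2_max", "km_atm",
                      "km_chk2", "inact_wip1"):
            assert param in by_species["p53_pn"]
        for param in ("deg_spont", "deg_mdm2"):
            assert param in by_species["p53_pn"]
            assert param not in by_species["p53_n"]

    def test_unstressed_steady_state_has_low_damage_arm(self, fixture_model):
        # linear drivers: with IR = 0, ATM and Chk2 production is zero and
        # both decay to 0; Wip1 and Mdm2 settle at synthesis/decay
        traj = quiet_simulate(
            fixture_model, SimulationProtocol(ir_dose=0.0, step=0.5)
        )
        final = {s: traj[s][-1] for s in fixture_model.species}
        p = fixture_model.parameters
        assert final["ATM_an"] == pytest.approx(0.0, abs=1e-8)
        assert final["CHK2_pn"] == pytest.approx(0.0, abs=1e-8)
        assert final["WIP1_n"] == pytest.approx(
            p["wip1_syn"] / p["wip1_deg"], rel=1e-4
        )
        assert final["MDM2_pn"] == pytest.approx(
            p["mdm2_syn"] / p["mdm2_deg"], rel=1e-4
        )


class TestSimulateProtocol:
    def test_equilibrium_start_gives_flat_trajectory(self, fixture_model):
        protocol = SimulationProtocol(ir_dose=0.0, tnf_level=0.0, step=0.5)
        settled = quiet_simulate(fixture_model, protocol).final_state()
        traj = simulate_protocol(fixture_model, protocol, initial_state=settled)
        for s in fixture_model.species:
            x = traj[s]
            assert np.all(np.abs(x - x[0]) <= 1e-5 * max(abs(x[0]), 1e-9) + 1e-7)

    def test_pure_decay_matches_closed_form(self):
        traj = quiet_simulate(decay_model(p=0.5, x0=2.0), SHORT_PROTOCOL)
        exact = 2.0 * np.exp(-0.5 * traj.time)
        assert np.max(np.abs(traj["x"] - exact)) < 1e-5

    def test_radiation_pulse_transiently_raises_p53(self, fixture_model):
        traj = simulate_protocol(fixture_model, SimulationProtocol(step=0.25))
        b1, b2 = traj.phase_boundaries
        pre = traj["p53_pn"][traj.time <= b1][-1]
        post = traj["p53_pn"][traj.time >= b1]
        assert post.max() > 2 * pre          # rises under the pulse
        assert traj["p53_pn"][-1] == pytest.approx(pre, rel=0.05)  # relaxes back

    def test_phase1_equilibrium_warning(self, fixture_model):
        protocol = SimulationProtocol(phase1_duration=0.5, step=0.1)
        with pytest.warns(UserWarning, match="equilibrium"):
            simulate_protocol(fixture_model, protocol)

    def test_trajectory_nonnegative(self, fixture_model):
        traj = simulate_protocol(fixture_model, SimulationProtocol(step=0.25))
        assert np.all(traj.values >= 0.0)

    def test_tolerance_halving_convergence(self, fixture_model):
        protocol = SimulationProtocol(step=0.25)
        coarse = quiet_simulate(fixture_model, protocol, rtol=1e-6, atol=1e-9)
        fine = quiet_simulate(fixture_model, protocol, rtol=5e-7, atol=5e-10)
        scale = np.abs(fine.values).max()
        assert np.abs(coarse.values - fine.values).max() < 1e-3 * scale


class TestSettlingTime:
    def test_constant_trajectory_settles_immediately(self):
        t = np.linspace(0.0, 10.0, 101)
        traj = Trajectory(t, np.full((1, t.size), 3.0), ("x",), (1.0, 2.0))
        assert settling_time(traj, "x") == 0.0

    def test_exponential_decay_closed_form(self):
        # x0 e^{-pt} enters the band ±band·x0 around 0 at t = ln(1/band)/p
        p, x0, band = 0.8, 2.0, 0.05
        t = np.linspace(0.0, 40.0, 8001)
        x = x0 * np.exp(-p * t)
        traj = Trajectory(t, x[None, :], ("x",), (0.0, 0.0))
        expected = np.log(1.0 / band) / p
        got = settling_time(traj, "x", band=band, reference=x0)
        assert got == pytest.approx(expected, abs=2 * (t[1] - t[0]))

    def test_sustained_oscillation_never_settles(self):
        t = np.linspace(0.0, 50.0, 2001)
        x = 1.0 + np.sin(2 * np.pi * t)
        traj = Trajectory(t, x[None, :], ("x",), (0.0, 1.0))
        assert np.isnan(settling_time(traj, "x", band=0.05))

    def test_requires_post_stimulus_samples(self):
        t = np.linspace(0.0, 1.0, 11)
        traj = Trajectory(t, np.ones((1, 11)), ("x",), (2.0, 3.0))
        with pytest.raises(ModelError, match="stimulation"):
            settling_time(traj, "x")


class TestModelConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "name: toy\n"
            "species: [x]\n"
            "inputs: [TNF, IR]\n"
            "parameters: {a: 1.0, b: 0.5}\n"
            "initial_state: {x: 0.0}\n"
            "terms:\n"
            "  - {target: x, sign: '+', rate: a, name: production}\n"
            "  - {target: x, sign: '-', rate: b * x, name: decay}\n"
        )
        model = load_model(str(cfg))
        assert model.species == ["x"]
        assert evaluate_rhs(model, [2.0])[0] == pytest.approx(1.0 - 0.5 * 2.0)

    def test_missing_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("species: [x]\nparameters: {}\n")
        with pytest.raises(ModelError, match="terms"):
            load_model(str(cfg))
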