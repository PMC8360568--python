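"""AP model: gating, mutation/maturation orthogonality, integration."""

import copy
import math
from dataclasses import replace

import numpy as np
import pytest
import yaml

from aprepair.ap_model import (
    CURRENT_IDS,
    GateModel,
    PacingProtocol,
    SimulationError,
    Trace,
    build_model,
    default_model_path,
    diastolic_threshold,
    pace_to_steady,
    simulate,
    simulate_reference,
    translate_cell_type,
    xkr2_inf,
)
from aprepair.biomarkers import compute_biomarkers


def _config():
    with open(default_model_path()) as fh:
        return yaml.safe_load(fh)


class TestIKrInactivationGate:
    def test_wild_type_midpoint(self):
        assert xkr2_inf(-70.0, "WT") == pytest.approx(0.5, rel=1e-12)

    def test_mutant_midpoint_shifted_62mV(self):
        assert xkr2_inf(-8.0, "N588K") == pytest.approx(0.5, rel=1e-12)

    def test_one_slope_unit_above_midpoint(self):
        assert xkr2_inf(-70.0 + 20.9, "WT") == pytest.approx(1 / (1 + math.e), rel=1e-12)

    def test_value_at_zero_mV(self):
        # high-precision evaluation via sympy as an independent oracle
        import sympy

        expected = float(1 / (1 + sympy.exp(sympy.Rational(70) / sympy.Rational(209, 10))).evalf(30))
        assert xkr2_inf(0.0, "WT") == pytest.approx(expected, rel=1e-12)

    def test_mutant_exceeds_wild_type_above_minus_140(self):
        v = np.linspace(-140.0, 60.0, 2001)
        assert np.all(xkr2_inf(v, "N588K") > xkr2_inf(v, "WT"))

    def test_bounded_in_unit_interval(self):
        v = np.linspace(-200.0, 200.0, 801)
        for variant in ("WT", "N588K"):
            x = xkr2_inf(v, variant)
            assert np.all((x > 0) & (x < 1))

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            xkr2_inf(float("nan"), "WT")
        with pytest.raises(ValueError):
            xkr2_inf(float("inf"), "N588K")


class TestModelConstruction:
    def test_variants_differ_only_in_ikr_gate(self, adult_wt, adult_mutant):
        # rho values and every other packed parameter are identical
        p_wt, p_mut = adult_wt.packed_params(), adult_mutant.packed_params()
        diff = np.nonzero(p_wt != p_mut)[0]
        assert len(diff) == 2  # the two I_Kr-inactivation parameters only
        for cid in CURRENT_IDS:
            assert adult_wt.currents[cid].rho == adult_mutant.currents[cid].rho

    def test_missing_rho_for_cell_type_is_an_error(self):
        cfg = _config()
        del cfg["currents"]["I_f"]["rho"]["rabbit"]
        with pytest.raises(ValueError, match="I_f.*rabbit"):
            build_model(cfg, "rabbit", "WT")

    def test_unknown_current_id_is_an_error(self):
        cfg = _config()
        cfg["currents"]["I_bogus"] = {"g0": 1.0, "rho": {"adult-human": 1.0}}
        with pytest.raises(ValueError, match="I_bogus"):
            build_model(cfg, "adult-human", "WT")

    def test_gate_validation(self):
        with pytest.raises(ValueError):
            GateModel(v_half=0.0, slope=0.0)
        with pytest.raises(ValueError):
            GateModel(v_half=0.0, slope=1.0, tau_base=-1.0)

    def test_gate_steady_state_bounded(self, adult_wt):
        for gate in adult_wt.gates.values():
            for v in np.linspace(-150, 80, 47):
                assert 0.0 <= gate.steady_state(v) <= 1.0
                assert gate.time_constant(v) > 0.0


class TestTranslation:
    def test_identity(self, adult_wt):
        assert translate_cell_type(adult_wt, "adult-human") is adult_wt

    def test_unknown_cell_type(self, adult_wt):
        with pytest.raises(ValueError):
            translate_cell_type(adult_wt, "dog")

    def test_only_rho_changes_and_mutation_survives(self, adult_mutant):
        hipsc = translate_cell_type(adult_mutant, "hiPSC-CM")
        assert hipsc.mutation == "N588K"
        assert hipsc.gates == adult_mutant.gates
        for cid in CURRENT_IDS:
            assert (hipsc.currents[cid].flux_params
                    == adult_mutant.currents[cid].flux_params)

    def test_current_scales_by_rho_ratio(self, adult_wt):
        hipsc = translate_cell_type(adult_wt, "hiPSC-CM")
        state = _mid_plateau_state(adult_wt)
        i_adult = adult_wt.current_values(state)
        i_hipsc = hipsc.current_values(state)
        for cid in CURRENT_IDS:
            r = hipsc.currents[cid].rho / adult_wt.currents[cid].rho
            assert i_hipsc[cid] == pytest.approx(r * i_adult[cid], rel=1e-12)


def _mid_plateau_state(model):
    """A frozen mid-plateau state with every current away from zero."""
    y = model.resting_state()
    y[0] = -20.0  # away from every reversal potential
    y[1:-1] = 0.5
    y[-1] = 0.4
    return y


class TestOrthogonality:
    """Maturation scaling and the mutation act on orthogonal factors."""

    def test_maturation_ratio_independent_of_mutation(self):
        path = default_model_path()
        for a, b in (("adult-human", "hiPSC-CM"), ("rabbit", "adult-human")):
            ratios = {}
            for mut in ("WT", "N588K"):
                ma = build_model(path, a, mut)
                mb = build_model(path, b, mut)
                state = _mid_plateau_state(ma)
                ia, ib = ma.current_values(state), mb.current_values(state)
                ratios[mut] = np.array([ia[c] / ib[c] for c in CURRENT_IDS])
            np.testing.assert_allclose(ratios["WT"], ratios["N588K"], rtol=1e-12)

    def test_mutation_ratio_independent_of_cell_type(self):
        path = default_model_path()
        ratios = {}
        for ct in ("adult-human", "rabbit", "hiPSC-CM"):
            wt = build_model(path, ct, "WT")
            mut = build_model(path, ct, "N588K")
            state = _mid_plateau_state(wt)
            iw, im = wt.current_values(state), mut.current_values(state)
            ratios[ct] = np.array([im[c] / iw[c] for c in CURRENT_IDS])
        np.testing.assert_allclose(ratios["adult-human"], ratios["rabbit"], rtol=1e-12)
        np.testing.assert_allclose(ratios["adult-human"], ratios["hiPSC-CM"], rtol=1e-12)

    def test_ohmic_currents_vanish_at_reversal(self, adult_wt):
        rev = adult_wt.config["reversal"]
        y = _mid_plateau_state(adult_wt)
        y[0] = rev["E_K"]
        vals = adult_wt.current_values(y)
        for cid in ("I_Kr", "I_Ks", "I_K1"):
            assert vals[cid] == pytest.approx(0.0, abs=1e-12)
        y[0] = rev["E_Na"]
        vals = adult_wt.current_values(y)
        assert vals["I_Na"] == pytest.approx(0.0, abs=1e-12)
        assert vals["I_NaL"] == pytest.approx(0.0, abs=1e-12)


class TestSimulation:
    def test_unit_factors_reproduce_drug_free_solution_bitwise(self, adult_wt):
        proto = PacingProtocol(n_prebeats=3)
        plain = simulate(adult_wt, proto)
        unit = simulate(adult_wt, proto, factors={c: 1.0 for c in CURRENT_IDS})
        assert np.array_equal(plain.v, unit.v)
        assert np.array_equal(plain.ca, unit.ca)

    def test_silent_model_keeps_constant_voltage(self):
        cfg = _config()
        for block in cfg["currents"].values():
            block["g0"] = 0.0
        model = build_model(cfg, "adult-human", "WT")
        proto = PacingProtocol(stimulus_amplitude=0.0, n_prebeats=1)
        trace = simulate(model, proto)
        assert np.all(trace.v == trace.v[0])

    def test_negative_factor_rejected(self, adult_wt):
        with pytest.raises(ValueError):
            simulate(adult_wt, PacingProtocol(n_prebeats=1), factors={"I_Kr": -0.5})

    def test_unknown_factor_current_warns(self, adult_wt):
        with pytest.warns(UserWarning, match="I_to"):
            simulate(adult_wt, PacingProtocol(n_prebeats=1), factors={"I_to": 0.5})

    def test_divergence_reports_failing_time(self):
        cfg = _config()
        cfg["currents"]["I_Na"]["g0"] = 1e9  # force a blow-up
        model = build_model(cfg, "adult-human", "WT")
        with pytest.raises(SimulationError) as err:
            simulate(model, PacingProtocol(n_prebeats=1))
        assert err.value.t_fail is not None and err.value.t_fail >= 0.0

    def test_steady_pacing_converges_before_beat_cap(self, adult_wt, protocol):
        _, n_beats = pace_to_steady(adult_wt, protocol)
        assert 1 < n_beats < protocol.n_prebeats

    def test_halving_dt_changes_apd90_below_half_ms(self, adult_wt, wt_biomarkers, protocol):
        fine = replace(protocol, dt=protocol.dt / 2, record_stride=protocol.record_stride * 2)
        bm_fine = compute_biomarkers(simulate(adult_wt, fine))
        assert abs(bm_fine["APD90"] - wt_biomarkers["APD90"]) < 0.5

    def test_adaptive_reference_solver_agrees(self, adult_wt, protocol):
        state, _ = pace_to_steady(adult_wt, protocol)
        fixed = compute_biomarkers(simulate(adult_wt, protocol, initial_state=state))
        ref = compute_biomarkers(simulate_reference(adult_wt, protocol, initial_state=state))
        assert fixed["APD90"] == pytest.approx(ref["APD90"], abs=0.5)
        assert fixed["CaA"] == pytest.approx(ref["CaA"], rel=1e-3)

    def test_diastolic_threshold_below_default_stimulus(self, adult_wt, protocol):
        thr = diastolic_threshold(adult_wt)
        assert 0.0 < thr < protocol.stimulus_amplitude

    def test_trace_validation(self):
        t = np.array([0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            Trace(time=t, v=np.zeros(3), ca=np.zeros(3))
        with pytest.raises(ValueError):
            Trace(time=np.array([0.0, 1.0]), v=np.array([0.0, np.nan]),
                  ca=np.zeros(2))

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            PacingProtocol(cycle_length=1.0, stimulus_duration=2.0)
        with pytest.raises(ValueError):
            PacingProtocol(n_prebeats=0)
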