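"""Cost function and dose search, checked against brute-force grid oracles."""

import numpy as np
import pytest

from aprepair.biomarkers import BIOMARKER_NAMES
from aprepair.cost_optimizer import (
    CostSpec,
    DoseBounds,
    cost_from_biomarkers,
    optimize_incremental,
    optimize_single,
    pairwise_scan,
)


def _panel(**overrides):
    """A synthetic biomarker dict: 100.0 everywhere unless overridden."""
    values = {name: 100.0 for name in BIOMARKER_NAMES}
    values.update(overrides)
    return values


class TestCost:
    def test_identical_biomarkers_cost_zero(self):
        assert cost_from_biomarkers(_panel(), _panel()) == 0.0

    def test_single_weighted_deviation(self):
        # APD90 off by 10% with weight 5 -> cost 0.5
        treated = _panel(APD90=110.0)
        assert cost_from_biomarkers(treated, _panel()) == pytest.approx(0.5)

    def test_two_unit_weight_deviations_add(self):
        treated = _panel(CaR=120.0, CaA=90.0)  # +20% and -10%
        assert cost_from_biomarkers(treated, _panel()) == pytest.approx(0.3)

    def test_sign_insensitive_reference(self):
        # relative deviations use |R_W|; a negative reference (RMP) works
        wt = _panel(RMP=-80.0)
        treated = _panel(RMP=-88.0)  # 10% of |RMP|
        assert cost_from_biomarkers(treated, wt) == pytest.approx(0.1)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="CaR"):
            cost_from_biomarkers(_panel(), _panel(CaR=0.0))

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            CostSpec(weights={"APD90": -1.0})
        with pytest.raises(ValueError):
            CostSpec(weights={name: 0.0 for name in BIOMARKER_NAMES})
        with pytest.raises(ValueError):
            CostSpec(weights={"not_a_biomarker": 1.0})

    def test_default_weights(self):
        spec = CostSpec()
        assert spec.weights["APD80"] == spec.weights["APD90"] == 5.0
        assert spec.weights["dvdt_max"] == 5.0
        assert spec.weights["APD50"] == 1.0


class TestDoseBounds:
    def test_saturation_cap_matches_hill_inversion(self, library):
        cap = DoseBounds(mode="saturation-cap").resolve(library["veratridine"])
        assert cap == pytest.approx(0.426 * 19.0 ** 0.5, rel=1e-12)  # ~1.857 uM

    def test_ec50_modes(self, library):
        quin = library["quinidine"]  # smallest EC50 is 8.14 uM on I_Kr
        assert DoseBounds(mode="min-EC50").resolve(quin) == 8.14
        assert DoseBounds(mode="half-min-EC50").resolve(quin) == 4.07

    def test_explicit_mode(self, library):
        b = DoseBounds(mode="explicit", explicit={"quinidine": 2.0})
        assert b.resolve(library["quinidine"]) == 2.0
        with pytest.raises(KeyError):
            b.resolve(library["veratridine"])

    def test_validation(self):
        with pytest.raises(ValueError):
            DoseBounds(mode="unbounded")
        with pytest.raises(ValueError):
            DoseBounds(mode="explicit", explicit={"a": -1.0})


# ---------------------------------------------------------------------------
# analytic cost landscapes (cheap to grid-scan)
# ---------------------------------------------------------------------------


def _toy_objective():
    """Smooth 'cost' over doses of drugs a (optimum 3.1) and b (optimum 1.2),
    with a mild interaction; drug z has no effect."""

    def objective(doses):
        a = doses.get("a", 0.0)
        b = doses.get("b", 0.0)
        return 0.05 + 0.1 * (a - 3.1) ** 2 + 0.4 * (b - 1.2) ** 2 + 0.02 * a * b

    return objective


BOUNDS = {"a": 10.0, "b": 5.0, "z": 8.0}


class TestSingleDrug:
    def test_matches_1001_point_grid_scan(self):
        objective = _toy_objective()
        grid = np.linspace(0.0, BOUNDS["a"], 1001)
        scan_best = grid[np.argmin([objective({"a": g}) for g in grid])]
        res = optimize_single("a", BOUNDS["a"], objective)
        assert abs(res.doses["a"] - scan_best) <= grid[1] - grid[0]

    def test_cost_is_reevaluation_at_reported_doses(self):
        objective = _toy_objective()
        res = optimize_single("a", BOUNDS["a"], objective)
        assert res.cost == pytest.approx(objective(res.doses), rel=1e-12)

    def test_ineffective_drug_reports_zero_dose(self):
        objective = _toy_objective()
        res = optimize_single("z", BOUNDS["z"], objective)
        assert res.doses["z"] == 0.0
        assert res.cost == pytest.approx(objective({}), rel=1e-12)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError):
            optimize_single("a", 0.0, _toy_objective())


class TestIncremental:
    def test_two_drug_matches_101x101_grid_scan(self):
        objective = _toy_objective()
        ga = np.linspace(0.0, BOUNDS["a"], 101)
        gb = np.linspace(0.0, BOUNDS["b"], 101)
        costs = np.array([[objective({"a": x, "b": y}) for y in gb] for x in ga])
        i, j = np.unravel_index(np.argmin(costs), costs.shape)
        results = optimize_incremental(["a", "b"], BOUNDS, objective, max_n=2)
        final = results[-1]
        assert abs(final.doses["a"] - ga[i]) <= ga[1] - ga[0]
        assert abs(final.doses["b"] - gb[j]) <= gb[1] - gb[0]
        assert final.cost <= costs[i, j] + 1e-6

    def test_cost_sequence_non_increasing(self):
        objective = _toy_objective()
        results = optimize_incremental(["a", "b", "z"], BOUNDS, objective)
        costs = [r.cost for r in results]
        assert costs == sorted(costs, reverse=True) or all(
            c2 <= c1 + 1e-12 for c1, c2 in zip(costs, costs[1:])
        )

    def test_null_drug_enters_at_zero_dose_without_cost_change(self):
        objective = _toy_objective()
        results = optimize_incremental(["a", "b", "z"], BOUNDS, objective, max_n=3)
        assert set(results[-1].drugs) == {"a", "b", "z"}
        assert results[-1].doses["z"] <= 1e-6 * BOUNDS["z"]
        # cost unchanged to within the solver's cost tolerance (the
        # continuation may still polish the active doses slightly)
        assert results[-1].cost <= results[1].cost + 1e-12
        assert results[-1].cost == pytest.approx(results[1].cost, abs=1e-4)

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError):
            optimize_incremental([], BOUNDS, _toy_objective())


class TestPairwiseScan:
    def test_matrix_matches_grid_oracle_and_is_symmetric(self):
        objective = _toy_objective()
        matrix, best = pairwise_scan(["a", "b", "z"], BOUNDS, objective)
        assert np.allclose(matrix.values, matrix.values.T, equal_nan=False)
        # oracle for the (a, b) entry
        ga = np.linspace(0.0, BOUNDS["a"], 101)
        gb = np.linspace(0.0, BOUNDS["b"], 101)
        oracle = min(objective({"a": x, "b": y}) for x in ga for y in gb)
        assert matrix.loc["a", "b"] == pytest.approx(oracle, abs=1e-3)
        assert best == ("a", "b")

    def test_null_drug_column_equals_single_drug_diagonal(self):
        objective = _toy_objective()
        matrix, _ = pairwise_scan(["a", "z"], BOUNDS, objective)
        assert matrix.loc["a", "z"] == pytest.approx(matrix.loc["a", "a"], abs=1e-6)

    def test_extra_degree_of_freedom_never_hurts(self):
        objective = _toy_objective()
        matrix, _ = pairwise_scan(["a", "b"], BOUNDS, objective)
        assert matrix.loc["a", "b"] <= matrix.loc["a", "a"] + 1e-9
        assert matrix.loc["a", "b"] <= matrix.loc["b", "b"] + 1e-9

    def test_needs_two_drugs(self):
        with pytest.raises(ValueError):
            pairwise_scan(["a"], BOUNDS, _toy_objective())
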