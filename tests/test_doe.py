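"""Box-Behnken construction, coded quadratic fitting, ANOVA identities, and
desirability optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoval import (DesirabilityGoal, FactorSpec, ResponseConstraint, anova,
                      code_levels, desirability, fit_quadratic, generate_bbd,
                      optimize_desirability, overlay_region, uncode_levels)
from chemoval.doe import (OutOfBoundsWarning, QuadraticSurfaceModel,
                          SingularDesignError, UnsupportedDesignError,
                          quadratic_basis)
from chemoval.datasets import BBD_FACTORS
from chemoval.synth import DEFAULT_TRUTH, TruthSurface, make_design_data


class TestBBDStructure:
    @pytest.mark.parametrize("n_center, expected", [(5, 17), (1, 13), (3, 15)])
    def test_run_count(self, n_center, expected):
        d = generate_bbd(BBD_FACTORS, n_center=n_center)
        assert d.n_runs == expected

    def test_edge_and_center_geometry(self):
        d = generate_bbd(BBD_FACTORS, n_center=5)
        coded = d.coded
        # each coded column balances and each edge column has sum of squares 8
        assert np.allclose(coded.sum(axis=0), 0.0)
        assert np.allclose((coded ** 2).sum(axis=0), 8.0)
        # the 12 edge runs enumerate every (+-1,+-1,0)-type combination once
        edges = {tuple(row) for row in coded[:12]}
        expected = set()
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            for si in (-1, 1):
                for sj in (-1, 1):
                    point = [0, 0, 0]
                    point[i], point[j] = si, sj
                    expected.add(tuple(point))
        assert edges == expected
        assert np.allclose(coded[12:], 0.0)

    def test_run_order_shuffle_is_seeded(self):
        a = generate_bbd(BBD_FACTORS, seed=7)
        b = generate_bbd(BBD_FACTORS, seed=7)
        c = generate_bbd(BBD_FACTORS, seed=8)
        assert np.array_equal(a.run_order, b.run_order)
        assert not np.array_equal(a.run_order, c.run_order)

    def test_wrong_factor_count_rejected(self):
        with pytest.raises(UnsupportedDesignError):
            generate_bbd(BBD_FACTORS[:2])


class TestCoding:
    @pytest.mark.parametrize("point, expected", [
        ((30.0, 65.0, 5.0), (0.0, 0.0, 0.0)),
        ((35.0, 70.0, 7.0), (1.0, 1.0, 1.0)),
        ((30.0, 62.5, 3.0), (0.0, -0.5, -1.0)),
    ])
    def test_known_levels(self, point, expected):
        assert np.allclose(code_levels(BBD_FACTORS, point), expected)

    @given(st.floats(min_value=25.0, max_value=35.0),
           st.floats(min_value=60.0, max_value=70.0),
           st.floats(min_value=3.0, max_value=7.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity(self, t, a, p):
        coded = code_levels(BBD_FACTORS, (t, a, p))
        back = uncode_levels(BBD_FACTORS, coded)
        assert np.allclose(back, (t, a, p), atol=1e-12)

    def test_asymmetric_center_stays_monotone(self):
        f = FactorSpec("x", 1.0, 2.0, 10.0)
        xs = np.linspace(1.0, 10.0, 50)
        coded = f.code(xs)
        assert np.all(np.diff(coded) > 0)
        assert f.code(1.0) == -1.0 and f.code(2.0) == 0.0 and f.code(10.0) == 1.0

    def test_out_of_range_warns_and_extrapolates(self):
        f = BBD_FACTORS[0]
        with pytest.warns(OutOfBoundsWarning):
            assert f.code(40.0) == pytest.approx(2.0)


class TestFit:
    def test_printed_coefficients_reproduced(self, models):
        # linear coefficients of the fitted retention-time and resolution surfaces
        assert abs(models["Rt"].b_linear[1]) == pytest.approx(0.8749, abs=5e-5)
        assert models["Rt"].b_linear[0] == pytest.approx(-0.1453, abs=1e-4)
        assert models["Rs"].b_linear[2] == pytest.approx(-1.17, abs=5e-3)
        assert models["Rs"].b0 == pytest.approx(3.22, abs=5e-3)

    def test_zero_noise_recovery_to_1e8(self):
        design = generate_bbd(BBD_FACTORS, n_center=5)
        truth = TruthSurface(models=DEFAULT_TRUTH.models, noise_sd={})
        filled = make_design_data(truth, design, seed=0)
        for true_model in truth.models:
            fitted = fit_quadratic(filled, true_model.response_name)
            assert np.allclose(fitted.coefficients, true_model.coefficients,
                               atol=1e-8)

    def test_agrees_with_statsmodels(self, design):
        sm = pytest.importorskip("statsmodels.api")
        X = quadratic_basis(design.coded)
        for name in ("Rs", "Rt"):
            ours = fit_quadratic(design, name).coefficients
            theirs = sm.OLS(design.responses[name], X).fit().params
            assert np.allclose(ours, theirs, atol=1e-10)

    def test_collinear_terms_named(self, design):
        coded = design.coded.copy()
        coded[:, 2] = coded[:, 1]  # pH slaved to %ACN
        bad = design.__class__(factors=design.factors, coded=coded,
                               std_order=design.std_order,
                               run_order=design.run_order,
                               responses=dict(design.responses))
        with pytest.raises(SingularDesignError, match="collinear"):
            fit_quadratic(bad, "Rs")

    def test_prediction_at_origin_is_intercept(self, models):
        for m in models.values():
            assert m.predict(np.zeros(3)) == pytest.approx(m.b0, abs=1e-12)

    def test_predict_exact_on_training_points_when_sse_zero(self):
        design = generate_bbd(BBD_FACTORS, n_center=1)
        truth = TruthSurface(models=DEFAULT_TRUTH.models, noise_sd={})
        filled = make_design_data(truth, design)
        m = fit_quadratic(filled, "Rs")
        assert np.allclose(m.predict(filled.coded), filled.responses["Rs"],
                           atol=1e-10)


class TestAnova:
    def test_printed_table_reproduced(self, design, models):
        a_rs = anova(design, models["Rs"])
        a_rt = anova(design, models["Rt"])
        assert a_rs["Model"].f == pytest.approx(19.24, abs=0.01)
        assert a_rt["Model"].f == pytest.approx(27.30, abs=0.01)
        assert a_rs["C"].f == pytest.approx(90.25, abs=0.01)
        assert a_rt["B"].f == pytest.approx(210.35, abs=0.01)
        assert a_rs["Model"].p == pytest.approx(0.0004, abs=5e-5)
        assert round(a_rs.r2, 2) == 0.96 and round(a_rt.r2, 2) == 0.97
        assert round(a_rs.r2_adj, 2) == 0.91

    def test_ss_decomposition(self, design, models):
        for name, m in models.items():
            table = anova(design, m)
            assert table["Model"].ss + table["Residual"].ss == pytest.approx(
                table["CorTotal"].ss, rel=1e-9)
            assert table["LackOfFit"].ss + table["PureError"].ss == pytest.approx(
                table["Residual"].ss, rel=1e-9, abs=1e-12)
            assert table["Model"].df == 9
            assert table["CorTotal"].df == design.n_runs - 1

    def test_orthogonal_partial_ss_identities(self, design, models):
        # on an exact BBD: linear partial SS = 8 b^2, interaction = 4 b^2
        for name, m in models.items():
            table = anova(design, m)
            for term, b in zip(("A", "B", "C"), m.b_linear):
                assert table[term].ss == pytest.approx(8 * b ** 2, rel=1e-9)
            for term, b in zip(("AB", "AC", "BC"), m.b_interaction):
                assert table[term].ss == pytest.approx(4 * b ** 2, rel=1e-9)

    def test_adjusted_r2_never_exceeds_r2(self, design, models):
        for m in models.values():
            table = anova(design, m)
            assert table.r2_adj <= table.r2 <= 1.0

    def test_identical_center_replicates_zero_pure_error(self, design, models):
        table = anova(design, models["Rs"])
        assert table["PureError"].ss == pytest.approx(0.0, abs=1e-12)
        assert table["LackOfFit"].f is None  # undefined, not NaN

    def test_zero_residual_df_degenerate_flag(self):
        # a saturated 10-run design (generic points, full rank, residual df 0)
        import chemoval.doe as doe_mod
        rng = np.random.default_rng(19)
        coded = rng.uniform(-1.0, 1.0, size=(10, 3))
        order = np.arange(1, 11)
        sat = doe_mod.DesignTable(factors=BBD_FACTORS, coded=coded,
                                  std_order=order, run_order=order)
        truth = TruthSurface(models=DEFAULT_TRUTH.models, noise_sd={})
        filled = make_design_data(truth, sat)
        table = anova(filled, fit_quadratic(filled, "Rs"))
        assert table.degenerate
        assert table["Model"].f is None and table["Model"].p is None


class TestDesirability:
    def _goals(self):
        return [DesirabilityGoal("Rs", "maximize", 1.5, 5.0),
                DesirabilityGoal("Rt", "minimize", 1.5, 2.0)]

    def test_saturated_ramps_give_one(self, models):
        goals = [DesirabilityGoal("Rs", "maximize", -10.0, 0.0),
                 DesirabilityGoal("Rt", "minimize", 10.0, 20.0)]
        assert desirability(list(models.values()), goals, np.zeros(3)) == 1.0

    def test_any_zero_ramp_kills_overall(self, models):
        goals = [DesirabilityGoal("Rs", "maximize", 100.0, 200.0),
                 DesirabilityGoal("Rt", "minimize", 10.0, 20.0)]
        assert desirability(list(models.values()), goals, np.zeros(3)) == 0.0

    def test_hand_evaluated_ramp_arithmetic(self, models):
        # direct ramp evaluation at coded (0, +1, 0) against the library
        point = np.array([0.0, 1.0, 0.0])
        rs, rt = models["Rs"].predict(point), models["Rt"].predict(point)
        d1 = (rs - 1.5) / (5.0 - 1.5)
        d2 = (2.0 - rt) / (2.0 - 1.5)
        expected = np.sqrt(d1 * d2)
        got = desirability(list(models.values()), self._goals(), point)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_goals_is_an_error(self, models):
        with pytest.raises(ValueError):
            desirability(list(models.values()), [], np.zeros(3))

    def test_optimum_meets_chromatographic_goals(self, models):
        res = optimize_desirability(list(models.values()), self._goals(),
                                    grid_resolution=41)
        assert res.feasible
        assert res.predictions["Rs"] > 1.5
        assert res.predictions["Rt"] < 2.0

    def test_refinement_never_worse_than_grid(self, models):
        goals = self._goals()
        coarse = optimize_desirability(list(models.values()), goals,
                                       grid_resolution=11, refine=False)
        polished = optimize_desirability(list(models.values()), goals,
                                         grid_resolution=11, refine=True)
        assert polished.desirability >= coarse.desirability

    def test_grid_refinement_consistency(self, models):
        goals = self._goals()
        a = optimize_desirability(list(models.values()), goals, 21, refine=False)
        b = optimize_desirability(list(models.values()), goals, 41, refine=False)
        assert np.all(np.abs(a.point - b.point) <= 0.1 + 1e-12)

    def test_linear_single_response_optimum_at_vertex(self):
        linear = QuadraticSurfaceModel("y", 0.0, (1.0, 0.5, -0.25),
                                       (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        goals = [DesirabilityGoal("y", "maximize", -2.0, 1.75)]
        res = optimize_desirability([linear], goals, grid_resolution=9)
        assert np.allclose(np.abs(res.point), 1.0)

    def test_infeasible_goals_reported_not_raised(self, models):
        goals = [DesirabilityGoal("Rs", "maximize", 50.0, 60.0)]
        res = optimize_desirability([models["Rs"]], goals, grid_resolution=5)
        assert not res.feasible and res.desirability == 0.0


class TestOverlay:
    def test_mask_matches_pointwise_prediction(self, models):
        constraints = [ResponseConstraint("Rs", "min", 1.5),
                       ResponseConstraint("Rt", "max", 2.0)]
        axis, mask = overlay_region(list(models.values()), constraints,
                                    grid_resolution=15, axes=(0, 1),
                                    fixed_value=0.0)
        for i, u in enumerate(axis):
            for j, v in enumerate(axis):
                point = np.array([u, v, 0.0])
                ok = (models["Rs"].predict(point) >= 1.5
                      and models["Rt"].predict(point) <= 2.0)
                assert mask[i, j] == ok

    def test_region_contains_reported_optimum(self, models):
        constraints = [ResponseConstraint("Rs", "min", 1.5),
                       ResponseConstraint("Rt", "max", 2.0)]
        res = optimize_desirability(
            list(models.values()),
            [DesirabilityGoal("Rs", "maximize", 1.5, 5.0),
             DesirabilityGoal("Rt", "minimize", 1.5, 2.0)], 21)
        axis, mask = overlay_region(list(models.values()), constraints,
                                    grid_resolution=41, axes=(0, 1),
                                    fixed_value=res.point[2])
        assert mask.any()
        i = int(np.argmin(np.abs(axis - res.point[0])))
        j = int(np.argmin(np.abs(axis - res.point[1])))
        assert mask[i, j]

    def test_impossible_constraint_empty_mask(self, models):
        constraints = [ResponseConstraint("Rs", "min", 10.0)]
        _, mask = overlay_region([models["Rs"]], constraints, grid_resolution=9)
        assert not mask.any()
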