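"""Constrained dose nomination: SLSQP vs brute-force grid oracle."""

import dataclasses

import numpy as np
import pytest

from helpers import agg_from

from prsopt import (
    AgentSpec,
    DesignSpec,
    NominationProblem,
    QuadraticResponseSurface,
    coefficients_from_scaled,
    default_panel,
    grid_oracle,
    nominate,
    nominate_context_pair,
    scalarize_weighted,
)
from prsopt.errors import ConfigError
from prsopt.surface import quadratic_term_names


NAMES = ["propolis", "metformin", "regorafenib"]


def _surface(scaled, panel):
    return QuadraticResponseSurface.from_coefficients(
        coefficients_from_scaled(scaled, panel),
        feature_names=[a.name for a in panel],
        upper_bounds=[a.upper_bound for a in panel],
        allow_extrapolation=True,
    )


def _random_problem(seed, panel, with_constraint=True):
    """Random quadratic objective (in scaled space) + quantile-floor constraint."""
    rng = np.random.default_rng(seed)
    terms = quadratic_term_names(NAMES)

    def rand_surface(intercept):
        scaled = {t: float(rng.normal(0, 20)) for t in terms[1:]}
        scaled["intercept"] = intercept
        return _surface(scaled, panel)

    obj = rand_surface(float(rng.normal(60, 20)))
    constraints = ()
    if with_constraint:
        con = rand_surface(float(rng.normal(80, 10)))
        lo = np.array([a.lower_bound for a in panel])
        hi = np.array([a.upper_bound for a in panel])
        axes = [np.linspace(lo[i], hi[i], 11) for i in range(3)]
        G = np.stack([g.ravel() for g in np.meshgrid(*axes)], axis=1)
        floor = float(np.quantile(con.predict(G), 0.3))  # nonempty feasible set
        constraints = ((con, floor),)
    return NominationProblem(
        objective_model=obj,
        panel=tuple(panel),
        constraint_models=constraints,
        n_starts=12,
        seed=seed,
    )


def _cell_tolerance(problem, points_per_axis=51):
    """One grid cell of objective variation: max gradient norm * cell diagonal."""
    lo, hi = problem.box
    est = problem.objective_model
    axes = [np.linspace(lo[i], hi[i], 11) for i in range(3)]
    G = np.stack([g.ravel() for g in np.meshgrid(*axes)], axis=1)
    h = (hi - lo) / (points_per_axis - 1)
    gn = max(float(np.linalg.norm(est.gradient(x) * h)) for x in G)
    return gn + 1e-9


class TestNominate:
    def test_monotone_objective_hits_upper_corner(self):
        panel = default_panel()
        obj = _surface(
            {"intercept": 100.0, "propolis": -30.0, "metformin": -20.0, "regorafenib": -10.0},
            panel,
        )
        res = nominate(NominationProblem(objective_model=obj, panel=panel, seed=0))
        np.testing.assert_allclose(
            res.dose_array, [a.upper_bound for a in panel], rtol=1e-6
        )
        assert res.feasible

    def test_unattainable_floor_reports_infeasible(self):
        panel = default_panel()
        obj = _surface({"intercept": 100.0, "metformin": -5.0}, panel)
        con = _surface({"intercept": 50.0, "propolis": -10.0}, panel)
        res = nominate(
            NominationProblem(
                objective_model=obj,
                panel=panel,
                constraint_models=((con, 90.0),),  # above box-wide max 50
                seed=0,
            )
        )
        assert not res.feasible
        assert res.notes

    @pytest.mark.parametrize("seed", range(25))
    def test_never_worse_than_grid_oracle(self, seed):
        panel = default_panel()
        problem = _random_problem(seed, panel)
        res = nominate(problem)
        oracle = grid_oracle(problem, points_per_axis=51)
        if oracle.feasible:
            assert res.feasible
            assert res.objective_value <= oracle.objective_value + _cell_tolerance(problem)
        lo, hi = problem.box
        assert np.all(res.dose_array >= lo - 1e-12)
        assert np.all(res.dose_array <= hi * (1 + 1e-12))

    def test_deterministic_under_seed(self):
        panel = default_panel()
        problem = _random_problem(3, panel)
        r1, r2 = nominate(problem), nominate(problem)
        np.testing.assert_array_equal(r1.dose_array, r2.dose_array)
        assert r1.objective_value == r2.objective_value

    def test_tightening_floor_never_improves_objective(self):
        panel = default_panel()
        problem = _random_problem(7, panel, with_constraint=True)
        (con, floor0) = problem.constraint_models[0]
        prev = -np.inf
        for floor in np.linspace(floor0 - 5, floor0 + 15, 6):
            p = dataclasses.replace(problem, constraint_models=((con, float(floor)),))
            res = nominate(p)
            if not res.feasible:
                break
            assert res.objective_value >= prev - 1e-6
            prev = res.objective_value


class TestGridOracle:
    def test_separable_interior_minimum_on_grid(self):
        panel = (
            AgentSpec("a", "u", 0.0, 1.0),
            AgentSpec("b", "u", 0.0, 1.0),
            AgentSpec("c", "u", 0.0, 1.0),
        )
        # minimum at (0.5, 0.5, 0.5), exactly a grid node for odd grids
        obj = _surface(
            {
                "intercept": 10.0,
                "a": -2.0, "b": -2.0, "c": -2.0,
                "a^2": 2.0, "b^2": 2.0, "c^2": 2.0,
            },
            panel,
        )
        res = grid_oracle(
            NominationProblem(objective_model=obj, panel=panel), points_per_axis=11
        )
        np.testing.assert_allclose(res.dose_array, [0.5, 0.5, 0.5], atol=1e-12)
        assert res.objective_value == pytest.approx(10 - 3 * 0.5)

    def test_refinement_consistency(self):
        panel = default_panel()
        problem = _random_problem(11, panel)
        r51 = grid_oracle(problem, 51)
        r101 = grid_oracle(problem, 101)
        assert r101.objective_value <= r51.objective_value + 1e-9
        assert r51.objective_value <= r101.objective_value + _cell_tolerance(problem)

    def test_all_infeasible_flagged(self):
        panel = default_panel()
        obj = _surface({"intercept": 100.0}, panel)
        con = _surface({"intercept": 0.0}, panel)
        res = grid_oracle(
            NominationProblem(
                objective_model=obj, panel=panel, constraint_models=((con, 50.0),)
            ),
            points_per_axis=11,
        )
        assert not res.feasible

    def test_minimum_points_per_axis(self):
        panel = default_panel()
        with pytest.raises(ValueError):
            grid_oracle(_random_problem(0, panel), points_per_axis=5)


class TestWeightedSum:
    def test_objective_only_weights_reduce_to_unconstrained(self):
        panel = default_panel()
        base = _random_problem(13, panel, with_constraint=True)
        unconstrained = dataclasses.replace(base, constraint_models=())
        w = dataclasses.replace(
            base, mode="weighted_sum", weights=(1.0, 0.0)
        )
        r_w = scalarize_weighted(w)
        r_u = nominate(unconstrained)
        np.testing.assert_allclose(r_w.dose_array, r_u.dose_array, atol=1e-5 * 10)

    def test_all_weight_on_constraint_maximizes_it(self):
        panel = default_panel()
        base = _random_problem(17, panel, with_constraint=True)
        w = dataclasses.replace(base, mode="weighted_sum", weights=(0.0, 1.0))
        res = scalarize_weighted(w)
        oracle = grid_oracle(w, points_per_axis=51)
        # score = -constraint prediction; optimizer should not be worse
        assert res.objective_value <= oracle.objective_value + _cell_tolerance(w)

    def test_symmetric_two_agent_toy(self):
        panel = (
            AgentSpec("a", "u", 0.0, 1.0),
            AgentSpec("b", "u", 0.0, 1.0),
            AgentSpec("c", "u", 0.0, 1.0),
        )
        # equal weights give score = (a-1/2)^2 + (b-1/2)^2 - 1/2: symmetric
        # bowl with its minimum at a = b = 1/2
        obj = _surface({"intercept": 0.0, "a": -1.0, "a^2": 1.0}, panel)
        con = _surface({"intercept": 0.0, "b": 1.0, "b^2": -1.0}, panel)
        prob = NominationProblem(
            objective_model=obj,
            panel=panel,
            constraint_models=((con, 0.0),),
            mode="weighted_sum",
            weights=(1.0, 1.0),
            seed=0,
        )
        res = scalarize_weighted(prob)
        assert res.dose_array[0] == pytest.approx(0.5, abs=1e-5)
        assert res.dose_array[1] == pytest.approx(0.5, abs=1e-5)
        oracle = grid_oracle(prob, points_per_axis=51)
        assert res.objective_value <= oracle.objective_value + 1e-6

    def test_missing_weights_config_error(self):
        panel = default_panel()
        with pytest.raises(ConfigError):
            scalarize_weighted(
                dataclasses.replace(_random_problem(0, panel), mode="weighted_sum")
            )


class TestContextPair:
    @staticmethod
    def _context_data(panel, obj_surface, con_surface, grid=15, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(grid, 3)) * [a.upper_bound for a in panel]
        return (
            agg_from(X, obj_surface.predict(X), panel),
            [agg_from(X, con_surface.predict(X), panel)],
        )

    def test_designed_shift_moves_nomination(self):
        panel = default_panel()
        spec = DesignSpec(agents=panel)
        obj = _surface(
            {"intercept": 100.0, "propolis": -40.0, "metformin": -30.0,
             "regorafenib": -20.0},
            panel,
        )
        con_free = _surface(
            {"intercept": 100.0, "propolis": -30.0, "metformin": -10.0},
            panel,
        )
        # FA: hepatocytes much more propolis-sensitive, metformin-tolerant
        con_fa = _surface(
            {"intercept": 100.0, "propolis": -80.0, "metformin": -2.0},
            panel,
        )
        data = {
            "FA-free": self._context_data(panel, obj, con_free, grid=25, seed=1),
            "FA": self._context_data(panel, obj, con_fa, grid=25, seed=2),
        }
        out = nominate_context_pair(data, spec, floors=[70.0], seed=0)
        d_free = out["FA-free"]["result"].dose_array
        d_fa = out["FA"]["result"].dose_array
        assert d_fa[0] < d_free[0]  # propolis backed off under FA
        assert d_fa[1] >= d_free[1] - 1e-9  # metformin holds or increases
        # verify each context against its own grid oracle
        for ctx, con in (("FA-free", con_free), ("FA", con_fa)):
            prob = NominationProblem(
                objective_model=obj, panel=panel,
                constraint_models=((con, 70.0),), seed=0,
            )
            oracle = grid_oracle(prob, points_per_axis=51)
            res = out[ctx]["result"]
            assert res.objective_value <= oracle.objective_value + _cell_tolerance(prob)

    def test_identical_data_identical_nominations(self):
        panel = default_panel()
        spec = DesignSpec(agents=panel)
        obj = _surface({"intercept": 100.0, "metformin": -30.0, "propolis": -20.0}, panel)
        con = _surface({"intercept": 100.0, "metformin": -20.0}, panel)
        payload = self._context_data(panel, obj, con, grid=20, seed=3)
        out = nominate_context_pair({"A": payload, "B": payload}, spec, floors=[75.0])
        np.testing.assert_array_equal(
            out["A"]["result"].dose_array, out["B"]["result"].dose_array
        )

    def test_one_rank_deficient_context_isolated(self):
        panel = default_panel()
        spec = DesignSpec(agents=panel)
        obj = _surface({"intercept": 100.0, "metformin": -30.0}, panel)
        good = self._context_data(panel, obj, obj, grid=20, seed=4)
        rng = np.random.default_rng(0)
        X_bad = np.zeros((20, 3))
        X_bad[:, 1] = rng.uniform(0, 10, 20)  # only metformin varies
        bad = (agg_from(X_bad, obj.predict(X_bad), panel), [])
        out = nominate_context_pair({"good": good, "bad": bad}, spec, floors=[50.0])
        assert "error" in out["bad"]
        assert out["good"]["result"].feasible
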