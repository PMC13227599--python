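"""Constrained multi-objective dose nomination within the tested dose box.

The default ("hard constraint") formulation minimizes the objective
surface's prediction (e.g., tumor-cell viability, or the hepatic macrophage
infiltration ratio) subject to floor constraints on other surfaces (e.g.,
predicted non-malignant hepatocyte viability >= theta) and box bounds equal
to the experimentally tested dose extremes.  Dose sets are never nominated
outside the tested box.

Quadratic surfaces on a box can be indefinite, so the solver is multi-start
sequential quadratic programming (SLSQP) with the analytic gradient of the
quadratic form, started from a seeded Latin hypercube plus the box corners
and center.  A brute-force tensor-grid oracle is provided for verification.

A weighted-sum scalarization is available as an alternative formulation;
the hard-constraint mode remains the default reproduction path.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize
from scipy.stats import qmc

from .errors import ConfigError
from .io import AgentSpec, DoseCombination
from .surface import DesignSpec, FittedSurface, QuadraticResponseSurface, _with_extrapolation, fit_quadratic_surface

#: Constraint / feasibility tolerance in endpoint units.
FEAS_TOL = 1e-6
#: Objective ties within this are broken by total normalized dose burden.
TIE_TOL = 1e-6


def _estimator(model) -> QuadraticResponseSurface:
    est = model.estimator if isinstance(model, FittedSurface) else model
    return _with_extrapolation(est)  # SLSQP iterates may graze the box edge


def _label(model, default: str) -> str:
    if isinstance(model, FittedSurface):
        return f"{model.endpoint_name}/{model.context}"
    return default


@dataclass(frozen=True)
class NominationProblem:
    """One constrained dose-nomination instance.

    ``constraint_models`` pairs each tolerance surface with its floor: the
    surface's prediction must stay at or above the floor (endpoint units).
    The box is taken from the agent panel's tested bounds.
    """

    objective_model: FittedSurface | QuadraticResponseSurface
    panel: tuple[AgentSpec, ...]
    constraint_models: tuple[tuple[object, float], ...] = ()
    n_starts: int = 32
    seed: int = 0
    mode: str = "hard_constraint"  # or "weighted_sum"
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("hard_constraint", "weighted_sum"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    @property
    def box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([a.lower_bound for a in self.panel])
        hi = np.array([a.upper_bound for a in self.panel])
        return lo, hi

    def with_objective(self, model) -> "NominationProblem":
        return dataclasses.replace(self, objective_model=model)


@dataclass
class NominationResult:
    """Optimizer output: nominated dose set with predictions and provenance."""

    dose: DoseCombination
    dose_array: np.ndarray
    predicted: dict[str, float]
    feasible: bool
    active_constraints: list[str]
    solver: str
    n_starts_converged: int
    objective_value: float
    mode: str = "hard_constraint"
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dose": self.dose.as_dict(),
            "predicted": self.predicted,
            "feasible": self.feasible,
            "active_constraints": self.active_constraints,
            "solver": self.solver,
            "n_starts_converged": self.n_starts_converged,
            "objective_value": self.objective_value,
            "mode": self.mode,
            "notes": self.notes,
        }


def _starts(problem: NominationProblem) -> np.ndarray:
    """Deterministic multi-start set: seeded LHS + box corners + center."""
    lo, hi = problem.box
    d = lo.size
    pts = [0.5 * (lo + hi)]
    if d <= 6:  # corners only while 2^d stays small
        pts += [np.array(c) for c in itertools.product(*zip(lo, hi))]
    if problem.n_starts > 0:
        lhs = qmc.LatinHypercube(d=d, seed=problem.seed).random(problem.n_starts)
        pts += list(qmc.scale(lhs, lo, hi))
    return np.array(pts)


def _prescan(problem: NominationProblem, points_per_axis: int = 31):
    """Vectorized coarse tensor-grid scan: (grid, objective, feasibility mask).

    Quadratic surfaces on a box can have several local minima, so SLSQP
    starts are augmented with the best feasible scan points (global-local
    hybrid); the scan also provides the feasibility pre-check.
    """
    lo, hi = problem.box
    axes = [np.linspace(lo[i], hi[i], points_per_axis) for i in range(lo.size)]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    obj = _estimator(problem.objective_model).predict(grid)
    feas = np.ones(len(grid), dtype=bool)
    for m, floor in problem.constraint_models:
        feas &= _estimator(m).predict(grid) >= floor - FEAS_TOL
    return grid, obj, feas


def _pick_best(
    candidates: list[tuple[float, np.ndarray]], hi: np.ndarray
) -> tuple[float, np.ndarray]:
    """Lowest objective; ties broken by total normalized dose, then lexicographic."""
    best_obj = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_obj + TIE_TOL]
    tied.sort(key=lambda c: (float(np.sum(c[1] / hi)), tuple(c[1])))
    return tied[0]


def _result(
    problem: NominationProblem,
    x: np.ndarray,
    feasible: bool,
    n_converged: int,
    solver: str,
    notes: list[str] | None = None,
) -> NominationResult:
    lo, hi = problem.box
    x = np.clip(x, lo, hi)
    obj_est = _estimator(problem.objective_model)
    obj_val = float(obj_est.predict(x.reshape(1, -1))[0])
    predicted = {"objective:" + _label(problem.objective_model, "model"): obj_val}
    active = []
    for i, (m, floor) in enumerate(problem.constraint_models):
        lab = f"constraint_{i}:" + _label(m, "model")
        v = float(_estimator(m).predict(x.reshape(1, -1))[0])
        predicted[lab] = v
        if v - floor <= FEAS_TOL:
            active.append(lab)
    dose = DoseCombination.from_mapping(
        {a.name: float(xi) for a, xi in zip(problem.panel, x)}
    )
    return NominationResult(
        dose=dose,
        dose_array=x,
        predicted=predicted,
        feasible=feasible,
        active_constraints=active if feasible else [],
        solver=solver,
        n_starts_converged=n_converged,
        objective_value=obj_val,
        mode=problem.mode,
        notes=notes or [],
    )


def _slsqp_multistart(
    problem: NominationProblem,
    fun,
    jac,
    constraints: list[dict],
    extra_starts: np.ndarray | None = None,
) -> tuple[list[tuple[float, np.ndarray]], int]:
    """Multi-start SLSQP in box-normalized coordinates.

    Agent doses can span many orders of magnitude (fold-dilutions next to
    millimolar concentrations), which wrecks SLSQP's internal step and
    tolerance heuristics; solving in u = x/upper coordinates conditions the
    problem.  Inputs and outputs stay in original dose units.
    """
    lo, hi = problem.box
    s = np.where(hi > 0, hi, 1.0)
    bounds = list(zip(lo / s, hi / s))
    cons_u = [
        {
            "type": c["type"],
            "fun": (lambda u, c=c: c["fun"](u * s)),
            "jac": (lambda u, c=c: c["jac"](u * s) * s),
        }
        for c in constraints
    ]
    feasible_local: list[tuple[float, np.ndarray]] = []
    n_converged = 0
    starts = _starts(problem)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([starts, extra_starts])
    for x0 in starts:
        res = scipy.optimize.minimize(
            lambda u: fun(u * s),
            x0 / s,
            jac=lambda u: jac(u * s) * s,
            bounds=bounds,
            constraints=cons_u,
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if not res.success:
            continue
        n_converged += 1
        x = np.clip(res.x * s, lo, hi)
        ok = all(
            float(c["fun"](x)) >= -FEAS_TOL for c in constraints
        )
        if ok:
            feasible_local.append((float(fun(x)), x))
    return feasible_local, n_converged


def nominate(problem: NominationProblem) -> NominationResult:
    """Solve the constrained nomination problem by multi-start SLSQP.

    Returns the best feasible local optimum across starts.  When no start
    yields a feasible point and a grid pre-scan confirms an empty feasible
    region, the result carries ``feasible=False`` and the dose minimizing
    total constraint violation, never a silent answer.
    """
    if problem.mode == "weighted_sum":
        return scalarize_weighted(problem)
    obj = _estimator(problem.objective_model)
    fun = lambda x: float(obj.predict(x.reshape(1, -1))[0])  # noqa: E731
    jac = lambda x: obj.gradient(x)  # noqa: E731
    cons = []
    for m, floor in problem.constraint_models:
        est = _estimator(m)
        cons.append(
            {
                "type": "ineq",
                "fun": (lambda x, e=est, f=floor: float(e.predict(x.reshape(1, -1))[0]) - f),
                "jac": (lambda x, e=est: e.gradient(x)),
            }
        )
    grid, obj_scan, feas = _prescan(problem)
    extra = None
    if feas.any():
        idx = np.flatnonzero(feas)
        extra = grid[idx[np.argsort(obj_scan[idx])[:8]]]
    feasible_local, n_conv = _slsqp_multistart(problem, fun, jac, cons, extra)
    if extra is not None:
        # guarantee we are never worse than the best feasible scan point
        feasible_local.append((float(obj_scan[feas].min()), extra[0]))
    if feasible_local:
        _, x = _pick_best(feasible_local, problem.box[1])
        return _result(problem, x, True, n_conv, "SLSQP")

    lo, hi = problem.box
    s = np.where(hi > 0, hi, 1.0)
    viol = lambda x: float(  # noqa: E731
        sum(max(0.0, -(c["fun"](x))) for c in cons)
    )
    best = None
    for x0 in _starts(problem):
        res = scipy.optimize.minimize(
            lambda u: viol(u * s), x0 / s, bounds=list(zip(lo / s, hi / s)),
            method="SLSQP", options={"maxiter": 200},
        )
        x = np.clip(res.x * s, lo, hi)
        v = viol(x)
        if best is None or v < best[0]:
            best = (v, x)
    return _result(
        problem, best[1], False, n_conv, "SLSQP",
        notes=["no feasible point in the tested box; constraint-violation minimizer"],
    )


def grid_oracle(problem: NominationProblem, points_per_axis: int = 51) -> NominationResult:
    """Exhaustive tensor-grid search over the box, including the endpoints.

    Exact arg-min among feasible grid points; deterministic.  Serves as the
    independent verification oracle for :func:`nominate`.
    """
    if points_per_axis < 11:
        raise ValueError("points_per_axis must be >= 11")
    lo, hi = problem.box
    axes = [np.linspace(lo[i], hi[i], points_per_axis) for i in range(lo.size)]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    obj = _estimator(problem.objective_model).predict(grid)
    if problem.mode == "weighted_sum":
        w = _checked_weights(problem)
        total = w[0] * obj
        for wi, (m, _) in zip(w[1:], problem.constraint_models):
            total = total - wi * _estimator(m).predict(grid)
        score, feas = total, np.ones(len(grid), dtype=bool)
    else:
        score = obj
        feas = np.ones(len(grid), dtype=bool)
        for m, floor in problem.constraint_models:
            feas &= _estimator(m).predict(grid) >= floor - FEAS_TOL
    if not feas.any():
        j = int(np.argmin(score))
        return _result(
            problem, grid[j], False, 0, f"grid({points_per_axis})",
            notes=["all grid points infeasible"],
        )
    idx = np.flatnonzero(feas)
    cands = [(float(score[j]), grid[j]) for j in idx[np.argsort(score[idx])[:64]]]
    _, x = _pick_best(cands, hi)
    res = _result(problem, x, True, 0, f"grid({points_per_axis})")
    if problem.mode == "weighted_sum":
        res.objective_value = float(_pick_best(cands, hi)[0])
    return res


def _checked_weights(problem: NominationProblem) -> np.ndarray:
    if problem.weights is None:
        raise ConfigError("weighted_sum mode requires weights")
    w = np.asarray(problem.weights, dtype=float)
    if w.size != 1 + len(problem.constraint_models):
        raise ConfigError(
            "need one weight for the objective plus one per constraint model"
        )
    if (w < 0).any() or not w.any():
        raise ConfigError("weights must be nonnegative and not all zero")
    return w


def scalarize_weighted(problem: NominationProblem) -> NominationResult:
    """Weighted-sum scalarization: minimize w0*objective - sum_c w_c*constraint.

    Floors are ignored in this mode; the result is labeled with the mode so
    the hard-constraint formulation remains the default reproduction path.
    """
    w = _checked_weights(problem)
    obj = _estimator(problem.objective_model)
    cons_est = [_estimator(m) for m, _ in problem.constraint_models]

    def fun(x):
        v = w[0] * float(obj.predict(x.reshape(1, -1))[0])
        for wi, e in zip(w[1:], cons_est):
            v -= wi * float(e.predict(x.reshape(1, -1))[0])
        return v

    def jac(x):
        g = w[0] * obj.gradient(x)
        for wi, e in zip(w[1:], cons_est):
            g = g - wi * e.gradient(x)
        return g

    prob = dataclasses.replace(problem, mode="weighted_sum")
    feasible_local, n_conv = _slsqp_multistart(prob, fun, jac, [])
    if not feasible_local:  # box-constrained smooth problem: always solvable
        j = int(np.argmin([fun(x) for x in _starts(prob)]))
        x = _starts(prob)[j]
    else:
        _, x = _pick_best(feasible_local, prob.box[1])
    res = _result(prob, x, True, n_conv, "SLSQP")
    res.objective_value = fun(res.dose_array)
    return res


def nominate_context_pair(
    data_by_context: dict,
    spec: DesignSpec,
    floors: Sequence[float] = (),
    n_starts: int = 32,
    seed: int = 0,
) -> dict:
    """Fit and nominate independently per context (e.g., FA-free vs FA).

    ``data_by_context`` maps a context label to a tuple
    ``(objective_agg, [constraint_agg, ...])`` of aggregated responses; the
    i-th constraint table is paired with ``floors[i]``.  Contexts that fail
    the fit (e.g., rank-deficient design) are reported with an ``"error"``
    entry while the remaining contexts are returned.
    """
    out: dict = {}
    for context in sorted(data_by_context):
        payload = data_by_context[context]
        obj_agg, cons_aggs = payload if isinstance(payload, tuple) else (payload, [])
        try:
            obj_fit = fit_quadratic_surface(obj_agg, spec)
            cons_fits = [fit_quadratic_surface(c, spec) for c in cons_aggs]
            problem = NominationProblem(
                objective_model=obj_fit,
                panel=tuple(spec.agents),
                constraint_models=tuple(zip(cons_fits, floors)),
                n_starts=n_starts,
                seed=seed,
            )
            out[context] = {
                "result": nominate(problem),
                "objective": obj_fit,
                "constraints": cons_fits,
            }
        except Exception as exc:  # propagate per-context, keep the rest
            out[context] = {"error": f"{type(exc).__name__}: {exc}"}
    if all("error" in v for v in out.values()):
        raise ConfigError(f"every context failed: {out}")
    return out
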