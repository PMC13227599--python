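"""Quadratic response-surface regression for multi-drug dose-response data.

The model is a full second-order polynomial in the agent doses,

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j,

fit by ordinary least squares to condition-mean responses.  For three agents
this is 10 terms: intercept, 3 linear, 3 squared, 3 pairwise interactions,
always in that fixed order so coefficient reports are comparable across
contexts and endpoints.

Because agents can span wildly different numeric ranges (a fold-dilution of
order 1e-4 next to a millimolar concentration), doses are internally divided
by each agent's upper bound before the polynomial expansion, and the
coefficients are back-transformed to original units for reporting.  This
rescaling is exact in exact arithmetic and purely a conditioning device.
A z-score standardized fit is available as a sensitivity analysis; it leaves
fitted values and R^2 unchanged and reports coefficients per SD.

:class:`QuadraticResponseSurface` follows the scikit-learn estimator
protocol (``fit``/``predict``/``get_params``) so it composes with sklearn
model selection; the module-level functions mirror the pipeline's functional
surface and are thin wrappers over the estimator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import (
    ExtrapolationError,
    SingularDesignError,
    StandardizationError,
    UnderdeterminedError,
)
from .io import AggregatedResponse, AgentSpec, DoseCombination

__all__ = [
    "DesignSpec",
    "QuadraticResponseSurface",
    "quadratic_term_names",
    "build_design_matrix",
    "fit_quadratic_surface",
    "predict",
    "predicted_vs_observed",
]


def quadratic_term_names(names: Sequence[str]) -> list[str]:
    """Fixed term order: intercept, linear, squared, pairwise interactions."""
    names = list(names)
    return (
        ["intercept"]
        + names
        + [f"{n}^2" for n in names]
        + [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    )


def _expand(W: np.ndarray) -> np.ndarray:
    """Second-order polynomial expansion of an (n, d) dose matrix."""
    n, d = W.shape
    cols = [np.ones(n)]
    cols += [W[:, i] for i in range(d)]
    cols += [W[:, i] ** 2 for i in range(d)]
    cols += [W[:, i] * W[:, j] for i, j in itertools.combinations(range(d), 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class DesignSpec:
    """Design options for one surface fit.

    ``standardize`` selects original-unit coefficients (with internal
    rescaling for conditioning when ``internal_rescale``) or a z-scored
    sensitivity fit; ``center_for_vif`` mean-centers non-intercept columns,
    the convention under which collinearity is assessed.
    """

    agents: tuple[AgentSpec, ...]
    standardize: str = "original_units"  # or "zscore"
    center_for_vif: bool = False
    internal_rescale: bool = True

    def __post_init__(self) -> None:
        if self.standardize not in ("original_units", "zscore"):
            raise ValueError(f"unknown standardize mode {self.standardize!r}")

    @property
    def term_names(self) -> list[str]:
        return quadratic_term_names([a.name for a in self.agents])

    @property
    def n_terms(self) -> int:
        d = len(self.agents)
        return 1 + 2 * d + d * (d - 1) // 2


def build_design_matrix(
    doses: Sequence[DoseCombination] | np.ndarray, spec: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Quadratic design matrix in the fixed term order.

    Under ``zscore`` the linear dose columns are z-scored *before* squaring
    and multiplying; under ``center_for_vif`` every non-intercept column of
    the expanded design is mean-centered.
    """
    if isinstance(doses, np.ndarray):
        X = np.asarray(doses, dtype=float)
    else:
        X = np.array([d.as_array(spec.agents) for d in doses], dtype=float)
    if X.ndim != 2 or X.shape[1] != len(spec.agents):
        raise ValueError("doses must be (n, n_agents)")
    if spec.standardize == "zscore":
        sd = X.std(axis=0, ddof=0)
        for a, s in zip(spec.agents, sd):
            if s == 0:
                raise StandardizationError(
                    f"agent {a.name!r} has zero dose variance; cannot z-score"
                )
        W = (X - X.mean(axis=0)) / sd
    elif spec.internal_rescale:
        W = X / np.array([a.upper_bound for a in spec.agents])
    else:
        W = X
    if spec.center_for_vif:
        # Doses are centered before squaring/multiplying (the standard
        # polynomial-collinearity remedy), then the expanded columns are
        # centered so every non-intercept column has mean zero.
        W = W - W.mean(axis=0)
    D = _expand(W)
    if spec.center_for_vif:
        D[:, 1:] -= D[:, 1:].mean(axis=0)
    return D, spec.term_names


class QuadraticResponseSurface(RegressorMixin, BaseEstimator):
    """OLS quadratic dose-response surface with interaction terms.

    Parameters
    ----------
    feature_names : sequence of str, optional
        Agent names in column order of ``X``; defaults to ``x0..x{d-1}``.
    upper_bounds : sequence of float, optional
        Tested upper dose bound per agent.  Used for internal rescaling and
        for the extrapolation guard in :meth:`predict`.
    standardize : {"original_units", "zscore"}
        Coefficient parameterization.  ``original_units`` (default) reports
        back-transformed coefficients in dose units; ``zscore`` is the
        sensitivity parameterization (identical fitted values and R^2).
    rescale : bool
        Divide doses by ``upper_bounds`` internally before the polynomial
        expansion (numerical conditioning; ignored under ``zscore``).
    allow_extrapolation : bool
        Permit predictions outside ``[0, upper_bound]``.

    Attributes
    ----------
    coefficients_ : dict[str, float]
        Term -> coefficient in the reporting parameterization.
    coef_working_ : ndarray
        Coefficients in the internal (rescaled/z-scored) space.
    fitted_, residuals_ : ndarray
        In-sample predictions and residuals, training order.
    r_squared_ : float
        1 - SSE/SST; reported as 1.0 with ``degenerate_fit_`` set when the
        response is constant (SST = 0).
    """

    def __init__(
        self,
        feature_names: Sequence[str] | None = None,
        upper_bounds: Sequence[float] | None = None,
        standardize: str = "original_units",
        rescale: bool = True,
        allow_extrapolation: bool = False,
    ):
        self.feature_names = feature_names
        self.upper_bounds = upper_bounds
        self.standardize = standardize
        self.rescale = rescale
        self.allow_extrapolation = allow_extrapolation

    # -- internal helpers ---------------------------------------------------

    def _working(self, X: np.ndarray) -> np.ndarray:
        return (X - self.shift_) / self.scale_

    def _check_box(self, X: np.ndarray) -> None:
        if self.allow_extrapolation or self.bounds_upper_ is None:
            return
        lo_bad = X < -1e-12
        hi_bad = X > self.bounds_upper_ * (1 + 1e-12)
        if lo_bad.any() or hi_bad.any():
            raise ExtrapolationError(
                "dose outside the tested box [0, upper_bound]; pass "
                "allow_extrapolation=True to predict anyway"
            )

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        if self.standardize not in ("original_units", "zscore"):
            raise ValueError(f"unknown standardize mode {self.standardize!r}")
        X, y = check_X_y(X, y, y_numeric=True)
        n, d = X.shape
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"x{i}" for i in range(d)]
        )
        if len(names) != d:
            raise ValueError("feature_names length does not match X columns")
        self.terms_ = quadratic_term_names(names)
        p = len(self.terms_)
        if n < p:
            raise UnderdeterminedError(f"need >= {p} observations, got {n}")

        self.bounds_upper_ = (
            np.asarray(self.upper_bounds, dtype=float)
            if self.upper_bounds is not None
            else None
        )
        if self.standardize == "zscore":
            sd = X.std(axis=0, ddof=0)
            zero = [names[i] for i in range(d) if sd[i] == 0]
            if zero:
                raise StandardizationError(
                    f"zero dose variance for {zero}; cannot z-score"
                )
            self.shift_, self.scale_ = X.mean(axis=0), sd
        elif self.rescale and self.bounds_upper_ is not None:
            self.shift_, self.scale_ = np.zeros(d), self.bounds_upper_.copy()
        elif self.rescale:
            span = np.abs(X).max(axis=0)
            span[span == 0] = 1.0
            self.shift_, self.scale_ = np.zeros(d), span
        else:
            self.shift_, self.scale_ = np.zeros(d), np.ones(d)

        D = _expand(self._working(X))
        rank = np.linalg.matrix_rank(D)
        if rank < p:
            _, _, piv = scipy.linalg.qr(D, pivoting=True, mode="economic")
            bad = sorted(self.terms_[j] for j in piv[rank:])
            raise SingularDesignError(
                f"rank-deficient quadratic design (rank {rank} < {p}); "
                f"collinear terms: {bad}"
            )
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        self.coef_working_ = coef
        self.fitted_ = D @ coef
        self.residuals_ = y - self.fitted_
        sse = float(self.residuals_ @ self.residuals_)
        sst = float(((y - y.mean()) ** 2).sum())
        self.degenerate_fit_ = sst == 0.0
        if self.degenerate_fit_:
            self.r_squared_ = 1.0
            warnings.warn("constant response (SST = 0); R^2 reported as 1 by convention")
        else:
            self.r_squared_ = 1.0 - sse / sst
        self.n_obs_ = n
        self.n_features_in_ = d
        self.coefficients_ = dict(zip(self.terms_, self._report_coef(names)))
        return self

    def _report_coef(self, names: Sequence[str]) -> np.ndarray:
        """Back-transform working coefficients to the reporting scale."""
        d = len(names)
        b = self.coef_working_
        if self.standardize == "zscore":
            return b.copy()  # reported per SD, the sensitivity contract
        # pure scaling u = x/s: a_i = b_i/s_i, a_ii = b_ii/s_i^2, a_ij = b_ij/(s_i s_j)
        s = self.scale_
        out = [b[0]]
        out += [b[1 + i] / s[i] for i in range(d)]
        out += [b[1 + d + i] / s[i] ** 2 for i in range(d)]
        for k, (i, j) in enumerate(itertools.combinations(range(d), 2)):
            out.append(b[1 + 2 * d + k] / (s[i] * s[j]))
        return np.array(out)

    def predict(self, X):
        """Evaluate the fitted quadratic form (no clipping)."""
        check_is_fitted(self, "coef_working_")
        X = check_array(X)
        self._check_box(X)
        return _expand(self._working(X)) @ self.coef_working_

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of the surface at one dose point (original units)."""
        check_is_fitted(self, "coef_working_")
        x = np.asarray(x, dtype=float)
        d = x.size
        w = (x - self.shift_) / self.scale_
        b = self.coef_working_
        g = b[1 : 1 + d] + 2 * b[1 + d : 1 + 2 * d] * w
        for k, (i, j) in enumerate(itertools.combinations(range(d), 2)):
            g[i] += b[1 + 2 * d + k] * w[j]
            g[j] += b[1 + 2 * d + k] * w[i]
        return g / self.scale_

    # -- construction from known coefficients -------------------------------

    @classmethod
    def from_coefficients(
        cls,
        coefficients: dict[str, float],
        feature_names: Sequence[str],
        upper_bounds: Sequence[float] | None = None,
        allow_extrapolation: bool = False,
    ) -> "QuadraticResponseSurface":
        """Build a surface directly from original-unit coefficients.

        Used for truth surfaces in simulation and for analytically
        constructed test problems.  Missing terms default to zero.
        """
        model = cls(
            feature_names=list(feature_names),
            upper_bounds=upper_bounds,
            allow_extrapolation=allow_extrapolation,
        )
        d = len(feature_names)
        model.terms_ = quadratic_term_names(feature_names)
        unknown = set(coefficients) - set(model.terms_)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")
        model.coef_working_ = np.array(
            [coefficients.get(t, 0.0) for t in model.terms_], dtype=float
        )
        model.shift_ = np.zeros(d)
        model.scale_ = np.ones(d)
        model.bounds_upper_ = (
            np.asarray(upper_bounds, dtype=float) if upper_bounds is not None else None
        )
        model.coefficients_ = dict(zip(model.terms_, model.coef_working_))
        model.n_features_in_ = d
        model.fitted_ = np.empty(0)
        model.residuals_ = np.empty(0)
        model.r_squared_ = float("nan")
        model.degenerate_fit_ = False
        model.n_obs_ = 0
        return model


# ---------------------------------------------------------------------------
# Functional pipeline surface


@dataclass
class FittedSurface:
    """A fitted surface tagged with its (endpoint, context) provenance."""

    estimator: QuadraticResponseSurface
    design: DesignSpec
    context: str
    endpoint_name: str
    doses: np.ndarray = field(repr=False, default=None)
    response: np.ndarray = field(repr=False, default=None)

    @property
    def coefficients(self) -> dict[str, float]:
        return self.estimator.coefficients_

    @property
    def r_squared(self) -> float:
        return self.estimator.r_squared_


def fit_quadratic_surface(
    agg: Sequence[AggregatedResponse],
    spec: DesignSpec,
    on: str = "mean",
) -> FittedSurface:
    """Fit the quadratic surface to aggregated condition means.

    ``on="mean"`` (default) fits one row per condition, the primary
    workflow; ``on="bio_rep"`` fits per-biological-replicate rows as a
    sensitivity analysis.
    """
    if not agg:
        raise ValueError("no aggregated responses to fit")
    contexts = {a.context for a in agg}
    endpoints = {a.endpoint_name for a in agg}
    if len(contexts) > 1 or len(endpoints) > 1:
        raise ValueError("fit one (endpoint, context) pair at a time")
    X_rows, y_rows = [], []
    for a in agg:
        x = a.dose.as_array(spec.agents)
        if on == "mean":
            X_rows.append(x)
            y_rows.append(a.mean_value)
        elif on == "bio_rep":
            for v in a.per_bio_values:
                X_rows.append(x)
                y_rows.append(v)
        else:
            raise ValueError(f"unknown fit target {on!r}")
    est = QuadraticResponseSurface(
        feature_names=[a.name for a in spec.agents],
        upper_bounds=[a.upper_bound for a in spec.agents],
        standardize=spec.standardize,
        rescale=spec.internal_rescale,
    )
    X = np.array(X_rows)
    y = np.array(y_rows)
    est.fit(X, y)
    return FittedSurface(
        estimator=est,
        design=spec,
        context=contexts.pop(),
        endpoint_name=endpoints.pop(),
        doses=X,
        response=y,
    )


def predict(
    model: FittedSurface | QuadraticResponseSurface,
    dose: DoseCombination | np.ndarray,
    allow_extrapolation: bool = False,
) -> float:
    """Evaluate a fitted surface at one dose combination."""
    est = model.estimator if isinstance(model, FittedSurface) else model
    if isinstance(dose, DoseCombination):
        panel = model.design.agents if isinstance(model, FittedSurface) else None
        x = dose.as_array(panel) if panel is not None else np.array(
            [v for _, v in dose.doses]
        )
    else:
        x = np.asarray(dose, dtype=float)
    if allow_extrapolation and not est.allow_extrapolation:
        est = _with_extrapolation(est)
    return float(est.predict(x.reshape(1, -1))[0])


def _with_extrapolation(est: QuadraticResponseSurface) -> QuadraticResponseSurface:
    import copy

    out = copy.copy(est)
    out.allow_extrapolation = True
    return out


def predicted_vs_observed(
    model: FittedSurface,
) -> tuple[list[tuple[float, float]], float]:
    """(observed, predicted) pairs in training order, plus R^2."""
    est = model.estimator
    obs = est.fitted_ + est.residuals_
    return list(zip(obs.tolist(), est.fitted_.tolist())), est.r_squared_
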