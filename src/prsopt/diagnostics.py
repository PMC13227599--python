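"""Model adequacy and robustness checks for fitted response surfaces.

Residual-based assumption tests (Shapiro-Wilk normality, Breusch-Pagan
heteroscedasticity, Durbin-Watson independence), variance inflation factors
on the mean-centered quadratic design, K-fold cross-validated RMSE, and
nonparametric (case-resampling) bootstrap confidence intervals.

Diagnostics warn; they never abort dose nomination.  When assumptions fail
the OLS surface is retained for interpretability and nomination is supported
by the out-of-sample and bootstrap evidence instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats
from sklearn.model_selection import KFold
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

from .errors import (
    BootstrapUnstableError,
    CVInfeasibleError,
    SingularDesignError,
    UndefinedStatisticError,
)
from .io import AggregatedResponse
from .surface import DesignSpec, FittedSurface, build_design_matrix, fit_quadratic_surface

logger = logging.getLogger(__name__)

#: Terms with VIF at or above this are flagged as potentially severely collinear.
VIF_FLAG_THRESHOLD = 3.0


@dataclass
class DiagnosticsReport:
    """Adequacy and robustness summary for one fitted surface."""

    shapiro_w: float
    shapiro_p: float
    bp_stat: float
    bp_p: float
    dw_stat: float
    vif: dict[str, float]
    vif_flag_threshold: float
    cv_rmse: float
    cv_k: int
    bootstrap_ci: dict[str, tuple[float, float]]
    bootstrap_B: int
    seed: int
    flagged_vif_terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["bootstrap_ci"] = {k: list(v) for k, v in self.bootstrap_ci.items()}
        return d


def durbin_watson(residuals: Sequence[float]) -> float:
    """First-order serial-correlation statistic sum((e_t - e_{t-1})^2)/sum(e_t^2).

    Residuals must be in acquisition (run) order.  Near 2 for independent
    errors; 0 signals strong positive, 4 strong negative autocorrelation.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise UndefinedStatisticError("Durbin-Watson needs >= 2 residuals")
    if np.all(e == 0):
        raise UndefinedStatisticError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_durbin_watson(e))


def breusch_pagan(model: FittedSurface) -> tuple[float, float]:
    """Lagrange-multiplier heteroscedasticity test against the model regressors.

    Regresses squared residuals on the quadratic design; the statistic is
    n * R^2 of that auxiliary regression, chi-square with p-1 df under
    homoscedasticity.
    """
    est = model.estimator
    D, _ = build_design_matrix(model.doses, model.design)
    if est.n_obs_ <= D.shape[1]:
        raise UndefinedStatisticError("Breusch-Pagan needs n_obs > n_terms")
    with np.errstate(all="ignore"):
        lm, lm_p, _, _ = het_breuschpagan(est.residuals_, D)
    if not np.isfinite(lm):
        raise SingularDesignError("singular auxiliary design in Breusch-Pagan")
    return float(lm), float(lm_p)


def shapiro_wilk(residuals: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test of the residuals (3 <= n <= 5000)."""
    e = np.asarray(residuals, dtype=float)
    if not 3 <= e.size <= 5000:
        raise UndefinedStatisticError(
            f"Shapiro-Wilk supports 3 <= n <= 5000, got n={e.size}"
        )
    if np.ptp(e) == 0:
        raise UndefinedStatisticError("Shapiro-Wilk undefined for identical values")
    w, p = scipy.stats.shapiro(e)
    return float(w), float(p)


def vif(design: np.ndarray, term_names: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    ``design`` is the mean-centered design *without* the intercept column.
    Exactly collinear columns get ``inf`` rather than raising, so the report
    can still name the offending terms.
    """
    D = np.asarray(design, dtype=float)
    if D.ndim != 2 or D.shape[1] < 2:
        raise ValueError("VIF needs >= 2 non-intercept columns")
    if len(term_names) != D.shape[1]:
        raise ValueError("term_names length mismatch")
    out: dict[str, float] = {}
    n = D.shape[0]
    for j, name in enumerate(term_names):
        yj = D[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(D, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        sst = float(((yj - yj.mean()) ** 2).sum())
        if sst == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_report(
    model: FittedSurface, threshold: float = VIF_FLAG_THRESHOLD
) -> tuple[dict[str, float], list[str]]:
    """VIFs of the model's mean-centered design and the flagged terms."""
    spec = DesignSpec(
        agents=model.design.agents,
        standardize=model.design.standardize,
        center_for_vif=True,
        internal_rescale=model.design.internal_rescale,
    )
    D, names = build_design_matrix(model.doses, spec)
    vals = vif(D[:, 1:], names[1:])
    flagged = [t for t, v in vals.items() if v >= threshold]
    return vals, flagged


def kfold_cv_rmse(
    agg: Sequence[AggregatedResponse],
    spec: DesignSpec,
    k: int = 5,
    seed: int = 0,
) -> float:
    """K-fold cross-validated RMSE of the surface on condition means.

    Conditions are shuffled with ``seed`` and split into ``k`` folds; the
    surface is refit on each training fold and scored on the held-out
    conditions; the RMSE pools all held-out squared errors.  Folds whose
    training design is rank deficient are skipped with a warning.
    """
    n = len(agg)
    if not n >= k >= 2:
        raise ValueError(f"need n_conditions >= k >= 2, got n={n}, k={k}")
    agg = list(agg)
    errors: list[float] = []
    skipped = 0
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.arange(n)
    ):
        train = [agg[i] for i in train_idx]
        try:
            fold = fit_quadratic_surface(train, spec)
        except Exception:  # rank-deficient or under-determined fold
            skipped += 1
            continue
        est = fold.estimator
        X_test = np.array([agg[i].dose.as_array(spec.agents) for i in test_idx])
        y_test = np.array([agg[i].mean_value for i in test_idx])
        pred = est.predict(X_test)
        errors.extend(((y_test - pred) ** 2).tolist())
    if skipped:
        warnings.warn(f"{skipped} CV fold(s) skipped (rank-deficient training design)")
    if not errors:
        raise CVInfeasibleError("every CV training fold was rank deficient")
    return float(np.sqrt(np.mean(errors)))


def bootstrap_model(
    agg: Sequence[AggregatedResponse],
    spec: DesignSpec,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    nomination_problem=None,
) -> dict:
    """Case-resampling bootstrap of the surface fit.

    Aggregated conditions are resampled with replacement; the surface is
    refit per replicate and percentile ``1-alpha`` CIs are formed per
    coefficient.  Rank-deficient resamples are redrawn (count logged); if
    more than half of the draws are rank deficient the data are declared
    bootstrap-unstable.  When ``nomination_problem`` is supplied the dose
    nominated from each replicate's refit yields per-agent dose CIs.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    agg = list(agg)
    n = len(agg)
    rng = np.random.default_rng(seed)
    terms = spec.term_names
    coefs = np.empty((B, len(terms)))
    doses = [] if nomination_problem is not None else None
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                fit = fit_quadratic_surface([agg[i] for i in idx], spec)
            except Exception:
                redrawn += 1
                if redrawn > B // 2 + 50:
                    raise BootstrapUnstableError(
                        f"more than half of bootstrap resamples rank deficient "
                        f"({redrawn} redraws at replicate {b})"
                    )
                continue
            break
        coefs[b] = [fit.coefficients[t] for t in terms]
        if doses is not None:
            from .nomination import nominate  # local import, avoids cycle

            problem = nomination_problem.with_objective(fit)
            doses.append(nominate(problem).dose_array)
    if redrawn:
        logger.info("bootstrap: %d rank-deficient resamples redrawn", redrawn)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci = {
        t: (float(np.percentile(coefs[:, j], lo)), float(np.percentile(coefs[:, j], hi)))
        for j, t in enumerate(terms)
    }
    out = {"bootstrap_ci": ci, "B": B, "seed": seed, "n_redrawn": redrawn}
    if doses is not None:
        darr = np.array(doses)
        out["dose_ci"] = {
            a.name: (
                float(np.percentile(darr[:, j], lo)),
                float(np.percentile(darr[:, j], hi)),
            )
            for j, a in enumerate(spec.agents)
        }
    return out


def diagnose(
    model: FittedSurface,
    agg: Sequence[AggregatedResponse],
    k: int = 5,
    B: int = 1000,
    seed: int = 0,
    vif_threshold: float = VIF_FLAG_THRESHOLD,
) -> DiagnosticsReport:
    """Full adequacy/robustness suite for one fitted surface."""
    est = model.estimator
    sw_w, sw_p = shapiro_wilk(est.residuals_)
    bp_stat, bp_p = breusch_pagan(model)
    dw = durbin_watson(est.residuals_)
    vifs, flagged = vif_report(model, threshold=vif_threshold)
    cv = kfold_cv_rmse(agg, model.design, k=k, seed=seed)
    boot = bootstrap_model(agg, model.design, B=B, seed=seed)
    if flagged:
        warnings.warn(f"VIF >= {vif_threshold} for terms {flagged}")
    return DiagnosticsReport(
        shapiro_w=sw_w,
        shapiro_p=sw_p,
        bp_stat=bp_stat,
        bp_p=bp_p,
        dw_stat=dw,
        vif=vifs,
        vif_flag_threshold=vif_threshold,
        cv_rmse=cv,
        cv_k=k,
        bootstrap_ci=boot["bootstrap_ci"],
        bootstrap_B=B,
        seed=seed,
        flagged_vif_terms=flagged,
    )
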