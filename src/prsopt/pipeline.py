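"""Pipeline orchestration: ingest -> aggregate -> fit -> diagnose -> nominate.

A single YAML (or JSON) config drives the whole five-stage workflow per
(endpoint, context) pair; the report bundle is written as JSON plus
delimited coefficient/pairs tables.  Every stochastic stage carries an
explicit seed, so a rerun with the same config is numerically identical
(the timestamp field is informational and excluded from comparisons).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import yaml

from .diagnostics import VIF_FLAG_THRESHOLD, diagnose
from .errors import ConfigError
from .io import (
    SCHEMA_VERSION,
    AgentSpec,
    aggregate_replicates,
    dilution_to_mass,
    read_dose_response_table,
    records_to_frame,
    write_dose_response_table,
)
from .nomination import NominationProblem, NominationResult, nominate
from .surface import DesignSpec, fit_quadratic_surface, predicted_vs_observed
from .synthetic import example_truths, generate_fa_shift_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    panel: list[dict]
    objective_table: str
    endpoint: str = "viability_pct"
    contexts: list[str] | None = None
    constraint_tables: list[str] = field(default_factory=list)
    floors: list[float] = field(default_factory=list)
    standardize: str = "original_units"
    internal_rescale: bool = True
    fit_on: str = "mean"
    cv_k: int = 5
    bootstrap_B: int = 200
    diagnostics_seed: int = 0
    vif_threshold: float = VIF_FLAG_THRESHOLD
    mode: str = "hard_constraint"
    weights: list[float] | None = None
    n_starts: int = 32
    nomination_seed: int = 0
    schema_version: str = SCHEMA_VERSION

    def agent_panel(self) -> tuple[AgentSpec, ...]:
        return tuple(AgentSpec(**a) for a in self.panel)

    def validate(self) -> None:
        if self.constraint_tables and self.mode == "hard_constraint":
            if len(self.floors) != len(self.constraint_tables):
                raise ConfigError(
                    "hard_constraint mode requires one floor (theta) per "
                    "constraint table; none may be omitted"
                )
        if self.mode == "weighted_sum" and not self.weights:
            raise ConfigError("weighted_sum mode requires weights")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _round(obj):
    """Round floats to 1e-9 relative in serialized output for stable hashing."""
    if isinstance(obj, float):
        return 0.0 if obj == 0 else (obj if not math.isfinite(obj) else float(f"{obj:.9e}"))
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages per context and return (and optionally write) the bundle."""
    config.validate()
    panel = config.agent_panel()
    spec = DesignSpec(
        agents=panel,
        standardize=config.standardize,
        internal_rescale=config.internal_rescale,
    )
    objective_records = read_dose_response_table(config.objective_table, panel)
    constraint_records = [
        read_dose_response_table(p, panel) for p in config.constraint_tables
    ]
    contexts = config.contexts or sorted({r.context for r in objective_records})

    bundle: dict = {
        "schema_version": config.schema_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "contexts": {},
    }
    for context in contexts:
        try:
            bundle["contexts"][context] = _run_context(
                config, spec, context, objective_records, constraint_records
            )
        except Exception as exc:
            raise type(exc)(f"[context={context}] {exc}") from exc

    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _run_context(config, spec, context, objective_records, constraint_records) -> dict:
    obj_agg = aggregate_replicates(
        [r for r in objective_records if r.context == context]
    )
    if not obj_agg:
        raise ConfigError("no objective records for this context")
    obj_fit = fit_quadratic_surface(obj_agg, spec, on=config.fit_on)
    report = diagnose(
        obj_fit,
        obj_agg,
        k=config.cv_k,
        B=config.bootstrap_B,
        seed=config.diagnostics_seed,
        vif_threshold=config.vif_threshold,
    )
    cons_fits = []
    for recs in constraint_records:
        cons_agg = aggregate_replicates([r for r in recs if r.context == context])
        if not cons_agg:
            raise ConfigError("no constraint records for this context")
        cons_fits.append(fit_quadratic_surface(cons_agg, spec, on=config.fit_on))
    problem = NominationProblem(
        objective_model=obj_fit,
        panel=tuple(spec.agents),
        constraint_models=tuple(zip(cons_fits, config.floors)),
        n_starts=config.n_starts,
        seed=config.nomination_seed,
        mode=config.mode,
        weights=tuple(config.weights) if config.weights else None,
    )
    result = nominate(problem)
    pairs, r2 = predicted_vs_observed(obj_fit)
    return {
        "endpoint": obj_fit.endpoint_name,
        "n_conditions": len(obj_agg),
        "coefficients": obj_fit.coefficients,
        "constraint_coefficients": [f.coefficients for f in cons_fits],
        "r_squared": r2,
        "predicted_vs_observed": pairs,
        "diagnostics": report.to_dict(),
        "nomination": result.to_dict(),
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Write report JSON plus per-context coefficient and pairs CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(_round(bundle), indent=2))
    import pandas as pd

    rows = []
    for ctx, res in bundle["contexts"].items():
        for term, beta in res["coefficients"].items():
            rows.append({"context": ctx, "term": term, "coefficient": beta})
    pd.DataFrame(rows).to_csv(out / "coefficients.csv", index=False)
    rows = []
    for ctx, res in bundle["contexts"].items():
        for obs, pred in res["predicted_vs_observed"]:
            rows.append({"context": ctx, "observed": obs, "predicted": pred})
    pd.DataFrame(rows).to_csv(out / "predicted_vs_observed.csv", index=False)
    return out / "report.json"


def report_summary(bundle: dict) -> str:
    """Human-readable per-context summary of the report bundle.

    Displayed predictions are clipped at 0 (with a flag) while the stored
    values remain unclipped; propolis doses are also shown as ug/mL via the
    stock conversion when the panel provides a stock concentration.
    """
    panel = [AgentSpec(**a) for a in bundle["config"]["panel"]]
    lines = []
    for ctx in sorted(bundle["contexts"]):
        res = bundle["contexts"][ctx]
        nom = res["nomination"]
        lines.append(f"context: {ctx}  (endpoint: {res['endpoint']})")
        if not nom["feasible"]:
            lines.append("  *** INFEASIBLE: no dose in the tested box meets all floors ***")
        for a in panel:
            dose = nom["dose"][a.name]
            extra = ""
            if a.stock_mass_conc is not None and a.unit == "fold-dilution":
                extra = f"  ({dilution_to_mass(dose, a.stock_mass_conc):.4g} ug/mL)"
            lines.append(f"  {a.name:<14} {dose:.6g} {a.unit}{extra}")
        for label, v in nom["predicted"].items():
            flag = "  [clipped from {:.3g}]".format(v) if v < 0 else ""
            lines.append(f"  predicted {label:<28} {max(v, 0.0):.4g}{flag}")
        diag = res["diagnostics"]
        lines.append(
            f"  R^2 {res['r_squared']:.4f}  CV-RMSE(k={diag['cv_k']}) "
            f"{diag['cv_rmse']:.4g}  DW {diag['dw_stat']:.3f}"
        )
        flagged = diag["flagged_vif_terms"]
        lines.append(
            f"  VIF>= {diag['vif_flag_threshold']:g}: "
            + (", ".join(flagged) if flagged else "none")
        )
        ci = diag["bootstrap_ci"]
        for term, beta in res["coefficients"].items():
            lo, hi = ci[term]
            lines.append(f"    {term:<28} {beta:+.4g}  [{lo:+.4g}, {hi:+.4g}]")
        lines.append("")
    return "\n".join(lines)


def simulate_example_tables(
    out_dir: str | Path, seed: int = 0, noise_sd: float = 5.0
) -> dict[str, Path]:
    """Write the worked-example synthetic tables (tumor + hepatocyte, two contexts).

    The FA context shifts the truth surfaces the way lipid loading shifts
    the real landscape: weaker propolis/regorafenib tumor kill, stronger
    metformin contribution, better hepatocyte tolerance of propolis.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = example_truths()
    panel = truths["tumor"].panel

    def scaled(shift):
        from .synthetic import coefficients_from_scaled

        return coefficients_from_scaled(shift, panel)

    tumor_shift = scaled(
        {"propolis": 25.0, "regorafenib": 20.0, "metformin": -15.0}
    )
    hep_shift = scaled({"propolis": 15.0, "metformin": 2.0})
    paths = {}
    for name, shift in (("tumor", tumor_shift), ("hepatocyte", hep_shift)):
        truth = dataclasses.replace(
            truths[name], seed=seed, noise_sd=noise_sd
        )
        records = generate_fa_shift_pair(truth, shift)
        path = out / f"{name}_viability.csv"
        write_dose_response_table(records, path)
        paths[name] = path
    return paths


def example_config(out_dir: str | Path, seed: int = 0, floor: float = 70.0) -> RunConfig:
    """Config for the worked example: tumor objective, hepatocyte floor.

    The 70% hepatocyte-viability floor is a documented example default, not
    a reproduced study value; real analyses must set their own theta.
    """
    out = Path(out_dir)
    truths = example_truths()
    return RunConfig(
        panel=[dataclasses.asdict(a) for a in truths["tumor"].panel],
        objective_table=str(out / "tumor_viability.csv"),
        constraint_tables=[str(out / "hepatocyte_viability.csv")],
        floors=[floor],
        bootstrap_B=200,
        diagnostics_seed=seed,
        nomination_seed=seed,
    )
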