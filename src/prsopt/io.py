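"""Domain types, dose-response table I/O, normalization and aggregation.

The on-disk schema is a single long (tidy) delimited table: one row per
measured well or fish, with one column per agent dose, plus endpoint/value/
context/subject/replicate columns.  Wide plate maps are never consumed
directly.  All parsing goes through pandas; this module adds schema
validation, unit bookkeeping and the two-stage replicate mean that feeds the
response-surface fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePlateError,
    DoseRangeError,
    SchemaError,
    TableParseError,
)

logger = logging.getLogger(__name__)

#: Endpoints recognised by the pipeline.
ENDPOINTS = ("viability_pct", "macrophage_density", "macrophage_ratio")

#: Non-dose columns of the long table schema.
TABLE_COLUMNS = ("endpoint", "value", "context", "subject", "bio_rep", "tech_rep")

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class AgentSpec:
    """One drug/agent of the panel, with its tested dose interval.

    The [lower_bound, upper_bound] interval is the experimentally tested
    extreme range and defines the box inside which doses may be nominated.

    Parameters
    ----------
    name : str
        Agent name; must match the dose column header in input tables.
    unit : str
        Free-text unit, e.g. ``"fold-dilution"``, ``"mM"``, ``"uM"``, ``"nM"``.
    lower_bound, upper_bound : float
        Tested extremes in `unit`; ``lower_bound < upper_bound`` and
        ``lower_bound >= 0``.
    stock_mass_conc : float, optional
        Stock concentration in mg/mL for fold-dilution agents (propolis),
        enabling conversion of dilutions to mass concentrations.
    """

    name: str
    unit: str
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    stock_mass_conc: float | None = None

    def __post_init__(self) -> None:
        if self.lower_bound < 0:
            raise ValueError(f"{self.name}: lower_bound must be >= 0")
        if not self.lower_bound < self.upper_bound:
            raise ValueError(f"{self.name}: lower_bound must be < upper_bound")
        if self.stock_mass_conc is not None and self.stock_mass_conc <= 0:
            raise ValueError(f"{self.name}: stock_mass_conc must be > 0")


@dataclass(frozen=True)
class DoseCombination:
    """A point in multi-agent dose space (one dose per panel agent)."""

    doses: tuple[tuple[str, float], ...]

    @classmethod
    def from_mapping(cls, doses: Mapping[str, float]) -> "DoseCombination":
        return cls(tuple((str(k), float(v)) for k, v in doses.items()))

    def as_dict(self) -> dict[str, float]:
        return dict(self.doses)

    def as_array(self, panel: Sequence[AgentSpec]) -> np.ndarray:
        """Dose vector ordered by the panel; raises if agents mismatch."""
        d = self.as_dict()
        if set(d) != {a.name for a in panel}:
            raise DoseRangeError(
                f"dose agents {sorted(d)} do not match panel "
                f"{sorted(a.name for a in panel)}"
            )
        return np.array([d[a.name] for a in panel], dtype=float)

    def validate(self, panel: Sequence[AgentSpec]) -> None:
        x = self.as_array(panel)
        for xi, a in zip(x, panel):
            if xi < 0 or xi > a.upper_bound:
                raise DoseRangeError(
                    f"{a.name} dose {xi} outside [0, {a.upper_bound}] {a.unit}"
                )


@dataclass(frozen=True)
class DoseResponseRecord:
    """One measured endpoint value at one dose combination."""

    dose: DoseCombination
    endpoint_name: str
    value: float
    context: str
    subject: str
    bio_rep: int
    tech_rep: int
    timepoint_dpf: int | None = None

    def __post_init__(self) -> None:
        if self.endpoint_name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint_name!r}")
        if self.endpoint_name in ("viability_pct", "macrophage_density") and (
            self.value < 0
        ):
            raise ValueError(f"{self.endpoint_name} must be >= 0, got {self.value}")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError("replicate indices start at 1")


@dataclass(frozen=True)
class AggregatedResponse:
    """Two-stage replicate mean at one (dose, context) condition.

    ``per_bio_values`` holds one technical-replicate mean per biological
    replicate; ``mean_value`` is their arithmetic mean.  The per-bio values
    are retained so the bootstrap can resample conditions.
    """

    dose: DoseCombination
    context: str
    endpoint_name: str
    mean_value: float
    n_bio: int
    per_bio_values: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_bio != len(self.per_bio_values) or self.n_bio < 1:
            raise ValueError("n_bio must equal len(per_bio_values) >= 1")
        if not math.isclose(
            self.mean_value, float(np.mean(self.per_bio_values)), rel_tol=1e-9,
            abs_tol=1e-12,
        ):
            raise ValueError("mean_value must equal the mean of per_bio_values")


# ---------------------------------------------------------------------------
# Table reading / writing


def _detect_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_dose_response_table(
    path: str | Path, panel: Sequence[AgentSpec]
) -> list[DoseResponseRecord]:
    """Read a long-format dose-response table (CSV or TSV) into records.

    The delimiter is auto-detected among comma and tab.  Dose columns must
    match the panel agent names exactly; doses are validated against
    ``[0, upper_bound]``.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_detect_sep(path), dtype=str, keep_default_na=False
    )
    agent_names = [a.name for a in panel]
    required = list(agent_names) + list(TABLE_COLUMNS)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path.name}")
    has_tp = "timepoint_dpf" in df.columns
    records: list[DoseResponseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        row_d = dict(zip(df.columns, row))

        def _num(col: str, *, _i=i, _row=row_d) -> float:
            try:
                return float(_row[col])
            except (TypeError, ValueError):
                raise TableParseError(
                    f"non-numeric value {_row[col]!r} in column {col!r}, row {_i}"
                ) from None

        dose = DoseCombination.from_mapping({n: _num(n) for n in agent_names})
        dose.validate(panel)
        tp = None
        if has_tp and str(row_d["timepoint_dpf"]) not in ("", "nan", "None"):
            tp = int(_num("timepoint_dpf"))
        records.append(
            DoseResponseRecord(
                dose=dose,
                endpoint_name=str(row_d["endpoint"]),
                value=_num("value"),
                context=str(row_d["context"]),
                subject=str(row_d["subject"]),
                bio_rep=int(_num("bio_rep")),
                tech_rep=int(_num("tech_rep")),
                timepoint_dpf=tp,
            )
        )
    return records


def records_to_frame(records: Iterable[DoseResponseRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of records (inverse of the reader)."""
    rows = []
    for r in records:
        row = r.dose.as_dict()
        row.update(
            endpoint=r.endpoint_name,
            value=r.value,
            context=r.context,
            subject=r.subject,
            bio_rep=r.bio_rep,
            tech_rep=r.tech_rep,
            timepoint_dpf=r.timepoint_dpf,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_dose_response_table(
    records: Iterable[DoseResponseRecord], path: str | Path
) -> None:
    """Write records back to disk in the same long schema (delimiter by suffix).

    Uses repr-precision floats so a write/read round trip is value-exact for
    decimals of <= 12 significant digits.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = records_to_frame(records)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Normalization and aggregation


def normalize_viability(raw_signal: float, blank: float, vehicle_mean: float) -> float:
    """Percent viability from a background-corrected colorimetric signal.

    ``100 * (raw - blank) / (vehicle_mean - blank)``: vehicle wells map to
    100, blank wells to 0.  Values above 100 are retained (not clipped).
    """
    if vehicle_mean <= blank:
        raise DegeneratePlateError(
            f"vehicle_mean ({vehicle_mean}) must exceed blank ({blank})"
        )
    return 100.0 * (raw_signal - blank) / (vehicle_mean - blank)


def aggregate_replicates(
    records: Sequence[DoseResponseRecord],
) -> list[AggregatedResponse]:
    """Two-stage replicate mean: tech reps within bio rep, then across bio reps.

    Technical replicates are first averaged within each (dose, context,
    bio_rep) cell to give one value per biological replicate; the condition
    mean is then the mean of those per-bio values.  Per-bio values are kept
    for bootstrap resampling.  Unbalanced technical replication is averaged
    as-is and logged.
    """
    if not records:
        return []
    endpoints = {r.endpoint_name for r in records}
    if len(endpoints) > 1:
        raise ValueError(f"records mix endpoints {sorted(endpoints)}")
    endpoint = endpoints.pop()

    by_condition: dict[tuple, dict[int, list[float]]] = {}
    dose_of: dict[tuple, DoseCombination] = {}
    for r in records:
        key = (r.dose.doses, r.context)
        by_condition.setdefault(key, {}).setdefault(r.bio_rep, []).append(r.value)
        dose_of[key] = r.dose

    tech_counts = {
        len(v) for cell in by_condition.values() for v in cell.values()
    }
    if len(tech_counts) > 1:
        logger.info("unbalanced technical replication: counts %s", sorted(tech_counts))

    out: list[AggregatedResponse] = []
    for key, cell in by_condition.items():
        per_bio = tuple(
            float(np.mean(cell[b])) for b in sorted(cell)
        )
        out.append(
            AggregatedResponse(
                dose=dose_of[key],
                context=key[1],
                endpoint_name=endpoint,
                mean_value=float(np.mean(per_bio)),
                n_bio=len(per_bio),
                per_bio_values=per_bio,
            )
        )
    return out


def dilution_to_mass(dilution: float, stock_mass_conc: float) -> float:
    """Convert a fold-dilution of a stock (mg/mL) to a mass concentration (ug/mL).

    A 1e-4 dilution of a 200 mg/mL stock is 20 ug/mL.
    """
    if stock_mass_conc <= 0:
        raise ValueError("stock_mass_conc must be > 0")
    if dilution < 0:
        raise DoseRangeError(f"dilution must be >= 0, got {dilution}")
    return dilution * stock_mass_conc * 1000.0
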