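"""In vivo and molecular endpoint computations.

Per-fish hepatic macrophage infiltration ratios (endpoint density at 15 dpf
over the baseline density at 9 or 12 dpf, both already normalized to liver
area upstream), and efficiency-corrected qPCR fold changes
(``efficiency^(-ddCt)``; with a calibrated per-cycle amplification factor of
1.94 this is the ~94%-efficiency correction of the classic 2^(-ddCt) rule).

The contract starts at per-fish area-normalized densities; image analysis
(ROI definition, thresholding) is upstream and out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .errors import MixedBaselineError, UndefinedRatioError
from .io import DoseCombination, DoseResponseRecord

logger = logging.getLogger(__name__)

#: Calibrated per-cycle amplification factor used by default (~94% efficiency).
DEFAULT_EFFICIENCY = 1.94


@dataclass(frozen=True)
class FishObservation:
    """One larva's baseline and endpoint area-normalized macrophage densities."""

    fish_id: str
    context: str
    dose: DoseCombination
    batch: int
    density_baseline: float
    baseline_dpf: int
    density_15dpf: float

    def __post_init__(self) -> None:
        if self.density_baseline < 0 or self.density_15dpf < 0:
            raise ValueError("densities must be >= 0")
        if self.baseline_dpf not in (9, 12):
            raise ValueError(f"baseline_dpf must be 9 or 12, got {self.baseline_dpf}")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct quartet for one target/reference pair in treated vs control."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_treated,
            self.ct_ref_treated,
            self.ct_target_control,
            self.ct_ref_control,
        ):
            if not math.isfinite(v):
                raise ValueError("Ct values must be finite")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("per-cycle efficiency must be in (1, 2]")


def infiltration_ratio(obs: FishObservation) -> float:
    """Endpoint / baseline area-normalized macrophage density, one per fish."""
    if obs.density_baseline <= 0:
        raise UndefinedRatioError(
            f"fish {obs.fish_id}: baseline density is zero; ratio undefined"
        )
    return obs.density_15dpf / obs.density_baseline


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Efficiency-corrected relative expression ``E^(-ddCt)``.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control;
    at E = 2 this reduces to the textbook 2^(-ddCt).
    """
    dct_treated = m.ct_target_treated - m.ct_ref_treated
    dct_control = m.ct_target_control - m.ct_ref_control
    return m.efficiency ** (-(dct_treated - dct_control))


def percent_efficiency(per_cycle_factor: float) -> float:
    """Amplification efficiency as a percent: factor 1.94 -> 94%."""
    if not 1.0 < per_cycle_factor <= 2.0:
        raise ValueError("per-cycle factor must be in (1, 2]")
    return (per_cycle_factor - 1.0) * 100.0


def ratio_table_to_responses(
    cohort: Sequence[FishObservation],
    allow_mixed_baseline: bool = False,
) -> list[DoseResponseRecord]:
    """Per-fish infiltration ratios as model-ready dose-response records.

    One record per fish (``bio_rep`` = batch, ``tech_rep`` = 1).  Fish with
    zero baseline density are excluded and counted in the log.  Cohorts
    mixing 9 and 12 dpf baselines are rejected unless explicitly allowed,
    since the baseline timepoint is fixed within one experiment.
    """
    baselines = {o.baseline_dpf for o in cohort}
    if len(baselines) > 1 and not allow_mixed_baseline:
        raise MixedBaselineError(
            f"cohort mixes baseline timepoints {sorted(baselines)} dpf; "
            "pass allow_mixed_baseline=True to fit anyway"
        )
    records: list[DoseResponseRecord] = []
    excluded = 0
    for obs in cohort:
        try:
            ratio = infiltration_ratio(obs)
        except UndefinedRatioError:
            excluded += 1
            continue
        records.append(
            DoseResponseRecord(
                dose=obs.dose,
                endpoint_name="macrophage_ratio",
                value=ratio,
                context=obs.context,
                subject=obs.fish_id,
                bio_rep=obs.batch,
                tech_rep=1,
                timepoint_dpf=15,
            )
        )
    if excluded:
        logger.info("excluded %d fish with zero baseline density", excluded)
    return records
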