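"""Seeded synthetic-data generators with the replicate structure of the assays.

The in vitro generator emulates plate-based viability profiling: a quadratic
true surface over the three-agent dose grid, an additive Gaussian offset per
biological replicate (day/culture effect), and Gaussian technical noise per
well, with triplicate technical wells in each of three biological replicates
by default.  The in vivo generator emulates zebrafish cohorts: per-fish
baseline densities are lognormal, the endpoint density is the baseline times
the true dose-dependent infiltration ratio times multiplicative lognormal
fish noise and a shared per-batch factor.

Every generator is a pure function of (truth, seed).  Random streams are
split per (context, biological replicate/batch) so adding a group never
perturbs the draws of existing groups.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io import AgentSpec, DoseCombination, DoseResponseRecord
from .endpoints import FishObservation
from .surface import QuadraticResponseSurface, quadratic_term_names

__all__ = [
    "SurfaceTruth",
    "CohortTruth",
    "default_panel",
    "default_in_vivo_panel",
    "default_dose_grid",
    "coefficients_from_scaled",
    "truth_surface",
    "generate_viability_table",
    "generate_fa_shift_pair",
    "generate_fish_cohort",
    "example_truths",
]


def default_panel() -> tuple[AgentSpec, ...]:
    """The in vitro three-agent panel with the tested dose extremes.

    Propolis is dosed as fold-dilutions of a 200 mg/mL raw-equivalent stock
    (tested up to 1e-4), metformin in mM (up to 10), regorafenib in uM
    (up to 6.5).
    """
    return (
        AgentSpec("propolis", "fold-dilution", 0.0, 1e-4, stock_mass_conc=200.0),
        AgentSpec("metformin", "mM", 0.0, 10.0),
        AgentSpec("regorafenib", "uM", 0.0, 6.5),
    )


def default_in_vivo_panel() -> tuple[AgentSpec, ...]:
    """Zebrafish bath-exposure panel (micromolar-scale, embryotoxicity-bounded)."""
    return (
        AgentSpec("propolis", "fold-dilution", 0.0, 1e-5, stock_mass_conc=200.0),
        AgentSpec("metformin", "uM", 0.0, 20.0),
        AgentSpec("regorafenib", "nM", 0.0, 25.0),
    )


def default_dose_grid(
    panel: Sequence[AgentSpec], n_points: int | None = None
) -> list[DoseCombination]:
    """Space-filling subset of the 5-level tensor grid per agent.

    Candidate levels are {0, 1/4, 1/2, 3/4, 1} x upper_bound per agent; the
    subset is grown greedily by maximin distance (in normalized coordinates)
    from the box corners plus center, deterministically.  Default size is
    27 points, comfortably above twice the 10 quadratic terms.
    """
    d = len(panel)
    p = 1 + 2 * d + d * (d - 1) // 2
    if n_points is None:
        n_points = max(27, 2 * p + 2)
    levels = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    candidates = np.array(list(itertools.product(levels, repeat=d)))
    corners = np.array(list(itertools.product([0.0, 1.0], repeat=d)))
    center = np.full((1, d), 0.5)
    chosen = [tuple(c) for c in np.vstack([corners, center])]
    chosen_set = set(chosen)
    while len(chosen) < min(n_points, len(candidates)):
        best, best_d = None, -1.0
        arr = np.array(chosen)
        for c in candidates:
            t = tuple(c)
            if t in chosen_set:
                continue
            dist = float(np.min(np.linalg.norm(arr - c, axis=1)))
            if dist > best_d:
                best, best_d = t, dist
        chosen.append(best)
        chosen_set.add(best)
    uppers = np.array([a.upper_bound for a in panel])
    return [
        DoseCombination.from_mapping(
            {a.name: float(u * up) for a, u, up in zip(panel, c, uppers)}
        )
        for c in chosen
    ]


def coefficients_from_scaled(
    scaled: Mapping[str, float], panel: Sequence[AgentSpec]
) -> dict[str, float]:
    """Convert coefficients on normalized doses (u = x/upper) to original units.

    Writing the same surface in original units divides linear terms by the
    upper bound, squared terms by its square, and interactions by the
    product of the two bounds.
    """
    names = [a.name for a in panel]
    terms = quadratic_term_names(names)
    unknown = set(scaled) - set(terms)
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    upper = {a.name: a.upper_bound for a in panel}
    out: dict[str, float] = {}
    for t, v in scaled.items():
        if t == "intercept":
            out[t] = v
        elif t.endswith("^2"):
            out[t] = v / upper[t[:-2]] ** 2
        elif ":" in t:
            a, b = t.split(":")
            out[t] = v / (upper[a] * upper[b])
        else:
            out[t] = v / upper[t]
    return out


def truth_surface(
    coefficients: Mapping[str, float], panel: Sequence[AgentSpec]
) -> QuadraticResponseSurface:
    """A predict-ready surface from original-unit truth coefficients."""
    return QuadraticResponseSurface.from_coefficients(
        dict(coefficients),
        feature_names=[a.name for a in panel],
        upper_bounds=[a.upper_bound for a in panel],
        allow_extrapolation=True,
    )


def _stream(seed: int, context: str, group: int) -> np.random.Generator:
    """Named substream: (root seed, context hash, group index)."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(context.encode()), int(group)]
    )


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground truth for the in vitro viability generator.

    ``coefficients`` are in original dose units (use
    :func:`coefficients_from_scaled` to build them from the normalized-dose
    parameterization).  ``noise_sd`` is the per-well technical SD and
    ``bio_rep_sd`` the SD of the additive per-biological-replicate offset,
    both in viability percentage points.
    """

    coefficients: Mapping[str, float]
    panel: tuple[AgentSpec, ...] = field(default_factory=default_panel)
    grid: tuple[DoseCombination, ...] | None = None
    noise_sd: float = 5.0
    bio_rep_sd: float = 2.0
    n_tech: int = 3
    n_bio: int = 3
    context: str = "FA-free"
    subject: str = "tumor"
    endpoint_name: str = "viability_pct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.bio_rep_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.n_tech < 1 or self.n_bio < 1:
            raise ConfigError("replicate counts must be >= 1")

    def resolved_grid(self) -> tuple[DoseCombination, ...]:
        return self.grid if self.grid is not None else tuple(default_dose_grid(self.panel))

    def surface(self) -> QuadraticResponseSurface:
        return truth_surface(self.coefficients, self.panel)


def generate_viability_table(truth: SurfaceTruth) -> list[DoseResponseRecord]:
    """Simulate the triplicate-well x replicate-run viability table.

    Values are truncated at 0 (a normalized viability cannot be negative),
    so noise is mildly right-truncated wherever the true surface approaches
    full kill; keep the truth surface comfortably positive on the grid when
    unbiased recovery matters.
    """
    grid = truth.resolved_grid()
    if not grid:
        raise ConfigError("empty dose grid")
    surf = truth.surface()
    X = np.array([d.as_array(truth.panel) for d in grid])
    mu = surf.predict(X)
    records: list[DoseResponseRecord] = []
    for bio in range(1, truth.n_bio + 1):
        rng = _stream(truth.seed, truth.context, bio)
        offset = rng.normal(0.0, truth.bio_rep_sd) if truth.bio_rep_sd > 0 else 0.0
        for dose, m in zip(grid, mu):
            noise = (
                rng.normal(0.0, truth.noise_sd, size=truth.n_tech)
                if truth.noise_sd > 0
                else np.zeros(truth.n_tech)
            )
            for tech in range(1, truth.n_tech + 1):
                records.append(
                    DoseResponseRecord(
                        dose=dose,
                        endpoint_name=truth.endpoint_name,
                        value=max(0.0, float(m + offset + noise[tech - 1])),
                        context=truth.context,
                        subject=truth.subject,
                        bio_rep=bio,
                        tech_rep=tech,
                    )
                )
    return records


def generate_fa_shift_pair(
    truth_fa_free: SurfaceTruth,
    shift: Mapping[str, float],
    fa_context: str = "FA",
) -> list[DoseResponseRecord]:
    """Two-context table: the FA surface is the FA-free truth plus deltas.

    Both contexts share the grid, replication and root seed; the context
    label splits the random streams, so zero deltas give two statistically
    identical but independently noised contexts.
    """
    base = dict(truth_fa_free.coefficients)
    terms = quadratic_term_names([a.name for a in truth_fa_free.panel])
    unknown = set(shift) - set(terms)
    if unknown:
        raise ValueError(f"unknown shift terms {sorted(unknown)}")
    shifted = {t: base.get(t, 0.0) + shift.get(t, 0.0) for t in set(base) | set(shift)}
    truth_fa = replace(truth_fa_free, coefficients=shifted, context=fa_context)
    return generate_viability_table(truth_fa_free) + generate_viability_table(truth_fa)


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for the zebrafish cohort generator.

    The infiltration-ratio surface must be positive over the tested box.
    ``sigma`` is the per-fish lognormal noise SD (log scale);
    ``batch_log_sd`` the SD of the shared per-batch lognormal factor;
    baseline densities are lognormal with the given log-scale parameters
    (arbitrary per-area units).
    """

    ratio_coefficients: Mapping[str, float]
    panel: tuple[AgentSpec, ...] = field(default_factory=default_in_vivo_panel)
    sigma: float = 0.15
    n_batches: int = 2
    fish_per_group: int = 12
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.25
    batch_log_sd: float = 0.05
    baseline_dpf: int = 9
    context: str = "MASLD-HCC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fish_per_group < 1:
            raise ConfigError("fish_per_group must be >= 1")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if self.sigma < 0 or self.batch_log_sd < 0:
            raise ConfigError("noise SDs must be >= 0")

    def surface(self) -> QuadraticResponseSurface:
        return truth_surface(self.ratio_coefficients, self.panel)


def generate_fish_cohort(
    truth: CohortTruth, dose_groups: Sequence[DoseCombination]
) -> list[FishObservation]:
    """Simulate per-fish baseline/endpoint densities across batches and groups."""
    surf = truth.surface()
    X = np.array([d.as_array(truth.panel) for d in dose_groups])
    true_ratio = surf.predict(X)
    if (true_ratio <= 0).any():
        raise ConfigError("true infiltration ratio must be positive on all groups")
    out: list[FishObservation] = []
    for batch in range(1, truth.n_batches + 1):
        rng = _stream(truth.seed, truth.context, batch)
        batch_factor = (
            float(np.exp(rng.normal(0.0, truth.batch_log_sd)))
            if truth.batch_log_sd > 0
            else 1.0
        )
        for g, (dose, r) in enumerate(zip(dose_groups, true_ratio)):
            for f in range(truth.fish_per_group):
                baseline = float(
                    np.exp(rng.normal(truth.baseline_log_mean, truth.baseline_log_sd))
                )
                fish_noise = (
                    float(np.exp(rng.normal(0.0, truth.sigma)))
                    if truth.sigma > 0
                    else 1.0
                )
                out.append(
                    FishObservation(
                        fish_id=f"b{batch}g{g}f{f}",
                        context=truth.context,
                        dose=dose,
                        batch=batch,
                        density_baseline=baseline,
                        baseline_dpf=truth.baseline_dpf,
                        density_15dpf=baseline * float(r) * fish_noise * batch_factor,
                    )
                )
    return out


def example_truths() -> dict[str, SurfaceTruth]:
    """Plausible study-condition truths for the worked example and pipeline demo.

    Tumor-cell viability drops steeply with all three agents; hepatocyte
    viability is less sensitive.  Under the FA context the propolis and
    regorafenib contributions to tumor kill weaken while metformin's
    tumor-selective contribution strengthens, and hepatocytes tolerate
    propolis better -- the qualitative landscape shift the workflow is built
    to re-optimize across.
    """
    panel = default_panel()
    tumor = coefficients_from_scaled(
        {
            "intercept": 100.0,
            "propolis": -45.0,
            "metformin": -18.0,
            "regorafenib": -45.0,
            "propolis^2": 10.0,
            "metformin^2": 4.0,
            "regorafenib^2": 12.0,
            "propolis:metformin": -4.0,
            "propolis:regorafenib": -6.0,
            "metformin:regorafenib": -2.0,
        },
        panel,
    )
    hepatocyte = coefficients_from_scaled(
        {
            "intercept": 100.0,
            "propolis": -22.0,
            "metformin": -5.0,
            "regorafenib": -16.0,
            "propolis^2": 6.0,
            "metformin^2": 1.0,
            "regorafenib^2": 5.0,
            "propolis:metformin": -1.0,
            "propolis:regorafenib": -2.0,
            "metformin:regorafenib": -0.5,
        },
        panel,
    )
    return {
        "tumor": SurfaceTruth(coefficients=tumor, panel=panel, subject="tumor"),
        "hepatocyte": SurfaceTruth(
            coefficients=hepatocyte, panel=panel, subject="hepatocyte"
        ),
    }
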