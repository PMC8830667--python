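"""Synthetic multi-country inputs and an agent-level Monte-Carlo oracle.

The public coverage and survey sources the model is normally fed (national
coverage estimates, facility and household surveys) cannot be redistributed,
so this module generates internally consistent stand-ins with the same
table shapes: a regions table (observed calibration coverage C_c, maximum
technology-achievable coverage M, birth cohort, routine-channel share), a
proxy-indicator table with a two-level priority hierarchy and controllable
missingness, and a presentations table holding a currently-deployed
calibration-like presentation plus two test presentations (a conservative
and an optimistic profile of the same new technology).

:func:`simulate_agents` is an independent stochastic check on the closed
form for uncalibrated coverage: it simulates individuals who must clear
every barrier for every dose, optionally with positively correlated barrier
failures (a shared Gaussian latent factor), which the analytic product
formula deliberately ignores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .model import (
    DEFAULT_D_WORST,
    PopulationProfile,
    VaccinePresentation,
    uncalibrated_coverage,
)
from .rubric import PresentationSpec, RubricTable, load_default_rubric, score_presentation

__all__ = [
    "BARRIERS",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_dataset",
    "simulate_agents",
]

#: Default technology-addressable barrier set (dose requirements are
#: handled through the dose count, not as a vector entry).
BARRIERS = (
    "vaccine_schedule",
    "temperature_storage",
    "administration",
    "acceptability",
    "doses_per_container",
)

#: Plausible per-barrier prevalence ranges for low- and middle-income
#: settings: schedule non-compliance and cold-chain/administration gaps are
#: common; refusal to open a multi-dose vial is rarer.
DEFAULT_PREVALENCE_BOUNDS: dict[str, tuple[float, float]] = {
    "vaccine_schedule": (0.05, 0.60),
    "temperature_storage": (0.05, 0.60),
    "administration": (0.05, 0.50),
    "acceptability": (0.00, 0.40),
    "doses_per_container": (0.00, 0.15),
}

# A currently-deployed measles-like comparator: 10-dose vial, 2-8C cold
# chain, nurse-administered, schedule-aligned, single dose here for the
# antigen of interest; and two profiles of a patch-like successor.
_PRESENTATION_LEVELS: dict[str, tuple[dict[str, str], int]] = {
    "calibration_sc": (
        {
            "vaccine_schedule": "Medium-High",
            "temperature_storage": "Medium-Low",
            "administration": "Medium-Low",
            "acceptability": "Medium-Low",
            "doses_per_container": "Medium-Low",
        },
        1,
    ),
    "test_minimum": (
        {
            "vaccine_schedule": "Medium-High",
            "temperature_storage": "Medium",
            "administration": "Medium",
            "acceptability": "Medium-Low",
            "doses_per_container": "Medium",
        },
        1,
    ),
    "test_optimal": (
        {
            "vaccine_schedule": "Medium-High",
            "temperature_storage": "Medium-High",
            "administration": "Medium-High",
            "acceptability": "Medium-High",
            "doses_per_container": "High",
        },
        1,
    ),
}

_ACCEPTABILITY_VARIANT = "pork_product"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic multi-country dataset.

    The same seed and spec always produce identical tables.  When
    ``calibration_truth`` is set, each region's C_c and M are constructed
    from a drawn slope/intercept pair (C_c = S*U_c + beta, M = S + beta)
    so that refitting the calibration must recover them exactly; the drawn
    pairs are emitted in a truth table.
    """

    n_countries: int = 73
    n_subregions: int = 1  # >1 produces subnational regions per country
    seed: int = 0
    prevalence_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_BOUNDS)
    )
    c_c_bounds: tuple[float, float] = (0.40, 0.92)
    m_headroom_bounds: tuple[float, float] = (0.02, 0.15)  # M = min(C_c + headroom, 1)
    births_bounds: tuple[int, int] = (20_000, 5_000_000)
    routine_share_bounds: tuple[float, float] = (0.60, 1.00)
    missing_rate: dict[int, float] = field(default_factory=lambda: {1: 0.30, 2: 0.00})
    overreported_m_rate: float = 0.0  # fraction of regions with M drawn above 1
    calibration_truth: bool = False
    d_worst: int = DEFAULT_D_WORST

    def __post_init__(self):
        if self.n_countries < 1 or self.n_subregions < 1:
            raise ValidationError("need at least one country and one subregion", field="n_countries")
        for b, (lo, hi) in self.prevalence_bounds.items():
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValidationError(f"infeasible prevalence bounds {lo}..{hi}", field=b)
        lo, hi = self.c_c_bounds
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError(f"infeasible C_c bounds {lo}..{hi}", field="c_c_bounds")
        lo, hi = self.m_headroom_bounds
        if not 0.0 <= lo <= hi:
            raise ValidationError(f"infeasible headroom bounds {lo}..{hi}", field="m_headroom_bounds")
        for pr, rate in self.missing_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"missing rate {rate} at priority {pr}", field="missing_rate")
        if not 0.0 <= self.overreported_m_rate <= 1.0:
            raise ValidationError("rate must be in [0, 1]", field="overreported_m_rate")


@dataclass
class SyntheticDataset:
    regions: pd.DataFrame
    indicators: pd.DataFrame
    presentations: pd.DataFrame
    doses: pd.DataFrame
    truth: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.regions.to_csv(out / "regions.csv", index=False)
        self.indicators.to_csv(out / "indicators.csv", index=False)
        self.presentations.to_csv(out / "presentations.csv", index=False)
        self.doses.to_csv(out / "doses.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "calibration_truth.csv", index=False)


def _presentation_frames() -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    doses = []
    for pid, (levels, d) in _PRESENTATION_LEVELS.items():
        for barrier, level in levels.items():
            rows.append(
                {
                    "presentation_id": pid,
                    "barrier_id": barrier,
                    "variant": _ACCEPTABILITY_VARIANT if barrier == "acceptability" else "",
                    "level": level,
                }
            )
        doses.append({"presentation_id": pid, "doses_required": d})
    return pd.DataFrame(rows), pd.DataFrame(doses)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a complete, internally consistent input bundle.

    All quantities are uniform within their bounds; every region/barrier
    pair is guaranteed resolvable at priority 2 even when the priority-1
    indicator is missing.
    """
    rng = np.random.default_rng(spec.seed)
    region_rows = []
    indicator_rows = []
    rubric = load_default_rubric()

    calib_levels, calib_doses = _PRESENTATION_LEVELS["calibration_sc"]
    calib_spec = PresentationSpec(
        "calibration_sc",
        calib_levels,
        calib_doses,
        variants={"acceptability": _ACCEPTABILITY_VARIANT},
    )
    calib_pres = score_presentation(calib_spec, rubric, BARRIERS)

    truth_rows = []
    for ci in range(spec.n_countries):
        country = f"C{ci + 1:03d}"
        for si in range(spec.n_subregions):
            region = country if spec.n_subregions == 1 else f"{country}-R{si + 1:02d}"
            p = np.empty(len(BARRIERS))
            for bi, barrier in enumerate(BARRIERS):
                lo, hi = spec.prevalence_bounds[barrier]
                p[bi] = rng.uniform(lo, hi)
                # priority-1 proxy sometimes missing; priority-2 fallback
                # carries the same quantity (possibly via its complement)
                p1_missing = rng.random() < spec.missing_rate.get(1, 0.0)
                p2_missing = rng.random() < spec.missing_rate.get(2, 0.0)
                indicator_rows.append(
                    {
                        "region_id": region,
                        "barrier_id": barrier,
                        "priority": 1,
                        "value": np.nan if p1_missing else round(p[bi], 6),
                        "source": "survey_direct",
                        "complement": 0,
                    }
                )
                indicator_rows.append(
                    {
                        "region_id": region,
                        "barrier_id": barrier,
                        "priority": 2,
                        "value": np.nan if (p2_missing and not p1_missing) else round(1.0 - p[bi], 6),
                        "source": "subregion_average",
                        "complement": 1,
                    }
                )
                p[bi] = round(p[bi], 6)

            births = int(rng.integers(spec.births_bounds[0], spec.births_bounds[1] + 1))
            routine_share = round(float(rng.uniform(*spec.routine_share_bounds)), 4)

            if spec.calibration_truth:
                profile = PopulationProfile(BARRIERS, p)
                U_c = uncalibrated_coverage(profile, calib_pres)
                # draw a line with non-negative slope and an intercept that
                # keeps M = S + beta at or below 1
                S = float(rng.uniform(0.05, 0.45))
                beta = float(rng.uniform(0.30, min(0.55, 1.0 - S)))
                C_c = S * U_c + beta
                M = S + beta
                truth_rows.append({"region_id": region, "S": S, "beta": beta})
            else:
                C_c = round(float(rng.uniform(*spec.c_c_bounds)), 4)
                headroom = float(rng.uniform(*spec.m_headroom_bounds))
                if rng.random() < spec.overreported_m_rate:
                    # the ceiling-defining vaccine is administratively
                    # over-reported: M well above 100%, decoupled from C_c
                    M = round(float(rng.uniform(1.10, 1.35)), 4)
                else:
                    M = round(min(C_c + headroom, 1.0), 4)

            region_rows.append(
                {
                    "region_id": region,
                    "country_id": country,
                    "births": births,
                    "C_c": C_c,
                    "M": M,
                    "channel_routine_share": routine_share,
                }
            )

    presentations, doses = _presentation_frames()
    return SyntheticDataset(
        regions=pd.DataFrame(region_rows),
        indicators=pd.DataFrame(indicator_rows),
        presentations=presentations,
        doses=doses,
        truth=pd.DataFrame(truth_rows) if truth_rows else None,
    )


def simulate_agents(
    profile: PopulationProfile,
    pres: VaccinePresentation,
    n_agents: int,
    seed: int,
    correlation: float = 0.0,
) -> float:
    """Empirical vaccinated fraction from individual-level simulation.

    Each agent must clear every barrier for each of the ``D`` required
    doses; barrier ``i`` is cleared with probability ``1 - p_i (1 - v_i)``.
    At ``correlation = 0`` clearances are independent across barriers and
    doses, matching the analytic product formula in expectation.  At
    ``correlation > 0`` barrier failures are positively coupled through a
    single standard-normal factor shared by all of an agent's barrier
    draws (a Gaussian-copula frailty): agents are then consistently lucky
    or unlucky, which inflates coverage relative to independence when no
    technology helps.  This is a testing device for probing the
    independence assumption, not part of the analytic model.
    """
    if n_agents < 1:
        raise ValidationError(f"need at least one agent, got {n_agents}", field="n_agents")
    if not 0.0 <= correlation <= 1.0:
        raise ValidationError(
            f"correlation must be in [0, 1], got {correlation}", field="correlation"
        )
    if profile.barrier_ids != pres.barrier_ids:
        raise ValidationError("profile and presentation barrier ids differ", field="barrier_ids")
    rng = np.random.default_rng(seed)
    fail = profile.p * (1.0 - pres.v)  # per-barrier failure probability
    D = pres.doses
    n = len(fail)
    if correlation == 0.0:
        draws = rng.random((n_agents, D, n))
        vaccinated = np.all(draws >= fail, axis=(1, 2))
    else:
        rho = correlation
        shared = rng.standard_normal((n_agents, 1, 1))
        idio = rng.standard_normal((n_agents, D, n))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio
        # fail when the latent quantile falls below the failure probability
        thresholds = norm.ppf(np.clip(fail, 0.0, 1.0))
        vaccinated = np.all(latent >= thresholds, axis=(1, 2))
    return float(vaccinated.mean())
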