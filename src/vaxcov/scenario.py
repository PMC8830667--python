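"""Scenario runner: configuration, model object, results object, sweeps.

The public surface follows the fit-then-inspect convention of statistical
modelling packages: :class:`VaccineCoverageModel` is built from the input
tables (regions, proxy indicators, presentation specs, rubric) and
:meth:`~VaccineCoverageModel.fit` calibrates the linear coverage map for
every region and channel, returning a :class:`VaccineCoverageResults`
holding per-region estimates, cohort-weighted aggregates, equity indices,
rankings and a full audit trail.  :func:`run_scenario` and
:func:`sensitivity_sweep` are thin config-driven wrappers over those two
objects.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .aggregate import (
    AggregateSummary,
    BlendedEstimate,
    ChannelSpec,
    RegionResult,
    aggregate_regions,
    channel_blend,
    equity_index,
    rank_regions,
)
from .errors import ValidationError, VaxcovError
from .model import DEFAULT_D_WORST
from .population import build_profile
from .rubric import (
    PresentationSpec,
    RubricTable,
    load_default_rubric,
    read_presentations,
    score_presentation,
    validate_rubric,
)

logger = logging.getLogger("vaxcov")

__all__ = [
    "ChannelConfig",
    "SensitivityParam",
    "ScenarioConfig",
    "VaccineCoverageModel",
    "VaccineCoverageResults",
    "run_scenario",
    "sensitivity_sweep",
]

#: Regions-table column giving the share of the cohort reached through the
#: first configured channel (the second channel receives the remainder).
ROUTINE_SHARE_COLUMN = "channel_routine_share"

SENSITIVITY_PARAMETERS = ("M", "C_c", "d_worst")


class ChannelConfig(BaseModel):
    channel_id: str
    applicable_barriers: Optional[list[str]] = None  # None = all barriers apply


class SensitivityParam(BaseModel):
    parameter: str
    values: list[float] = Field(min_length=1)

    @field_validator("parameter")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in SENSITIVITY_PARAMETERS:
            raise ValueError(
                f"unknown sensitivity parameter {v!r}; supported: {SENSITIVITY_PARAMETERS}"
            )
        return v


class ScenarioConfig(BaseModel):
    """Declarative description of one analysis run."""

    barriers: list[str] = Field(min_length=1)
    calibration_presentation: str
    test_presentations: list[str] = Field(min_length=1)
    regions_csv: Path
    indicators_csv: Path
    presentations_csv: Path
    doses_csv: Path
    rubric_csv: Optional[Path] = None  # None -> shipped default rubric
    d_worst: int = DEFAULT_D_WORST
    channels: list[ChannelConfig] = Field(
        default_factory=lambda: [ChannelConfig(channel_id="routine")]
    )
    sensitivity: list[SensitivityParam] = Field(default_factory=list, max_length=3)
    seed: Optional[int] = None
    top_k: int = 10

    @field_validator("channels")
    @classmethod
    def _max_two_channels(cls, v):
        if not 1 <= len(v) <= 2:
            raise ValueError("one or two channels are supported")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        cfg = cls.model_validate(raw)
        # relative data paths are resolved against the config file location
        base = path.parent
        for name in ("regions_csv", "indicators_csv", "presentations_csv", "doses_csv", "rubric_csv"):
            p = getattr(cfg, name)
            if p is not None and not p.is_absolute():
                object.__setattr__(cfg, name, base / p)
        return cfg


class VaccineCoverageModel:
    """Coverage-impact model for a set of regions and test presentations.

    Parameters
    ----------
    regions : DataFrame
        One row per region: region_id, country_id, births, C_c, M and,
        when two channels are configured, the first channel's share in
        ``channel_routine_share``.
    indicators : DataFrame
        Proxy indicators (region_id, barrier_id, priority, value, source,
        complement) from which per-region barrier prevalences are resolved.
    presentation_specs : dict
        presentation_id -> :class:`PresentationSpec`; must contain the
        calibration presentation and every test presentation.
    rubric : RubricTable
        Level -> score mapping used to turn specs into score vectors.
    """

    def __init__(
        self,
        regions: pd.DataFrame,
        indicators: pd.DataFrame,
        presentation_specs: dict[str, PresentationSpec],
        rubric: RubricTable | None = None,
        *,
        barriers: list[str] | tuple[str, ...],
        calibration_presentation: str,
        test_presentations: list[str],
        channels: list[ChannelConfig] | None = None,
        d_worst: int = DEFAULT_D_WORST,
    ):
        self.rubric = rubric if rubric is not None else load_default_rubric()
        violations = validate_rubric(self.rubric)
        if violations:
            raise ValidationError(
                "rubric is invalid:\n  " + "\n  ".join(str(v) for v in violations),
                field="rubric",
            )
        self.barriers = tuple(barriers)
        self.regions = regions.reset_index(drop=True)
        self.indicators = indicators
        self.presentation_specs = presentation_specs
        self.calibration_presentation = calibration_presentation
        self.test_presentations = list(test_presentations)
        self.channels = channels or [ChannelConfig(channel_id="routine")]
        self.d_worst = int(d_worst)

        required = {"region_id", "births", "C_c", "M"}
        missing_cols = required - set(self.regions.columns)
        if missing_cols:
            raise ValidationError(
                f"regions table lacks columns {sorted(missing_cols)}", field="regions"
            )
        if len(self.channels) == 2 and ROUTINE_SHARE_COLUMN not in self.regions.columns:
            raise ValidationError(
                f"two channels configured but regions table lacks {ROUTINE_SHARE_COLUMN!r}",
                field="regions",
            )
        for ch in self.channels:
            if ch.applicable_barriers is not None:
                unknown = set(ch.applicable_barriers) - set(self.barriers)
                if unknown:
                    raise ValidationError(
                        f"channel {ch.channel_id!r} masks unknown barriers {sorted(unknown)}",
                        field="channels",
                    )
        for pid in [calibration_presentation, *test_presentations]:
            if pid not in presentation_specs:
                raise ValidationError(
                    f"presentation {pid!r} not found in presentation specs",
                    field="presentations",
                )
        # score once: vectors are reused for every region
        self._scored = {
            pid: score_presentation(presentation_specs[pid], self.rubric, self.barriers)
            for pid in {calibration_presentation, *test_presentations}
        }

    # ------------------------------------------------------------------
    @classmethod
    def from_config(cls, config: ScenarioConfig | str | Path) -> "VaccineCoverageModel":
        if not isinstance(config, ScenarioConfig):
            config = ScenarioConfig.from_file(config)
        rubric = (
            RubricTable.from_csv(config.rubric_csv)
            if config.rubric_csv is not None
            else load_default_rubric()
        )
        specs = read_presentations(config.presentations_csv, config.doses_csv)
        return cls(
            regions=pd.read_csv(config.regions_csv),
            indicators=pd.read_csv(config.indicators_csv),
            presentation_specs=specs,
            rubric=rubric,
            barriers=config.barriers,
            calibration_presentation=config.calibration_presentation,
            test_presentations=config.test_presentations,
            channels=config.channels,
            d_worst=config.d_worst,
        )

    # ------------------------------------------------------------------
    def _channel_specs(self, row) -> list[ChannelSpec]:
        if len(self.channels) == 1:
            ch = self.channels[0]
            mask = None if ch.applicable_barriers is None else frozenset(ch.applicable_barriers)
            return [ChannelSpec(ch.channel_id, 1.0, mask)]
        share = float(getattr(row, ROUTINE_SHARE_COLUMN))
        specs = []
        for ch, s in zip(self.channels, (share, 1.0 - share)):
            mask = None if ch.applicable_barriers is None else frozenset(ch.applicable_barriers)
            specs.append(ChannelSpec(ch.channel_id, s, mask))
        return specs

    def fit(
        self,
        *,
        m_override: float | None = None,
        c_c_override: float | None = None,
        d_worst: int | None = None,
    ) -> "VaccineCoverageResults":
        """Calibrate and estimate coverage for every region, channel and
        test presentation.

        The overrides replace M / C_c uniformly across regions and exist
        for sensitivity sweeps.
        """
        d_worst = self.d_worst if d_worst is None else int(d_worst)
        results: dict[str, list[RegionResult]] = {pid: [] for pid in self.test_presentations}
        calib = self._scored[self.calibration_presentation]
        for row in self.regions.itertuples(index=False):
            region_id = str(row.region_id)
            country_id = str(getattr(row, "country_id", "") or "")
            M = float(row.M) if m_override is None else float(m_override)
            C_c = float(row.C_c) if c_c_override is None else float(c_c_override)
            births = float(row.births)
            try:
                profile = build_profile(region_id, self.barriers, self.indicators)
                channels = self._channel_specs(row)
                for line in profile.provenance:
                    logger.info("region %s: %s", region_id, line)
                for pid in self.test_presentations:
                    blended = channel_blend(
                        profile, self._scored[pid], calib, channels, M, C_c, d_worst=d_worst
                    )
                    results[pid].append(_to_region_result(region_id, country_id, births, blended))
            except VaxcovError as exc:
                raise type(exc)(f"region {region_id!r}: {exc}") from exc
        return VaccineCoverageResults(self, results, d_worst=d_worst)

    # ------------------------------------------------------------------
    def sensitivity(self, params: list[SensitivityParam]) -> pd.DataFrame:
        """Cartesian sweep over up to three global parameters, one full
        fit per combination, long-format output keyed by parameter values."""
        if not 1 <= len(params) <= 3:
            raise ValidationError(
                f"between 1 and 3 sensitivity parameters supported, got {len(params)}",
                field="sensitivity",
            )
        names = [p.parameter for p in params]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate sensitivity parameters", field="sensitivity")
        rows: list[dict[str, Any]] = []
        for combo in itertools.product(*(p.values for p in params)):
            overrides: dict[str, Any] = dict(zip(names, combo))
            res = self.fit(
                m_override=overrides.get("M"),
                c_c_override=overrides.get("C_c"),
                d_worst=None if "d_worst" not in overrides else int(overrides["d_worst"]),
            )
            for pid, agg in res.aggregates.items():
                rows.append(
                    {
                        **overrides,
                        "test_presentation": pid,
                        "C_t": agg.C_t,
                        "C_c": agg.C_c,
                        "delta_pp": agg.delta_pp,
                        "additional_vaccinated": agg.additional_vaccinated,
                        "excluded_cohort_share": agg.excluded_cohort_share,
                    }
                )
        return pd.DataFrame(rows)


def _to_region_result(
    region_id: str, country_id: str, births: float, blended: BlendedEstimate
) -> RegionResult:
    reason = "" if blended.valid else "estimated coverage exceeds 100%"
    audit = blended.audit()
    audit["_shares"] = blended.shares
    return RegionResult(
        region_id=region_id,
        country_id=country_id,
        C_t=blended.C_t,
        C_c=blended.C_c,
        births=births,
        valid=blended.valid,
        exclusion_reason=reason,
        audit=audit,
    )


class VaccineCoverageResults:
    """Fitted coverage estimates with aggregation, equity and ranking views."""

    def __init__(
        self,
        model: VaccineCoverageModel,
        region_results: dict[str, list[RegionResult]],
        d_worst: int,
    ):
        self.model = model
        self.region_results = region_results
        self.d_worst = d_worst
        self.aggregates: dict[str, AggregateSummary] = {
            pid: aggregate_regions(rows) for pid, rows in region_results.items()
        }

    # -- tabular views --------------------------------------------------
    @property
    def regions(self) -> pd.DataFrame:
        rows = []
        for pid, results in self.region_results.items():
            for r in results:
                rows.append(
                    {
                        "test_presentation": pid,
                        "region_id": r.region_id,
                        "country_id": r.country_id,
                        "C_c": r.C_c,
                        "C_t": r.C_t,
                        "delta_pp": r.delta_pp,
                        "births": r.births,
                        "additional_vaccinated": r.additional_vaccinated,
                        "valid": r.valid,
                        "exclusion_reason": r.exclusion_reason,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def aggregate_frame(self) -> pd.DataFrame:
        rows = []
        for pid, agg in self.aggregates.items():
            rows.append(
                {
                    "test_presentation": pid,
                    "C_t": agg.C_t,
                    "C_c": agg.C_c,
                    "delta_pp": agg.delta_pp,
                    "additional_vaccinated": agg.additional_vaccinated,
                    "n_regions": agg.n_regions,
                    "n_excluded": agg.n_excluded,
                    "excluded_cohort_share": agg.excluded_cohort_share,
                }
            )
        return pd.DataFrame(rows)

    def ranking(self, k: int | None = None, test_presentation: str | None = None) -> pd.DataFrame:
        """Regions with the greatest coverage gain over the calibration
        vaccine, descending."""
        k = k if k is not None else 10
        pid = test_presentation or self.model.test_presentations[0]
        top = rank_regions(self.region_results[pid], k)
        return pd.DataFrame(
            {
                "rank": range(1, len(top) + 1),
                "region_id": [r.region_id for r in top],
                "delta_pp": [r.delta_pp for r in top],
                "C_t": [r.C_t for r in top],
                "C_c": [r.C_c for r in top],
            }
        )

    def equity(self, test_presentation: str | None = None) -> pd.DataFrame:
        """Equity index per country across its (valid) sub-regions.

        Countries contributing fewer than two valid regions are omitted —
        the index is undefined for a single region.
        """
        pid = test_presentation or self.model.test_presentations[0]
        rows = []
        by_country: dict[str, list[RegionResult]] = {}
        for r in self.region_results[pid]:
            if r.valid and r.country_id:
                by_country.setdefault(r.country_id, []).append(r)
        for country, results in sorted(by_country.items()):
            if len(results) < 2:
                continue
            c = [r.C_t for r in results]
            rows.append(
                {
                    "country_id": country,
                    "n_regions": len(results),
                    "equity_index": equity_index(c),
                    "min_C_t": min(c),
                    "max_C_t": max(c),
                }
            )
        return pd.DataFrame(rows, columns=["country_id", "n_regions", "equity_index", "min_C_t", "max_C_t"])

    def audit_log(self) -> dict[str, dict[str, dict]]:
        """test presentation -> region -> per-channel intermediates
        (U_c, U_l, S, beta, C_l, k, U_t, x_t, C_t)."""
        return {
            pid: {r.region_id: r.audit for r in results}
            for pid, results in self.region_results.items()
        }

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        """Aggregate coverage table, one row per test presentation.

        Percentages are shown to one decimal place; counts of additional
        vaccinated individuals are rounded (half-even) at this final step.
        """
        lines = [
            "Vaccination coverage impact (cohort-weighted aggregate)",
            "=" * 78,
            f"{'Test presentation':<28}{'Coverage':>10}{'Change (pp)':>13}{'Add. vaccinated':>18}",
            "-" * 78,
        ]
        for pid, agg in self.aggregates.items():
            lines.append(
                f"{pid:<28}{agg.C_t * 100:>9.1f}%{agg.delta_pp:>+13.1f}"
                f"{round(agg.additional_vaccinated):>18,d}"
            )
        lines.append("-" * 78)
        lines.append(
            f"Calibration coverage: {next(iter(self.aggregates.values())).C_c * 100:.1f}%   "
            f"regions: {next(iter(self.aggregates.values())).n_regions}   "
            f"d_worst: {self.d_worst}"
        )
        for pid, agg in self.aggregates.items():
            if agg.n_excluded:
                lines.append(
                    f"Excluded ({pid}): {', '.join(agg.excluded_regions)} "
                    f"({agg.excluded_cohort_share * 100:.1f}% of the total birth cohort)"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path, top_k: int = 10) -> None:
        """Write results.csv, ranking.csv, equity.csv, aggregate.json and
        audit.json to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.regions.to_csv(out / "results.csv", index=False)
        rankings = []
        for pid in self.model.test_presentations:
            rk = self.ranking(top_k, pid)
            rk.insert(0, "test_presentation", pid)
            rankings.append(rk)
        pd.concat(rankings, ignore_index=True).to_csv(out / "ranking.csv", index=False)
        equities = []
        for pid in self.model.test_presentations:
            eq = self.equity(pid)
            eq.insert(0, "test_presentation", pid)
            equities.append(eq)
        pd.concat(equities, ignore_index=True).to_csv(out / "equity.csv", index=False)
        agg = {
            pid: {
                "C_t": a.C_t,
                "C_c": a.C_c,
                "delta_pp": a.delta_pp,
                "additional_vaccinated": a.additional_vaccinated,
                "total_births": a.total_births,
                "n_regions": a.n_regions,
                "n_excluded": a.n_excluded,
                "excluded_regions": list(a.excluded_regions),
                "excluded_cohort_share": a.excluded_cohort_share,
            }
            for pid, a in self.aggregates.items()
        }
        (out / "aggregate.json").write_text(json.dumps(agg, indent=2, sort_keys=True))
        (out / "audit.json").write_text(
            json.dumps(self.audit_log(), indent=2, sort_keys=True)
        )


def run_scenario(
    config: ScenarioConfig | str | Path, out_dir: str | Path | None = None
) -> VaccineCoverageResults:
    """Build the model from a config, fit it, optionally write outputs."""
    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.from_file(config)
    model = VaccineCoverageModel.from_config(config)
    results = model.fit()
    if out_dir is not None:
        results.save(out_dir, top_k=config.top_k)
    return results


def sensitivity_sweep(
    config: ScenarioConfig | str | Path, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """One full scenario run per point on the configured parameter grid."""
    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.from_file(config)
    if not config.sensitivity:
        raise ValidationError("config defines no sensitivity parameters", field="sensitivity")
    model = VaccineCoverageModel.from_config(config)
    sweep = model.sensitivity(config.sensitivity)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sweep.to_csv(out / "sweep.csv", index=False)
    return sweep
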