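"""Population scores from proxy indicators with priority fallback.

Real barrier prevalences are rarely measured directly, so each barrier is
served by a hierarchy of proxy indicators (priority 1 = best available
definition, priority 2 the next best, ...).  Resolution takes the value
with the smallest priority that is non-missing and records which priority
was used, so every profile is auditable.  Missingness is an explicit
marker: a recorded 0 means the barrier is absent, which is informative and
must not be conflated with "no data".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError
from .model import PopulationProfile

__all__ = [
    "IndicatorRecord",
    "ResolvedScore",
    "resolve_score",
    "subregion_weighted_average",
    "build_profile",
]


@dataclass(frozen=True)
class IndicatorRecord:
    """One proxy-indicator observation for a region/barrier pair.

    ``complement`` flips the polarity: set it when the source reports the
    probability of *overcoming* the barrier, so the stored score is
    1 - value.  ``value`` is None when the source has no data.
    """

    region_id: str
    barrier_id: str
    priority: int
    value: float | None
    source: str = ""
    complement: bool = False

    def __post_init__(self):
        if self.priority < 1:
            raise ValidationError(f"priority must be >= 1, got {self.priority}", field="priority")
        if self.value is not None and not 0.0 <= self.value <= 1.0:
            raise ValidationError(
                f"indicator value must be in [0, 1], got {self.value}", field="value"
            )

    @property
    def score(self) -> float | None:
        if self.value is None:
            return None
        return 1.0 - self.value if self.complement else self.value


@dataclass(frozen=True)
class ResolvedScore:
    region_id: str
    barrier_id: str
    p: float
    priority_used: int
    provenance: str


def resolve_score(records: list[IndicatorRecord]) -> ResolvedScore:
    """Resolve one region/barrier pair: best-priority non-missing value wins."""
    if not records:
        raise MissingDataError("no indicator records supplied")
    region = records[0].region_id
    barrier = records[0].barrier_id
    for rec in records:
        if (rec.region_id, rec.barrier_id) != (region, barrier):
            raise ValidationError(
                f"records mix pairs: ({region}, {barrier}) vs ({rec.region_id}, {rec.barrier_id})",
                field="records",
            )
    priorities = [r.priority for r in records]
    if len(set(priorities)) != len(priorities):
        dupes = sorted({p for p in priorities if priorities.count(p) > 1})
        raise ValidationError(
            f"duplicate priorities {dupes} for {region}/{barrier}; "
            "each priority level must be unique",
            field="priority",
        )
    for rec in sorted(records, key=lambda r: r.priority):
        if rec.score is not None:
            note = f"priority {rec.priority}" + (f" ({rec.source})" if rec.source else "")
            return ResolvedScore(region, barrier, rec.score, rec.priority, note)
    raise MissingDataError(
        f"no value for {region}/{barrier} at any priority (tried {sorted(priorities)})"
    )


def subregion_weighted_average(values, weights) -> float:
    """Population-weighted mean, for rolling sub-region proxies up to a
    region when only neighbouring data exist."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValidationError(
            f"{values.size} values but {weights.size} weights", field="weights"
        )
    if np.any(weights < 0):
        raise ValidationError("weights must be non-negative", field="weights")
    total = weights.sum()
    if total == 0:
        raise ValidationError("weights sum to zero", field="weights")
    return float(np.dot(values, weights) / total)


def _records_from_frame(df: pd.DataFrame, region_id: str, barrier_id: str) -> list[IndicatorRecord]:
    sub = df[(df["region_id"] == region_id) & (df["barrier_id"] == barrier_id)]
    records = []
    for row in sub.itertuples(index=False):
        value = getattr(row, "value", None)
        if value is not None and pd.isna(value):
            value = None
        complement = bool(getattr(row, "complement", 0) or 0)
        records.append(
            IndicatorRecord(
                region_id=str(row.region_id),
                barrier_id=str(row.barrier_id),
                priority=int(row.priority),
                value=None if value is None else float(value),
                source=str(getattr(row, "source", "") or ""),
                complement=complement,
            )
        )
    return records


def build_profile(
    region_id: str,
    barrier_ids: tuple[str, ...] | list[str],
    indicators: pd.DataFrame,
) -> PopulationProfile:
    """Assemble the ordered prevalence vector for one region from an
    indicator table (columns: region_id, barrier_id, priority, value,
    source, complement).  Fails listing every unresolvable barrier at once
    rather than one at a time."""
    barrier_ids = tuple(barrier_ids)
    resolved: list[ResolvedScore] = []
    failures: list[str] = []
    for barrier in barrier_ids:
        records = _records_from_frame(indicators, region_id, barrier)
        try:
            resolved.append(resolve_score(records))
        except MissingDataError as exc:
            failures.append(f"{barrier}: {exc}")
    if failures:
        raise MissingDataError(
            f"region {region_id!r} has unresolvable barriers:\n  " + "\n  ".join(failures)
        )
    return PopulationProfile(
        barrier_ids=barrier_ids,
        p=np.array([r.p for r in resolved]),
        provenance=tuple(f"{r.barrier_id}: {r.provenance}" for r in resolved),
    )
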