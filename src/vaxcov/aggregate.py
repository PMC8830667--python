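"""Channel blending, multi-region aggregation, equity and ranking.

A population can be reached through more than one vaccination channel
(routine immunisation and supplementary immunisation activities).  Some
barriers only operate in one channel — schedule compliance is moot during
a campaign — so the full calibrated estimate is computed per channel with
the non-applicable barriers treated as absent, and the per-channel
estimates are combined as a share-weighted average.

Multi-region results are birth-cohort-weighted means over the *valid*
regions; regions whose estimate exceeds 100% signal model misuse and are
excluded, with the excluded share of the total cohort always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .model import (
    DEFAULT_D_WORST,
    CoverageEstimate,
    PopulationProfile,
    VaccinePresentation,
    estimate_coverage,
)

__all__ = [
    "ChannelSpec",
    "BlendedEstimate",
    "RegionResult",
    "AggregateSummary",
    "channel_blend",
    "aggregate_regions",
    "equity_index",
    "rank_regions",
]

SHARE_TOL = 1e-9


@dataclass(frozen=True)
class ChannelSpec:
    """One vaccination channel: its population share and which barriers
    apply to it.  ``applicable_barriers=None`` means all barriers apply."""

    channel_id: str
    share: float
    applicable_barriers: frozenset[str] | None = None

    def __post_init__(self):
        if not 0.0 <= self.share <= 1.0:
            raise ValidationError(
                f"channel share must be in [0, 1], got {self.share}", field=self.channel_id
            )
        if self.applicable_barriers is not None:
            object.__setattr__(self, "applicable_barriers", frozenset(self.applicable_barriers))


@dataclass(frozen=True)
class BlendedEstimate:
    """Share-weighted combination of per-channel calibrated estimates."""

    C_t: float
    C_c: float
    valid: bool
    per_channel: dict[str, CoverageEstimate]
    shares: dict[str, float]

    @property
    def delta(self) -> float:
        return self.C_t - self.C_c

    def audit(self) -> dict[str, dict[str, float]]:
        return {ch: est.audit() for ch, est in self.per_channel.items()}


def channel_blend(
    profile: PopulationProfile,
    test_pres: VaccinePresentation,
    calib_pres: VaccinePresentation,
    channels: list[ChannelSpec],
    M: float,
    C_c: float,
    d_worst: int = DEFAULT_D_WORST,
) -> BlendedEstimate:
    """Run the full calibrated estimate separately per channel and combine.

    Barriers masked out of a channel are treated as absent for that
    channel's population (effective p_i = 0): the barrier is a property of
    the delivery context, not of the technology, so it is removed on the
    population side.  The blend is invalid if any constituent channel
    estimate is invalid.
    """
    if not channels:
        raise ValidationError("at least one channel required", field="channels")
    total = sum(ch.share for ch in channels)
    if abs(total - 1.0) > SHARE_TOL:
        raise ValidationError(
            f"channel shares must sum to 1, got {total}", field="channels"
        )
    per_channel: dict[str, CoverageEstimate] = {}
    for ch in channels:
        ch_profile = (
            profile
            if ch.applicable_barriers is None
            else profile.mask(ch.applicable_barriers)
        )
        per_channel[ch.channel_id] = estimate_coverage(
            ch_profile, test_pres, calib_pres, M, C_c, d_worst=d_worst
        )
    C_t = sum(ch.share * per_channel[ch.channel_id].C_t for ch in channels)
    valid = all(est.valid for est in per_channel.values())
    return BlendedEstimate(
        C_t=float(C_t),
        C_c=float(C_c),
        valid=valid,
        per_channel=per_channel,
        shares={ch.channel_id: ch.share for ch in channels},
    )


@dataclass(frozen=True)
class RegionResult:
    """Per-region outcome row (one test presentation)."""

    region_id: str
    C_t: float
    C_c: float
    births: float
    valid: bool = True
    country_id: str = ""
    exclusion_reason: str = ""
    audit: dict = field(default_factory=dict, compare=False)

    @property
    def delta_pp(self) -> float:
        """Change vs the calibration vaccine, percentage points."""
        return (self.C_t - self.C_c) * 100.0

    @property
    def additional_vaccinated(self) -> float:
        return (self.C_t - self.C_c) * self.births


@dataclass(frozen=True)
class AggregateSummary:
    """Cohort-weighted multi-region summary over valid regions."""

    C_t: float
    C_c: float
    delta_pp: float
    additional_vaccinated: float
    total_births: float
    n_regions: int
    n_excluded: int
    excluded_regions: tuple[str, ...]
    excluded_cohort_share: float


def aggregate_regions(results: list[RegionResult]) -> AggregateSummary:
    """Birth-cohort-weighted aggregate over valid regions, with the
    excluded regions and their cohort share reported alongside."""
    if not results:
        raise ValidationError("no region results to aggregate", field="results")
    valid = [r for r in results if r.valid]
    excluded = [r for r in results if not r.valid]
    if not valid:
        raise ValidationError("no valid region results to aggregate", field="results")
    births = np.array([r.births for r in valid], dtype=float)
    if births.sum() <= 0:
        raise ValidationError("total birth cohort of valid regions is zero", field="births")
    C_t = float(np.average([r.C_t for r in valid], weights=births))
    C_c = float(np.average([r.C_c for r in valid], weights=births))
    additional = float(sum(r.additional_vaccinated for r in valid))
    all_births = sum(r.births for r in results)
    excl_share = sum(r.births for r in excluded) / all_births if all_births > 0 else 0.0
    return AggregateSummary(
        C_t=C_t,
        C_c=C_c,
        delta_pp=(C_t - C_c) * 100.0,
        additional_vaccinated=additional,
        total_births=float(births.sum()),
        n_regions=len(valid),
        n_excluded=len(excluded),
        excluded_regions=tuple(sorted(r.region_id for r in excluded)),
        excluded_cohort_share=float(excl_share),
    )


def equity_index(c) -> float:
    """Equity of coverage across the sub-regions of one country:
    ``E = 1 - sum_i (max(c) - c_i) / (r - 1)``.

    E = 1 means perfectly even coverage; larger shortfalls from the
    best-covered region pull E down.  Needs at least two regions.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValidationError(
            f"equity index needs at least 2 region estimates, got {c.size}", field="c"
        )
    return float(1.0 - np.sum(c.max() - c) / (c.size - 1))


def rank_regions(results: list[RegionResult], k: int) -> list[RegionResult]:
    """Top-k valid regions by coverage gain (percentage points),
    descending; ties broken by region id for determinism."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}", field="k")
    valid = [r for r in results if r.valid]
    ranked = sorted(valid, key=lambda r: (-r.delta_pp, r.region_id))
    return ranked[:k]
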