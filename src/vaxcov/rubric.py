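"""Five-level scoring rubric for vaccine-presentation characteristics.

Each technology-addressable barrier has a categorical five-level scale
(Low .. High) describing how much a presentation characteristic helps the
population overcome that barrier; the rubric maps levels to numeric
technology scores in [0, 1].  The shipped defaults cover the standard
barrier set (vaccine schedule alignment, temperature storage,
administration requirements, acceptability, doses per container) and are
expert judgements, so they live in a CSV that users can replace, not in
code.  Acceptability carries two variants — a generic scale and one
specific to the presence of a pork product in manufacture — because which
concern applies is an analysis choice, not something the rubric can infer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .model import VaccinePresentation

__all__ = [
    "LEVELS",
    "RubricTable",
    "PresentationSpec",
    "RubricViolation",
    "load_default_rubric",
    "score_presentation",
    "validate_rubric",
    "read_presentations",
]

#: The five rubric levels, from least to most helpful.
LEVELS = ("Low", "Medium-Low", "Medium", "Medium-High", "High")

DEFAULT_VARIANT = "default"


@dataclass(frozen=True)
class RubricViolation:
    barrier_id: str
    variant: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"{self.barrier_id}/{self.variant}: {self.message}"


class RubricTable:
    """Level -> score mapping per (barrier, variant)."""

    def __init__(self, scores: dict[tuple[str, str], dict[str, float]]):
        self._scores = {k: dict(v) for k, v in scores.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RubricTable":
        required = {"barrier_id", "level", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"rubric table lacks columns {sorted(missing)}", field="rubric")
        scores: dict[tuple[str, str], dict[str, float]] = {}
        for row in df.itertuples(index=False):
            variant = getattr(row, "variant", DEFAULT_VARIANT)
            if pd.isna(variant) or variant == "":
                variant = DEFAULT_VARIANT
            key = (str(row.barrier_id), str(variant))
            scores.setdefault(key, {})[str(row.level)] = float(row.score)
        return cls(scores)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RubricTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"barrier_id": b, "variant": var, "level": lvl, "score": s}
            for (b, var), levels in self._scores.items()
            for lvl, s in levels.items()
        ]
        return pd.DataFrame(rows)

    @property
    def barrier_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b, _ in self._scores:
            if b not in seen:
                seen.append(b)
        return tuple(seen)

    def variants(self, barrier_id: str) -> tuple[str, ...]:
        return tuple(var for b, var in self._scores if b == barrier_id)

    def score(self, barrier_id: str, level: str, variant: str | None = None) -> float:
        """Numeric technology score for one barrier level."""
        if variant is None:
            variant = DEFAULT_VARIANT
        key = (barrier_id, variant)
        if key not in self._scores:
            known = self.variants(barrier_id)
            if not known:
                raise ValidationError("barrier not present in rubric", field=barrier_id)
            raise ValidationError(
                f"unknown variant {variant!r} (known: {list(known)})", field=barrier_id
            )
        if level not in LEVELS:
            raise ValidationError(
                f"unknown level {level!r}; levels are {list(LEVELS)}", field=barrier_id
            )
        levels = self._scores[key]
        if level not in levels:
            raise ValidationError(f"rubric has no score for level {level!r}", field=barrier_id)
        return levels[level]


def load_default_rubric() -> RubricTable:
    """The shipped default rubric."""
    with resources.files("vaxcov.data").joinpath("default_rubric.csv").open() as fh:
        return RubricTable.from_frame(pd.read_csv(fh))


def validate_rubric(rubric: RubricTable) -> list[RubricViolation]:
    """Check every (barrier, variant): exactly five levels, scores in
    [0, 1], non-decreasing from Low to High.  Returns violations rather
    than raising, so a whole custom rubric can be reviewed at once."""
    violations: list[RubricViolation] = []
    for (barrier, variant), levels in rubric._scores.items():
        missing = [lvl for lvl in LEVELS if lvl not in levels]
        extra = [lvl for lvl in levels if lvl not in LEVELS]
        if missing:
            violations.append(RubricViolation(barrier, variant, f"missing levels {missing}"))
        if extra:
            violations.append(RubricViolation(barrier, variant, f"unknown levels {extra}"))
        for lvl, score in levels.items():
            if not 0.0 <= score <= 1.0:
                violations.append(
                    RubricViolation(barrier, variant, f"score {score} for {lvl!r} outside [0, 1]")
                )
        ordered = [levels[lvl] for lvl in LEVELS if lvl in levels]
        for i in range(1, len(ordered)):
            if ordered[i] < ordered[i - 1]:
                violations.append(
                    RubricViolation(
                        barrier,
                        variant,
                        f"scores decrease at level {i + 1} "
                        f"({ordered[i - 1]} -> {ordered[i]})",
                    )
                )
    return violations


@dataclass(frozen=True)
class PresentationSpec:
    """Categorical description of one presentation: a rubric level (and
    variant, where a barrier has several) per barrier, plus the dose count."""

    presentation_id: str
    levels: dict[str, str]
    doses_required: int
    variants: dict[str, str] = field(default_factory=dict)


def score_presentation(
    spec: PresentationSpec,
    rubric: RubricTable,
    barrier_order: tuple[str, ...] | list[str] | None = None,
) -> VaccinePresentation:
    """Map a categorical presentation spec to a numeric score vector.

    ``barrier_order`` fixes the vector order; it defaults to the order the
    spec lists its barriers in.
    """
    order = tuple(barrier_order) if barrier_order is not None else tuple(spec.levels)
    missing = [b for b in order if b not in spec.levels]
    if missing:
        raise ValidationError(
            f"presentation {spec.presentation_id!r} lacks levels for barriers {missing}",
            field="levels",
        )
    v = [
        rubric.score(b, spec.levels[b], spec.variants.get(b))
        for b in order
    ]
    return VaccinePresentation(
        barrier_ids=order,
        v=v,
        doses=spec.doses_required,
        presentation_id=spec.presentation_id,
    )


def read_presentations(
    presentations_csv: str | Path | pd.DataFrame,
    doses_csv: str | Path | pd.DataFrame,
) -> dict[str, PresentationSpec]:
    """Load presentation specs from the long-format CSV pair.

    ``presentations_csv`` has columns presentation_id, barrier_id, variant,
    level; ``doses_csv`` maps presentation_id to doses_required.
    """
    pres = presentations_csv if isinstance(presentations_csv, pd.DataFrame) else pd.read_csv(presentations_csv)
    doses = doses_csv if isinstance(doses_csv, pd.DataFrame) else pd.read_csv(doses_csv)
    dose_map = dict(zip(doses["presentation_id"], doses["doses_required"]))
    specs: dict[str, PresentationSpec] = {}
    for pid, grp in pres.groupby("presentation_id", sort=False):
        if pid not in dose_map:
            raise ValidationError(f"no dose count for presentation {pid!r}", field="doses_required")
        levels = dict(zip(grp["barrier_id"], grp["level"]))
        variants = {
            b: str(var)
            for b, var in zip(grp["barrier_id"], grp.get("variant", pd.Series(dtype=object)))
            if not pd.isna(var) and var != ""
        }
        specs[str(pid)] = PresentationSpec(
            presentation_id=str(pid),
            levels=levels,
            doses_required=int(dose_map[pid]),
            variants=variants,
        )
    return specs
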