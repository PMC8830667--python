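"""Barrier-probability coverage model and its linear calibration.

The model treats vaccination as the joint event of overcoming a set of
independent technology-addressable barriers, once per required dose.  For a
population with per-barrier failure prevalences ``p`` and a vaccine
presentation with technology scores ``v`` and dose count ``D``, the
*uncalibrated coverage* is

    U = (prod_i [1 - p_i (1 - v_i)])**D

U only accounts for technology-addressable barriers, so it is mapped onto
the observed coverage scale by a linear calibration ``C = S*U + beta``
anchored at two points: a "calibration" vaccine already deployed in the
population (observed coverage ``C_c``, uncalibrated coverage ``U_c``) and a
hypothetical perfect presentation (U = 1) whose coverage is the
population's maximum technology-achievable coverage ``M``.  The calibrated
estimate for a test presentation can equivalently be written

    C_t = M - k * x_t

where ``k = M - C_l`` is the coverage headroom addressable by technology
(``C_l`` being the calibrated coverage of a "least desirable" presentation
with all scores zero and the maximal dose count) and ``x_t`` is the
residual probability that the test presentation still fails at least one
technology-addressable barrier, renormalised against that baseline.

All probabilities are carried as fractions in [0, 1]; percent formatting
happens only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ValidationError

__all__ = [
    "PopulationProfile",
    "VaccinePresentation",
    "CalibrationContext",
    "CoverageEstimate",
    "uncalibrated_coverage",
    "least_desirable_coverage",
    "fit_calibration",
    "calibrate",
    "residual_risk",
    "estimate_coverage",
    "DEFAULT_D_WORST",
]

#: Dose count of the "least desirable" presentation: the highest number of
#: doses required by any vaccine available for full protection.
DEFAULT_D_WORST = 4


def _check_prob_vector(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("must be a 1-d vector", field=name)
    if arr.size == 0:
        raise ValidationError("must contain at least one barrier", field=name)
    if np.any(np.isnan(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError(
            f"all entries must be probabilities in [0, 1], got {arr.tolist()}",
            field=name,
        )
    return arr


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value) or not 0.0 <= value <= 1.0:
        raise ValidationError(f"must be a probability in [0, 1], got {value}", field=name)
    return value


@dataclass(frozen=True)
class PopulationProfile:
    """Per-barrier failure prevalences for one region (and channel).

    ``p[i]`` is the probability that an individual does *not* overcome
    barrier ``barrier_ids[i]`` absent any helpful technology.  The barrier
    order is fixed and must be shared with any presentation the profile is
    combined with.
    """

    barrier_ids: tuple[str, ...]
    p: np.ndarray
    provenance: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        ids = tuple(self.barrier_ids)
        object.__setattr__(self, "barrier_ids", ids)
        arr = _check_prob_vector("p", self.p)
        if arr.size != len(ids):
            raise ValidationError(
                f"p has {arr.size} entries but {len(ids)} barrier ids", field="p"
            )
        if len(set(ids)) != len(ids):
            raise ValidationError("barrier ids must be unique", field="barrier_ids")
        arr.setflags(write=False)
        object.__setattr__(self, "p", arr)

    @property
    def n_barriers(self) -> int:
        return len(self.barrier_ids)

    def mask(self, applicable: set[str] | frozenset[str]) -> "PopulationProfile":
        """Return a profile where non-applicable barriers are absent (p_i = 0).

        Used for vaccination channels in which a barrier does not operate
        (e.g. schedule compliance during a campaign); the barrier then poses
        no risk to that channel's population.
        """
        unknown = set(applicable) - set(self.barrier_ids)
        if unknown:
            raise ValidationError(
                f"mask names unknown barriers {sorted(unknown)}", field="applicable"
            )
        p = np.array(
            [pi if bid in applicable else 0.0 for bid, pi in zip(self.barrier_ids, self.p)]
        )
        return PopulationProfile(self.barrier_ids, p, provenance=self.provenance)


@dataclass(frozen=True)
class VaccinePresentation:
    """Technology scores ``v`` (one per barrier) and dose count ``D``.

    ``v[i] = 0`` means the presentation gives no help with barrier ``i``;
    ``v[i] = 1`` fully neutralises it.
    """

    barrier_ids: tuple[str, ...]
    v: np.ndarray
    doses: int
    presentation_id: str = field(default="", compare=False)

    def __post_init__(self):
        ids = tuple(self.barrier_ids)
        object.__setattr__(self, "barrier_ids", ids)
        arr = _check_prob_vector("v", self.v)
        if arr.size != len(ids):
            raise ValidationError(
                f"v has {arr.size} entries but {len(ids)} barrier ids", field="v"
            )
        if not (isinstance(self.doses, (int, np.integer)) and not isinstance(self.doses, bool)):
            raise ValidationError(
                f"dose count must be an integer, got {self.doses!r}", field="doses"
            )
        if self.doses < 1:
            raise ValidationError(f"dose count must be >= 1, got {self.doses}", field="doses")
        arr.setflags(write=False)
        object.__setattr__(self, "v", arr)
        object.__setattr__(self, "doses", int(self.doses))


def _check_aligned(profile: PopulationProfile, pres: VaccinePresentation) -> None:
    if profile.barrier_ids != pres.barrier_ids:
        raise ValidationError(
            "profile and presentation barrier ids differ: "
            f"{profile.barrier_ids} vs {pres.barrier_ids}",
            field="barrier_ids",
        )


def uncalibrated_coverage(profile: PopulationProfile, pres: VaccinePresentation) -> float:
    """Probability of overcoming every technology-addressable barrier for
    all ``D`` required doses, assuming independent barriers and doses:
    ``(prod_i [1 - p_i (1 - v_i)])**D``."""
    _check_aligned(profile, pres)
    per_dose = float(np.prod(1.0 - profile.p * (1.0 - pres.v)))
    return per_dose ** pres.doses


def least_desirable_coverage(profile: PopulationProfile, d_worst: int = DEFAULT_D_WORST) -> float:
    """Uncalibrated coverage of the least-desirable presentation: no
    technology help (v = 0) and the maximal dose count ``d_worst``."""
    worst = VaccinePresentation(
        profile.barrier_ids, np.zeros(profile.n_barriers), d_worst, presentation_id="least-desirable"
    )
    return uncalibrated_coverage(profile, worst)


@dataclass(frozen=True)
class CalibrationContext:
    """Fitted linear map from uncalibrated to calibrated coverage.

    The line passes through (U_c, C_c) — the calibration vaccine — and
    (1, M) — the perfect presentation — so ``S = (M - C_c) / (1 - U_c)``
    and ``beta = C_c - S * U_c``.  ``beta`` is the coverage the least
    attractive imaginable presentation (U = 0) would achieve.
    """

    M: float
    C_c: float
    U_c: float
    U_l: float
    S: float
    beta: float
    d_worst: int = DEFAULT_D_WORST

    @property
    def C_l(self) -> float:
        """Calibrated coverage of the least-desirable presentation."""
        return self.S * self.U_l + self.beta

    @property
    def k(self) -> float:
        """Headroom: coverage percentage points addressable by technology."""
        return self.M - self.C_l


def fit_calibration(
    M: float,
    C_c: float,
    U_c: float,
    U_l: float,
    d_worst: int = DEFAULT_D_WORST,
) -> CalibrationContext:
    """Fit the two-point linear calibration.

    ``M`` may exceed 1: reported administrative coverage rates sometimes do,
    and a large gap between ``M`` and ``C_c`` is exactly the regime in which
    downstream estimates can exceed 100% and get flagged for exclusion.
    """
    M = float(M)
    if math.isnan(M) or M < 0.0:
        raise ValidationError(f"must be non-negative, got {M}", field="M")
    C_c = _check_prob("C_c", C_c) if C_c <= 1.0 else float(C_c)
    if C_c < 0.0 or math.isnan(C_c):
        raise ValidationError(f"must be non-negative, got {C_c}", field="C_c")
    U_c = _check_prob("U_c", U_c)
    U_l = _check_prob("U_l", U_l)
    if C_c > M:
        raise CalibrationError(
            f"calibration coverage C_c={C_c} exceeds maximum coverage M={M}; "
            "the calibration vaccine cannot outperform the technology ceiling",
            field="C_c",
        )
    if U_c >= 1.0:
        raise CalibrationError(
            "U_c = 1 makes the calibration line vertical (zero denominator); "
            "choose a calibration vaccine with at least one unaddressed barrier",
            field="U_c",
        )
    if U_l > U_c:
        raise CalibrationError(
            f"least-desirable presentation has higher uncalibrated coverage "
            f"(U_l={U_l}) than the calibration vaccine (U_c={U_c}); "
            "the least-desirable presentation is mis-specified",
            field="U_l",
        )
    S = (M - C_c) / (1.0 - U_c)
    beta = C_c - S * U_c
    return CalibrationContext(M=M, C_c=C_c, U_c=U_c, U_l=U_l, S=S, beta=beta, d_worst=int(d_worst))


def calibrate(U: float, ctx: CalibrationContext) -> float:
    """Map an uncalibrated coverage onto the observed scale: ``S*U + beta``."""
    return ctx.S * _check_prob("U", U) + ctx.beta


def residual_risk(U_t: float, U_l: float) -> float:
    """Probability the test presentation still fails at least one
    technology-addressable barrier, net of the least-desirable baseline:
    ``x_t = 1 - (U_t - U_l) / (1 - U_l)``."""
    U_t = _check_prob("U_t", U_t)
    U_l = _check_prob("U_l", U_l)
    if U_l >= 1.0:
        raise ValidationError(
            "U_l = 1 leaves no addressable failure to renormalise against", field="U_l"
        )
    if U_t < U_l:
        raise ValidationError(
            f"test presentation is worse than the least-desirable one "
            f"(U_t={U_t} < U_l={U_l}); check the least-desirable dose count",
            field="U_t",
        )
    return 1.0 - (U_t - U_l) / (1.0 - U_l)


@dataclass(frozen=True)
class CoverageEstimate:
    """Calibrated coverage estimate with every intermediate kept for audit.

    ``valid`` is False when C_t exceeds 100%; such estimates signal model
    misuse (typically a calibration vaccine poorly aligned with the vaccine
    defining M) and are excluded from multi-region aggregates rather than
    clamped.
    """

    C_t: float
    U_t: float
    x_t: float
    k: float
    valid: bool
    context: CalibrationContext

    @property
    def C_l(self) -> float:
        return self.context.C_l

    @property
    def delta(self) -> float:
        """Change relative to the calibration vaccine, as a fraction."""
        return self.C_t - self.context.C_c

    def audit(self) -> dict[str, float]:
        """All intermediates, for provenance logging."""
        c = self.context
        return {
            "M": c.M,
            "C_c": c.C_c,
            "U_c": c.U_c,
            "U_l": c.U_l,
            "S": c.S,
            "beta": c.beta,
            "C_l": c.C_l,
            "k": self.k,
            "U_t": self.U_t,
            "x_t": self.x_t,
            "C_t": self.C_t,
            "valid": float(self.valid),
        }


def estimate_coverage(
    profile: PopulationProfile,
    test_pres: VaccinePresentation,
    calib_pres: VaccinePresentation,
    M: float,
    C_c: float,
    d_worst: int = DEFAULT_D_WORST,
) -> CoverageEstimate:
    """End-to-end calibrated estimate ``C_t = M - k * x_t`` for a test
    presentation, anchored on the observed coverage of a calibration
    presentation in the same population."""
    U_c = uncalibrated_coverage(profile, calib_pres)
    U_l = least_desirable_coverage(profile, d_worst)
    ctx = fit_calibration(M, C_c, U_c, U_l, d_worst=d_worst)
    U_t = uncalibrated_coverage(profile, test_pres)
    x_t = residual_risk(U_t, U_l)
    C_t = ctx.M - ctx.k * x_t
    return CoverageEstimate(
        C_t=C_t, U_t=U_t, x_t=x_t, k=ctx.k, valid=bool(C_t <= 1.0), context=ctx
    )
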