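"""Closed-form attributable-effect calculations and a Monte-Carlo oracle.

The effect model is multiplicative on annual per-person rates: the exposed
group's rate is the literature rate times the pathway's odds ratio (rare-
outcome approximation, no odds-to-risk conversion), clamped into [0, 1].
Attributable quantities are the difference between the with-exposure total
and the no-exposure expectation, so protective effects (OR < 1) come out
negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import EvaluationError, ValidationError
from .population import ExposureSplit, PopulationProfile

logger = logging.getLogger(__name__)

__all__ = [
    "MortalityResult",
    "MorbidityResult",
    "attributable_deaths",
    "attributable_yll",
    "attributable_cases",
    "attributable_yld",
    "mc_oracle",
]


@dataclass(frozen=True)
class MortalityResult:
    """Annual mortality effect of one pathway on one split population."""

    MRe: float
    MRu: float
    De: float
    Du: float
    Dexpected: float
    Dattributed: float
    YLLe: Optional[float] = None
    YLLu: Optional[float] = None
    YLLattributed: Optional[float] = None


@dataclass(frozen=True)
class MorbidityResult:
    """Annual morbidity effect of one pathway on one split population."""

    IRe: float
    IRu: float
    Ce: float
    Cu: float
    Cexpected: float
    Cattributed: float
    YLD: Optional[float] = None  # per-case years lived with the illness
    YLDattributed: Optional[float] = None


def _scaled_rate(rate: float, odds_ratio: float, what: str) -> float:
    scaled = rate * odds_ratio
    if scaled > 1.0:
        logger.warning(
            "%s rate %.6g x OR %.4g exceeds 1; clamped to 1", what, rate, odds_ratio
        )
        return 1.0
    return scaled


def _check_rate_or(rate: float, odds_ratio: float) -> None:
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"annual rate must be in [0, 1], got {rate}")
    if not odds_ratio > 0:
        raise ValidationError(f"odds ratio must be > 0, got {odds_ratio}")


def attributable_deaths(
    split: ExposureSplit, MRlit: float, OR: float
) -> MortalityResult:
    """Annual deaths attributable to exposure.

    De = (MRlit·OR)·ne, Du = MRlit·nu, Dexpected = MRlit·n and
    Dattributed = (De + Du) − Dexpected = ne·MRlit·(OR − 1).
    """
    _check_rate_or(MRlit, OR)
    MRe = _scaled_rate(MRlit, OR, "mortality")
    De = MRe * split.ne
    Du = MRlit * split.nu
    Dexpected = MRlit * split.n
    # algebraically (De + Du) − Dexpected; this form is exactly 0 at OR = 1
    Dattributed = split.ne * (MRe - MRlit)
    return MortalityResult(
        MRe=MRe,
        MRu=MRlit,
        De=De,
        Du=Du,
        Dexpected=Dexpected,
        Dattributed=Dattributed,
    )


def attributable_yll(result: MortalityResult, mean_LY: float) -> MortalityResult:
    """Populate life-years-lost fields from mean remaining life expectancy."""
    if not mean_LY > 0:
        raise ValidationError(f"mean remaining life must be > 0, got {mean_LY}")
    return replace(
        result,
        YLLe=mean_LY * result.De,
        YLLu=mean_LY * result.Du,
        YLLattributed=mean_LY * result.Dattributed,
    )


def attributable_cases(
    split: ExposureSplit, IRlit: float, OR: float
) -> MorbidityResult:
    """Annual cases of illness attributable to exposure (morbidity analogue)."""
    _check_rate_or(IRlit, OR)
    IRe = _scaled_rate(IRlit, OR, "incidence")
    Ce = IRe * split.ne
    Cu = IRlit * split.nu
    Cexpected = IRlit * split.n
    return MorbidityResult(
        IRe=IRe,
        IRu=IRlit,
        Ce=Ce,
        Cu=Cu,
        Cexpected=Cexpected,
        Cattributed=split.ne * (IRe - IRlit),
    )


def yld_per_case(Tsick: float, affected_profile: PopulationProfile) -> float:
    """Expected years lived with one case: count-weighted mean of min(Tsick, LE).

    The cap is applied per stratum — no individual can live with an illness
    longer than their remaining life expectancy.
    """
    if not Tsick > 0:
        raise ValidationError(f"illness duration must be > 0, got {Tsick}")
    n = affected_profile.n
    if n <= 0:
        raise EvaluationError(
            f"cannot compute illness years on empty profile {affected_profile.label!r}"
        )
    total = sum(s.count * min(Tsick, s.life_expectancy) for s in affected_profile.strata)
    return total / n


def attributable_yld(
    Cattributed: float, Tsick: float, affected_profile: PopulationProfile
) -> float:
    """Attributable years lived with illness: Cattributed × capped per-case years."""
    per_case = yld_per_case(Tsick, affected_profile)
    return Cattributed * per_case


def mc_oracle(
    split: ExposureSplit,
    rate: float,
    OR: float,
    reps: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the annual attributable count and its SE.

    Each replicate draws every exposed person's event with probability
    min(rate·OR, 1) and every unexposed person's with ``rate``, then records
    (events − n·rate). Serves as an independent check of the closed forms;
    operates on whole persons only.
    """
    _check_rate_or(rate, OR)
    if reps < 1:
        raise ValidationError(f"reps must be >= 1, got {reps}")
    ne, nu = split.ne, split.nu
    if ne != int(ne) or nu != int(nu):
        raise ValidationError(
            f"Monte-Carlo oracle needs integer group sizes, got ne={ne}, nu={nu}"
        )
    rng = np.random.default_rng(seed)
    p_exposed = min(rate * OR, 1.0)
    events = rng.binomial(int(ne), p_exposed, size=reps) + rng.binomial(
        int(nu), rate, size=reps
    )
    attributed = events - split.n * rate
    mean = float(np.mean(attributed))
    se = float(np.std(attributed, ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mean, se
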