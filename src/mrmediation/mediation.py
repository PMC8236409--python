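"""Mediation arithmetic on the log-odds scale.

The proportion of an exposure's total effect on the outcome mediated by a
set of risk factors is estimated as

    proportion = 1 - theta_D / theta_T

where theta_T is the total effect (univariable MR) and theta_D the direct
effect after adjusting for the genetically predicted mediators
(multivariable MR), both log-scale. The standard error comes from
first-order propagation of error (delta method) on the ratio with the
covariance between the two estimates set to zero:

    SE(theta_D / theta_T) = |R| * sqrt((se_D/theta_D)^2 + (se_T/theta_T)^2),
    R = theta_D / theta_T

implemented in the algebraically equivalent form
sqrt((se_D/theta_T)^2 + (theta_D * se_T / theta_T^2)^2), which remains
defined at theta_D = 0. Proportions and their CIs are never truncated to
[0, 1] — a mediator with no role can legitimately yield a negative interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .mr_estimators import MREstimate, Z95
from .mvmr import MVMRResult

logger = logging.getLogger(__name__)


class MediationError(ValueError):
    """Fatal condition in mediation arithmetic."""


@dataclass
class EffectWithCI:
    """A log-scale effect estimate with standard error.

    Can be built from a fitted model or from a printed odds ratio with its
    95% CI via ``from_or`` (se = (ln hi - ln lo) / 3.92).
    """

    beta: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise MediationError(f"EffectWithCI requires se > 0, got {self.se}")

    @classmethod
    def from_or(cls, or_point: float, or_low: float, or_high: float) -> "EffectWithCI":
        """Log-transform a printed odds ratio and its 95% confidence interval."""
        if not (0 < or_low <= or_point <= or_high):
            raise MediationError(
                f"odds-ratio ordering violated: {or_low} <= {or_point} <= {or_high}"
            )
        beta = math.log(or_point)
        se = (math.log(or_high) - math.log(or_low)) / (2.0 * 1.96)
        if se <= 0:
            raise MediationError("degenerate confidence interval (zero width)")
        return cls(beta=beta, se=se)

    @classmethod
    def from_estimate(cls, est: MREstimate) -> "EffectWithCI":
        if est.se is None:
            raise MediationError(
                f"{est.method} has no symmetric SE; use a normal-theory estimator "
                "for mediation arithmetic"
            )
        return cls(beta=est.beta, se=est.se)

    @classmethod
    def from_mvmr(cls, result: MVMRResult, predictor: str) -> "EffectWithCI":
        beta, se = result.coefficient(predictor)
        return cls(beta=beta, se=se)

    def odds_ratio(self) -> tuple[float, float, float]:
        """(point, low, high) on the OR scale."""
        return (
            math.exp(self.beta),
            math.exp(self.beta - Z95 * self.se),
            math.exp(self.beta + Z95 * self.se),
        )


# backwards-friendly functional alias
def effect_from_or(or_point: float, or_low: float, or_high: float) -> EffectWithCI:
    return EffectWithCI.from_or(or_point, or_low, or_high)


@dataclass
class MediationResult:
    """Proportion mediated with delta-method uncertainty."""

    mediators: list[str]
    total: EffectWithCI
    direct: EffectWithCI
    proportion: float
    proportion_se: float
    ci_low: float
    ci_high: float

    def as_percent(self) -> tuple[int, int, int]:
        """(point, low, high) rounded to whole percentages (presentation only)."""
        return (
            round(100.0 * self.proportion),
            round(100.0 * self.ci_low),
            round(100.0 * self.ci_high),
        )


def proportion_mediated(
    total: EffectWithCI,
    direct: EffectWithCI,
    mediators: Sequence[str] = (),
) -> MediationResult:
    """Proportion mediated, 1 - direct/total, with propagation-of-error CI.

    The covariance between the total- and direct-effect estimates is set to
    zero (it is not identifiable from two-sample summary data); the 95% CI
    is proportion +/- 1.96 SE and is not truncated to [0, 1].
    """
    if total.beta == 0.0:
        raise MediationError("total effect is zero; proportion mediated undefined")
    ratio = direct.beta / total.beta
    proportion = 1.0 - ratio
    # |R| sqrt((se_D/th_D)^2 + (se_T/th_T)^2) rewritten to stay defined at th_D = 0
    se = math.sqrt(
        (direct.se / total.beta) ** 2 + (direct.beta * total.se / total.beta**2) ** 2
    )
    return MediationResult(
        mediators=list(mediators),
        total=total,
        direct=direct,
        proportion=proportion,
        proportion_se=se,
        ci_low=proportion - Z95 * se,
        ci_high=proportion + Z95 * se,
    )


def mediation_table(
    total: MREstimate, directs: Sequence[MVMRResult]
) -> list[MediationResult]:
    """One mediation result per fitted multivariable model.

    Each model's exposure coefficient (its first predictor) provides the
    direct effect; the exposure and outcome labels must match the total
    effect's when both carry labels. The sum of single-mediator proportions
    versus the joint proportion is logged descriptively (the paths are not
    constrained to be disjoint, so it is not asserted).
    """
    if not directs:
        raise MediationError("no multivariable models supplied; nothing to mediate")
    total_eff = EffectWithCI.from_estimate(total)
    out: list[MediationResult] = []
    for res in directs:
        if total.exposure is not None and res.predictors[0] != total.exposure:
            raise MediationError(
                f"exposure mismatch: total effect is for {total.exposure!r}, "
                f"model predicts {res.predictors[0]!r}"
            )
        if (
            total.outcome is not None
            and res.outcome is not None
            and res.outcome != total.outcome
        ):
            raise MediationError(
                f"outcome mismatch: {total.outcome!r} vs {res.outcome!r}"
            )
        direct = EffectWithCI.from_mvmr(res, res.predictors[0])
        out.append(
            proportion_mediated(total_eff, direct, mediators=res.predictors[1:])
        )
    singles = [r for r in out if len(r.mediators) == 1]
    joints = [r for r in out if len(r.mediators) > 1]
    if singles and joints:
        logger.info(
            "sum of single-mediator proportions = %.3f vs joint proportion(s) %s "
            "(descriptive comparison only)",
            sum(r.proportion for r in singles),
            ", ".join(f"{r.proportion:.3f}" for r in joints),
        )
    return out
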