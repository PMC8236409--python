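"""Multivariable Mendelian randomization (MVMR).

The variant-outcome association estimates are regressed jointly on the
variant-exposure and variant-mediator estimates, weighted by the precision
of the variant-outcome association, with the intercept fixed to zero. Each
coefficient is the direct effect of its trait on the outcome conditional on
the other genetically predicted traits — for a mediation model, the
exposure's coefficient is its effect not acting through the included
mediators.

No method exists for assessing conditional instrument strength from
two-sample summary data; a descriptive marginal mean F statistic per
predictor is logged instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mr_estimators import Z95, _two_sided_p
from .summary_data import HarmonizedPanel, SummaryDataError

logger = logging.getLogger(__name__)


class MVMRError(ValueError):
    """Fatal condition in a multivariable MR fit."""


@dataclass
class MVMRResult:
    """Direct-effect estimates for each predictor (exposure first)."""

    predictors: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    n_variants: int
    re_scale: float
    outcome: str | None = None

    def __post_init__(self) -> None:
        k = len(self.predictors)
        if not all(len(a) == k for a in (self.beta, self.se, self.ci_low, self.ci_high, self.pvalue)):
            raise MVMRError("inconsistent MVMR result lengths")
        if not np.all((self.ci_low <= self.beta) & (self.beta <= self.ci_high)):
            raise MVMRError("MVMR confidence bounds do not bracket estimates")

    def coefficient(self, predictor: str) -> tuple[float, float]:
        """(beta, se) for one predictor by trait name."""
        i = self.predictors.index(predictor)
        return float(self.beta[i]), float(self.se[i])


def multivariable_ivw(panel: HarmonizedPanel, binary_mediator_warning: bool = True) -> MVMRResult:
    """Weighted zero-intercept regression of variant-outcome on variant-trait betas.

    Panel convention: exposure first, outcome last, mediators (or a second
    exposure) in between. Weights are 1/se_Yj^2; standard errors carry the
    multiplicative random-effects scaling max(1, sqrt(RSS_w / (J - K))).
    Requires more variants than predictors and a full-rank predictor matrix.

    A binary trait entering as a predictor contributes its log-odds of
    liability directly; this can bias mediation estimates because genetic
    liability does not guarantee trait expression, so its presence is
    logged as a caveat (and the pipeline offers a joint model excluding it).
    """
    if panel.n_traits < 3:
        raise SummaryDataError("multivariable panel needs exposure, >=1 mediator, outcome")
    predictors = panel.traits[:-1]
    x = panel.beta[:, :-1]
    by = panel.beta[:, -1]
    sy = panel.se[:, -1]
    j, k = x.shape
    if j <= k:
        raise MVMRError(f"need more variants than predictors (J={j}, K={k})")
    if binary_mediator_warning:
        binary = [t for t, tt in zip(predictors, panel.trait_types[:-1]) if tt == "binary"]
        if binary:
            logger.warning(
                "binary predictor(s) %s enter as log-odds of liability; "
                "mediation estimates may be biased because genetic liability "
                "does not guarantee trait expression",
                ", ".join(binary),
            )

    w = 1.0 / sy**2
    # an all-zero predictor column carries no information: its direct effect
    # is unidentified (reported as 0 with infinite SE) and it is excluded
    # from the normal equations so the remaining fit is the nested model
    live = np.flatnonzero(np.any(x != 0.0, axis=0))
    dead = [predictors[i] for i in range(k) if i not in live]
    if dead:
        logger.warning("predictor(s) with all-zero betas left unidentified: %s", ", ".join(dead))
    xl = x[:, live]
    xtwx = xl.T @ (w[:, None] * xl)
    if np.linalg.cond(xtwx) > 1e12:
        raise MVMRError(
            "singular (collinear) predictor matrix for traits: " + ", ".join(predictors)
        )
    coef_l = np.linalg.solve(xtwx, xl.T @ (w * by))
    resid = by - xl @ coef_l
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, float(np.sqrt(rss_w / (j - len(live)))))
    cov = np.linalg.inv(xtwx) * scale**2
    coef = np.zeros(k)
    coef[live] = coef_l
    se = np.full(k, np.inf)
    se[live] = np.sqrt(np.diag(cov))

    # descriptive only: marginal mean F per predictor (no conditional version
    # exists for two-sample summary data)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_f = np.nanmean((x / panel.se[:, :-1]) ** 2, axis=0)
    logger.info(
        "MVMR marginal mean F: %s",
        ", ".join(f"{t}={f:.1f}" for t, f in zip(predictors, mean_f)),
    )

    z = coef / se
    return MVMRResult(
        predictors=list(predictors),
        beta=coef,
        se=se,
        ci_low=coef - Z95 * se,
        ci_high=coef + Z95 * se,
        pvalue=np.array([_two_sided_p(zi) for zi in z]),
        n_variants=j,
        re_scale=scale,
        outcome=panel.traits[-1],
    )


def mutual_adjustment(panel: HarmonizedPanel) -> MVMRResult:
    """Direct effects of two exposures on the outcome, mutually adjusted.

    A multivariable fit with exactly two predictor traits; panel columns
    must be [exposure_a, exposure_b, outcome].
    """
    if panel.n_traits != 3:
        raise MVMRError(
            f"mutual adjustment needs exactly [exposure_a, exposure_b, outcome], "
            f"got {panel.traits}"
        )
    return multivariable_ivw(panel)
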