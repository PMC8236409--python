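"""Univariable two-sample Mendelian randomization estimators.

Four estimators operate on a harmonized exposure/outcome panel of
variant-level association estimates (beta_Xj, beta_Yj with SEs):

* ``ivw`` — multiplicative random-effects inverse-variance weighted
  estimate: weighted regression of beta_Y on beta_X through the origin with
  weights 1/se_Yj^2; the fixed-effect SE is inflated by
  max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic.
* ``mr_egger`` — the same weighted regression with an unconstrained
  intercept; the intercept estimates the average directional pleiotropic
  effect and its test (p > 0.05 read as no evidence) is reported alongside
  the slope.
* ``weighted_median`` — the precision-weighted 50th percentile of the
  per-variant ratio estimates, consistent when at least half the weight
  comes from valid instruments; SE by parametric bootstrap.
* ``contamination_mixture`` — profile likelihood over a grid of candidate
  causal effects, assigning each variant to a valid component centred on the
  causal effect or an invalid component centred on the null with inflated
  variance psi^2; the 95% CI collects grid values within chi2(1)/2 = 1.92
  log-likelihood units of the maximum and may be asymmetric.

All estimators consume ratio scale-free summary data, so a binary outcome
yields log-odds-ratio estimates per SD of exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedPanel, SummaryDataError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile
CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207... profile-CI cutoff


class EstimatorError(ValueError):
    """Fatal condition in an MR estimator (too few variants, bad grid...)."""


@dataclass
class RatioEstimates:
    """Per-variant Wald ratio estimates beta_Yj / beta_Xj with first-order SEs."""

    variant_ids: list[str]
    ratio: np.ndarray
    ratio_se: np.ndarray


@dataclass
class MREstimate:
    """One causal-effect estimate with its uncertainty and diagnostics.

    ``beta`` is on the log-odds scale for binary outcomes (exponentiate for
    an odds ratio per 1-SD increase of the exposure). ``se`` is ``None`` for
    the contamination mixture, whose profile-likelihood CI can be asymmetric.
    """

    method: str
    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    heterogeneity_q: float | None = None
    re_scale: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    n_valid: int | None = None
    exposure: str | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimatorError(
                f"{self.method}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket estimate {self.beta}"
            )
        if self.se is not None and self.se <= 0:
            raise EstimatorError(f"{self.method}: non-positive SE")


def _exposure_outcome(panel: HarmonizedPanel) -> tuple[np.ndarray, ...]:
    """First panel column is the exposure, last is the outcome."""
    if panel.n_traits < 2:
        raise SummaryDataError("panel must contain an exposure and an outcome")
    bx, by = panel.beta[:, 0], panel.beta[:, -1]
    sx, sy = panel.se[:, 0], panel.se[:, -1]
    return bx, by, sx, sy


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Ratio estimates
# ---------------------------------------------------------------------------


def ratio_estimates(panel: HarmonizedPanel) -> RatioEstimates:
    """Per-variant ratio (Wald) estimates with first-order standard errors.

    ratio_j = beta_Yj / beta_Xj, se_j = se_Yj / |beta_Xj|. The first-order
    SE neglects uncertainty in beta_Xj, a good approximation for instruments
    selected at genome-wide significance.
    """
    bx, by, _, sy = _exposure_outcome(panel)
    zero = [panel.variant_ids[i] for i in np.nonzero(bx == 0.0)[0]]
    if zero:
        raise EstimatorError(
            "zero exposure beta for variant(s): " + ", ".join(zero)
        )
    return RatioEstimates(
        variant_ids=list(panel.variant_ids),
        ratio=by / bx,
        ratio_se=sy / np.abs(bx),
    )


# ---------------------------------------------------------------------------
# Inverse-variance weighted
# ---------------------------------------------------------------------------


def ivw(panel: HarmonizedPanel) -> MREstimate:
    """Multiplicative random-effects inverse-variance weighted estimate.

    With a single variant the Wald ratio (fixed-effect) is returned.
    """
    bx, by, _, sy = _exposure_outcome(panel)
    j = len(bx)
    if j == 0:
        raise EstimatorError("ivw requires at least one variant")
    if j == 1:
        if bx[0] == 0.0:
            raise EstimatorError(f"zero exposure beta for variant {panel.variant_ids[0]}")
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        return MREstimate(
            method="ivw",
            beta=beta,
            se=se,
            ci_low=beta - Z95 * se,
            ci_high=beta + Z95 * se,
            pvalue=_two_sided_p(beta / se),
            n_variants=1,
            heterogeneity_q=0.0,
            re_scale=1.0,
            exposure=panel.traits[0],
            outcome=panel.traits[-1],
        )
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(np.sum(w * bx**2) ** -0.5)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * scale
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_two_sided_p(beta / se),
        n_variants=j,
        heterogeneity_q=q,
        re_scale=float(scale),
        exposure=panel.traits[0],
        outcome=panel.traits[-1],
    )


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def mr_egger(panel: HarmonizedPanel, pvalue_dist: str = "normal") -> MREstimate:
    """MR-Egger regression: weighted regression of variant-outcome on
    variant-exposure estimates with an unconstrained intercept.

    Variants are first re-oriented so every exposure beta is positive (the
    estimate is invariant to this joint flip; the intercept is not, so a
    fixed orientation is required). SEs use the multiplicative
    random-effects scaling with J - 2 degrees of freedom. ``pvalue_dist``
    may be ``"normal"`` (default) or ``"t"`` (J - 2 df).
    """
    bx, by, _, sy = _exposure_outcome(panel)
    j = len(bx)
    if j < 3:
        raise EstimatorError(f"mr_egger requires at least 3 variants, got {j}")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    if pvalue_dist == "t":
        pfun = lambda z: float(2.0 * stats.t.sf(abs(z), df=j - 2))
    elif pvalue_dist == "normal":
        pfun = _two_sided_p
    else:
        raise EstimatorError(f"unknown pvalue_dist {pvalue_dist!r}")
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - Z95 * se_slope,
        ci_high=slope + Z95 * se_slope,
        pvalue=pfun(slope / se_slope),
        n_variants=j,
        heterogeneity_q=rss_w,
        re_scale=float(scale),
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=pfun(intercept / se_int),
        exposure=panel.traits[0],
        outcome=panel.traits[-1],
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------


def _weighted_median_point(ratio: np.ndarray, ratio_se: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = 1.0 / ratio_se[order] ** 2
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    panel: HarmonizedPanel, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Precision-weighted median of the per-variant ratio estimates.

    The ratio estimates are ordered, given standardized inverse-variance
    weights, and the estimate is read off at cumulative weight 0.5 by linear
    interpolation. The SE is the standard deviation of the estimator over
    ``n_boot`` parametric resamples of (beta_Xj, beta_Yj) from normal
    distributions with the panel's SEs; the seed is mandatory and recorded
    implicitly through the caller's configuration.
    """
    bx, by, sx, sy = _exposure_outcome(panel)
    j = len(bx)
    if j < 3:
        raise EstimatorError(f"weighted_median requires at least 3 variants, got {j}")
    re = ratio_estimates(panel)
    beta = _weighted_median_point(re.ratio, re.ratio_se)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    bx_star[bx_star == 0.0] = np.finfo(float).tiny  # guard exact zeros
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = _weighted_median_point(by_star[b] / bx_star[b], sy / np.abs(bx_star[b]))
    se = float(np.std(est, ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_two_sided_p(beta / se),
        n_variants=j,
        exposure=panel.traits[0],
        outcome=panel.traits[-1],
    )


# ---------------------------------------------------------------------------
# Contamination mixture
# ---------------------------------------------------------------------------


def _conmix_profile(
    ratio: np.ndarray, ratio_se: np.ndarray, theta: np.ndarray, psi: float
) -> np.ndarray:
    """Profile log-likelihood at each candidate causal effect.

    Each variant contributes the larger of its valid-component and
    invalid-component log-densities, i.e. it is assigned to whichever
    component fits it better at that theta.
    """
    ll_valid = stats.norm.logpdf(ratio[None, :], loc=theta[:, None], scale=ratio_se[None, :])
    sd_inv = np.sqrt(ratio_se**2 + psi**2)
    ll_invalid = stats.norm.logpdf(ratio, loc=0.0, scale=sd_inv)
    return np.sum(np.maximum(ll_valid, ll_invalid[None, :]), axis=1)


def contamination_mixture(
    panel: HarmonizedPanel,
    psi: float | None = None,
    grid: np.ndarray | None = None,
    grid_points: int = 500,
) -> MREstimate:
    """Contamination-mixture estimate by profile likelihood over a grid.

    Valid instruments' ratio estimates are modelled as N(theta, se_j^2) and
    invalid ones as N(0, se_j^2 + psi^2); each variant is assigned to the
    better-fitting component at each candidate theta. Defaults: psi is 1.5
    times the SD of the ratio estimates; the grid spans the ratio-estimate
    range plus/minus 3 pooled SEs with ``grid_points`` points. The p-value is
    from the likelihood-ratio test against theta = 0.
    """
    re = ratio_estimates(panel)
    j = len(re.ratio)
    if j < 3:
        raise EstimatorError(f"contamination_mixture requires at least 3 variants, got {j}")
    if psi is None:
        psi = 1.5 * float(np.std(re.ratio, ddof=1))
        if psi <= 0:
            psi = float(np.mean(re.ratio_se))  # degenerate all-equal ratios
        logger.info("contamination_mixture: defaulting psi to %.6g", psi)
    if grid is None:
        pooled = float(np.sqrt(np.mean(re.ratio_se**2)))
        lo = float(np.min(re.ratio)) - 3.0 * pooled
        hi = float(np.max(re.ratio)) + 3.0 * pooled
        grid = np.linspace(lo, hi, grid_points)
    grid = np.asarray(grid, dtype=float)

    ll = _conmix_profile(re.ratio, re.ratio_se, grid, psi)
    k = int(np.argmax(ll))
    if k in (0, len(grid) - 1):
        raise EstimatorError(
            "contamination_mixture: maximum on grid boundary; widen the grid"
        )
    in_ci = ll >= ll[k] - CHI2_95_HALF
    if not in_ci.any():  # unreachable (MLE always qualifies); defensive
        raise EstimatorError("contamination_mixture: empty confidence set")
    if in_ci[0] or in_ci[-1]:
        logger.warning(
            "contamination_mixture: confidence set reaches the grid edge; "
            "the reported CI is truncated to the grid range"
        )
    beta = float(grid[k])
    ci_low = float(grid[in_ci].min())
    ci_high = float(grid[in_ci].max())

    ll_valid_at_mle = stats.norm.logpdf(re.ratio, loc=beta, scale=re.ratio_se)
    ll_invalid = stats.norm.logpdf(re.ratio, loc=0.0, scale=np.sqrt(re.ratio_se**2 + psi**2))
    n_valid = int(np.sum(ll_valid_at_mle > ll_invalid))

    ll_null = float(_conmix_profile(re.ratio, re.ratio_se, np.array([0.0]), psi)[0])
    lr = max(0.0, 2.0 * (float(ll[k]) - ll_null))
    pvalue = float(stats.chi2.sf(lr, df=1))
    return MREstimate(
        method="contamination_mixture",
        beta=beta,
        se=None,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=pvalue,
        n_variants=j,
        n_valid=n_valid,
        exposure=panel.traits[0],
        outcome=panel.traits[-1],
    )


def all_estimators(
    panel: HarmonizedPanel,
    n_boot: int = 1000,
    seed: int = 0,
    psi: float | None = None,
) -> list[MREstimate]:
    """Run IVW (main), contamination mixture, weighted median and MR-Egger."""
    return [
        ivw(panel),
        contamination_mixture(panel, psi=psi),
        weighted_median(panel, n_boot=n_boot, seed=seed),
        mr_egger(panel),
    ]
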