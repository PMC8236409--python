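"""Synthetic GWAS summary statistics with known mediation structure.

The generator emulates a two-sample summary-data setting under a linear
structural model: variant j has effect alpha_j on the exposure X, each
mediator follows M_m = delta_m * X + sum_j kappa_mj G_j + noise (its own
genetic effects kappa on top of the exposure-driven path — without them
every variant-mediator association would be proportional to the
variant-exposure association and the multivariable design matrix would be
collinear), and the outcome follows Y = tau_direct * X + sum_m tau_m * M_m
(+ a direct pleiotropic variant effect for a configurable fraction of
variants). Variants are partitioned into exposure-specific and
mediator-specific sets, mirroring how a mediator's GWAS hits are mostly not
exposure hits; pooled instrument selection therefore picks up variants
significant only for a mediator, as the multivariable analysis requires.
True direct effects are propagated through a block-diagonal LD matrix to
marginal associations, and each trait's observed summary betas are drawn
independently — the idealized two-sample, non-overlapping design — as

    beta_hat ~ N(beta_true, se^2),    se = 1 / sqrt(2 n f (1 - f))

for a unit-variance trait with effect-allele frequency f and GWAS sample
size n. Binary traits are simulated directly on the log-odds scale (the
estimators consume betas and SEs only).

Two pleiotropy modes are supported: ``additive`` adds a null-centred direct
effect on top of the causal path (balanced pleiotropy, inflating
heterogeneity but not biasing IVW), while ``null`` replaces the causal path
for the flagged variants so their ratio estimates centre on zero — the
contamination-mixture model's invalid-instrument scenario.

The default configuration represents a well-powered consortium setting:
200 independent variants, 200,000 participants per GWAS, two quantitative
mediators carrying half the total effect, and 20% of variants with balanced
pleiotropy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .summary_data import (
    HarmonizedPanel,
    SummaryDataset,
    VariantAssociation,
    write_summary_table,
)

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic mediation GWAS.

    Path coefficients are on the SD scale (log-odds for the outcome):
    ``delta[m]`` is the exposure->mediator_m path, ``tau_mediator[m]`` the
    mediator_m->outcome path and ``tau_direct`` the residual direct path, so
    the true total effect is tau_direct + sum_m delta[m] * tau_mediator[m].
    """

    n_variants: int = 200
    n_exposure_gwas: int = 200_000
    n_mediator_gwas: int = 200_000
    n_outcome_gwas: int = 200_000
    n_mediators: int = 2
    alpha_sd: float = 0.025
    kappa_sd: float = 0.025
    mediator_variant_fraction: float = 0.2
    delta: tuple[float, ...] = (0.3, 0.25)
    tau_direct: float = 0.25
    tau_mediator: tuple[float, ...] = (0.5, 0.4)
    pleiotropy_fraction: float = 0.2
    pleiotropy_sd: float = 0.01
    pleiotropy_mode: str = "additive"  # "additive" or "null"
    ld_block_size: int = 1
    within_block_r: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_variants < 1:
            bad.append("n_variants")
        for name in ("n_exposure_gwas", "n_mediator_gwas", "n_outcome_gwas"):
            if getattr(self, name) <= 0:
                bad.append(name)
        if self.n_mediators < 0:
            bad.append("n_mediators")
        if len(self.delta) != self.n_mediators or len(self.tau_mediator) != self.n_mediators:
            bad.append("delta/tau_mediator length vs n_mediators")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            bad.append("pleiotropy_fraction")
        if not (0.0 <= self.n_mediators * self.mediator_variant_fraction < 1.0):
            bad.append("mediator_variant_fraction")
        if self.kappa_sd < 0:
            bad.append("kappa_sd")
        if self.pleiotropy_mode not in ("additive", "null"):
            bad.append("pleiotropy_mode")
        if self.ld_block_size < 1:
            bad.append("ld_block_size")
        if not (-1.0 < self.within_block_r < 1.0):
            bad.append("within_block_r")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            bad.append("maf_range")
        if bad:
            raise SimulationError("invalid simulation config field(s): " + ", ".join(bad))

    @property
    def true_total(self) -> float:
        return self.tau_direct + sum(d * t for d, t in zip(self.delta, self.tau_mediator))

    @property
    def true_direct(self) -> float:
        return self.tau_direct


@dataclass
class SyntheticTruth:
    """Generating truth paired with a simulated panel set."""

    true_total: float
    true_direct: float
    true_proportion_mediated: float
    valid: dict[str, bool]
    seed: int
    #: per-trait true marginal betas (variant order of the datasets); lets
    #: tests compare sampling noise against the nominal standard errors
    true_beta: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        implied = 1.0 - self.true_direct / self.true_total
        if abs(implied - self.true_proportion_mediated) > 1e-12:
            raise SimulationError("truth fields violate 1 - direct/total identity")


def _block_ld(n: int, block: int, r: float) -> np.ndarray:
    m = np.eye(n)
    if block > 1 and r != 0.0:
        for start in range(0, n, block):
            stop = min(start + block, n)
            m[start:stop, start:stop] = r
            np.fill_diagonal(m[start:stop, start:stop], 1.0)
    return m


def _dataset(
    name: str,
    trait_type: str,
    variant_ids: Sequence[str],
    beta_true: np.ndarray,
    se: np.ndarray,
    eaf: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> SummaryDataset:
    beta_hat = rng.normal(beta_true, se)
    ds = SummaryDataset(trait_name=name, trait_type=trait_type)
    for i, vid in enumerate(variant_ids):
        z = beta_hat[i] / se[i]
        ds.records[vid] = VariantAssociation(
            variant_id=vid,
            effect_allele="A",
            other_allele="G",
            beta=float(beta_hat[i]),
            se=float(se[i]),
            eaf=float(eaf[i]),
            pvalue=float(max(2.0 * stats.norm.sf(abs(z)), 5e-324)),
            n=n,
        )
    return ds


def simulate_mediation_gwas(
    config: SimulationConfig,
) -> tuple[list[SummaryDataset], LDMatrix, SyntheticTruth]:
    """Simulate one summary-data panel set with known mediation structure.

    Returns ([exposure, mediator_1..m, outcome], LD matrix, truth). All
    randomness flows from ``config.seed``; identical configs give identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_variants
    vids = [f"rs{i + 1:05d}" for i in range(j)]

    maf = rng.uniform(*config.maf_range, size=j)

    # partition variants: exposure-specific first, then one block per mediator
    n_per_med = int(round(config.mediator_variant_fraction * j))
    n_exp = j - config.n_mediators * n_per_med
    alpha = np.zeros(j)
    alpha[:n_exp] = rng.normal(0.0, config.alpha_sd, size=n_exp)
    kappa = np.zeros((config.n_mediators, j))
    for m in range(config.n_mediators):
        lo = n_exp + m * n_per_med
        kappa[m, lo : lo + n_per_med] = rng.normal(0.0, config.kappa_sd, size=n_per_med)

    bx_true = alpha
    bm_true = [config.delta[m] * alpha + kappa[m] for m in range(config.n_mediators)]
    by_causal = config.tau_direct * bx_true + sum(
        t * bm for t, bm in zip(config.tau_mediator, bm_true)
    )

    flagged = rng.random(j) < config.pleiotropy_fraction
    gamma = np.where(flagged, rng.normal(0.0, config.pleiotropy_sd, size=j), 0.0)
    if config.pleiotropy_mode == "additive":
        by_true = by_causal + gamma
    else:  # "null": flagged variants act on the outcome only through gamma
        by_true = np.where(flagged, gamma, by_causal)
    valid = ~flagged

    # marginal (LD-propagated) associations feed the summary statistics
    r = _block_ld(j, config.ld_block_size, config.within_block_r)
    bx_marg = r @ bx_true
    bm_marg = [r @ bm for bm in bm_true]
    by_marg = r @ by_true

    var_g = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_g * config.n_exposure_gwas)
    se_m = 1.0 / np.sqrt(var_g * config.n_mediator_gwas)
    se_y = 1.0 / np.sqrt(var_g * config.n_outcome_gwas)

    datasets = [
        _dataset("exposure", "continuous", vids, bx_marg, se_x, maf, config.n_exposure_gwas, rng)
    ]
    for m in range(config.n_mediators):
        datasets.append(
            _dataset(
                f"mediator_{m + 1}",
                "continuous",
                vids,
                bm_marg[m],
                se_m,
                maf,
                config.n_mediator_gwas,
                rng,
            )
        )
    datasets.append(
        _dataset("outcome", "binary", vids, by_marg, se_y, maf, config.n_outcome_gwas, rng)
    )
    total = config.true_total

    ld = LDMatrix(variant_ids=vids, r=r)
    truth = SyntheticTruth(
        true_total=total,
        true_direct=config.true_direct,
        true_proportion_mediated=1.0 - config.true_direct / total,
        valid={vid: bool(v) for vid, v in zip(vids, valid)},
        seed=config.seed,
        true_beta={
            "exposure": bx_marg,
            **{f"mediator_{m + 1}": bm_marg[m] for m in range(config.n_mediators)},
            "outcome": by_marg,
        },
    )
    return datasets, ld, truth


def write_simulation(
    datasets: Sequence[SummaryDataset],
    ld: LDMatrix,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> None:
    """Write per-trait TSVs, the LD matrix and the truth record to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_summary_table(ds, out / f"{ds.trait_name}.tsv")
    ld.write_tsv(out / "ld_matrix.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "true_total": truth.true_total,
                "true_direct": truth.true_direct,
                "true_proportion_mediated": truth.true_proportion_mediated,
                "seed": truth.seed,
                "valid": truth.valid,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


# ---------------------------------------------------------------------------
# Tiny deterministic fixtures for unit tests and documentation
# ---------------------------------------------------------------------------


def fixture_panels() -> dict[str, object]:
    """Hand-checkable miniature inputs.

    * ``proportional`` — a 5-variant exposure/outcome panel whose outcome
      betas are exactly half the exposure betas (every ratio 0.5, IVW 0.5,
      zero heterogeneity).
    * ``egger-line`` — a 5-variant panel lying exactly on
      beta_Y = 0.1 + 0.5 * beta_X with all exposure betas positive.
    * ``two-block-ld`` — a 6-variant dataset in two tight LD blocks such
      that clumping at r^2 < 0.001 retains exactly one variant per block.
    """
    bx = np.array([0.20, 0.30, 0.40, 0.25, 0.35])
    sx = np.full(5, 0.02)
    sy = np.array([0.05, 0.04, 0.06, 0.05, 0.04])
    vids = [f"rs{i + 1}" for i in range(5)]
    proportional = HarmonizedPanel(
        variant_ids=list(vids),
        traits=["exposure", "outcome"],
        trait_types=["continuous", "binary"],
        beta=np.column_stack([bx, 0.5 * bx]),
        se=np.column_stack([sx, sy]),
        orientation_allele=["A"] * 5,
    )
    egger_line = HarmonizedPanel(
        variant_ids=list(vids),
        traits=["exposure", "outcome"],
        trait_types=["continuous", "binary"],
        beta=np.column_stack([bx, 0.1 + 0.5 * bx]),
        se=np.column_stack([sx, sy]),
        orientation_allele=["A"] * 5,
    )

    ds = SummaryDataset(trait_name="exposure", trait_type="continuous")
    pvals = [1e-12, 1e-10, 1e-9, 1e-11, 1e-9, 1e-8 / 2]
    betas = [0.050, 0.045, 0.040, 0.048, 0.042, 0.038]
    for i in range(6):
        vid = f"rs{i + 1}"
        ds.records[vid] = VariantAssociation(
            variant_id=vid,
            effect_allele="A",
            other_allele="G",
            beta=betas[i],
            se=0.005,
            eaf=0.3,
            pvalue=pvals[i],
            n=100_000,
        )
    r = np.eye(6)
    for block in ((0, 1, 2), (3, 4, 5)):
        for a in block:
            for b in block:
                if a != b:
                    r[a, b] = 0.9
    two_block_ld = (ds, LDMatrix(variant_ids=[f"rs{i + 1}" for i in range(6)], r=r))

    return {
        "proportional": proportional,
        "egger-line": egger_line,
        "two-block-ld": two_block_ld,
    }
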