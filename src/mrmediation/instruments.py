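"""Instrument selection: genome-wide significance filtering, greedy LD
clumping (single-trait and pooled multi-trait), and variance explained.

Clumping repeatedly retains the remaining variant with the smallest
association p-value and discards every remaining variant correlated with it
at r^2 at or above the threshold, so the retained set is mutually
quasi-independent. Defaults mirror standard practice: p < 5e-8,
pairwise r^2 < 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_data import SummaryDataError, SummaryDataset

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_R2 = 0.001


class InstrumentError(ValueError):
    """Fatal condition during instrument selection."""


@dataclass
class LDMatrix:
    """Square matrix of pairwise LD correlations r, keyed by variant id."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        j = len(self.variant_ids)
        if self.r.shape != (j, j):
            raise InstrumentError("LD matrix shape does not match variant ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InstrumentError("LD matrix is not symmetric (tolerance 1e-8)")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise InstrumentError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise InstrumentError("LD correlations outside [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a square numeric TSV whose first row and column are ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(v) for v in df.index]
        if list(df.columns) != ids:
            raise InstrumentError(f"{path}: row and column variant ids differ")
        return cls(variant_ids=ids, r=df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids)
        df.to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Clumped instruments with the p-value that drove each one's selection."""

    variant_ids: list[str]
    selection_pvalues: list[float]
    source_trait: str

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __iter__(self):
        return iter(self.variant_ids)


def _selection_pvalue(ds: SummaryDataset, vid: str) -> float:
    rec = ds.records[vid]
    return rec.pvalue if rec.pvalue is not None else rec.z_pvalue()


def _greedy_clump(
    candidates: dict[str, float], ld: LDMatrix, r2_threshold: float
) -> tuple[list[str], list[float]]:
    # ascending p, ties broken by lexicographic variant id for determinism
    remaining = sorted(candidates, key=lambda v: (candidates[v], v))
    kept: list[str] = []
    for vid in remaining:
        if all(ld.r2(vid, k) < r2_threshold for k in kept):
            kept.append(vid)
    return kept, [candidates[v] for v in kept]


def select_instruments(
    dataset: SummaryDataset,
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_R2,
) -> InstrumentSet:
    """Select clumped instruments for one trait.

    Variants associated at ``p < p_threshold`` are greedily clumped to
    pairwise ``r^2 < r2_threshold``, preferring the smallest p-value.
    Significant variants absent from the LD matrix cannot be clumped and are
    dropped with a warning rather than assumed independent.
    """
    sig = {
        vid: _selection_pvalue(dataset, vid)
        for vid in dataset.records
        if _selection_pvalue(dataset, vid) < p_threshold
    }
    if not sig:
        raise InstrumentError(
            f"no variant reaches p < {p_threshold:g} for trait {dataset.trait_name!r}"
        )
    absent = [v for v in sig if v not in ld]
    if absent:
        logger.warning(
            "trait %s: dropping %d significant variant(s) absent from the LD matrix",
            dataset.trait_name,
            len(absent),
        )
        for v in absent:
            del sig[v]
    if not sig:
        raise InstrumentError(
            f"all significant variants for {dataset.trait_name!r} are absent from the LD matrix"
        )
    kept, pvals = _greedy_clump(sig, ld, r2_threshold)
    return InstrumentSet(variant_ids=kept, selection_pvalues=pvals, source_trait=dataset.trait_name)


def pooled_select_instruments(
    datasets: Sequence[SummaryDataset],
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_R2,
) -> InstrumentSet:
    """Pool genome-wide significant variants across traits and clump once.

    A variant enters the pool if it is significant for any trait; its
    selection p-value is the minimum across the traits for which it passes
    the threshold, and clumping prefers that pooled p. Used to build the
    instrument set for multivariable models.
    """
    if not datasets:
        raise InstrumentError("pooled selection requires at least one dataset")
    pooled: dict[str, float] = {}
    for ds in datasets:
        for vid in ds.records:
            p = _selection_pvalue(ds, vid)
            if p < p_threshold and p < pooled.get(vid, np.inf):
                pooled[vid] = p
    if not pooled:
        traits = ", ".join(d.trait_name for d in datasets)
        raise InstrumentError(f"no variant reaches p < {p_threshold:g} for any of: {traits}")
    absent = [v for v in pooled if v not in ld]
    if absent:
        logger.warning(
            "pooled selection: dropping %d significant variant(s) absent from the LD matrix",
            len(absent),
        )
        for v in absent:
            del pooled[v]
    if not pooled:
        raise InstrumentError("all pooled significant variants are absent from the LD matrix")
    kept, pvals = _greedy_clump(pooled, ld, r2_threshold)
    return InstrumentSet(variant_ids=kept, selection_pvalues=pvals, source_trait="pooled")


def variance_explained(
    dataset: SummaryDataset,
    instruments: InstrumentSet,
    method: str = "eaf",
) -> float:
    """Fraction of trait variance explained by the instruments.

    ``method='eaf'`` (default) uses the standardized-trait approximation
    sum_j 2 f_j (1 - f_j) beta_j^2, requiring the effect-allele frequency for
    every instrument and a continuous trait in SD units. ``method='z2'``
    instead sums z_j^2 / (z_j^2 + n_j - 2), requiring per-variant sample
    sizes. Multiply by 100 for a percentage.
    """
    if method not in ("eaf", "z2"):
        raise InstrumentError(f"unknown variance_explained method {method!r}")
    total = 0.0
    missing: list[str] = []
    for vid in instruments:
        rec = dataset.records.get(vid)
        if rec is None:
            missing.append(vid)
            continue
        if method == "eaf":
            if rec.eaf is None:
                missing.append(vid)
                continue
            total += 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
        else:
            if rec.n is None:
                missing.append(vid)
                continue
            z2 = (rec.beta / rec.se) ** 2
            total += z2 / (z2 + rec.n - 2)
    if missing:
        raise InstrumentError(
            "variance_explained: missing "
            + ("eaf" if method == "eaf" else "n")
            + " or record for variant(s): "
            + ", ".join(missing)
        )
    return total
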