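"""GWAS summary-statistic containers, file I/O, allele harmonization and
fixed-effects meta-analysis.

The central objects are :class:`SummaryDataset` (one trait's per-variant
association estimates) and :class:`HarmonizedPanel` (an allele-aligned,
complete-case J-variant x T-trait matrix of betas and standard errors, the
input to every MR regression downstream).

Harmonization follows the face-value allele-matching convention: variants are
aligned by their effect alleles, a swapped effect/other pair negates the beta
and reflects the effect-allele frequency, palindromic (A/T, G/C) variants are
treated like any other, and strand flipping is never attempted.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
#: Columns that must be present in an input table; the rest may be absent.
MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")

TRAIT_TYPES = ("continuous", "binary")

#: Palindromic allele pairs; retained at face value, never frequency-checked.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryDataError(ValueError):
    """Fatal condition in summary-data handling (bad file, empty overlap...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-effect-allele estimate, in SD units for continuous
    traits and log-odds for binary traits; ``se`` its standard error.
    ``eaf`` (effect-allele frequency), ``pvalue`` and ``n`` may be missing
    (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None

    def problems(self) -> list[str]:
        """Invariant violations that make the record unusable."""
        out: list[str] = []
        if not self.variant_id:
            out.append("empty variant_id")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (np.isfinite(self.beta)):
            out.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append("se not a positive finite number")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append("eaf outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            out.append("pvalue outside (0, 1]")
        if self.n is not None and self.n <= 0:
            out.append("non-positive sample size")
        return out

    def pvalue_consistent(self) -> bool:
        """True when the stored p-value is within one order of magnitude of
        the two-sided normal p implied by beta/se (or when either is absent).

        Rounded consortium files routinely disagree slightly, so callers
        treat an inconsistency as a warning, never an error.
        """
        if self.pvalue is None or self.se <= 0:
            return True
        z = abs(self.beta / self.se)
        expected = 2.0 * stats.norm.sf(z)
        if expected <= 0.0:  # underflow; nothing meaningful to compare
            return True
        ratio = self.pvalue / expected
        return 0.1 <= ratio <= 10.0

    def z_pvalue(self) -> float:
        """Two-sided normal p from beta/se; fallback when pvalue is missing."""
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))


@dataclass
class SummaryDataset:
    """All summary associations of one trait, keyed by variant id."""

    trait_name: str
    trait_type: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise SummaryDataError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.records[variant_id]

    def variant_ids(self) -> list[str]:
        return list(self.records)

    def add(self, rec: VariantAssociation) -> None:
        if rec.variant_id in self.records:
            raise SummaryDataError(f"duplicate variant id {rec.variant_id!r}")
        self.records[rec.variant_id] = rec


@dataclass
class HarmonizedPanel:
    """Allele-aligned J x T matrices of betas and SEs, complete cases only.

    Column order follows the order datasets were aligned in; by convention
    the exposure is first and the outcome last. ``orientation_allele`` is the
    effect allele of the reference dataset for each variant, defining the
    shared orientation of every beta in its row.
    """

    variant_ids: list[str]
    traits: list[str]
    trait_types: list[str]
    beta: np.ndarray
    se: np.ndarray
    orientation_allele: list[str]

    def __post_init__(self) -> None:
        j, t = self.beta.shape
        if j < 1:
            raise SummaryDataError("harmonized panel has no variants")
        if self.se.shape != (j, t) or len(self.variant_ids) != j or len(self.traits) != t:
            raise SummaryDataError("inconsistent panel dimensions")
        if not np.all(self.se > 0):
            raise SummaryDataError("panel contains non-positive standard errors")

    @property
    def n_variants(self) -> int:
        return self.beta.shape[0]

    @property
    def n_traits(self) -> int:
        return self.beta.shape[1]

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise SummaryDataError(f"trait {trait!r} not in panel {self.traits}") from None

    def subset(self, variant_ids: Sequence[str]) -> "HarmonizedPanel":
        """Row-subset the panel to ``variant_ids`` (panel order preserved)."""
        wanted = set(variant_ids)
        idx = [i for i, v in enumerate(self.variant_ids) if v in wanted]
        if not idx:
            raise SummaryDataError("subset leaves no variants in panel")
        return HarmonizedPanel(
            variant_ids=[self.variant_ids[i] for i in idx],
            traits=list(self.traits),
            trait_types=list(self.trait_types),
            beta=self.beta[idx, :].copy(),
            se=self.se[idx, :].copy(),
            orientation_allele=[self.orientation_allele[i] for i in idx],
        )

    def select_traits(self, traits: Sequence[str]) -> "HarmonizedPanel":
        """Column-subset the panel, reordering to ``traits``."""
        idx = [self.trait_index(t) for t in traits]
        return HarmonizedPanel(
            variant_ids=list(self.variant_ids),
            traits=[self.traits[i] for i in idx],
            trait_types=[self.trait_types[i] for i in idx],
            beta=self.beta[:, idx].copy(),
            se=self.se[:, idx].copy(),
            orientation_allele=list(self.orientation_allele),
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _coerce_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _coerce_optional_int(value) -> int | None:
    v = _coerce_optional_float(value)
    return None if v is None else int(round(v))


def read_summary_table(
    path: str | Path,
    trait_name: str,
    trait_type: str,
    aliases: Mapping[str, str] | None = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistic table into a SummaryDataset.

    The header must contain the mandatory columns (variant_id, effect_allele,
    other_allele, beta, se); eaf, pvalue and n are optional. ``aliases`` maps
    canonical column names to the names actually used in the file. Rows
    violating record invariants are dropped with a logged count; duplicated
    variant ids keep the first occurrence. Gzip-compressed files are read
    transparently.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryDataError(f"summary table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", compression="infer")
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise SummaryDataError(f"cannot read summary table {path}: {exc}") from exc

    if aliases:
        rename = {actual: canonical for canonical, actual in aliases.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryDataError(f"{path}: missing mandatory column(s) {missing}")

    ds = SummaryDataset(trait_name=trait_name, trait_type=trait_type)
    n_dropped = 0
    n_duplicate = 0
    n_inconsistent_p = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            rec = VariantAssociation(
                variant_id=str(d["variant_id"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                eaf=_coerce_optional_float(d.get("eaf")),
                pvalue=_coerce_optional_float(d.get("pvalue")),
                n=_coerce_optional_int(d.get("n")),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if rec.problems():
            n_dropped += 1
            continue
        if rec.variant_id in ds.records:
            n_duplicate += 1
            continue
        if not rec.pvalue_consistent():
            n_inconsistent_p += 1
        ds.records[rec.variant_id] = rec

    if n_dropped:
        logger.warning("%s: dropped %d row(s) failing record invariants", path, n_dropped)
    if n_duplicate:
        logger.warning("%s: kept first of %d duplicated variant id(s)", path, n_duplicate)
    if n_inconsistent_p:
        logger.warning(
            "%s: %d record(s) with p-value inconsistent with beta/se "
            "(> 1 order of magnitude; kept)",
            path,
            n_inconsistent_p,
        )
    return ds


def _format_float(x: float | None) -> str:
    return "NA" if x is None else repr(float(x))


def write_summary_table(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset in the canonical TSV dialect (bit-identical round-trip).

    Floats are serialized with ``repr`` so that read-after-write restores the
    exact binary values; missing fields become ``NA``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for rec in dataset.records.values():
            fh.write(
                "\t".join(
                    [
                        rec.variant_id,
                        rec.effect_allele,
                        rec.other_allele,
                        _format_float(rec.eaf),
                        _format_float(rec.beta),
                        _format_float(rec.se),
                        _format_float(rec.pvalue),
                        "NA" if rec.n is None else str(int(rec.n)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Harmonization and alignment
# ---------------------------------------------------------------------------


def harmonize(reference: SummaryDataset, other: SummaryDataset) -> SummaryDataset:
    """Align ``other`` to the allele orientation of ``reference``.

    For each variant shared by id: a matching (effect, other) allele pair is
    kept unchanged; a swapped pair negates beta and replaces eaf by 1 - eaf;
    any other pair is dropped with a logged count. Palindromic variants are
    handled identically (no exclusion, no frequency check) and strands are
    never flipped. Output is restricted to the shared, matchable variants, in
    reference order.
    """
    if not reference.records or not other.records:
        raise SummaryDataError("harmonize requires two non-empty datasets")
    out = SummaryDataset(trait_name=other.trait_name, trait_type=other.trait_type)
    n_swapped = 0
    n_unmatched = 0
    n_shared = 0
    for vid, ref in reference.records.items():
        rec = other.records.get(vid)
        if rec is None:
            continue
        n_shared += 1
        if (rec.effect_allele, rec.other_allele) == (ref.effect_allele, ref.other_allele):
            out.records[vid] = rec
        elif (rec.other_allele, rec.effect_allele) == (ref.effect_allele, ref.other_allele):
            n_swapped += 1
            out.records[vid] = replace(
                rec,
                effect_allele=ref.effect_allele,
                other_allele=ref.other_allele,
                beta=-rec.beta,
                eaf=None if rec.eaf is None else 1.0 - rec.eaf,
            )
        else:
            n_unmatched += 1
    if n_shared == 0:
        raise SummaryDataError(
            f"no shared variants between {reference.trait_name!r} and {other.trait_name!r}"
        )
    if n_unmatched:
        logger.warning(
            "harmonize %s -> %s: dropped %d variant(s) with unmatchable allele pairs",
            other.trait_name,
            reference.trait_name,
            n_unmatched,
        )
    if n_swapped:
        logger.info(
            "harmonize %s -> %s: swapped orientation of %d variant(s)",
            other.trait_name,
            reference.trait_name,
            n_swapped,
        )
    if not out.records:
        raise SummaryDataError(
            f"harmonization of {other.trait_name!r} against "
            f"{reference.trait_name!r} left no variants"
        )
    return out


def align_panels(datasets: Sequence[SummaryDataset]) -> HarmonizedPanel:
    """Harmonize datasets to the first one and build the complete-case panel.

    The first dataset defines the reference allele orientation. The panel is
    restricted to variants present (and allele-matchable) in every dataset;
    no proxy substitution is performed. Column order follows input order.
    """
    if len(datasets) < 2:
        raise SummaryDataError("align_panels requires at least two datasets")
    reference = datasets[0]
    aligned = [reference] + [harmonize(reference, d) for d in datasets[1:]]
    shared = [vid for vid in reference.records if all(vid in d for d in aligned[1:])]
    if not shared:
        raise SummaryDataError(
            "no variants with association estimates available for all traits: "
            + ", ".join(d.trait_name for d in datasets)
        )
    beta = np.array([[d.records[v].beta for d in aligned] for v in shared], dtype=float)
    se = np.array([[d.records[v].se for d in aligned] for v in shared], dtype=float)
    return HarmonizedPanel(
        variant_ids=shared,
        traits=[d.trait_name for d in datasets],
        trait_types=[d.trait_type for d in datasets],
        beta=beta,
        se=se,
        orientation_allele=[reference.records[v].effect_allele for v in shared],
    )


# ---------------------------------------------------------------------------
# Fixed-effects meta-analysis of strata
# ---------------------------------------------------------------------------


def meta_analyze_strata(a: SummaryDataset, b: SummaryDataset) -> SummaryDataset:
    """Fixed-effects inverse-variance pooling of two strata of one GWAS.

    Used e.g. to combine sex-stratified summary results into one dataset.
    ``b`` is first harmonized to ``a``'s orientation. Per shared variant:

        beta = (b_a/se_a^2 + b_b/se_b^2) / (1/se_a^2 + 1/se_b^2)
        se   = (1/se_a^2 + 1/se_b^2)^(-1/2)

    with the p-value recomputed from the pooled z and sample sizes summed.
    """
    b_aligned = harmonize(a, b)
    out = SummaryDataset(trait_name=a.trait_name, trait_type=a.trait_type)
    for vid, rec_b in b_aligned.records.items():
        rec_a = a.records[vid]
        wa, wb = 1.0 / rec_a.se**2, 1.0 / rec_b.se**2
        beta = (rec_a.beta * wa + rec_b.beta * wb) / (wa + wb)
        se = (wa + wb) ** -0.5
        if rec_a.eaf is not None and rec_b.eaf is not None:
            eaf = (rec_a.eaf * wa + rec_b.eaf * wb) / (wa + wb)
        else:
            eaf = rec_a.eaf if rec_a.eaf is not None else rec_b.eaf
        n = None
        if rec_a.n is not None and rec_b.n is not None:
            n = rec_a.n + rec_b.n
        out.records[vid] = VariantAssociation(
            variant_id=vid,
            effect_allele=rec_a.effect_allele,
            other_allele=rec_a.other_allele,
            beta=beta,
            se=se,
            eaf=eaf,
            pvalue=float(2.0 * stats.norm.sf(abs(beta / se))),
            n=n,
        )
    if not out.records:  # unreachable given harmonize's own check; defensive
        raise SummaryDataError("meta-analysis found no shared variants")
    return out
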