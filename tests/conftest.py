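import numpy as np
import pytest

from mrmediation import (
    HarmonizedPanel,
    LDMatrix,
    SummaryDataset,
    VariantAssociation,
)


def make_record(
    vid,
    beta,
    se=0.01,
    effect="A",
    other="G",
    eaf=0.3,
    pvalue=None,
    n=100_000,
):
    return VariantAssociation(
        variant_id=vid,
        effect_allele=effect,
        other_allele=other,
        beta=beta,
        se=se,
        eaf=eaf,
        pvalue=pvalue,
        n=n,
    )


def make_dataset(name, records, trait_type="continuous"):
    ds = SummaryDataset(trait_name=name, trait_type=trait_type)
    for rec in records:
        ds.records[rec.variant_id] = rec
    return ds


def make_panel(bx, by, sx, sy, extra_cols=(), extra_ses=(), traits=None):
    """Exposure/[mediators]/outcome panel from plain arrays."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    sx, sy = np.asarray(sx, float), np.asarray(sy, float)
    cols = [bx] + [np.asarray(c, float) for c in extra_cols] + [by]
    ses = [sx] + [np.asarray(s, float) for s in extra_ses] + [sy]
    j = len(bx)
    if traits is None:
        n_med = len(extra_cols)
        traits = ["exposure"] + [f"mediator_{i+1}" for i in range(n_med)] + ["outcome"]
    return HarmonizedPanel(
        variant_ids=[f"rs{i+1}" for i in range(j)],
        traits=list(traits),
        trait_types=["continuous"] * (len(traits) - 1) + ["binary"],
        beta=np.column_stack(cols),
        se=np.column_stack(ses),
        orientation_allele=["A"] * j,
    )


def random_panel(rng, j=20, n_extra=0, causal=0.5, het=0.0):
    """Random exposure/outcome panel with optional mediator columns and
    per-variant heterogeneity of SD ``het`` added to the outcome betas."""
    bx = rng.normal(0.05, 0.02, j)
    bx[np.abs(bx) < 5e-3] = 5e-3  # keep ratios finite
    sx = rng.uniform(0.002, 0.006, j)
    sy = rng.uniform(0.005, 0.02, j)
    extras = [rng.normal(0.03, 0.015, j) for _ in range(n_extra)]
    extra_ses = [rng.uniform(0.002, 0.006, j) for _ in range(n_extra)]
    by = causal * bx + sum(0.2 * e for e in extras) + rng.normal(0, het, j) + rng.normal(0, sy)
    return make_panel(bx, by, sx, sy, extra_cols=extras, extra_ses=extra_ses)


def diagonal_ld(vids):
    return LDMatrix(variant_ids=list(vids), r=np.eye(len(vids)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
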