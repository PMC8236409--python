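"""Config-driven orchestration of the full MR mediation analysis.

One run reproduces the analysis graph: read and harmonize summary tables,
select instruments (single-trait clumping for the total effect, pooled
multi-trait clumping for each multivariable model), estimate the total
effect with four estimators, fit multivariable models for every mediator
set (each singleton or declared group, all mediators jointly, and the joint
model excluding binary mediators as a sensitivity analysis), optionally a
two-exposure mutual-adjustment model, and finally the mediation table.

Every source of randomness derives from the configured seed, and report
rendering uses fixed formats, so repeated runs with the same config are
byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import instruments as instr
from . import mediation as med
from . import mr_estimators as mre
from . import mvmr as mv
from . import summary_data as sd

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Fatal pipeline condition, labelled with the failing stage."""


@dataclass
class TraitFile:
    name: str
    path: str
    trait_type: str = "continuous"
    group: str | None = None


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    exposure: TraitFile
    outcome: TraitFile
    ld_matrix: str
    mediators: list[TraitFile] = field(default_factory=list)
    second_exposure: TraitFile | None = None
    p_threshold: float = instr.GENOME_WIDE_P
    r2_threshold: float = instr.DEFAULT_R2
    n_boot: int = 1000
    psi: float | None = None
    seed: int = 0
    shared_instruments: bool = False
    exclude_binary_joint: bool = True
    out_dir: str | None = None
    column_aliases: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                exposure=TraitFile(**raw["exposure"]),
                outcome=TraitFile(**raw["outcome"]),
                ld_matrix=raw["ld_matrix"],
                mediators=[TraitFile(**m) for m in raw.get("mediators", [])],
                second_exposure=(
                    TraitFile(**raw["second_exposure"]) if raw.get("second_exposure") else None
                ),
                p_threshold=float(raw.get("p_threshold", instr.GENOME_WIDE_P)),
                r2_threshold=float(raw.get("r2_threshold", instr.DEFAULT_R2)),
                n_boot=int(raw.get("n_boot", 1000)),
                psi=(None if raw.get("psi") is None else float(raw["psi"])),
                seed=int(raw.get("seed", 0)),
                shared_instruments=bool(raw.get("shared_instruments", False)),
                exclude_binary_joint=bool(raw.get("exclude_binary_joint", True)),
                out_dir=raw.get("out_dir"),
                column_aliases=dict(raw.get("column_aliases", {})),
            )
        except (KeyError, TypeError) as exc:
            raise PipelineError(f"invalid run config {path}: {exc}") from exc

    def mediator_sets(self) -> list[tuple[str, list[str]]]:
        """(label, mediator names) per fitted model: singletons/groups first,
        then the joint model, then joint-without-binary when applicable."""
        sets: list[tuple[str, list[str]]] = []
        seen_groups: dict[str, list[str]] = {}
        for m in self.mediators:
            if m.group:
                seen_groups.setdefault(m.group, []).append(m.name)
            else:
                sets.append((m.name, [m.name]))
        # declared groups keep first-appearance order after singletons
        for g, names in seen_groups.items():
            sets.append((g, names))
        if len(self.mediators) > 1 and len(sets) > 1:
            sets.append(("joint", [m.name for m in self.mediators]))
            if self.exclude_binary_joint:
                non_binary = [m.name for m in self.mediators if m.trait_type != "binary"]
                if 0 < len(non_binary) < len(self.mediators):
                    sets.append(("joint_excluding_binary", non_binary))
        return sets


@dataclass
class RunReport:
    """All fitted results of one run plus filtering diagnostics."""

    exposure: str
    outcome: str
    seed: int
    variance_explained: float | None
    total_effects: list[mre.MREstimate]
    mvmr_blocks: list[tuple[str, mv.MVMRResult]]
    mediation_rows: list[tuple[str, med.MediationResult]]
    mutual: mv.MVMRResult | None
    instrument_counts: dict[str, int]
    outcome_binary: bool

    def render(self) -> str:
        """Plain-text report mirroring a forest-table layout; deterministic."""
        L: list[str] = []
        fmt = lambda x: f"{x:.6g}"

        def or_cols(beta: float, lo: float, hi: float) -> str:
            if not self.outcome_binary:
                return ""
            return (
                f"\tOR={fmt(math.exp(beta))} "
                f"({fmt(math.exp(lo))}, {fmt(math.exp(hi))})"
            )

        L.append(f"# MR mediation report: {self.exposure} -> {self.outcome}")
        L.append(f"seed: {self.seed}")
        if self.variance_explained is not None:
            L.append(
                f"variance explained by {self.exposure} instruments: "
                f"{fmt(100 * self.variance_explained)}%"
            )
        L.append("")
        L.append("## Total effects")
        L.append("method\tbeta\tse\tci_low\tci_high\tpvalue\tn_variants")
        for e in self.total_effects:
            se_txt = "NA" if e.se is None else fmt(e.se)
            L.append(
                f"{e.method}\t{fmt(e.beta)}\t{se_txt}\t{fmt(e.ci_low)}\t{fmt(e.ci_high)}"
                f"\t{fmt(e.pvalue)}\t{e.n_variants}" + or_cols(e.beta, e.ci_low, e.ci_high)
            )
            if e.method == "egger":
                L.append(
                    f"  egger_intercept\t{fmt(e.egger_intercept)}"
                    f"\tp={fmt(e.egger_intercept_p)}"
                )
        L.append("")
        L.append("## Direct effects (multivariable MR)")
        for label, res in self.mvmr_blocks:
            L.append(f"[adjusted for: {label}] J={res.n_variants} re_scale={fmt(res.re_scale)}")
            L.append("predictor\tbeta\tse\tci_low\tci_high\tpvalue")
            for i, p in enumerate(res.predictors):
                L.append(
                    f"{p}\t{fmt(res.beta[i])}\t{fmt(res.se[i])}\t{fmt(res.ci_low[i])}"
                    f"\t{fmt(res.ci_high[i])}\t{fmt(res.pvalue[i])}"
                    + or_cols(res.beta[i], res.ci_low[i], res.ci_high[i])
                )
        if self.mutual is not None:
            res = self.mutual
            L.append(f"[mutual adjustment] J={res.n_variants} re_scale={fmt(res.re_scale)}")
            L.append("predictor\tbeta\tse\tci_low\tci_high\tpvalue")
            for i, p in enumerate(res.predictors):
                L.append(
                    f"{p}\t{fmt(res.beta[i])}\t{fmt(res.se[i])}\t{fmt(res.ci_low[i])}"
                    f"\t{fmt(res.ci_high[i])}\t{fmt(res.pvalue[i])}"
                    + or_cols(res.beta[i], res.ci_low[i], res.ci_high[i])
                )
        L.append("")
        L.append("## Proportion mediated (percent; unbounded)")
        L.append("mediator_set\tpercent\tci_low\tci_high")
        for label, row in self.mediation_rows:
            pc, lo, hi = row.as_percent()
            L.append(f"{label}\t{pc}\t{lo}\t{hi}")
        L.append("")
        L.append("## Instrument counts")
        for k in sorted(self.instrument_counts):
            L.append(f"{k}: {self.instrument_counts[k]}")
        return "\n".join(L) + "\n"


def _stage(name: str):
    """Re-raise stage failures with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis graph described by ``config``."""
    counts: dict[str, int] = {}

    with _stage("read"):
        exposure = sd.read_summary_table(
            config.exposure.path,
            config.exposure.name,
            config.exposure.trait_type,
            aliases=config.column_aliases or None,
        )
        outcome = sd.read_summary_table(
            config.outcome.path,
            config.outcome.name,
            config.outcome.trait_type,
            aliases=config.column_aliases or None,
        )
        mediators = {
            m.name: sd.read_summary_table(
                m.path, m.name, m.trait_type, aliases=config.column_aliases or None
            )
            for m in config.mediators
        }
        second = None
        if config.second_exposure is not None:
            second = sd.read_summary_table(
                config.second_exposure.path,
                config.second_exposure.name,
                config.second_exposure.trait_type,
                aliases=config.column_aliases or None,
            )
        ld = instr.LDMatrix.read_tsv(config.ld_matrix)

    with _stage("total_effects"):
        exp_instruments = instr.select_instruments(
            exposure, ld, config.p_threshold, config.r2_threshold
        )
        counts[f"instruments[{exposure.trait_name}]"] = len(exp_instruments)
        panel_total = sd.align_panels([exposure, outcome])
        usable = [v for v in exp_instruments if v in set(panel_total.variant_ids)]
        counts["instruments_lost_to_alignment[total]"] = len(exp_instruments) - len(usable)
        panel_total = panel_total.subset(usable)
        total_effects = mre.all_estimators(
            panel_total, n_boot=config.n_boot, seed=config.seed, psi=config.psi
        )
        try:
            ve = instr.variance_explained(exposure, exp_instruments)
        except instr.InstrumentError:
            ve = None  # eaf not available; report omits the figure

    mvmr_blocks: list[tuple[str, mv.MVMRResult]] = []
    shared_pool: instr.InstrumentSet | None = None
    if config.shared_instruments and config.mediators:
        with _stage("pooled_instruments"):
            shared_pool = instr.pooled_select_instruments(
                [exposure, *mediators.values()], ld, config.p_threshold, config.r2_threshold
            )
            counts["instruments[shared_pool]"] = len(shared_pool)

    with _stage("multivariable"):
        for label, names in config.mediator_sets():
            model_datasets = [exposure, *(mediators[n] for n in names), outcome]
            if shared_pool is not None:
                pool = shared_pool
            else:
                pool = instr.pooled_select_instruments(
                    [exposure, *(mediators[n] for n in names)],
                    ld,
                    config.p_threshold,
                    config.r2_threshold,
                )
            counts[f"instruments[{label}]"] = len(pool)
            panel = sd.align_panels(model_datasets)
            usable = [v for v in pool if v in set(panel.variant_ids)]
            counts[f"instruments_lost_to_alignment[{label}]"] = len(pool) - len(usable)
            panel = panel.subset(usable)
            mvmr_blocks.append((label, mv.multivariable_ivw(panel)))

    mutual = None
    if second is not None:
        with _stage("mutual_adjustment"):
            pool = instr.pooled_select_instruments(
                [exposure, second], ld, config.p_threshold, config.r2_threshold
            )
            counts["instruments[mutual]"] = len(pool)
            panel = sd.align_panels([exposure, second, outcome])
            usable = [v for v in pool if v in set(panel.variant_ids)]
            panel = panel.subset(usable)
            mutual = mv.mutual_adjustment(panel)

    mediation_rows: list[tuple[str, med.MediationResult]] = []
    if config.mediators:
        with _stage("mediation"):
            ivw_total = total_effects[0]
            results = med.mediation_table(ivw_total, [res for _, res in mvmr_blocks])
            mediation_rows = [(label, r) for (label, _), r in zip(mvmr_blocks, results)]
    else:
        logger.info("no mediators configured; mediation table skipped")

    report = RunReport(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        seed=config.seed,
        variance_explained=ve,
        total_effects=total_effects,
        mvmr_blocks=mvmr_blocks,
        mediation_rows=mediation_rows,
        mutual=mutual,
        instrument_counts=counts,
        outcome_binary=outcome.trait_type == "binary",
    )

    if config.out_dir:
        with _stage("write"):
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.txt").write_text(report.render())
            _write_tidy_tables(report, out)
    return report


def _write_tidy_tables(report: RunReport, out: Path) -> None:
    fmt = lambda x: f"{x:.6g}"
    with open(out / "total_effects.tsv", "w") as fh:
        fh.write("method\tbeta\tse\tci_low\tci_high\tpvalue\tn_variants\n")
        for e in report.total_effects:
            se_txt = "NA" if e.se is None else fmt(e.se)
            fh.write(
                f"{e.method}\t{fmt(e.beta)}\t{se_txt}\t{fmt(e.ci_low)}\t{fmt(e.ci_high)}"
                f"\t{fmt(e.pvalue)}\t{e.n_variants}\n"
            )
    with open(out / "direct_effects.tsv", "w") as fh:
        fh.write("mediator_set\tpredictor\tbeta\tse\tci_low\tci_high\tpvalue\tn_variants\n")
        blocks = list(report.mvmr_blocks)
        if report.mutual is not None:
            blocks.append(("mutual", report.mutual))
        for label, res in blocks:
            for i, p in enumerate(res.predictors):
                fh.write(
                    f"{label}\t{p}\t{fmt(res.beta[i])}\t{fmt(res.se[i])}"
                    f"\t{fmt(res.ci_low[i])}\t{fmt(res.ci_high[i])}"
                    f"\t{fmt(res.pvalue[i])}\t{res.n_variants}\n"
                )
    with open(out / "mediation.tsv", "w") as fh:
        fh.write("mediator_set\tproportion\tse\tci_low\tci_high\tpercent\tpercent_ci\n")
        for label, r in report.mediation_rows:
            pc, lo, hi = r.as_percent()
            fh.write(
                f"{label}\t{fmt(r.proportion)}\t{fmt(r.proportion_se)}"
                f"\t{fmt(r.ci_low)}\t{fmt(r.ci_high)}\t{pc}\t({lo}, {hi})\n"
            )
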