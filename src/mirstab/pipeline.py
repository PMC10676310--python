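"""End-to-end pipeline: exports -> QC -> stability tables -> report.

`run_pipeline` executes the fixed stage order (interplate calibration,
detection-limit cutoff, reaction categorisation + melt review, spike-in
sample exclusion, complete-case assembly per group, group merging,
stability analysis incl. the grouped best-pair search), keeping a
datapoint-conserving workflow ledger and a per-removal audit log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as qio
from . import qc as qqc
from . import stability as qstab
from .io import CpMatrix, Dialect, MeltCurve, ReactionRecord, SampleRecord
from .qc import AuditLog, QcRules, WorkflowStage, WorkflowSummary
from .simulate import Cohort, SimulationConfig, simulate_cohort
from .stability import PairStability

logger = logging.getLogger("mirstab")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to/from YAML."""

    indir: str | None = None        # instrument-export directory (see write_cohort)
    outdir: str | None = None
    rules: QcRules = field(default_factory=QcRules)
    bestkeeper_center: str = "arithmetic"
    override_file: str | None = None  # JSON {"plate:well": verdict}
    simulation: SimulationConfig | None = None  # simulate instead of reading indir
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "indir": self.indir,
            "outdir": self.outdir,
            "seed": self.seed,
            "bestkeeper_center": self.bestkeeper_center,
            "override_file": self.override_file,
            "rules": dataclasses.asdict(self.rules),
        }
        data["rules"]["spike_delta_window"] = list(self.rules.spike_delta_window)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        rules_data = data.pop("rules", {})
        if "spike_delta_window" in rules_data:
            rules_data["spike_delta_window"] = tuple(rules_data["spike_delta_window"])
        return cls(rules=QcRules(**rules_data), **data)


@dataclass
class ResultBundle:
    """All artifacts of one pipeline run."""

    calibrated: CpMatrix
    filtered: CpMatrix                       # after cutoff + reaction QC + sample exclusion
    complete: dict[str, CpMatrix]            # per group
    summaries: dict[str, pd.DataFrame]       # per-group complete/incomplete/excluded tables
    combined: CpMatrix
    stability: dict[str, pd.DataFrame]       # per group + "combined"
    pair_table: pd.DataFrame
    best_pair: PairStability
    workflow: WorkflowSummary
    audit: AuditLog
    samples: list[SampleRecord]
    group_of: pd.Series
    plate_offsets: dict[str, float]
    dropped_assays: list[str]


def load_overrides(path: str | Path) -> dict[tuple[str, str], str]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for key, verdict in raw.items():
        plate, well = key.split(":", 1)
        out[(plate, well)] = verdict
    return out


# ---------------------------------------------------------------------------
# Core (in-memory) pipeline
# ---------------------------------------------------------------------------


def run_pipeline_from_data(
    records: list[ReactionRecord],
    layout: qio.PanelLayout,
    samples: list[SampleRecord],
    panel: Mapping[str, qio.AssayDefinition],
    melt_curves: Mapping[tuple[str, str], MeltCurve],
    rules: QcRules | None = None,
    overrides: Mapping[tuple[str, str], str] | None = None,
    bestkeeper_center: str = "arithmetic",
) -> ResultBundle:
    rules = rules or QcRules()
    audit = AuditLog()
    stages: list[WorkflowStage] = []

    # 1. interplate calibration --------------------------------------------
    layout_assay = {key: assay for key, (_, assay) in layout.wells.items()}
    calibrator = next(a.name for a in panel.values() if a.assay_type == "interplate_calibrator")
    records, offsets = qqc.calibrate_interplate(records, layout_assay, calibrator)

    # 2. assembly ----------------------------------------------------------
    matrix, joined, _controls = qio.assemble_dataset(records, layout, samples, panel)
    n0 = matrix.n_datapoints()
    stages.append(WorkflowStage("input", n0, 0))

    # 3. detection-limit cutoff --------------------------------------------
    cut, dropped = qqc.apply_cp_cutoff(matrix, rules, audit)
    stages.append(WorkflowStage("cp_cutoff", n0, n0 - cut.n_datapoints(),
                                assays_removed=len(dropped)))

    # 4. reaction categorisation + melt review -----------------------------
    joined = qqc.categorize_reactions(joined)
    joined, _verdicts = qqc.melt_review(joined, melt_curves, rules, overrides, audit)
    reviewed = qqc.apply_categories(cut, joined, audit)
    stages.append(WorkflowStage("reaction_qc", cut.n_datapoints(),
                                cut.n_datapoints() - reviewed.n_datapoints()))

    # 5. spike-in sample exclusion -----------------------------------------
    samples = qqc.spike_in_qc(samples, rules, audit)
    retained = [s.sample_id for s in samples if not s.excluded]
    kept = reviewed.select_samples(retained)
    stages.append(WorkflowStage(
        "spike_qc", reviewed.n_datapoints(),
        reviewed.n_datapoints() - kept.n_datapoints(),
        samples_removed=len(samples) - len(retained),
    ))

    # 6. complete cases per group ------------------------------------------
    group_of = pd.Series({s.sample_id: s.group for s in samples if not s.excluded})
    groups = list(dict.fromkeys(group_of))
    complete: dict[str, CpMatrix] = {}
    summaries: dict[str, pd.DataFrame] = {}
    total_complete = 0
    for g in groups:
        members = list(group_of.index[group_of == g])
        comp, summary, excluded = qqc.build_complete_cases(kept, members)
        complete[g] = comp
        summaries[g] = summary
        total_complete += comp.n_datapoints()
        for assay in summary.index[summary["status"] == "incomplete"]:
            audit.add("complete_cases", "assay", f"incomplete in group {g}",
                      assay=assay, group=g)
        for assay in excluded:
            audit.add("complete_cases", "assay", f"no Cp values in group {g}",
                      assay=assay, group=g)
    stages.append(WorkflowStage("complete_cases", kept.n_datapoints(),
                                kept.n_datapoints() - total_complete))

    # 7. merge groups on the common assay set ------------------------------
    if len(groups) >= 2:
        combined = qqc.combine_groups(complete[groups[0]], complete[groups[1]])
        for g in groups[2:]:
            combined = qqc.combine_groups(combined, complete[g])
    else:
        combined = complete[groups[0]]
    stages.append(WorkflowStage("combine_groups", total_complete,
                                total_complete - combined.n_datapoints()))

    workflow = qqc.summarize_workflow(stages)

    # 8. stability ---------------------------------------------------------
    stab: dict[str, pd.DataFrame] = {}
    for g in groups:
        stab[g] = qstab.stability_table(complete[g], bestkeeper_center=bestkeeper_center)
    stab["combined"] = qstab.stability_table(combined, bestkeeper_center=bestkeeper_center)
    best_pair, pair_table = qstab.normfinder_best_pair(
        combined, group_of.loc[combined.samples]
    )

    return ResultBundle(
        calibrated=matrix, filtered=kept, complete=complete, summaries=summaries,
        combined=combined, stability=stab, pair_table=pair_table, best_pair=best_pair,
        workflow=workflow, audit=audit, samples=samples, group_of=group_of,
        plate_offsets=offsets, dropped_assays=dropped,
    )


def run_pipeline_from_cohort(
    cohort: Cohort, rules: QcRules | None = None, **kwargs
) -> ResultBundle:
    """Run on an in-memory synthetic cohort (no file round trip)."""
    return run_pipeline_from_data(
        [dataclasses.replace(r) for r in cohort.records],
        cohort.layout,
        [dataclasses.replace(s, spike_cp=dict(s.spike_cp)) for s in cohort.samples],
        cohort.panel,
        cohort.melt_curves,
        rules=rules,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# File-based entry point
# ---------------------------------------------------------------------------


def read_export_dir(
    indir: str | Path, dialect: Dialect | None = None
) -> tuple[list[ReactionRecord], qio.PanelLayout, list[SampleRecord],
           dict[str, qio.AssayDefinition], dict[tuple[str, str], MeltCurve]]:
    """Read a directory of instrument exports laid out as write_cohort emits."""
    dialect = dialect or Dialect()
    indir = Path(indir)
    records: list[ReactionRecord] = []
    tm_data: dict = {}
    for path in sorted((indir / "cp").glob("*.tsv")):
        records.extend(qio.read_cp_export(path, dialect))
    for path in sorted((indir / "tm").glob("*.tsv")):
        tm_data.update(qio.read_tm_export(path, dialect))
    records = qio.merge_tm(records, tm_data)
    curves: dict[tuple[str, str], MeltCurve] = {}
    melt_dir = indir / "melt"
    if melt_dir.is_dir():
        for path in sorted(melt_dir.glob("*.tsv")):
            for curve in qio.read_melt_export(path, dialect):
                curves[(curve.plate_id, curve.well)] = curve
    layout = qio.PanelLayout.read(indir / "layout.tsv", dialect)
    samples = qio.read_sample_sheet(indir / "samples.tsv", dialect)
    panel = qio.read_panel(indir / "panel.tsv", dialect)
    return records, layout, samples, panel, curves


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the whole pipeline per the run configuration.

    Either reads instrument exports from ``config.indir`` or, when a
    simulation config is given, generates the cohort first.  Writes all
    artifacts to ``config.outdir`` when set.
    """
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation, seed=config.seed)
        data = (cohort.records, cohort.layout, cohort.samples, cohort.panel,
                cohort.melt_curves)
    elif config.indir is not None:
        data = read_export_dir(config.indir)
    else:
        raise ValueError("RunConfig needs either indir or a simulation config")
    overrides = load_overrides(config.override_file) if config.override_file else None
    bundle = run_pipeline_from_data(
        *data, rules=config.rules, overrides=overrides,
        bestkeeper_center=config.bestkeeper_center,
    )
    if config.outdir:
        write_bundle(bundle, config.outdir)
    return bundle


# ---------------------------------------------------------------------------
# Output rendering
# ---------------------------------------------------------------------------


def write_bundle(bundle: ResultBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    qio.write_table(bundle.filtered, out / "filtered_matrix.tsv")
    for g, m in bundle.complete.items():
        qio.write_table(m, out / f"complete_cases_{g}.tsv")
        qio.write_table(bundle.summaries[g].round(6), out / f"assay_summary_{g}.tsv")
    qio.write_table(bundle.combined, out / "complete_cases_combined.tsv")
    for name, table in bundle.stability.items():
        qstab.format_stability_table(table).to_csv(
            out / f"stability_{name}.tsv", sep="\t", index=False)
    bundle.pair_table.round(6).to_csv(out / "pair_stability.tsv", sep="\t", index=False)
    bundle.audit.write(out / "audit.jsonl")
    (out / "workflow.txt").write_text(bundle.workflow.render() + "\n")
    (out / "report.md").write_text(render_report(bundle))


def render_report(bundle: ResultBundle) -> str:
    """Markdown report: workflow counts, per-group assay summaries, and the
    stability tables."""
    lines: list[str] = ["# RT-qPCR reference-stability report", ""]

    lines += ["## Filtering workflow", "", "```", bundle.workflow.render(), "```", ""]

    excluded_samples = [s for s in bundle.samples if s.excluded]
    lines += [f"Samples excluded by spike-in QC: {len(excluded_samples)}", ""]
    for s in excluded_samples:
        lines.append(f"- {s.sample_id} ({s.group}): {s.exclusion_reason}")
    lines.append("")
    if bundle.dropped_assays:
        lines += [
            "Assays removed at the Cp cutoff (all values above threshold): "
            + ", ".join(bundle.dropped_assays),
            "",
        ]

    for g, summary in bundle.summaries.items():
        lines += [f"## Group {g}: assay detection summary", ""]
        counts = summary["status"].value_counts()
        lines += [
            f"complete: {counts.get('complete', 0)}, "
            f"incomplete: {counts.get('incomplete', 0)}, "
            f"excluded: {counts.get('excluded', 0)}",
            "",
            "```",
            summary.round(3).to_string(),
            "```",
            "",
        ]

    for name, table in bundle.stability.items():
        lines += [f"## Stability ranking: {name}", "", "```",
                  qstab.format_stability_table(table).to_string(index=False), "```", ""]

    lines += [
        "## Most stable pair (grouped NormFinder)",
        "",
        f"{bundle.best_pair.pair[0]} + {bundle.best_pair.pair[1]}: "
        f"stability {bundle.best_pair.value:.3f}",
        "",
    ]
    return "\n".join(lines)
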