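"""Quality-control filtering for plasma RT-qPCR panels.

Implements the full filtering workflow applied before any stability
analysis, in its fixed order:

1. interplate calibration against the calibrator assay (UniSp3);
2. detection-limit cutoff (Cp > 35 set to missing; fully undetected
   assays dropped);
3. reaction categorisation from the instrument's Cp/Tm status calls and
   automated melt-curve classification of the reactions that would
   otherwise need manual review;
4. spike-in based sample exclusion (UniSp2 1.5xIQR outliers within group,
   UniSp2/UniSp4 delta-Cp outside 5..8 cycles);
5. complete-case assembly per group and merging of groups on the common
   assay set.

Every removal is logged so the workflow summary can assert datapoint
conservation at each node.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CpMatrix, MeltCurve, ReactionRecord, SampleRecord

logger = logging.getLogger("mirstab")


# ---------------------------------------------------------------------------
# Rules / configuration
# ---------------------------------------------------------------------------


@dataclass
class QcRules:
    """Thresholds of the QC workflow.

    cp_cutoff
        Detection limit in cycles; Cp values strictly above it are censored.
    peak_height_min
        Minimum melt-peak height in fluorescence units (FU).
    secondary_peak_fraction
        A second peak at least this fraction of the primary rejects the well.
    max_peaks
        More than this many peaks rejects the well.
    tm_tolerance
        Maximum distance (degC) of the primary peak from the reference Tm of
        auto-approved reactions of the same assay.
    iqr_multiplier
        Fence multiplier of the spike-in outlier rule.
    spike_delta_window
        Closed interval (cycles) for Cp(UniSp4) - Cp(UniSp2).
    hemolysis_delta_threshold
        Cp(miR-23a-3p) - Cp(miR-451a) above this flags hemolysis.
    """

    cp_cutoff: float = 35.0
    peak_height_min: float = 0.5
    secondary_peak_fraction: float = 0.5
    max_peaks: int = 2
    tm_tolerance: float = 1.5
    iqr_multiplier: float = 1.5
    spike_delta_window: tuple[float, float] = (5.0, 8.0)
    hemolysis_delta_threshold: float = 7.0
    # peak detection internals
    smooth_window: int = 5
    derivative_noise_floor: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.spike_delta_window
        if lo >= hi:
            raise ValueError("spike_delta_window lower bound must be < upper bound")
        for name in ("cp_cutoff", "peak_height_min", "secondary_peak_fraction",
                     "tm_tolerance", "iqr_multiplier", "hemolysis_delta_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: default categorisation matrix: (cp_status, tm_status) -> qc_category.
#: Auto-approval needs both calls approved; a missing or late Cp rejects the
#: reaction; every other combination that carries a Cp goes to melt-curve
#: review.  Overridable via `categorize_reactions(..., matrix=...)`.
DEFAULT_CATEGORY_MATRIX: dict[tuple[str, str], str] = {}
for _cp in ("approved", "uncertain", "absent", "late"):
    for _tm in ("approved", "inconclusive", "absent"):
        if _cp == "approved" and _tm == "approved":
            DEFAULT_CATEGORY_MATRIX[(_cp, _tm)] = "auto_approved"
        elif _cp in ("absent", "late"):
            DEFAULT_CATEGORY_MATRIX[(_cp, _tm)] = "rejected"
        else:
            DEFAULT_CATEGORY_MATRIX[(_cp, _tm)] = "manual_review"


# ---------------------------------------------------------------------------
# Workflow accounting
# ---------------------------------------------------------------------------


@dataclass
class WorkflowStage:
    name: str
    datapoints_in: int
    datapoints_removed: int
    samples_removed: int = 0
    assays_removed: int = 0

    @property
    def datapoints_out(self) -> int:
        return self.datapoints_in - self.datapoints_removed


@dataclass
class WorkflowSummary:
    """Ordered ledger of the filtering workflow (datapoints = Cp values)."""

    stages: list[WorkflowStage] = field(default_factory=list)

    def render(self) -> str:
        lines = []
        for st in self.stages:
            lines.append(
                f"[{st.name}] in={st.datapoints_in} removed={st.datapoints_removed} "
                f"(samples -{st.samples_removed}, assays -{st.assays_removed}) "
                f"-> out={st.datapoints_out}"
            )
        return "\n".join(lines)


def summarize_workflow(stages: Sequence[WorkflowStage]) -> WorkflowSummary:
    """Validate datapoint conservation across consecutive stages."""
    for prev, nxt in zip(stages, stages[1:]):
        if prev.datapoints_out != nxt.datapoints_in:
            raise ValueError(
                f"datapoint conservation violated between stages "
                f"{prev.name!r} ({prev.datapoints_out} out) and "
                f"{nxt.name!r} ({nxt.datapoints_in} in)"
            )
    return WorkflowSummary(stages=list(stages))


class AuditLog:
    """One JSON record per removed datapoint/sample/assay, with stage + reason."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, stage: str, kind: str, reason: str, **ids) -> None:
        self.records.append({"stage": stage, "kind": kind, "reason": reason, **ids})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    def counts_by_stage(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec["stage"]] = out.get(rec["stage"], 0) + 1
        return out


# ---------------------------------------------------------------------------
# 1. Interplate calibration
# ---------------------------------------------------------------------------


def calibrate_interplate(
    records: Sequence[ReactionRecord],
    layout_assay: Mapping[tuple[str, str], str] | None = None,
    calibrator_assay: str = "UniSp3",
) -> tuple[list[ReactionRecord], dict[str, float]]:
    """Adjust Cp values for plate-to-plate offsets using the calibrator assay.

    Cp_adj = Cp - (mean calibrator Cp on the well's plate - grand mean
    calibrator Cp over all plates).  Records may either carry their assay
    name already or be resolved through ``layout_assay``.

    Returns the adjusted records and the per-plate offsets applied.  The
    offset is applied to every well of the plate, calibrator wells
    included: their per-plate means are thereby equalised, which makes the
    operation idempotent.  (Calibrator wells are excluded from downstream
    analysis by assembly/routing regardless.)
    """

    def assay_of(rec: ReactionRecord) -> str | None:
        if rec.assay is not None:
            return rec.assay
        if layout_assay is not None:
            return layout_assay.get((rec.plate_id, rec.well))
        return None

    cal: dict[str, list[float]] = {}
    plates: set[str] = set()
    for rec in records:
        plates.add(rec.plate_id)
        if assay_of(rec) == calibrator_assay and rec.cp is not None:
            cal.setdefault(rec.plate_id, []).append(rec.cp)
    missing = sorted(plates - set(cal))
    if missing:
        raise ValueError(
            f"plate(s) without a non-missing {calibrator_assay} calibrator Cp: {missing}"
        )
    plate_means = {p: float(np.mean(v)) for p, v in cal.items()}
    grand_mean = float(np.mean(list(plate_means.values())))
    offsets = {p: m - grand_mean for p, m in plate_means.items()}

    adjusted: list[ReactionRecord] = []
    for rec in records:
        if rec.cp is None:
            adjusted.append(replace(rec))
        else:
            adjusted.append(replace(rec, cp=rec.cp - offsets[rec.plate_id]))
    return adjusted, offsets


# ---------------------------------------------------------------------------
# 2. Detection-limit cutoff
# ---------------------------------------------------------------------------


def apply_cp_cutoff(
    matrix: CpMatrix, rules: QcRules, audit: AuditLog | None = None
) -> tuple[CpMatrix, list[str]]:
    """Censor entries with Cp strictly above the cutoff; drop assays with no
    remaining detected value.  Cp exactly at the cutoff is retained."""
    vals = matrix.values.copy()
    over = vals > rules.cp_cutoff
    if audit is not None:
        for assay, sample in zip(*np.nonzero(over.values)):
            audit.add(
                "cp_cutoff", "datapoint", f"Cp > {rules.cp_cutoff}",
                assay=vals.index[assay], sample=vals.columns[sample],
                cp=float(vals.iat[assay, sample]),
            )
    vals = vals.mask(over)
    dead = vals.isna().all(axis=1)
    dropped = list(vals.index[dead])
    if audit is not None:
        for assay in dropped:
            audit.add("cp_cutoff", "assay", "all Cp values above cutoff", assay=assay)
    return CpMatrix(vals.loc[~dead]), dropped


# ---------------------------------------------------------------------------
# 3. Reaction categorisation + melt-curve classification
# ---------------------------------------------------------------------------


def categorize_reactions(
    records: Sequence[ReactionRecord],
    matrix: Mapping[tuple[str, str], str] | None = None,
) -> list[ReactionRecord]:
    """Assign each reaction a QC category from its Cp and Tm status calls."""
    table = DEFAULT_CATEGORY_MATRIX if matrix is None else matrix
    out: list[ReactionRecord] = []
    for rec in records:
        if rec.tm_status is None:
            raise ValueError(f"{rec.plate_id}:{rec.well}: Tm status not populated")
        try:
            category = table[(rec.cp_status, rec.tm_status)]
        except KeyError:
            raise ValueError(
                f"no category for status combination ({rec.cp_status}, {rec.tm_status})"
            ) from None
        out.append(replace(rec, qc_category=category))
    return out


def detect_melt_peaks(curve: MeltCurve, rules: QcRules) -> list[tuple[float, float]]:
    """Find melting peaks as local maxima of -dF/dT.

    The fluorescence series is smoothed with a centred moving average
    (window ``rules.smooth_window``), differentiated numerically, and local
    maxima below ``rules.derivative_noise_floor`` (FU/degC) are ignored.
    Returns (temperature, -dF/dT amplitude) sorted by descending amplitude.
    """
    w = max(1, int(rules.smooth_window))
    f = curve.fluorescence
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.concatenate([np.full(pad, f[0]), f, np.full(w - 1 - pad, f[-1])])
        f = np.convolve(padded, kernel, mode="valid")
    smooth = MeltCurve(curve.plate_id, curve.well, curve.temperatures, f)
    t, d = smooth.negative_derivative()
    peaks: list[tuple[float, float]] = []
    for i in range(1, len(d) - 1):
        if d[i] >= d[i - 1] and d[i] > d[i + 1] and d[i] >= rules.derivative_noise_floor:
            # refine by local parabola through the three points
            denom = d[i - 1] - 2 * d[i] + d[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (d[i - 1] - d[i + 1]) / denom
            step = t[min(i + 1, len(t) - 1)] - t[i - 1] if len(t) > 2 else 0.0
            peaks.append((float(t[i] + shift * step / 2.0), float(d[i])))
    peaks.sort(key=lambda p: -p[1])
    return peaks


def classify_melt_curve(
    curve: MeltCurve,
    reference_tm: Iterable[float],
    rules: QcRules,
    reported_peaks: Sequence[tuple[float, float]] | None = None,
) -> tuple[str, str]:
    """Automated stand-in for manual melt-curve review.

    A reaction is rejected if no clear peak is found, the primary peak is
    below the 0.5 FU threshold, a second peak reaches at least half the
    primary, more than two peaks are present, or the primary peak lies
    farther than ``tm_tolerance`` from the reference Tm (median peak
    temperature of auto-approved reactions of the same assay).

    Peak heights use the instrument-reported peaks when given, otherwise
    the -dF/dT amplitude of the detected peaks.  Returns
    ``(verdict, reason)`` with verdict in {"approved", "rejected"}.
    """
    detected = detect_melt_peaks(curve, rules)
    peaks = list(reported_peaks) if reported_peaks else detected
    peaks = sorted(peaks, key=lambda p: -p[1])
    if not peaks:
        return "rejected", "no clear peak"
    if peaks[0][1] < rules.peak_height_min:
        return "rejected", f"peak below {rules.peak_height_min} FU"
    if len(peaks) > rules.max_peaks:
        return "rejected", f"more than {rules.max_peaks} peaks"
    if len(peaks) >= 2 and peaks[1][1] >= rules.secondary_peak_fraction * peaks[0][1]:
        return "rejected", "secondary peak at least half the primary"
    refs = [float(x) for x in reference_tm]
    if not refs:
        return "approved", "approved (no auto-approved reference Tm available)"
    ref = float(np.median(refs))
    if abs(peaks[0][0] - ref) > rules.tm_tolerance:
        return "rejected", f"primary peak {peaks[0][0]:.1f} degC off reference {ref:.1f} degC"
    return "approved", "approved"


def melt_review(
    records: Sequence[ReactionRecord],
    curves: Mapping[tuple[str, str], MeltCurve],
    rules: QcRules,
    overrides: Mapping[tuple[str, str], str] | None = None,
    audit: AuditLog | None = None,
) -> tuple[list[ReactionRecord], dict[tuple[str, str], tuple[str, str]]]:
    """Resolve every ``manual_review`` reaction to approved/rejected.

    Reference Tm sets are taken from auto-approved reactions of the same
    assay (their reported primary peak temperatures).  ``overrides`` maps
    (plate, well) to a verdict and mimics true manual calls.
    """
    reference: dict[str, list[float]] = {}
    for rec in records:
        if rec.qc_category == "auto_approved" and rec.tm_peaks:
            reference.setdefault(rec.assay, []).append(rec.tm_peaks[0][0])

    verdicts: dict[tuple[str, str], tuple[str, str]] = {}
    out: list[ReactionRecord] = []
    for rec in records:
        if rec.qc_category != "manual_review":
            out.append(rec)
            continue
        key = (rec.plate_id, rec.well)
        if overrides and key in overrides:
            verdict, reason = overrides[key], "manual override"
        else:
            curve = curves.get(key)
            if curve is None:
                verdict, reason = "rejected", "no melt curve available for review"
            else:
                verdict, reason = classify_melt_curve(
                    curve, reference.get(rec.assay, []), rules,
                    reported_peaks=rec.tm_peaks or None,
                )
        verdicts[key] = (verdict, reason)
        if verdict == "rejected" and audit is not None:
            audit.add(
                "melt_review", "datapoint", reason,
                plate=rec.plate_id, well=rec.well, sample=rec.sample_id, assay=rec.assay,
            )
        out.append(replace(rec, qc_category="auto_approved" if verdict == "approved" else "rejected"))
    return out, verdicts


def apply_categories(
    matrix: CpMatrix, records: Sequence[ReactionRecord], audit: AuditLog | None = None
) -> CpMatrix:
    """Blank matrix cells whose reaction was rejected during categorisation."""
    vals = matrix.values.copy()
    for rec in records:
        if rec.qc_category == "rejected" and rec.assay in vals.index and rec.sample_id in vals.columns:
            if pd.notna(vals.at[rec.assay, rec.sample_id]):
                if audit is not None:
                    audit.add(
                        "reaction_qc", "datapoint", "reaction rejected",
                        plate=rec.plate_id, well=rec.well,
                        sample=rec.sample_id, assay=rec.assay,
                    )
                vals.at[rec.assay, rec.sample_id] = np.nan
    return CpMatrix(vals)


# ---------------------------------------------------------------------------
# 4. Spike-in sample QC
# ---------------------------------------------------------------------------


def iqr_fences(values: Sequence[float], multiplier: float) -> tuple[float, float]:
    """Tukey fences with quartiles by linear interpolation."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def spike_in_qc(
    samples: Sequence[SampleRecord],
    rules: QcRules,
    audit: AuditLog | None = None,
    spike_low: str = "UniSp2",
    spike_mid: str = "UniSp4",
) -> list[SampleRecord]:
    """Flag samples whose extraction spike-ins indicate a failed extraction.

    Within each group, a sample is excluded if its UniSp2 Cp falls outside
    the Tukey fences (quartiles of the pre-exclusion group, single pass), or
    if Cp(UniSp4) - Cp(UniSp2) lies outside the closed window.  Samples with
    a missing spike Cp are excluded with reason "spike missing".  UniSp5 is
    not consulted (in plasma panels it sits above the detection limit).
    """
    samples = [replace(s, spike_cp=dict(s.spike_cp)) for s in samples]
    lo, hi = rules.spike_delta_window
    by_group: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_group.setdefault(s.group, []).append(s)

    for group, members in by_group.items():
        unisp2 = [
            s.spike_cp[spike_low]
            for s in members
            if s.spike_cp.get(spike_low) is not None
        ]
        fences = iqr_fences(unisp2, rules.iqr_multiplier) if unisp2 else (-np.inf, np.inf)
        for s in members:
            cp2 = s.spike_cp.get(spike_low)
            cp4 = s.spike_cp.get(spike_mid)
            if cp2 is None or cp4 is None:
                s.exclude("spike missing")
            else:
                if not (fences[0] <= cp2 <= fences[1]):
                    s.exclude(f"{spike_low} Cp outside {rules.iqr_multiplier}xIQR fences")
                delta = cp4 - cp2
                if not (lo <= delta <= hi):
                    s.exclude(
                        f"{spike_mid}-{spike_low} delta Cp {delta:.2f} outside [{lo}, {hi}]"
                    )
            if s.excluded and audit is not None:
                audit.add("spike_qc", "sample", s.exclusion_reason,
                          sample=s.sample_id, group=group)
    return samples


def hemolysis_delta(
    cp_mir23a: float | None, cp_mir451: float | None, rules: QcRules | None = None
) -> tuple[float | None, str]:
    """Hemolysis indicator: delta Cp = Cp(miR-23a-3p) - Cp(miR-451a).

    miR-451a is enriched in red blood cells while miR-23a-3p is insensitive
    to hemolysis, so a large delta flags a hemolysed plasma sample.  Flags:
    'hemolysed' above the threshold, 'borderline' within two cycles below
    it, else 'ok'; 'not assessed' when either input is missing.
    """
    rules = rules or QcRules()
    if cp_mir23a is None or cp_mir451 is None:
        return None, "not assessed"
    delta = cp_mir23a - cp_mir451
    thr = rules.hemolysis_delta_threshold
    if delta > thr:
        return delta, "hemolysed"
    if delta > thr - 2:
        return delta, "borderline"
    return delta, "ok"


# ---------------------------------------------------------------------------
# 5. Complete cases
# ---------------------------------------------------------------------------


def build_complete_cases(
    matrix: CpMatrix, retained_samples: Sequence[str]
) -> tuple[CpMatrix, pd.DataFrame, list[str]]:
    """Partition assays into complete / incomplete / excluded over the
    retained samples.

    Returns the complete-case matrix (no missing entries), a per-assay
    summary table with mean, sd, % missing and classification, and the list
    of excluded (fully missing) assays.
    """
    retained = list(retained_samples)
    if not retained:
        raise ValueError("no retained samples")
    sub = matrix.select_samples(retained)
    summary = sub.summary()
    n_missing = sub.values.isna().sum(axis=1)
    n = len(retained)
    status = pd.Series("incomplete", index=summary.index, name="status")
    status[n_missing == 0] = "complete"
    status[n_missing == n] = "excluded"
    summary = summary.assign(status=status)
    complete = CpMatrix(sub.values.loc[status == "complete"])
    excluded = list(summary.index[status == "excluded"])
    return complete, summary, excluded


def combine_groups(matrix_a: CpMatrix, matrix_b: CpMatrix) -> CpMatrix:
    """Merge two complete-case matrices on their common assays.

    Rows are the assay intersection (order of the first matrix), columns the
    concatenated samples of both groups.
    """
    if not matrix_a.is_complete() or not matrix_b.is_complete():
        raise ValueError("combine_groups requires complete-case matrices")
    common = [a for a in matrix_a.assays if a in set(matrix_b.assays)]
    if not common:
        raise ValueError("no assays in common between the two groups")
    merged = pd.concat(
        [matrix_a.values.loc[common], matrix_b.values.loc[common]], axis=1
    )
    return CpMatrix(merged)
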