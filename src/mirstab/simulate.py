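"""Synthetic two-group plasma-miRNA RT-qPCR cohorts with known ground truth.

Emulates the statistical structure of a plasma miRNA panel study: a custom
384-well panel (40 miRNA targets + U6, five spike-ins, an interplate
calibrator and a blank) run on 60 carcinoma (HGSOC) and 48 benign-tumor
samples, eight samples per plate.  Target Cp values follow

    Cp_ij = baseline_i(group) + sample_j + plate_{p(j)} + eps_ij

with detection-limit censoring (late calls up to the cycle maximum, absent
beyond), spike-in controls with bounded technical noise, plate offsets
removable by interplate calibration, and injectable QC failures (spike-in
failures, melt-curve artifacts) recorded in a :class:`GroundTruth` object
so QC exactness can be asserted.

Per-assay baseline means and SDs default to values observed in plasma for
this panel; four designed-stable assays (no group effect, low variance) are
planted so that stability-ranking recovery can be measured end to end.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AssayDefinition,
    CpMatrix,
    Dialect,
    MeltCurve,
    PanelLayout,
    ReactionRecord,
    SampleRecord,
    write_panel,
    write_sample_sheet,
)

# ---------------------------------------------------------------------------
# Default assay parameterisation
# ---------------------------------------------------------------------------

#: name -> (mean HGSOC, sd HGSOC, mean benign, sd benign), Cp cycles, as
#: observed in plasma for this panel.  Assays detected in one group only
#: reuse the observed values of the other group.  Fully undetected assays
#: get a baseline well above the detection limit.
ASSAY_BASELINES: dict[str, tuple[float, float, float, float]] = {
    "hsa-miR-101-3p": (27.72, 1.79, 28.80, 1.74),
    "hsa-miR-103a-3p": (24.94, 2.20, 25.52, 2.40),
    "hsa-miR-126-3p": (25.12, 2.00, 25.88, 2.16),
    "hsa-miR-130a-3p": (27.26, 2.09, 28.34, 2.04),
    "hsa-miR-143-3p": (30.39, 1.94, 31.36, 2.07),
    "hsa-miR-146b-5p": (29.72, 2.12, 30.51, 1.88),
    "hsa-miR-191-5p": (25.08, 1.91, 25.91, 2.00),
    "hsa-miR-193a-5p": (31.54, 1.15, 32.94, 1.47),
    "hsa-miR-199a-3p": (26.34, 1.96, 27.17, 2.11),
    "hsa-miR-199a-5p": (28.64, 2.14, 29.51, 1.97),
    "hsa-miR-21-5p": (24.55, 2.02, 25.53, 2.06),
    "hsa-miR-221-3p": (25.26, 2.04, 26.13, 2.33),
    "hsa-miR-223-3p": (22.52, 2.00, 23.48, 1.98),
    "hsa-miR-23a-3p": (24.38, 2.05, 25.20, 2.24),
    "hsa-miR-24-3p": (24.46, 1.98, 25.36, 2.31),
    "hsa-miR-27a-3p": (26.12, 2.12, 27.18, 2.11),
    "hsa-miR-486-5p": (24.17, 1.48, 25.47, 1.94),
    "hsa-miR-1301-3p": (30.21, 1.83, 30.59, 1.93),
    "hsa-miR-34a-5p": (32.11, 1.78, 32.81, 1.33),
    "hsa-miR-200c-3p": (31.42, 1.93, 32.10, 1.73),
    "hsa-miR-106b-3p": (31.41, 1.57, 31.88, 1.95),
    "hsa-miR-195-5p": (32.23, 1.45, 32.72, 1.34),
    "hsa-miR-205-5p": (32.40, 1.76, 33.64, 1.32),
    "hsa-miR-24-2-5p": (32.01, 1.68, 32.68, 1.78),
    "hsa-miR-1234-3p": (29.06, 1.43, 30.18, 1.78),
    "hsa-miR-139-3p": (32.37, 1.44, 32.86, 1.37),
    "hsa-miR-141-3p": (32.61, 1.68, 33.15, 1.36),
    "hsa-miR-200b-3p": (33.15, 1.44, 33.23, 1.15),
    "U6_snRNA": (34.03, 0.92, 34.08, 1.03),
    "hsa-miR-23a-5p": (33.81, 0.79, 33.83, 1.45),
    "hsa-miR-27a-5p": (33.80, 0.84, 34.43, 0.43),
    "hsa-miR-506-3p": (34.36, 0.65, 34.11, 0.78),
    "hsa-miR-665": (32.58, 2.56, 33.76, 0.80),
    "hsa-miR-149-3p": (34.91, 0.11, 34.80, 0.30),
    "hsa-miR-92b-5p": (34.25, 0.40, 34.76, 0.18),
    "hsa-miR-135a-3p": (34.59, 0.30, 34.16, 0.30),
    "hsa-miR-455-3p": (37.50, 0.80, 34.66, 0.22),
    "hsa-miR-1183": (37.50, 0.80, 37.50, 0.80),
    "hsa-miR-302d-3p": (37.50, 0.80, 37.50, 0.80),
    "hsa-miR-595": (37.50, 0.80, 37.50, 0.80),
    "hsa-miR-802": (37.50, 0.80, 37.50, 0.80),
}

#: assays planted with zero group effect and low residual variance; the
#: stability ensemble should recover these as the top-ranked references.
DESIGNED_STABLE: tuple[str, ...] = (
    "hsa-miR-23a-3p",
    "hsa-miR-27a-3p",
    "hsa-miR-126-3p",
    "hsa-miR-191-5p",
)

SPIKE_EXTRACTION = ("UniSp2", "UniSp4", "UniSp5")
SPIKE_RT = ("UniSp6", "cel-miR-39-3p")
CALIBRATOR = "UniSp3"
BLANK = "blank"


@dataclass
class AssaySim:
    """Simulation parameters for one target assay."""

    name: str
    mean_hgsoc: float
    sd_hgsoc: float
    mean_benign: float
    sd_benign: float
    tm: float  # melting-peak temperature, degC
    designed_stable: bool = False

    def mean(self, group: str) -> float:
        return self.mean_hgsoc if group == "HGSOC" else self.mean_benign

    def sd(self, group: str) -> float:
        return self.sd_hgsoc if group == "HGSOC" else self.sd_benign

    @property
    def group_shift(self) -> float:
        return self.mean_benign - self.mean_hgsoc


def default_assay_table(
    designed_stable: Sequence[str] = DESIGNED_STABLE,
    designed_stable_sd: float = 0.5,
) -> list[AssaySim]:
    """Default target panel: observed plasma baselines, with the designed
    stable references overridden to zero group shift and low variance."""
    assays: list[AssaySim] = []
    for idx, (name, (mh, sh, mb, sb)) in enumerate(ASSAY_BASELINES.items()):
        tm = 72.0 + (idx * 0.37) % 16.0  # spread peaks over 72-88 degC
        if name in designed_stable:
            assays.append(
                AssaySim(name, mh, designed_stable_sd, mh, designed_stable_sd,
                         tm=tm, designed_stable=True)
            )
        else:
            assays.append(AssaySim(name, mh, sh, mb, sb, tm=tm))
    return assays


@dataclass
class SimulationConfig:
    """Full parameterisation of a synthetic cohort; the seed fixes it all."""

    n_hgsoc: int = 60
    n_benign: int = 48
    assays: list[AssaySim] = field(default_factory=default_assay_table)
    sample_effect_sd: float = 0.8   # cycles, shared across assays within a sample
    plate_effect_sd: float = 0.3    # cycles, shared across wells of a plate
    samples_per_plate: int = 8
    detection_limit: float = 35.0   # Cp cutoff
    max_cycles: float = 45.0        # beyond this the call is 'absent'
    # spike-in expected Cps; UniSp2 > UniSp4 > UniSp5 at 100-fold dilution
    # steps (~6.64 cycles); UniSp5 sits above the detection limit in plasma.
    spike_expected: dict[str, float] = field(
        default_factory=lambda: {
            "UniSp2": 19.0, "UniSp4": 25.64, "UniSp5": 35.9,
            "UniSp6": 20.0, "cel-miR-39-3p": 21.0,
        }
    )
    # bounded technical noise on spike-in Cps, Uniform(-w, +w): pipetted
    # synthetic RNA varies within tight limits, and bounded noise keeps the
    # IQR outlier rule's fences (at ~2w for a uniform sample) clear of
    # natural samples so only planted failures are flagged
    spike_noise_half_width: float = 0.4
    calibrator_cp: float = 19.5
    calibrator_noise_sd: float = 0.1
    # QC failure injection rates (fractions of samples / eligible wells)
    rate_spike_low_delta: float = 0.06
    rate_spike_high_delta: float = 0.02
    rate_spike_outlier: float = 0.02
    rate_low_peak: float = 0.010
    rate_half_double: float = 0.008
    rate_triple_peak: float = 0.005
    rate_uncertain_clean: float = 0.05
    # melt artifacts concentrate in weakly amplifying assays (primer dimer
    # and non-specific product risk grows with Cp); only assays with a
    # baseline above this threshold receive planted artifacts
    artifact_cp_threshold: float = 28.0
    # melt-curve synthesis
    melt_grid: tuple[float, float, float] = (65.0, 95.0, 0.2)  # start, stop, step
    melt_peak_width: float = 0.8    # degC (Gaussian sigma)
    melt_peak_height: float = 2.0   # FU in -dF/dT
    melt_noise_sd: float = 0.002    # FU, on the fluorescence series
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_hgsoc <= 0 or self.n_benign <= 0:
            problems.append("group sizes must be > 0")
        if self.sample_effect_sd < 0 or self.plate_effect_sd < 0 or self.spike_noise_half_width < 0:
            problems.append("effect SDs must be >= 0")
        for name in ("rate_spike_low_delta", "rate_spike_high_delta", "rate_spike_outlier",
                     "rate_low_peak", "rate_half_double", "rate_triple_peak",
                     "rate_uncertain_clean"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                problems.append(f"{name} must be in [0, 1] (got {r})")
        for a in self.assays:
            if a.sd_hgsoc < 0 or a.sd_benign < 0:
                problems.append(f"assay {a.name}: negative sd")
        if self.detection_limit >= self.max_cycles:
            problems.append("detection_limit must be below max_cycles")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    @property
    def n_samples(self) -> int:
        return self.n_hgsoc + self.n_benign

    def assay_by_name(self) -> dict[str, AssaySim]:
        return {a.name: a for a in self.assays}


@dataclass
class GroundTruth:
    """What the generator planted, for exactness checks downstream."""

    designed_stable: list[str]
    group_shift: dict[str, float]
    failed_samples: dict[str, str] = field(default_factory=dict)   # sample -> reason
    artifact_wells: dict[str, str] = field(default_factory=dict)   # "plate:well" -> artifact

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Cohort:
    """A fully generated synthetic cohort, in memory."""

    config: SimulationConfig
    panel: dict[str, AssayDefinition]
    layout: PanelLayout
    samples: list[SampleRecord]
    records: list[ReactionRecord]
    melt_curves: dict[tuple[str, str], MeltCurve]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Melt-curve synthesis
# ---------------------------------------------------------------------------


def generate_melt_curve(
    peaks: Sequence[tuple[float, float, float]],
    grid: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    plate_id: str = "plate",
    well: str = "A1",
) -> MeltCurve:
    """Fluorescence series whose -dF/dT is a sum of Gaussian bumps.

    ``peaks`` are (Tm degC, width degC, height FU) triples; the curve is the
    integrated (decreasing) fluorescence plus optional Gaussian noise.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty temperature grid")
    deriv = np.zeros_like(grid)
    for tm, width, height in peaks:
        deriv += height * np.exp(-0.5 * ((grid - tm) / width) ** 2)
    # integrate -dF/dT to obtain F, anchored so F stays positive
    steps = np.diff(grid)
    increments = 0.5 * (deriv[1:] + deriv[:-1]) * steps
    drop = np.concatenate([[0.0], np.cumsum(increments)])
    fluor = (drop[-1] - drop) + 0.5
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        fluor = fluor + rng.normal(0.0, noise_sd, size=fluor.size)
    return MeltCurve(plate_id=plate_id, well=well, temperatures=grid, fluorescence=fluor)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def make_panel(config: SimulationConfig) -> dict[str, AssayDefinition]:
    panel: dict[str, AssayDefinition] = {}
    for a in config.assays:
        panel[a.name] = AssayDefinition(name=a.name, assay_type="target")
    for s in SPIKE_EXTRACTION:
        panel[s] = AssayDefinition(name=s, assay_type="spike_extraction")
    for s in SPIKE_RT:
        panel[s] = AssayDefinition(name=s, assay_type="spike_rt")
    panel[CALIBRATOR] = AssayDefinition(name=CALIBRATOR, assay_type="interplate_calibrator")
    panel[BLANK] = AssayDefinition(name=BLANK, assay_type="blank")
    return panel


def _well_label(slot: int, assay_idx: int, assays_per_sample: int) -> str:
    idx = slot * assays_per_sample + assay_idx
    row, col = divmod(idx, 24)
    return f"{chr(ord('A') + row)}{col + 1}"


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a complete synthetic cohort (deterministic under seed).

    The clean cohort is generated first; QC failures are then injected by
    :func:`inject_qc_failures` at the configured rates.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()

    panel = make_panel(config)
    assay_order = list(panel)  # generation order within a sample block
    assays_per_sample = len(assay_order)
    if assays_per_sample * config.samples_per_plate > 384:
        raise ValueError("panel does not fit the 384-well format")

    groups = ["HGSOC"] * config.n_hgsoc + ["benign"] * config.n_benign
    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    n_plates = math.ceil(config.n_samples / config.samples_per_plate)

    plate_rng = np.random.default_rng([config.seed, 10_000])
    plate_effects = plate_rng.normal(0.0, config.plate_effect_sd, size=n_plates)

    layout_wells: dict[tuple[str, str], tuple[str, str]] = {}
    samples: list[SampleRecord] = []
    records: list[ReactionRecord] = []

    for j, (sid, group) in enumerate(zip(sample_ids, groups)):
        p = j // config.samples_per_plate
        slot = j % config.samples_per_plate
        plate_id = f"plate{p + 1:02d}"
        rng = np.random.default_rng([config.seed, j])  # per-sample sub-stream
        sample_effect = rng.normal(0.0, config.sample_effect_sd)
        sample = SampleRecord(sample_id=sid, group=group)
        samples.append(sample)

        for a_idx, assay_name in enumerate(assay_order):
            well = _well_label(slot, a_idx, assays_per_sample)
            layout_wells[(plate_id, well)] = (sid, assay_name)
            kind = panel[assay_name].assay_type

            if kind == "target":
                sim = config.assay_by_name()[assay_name]
                cp = (
                    sim.mean(group)
                    + sample_effect
                    + plate_effects[p]
                    + rng.normal(0.0, sim.sd(group))
                )
                if cp <= config.detection_limit:
                    status, tm_status = "approved", "approved"
                    peaks = [(sim.tm + rng.normal(0.0, 0.1),
                              config.melt_peak_height + rng.normal(0.0, 0.15))]
                elif cp <= config.max_cycles:
                    status, tm_status, peaks = "late", "absent", []
                else:
                    cp, status, tm_status, peaks = None, "absent", "absent", []
            elif kind in ("spike_extraction", "spike_rt"):
                base = config.spike_expected[assay_name]
                w_noise = config.spike_noise_half_width
                cp = base + plate_effects[p] + rng.uniform(-w_noise, w_noise)
                status = "approved" if cp <= config.detection_limit else "late"
                tm_status = "approved" if status == "approved" else "absent"
                peaks = [(78.0, 2.0)] if status == "approved" else []
            elif kind == "interplate_calibrator":
                cp = config.calibrator_cp + plate_effects[p] + rng.normal(0.0, config.calibrator_noise_sd)
                status, tm_status, peaks = "approved", "approved", [(80.0, 2.0)]
            else:  # blank
                cp, status, tm_status, peaks = None, "absent", "absent", []

            records.append(
                ReactionRecord(
                    plate_id=plate_id, well=well, cp=cp, cp_status=status,
                    sample_id=sid, assay=assay_name,
                    tm_peaks=peaks, tm_status=tm_status,
                )
            )

    cohort = Cohort(
        config=config,
        panel=panel,
        layout=PanelLayout(wells=layout_wells),
        samples=samples,
        records=records,
        melt_curves={},
        ground_truth=GroundTruth(
            designed_stable=[a.name for a in config.assays if a.designed_stable],
            group_shift={a.name: a.group_shift for a in config.assays},
        ),
    )
    return inject_qc_failures(cohort, config)


def inject_qc_failures(cohort: Cohort, config: SimulationConfig | None = None) -> Cohort:
    """Plant spike-in failures and melt-curve artifacts into a cohort.

    Selection and planted values are a pure function of the config seed, so
    re-applying the injection reproduces the same cohort (idempotent).
    Rates that demand more failures than there are samples/wells raise.
    Everything planted is recorded in the cohort's :class:`GroundTruth`.
    """
    config = config or cohort.config
    rng = np.random.default_rng([config.seed, 99_000])
    by_id = {s.sample_id: s for s in cohort.samples}
    spike_expected = config.spike_expected

    # ---- spike-in failures: disjoint sample sets per failure mode --------
    n = len(cohort.samples)
    n_low = round(config.rate_spike_low_delta * n)
    n_high = round(config.rate_spike_high_delta * n)
    n_out = round(config.rate_spike_outlier * n)
    if n_low + n_high + n_out > n:
        raise ValueError("spike failure rates exceed the sample population")
    chosen = rng.choice(n, size=n_low + n_high + n_out, replace=False)
    modes = (["low_delta"] * n_low + ["high_delta"] * n_high + ["unisp2_outlier"] * n_out)
    spike_records: dict[tuple[str, str], ReactionRecord] = {
        (r.sample_id, r.assay): r
        for r in cohort.records
        if r.assay in ("UniSp2", "UniSp4")
    }
    for idx, mode in zip(chosen, modes):
        sample = cohort.samples[int(idx)]
        rec2 = spike_records[(sample.sample_id, "UniSp2")]
        rec4 = spike_records[(sample.sample_id, "UniSp4")]
        if mode == "low_delta":
            rec4.cp = rec2.cp + rng.uniform(3.2, 4.6)
        elif mode == "high_delta":
            rec4.cp = rec2.cp + rng.uniform(8.4, 9.6)
        else:  # extraction anomaly: both spikes shifted, delta preserved
            shift = rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 5.0)
            base = spike_expected["UniSp2"] + shift
            rec2.cp = base
            rec4.cp = base + 6.64 + rng.uniform(-0.1, 0.1)
        cohort.ground_truth.failed_samples[sample.sample_id] = mode

    # ---- melt artifacts and clean manual-review wells --------------------
    assay_sims = config.assay_by_name()
    detected = [
        r for r in cohort.records
        if r.assay in assay_sims and r.cp is not None and r.cp <= config.detection_limit
    ]
    artifact_pool = [
        r for r in detected
        if assay_sims[r.assay].mean_hgsoc > config.artifact_cp_threshold
    ]
    n_art = len(artifact_pool)
    n_lowpk = round(config.rate_low_peak * n_art)
    n_half = round(config.rate_half_double * n_art)
    n_triple = round(config.rate_triple_peak * n_art)
    if n_lowpk + n_half + n_triple > n_art:
        raise ValueError("melt artifact rates exceed the eligible well population")
    art_picked = rng.choice(n_art, size=n_lowpk + n_half + n_triple, replace=False)
    art_wells = {(artifact_pool[int(i)].plate_id, artifact_pool[int(i)].well)
                 for i in art_picked}
    clean_pool = [r for r in detected if (r.plate_id, r.well) not in art_wells]
    n_clean = round(config.rate_uncertain_clean * len(detected))
    if n_clean > len(clean_pool):
        raise ValueError("uncertain-well rate exceeds the eligible well population")
    clean_picked = rng.choice(len(clean_pool), size=n_clean, replace=False)
    eligible = [artifact_pool[int(i)] for i in art_picked] + \
        [clean_pool[int(i)] for i in clean_picked]
    picked = range(len(eligible))
    kinds = (["low_peak"] * n_lowpk + ["half_double"] * n_half
             + ["triple_peak"] * n_triple + ["uncertain_clean"] * n_clean)

    start, stop, step = config.melt_grid
    grid = np.arange(start, stop + step / 2, step)
    w = config.melt_peak_width
    h = config.melt_peak_height
    for idx, kind in zip(picked, kinds):
        rec = eligible[int(idx)]
        tm = assay_sims[rec.assay].tm
        if kind == "low_peak":
            peaks = [(tm, w, 0.35)]
        elif kind == "half_double":
            peaks = [(tm, w, h), (tm - 8.0, w, 0.6 * h)]
        elif kind == "triple_peak":
            peaks = [(tm, w, h), (tm - 8.0, w, 0.55 * h), (tm + 4.0, w, 0.45 * h)]
        else:  # clean curve, only the status call is shaky
            peaks = [(tm, w, h)]
        curve_rng = np.random.default_rng([config.seed, 77_000, int(idx)])
        cohort.melt_curves[(rec.plate_id, rec.well)] = generate_melt_curve(
            peaks, grid, noise_sd=config.melt_noise_sd, rng=curve_rng,
            plate_id=rec.plate_id, well=rec.well,
        )
        rec.tm_peaks = sorted(((tm_, h_) for tm_, _, h_ in peaks), key=lambda p: -p[1])
        if kind == "uncertain_clean":
            rec.cp_status = "uncertain"
            rec.tm_status = "approved"
        else:
            rec.tm_status = "inconclusive"
            cohort.ground_truth.artifact_wells[f"{rec.plate_id}:{rec.well}"] = kind

    # refresh spike_cp mappings on the sample records
    for s in cohort.samples:
        s.spike_cp = {}
    for r in cohort.records:
        if r.assay in SPIKE_EXTRACTION or r.assay in SPIKE_RT:
            by_id[r.sample_id].spike_cp[r.assay] = r.cp
    return cohort


# ---------------------------------------------------------------------------
# Writing instrument-export files
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | Path, dialect: Dialect | None = None) -> None:
    """Emit the cohort as the delimited exports the parsers read.

    Layout on disk::

        outdir/
          cp/<plate>.tsv      Plate, Pos, Cp, Status
          tm/<plate>.tsv      Plate, Pos, Status, Tm1, Height1, ...
          melt/<plate>.tsv    Temperature + one column per well (wide)
          layout.tsv, samples.tsv, panel.tsv, ground_truth.json
    """
    dialect = dialect or Dialect()
    out = Path(outdir)
    for sub in ("cp", "tm", "melt"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    by_plate: dict[str, list[ReactionRecord]] = {}
    for rec in cohort.records:
        by_plate.setdefault(rec.plate_id, []).append(rec)

    max_peaks = max((len(r.tm_peaks) for r in cohort.records), default=0)
    for plate, recs in by_plate.items():
        cp_rows = [
            {"Plate": r.plate_id, "Pos": r.well,
             "Cp": "" if r.cp is None else repr(float(r.cp)), "Status": r.cp_status}
            for r in recs
        ]
        pd.DataFrame(cp_rows).to_csv(out / "cp" / f"{plate}.tsv", sep=dialect.sep, index=False)

        tm_rows = []
        for r in recs:
            row: dict[str, str] = {"Plate": r.plate_id, "Pos": r.well, "Status": r.tm_status}
            for k in range(max_peaks):
                if k < len(r.tm_peaks):
                    row[f"Tm{k + 1}"] = f"{r.tm_peaks[k][0]:.10g}"
                    row[f"Height{k + 1}"] = f"{r.tm_peaks[k][1]:.10g}"
                else:
                    row[f"Tm{k + 1}"] = ""
                    row[f"Height{k + 1}"] = ""
            tm_rows.append(row)
        pd.DataFrame(tm_rows).to_csv(out / "tm" / f"{plate}.tsv", sep=dialect.sep, index=False)

        plate_curves = {
            well: c for (p, well), c in cohort.melt_curves.items() if p == plate
        }
        if plate_curves:
            first = next(iter(plate_curves.values()))
            melt = pd.DataFrame({"Temperature": first.temperatures})
            for well, c in plate_curves.items():
                melt[well] = c.fluorescence
            melt.to_csv(out / "melt" / f"{plate}.tsv", sep=dialect.sep,
                        index=False, float_format="%.6g")

    cohort.layout.write(out / "layout.tsv", dialect)
    write_sample_sheet(cohort.samples, out / "samples.tsv", dialect)
    write_panel(cohort.panel, out / "panel.tsv", dialect)
    cohort.ground_truth.to_json(out / "ground_truth.json")


# ---------------------------------------------------------------------------
# Convenience: expected censoring fraction
# ---------------------------------------------------------------------------


def expected_censoring_fraction(config: SimulationConfig, assay: str, group: str) -> float:
    """Normal-tail prediction of the fraction of Cp values above the
    detection limit for one assay in one group (marginal over sample,
    plate and residual noise)."""
    sim = config.assay_by_name()[assay]
    total_sd = math.sqrt(
        sim.sd(group) ** 2 + config.sample_effect_sd ** 2 + config.plate_effect_sd ** 2
    )
    if total_sd == 0:
        return float(sim.mean(group) > config.detection_limit)
    z = (config.detection_limit - sim.mean(group)) / total_sd
    return 0.5 * math.erfc(z / math.sqrt(2.0))
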