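"""Parsing of thermocycler text exports and the pipeline data model.

RT-qPCR instruments (e.g. the LightCycler 480) export three delimited text
files per plate: a Cp table (one crossing point + status per well), a
Tm-calling table (melting peaks per well) and the raw melt-curve
fluorescence series.  This module turns those exports, together with a
panel layout (well -> sample, assay) and a sample sheet, into the in-memory
objects the QC and stability stages operate on.

All readers are driven by a :class:`Dialect` so separator, decimal mark,
status vocabulary and melt-table layout can be adapted to local instrument
settings without touching the parsers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirstab")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: assay roles within a panel
ASSAY_TYPES = (
    "target",
    "spike_extraction",   # UniSp2 / UniSp4 / UniSp5, added to the lysis buffer
    "spike_rt",           # UniSp6 / cel-miR-39-3p, added at cDNA synthesis
    "interplate_calibrator",  # UniSp3, identical reaction on every plate
    "blank",
)

CP_STATUSES = ("approved", "uncertain", "absent", "late")
TM_STATUSES = ("approved", "inconclusive", "absent")
QC_CATEGORIES = ("auto_approved", "manual_review", "rejected", "pending")

#: default mapping from instrument status strings to the internal vocabulary
DEFAULT_CP_STATUS_MAP: Mapping[str, str] = {
    "approved": "approved",
    "uncertain": "uncertain",
    "absent": "absent",
    "late": "late",
}
DEFAULT_TM_STATUS_MAP: Mapping[str, str] = {
    "approved": "approved",
    "inconclusive": "inconclusive",
    "absent": "absent",
}

NA_TOKEN = "NA"


class FormatError(ValueError):
    """Raised when an export file does not match the expected layout."""


# ---------------------------------------------------------------------------
# Dialect
# ---------------------------------------------------------------------------


@dataclass
class Dialect:
    """Describes how the instrument's text exports are laid out.

    Parameters
    ----------
    sep, decimal
        Field separator and decimal mark of the delimited files.
    cp_status_map, tm_status_map
        Mapping from instrument status strings (case-insensitive) to the
        internal vocabularies.  Unknown strings raise :class:`FormatError`
        rather than being coerced silently.
    melt_layout
        ``"wide"``: first column is the temperature grid, one column per
        well.  ``"long"``: columns ``Pos``/``Temperature``/``Fluorescence``.
    max_peaks
        Number of (Tm, height) column pairs read from the Tm table; peaks
        beyond this cap are ignored with a warning.
    """

    sep: str = "\t"
    decimal: str = "."
    cp_status_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CP_STATUS_MAP))
    tm_status_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_TM_STATUS_MAP))
    melt_layout: str = "wide"
    max_peaks: int = 5

    def _read(self, path: str | Path) -> pd.DataFrame:
        return pd.read_csv(
            path, sep=self.sep, decimal=self.decimal, dtype=str,
            keep_default_na=False, na_values=[],
        )

    def map_status(self, raw: str, table: Mapping[str, str], kind: str) -> str:
        key = raw.strip().lower()
        try:
            return table[key]
        except KeyError:
            raise FormatError(f"unknown {kind} status string: {raw!r}") from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayDefinition:
    """One assay of the panel (a miRNA target, a spike-in control, ...)."""

    name: str
    assay_type: str
    catalog_id: str | None = None
    target_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay_type {self.assay_type!r} for {self.name}")

    @property
    def is_target(self) -> bool:
        """Only target assays are eligible for stability analysis."""
        return self.assay_type == "target"


@dataclass
class ReactionRecord:
    """One well: a single RT-qPCR reaction and its quality annotations."""

    plate_id: str
    well: str
    cp: float | None
    cp_status: str
    sample_id: str | None = None
    assay: str | None = None
    tm_peaks: list[tuple[float, float]] = field(default_factory=list)
    tm_status: str | None = None
    qc_category: str = "pending"

    def __post_init__(self) -> None:
        if (self.cp is None) != (self.cp_status == "absent"):
            raise ValueError(
                f"{self.plate_id}:{self.well}: cp_status 'absent' must coincide "
                f"with a missing Cp (got cp={self.cp}, status={self.cp_status})"
            )
        # tallest peak first
        self.tm_peaks = sorted(self.tm_peaks, key=lambda p: -p[1])


@dataclass
class MeltCurve:
    """Raw post-amplification melt data for one well."""

    plate_id: str
    well: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError(f"{self.well}: temperature/fluorescence length mismatch")
        if self.temperatures.size < 10:
            raise ValueError(f"{self.well}: melt curve needs >= 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise FormatError(f"{self.well}: temperature grid not strictly increasing")

    def negative_derivative(self) -> tuple[np.ndarray, np.ndarray]:
        """-dF/dT on the interior grid (melt peaks are its local maxima)."""
        t, f = self.temperatures, self.fluorescence
        d = -(f[2:] - f[:-2]) / (t[2:] - t[:-2])
        return t[1:-1], d


@dataclass
class SampleRecord:
    """Sample identity, group label and spike-in control readouts."""

    sample_id: str
    group: str
    spike_cp: dict[str, float | None] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = ""

    def exclude(self, reason: str) -> None:
        if not reason:
            raise ValueError("exclusion requires a non-empty reason")
        self.excluded = True
        self.exclusion_reason = (
            f"{self.exclusion_reason}; {reason}" if self.exclusion_reason else reason
        )


class CpMatrix:
    """Assays (rows) x samples (columns) table of Cp values with missingness.

    A thin wrapper around a float DataFrame that enforces unique row and
    column names and provides the per-assay summary used by the
    complete/incomplete/excluded bookkeeping.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.astype(float)
        if df.index.has_duplicates:
            raise ValueError("duplicate assay names in CpMatrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids in CpMatrix")
        df.index.name = "assay"
        self.values = df

    # -- basic container protocol ------------------------------------------
    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "CpMatrix":
        return CpMatrix(self.values.copy())

    def select_samples(self, samples: Sequence[str]) -> "CpMatrix":
        return CpMatrix(self.values.loc[:, list(samples)])

    def select_assays(self, assays: Sequence[str]) -> "CpMatrix":
        return CpMatrix(self.values.loc[list(assays), :])

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def n_datapoints(self) -> int:
        """Number of non-missing Cp values."""
        return int(self.values.notna().sum().sum())

    def summary(self) -> pd.DataFrame:
        """Per-assay mean, sd (n-1) and % missing over non-missing entries."""
        vals = self.values
        return pd.DataFrame(
            {
                "mean": vals.mean(axis=1),
                "sd": vals.std(axis=1, ddof=1),
                "pct_missing": vals.isna().mean(axis=1) * 100.0,
            }
        )

    def __eq__(self, other: object) -> bool:  # value + missingness equality
        if not isinstance(other, CpMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return a.shape == b.shape and a.index.equals(b.index) and \
            a.columns.equals(b.columns) and \
            bool(((a == b) | (a.isna() & b.isna())).all().all())


@dataclass
class PanelLayout:
    """Mapping (plate_id, well) -> (sample_id, assay name) for 384-well plates."""

    wells: dict[tuple[str, str], tuple[str, str]]
    plate_format: str = "384"

    def __post_init__(self) -> None:
        # every sample must cover the full assay panel
        per_sample: dict[str, set[str]] = {}
        for (_, _), (sample, assay) in self.wells.items():
            per_sample.setdefault(sample, set()).add(assay)
        panels = {frozenset(v) for v in per_sample.values()}
        if len(panels) > 1:
            raise ValueError("samples do not all cover the same assay panel")

    def lookup(self, plate_id: str, well: str) -> tuple[str, str]:
        return self.wells[(plate_id, well)]

    @classmethod
    def read(cls, path: str | Path, dialect: Dialect | None = None) -> "PanelLayout":
        dialect = dialect or Dialect()
        df = dialect._read(path)
        _require_columns(df, ["Plate", "Pos", "Sample", "Assay"], path)
        wells: dict[tuple[str, str], tuple[str, str]] = {}
        for row in df.itertuples(index=False):
            key = (str(row.Plate), str(row.Pos))
            if key in wells:
                raise FormatError(f"duplicate well {key} in layout {path}")
            wells[key] = (str(row.Sample), str(row.Assay))
        return cls(wells)

    def write(self, path: str | Path, dialect: Dialect | None = None) -> None:
        dialect = dialect or Dialect()
        rows = [
            {"Plate": p, "Pos": w, "Sample": s, "Assay": a}
            for (p, w), (s, a) in self.wells.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# Export readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def _parse_float(cell: str, decimal: str) -> float | None:
    text = cell.strip()
    if text in ("", NA_TOKEN, "nan"):
        return None
    if decimal != ".":
        text = text.replace(decimal, ".")
    try:
        value = float(text)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def _plate_of(df: pd.DataFrame, path: str | Path) -> pd.Series:
    # plates identified by file name unless a Plate column exists
    if "Plate" in df.columns:
        return df["Plate"].astype(str)
    return pd.Series([Path(path).stem] * len(df), index=df.index)


def read_cp_export(path: str | Path, dialect: Dialect | None = None) -> list[ReactionRecord]:
    """Parse a Cp table export into one :class:`ReactionRecord` per well.

    Unparseable Cp cells become missing with ``cp_status='absent'``; the
    status column is mapped through ``dialect.cp_status_map``.  Tm fields
    are left unset (filled later from the Tm table).
    """
    dialect = dialect or Dialect()
    df = dialect._read(path)
    _require_columns(df, ["Pos", "Cp", "Status"], path)
    plates = _plate_of(df, path)
    records: list[ReactionRecord] = []
    seen: set[tuple[str, str]] = set()
    for i in df.index:
        plate, well = plates[i], str(df.at[i, "Pos"])
        if (plate, well) in seen:
            raise FormatError(f"{path}: duplicate well {plate}:{well}")
        seen.add((plate, well))
        cp = _parse_float(str(df.at[i, "Cp"]), dialect.decimal)
        status = dialect.map_status(str(df.at[i, "Status"]), dialect.cp_status_map, "Cp")
        if cp is None:
            status = "absent"
        elif status == "absent":
            raise FormatError(f"{path}: well {well} has status 'absent' but a numeric Cp")
        records.append(ReactionRecord(plate_id=plate, well=well, cp=cp, cp_status=status))
    return records


def read_tm_export(
    path: str | Path, dialect: Dialect | None = None
) -> dict[tuple[str, str], tuple[list[tuple[float, float]], str]]:
    """Parse a Tm-calling export.

    Returns a mapping ``(plate, well) -> (peaks, tm_status)`` with peaks as
    (temperature degC, height FU) tuples sorted by descending height.  Wells
    with no reported peak get ``tm_status='absent'``.
    """
    dialect = dialect or Dialect()
    df = dialect._read(path)
    _require_columns(df, ["Pos", "Status"], path)
    plates = _plate_of(df, path)
    # detect Tm1/Height1 ... column pairs
    n_pairs = 0
    while f"Tm{n_pairs + 1}" in df.columns or f"Height{n_pairs + 1}" in df.columns:
        n_pairs += 1
        if (f"Tm{n_pairs}" in df.columns) != (f"Height{n_pairs}" in df.columns):
            raise FormatError(f"{path}: ragged peak columns at index {n_pairs}")
    if n_pairs > dialect.max_peaks:
        logger.warning(
            "%s: %d peak column pairs, reading only the first %d",
            path, n_pairs, dialect.max_peaks,
        )
        n_pairs = dialect.max_peaks

    out: dict[tuple[str, str], tuple[list[tuple[float, float]], str]] = {}
    for i in df.index:
        key = (plates[i], str(df.at[i, "Pos"]))
        if key in out:
            raise FormatError(f"{path}: duplicate well {key}")
        peaks: list[tuple[float, float]] = []
        for k in range(1, n_pairs + 1):
            tm = _parse_float(str(df.at[i, f"Tm{k}"]), dialect.decimal)
            h = _parse_float(str(df.at[i, f"Height{k}"]), dialect.decimal)
            if (tm is None) != (h is None):
                raise FormatError(f"{path}: well {key[1]} has a Tm without a height (pair {k})")
            if tm is not None:
                peaks.append((tm, h))
        peaks.sort(key=lambda p: -p[1])
        status = dialect.map_status(str(df.at[i, "Status"]), dialect.tm_status_map, "Tm")
        if not peaks:
            status = "absent"
        out[key] = (peaks, status)
    return out


def merge_tm(
    records: list[ReactionRecord],
    tm_data: Mapping[tuple[str, str], tuple[list[tuple[float, float]], str]],
) -> list[ReactionRecord]:
    """Attach Tm peaks/status to Cp records; wells absent from the Tm table
    get ``tm_status='absent'``."""
    merged = []
    for rec in records:
        peaks, status = tm_data.get((rec.plate_id, rec.well), ([], "absent"))
        merged.append(replace(rec, tm_peaks=list(peaks), tm_status=status))
    return merged


def read_melt_export(path: str | Path, dialect: Dialect | None = None) -> list[MeltCurve]:
    """Parse raw melt fluorescence series (wide or long layout).

    Temperatures duplicated consecutively are collapsed by averaging the
    fluorescence; a grid that is still non-monotone afterwards is a format
    error.
    """
    dialect = dialect or Dialect()
    df = dialect._read(path)
    plate = Path(path).stem
    curves: list[MeltCurve] = []
    if dialect.melt_layout == "wide":
        if df.shape[1] < 2:
            raise FormatError(f"{path}: wide melt export needs a temperature column plus wells")
        temp_col = df.columns[0]
        temps = np.array([_parse_float(v, dialect.decimal) for v in df[temp_col]], dtype=float)
        for well in df.columns[1:]:
            fluo = np.array([_parse_float(v, dialect.decimal) for v in df[well]], dtype=float)
            t, f = _collapse_duplicates(temps, fluo, well)
            curves.append(MeltCurve(plate_id=plate, well=str(well), temperatures=t, fluorescence=f))
    elif dialect.melt_layout == "long":
        _require_columns(df, ["Pos", "Temperature", "Fluorescence"], path)
        plates = _plate_of(df, path)
        for (p, well), sub in df.groupby([plates, "Pos"], sort=False):
            temps = np.array([_parse_float(v, dialect.decimal) for v in sub["Temperature"]])
            fluo = np.array([_parse_float(v, dialect.decimal) for v in sub["Fluorescence"]])
            t, f = _collapse_duplicates(temps, fluo, well)
            curves.append(MeltCurve(plate_id=str(p), well=str(well), temperatures=t, fluorescence=f))
    else:
        raise ValueError(f"unknown melt_layout {dialect.melt_layout!r}")
    return curves


def _collapse_duplicates(temps: np.ndarray, fluo: np.ndarray, well: str) -> tuple[np.ndarray, np.ndarray]:
    t_out: list[float] = []
    f_out: list[float] = []
    i = 0
    n = len(temps)
    while i < n:
        j = i
        while j + 1 < n and temps[j + 1] == temps[i]:
            j += 1
        t_out.append(temps[i])
        f_out.append(float(np.mean(fluo[i : j + 1])))
        i = j + 1
    t_arr, f_arr = np.array(t_out), np.array(f_out)
    if np.any(np.diff(t_arr) <= 0):
        raise FormatError(f"well {well}: non-monotone temperature grid after collapsing duplicates")
    return t_arr, f_arr


# ---------------------------------------------------------------------------
# Sample sheet and panel table
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path, dialect: Dialect | None = None) -> list[SampleRecord]:
    dialect = dialect or Dialect()
    df = dialect._read(path)
    _require_columns(df, ["Sample", "Group"], path)
    return [SampleRecord(sample_id=str(r.Sample), group=str(r.Group)) for r in df.itertuples(index=False)]


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    pd.DataFrame(
        [{"Sample": s.sample_id, "Group": s.group} for s in samples]
    ).to_csv(path, sep=dialect.sep, index=False)


def read_panel(path: str | Path, dialect: Dialect | None = None) -> dict[str, AssayDefinition]:
    dialect = dialect or Dialect()
    df = dialect._read(path)
    _require_columns(df, ["Assay", "Type"], path)
    panel: dict[str, AssayDefinition] = {}
    for r in df.itertuples(index=False):
        name = str(r.Assay)
        if name in panel:
            raise FormatError(f"{path}: duplicate assay {name}")
        panel[name] = AssayDefinition(
            name=name,
            assay_type=str(r.Type),
            catalog_id=str(getattr(r, "Catalog", "")) or None,
            target_sequence=str(getattr(r, "Sequence", "")) or None,
        )
    validate_panel(panel)
    return panel


def validate_panel(panel: Mapping[str, AssayDefinition]) -> None:
    n_ipc = sum(1 for a in panel.values() if a.assay_type == "interplate_calibrator")
    if n_ipc != 1:
        raise ValueError(f"panel must contain exactly one interplate calibrator, found {n_ipc}")


def write_panel(panel: Mapping[str, AssayDefinition], path: str | Path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    pd.DataFrame(
        [
            {
                "Assay": a.name,
                "Type": a.assay_type,
                "Catalog": a.catalog_id or "",
                "Sequence": a.target_sequence or "",
            }
            for a in panel.values()
        ]
    ).to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def assemble_dataset(
    reactions: Sequence[ReactionRecord],
    layout: PanelLayout,
    samples: Sequence[SampleRecord],
    panel: Mapping[str, AssayDefinition],
) -> tuple[CpMatrix, list[ReactionRecord], pd.DataFrame]:
    """Join reactions with the layout and route them by assay role.

    Target-assay Cp values populate the analysis :class:`CpMatrix`; spike-in
    Cps are written into each sample's ``spike_cp`` mapping; interplate
    calibrator and blank wells go to a separate controls table.  Spike and
    control assays therefore never appear as matrix rows.

    Returns ``(matrix, joined_records, controls)`` where ``joined_records``
    carry sample and assay names and ``controls`` is a tidy DataFrame of the
    calibrator/blank wells.
    """
    validate_panel(panel)
    sample_index = {s.sample_id: s for s in samples}
    orphans = [
        (r.plate_id, r.well) for r in reactions if (r.plate_id, r.well) not in layout.wells
    ]
    if orphans:
        raise ValueError(f"{len(orphans)} reaction well(s) not present in layout: {orphans[:10]}")

    target_names = [a.name for a in panel.values() if a.is_target]
    sample_ids = [s.sample_id for s in samples]
    matrix = pd.DataFrame(np.nan, index=pd.Index(target_names, name="assay"), columns=sample_ids)

    joined: list[ReactionRecord] = []
    control_rows: list[dict] = []
    for rec in reactions:
        sample_id, assay = layout.lookup(rec.plate_id, rec.well)
        if assay not in panel:
            raise ValueError(f"well {rec.plate_id}:{rec.well} maps to unknown assay {assay!r}")
        rec = replace(rec, sample_id=sample_id, assay=assay)
        joined.append(rec)
        kind = panel[assay].assay_type
        if kind == "target":
            if sample_id in matrix.columns:
                matrix.at[assay, sample_id] = rec.cp if rec.cp is not None else np.nan
        elif kind in ("spike_extraction", "spike_rt"):
            if sample_id in sample_index:
                sample_index[sample_id].spike_cp[assay] = rec.cp
        else:  # interplate_calibrator, blank
            control_rows.append(
                {
                    "plate": rec.plate_id,
                    "well": rec.well,
                    "sample": sample_id,
                    "assay": assay,
                    "cp": rec.cp,
                }
            )
    controls = pd.DataFrame(control_rows, columns=["plate", "well", "sample", "assay", "cp"])
    return CpMatrix(matrix), joined, controls


# ---------------------------------------------------------------------------
# Table round trip
# ---------------------------------------------------------------------------


def write_table(table: CpMatrix | pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix or results table as delimited text with 'NA' for missing."""
    df = table.values if isinstance(table, CpMatrix) else table
    df.to_csv(path, sep=sep, na_rep=NA_TOKEN, index=True)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False,
                       index_col=0, float_precision="round_trip")


def read_cp_matrix(path: str | Path, sep: str = "\t") -> CpMatrix:
    return CpMatrix(read_table(path, sep=sep))
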