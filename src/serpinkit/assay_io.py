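"""Domain types and plain-text readers/writers for all assay tables.

Canonical units: seconds for progress-curve time, minutes for stability
time, micromolar for concentrations, percent for residual activities.
Readers convert from the units declared in the schema config.

Tables are delimited text (comma or tab, sniffed from the header line);
sequences travel as FASTA with 1-based inclusive residue coordinates in
all annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ProgressCurve",
    "TitrationSeries",
    "DecaySeries",
    "ActivityMeasurement",
    "SerpinRecord",
    "read_progress_table",
    "write_progress_table",
    "read_titration_table",
    "write_titration_table",
    "read_decay_table",
    "write_decay_table",
    "read_activity_table",
    "write_activity_table",
    "read_fasta",
    "write_fasta",
]

SIGNAL_KINDS = ("absorbance", "fluorescence", "concentration")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TIME_TO_S = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0}
_TIME_TO_MIN = {"s": 1.0 / 60.0, "min": 1.0, "h": 60.0}
_CONC_TO_UM = {"uM": 1.0, "nM": 1e-3, "mM": 1e3, "M": 1e6}


@dataclass
class ProgressCurve:
    """One timed product-accumulation trace with its assay concentrations.

    times are seconds, strictly increasing; concentrations are µM.
    """

    curve_id: str
    times: np.ndarray
    signal: np.ndarray
    inhibitor_conc: float
    enzyme_conc: float
    substrate_conc: float
    signal_kind: str = "absorbance"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValidationError(
                f"curve {self.curve_id!r}: times and signal must be 1-D arrays "
                f"of equal length"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"curve {self.curve_id!r}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError(f"curve {self.curve_id!r}: signal contains non-finite values")
        for name in ("inhibitor_conc", "enzyme_conc", "substrate_conc"):
            if getattr(self, name) < 0:
                raise ValidationError(f"curve {self.curve_id!r}: {name} must be >= 0")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(
                f"curve {self.curve_id!r}: signal_kind must be one of {SIGNAL_KINDS}"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TitrationSeries:
    """Fractional activity vs inhibitor:enzyme molar ratio for one protease."""

    protease_id: str
    enzyme_conc: float
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        pts = [(float(r), float(a)) for r, a in self.points]
        if any(r < 0 for r, _ in pts):
            raise ValidationError(f"titration {self.protease_id!r}: ratios must be >= 0")
        self.points = sorted(pts)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([r for r, _ in self.points])

    @property
    def fractional_activity(self) -> np.ndarray:
        return np.array([a for _, a in self.points])


@dataclass
class DecaySeries:
    """Residual activity (% of t=0) over incubation time for one condition."""

    condition_kind: str
    condition_value: float
    times: np.ndarray  # minutes
    residual_activity: np.ndarray  # percent

    def __post_init__(self) -> None:
        if self.condition_kind not in ("temperature", "pH"):
            raise ValidationError("condition_kind must be 'temperature' or 'pH'")
        self.times = np.asarray(self.times, dtype=float)
        self.residual_activity = np.asarray(self.residual_activity, dtype=float)
        if self.times.shape != self.residual_activity.shape:
            raise ValidationError("times and residual_activity must have equal length")
        if np.any(self.times < 0):
            raise ValidationError("decay times must be non-negative")
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.residual_activity = self.residual_activity[order]

    @property
    def label(self) -> str:
        unit = "C" if self.condition_kind == "temperature" else ""
        return f"{self.condition_kind}={self.condition_value:g}{unit}"


@dataclass
class ActivityMeasurement:
    """One replicate activity reading inside a labelled group."""

    group_label: str
    replicate_id: str
    activity: float

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValidationError(
                f"activity of {self.group_label}/{self.replicate_id} must be >= 0"
            )


@dataclass
class SerpinRecord:
    """Amino-acid sequence with optional loop/cleavage annotations.

    All coordinates are 1-based inclusive.
    """

    seq_id: str
    residues: str
    signal_peptide_span: tuple[int, int] | None = None
    rcl_span: tuple[int, int] | None = None
    p1_index: int | None = None
    cleavage_bond: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        bad = sorted(set(self.residues) - AMINO_ACIDS)
        if bad:
            raise ValidationError(
                f"record {self.seq_id!r}: non-amino-acid symbols {bad}"
            )
        n = len(self.residues)
        for name in ("signal_peptide_span", "rcl_span"):
            span = getattr(self, name)
            if span is not None:
                lo, hi = span
                if not (1 <= lo <= hi <= n):
                    raise ValidationError(
                        f"record {self.seq_id!r}: {name}={span} outside sequence of length {n}"
                    )
        if self.cleavage_bond is not None:
            i, j = self.cleavage_bond
            if j != i + 1 or not (1 <= i < n):
                raise ValidationError(
                    f"record {self.seq_id!r}: cleavage_bond {self.cleavage_bond} "
                    f"must be consecutive indices inside the sequence"
                )
        if self.p1_index is not None:
            if not (1 <= self.p1_index <= n):
                raise ValidationError(f"record {self.seq_id!r}: p1_index outside sequence")
            if self.rcl_span is not None:
                lo, hi = self.rcl_span
                if not (lo <= self.p1_index <= hi):
                    raise ValidationError(
                        f"record {self.seq_id!r}: p1_index {self.p1_index} outside rcl_span {self.rcl_span}"
                    )

    def replace(self, **changes) -> "SerpinRecord":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# schema handling

_DEFAULT_UNITS = {"time": "s", "conc": "uM"}


@dataclass
class TableSchema:
    """Column-name map plus declared units for one delimited table."""

    columns: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def col(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def unit(self, kind: str) -> str:
        return self.units.get(kind, _DEFAULT_UNITS.get(kind, ""))


def _as_schema(schema: Mapping | TableSchema | None) -> TableSchema:
    if schema is None:
        return TableSchema()
    if isinstance(schema, TableSchema):
        return schema
    unknown = set(schema) - {"columns", "units"}
    if unknown:
        raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
    return TableSchema(dict(schema.get("columns", {})), dict(schema.get("units", {})))


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab from the header
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise SchemaError(f"cannot parse table {path}: {exc}") from exc


def _require(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_nonneg(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        bad = df.index[df[c] < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative value in column {c!r} at row {int(bad[0])}"
            )


def _time_factor(unit: str, to: str) -> float:
    table = _TIME_TO_S if to == "s" else _TIME_TO_MIN
    try:
        return table[unit]
    except KeyError:
        raise SchemaError(f"unknown time unit {unit!r}") from None


def _conc_factor(unit: str) -> float:
    try:
        return _CONC_TO_UM[unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {unit!r}") from None


# ---------------------------------------------------------------------------
# progress curves

def read_progress_table(path, schema: Mapping | TableSchema | None = None) -> list[ProgressCurve]:
    """Read a delimited progress-curve table into one ProgressCurve per curve_id.

    Expected columns (renamable through the schema): curve_id, time_s,
    signal, inhibitor_uM, enzyme_uM, substrate_uM and optionally
    signal_kind. Rows are grouped by curve_id and sorted by time.
    """
    sch = _as_schema(schema)
    df = _read_table(path)
    names = {
        "curve_id": sch.col("curve_id"),
        "time_s": sch.col("time_s"),
        "signal": sch.col("signal"),
        "inhibitor_uM": sch.col("inhibitor_uM"),
        "enzyme_uM": sch.col("enzyme_uM"),
        "substrate_uM": sch.col("substrate_uM"),
    }
    _require(df, names.values(), path)
    conc_cols = [names["inhibitor_uM"], names["enzyme_uM"], names["substrate_uM"]]
    _check_nonneg(df, conc_cols, path)

    tf = _time_factor(sch.unit("time"), "s")
    cf = _conc_factor(sch.unit("conc"))
    kind_col = sch.col("signal_kind")

    curves = []
    for cid, grp in df.groupby(names["curve_id"], sort=False):
        grp = grp.sort_values(names["time_s"])
        times = grp[names["time_s"]].to_numpy(float) * tf
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{path}: non-monotone or duplicated times in curve {cid!r}"
            )
        concs = grp[conc_cols].to_numpy(float)
        if not np.allclose(concs, concs[0]):
            raise ValidationError(
                f"{path}: concentrations vary within curve {cid!r}"
            )
        kind = (
            str(grp[kind_col].iloc[0]) if kind_col in grp.columns else "absorbance"
        )
        curves.append(
            ProgressCurve(
                curve_id=str(cid),
                times=times,
                signal=grp[names["signal"]].to_numpy(float),
                inhibitor_conc=float(concs[0, 0]) * cf,
                enzyme_conc=float(concs[0, 1]) * cf,
                substrate_conc=float(concs[0, 2]) * cf,
                signal_kind=kind,
            )
        )
    return curves


def write_progress_table(curves: Sequence[ProgressCurve], path) -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.signal):
            rows.append(
                {
                    "curve_id": c.curve_id,
                    "time_s": t,
                    "signal": s,
                    "inhibitor_uM": c.inhibitor_conc,
                    "enzyme_uM": c.enzyme_conc,
                    "substrate_uM": c.substrate_conc,
                    "signal_kind": c.signal_kind,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# titrations

def read_titration_table(path, schema: Mapping | TableSchema | None = None) -> list[TitrationSeries]:
    """Columns: protease_id, enzyme_uM, ratio, fractional_activity."""
    sch = _as_schema(schema)
    df = _read_table(path)
    cols = {k: sch.col(k) for k in ("protease_id", "enzyme_uM", "ratio", "fractional_activity")}
    _require(df, cols.values(), path)
    _check_nonneg(df, [cols["enzyme_uM"], cols["ratio"]], path)
    cf = _conc_factor(sch.unit("conc"))
    out = []
    for pid, grp in df.groupby(cols["protease_id"], sort=False):
        out.append(
            TitrationSeries(
                protease_id=str(pid),
                enzyme_conc=float(grp[cols["enzyme_uM"]].iloc[0]) * cf,
                points=list(
                    zip(grp[cols["ratio"]].astype(float), grp[cols["fractional_activity"]].astype(float))
                ),
            )
        )
    return out


def write_titration_table(series: Sequence[TitrationSeries], path) -> None:
    rows = [
        {
            "protease_id": s.protease_id,
            "enzyme_uM": s.enzyme_conc,
            "ratio": r,
            "fractional_activity": a,
        }
        for s in series
        for r, a in s.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stability decays

def read_decay_table(path, schema: Mapping | TableSchema | None = None) -> list[DecaySeries]:
    """Columns: condition_kind, condition_value, time_min, residual_pct."""
    sch = _as_schema(schema)
    df = _read_table(path)
    cols = {k: sch.col(k) for k in ("condition_kind", "condition_value", "time_min", "residual_pct")}
    _require(df, cols.values(), path)
    tf = _time_factor(sch.units.get("time", "min"), "min")
    out = []
    for (kind, value), grp in df.groupby([cols["condition_kind"], cols["condition_value"]], sort=False):
        out.append(
            DecaySeries(
                condition_kind=str(kind),
                condition_value=float(value),
                times=grp[cols["time_min"]].to_numpy(float) * tf,
                residual_activity=grp[cols["residual_pct"]].to_numpy(float),
            )
        )
    return out


def write_decay_table(series: Sequence[DecaySeries], path) -> None:
    rows = [
        {
            "condition_kind": s.condition_kind,
            "condition_value": s.condition_value,
            "time_min": t,
            "residual_pct": a,
        }
        for s in series
        for t, a in zip(s.times, s.residual_activity)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grouped activity measurements

def read_activity_table(path, schema: Mapping | TableSchema | None = None) -> list[ActivityMeasurement]:
    """Columns: group, replicate, activity."""
    sch = _as_schema(schema)
    df = _read_table(path)
    cols = {k: sch.col(k) for k in ("group", "replicate", "activity")}
    _require(df, cols.values(), path)
    _check_nonneg(df, [cols["activity"]], path)
    return [
        ActivityMeasurement(str(row[cols["group"]]), str(row[cols["replicate"]]), float(row[cols["activity"]]))
        for _, row in df.iterrows()
    ]


def write_activity_table(measurements: Sequence[ActivityMeasurement], path) -> None:
    rows = [
        {"group": m.group_label, "replicate": m.replicate_id, "activity": m.activity}
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SerpinRecord]:
    """Read a FASTA file of amino-acid sequences; rejects illegal residues."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SerpinRecord(seq_id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SerpinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _ensure_dir(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
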