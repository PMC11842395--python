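"""Cohort data model, endpoint derivation, biomarker summaries and file I/O.

Two granularities coexist.  A :class:`PatientRecord` holds a patient's
longitudinal NT-proBNP series and outcome dates (integer days relative to
enrollment, which is day 0).  An :class:`AnalysisRow` is the unit the
likelihood consumes: one summary concentration plus the binary composite
endpoint (all-cause death or heart transplant within a fixed horizon).

Files are plain delimited text.  Long format (one row per measurement)::

    id, time_days, ntprobnp_pgml, death_day, transplant_day, last_followup_day
    [, age_years, sex, weight_kg, height_cm]

Wide format (one pre-summarised row per patient)::

    id, ntprobnp_pgml, event

A schema mapping can rename nonstandard columns at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ParameterError

__all__ = [
    "AnalysisRow",
    "PatientRecord",
    "MissingDataError",
    "CohortReadError",
    "derive_endpoint",
    "summarize_biomarker",
    "derive_analysis_rows",
    "baseline_table",
    "read_cohort",
    "write_cohort",
    "rows_to_frame",
    "frame_to_rows",
]

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("id", "time_days", "ntprobnp_pgml", "death_day",
                "transplant_day", "last_followup_day")
WIDE_COLUMNS = ("id", "ntprobnp_pgml", "event")
OPTIONAL_COLUMNS = ("age_years", "sex", "weight_kg", "height_cm")

ENROLLMENT_WINDOW_DAYS = 30  # "nearest measurement to day 0" search window


class MissingDataError(ValueError):
    """Raised when a patient has no eligible biomarker measurement."""


class CohortReadError(ValueError):
    """Raised when a cohort file cannot be parsed into valid records."""


@dataclass(frozen=True)
class AnalysisRow:
    """One patient's NT-proBNP summary (pg/mL) and binary endpoint."""

    nt_probnp: float
    event: int

    def __post_init__(self) -> None:
        if not (self.nt_probnp > 0 and np.isfinite(self.nt_probnp)):
            raise ParameterError(f"nt_probnp must be finite and > 0, got {self.nt_probnp}")
        if self.event not in (0, 1):
            raise ParameterError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class PatientRecord:
    """Longitudinal record for one patient; times in days, day 0 = enrollment."""

    id: str
    nt_probnp_series: tuple  # ((time_days, value_pgml), ...)
    last_followup_time: float
    death_time: Optional[float] = None
    transplant_time: Optional[float] = None
    enrollment_time: float = 0.0
    age_years: Optional[float] = None
    sex: Optional[str] = None
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.nt_probnp_series) == 0:
            raise ParameterError(f"patient {self.id}: empty NT-proBNP series")
        for t, v in self.nt_probnp_series:
            if not (0 <= t <= self.last_followup_time):
                raise ParameterError(
                    f"patient {self.id}: measurement time {t} outside "
                    f"[0, {self.last_followup_time}]"
                )
            if not (v > 0 and np.isfinite(v)):
                raise ParameterError(f"patient {self.id}: NT-proBNP value {v} must be > 0")
        for name, t in (("death_time", self.death_time),
                        ("transplant_time", self.transplant_time)):
            if t is not None and t < 0:
                raise ParameterError(f"patient {self.id}: {name} must be >= 0")


def derive_endpoint(record: PatientRecord, horizon: float) -> int:
    """Composite endpoint: 1 if death or transplant occurred within ``horizon``
    days of enrollment, else 0.  When both dates exist the earlier one applies
    (the composite value is the same either way)."""

    if horizon <= 0:
        raise ParameterError("horizon must be > 0")
    times = [t for t in (record.death_time, record.transplant_time) if t is not None]
    if not times:
        return 0
    return int(min(times) <= horizon)


def summarize_biomarker(record: PatientRecord, mode: str, horizon: float,
                        enrollment_window: float = ENROLLMENT_WINDOW_DAYS) -> float:
    """Per-patient NT-proBNP summary used as the model covariate.

    ``mode='enrollment'`` takes the measurement nearest day 0 within
    ``enrollment_window`` days; ``mode='median_followup'`` the median of all
    measurements in [0, horizon].
    """

    if horizon <= 0:
        raise ParameterError("horizon must be > 0")
    series = record.nt_probnp_series
    if mode == "enrollment":
        eligible = [(abs(t), v) for t, v in series if abs(t) <= enrollment_window]
        if not eligible:
            raise MissingDataError(
                f"patient {record.id}: no measurement within {enrollment_window} "
                f"days of enrollment"
            )
        return min(eligible, key=lambda tv: tv[0])[1]
    if mode == "median_followup":
        values = [v for t, v in series if 0 <= t <= horizon]
        if not values:
            raise MissingDataError(
                f"patient {record.id}: no measurement in [0, {horizon}] days"
            )
        return float(np.median(values))
    raise ParameterError(f"unknown mode {mode!r}; use 'enrollment' or 'median_followup'")


def derive_analysis_rows(records: Sequence[PatientRecord], mode: str,
                         horizon: float) -> list:
    """Summaries + endpoints for a whole cohort; patients without an eligible
    measurement are excluded with a logged count (not an error)."""

    rows, excluded = [], 0
    for rec in records:
        try:
            conc = summarize_biomarker(rec, mode=mode, horizon=horizon)
        except MissingDataError:
            excluded += 1
            continue
        rows.append(AnalysisRow(nt_probnp=conc, event=derive_endpoint(rec, horizon)))
    if excluded:
        logger.info("excluded %d of %d patients with no eligible NT-proBNP value",
                    excluded, len(records))
    return rows


def _median_iqr(values: np.ndarray) -> tuple:
    # Inverse-CDF quantiles, the same convention as the event-rate binning.
    q = np.quantile(values, [0.25, 0.5, 0.75], method="inverted_cdf")
    return float(q[1]), float(q[0]), float(q[2])


def baseline_table(records: Sequence[PatientRecord], rows: Sequence[AnalysisRow],
                   horizon: float) -> pd.DataFrame:
    """Cohort characteristics report: count (%) for categorical fields, median
    (IQR) for continuous ones, death/transplant counts at ``horizon``, and
    missingness per optional field.  Percentages are rounded to integers."""

    if len(records) == 0:
        raise ParameterError("empty cohort")
    n = len(records)
    out = [("N", n, "")]

    def pct(k: int, denom: int = n) -> str:
        return f"{k} ({round(100.0 * k / denom)})"

    sexes = [r.sex for r in records if r.sex is not None]
    if sexes:
        males = sum(1 for s in sexes if str(s).upper().startswith("M"))
        out.append(("Male, n (%)", len(sexes), pct(males, len(sexes))))
    else:
        out.append(("Male, n (%)", 0, "missing " + pct(n)))

    for label, attr in (("Age at enrollment, median (IQR), years", "age_years"),
                        ("Weight, median (IQR), kg", "weight_kg"),
                        ("Height, median (IQR), cm", "height_cm")):
        vals = np.array([getattr(r, attr) for r in records
                         if getattr(r, attr) is not None], dtype=float)
        if vals.size:
            med, q1, q3 = _median_iqr(vals)
            out.append((label, vals.size, f"{med:g} ({q1:g}, {q3:g})"))
        else:
            out.append((label, 0, "missing " + pct(n)))

    conc = np.array([r.nt_probnp for r in rows], dtype=float)
    if conc.size:
        med, q1, q3 = _median_iqr(conc)
        out.append(("NT-proBNP, median (IQR), pg/mL", conc.size,
                    f"{med:g} ({q1:g}, {q3:g})"))

    deaths = sum(1 for r in records
                 if r.death_time is not None and r.death_time <= horizon)
    transplants = sum(1 for r in records
                      if r.transplant_time is not None and r.transplant_time <= horizon)
    events = sum(derive_endpoint(r, horizon) for r in records)
    out.append((f"Death, n (%) within {horizon:g} d", n, pct(deaths)))
    out.append((f"Transplantation, n (%) within {horizon:g} d", n, pct(transplants)))
    out.append((f"Composite endpoint, n (%) within {horizon:g} d", n, pct(events)))
    return pd.DataFrame(out, columns=["characteristic", "n_available", "value"])


# ---------------------------------------------------------------------------
# file I/O


def _apply_schema(df: pd.DataFrame, schema: Optional[dict]) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def read_cohort(path, schema: Optional[dict] = None, delimiter: Optional[str] = None):
    """Read a cohort file, auto-detecting long vs wide format from the header.

    Returns ``(records, diagnostics)`` for long files or ``(rows, diagnostics)``
    for wide files, where diagnostics is a list of human-readable messages for
    rejected rows (1-based data line numbers).  Raises :class:`CohortReadError`
    if required columns are missing or no valid rows remain.
    """

    path = Path(path)
    sep = delimiter
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df = _apply_schema(df, schema)

    if set(LONG_COLUMNS).issubset(df.columns):
        records, diagnostics = _records_from_long(df)
        logger.info("read %d patients (%d diagnostics) from %s",
                    len(records), len(diagnostics), path)
        return records, diagnostics
    if set(WIDE_COLUMNS).issubset(df.columns):
        rows, diagnostics = _rows_from_wide(df)
        logger.info("read %d analysis rows (%d diagnostics) from %s",
                    len(rows), len(diagnostics), path)
        return rows, diagnostics
    raise CohortReadError(
        f"{path}: header must contain the long columns {LONG_COLUMNS} "
        f"or the wide columns {WIDE_COLUMNS}"
    )


def _rows_from_wide(df: pd.DataFrame):
    rows, diagnostics = [], []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            conc = float(rec.ntprobnp_pgml)
            event = int(rec.event)
            rows.append(AnalysisRow(nt_probnp=conc, event=event))
        except (ParameterError, TypeError, ValueError) as exc:
            diagnostics.append(f"line {i}: column ntprobnp_pgml/event invalid: {exc}")
    if not rows:
        raise CohortReadError("no valid analysis rows in file")
    return rows, diagnostics


def _records_from_long(df: pd.DataFrame):
    records, diagnostics = [], []
    line_of = {}  # first data line per patient, for diagnostics
    for i, pid in enumerate(df["id"], start=1):
        line_of.setdefault(pid, i)
    for pid, grp in df.groupby("id", sort=False):
        try:
            series = tuple(
                (float(t), float(v))
                for t, v in zip(grp["time_days"], grp["ntprobnp_pgml"])
            )
            death = grp["death_day"].iloc[0]
            transplant = grp["transplant_day"].iloc[0]
            extra = {}
            for col in OPTIONAL_COLUMNS:
                if col in grp.columns and pd.notna(grp[col].iloc[0]):
                    extra[col] = (str(grp[col].iloc[0]) if col == "sex"
                                  else float(grp[col].iloc[0]))
            records.append(PatientRecord(
                id=str(pid),
                nt_probnp_series=series,
                last_followup_time=float(grp["last_followup_day"].iloc[0]),
                death_time=None if pd.isna(death) else float(death),
                transplant_time=None if pd.isna(transplant) else float(transplant),
                **extra,
            ))
        except (ParameterError, TypeError, ValueError) as exc:
            diagnostics.append(
                f"line {line_of.get(pid, '?')}: patient {pid} rejected: {exc}"
            )
    if not records:
        raise CohortReadError("no valid patient records in file")
    return records, diagnostics


def rows_to_frame(rows: Sequence[AnalysisRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(1, len(rows) + 1)],
        "ntprobnp_pgml": [r.nt_probnp for r in rows],
        "event": [r.event for r in rows],
    })


def frame_to_rows(df: pd.DataFrame) -> list:
    return [AnalysisRow(nt_probnp=float(c), event=int(e))
            for c, e in zip(df["ntprobnp_pgml"], df["event"])]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for t, v in rec.nt_probnp_series:
            rows.append({
                "id": rec.id,
                "time_days": t,
                "ntprobnp_pgml": v,
                "death_day": rec.death_time,
                "transplant_day": rec.transplant_time,
                "last_followup_day": rec.last_followup_time,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "weight_kg": rec.weight_kg,
                "height_cm": rec.height_cm,
            })
    return pd.DataFrame(rows)


def write_cohort(path, data, delimiter: str = ",") -> None:
    """Write analysis rows (wide) or patient records (long) as delimited text;
    floats are written with shortest round-trip precision so a write-then-read
    cycle reproduces the values exactly."""

    path = Path(path)
    data = list(data)
    if data and isinstance(data[0], AnalysisRow):
        df = rows_to_frame(data)
    elif data and isinstance(data[0], PatientRecord):
        df = records_to_frame(data)
    else:
        raise ParameterError("write_cohort expects AnalysisRow or PatientRecord items")
    df.to_csv(path, sep=delimiter, index=False,
              float_format=lambda v: repr(float(v)))
    logger.info("wrote %d rows to %s", len(df), path)
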