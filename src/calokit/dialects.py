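"""Registry of documented instrument-export text dialects.

Commercial metabolic-phenotyping platforms (TSE LabMaster/PhenoMaster,
Columbus CLAMS Oxymax, Sable Promethion, COSMED) export delimited text with
vendor-specific headers, column names, gas units, timestamp formats and —
for European instruments — decimal commas. This module defines five precise,
fully documented dialects that mimic those structures so that readers and
writers are testable offline, plus the generic reader/writer engine driven
by a :class:`DialectSpec`. The registry is a plain dict; new dialects can be
registered at run time.

Dialect summary
---------------
``tse_v1``
    Semicolon-delimited, decimal comma, two header lines (title + ``key=value``
    metadata), gases in ml/h, German-style timestamps.
``clams_v1``
    One CSV file per animal inside a directory; one header line naming the
    subject; gases in ml/min.
``sable_v1``
    Tab-separated; interleaved non-sample event rows (``RowType != Sample``)
    are skipped; gases in ml/h.
``cosmed_v1``
    Minimal generic table, gases in l/h; carries only the mandatory channels.
``calr_csv``
    Single header row (``Animal ID, Date/Time, VO2, VCO2, ...``), gases in
    ml/h; also the export target for CalR-style interchange.
"""

from __future__ import annotations

import difflib
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .frame import (
    CalorimetryFrame,
    GAS_CHANNELS,
    MANDATORY_COLUMNS,
    OPTIONAL_CHANNELS,
)

#: Conversion factors from a dialect's gas unit to the canonical ml/h.
GAS_UNIT_TO_MLH = {"ml/h": 1.0, "ml/min": 60.0, "l/h": 1000.0}

_FLOAT_FMT = ".12g"  # round-trips within 1e-9 relative tolerance


class DialectError(ValueError):
    """Raised for unknown/ambiguous dialects and malformed dialect files."""


@dataclass(frozen=True)
class DialectSpec:
    """Complete description of one text dialect.

    ``column_map`` maps dialect column names to canonical channel names and
    must cover at least the animal id, timestamp and both gas channels.
    ``gas_units`` gives the unit each gas channel is stored in on disk.
    """

    name: str
    header_lines: int
    delimiter: str
    column_map: Mapping[str, str]
    timestamp_format: str
    gas_units: Mapping[str, str]
    decimal_mark: str = "."
    signature: str = ""  # exact first-line prefix; "" -> match by header tokens
    per_animal_files: bool = False
    row_type_column: str | None = None
    data_row_value: str = ""
    meta_line: bool = False  # second header line carries key=value pairs

    def __post_init__(self) -> None:
        covered = set(self.column_map.values())
        required = {"animal_id", "timestamp", "vo2", "vco2"}
        if not required <= covered:
            raise DialectError(
                f"dialect {self.name!r}: column_map must cover {sorted(required)}"
            )
        if self.delimiter == self.decimal_mark:
            raise DialectError(
                f"dialect {self.name!r}: delimiter and decimal mark must differ"
            )
        for gas, unit in self.gas_units.items():
            if unit not in GAS_UNIT_TO_MLH:
                raise DialectError(f"dialect {self.name!r}: unknown gas unit {unit!r}")

    @property
    def inverse_map(self) -> dict[str, str]:
        """Canonical channel -> dialect column name."""
        return {v: k for k, v in self.column_map.items()}


REGISTRY: dict[str, DialectSpec] = {}


def register(spec: DialectSpec) -> DialectSpec:
    if spec.name in REGISTRY:
        raise DialectError(f"dialect {spec.name!r} already registered")
    REGISTRY[spec.name] = spec
    return spec


register(DialectSpec(
    name="tse_v1",
    header_lines=2,
    delimiter=";",
    column_map={
        "Animal No.": "animal_id",
        "Date Time": "timestamp",
        "VO2(1)": "vo2",
        "VCO2(1)": "vco2",
        "XT": "activity_x",
        "YT": "activity_y",
        "Feed": "food",
        "Drink": "water",
        "Temp": "temp_ambient",
    },
    timestamp_format="%d.%m.%Y %H:%M:%S",
    gas_units={"vo2": "ml/h", "vco2": "ml/h"},
    decimal_mark=",",
    signature="TSE PhenoMaster Export v1",
    meta_line=True,
))

register(DialectSpec(
    name="clams_v1",
    header_lines=1,
    delimiter=",",
    column_map={
        "SUBJECT": "animal_id",
        "DATE/TIME": "timestamp",
        "VO2": "vo2",
        "VCO2": "vco2",
        "XTOT": "activity_x",
        "YTOT": "activity_y",
        "FEED": "food",
        "DRINK": "water",
        "TEMP": "temp_ambient",
    },
    timestamp_format="%m/%d/%Y %H:%M:%S",
    gas_units={"vo2": "ml/min", "vco2": "ml/min"},
    signature="CLAMS Oxymax Export v1",
    per_animal_files=True,
))

register(DialectSpec(
    name="sable_v1",
    header_lines=1,
    delimiter="\t",
    column_map={
        "Animal": "animal_id",
        "DateTime": "timestamp",
        "VO2_mlh": "vo2",
        "VCO2_mlh": "vco2",
        "ActX": "activity_x",
        "ActY": "activity_y",
        "FoodMass": "food",
        "WaterMass": "water",
        "Ta": "temp_ambient",
    },
    timestamp_format="%Y-%m-%d %H:%M:%S",
    gas_units={"vo2": "ml/h", "vco2": "ml/h"},
    signature="Sable Promethion Export v1",
    row_type_column="RowType",
    data_row_value="Sample",
))

register(DialectSpec(
    name="cosmed_v1",
    header_lines=1,
    delimiter=",",
    column_map={
        "Subject": "animal_id",
        "Time": "timestamp",
        "VO2": "vo2",
        "VCO2": "vco2",
    },
    timestamp_format="%Y-%m-%dT%H:%M:%S",
    gas_units={"vo2": "l/h", "vco2": "l/h"},
    signature="COSMED Generic Export v1",
))

register(DialectSpec(
    name="calr_csv",
    header_lines=0,
    delimiter=",",
    column_map={
        "Animal ID": "animal_id",
        "Date/Time": "timestamp",
        "VO2": "vo2",
        "VCO2": "vco2",
        "Activity X": "activity_x",
        "Activity Y": "activity_y",
        "Food": "food",
        "Water": "water",
        "Ambient Temp": "temp_ambient",
    },
    timestamp_format="%Y-%m-%d %H:%M:%S",
    gas_units={"vo2": "ml/h", "vco2": "ml/h"},
))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _first_data_path(path: Path) -> Path:
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise DialectError(f"directory {path} contains no files")
        return files[0]
    return path


def _matches(spec: DialectSpec, first_line: str) -> bool:
    if spec.signature:
        return first_line.startswith(spec.signature)
    # header-token match (dialects whose first line is the column header)
    tokens = set(first_line.split(spec.delimiter))
    required = {c for c, canon in spec.column_map.items()
                if canon in ("animal_id", "timestamp", "vo2", "vco2")}
    return required <= tokens


def detect_dialect(path: str | Path) -> DialectSpec:
    """Identify the registered dialect of a file (or per-animal directory).

    Matching is deterministic: the first-line signature (exact title prefix,
    or the header-token set for header-only dialects) must match exactly one
    registry entry.
    """
    path = Path(path)
    probe = _first_data_path(path)
    first_line = ""
    with open(probe, "r", encoding="utf-8") as fh:
        first_line = fh.readline().rstrip("\r\n")
    if not first_line:
        raise DialectError(f"{probe}: file is empty")
    hits = [s for s in REGISTRY.values() if _matches(s, first_line)]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        names = [s.name for s in hits]
        raise DialectError(f"{probe}: ambiguous dialect, matches {names}")
    sigs = {s.name: (s.signature or s.delimiter.join(s.column_map)) for s in REGISTRY.values()}
    close = difflib.get_close_matches(first_line, list(sigs.values()), n=1, cutoff=0.0)
    closest = next(n for n, sig in sigs.items() if sig == close[0]) if close else "?"
    raise DialectError(
        f"{probe}: unknown dialect (closest registered candidate: {closest!r})"
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_numeric(series: pd.Series, decimal_mark: str) -> pd.Series:
    s = series.replace("", np.nan)
    if decimal_mark != ".":
        s = s.str.replace(decimal_mark, ".", regex=False)
    return pd.to_numeric(s)

def read_dialect_file(path: Path, spec: DialectSpec) -> tuple[pd.DataFrame, dict]:
    """Read one physical file of a dialect into a raw canonical table."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise DialectError(f"{path}: file is empty")
    meta: dict[str, str] = {}
    if spec.signature:
        if not lines[0].startswith(spec.signature):
            raise DialectError(f"{path}: first line does not match dialect {spec.name!r}")
        # clams-style per-file subject annotation
        for token in lines[0].split(spec.delimiter)[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k.strip()] = v.strip()
    if spec.meta_line and spec.header_lines >= 2 and len(lines) > 1:
        for token in lines[1].split(spec.delimiter):
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k.strip()] = v.strip()
    body = "\n".join(lines[spec.header_lines:])
    raw = pd.read_csv(io.StringIO(body), sep=spec.delimiter, dtype=str,
                      keep_default_na=False, engine="python")
    raw.columns = [c.strip() for c in raw.columns]

    missing = [c for c, canon in spec.column_map.items()
               if canon in ("animal_id", "timestamp", "vo2", "vco2")
               and c not in raw.columns]
    if missing:
        raise DialectError(f"{path}: missing mandatory column(s) {missing}")

    if spec.row_type_column is not None and spec.row_type_column in raw.columns:
        raw = raw[raw[spec.row_type_column] == spec.data_row_value]
        raw = raw.drop(columns=[spec.row_type_column])

    out = pd.DataFrame(index=raw.index)
    mapped = set()
    for col, canon in spec.column_map.items():
        if col not in raw.columns:
            continue
        mapped.add(col)
        if canon == "timestamp":
            ts = pd.to_datetime(raw[col], format=spec.timestamp_format, errors="coerce")
            if ts.isna().any():
                bad = raw.index[ts.isna()][0]
                line_no = int(bad) + spec.header_lines + 2  # 1-based incl. header row
                raise DialectError(
                    f"{path}: unparseable timestamp {raw[col].loc[bad]!r} on line {line_no}"
                )
            out[canon] = ts
        elif canon == "animal_id":
            out[canon] = raw[col].astype(str).str.strip()
        else:
            out[canon] = _parse_numeric(raw[col], spec.decimal_mark)
    # unmapped extra columns are preserved as additional numeric channels
    for col in raw.columns:
        if col in mapped or col == spec.row_type_column:
            continue
        canon = col.strip().lower().replace(" ", "_")
        warnings.warn(
            f"{path}: unmapped column {col!r} preserved as channel {canon!r}",
            stacklevel=2,
        )
        try:
            out[canon] = _parse_numeric(raw[col], spec.decimal_mark)
        except (ValueError, TypeError):
            out[canon] = raw[col]
    for gas in GAS_CHANNELS:
        out[gas] = out[gas] * GAS_UNIT_TO_MLH[spec.gas_units[gas]]
    if "Subject" in meta and "animal_id" not in out.columns:
        out["animal_id"] = meta["Subject"]
    return out, meta


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_value(v, decimal_mark: str) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    s = format(float(v), _FLOAT_FMT)
    if decimal_mark != ".":
        s = s.replace(".", decimal_mark)
    return s


def write_dialect_file(df: pd.DataFrame, spec: DialectSpec, path: Path,
                       header_meta: Mapping[str, str] | None = None,
                       subject: str | None = None) -> None:
    """Write one physical file of a dialect from a canonical sub-table."""
    inv = spec.inverse_map
    cols = [c for c in spec.column_map if spec.column_map[c] in df.columns
            or spec.column_map[c] in MANDATORY_COLUMNS]
    lines: list[str] = []
    first = spec.signature or ""
    if spec.per_animal_files and subject is not None:
        first = f"{first}{spec.delimiter}Subject={subject}"
    if spec.signature:
        lines.append(first)
    if spec.meta_line and spec.header_lines >= 2:
        meta = header_meta or {}
        lines.append(spec.delimiter.join(f"{k}={v}" for k, v in meta.items()))
    header_cols = [c for c in cols]
    if spec.row_type_column is not None:
        header_cols = [spec.row_type_column] + header_cols
    lines.append(spec.delimiter.join(header_cols))
    for _, row in df.iterrows():
        out_row = []
        if spec.row_type_column is not None:
            out_row.append(spec.data_row_value)
        for c in cols:
            canon = spec.column_map[c]
            if canon == "timestamp":
                out_row.append(row["timestamp"].strftime(spec.timestamp_format))
            elif canon == "animal_id":
                out_row.append(str(row["animal_id"]))
            else:
                v = row[canon]
                if canon in GAS_CHANNELS:
                    v = float(v) / GAS_UNIT_TO_MLH[spec.gas_units[canon]]
                out_row.append(_format_value(v, spec.decimal_mark))
        lines.append(spec.delimiter.join(out_row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def unrepresentable_channels(frame: CalorimetryFrame, spec: DialectSpec) -> list[str]:
    """Optional channels present in the frame the dialect cannot store."""
    representable = set(spec.column_map.values())
    return [c for c in frame.channels if c not in representable]
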