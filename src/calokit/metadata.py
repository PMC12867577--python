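"""Per-animal metadata: loading, label harmonization, zeitgeber time.

Multi-cohort studies arrive with inconsistently labelled metadata
("Genotype" vs "genotype ", "KO" vs "knockout"). Harmonization unifies
factor names and levels by trimming/case-folding and a synonym dictionary,
and records every applied rule in a :class:`HarmonizationMap` so the
mapping is auditable. Photoperiod (lights-on/lights-off) anchors zeitgeber
time: ZT0 is lights-on, the dark phase starts at ZT ``(lights_off −
lights_on) mod 24``.
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frame import CalorimetryFrame

#: Columns of a metadata table that are not grouping factors.
RESERVED_COLUMNS = ("animal_id", "cohort_id", "body_mass", "lean_mass",
                    "lights_on", "lights_off")

_ID_ALIASES = {"animal id", "animal", "id", "box", "animal no.", "subject"}
_MASS_ALIASES = {"body mass", "bodymass", "body_mass", "weight", "bm",
                 "body weight", "bodyweight"}
_LEAN_ALIASES = {"lean mass", "leanmass", "lean_mass"}
_LIGHTS_ON_ALIASES = {"lights on", "lights_on", "light on", "lighton"}
_LIGHTS_OFF_ALIASES = {"lights off", "lights_off", "light off", "lightoff"}

#: Core level/name synonyms shipped with the package; canonical -> aliases.
#: User dictionaries (YAML, same shape) extend or override these.
BUILTIN_SYNONYMS: dict[str, list[str]] = {
    "genotype": ["geno"],
    "sex": ["gender"],
    "diet": ["food type", "food"],
    "treatment": ["tx", "drug"],
    "knockout": ["ko", "k.o.", "knock-out", "-/-"],
    "wildtype": ["wt", "wild-type", "wild type", "+/+"],
    "male": ["m"],
    "female": ["f"],
    "hfd": ["high fat diet", "high-fat diet"],
    "chow": ["standard diet", "control diet"],
}

_DECIMAL_COMMA = re.compile(r"^-?\d+(,\d+)?$")


class MetadataError(ValueError):
    pass


@dataclass(frozen=True)
class Photoperiod:
    """Scheduled light cycle of the animal facility (local clock times)."""

    lights_on: dt.time = dt.time(7, 0)
    lights_off: dt.time = dt.time(19, 0)

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise MetadataError("lights_on and lights_off must differ")

    @property
    def dark_onset_zt(self) -> float:
        """ZT hour at which the dark phase begins."""
        return (_hours(self.lights_off) - _hours(self.lights_on)) % 24.0


#: Common vivarium default, used (with a prominent warning) when no
#: photoperiod is supplied anywhere.
DEFAULT_PHOTOPERIOD = Photoperiod(dt.time(7, 0), dt.time(19, 0))


def default_photoperiod_with_warning() -> Photoperiod:
    warnings.warn(
        "no photoperiod supplied anywhere; assuming the 12:12 vivarium "
        "default with lights-on 07:00 — verify against the facility schedule",
        stacklevel=2,
    )
    return DEFAULT_PHOTOPERIOD


def _hours(t: dt.time) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9


def zeitgeber_time(timestamp, photoperiod: Photoperiod):
    """Clock time -> zeitgeber hours in [0, 24); ZT0 is lights-on.

    Accepts a single timestamp or a datetime Series (vectorised).
    """
    if photoperiod is None:
        raise MetadataError(
            "photoperiod undefined; supply it via the metadata sheet or "
            "specify it manually"
        )
    on = _hours(photoperiod.lights_on)
    if isinstance(timestamp, pd.Series):
        clock = (timestamp.dt.hour + timestamp.dt.minute / 60.0
                 + timestamp.dt.second / 3600.0
                 + timestamp.dt.microsecond / 3.6e9)
        return (clock - on) % 24.0
    ts = pd.Timestamp(timestamp)
    clock = _hours(ts.time())
    return (clock - on) % 24.0


def phase_of(zt, photoperiod: Photoperiod):
    """'light' for ZT in [0, dark_onset), 'dark' for [dark_onset, 24)."""
    dark0 = photoperiod.dark_onset_zt
    if isinstance(zt, (pd.Series, np.ndarray)):
        return np.where(np.asarray(zt) < dark0, "light", "dark")
    return "light" if zt < dark0 else "dark"


# ---------------------------------------------------------------------------
# metadata table
# ---------------------------------------------------------------------------

@dataclass
class MetadataTable:
    """One row per animal: grouping factors, body mass, photoperiod."""

    data: pd.DataFrame
    photoperiod: Photoperiod | None = None

    def __post_init__(self) -> None:
        if "animal_id" not in self.data.columns:
            raise MetadataError("metadata lacks an animal-id column")
        self.data = self.data.copy()
        self.data["animal_id"] = self.data["animal_id"].astype(str).str.strip()
        dup = self.data["animal_id"].duplicated()
        if dup.any():
            raise MetadataError(
                f"duplicate animal ids: {sorted(self.data.loc[dup, 'animal_id'])}"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def factors(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def animals(self) -> list[str]:
        return sorted(self.data["animal_id"])


def _parse_clock(v) -> dt.time | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, dt.time):
        return v
    s = str(v).strip()
    for fmt in ("%H:%M:%S", "%H:%M", "%H"):
        try:
            return dt.datetime.strptime(s, fmt).time()
        except ValueError:
            continue
    raise MetadataError(f"cannot parse clock time {v!r}")


def _autotype(series: pd.Series) -> pd.Series:
    """Numeric auto-typing, tolerant of decimal commas ('25,3' -> 25.3)."""
    if series.dtype != object:
        return series
    s = series.astype(str).str.strip()
    nonempty = s[(s != "") & (s.str.lower() != "nan")]
    if len(nonempty) == 0:
        return series
    if nonempty.str.match(_DECIMAL_COMMA).all():
        return pd.to_numeric(s.str.replace(",", ".", regex=False), errors="coerce")
    try:
        return pd.to_numeric(s)
    except (ValueError, TypeError):
        return series


def load_metadata_sheet(path: str | Path, cohort_id: str | None = None) -> MetadataTable:
    """Load a per-animal metadata sheet (CSV, or first sheet of an XLSX).

    The animal-id column is located via a small alias list (Animal ID,
    Animal, ID, Box, Subject); body-mass / lean-mass / lights-on / lights-off
    columns likewise. Every remaining column becomes a grouping factor;
    numeric columns (including decimal-comma notation) are auto-typed.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0, dtype=object)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _ID_ALIASES:
            rename[col] = "animal_id"
        elif key in _MASS_ALIASES:
            rename[col] = "body_mass"
        elif key in _LEAN_ALIASES:
            rename[col] = "lean_mass"
        elif key in _LIGHTS_ON_ALIASES:
            rename[col] = "lights_on"
        elif key in _LIGHTS_OFF_ALIASES:
            rename[col] = "lights_off"
    df = df.rename(columns=rename)
    if "animal_id" not in df.columns:
        raise MetadataError(
            f"{path}: no animal-id column found (accepted aliases: "
            f"{sorted(_ID_ALIASES)})"
        )
    for col in df.columns:
        if col in ("animal_id", "lights_on", "lights_off"):
            continue
        df[col] = _autotype(df[col])
    photoperiod = None
    if "lights_on" in df.columns and "lights_off" in df.columns:
        on = _parse_clock(df["lights_on"].iloc[0])
        off = _parse_clock(df["lights_off"].iloc[0])
        if on is not None and off is not None:
            photoperiod = Photoperiod(on, off)
        df = df.drop(columns=["lights_on", "lights_off"])
    if cohort_id is not None:
        df["cohort_id"] = cohort_id
    return MetadataTable(df, photoperiod=photoperiod)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationMap:
    """Audit trail: every raw label with its canonical form and the rule used."""

    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["raw_label", "canonical_label", "rule"]))

    def record(self, raw: str, canonical: str, rule: str) -> None:
        row = {"raw_label": raw, "canonical_label": canonical, "rule": rule}
        self.entries = pd.concat(
            [self.entries, pd.DataFrame([row])], ignore_index=True)

    def lookup(self) -> dict[str, str]:
        return dict(zip(self.entries["raw_label"], self.entries["canonical_label"]))


def _build_alias_index(synonyms: dict[str, list[str]] | None) -> dict[str, str]:
    merged = {k: list(v) for k, v in BUILTIN_SYNONYMS.items()}
    for canon, aliases in (synonyms or {}).items():
        merged.setdefault(canon, [])
        merged[canon].extend(aliases)
    index: dict[str, str] = {}
    for canon, aliases in merged.items():
        for a in aliases:
            index[a.strip().casefold()] = canon
    return index


def load_synonyms(path: str | Path) -> dict[str, list[str]]:
    """Read a user synonym dictionary: YAML mapping canonical -> alias list."""
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    return {str(k): [str(a) for a in v] for k, v in loaded.items()}


def _canonicalise(label: str, alias_index: dict[str, str],
                  hmap: HarmonizationMap) -> str:
    folded = str(label).strip().casefold()
    if folded in alias_index:
        canon = alias_index[folded]
        rule = "exact" if canon == label else "synonym"
    else:
        canon = folded
        rule = "exact" if canon == label else "case_fold"
    existing = hmap.lookup()
    if label not in existing:
        hmap.record(label, canon, rule)
    return canon


def harmonize_labels(
    tables: list[MetadataTable],
    synonyms: dict[str, list[str]] | None = None,
    overrides: dict[str, str] | None = None,
) -> tuple[MetadataTable, HarmonizationMap]:
    """Unify factor names and levels across cohorts.

    Applied in order: (1) trim + case-fold, (2) built-in plus user synonym
    dictionary, (3) explicit per-label user overrides (which win and are
    logged as ``user_override``). Raises if two distinct factors of one
    cohort collapse onto the same canonical name.
    """
    if not tables:
        raise MetadataError("harmonize_labels requires at least one table")
    alias_index = _build_alias_index(synonyms)
    hmap = HarmonizationMap()
    overrides = overrides or {}

    harmonized_frames = []
    for table in tables:
        df = table.data.copy()
        new_names: dict[str, str] = {}
        for col in table.factors:
            if col in overrides:
                canon = overrides[col]
                hmap.record(col, canon, "user_override")
            else:
                canon = _canonicalise(col, alias_index, hmap)
            if canon in new_names.values() and col != canon:
                other = [k for k, v in new_names.items() if v == canon]
                raise MetadataError(
                    f"factors {other + [col]} collapse onto {canon!r} within one cohort"
                )
            new_names[col] = canon
        df = df.rename(columns=new_names)

        def _level(lv):
            if not isinstance(lv, str):
                return lv
            if lv in overrides:
                if lv not in hmap.lookup():
                    hmap.record(lv, overrides[lv], "user_override")
                return overrides[lv]
            return _canonicalise(lv, alias_index, hmap)

        for canon in new_names.values():
            if df[canon].dtype == object:
                df[canon] = df[canon].map(_level)
        harmonized_frames.append(df)

    merged = pd.concat(harmonized_frames, ignore_index=True)
    photoperiod = next((t.photoperiod for t in tables if t.photoperiod), None)
    return MetadataTable(merged, photoperiod=photoperiod), hmap


def apply_metadata(frame: CalorimetryFrame, meta: MetadataTable) -> CalorimetryFrame:
    """Annotate every sample with its animal's factors and body mass.

    Never changes row count or measurement values. Animals missing from the
    metadata are reported via a warning and retained with missing factors.
    """
    cols = ["animal_id"] + meta.factors
    for extra in ("body_mass", "lean_mass"):
        if extra in meta.data.columns:
            cols.append(extra)
    lookup = meta.data[cols]
    missing = sorted(set(frame.animals) - set(meta.animals))
    if missing:
        warnings.warn(
            f"animals missing from metadata (kept with missing factors): {missing}",
            stacklevel=2,
        )
    data = frame.data.drop(columns=[c for c in cols if c != "animal_id"
                                    and c in frame.data.columns])
    data = data.merge(lookup, on="animal_id", how="left")
    return CalorimetryFrame(data, dict(frame.header_meta))
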