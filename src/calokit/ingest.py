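"""Ingestion of instrument exports into the canonical frame.

`read_dataset` parses a file (or, for per-animal dialects, a directory of
files) in one of the registered text dialects, normalises gas units to ml/h
and returns a validated :class:`~calokit.frame.CalorimetryFrame`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .dialects import (
    REGISTRY,
    DialectError,
    DialectSpec,
    detect_dialect,
    read_dialect_file,
)
from .frame import CalorimetryFrame, MANDATORY_COLUMNS

__all__ = ["detect_dialect", "read_dataset", "merge_cohorts", "get_dialect"]


def get_dialect(name: str) -> DialectSpec:
    try:
        return REGISTRY[name]
    except KeyError:
        raise DialectError(
            f"unknown dialect {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


def read_dataset(path: str | Path, dialect: DialectSpec | str,
                 cohort_id: str | None = None) -> CalorimetryFrame:
    """Read a dialect-conformant export into a canonical frame.

    Parameters
    ----------
    path:
        A single file, or a directory of per-animal files for dialects with
        ``per_animal_files`` (e.g. ``clams_v1``).
    dialect:
        A :class:`DialectSpec` or registered dialect name.
    cohort_id:
        Cohort label attached to every row. Defaults to the ``cohort`` key of
        the file's header metadata if present, else the file (or directory)
        stem.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    path = Path(path)
    if dialect.per_animal_files:
        if path.is_dir():
            files: Iterable[Path] = sorted(
                p for p in path.iterdir() if p.is_file())
        else:
            files = [path]
    else:
        files = [path]

    parts = []
    meta: dict = {}
    for f in files:
        df, file_meta = read_dialect_file(f, dialect)
        df["source_file"] = str(f)
        parts.append(df)
        meta.update(file_meta)
    data = pd.concat(parts, ignore_index=True)
    data["dialect_name"] = dialect.name
    data["cohort_id"] = cohort_id or meta.get("cohort") or path.stem
    missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
    if missing:
        raise DialectError(f"{path}: missing mandatory column(s) {missing}")
    return CalorimetryFrame(data, header_meta=meta)


def merge_cohorts(frames: list[CalorimetryFrame]) -> CalorimetryFrame:
    """Concatenate cohorts for joint multi-cohort analysis.

    Animals must be globally unique or disambiguated by ``cohort_id``; a
    (cohort_id, animal_id) pair occurring in more than one input frame is an
    error because samples could no longer be attributed.
    """
    if not frames:
        raise ValueError("no frames to merge")
    seen: set[tuple[str, str]] = set()
    for fr in frames:
        pairs = set(map(tuple, fr.data[["cohort_id", "animal_id"]].drop_duplicates().to_numpy()))
        collision = seen & pairs
        if collision:
            raise ValueError(
                f"colliding (cohort_id, animal_id) pairs across frames: {sorted(collision)}"
            )
        seen |= pairs
    # animals sharing an id across cohorts are disambiguated by cohort prefix
    by_animal: dict[str, set[str]] = {}
    for cohort, animal in seen:
        by_animal.setdefault(animal, set()).add(cohort)
    colliding = {a for a, cohorts in by_animal.items() if len(cohorts) > 1}
    parts = []
    for fr in frames:
        df = fr.data
        mask = df["animal_id"].isin(colliding)
        if mask.any():
            df = df.copy()
            df.loc[mask, "animal_id"] = (
                df.loc[mask, "cohort_id"] + ":" + df.loc[mask, "animal_id"])
        parts.append(df)
    data = pd.concat(parts, ignore_index=True)
    meta: dict = {}
    for fr in frames:
        meta.update(fr.header_meta)
    return CalorimetryFrame(data, header_meta=meta)
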