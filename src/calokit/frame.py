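"""Canonical long-format container for indirect-calorimetry time series.

Every pipeline stage consumes and produces a :class:`CalorimetryFrame`: one
row per (animal, timestamp) sample with gas-exchange rates in canonical
units (ml/h) plus optional covariate channels (beam-break activity, food and
water intake per interval, ambient temperature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every frame must carry.
MANDATORY_COLUMNS = ("animal_id", "cohort_id", "timestamp", "vo2", "vco2")

#: Optional measurement channels, in canonical order.
OPTIONAL_CHANNELS = ("activity_x", "activity_y", "food", "water", "temp_ambient")

#: Gas-rate channels, stored in ml/h after ingestion.
GAS_CHANNELS = ("vo2", "vco2")

#: Channels that are counts or amounts per interval (summed on resampling,
#: as opposed to intensities, which are averaged).
COUNT_CHANNELS = ("activity_x", "activity_y", "food", "water")

#: Provenance columns attached by the reader.
PROVENANCE_COLUMNS = ("source_file", "dialect_name")


class FrameValidationError(ValueError):
    """Raised when a table violates the canonical-frame contract."""


@dataclass
class CalorimetryFrame:
    """Long-format per-sample table plus header metadata.

    Parameters
    ----------
    data:
        One row per (animal, timestamp) sample. Mandatory columns:
        ``animal_id``, ``cohort_id``, ``timestamp`` (naive datetime, local
        clock), ``vo2`` and ``vco2`` in ml/h. Negative gas values are legal
        here (curation flags them later).
    header_meta:
        Key-value metadata recovered from file headers, if any.
    """

    data: pd.DataFrame
    header_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _normalise(self.data)
        _validate(self.data)

    # -- introspection ---------------------------------------------------
    @property
    def animals(self) -> list[str]:
        return sorted(self.data["animal_id"].unique())

    @property
    def channels(self) -> list[str]:
        """Optional channels present (beyond the mandatory gas channels)."""
        return [c for c in OPTIONAL_CHANNELS if c in self.data.columns]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def median_interval(self) -> pd.Series:
        """Per-animal median sampling interval as Timedelta."""
        return self.data.groupby("animal_id", observed=True)["timestamp"].agg(
            lambda s: s.diff().median()
        )

    # -- manipulation ----------------------------------------------------
    def replace_data(self, data: pd.DataFrame) -> "CalorimetryFrame":
        return CalorimetryFrame(data, dict(self.header_meta))

    def equals_approx(self, other: "CalorimetryFrame", rtol: float = 1e-9) -> bool:
        """Channel-wise equality within relative tolerance.

        Compares animal ids, timestamps and every numeric channel present in
        both frames; ignores cohort/provenance columns.
        """
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        if not (a["animal_id"].to_numpy() == b["animal_id"].to_numpy()).all():
            return False
        if not (a["timestamp"].to_numpy() == b["timestamp"].to_numpy()).all():
            return False
        shared = [c for c in GAS_CHANNELS + OPTIONAL_CHANNELS
                  if c in a.columns and c in b.columns]
        for col in shared:
            x = a[col].to_numpy(dtype=float)
            y = b[col].to_numpy(dtype=float)
            both_nan = np.isnan(x) & np.isnan(y)
            close = np.isclose(x, y, rtol=rtol, atol=0.0, equal_nan=True)
            if not (close | both_nan).all():
                return False
        return True


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FrameValidationError(f"missing mandatory column(s): {missing}")
    df["animal_id"] = df["animal_id"].astype(str)
    df["cohort_id"] = df["cohort_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    for col in GAS_CHANNELS:
        df[col] = pd.to_numeric(df[col])
    for col in OPTIONAL_CHANNELS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    df = df.sort_values(["animal_id", "timestamp"], kind="mergesort")
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["animal_id", "timestamp"])
    if dup.any():
        pairs = df.loc[dup, ["animal_id", "timestamp"]].head(5).to_dict("records")
        raise FrameValidationError(f"duplicate (animal, timestamp) pairs, e.g. {pairs}")
    if df["timestamp"].isna().any():
        raise FrameValidationError("unparseable or missing timestamps present")
    # Strictly increasing within animal follows from the sort + no duplicates.
    if df[["vo2", "vco2"]].isna().all().all() and len(df):
        warnings.warn("frame carries no gas measurements at all", stacklevel=3)


def empty_frame() -> CalorimetryFrame:
    """A structurally valid frame with zero rows."""
    cols = {c: [] for c in MANDATORY_COLUMNS}
    df = pd.DataFrame(cols)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return CalorimetryFrame(df)
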