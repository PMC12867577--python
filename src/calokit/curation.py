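"""Consistency checks, outlier removal, trimming and day selection.

Checks *flag* problems (negative gas rates, over-frequent sampling,
incomplete days, implausible cage temperatures); removal only happens
through explicit corrective operations (z-score thresholding, rectangular
region removal, trimming, complete-day selection, exclusion lists,
resampling). Every operation contributes a row to the
:class:`CurationReport` so that ``rows_in − rows_out`` always reconciles
with the summed removal counts.

The full chain runs in a fixed order — checks → exclusions → outlier
removal → trim → day selection → resampling — and stamps the frame's header
metadata with a hash of the applied configuration: re-running ``curate``
with the identical configuration is a no-op, which keeps the pipeline
idempotent even though individual stages (trimming, single-pass z-scoring)
are not.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frame import CalorimetryFrame, COUNT_CHANNELS, GAS_CHANNELS
from .metadata import Photoperiod, _hours


class CurationError(ValueError):
    pass


@dataclass
class CurationConfig:
    """Tunable curation behaviour; defaults are deliberately conservative."""

    check_negative_gas: bool = True
    min_sample_interval: float = 0.0        # seconds; 0 disables the check
    enforce_complete_days: bool = False
    complete_day_min_fraction: float = 0.95
    temp_range: tuple[float, float] = (20.0, 26.0)
    z_threshold: float = 3.0
    z_scope: str = "per_animal"             # or "pooled"
    z_channels: tuple[str, ...] = ()        # empty: no automatic outlier removal
    trim_start: str | dt.timedelta = "0h"
    trim_end: str | dt.timedelta = "0h"
    day_selection: str = "zeitgeber"        # or "calendar"
    excluded_animals: tuple[str, ...] = ()
    excluded_days: tuple[str, ...] = ()     # ISO calendar dates
    drop_negative_gas: bool = False         # corrective action for the flag
    resample_interval: str | None = None    # e.g. "10min"; None disables

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise CurationError("z_threshold must be positive")
        if not 0 < self.complete_day_min_fraction <= 1:
            raise CurationError("complete_day_min_fraction must be in (0, 1]")
        if self.z_scope not in ("per_animal", "pooled"):
            raise CurationError("z_scope must be 'per_animal' or 'pooled'")
        if self.day_selection not in ("zeitgeber", "calendar"):
            raise CurationError("day_selection must be 'zeitgeber' or 'calendar'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CheckRecord:
    name: str
    n_flagged: int
    n_removed: int
    affected: list
    params: dict

    def __post_init__(self) -> None:
        if self.n_removed > self.n_flagged:
            raise CurationError(
                f"check {self.name}: removed {self.n_removed} > flagged {self.n_flagged}")


@dataclass
class CurationReport:
    """Audit trail of every enabled check/filter."""

    records: list[CheckRecord] = field(default_factory=list)

    def add(self, name: str, n_flagged: int, n_removed: int,
            affected=(), params=None) -> None:
        self.records.append(CheckRecord(name, int(n_flagged), int(n_removed),
                                        list(affected), dict(params or {})))

    @property
    def total_removed(self) -> int:
        return sum(r.n_removed for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "check": r.name,
            "n_flagged": r.n_flagged,
            "n_removed": r.n_removed,
            "affected": ";".join(map(str, r.affected)),
            "params": json.dumps(r.params, default=str, sort_keys=True),
        } for r in self.records])


# ---------------------------------------------------------------------------
# day partitioning (shared by checks, day selection, exclusions)
# ---------------------------------------------------------------------------

def day_key(timestamps: pd.Series, mode: str,
            photoperiod: Photoperiod | None) -> pd.Series:
    """Assign each timestamp to a day: zeitgeber days start at ZT0 (lights-on),
    calendar days at midnight."""
    if mode == "calendar":
        return timestamps.dt.normalize()
    if photoperiod is None:
        raise CurationError("zeitgeber day selection requires a photoperiod")
    shift = pd.Timedelta(hours=_hours(photoperiod.lights_on))
    return (timestamps - shift).dt.normalize()


def _complete_days(df: pd.DataFrame, mode: str, photoperiod,
                   min_fraction: float) -> tuple[pd.Series, list]:
    """Boolean mask of samples lying on complete days, plus the incomplete
    (animal, day) pairs. Expected samples/day = 24 h / per-animal median
    interval."""
    keep = pd.Series(False, index=df.index)
    incomplete: list[tuple[str, str]] = []
    for animal, sub in df.groupby("animal_id", observed=True):
        interval = sub["timestamp"].diff().median()
        if pd.isna(interval) or interval <= pd.Timedelta(0):
            incomplete.append((animal, "all"))
            continue
        expected = pd.Timedelta(hours=24) / interval
        days = day_key(sub["timestamp"], mode, photoperiod)
        counts = days.value_counts()
        good_days = set(counts.index[counts >= min_fraction * expected])
        keep.loc[sub.index] = days.isin(good_days)
        for d in sorted(set(counts.index) - good_days):
            incomplete.append((animal, str(pd.Timestamp(d).date())))
    return keep, incomplete


# ---------------------------------------------------------------------------
# consistency checks (flag, never remove)
# ---------------------------------------------------------------------------

def run_consistency_checks(frame: CalorimetryFrame, config: CurationConfig,
                           photoperiod: Photoperiod | None = None) -> CurationReport:
    """Run the enabled pre-defined checks; flags anomalies without removal."""
    if frame.n_rows == 0:
        raise CurationError("cannot run consistency checks on an empty frame")
    df = frame.data
    report = CurationReport()

    if config.check_negative_gas:
        mask = (df["vo2"] < 0) | (df["vco2"] < 0)
        animals = sorted(df.loc[mask, "animal_id"].unique())
        report.add("negative_gas", int(mask.sum()), 0, animals, {})

    if config.min_sample_interval > 0:
        med = frame.median_interval()
        fast = sorted(med.index[med < pd.Timedelta(seconds=config.min_sample_interval)])
        report.add("high_frequency", len(fast), 0, fast,
                   {"min_sample_interval_s": config.min_sample_interval})

    if config.enforce_complete_days:
        _, incomplete = _complete_days(
            df, config.day_selection, photoperiod, config.complete_day_min_fraction)
        report.add("complete_days", len(incomplete), 0, incomplete,
                   {"min_fraction": config.complete_day_min_fraction,
                    "mode": config.day_selection})

    if "temp_ambient" in df.columns:
        lo, hi = config.temp_range
        mask = df["temp_ambient"].notna() & (
            (df["temp_ambient"] < lo) | (df["temp_ambient"] > hi))
        report.add("temperature_range", int(mask.sum()), 0,
                   sorted(df.loc[mask, "animal_id"].unique()),
                   {"temp_range_c": list(config.temp_range)})
    return report


# ---------------------------------------------------------------------------
# corrective operations
# ---------------------------------------------------------------------------

def remove_outliers_zscore(
    frame: CalorimetryFrame, channel: str, config: CurationConfig,
) -> tuple[CalorimetryFrame, pd.DataFrame]:
    """Single-pass z-score thresholding on one channel.

    Each scope group's mean and standard deviation are computed exactly once
    on the pre-removal data (no iterative re-scoring); samples with
    ``|z| > z_threshold`` are removed. Zero-variance groups remove nothing.
    """
    df = frame.data
    if channel not in df.columns:
        raise CurationError(f"channel {channel!r} not present")
    groups = df.groupby("animal_id", observed=True) if config.z_scope == "per_animal" \
        else [(None, df)]
    drop_idx: list = []
    removed_rows: list[dict] = []
    for name, sub in groups:
        x = sub[channel].astype(float)
        if x.notna().sum() < 3:
            raise CurationError(
                f"z-score scope group {name or 'pooled'} has <3 samples")
        mu = x.mean()
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(
                f"zero variance in z-score group {name or 'pooled'}; nothing removed",
                stacklevel=2)
            continue
        z = (x - mu) / sd
        bad = z.abs() > config.z_threshold
        for idx in sub.index[bad]:
            removed_rows.append({
                "animal_id": df.loc[idx, "animal_id"],
                "timestamp": df.loc[idx, "timestamp"],
                "value": df.loc[idx, channel],
                "z": z.loc[idx],
            })
        drop_idx.extend(sub.index[bad])
    removed = pd.DataFrame(removed_rows,
                           columns=["animal_id", "timestamp", "value", "z"])
    return frame.replace_data(df.drop(index=drop_idx)), removed


def remove_region(
    frame: CalorimetryFrame, channel: str,
    time_window: tuple, value_window: tuple,
) -> tuple[CalorimetryFrame, pd.DataFrame]:
    """Programmatic equivalent of a rectangular selection: removes samples
    with timestamp in [t0, t1) and channel value in [v0, v1)."""
    t0, t1 = pd.Timestamp(time_window[0]), pd.Timestamp(time_window[1])
    v0, v1 = value_window
    if t1 < t0 or v1 < v0:
        raise CurationError("selection windows must be well-ordered")
    df = frame.data
    mask = ((df["timestamp"] >= t0) & (df["timestamp"] < t1)
            & (df[channel] >= v0) & (df[channel] < v1))
    removed = df.loc[mask, ["animal_id", "timestamp", channel]].copy()
    return frame.replace_data(df.loc[~mask]), removed


def trim_experiment(frame: CalorimetryFrame, trim_start, trim_end) -> CalorimetryFrame:
    """Drop each animal's initial/final segment (habituation and handling
    artifacts): samples within ``trim_start`` of that animal's first sample
    and within ``trim_end`` of its last."""
    ts0 = pd.Timedelta(trim_start)
    ts1 = pd.Timedelta(trim_end)
    if ts0 < pd.Timedelta(0) or ts1 < pd.Timedelta(0):
        raise CurationError("trim durations must be non-negative")
    df = frame.data
    keep = pd.Series(True, index=df.index)
    for animal, sub in df.groupby("animal_id", observed=True):
        first, last = sub["timestamp"].iloc[0], sub["timestamp"].iloc[-1]
        mask = (sub["timestamp"] >= first + ts0) & (sub["timestamp"] <= last - ts1)
        keep.loc[sub.index] = mask
        if not mask.any():
            warnings.warn(f"trim removes every sample of animal {animal!r}",
                          stacklevel=2)
    return frame.replace_data(df.loc[keep])


def select_days(
    frame: CalorimetryFrame, config: CurationConfig,
    photoperiod: Photoperiod | None = None,
    requested_days: list | None = None,
) -> CalorimetryFrame:
    """Keep only complete (and, optionally, explicitly requested) days.

    A day is complete when it holds at least ``complete_day_min_fraction``
    of the expected samples (24 h divided by the animal's median interval).
    Days start at ZT0 in zeitgeber mode, at midnight in calendar mode.
    """
    df = frame.data
    keep, _ = _complete_days(df, config.day_selection, photoperiod,
                             config.complete_day_min_fraction)
    if requested_days is not None:
        wanted = {pd.Timestamp(d).normalize() for d in requested_days}
        days = day_key(df["timestamp"], config.day_selection, photoperiod)
        keep &= days.isin(wanted)
    if not keep.any():
        raise CurationError("no complete day anywhere in the dataset")
    return frame.replace_data(df.loc[keep])


def exclude_records(
    frame: CalorimetryFrame,
    excluded_animals=(), excluded_days=(),
) -> tuple[CalorimetryFrame, int]:
    """Drop listed animals and listed (animal-agnostic) calendar days."""
    df = frame.data
    drop = df["animal_id"].isin(set(map(str, excluded_animals)))
    if excluded_days:
        dates = {pd.Timestamp(d).date() for d in excluded_days}
        drop |= df["timestamp"].dt.date.isin(dates)
    out = df.loc[~drop]
    if len(out) and out["animal_id"].nunique() == 0 or len(out) == 0:
        raise CurationError("exclusion removes every animal")
    return frame.replace_data(out), int(drop.sum())


def resample_uniform(frame: CalorimetryFrame, target_interval) -> CalorimetryFrame:
    """Aggregate to non-overlapping windows of ``target_interval`` aligned to
    each animal's first sample: intensities (gas rates, temperature) are
    averaged, per-interval amounts (activity, food, water) are summed; the
    window start becomes the new timestamp."""
    target = pd.Timedelta(target_interval)
    df = frame.data
    parts = []
    for animal, sub in df.groupby("animal_id", observed=True):
        native = sub["timestamp"].diff().median()
        if pd.notna(native) and target < native:
            raise CurationError(
                f"target interval {target} below native interval {native} "
                f"for animal {animal!r}")
        first = sub["timestamp"].iloc[0]
        bins = ((sub["timestamp"] - first) // target).astype(int)
        agg: dict[str, str] = {}
        for col in sub.columns:
            if col in GAS_CHANNELS or col == "temp_ambient":
                agg[col] = "mean"
            elif col in COUNT_CHANNELS:
                agg[col] = "sum"
            elif col not in ("animal_id", "timestamp"):
                agg[col] = "first"
        g = sub.groupby(bins).agg(agg)
        g["timestamp"] = first + g.index.to_series().map(lambda b: b * target)
        g["animal_id"] = animal
        parts.append(g.reset_index(drop=True))
    return frame.replace_data(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

def curate(
    frame: CalorimetryFrame, config: CurationConfig,
    photoperiod: Photoperiod | None = None,
) -> tuple[CalorimetryFrame, CurationReport]:
    """Run the complete curation chain in its fixed order.

    checks → exclusions → negative-gas drop (if requested) → z-score
    outlier removal → trim → complete-day selection → resampling.
    The applied configuration is stamped into the frame's header metadata;
    calling ``curate`` again with the same configuration returns the frame
    unchanged (with an empty report), making the chain idempotent.
    """
    stamp = config.config_hash()
    if frame.header_meta.get("curation_config_hash") == stamp:
        return frame, CurationReport()

    report = run_consistency_checks(frame, config, photoperiod)
    rows_in = frame.n_rows

    if config.excluded_animals or config.excluded_days:
        frame, n = exclude_records(frame, config.excluded_animals,
                                   config.excluded_days)
        report.add("exclusions", n, n,
                   list(config.excluded_animals) + list(config.excluded_days), {})

    if config.drop_negative_gas:
        df = frame.data
        mask = (df["vo2"] < 0) | (df["vco2"] < 0)
        frame = frame.replace_data(df.loc[~mask])
        report.add("drop_negative_gas", int(mask.sum()), int(mask.sum()),
                   sorted(df.loc[mask, "animal_id"].unique()), {})

    for channel in config.z_channels:
        frame, removed = remove_outliers_zscore(frame, channel, config)
        report.add(f"zscore_{channel}", len(removed), len(removed),
                   sorted(removed["animal_id"].unique()),
                   {"threshold": config.z_threshold, "scope": config.z_scope})

    ts0, ts1 = pd.Timedelta(config.trim_start), pd.Timedelta(config.trim_end)
    if ts0 > pd.Timedelta(0) or ts1 > pd.Timedelta(0):
        before = frame.n_rows
        frame = trim_experiment(frame, ts0, ts1)
        n = before - frame.n_rows
        report.add("trim", n, n, [], {"trim_start": str(ts0), "trim_end": str(ts1)})

    if config.enforce_complete_days:
        before = frame.n_rows
        frame = select_days(frame, config, photoperiod)
        n = before - frame.n_rows
        report.add("incomplete_days_removed", n, n, [],
                   {"min_fraction": config.complete_day_min_fraction,
                    "mode": config.day_selection})

    if config.resample_interval is not None:
        before = frame.n_rows
        frame = resample_uniform(frame, config.resample_interval)
        n = before - frame.n_rows
        report.add("resample", n, n, [], {"target": str(config.resample_interval)})

    assert rows_in - frame.n_rows == sum(
        r.n_removed for r in report.records), "curation report fails to reconcile"
    meta = dict(frame.header_meta)
    meta["curation_config_hash"] = stamp
    frame = CalorimetryFrame(frame.data, meta)
    return frame, report
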