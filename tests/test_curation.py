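"""Consistency checks, outlier/region removal, trimming, day selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from calokit.curation import (
    CurationConfig,
    CurationError,
    curate,
    exclude_records,
    remove_outliers_zscore,
    remove_region,
    resample_uniform,
    run_consistency_checks,
    select_days,
    trim_experiment,
)
from calokit.frame import CalorimetryFrame

from conftest import make_frame


def brute_force_zscore(df, channel, threshold, scope):
    """Independent oracle: explicit per-group mean/sd/z loop."""
    removed = []
    groups = df.groupby("animal_id") if scope == "per_animal" else [(None, df)]
    for _, sub in groups:
        x = sub[channel].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            continue
        for idx, v in zip(sub.index, x):
            if abs((v - mu) / sd) > threshold:
                removed.append(idx)
    return sorted(removed)


def test_negative_gas_check_flags_without_removing(small_frame):
    df = small_frame.data.copy()
    df.loc[3, "vo2"] = -5.0
    frame = CalorimetryFrame(df)
    report = run_consistency_checks(frame, CurationConfig())
    rec = next(r for r in report.records if r.name == "negative_gas")
    assert rec.n_flagged == 1 and rec.n_removed == 0


def test_all_clean_frame_flags_nothing():
    frame = make_frame(start="2024-01-01 00:00:00")  # one full calendar day
    config = CurationConfig(min_sample_interval=30,
                            enforce_complete_days=True,
                            day_selection="calendar")
    report = run_consistency_checks(frame, config)
    assert all(r.n_flagged == 0 for r in report.records)


def test_high_frequency_check_flags_fast_animal():
    frame = make_frame(n_samples=10, interval_min=0.5)  # 30 s sampling
    config = CurationConfig(min_sample_interval=60)
    report = run_consistency_checks(frame, config)
    rec = next(r for r in report.records if r.name == "high_frequency")
    assert set(rec.affected) == {"A1", "A2"}


def test_temperature_out_of_range_flagged():
    frame = make_frame(n_samples=4, temp_ambient=[23, 23, 35, 23])
    report = run_consistency_checks(frame, CurationConfig())
    rec = next(r for r in report.records if r.name == "temperature_range")
    assert rec.n_flagged == 2  # one bad sample in each of the 2 animals


def test_zscore_hand_example_removes_single_outlier():
    values = [10.0] * 9 + [100.0]
    frame = make_frame(n_animals=1, n_samples=10, vo2=values)
    config = CurationConfig(z_threshold=2.0)
    out, removed = remove_outliers_zscore(frame, "vo2", config)
    assert len(removed) == 1
    assert removed["value"].iloc[0] == 100.0
    # z of the outlier against the single-pass mean/sd: |z| = 2.846
    assert removed["z"].iloc[0] == pytest.approx(2.846, abs=1e-3)
    assert out.n_rows == 9


def test_zscore_infinite_threshold_removes_nothing(small_frame):
    config = CurationConfig(z_threshold=np.inf)
    out, removed = remove_outliers_zscore(small_frame, "vo2", config)
    assert out.n_rows == small_frame.n_rows and len(removed) == 0


def test_zscore_constant_channel_warns_removes_nothing():
    frame = make_frame(n_animals=1, n_samples=5, vo2=7.0)
    with pytest.warns(UserWarning, match="zero variance"):
        out, removed = remove_outliers_zscore(frame, "vo2", CurationConfig())
    assert out.n_rows == 5 and len(removed) == 0


@given(st.integers(min_value=0, max_value=2 ** 31 - 1),
       st.sampled_from(["per_animal", "pooled"]),
       st.floats(min_value=0.5, max_value=4.0))
def test_zscore_matches_brute_force_oracle(seed, scope, threshold):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 200))
    frame = make_frame(n_animals=2, n_samples=n, interval_min=5,
                       vo2=rng.normal(1000, 300, size=n))
    config = CurationConfig(z_threshold=threshold, z_scope=scope)
    out, removed = remove_outliers_zscore(frame, "vo2", config)
    expected_idx = brute_force_zscore(frame.data, "vo2", threshold, scope)
    expected = frame.data.loc[expected_idx, ["animal_id", "timestamp"]]
    assert sorted(map(tuple, expected.to_numpy())) == \
        sorted(map(tuple, removed[["animal_id", "timestamp"]].to_numpy()))
    assert frame.n_rows - out.n_rows == len(expected_idx)


def test_remove_region_rectangle_and_degenerate(small_frame):
    t0 = small_frame.data["timestamp"].iloc[2]
    t1 = small_frame.data["timestamp"].iloc[4]  # half-open: rows 2,3 per animal
    out, removed = remove_region(small_frame, "vo2", (t0, t1), (0, 2000))
    assert len(removed) == 4  # 2 samples x 2 animals
    out2, removed2 = remove_region(small_frame, "vo2", (t0, t0), (0, 2000))
    assert len(removed2) == 0 and out2.n_rows == small_frame.n_rows
    out3, removed3 = remove_region(
        small_frame, "vo2",
        (small_frame.data["timestamp"].min(),
         small_frame.data["timestamp"].max() + pd.Timedelta("1h")),
        (-np.inf, np.inf))
    assert out3.n_rows == 0 and len(removed3) == small_frame.n_rows


def test_trim_72h_trace_keeps_middle_48h():
    frame = make_frame(n_animals=1, n_samples=72, interval_min=60)
    out = trim_experiment(frame, "12h", "12h")
    # hand count: drop ts < first+12h (12 samples) and ts > last-12h (12)
    assert out.n_rows == 48
    assert out.data["timestamp"].min() == frame.data["timestamp"].min() + pd.Timedelta("12h")


def test_trim_zero_is_identity(small_frame):
    out = trim_experiment(small_frame, "0h", "0h")
    assert out.equals_approx(small_frame)


def test_trim_longer_than_trace_warns_empty_animal():
    frame = make_frame(n_animals=1, n_samples=4, interval_min=60)
    with pytest.warns(UserWarning, match="A1"):
        out = trim_experiment(frame, "10h", "0h")
    assert out.n_rows == 0


def _three_day_frame():
    """Day 1 half (12:00-24:00), day 2 full, day 3 half (00:00-12:00)."""
    ts = pd.date_range("2024-01-01 12:00", "2024-01-03 12:00",
                       freq="1h", inclusive="left")
    df = pd.DataFrame({"animal_id": "A1", "cohort_id": "c", "timestamp": ts,
                       "vo2": 1000.0, "vco2": 800.0})
    return CalorimetryFrame(df)


def test_select_days_keeps_only_the_complete_middle_day():
    frame = _three_day_frame()
    config = CurationConfig(day_selection="calendar",
                            complete_day_min_fraction=0.95)
    out = select_days(frame, config)
    days = out.data["timestamp"].dt.normalize().unique()
    assert list(pd.to_datetime(days)) == [pd.Timestamp("2024-01-02")]
    assert out.n_rows == 24


def test_select_days_tiny_fraction_keeps_all():
    frame = _three_day_frame()
    config = CurationConfig(day_selection="calendar",
                            complete_day_min_fraction=1e-9)
    out = select_days(frame, config)
    assert out.n_rows == frame.n_rows


def test_select_days_zeitgeber_boundary_splits_at_lights_on(photoperiod):
    ts = pd.date_range("2024-01-02 06:00", "2024-01-02 08:00", freq="30min")
    df = pd.DataFrame({"animal_id": "A1", "cohort_id": "c", "timestamp": ts,
                       "vo2": 1.0, "vco2": 1.0})
    from calokit.curation import day_key
    keys = day_key(df["timestamp"], "zeitgeber", photoperiod)
    # hand assignment: 06:00, 06:30 precede ZT0 (07:00) -> previous ZT day
    assert keys.tolist() == [pd.Timestamp("2024-01-01")] * 2 + \
        [pd.Timestamp("2024-01-02")] * 3


def test_select_days_nothing_complete_errors():
    frame = make_frame(n_animals=1, n_samples=6, interval_min=60)
    config = CurationConfig(day_selection="calendar",
                            complete_day_min_fraction=0.95)
    with pytest.raises(CurationError, match="no complete day"):
        select_days(frame, config)


def test_exclude_animals_and_days():
    frame = make_frame(n_animals=3, n_samples=24)  # spans into 2024-01-02
    out, n = exclude_records(frame, excluded_animals=["A2"])
    assert out.animals == ["A1", "A3"] and n == 24
    out2, n2 = exclude_records(frame, excluded_days=["2024-01-01"])
    # hand count: 17 samples/animal fall on Jan 1 (07:00..23:00)
    assert n2 == 17 * 3
    assert out2.n_rows == frame.n_rows - n2
    with pytest.raises(CurationError, match="every animal"):
        exclude_records(frame, excluded_animals=["A1", "A2", "A3"])


def test_resample_ramp_means_and_count_sums():
    frame = make_frame(n_animals=1, n_samples=60, interval_min=1,
                       vo2=np.arange(60.0), activity_x=1.0, activity_y=0.0)
    out = resample_uniform(frame, "10min")
    assert out.n_rows == 6
    # hand averaging of the 0..59 ramp in 10-sample windows
    assert out.data["vo2"].tolist() == [4.5, 14.5, 24.5, 34.5, 44.5, 54.5]
    # counts are summed: 1 per minute -> 10 per window
    assert out.data["activity_x"].tolist() == [10.0] * 6


def test_resample_native_interval_is_identity(small_frame):
    out = resample_uniform(small_frame, "60min")
    assert out.equals_approx(small_frame)


def test_resample_below_native_interval_errors(small_frame):
    with pytest.raises(CurationError, match="below native"):
        resample_uniform(small_frame, "30min")


def test_full_chain_reconciles_and_is_idempotent():
    rng = np.random.default_rng(7)
    frame = make_frame(n_animals=2, n_samples=72, interval_min=60,
                       vo2=rng.normal(1000, 100, size=72))
    config = CurationConfig(z_channels=("vo2",), z_threshold=2.0,
                            trim_start="2h", trim_end="2h")
    out, report = curate(frame, config)
    assert frame.n_rows - out.n_rows == report.total_removed
    again, report2 = curate(out, config)
    assert again.equals_approx(out)
    assert report2.total_removed == 0
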