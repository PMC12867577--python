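"""Seeded generator of synthetic calorimetry cohorts with known ground truth.

The simulated animal follows the structure the downstream analyses are
sensitive to: a resting plateau (``rmr``), a circadian dark-phase increment
smoothed over the light/dark transitions, exponentially decaying activity
bursts confined to the dark phase, and iid Gaussian measurement noise:

    EE_true(t) = rmr + dark_increment · s(t) + Σ bursts(t) + ε_t

with ``s(t)`` a dark indicator ramped linearly over ``transition_minutes``.
RER interpolates between a light- and a dark-phase value along the same
indicator, and gases are obtained by inverting the Heldmaier equation:
V̇O2 = EE·1000/3.6/(4.44 + 1.43·RER), V̇CO2 = RER·V̇O2 — so recomputing EE
from the generated gases reproduces EE_true exactly.

Seeding is hierarchical (cohort → animal → channel) via
``numpy.random.SeedSequence`` so adding an animal never perturbs the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dialects import DialectSpec, REGISTRY, unrepresentable_channels, write_dialect_file
from .energetics import HELDMAIER_INTERCEPT, HELDMAIER_SLOPE, MW_TO_KJ_PER_H
from .frame import CalorimetryFrame
from .metadata import MetadataTable, Photoperiod


class SimulationError(ValueError):
    pass


@dataclass
class AnimalSimParams:
    """Ground-truth parameters of one simulated animal (mouse-scale defaults)."""

    rmr: float = 8.0               # kJ/h resting plateau
    dark_increment: float = 6.0    # kJ/h added in the dark phase
    burst_rate: float = 1.0        # activity events per dark hour
    burst_amplitude: float = 4.0   # kJ/h at event onset
    burst_decay: float = 15.0      # minutes, exponential decay constant
    rer_light: float = 0.80
    rer_dark: float = 0.95
    noise_sd: float = 0.16         # kJ/h (2% of the default RMR)
    sampling_interval: float = 5.0  # minutes
    n_days: int = 3
    body_mass: float = 25.0        # g
    transition_minutes: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rmr <= 0:
            raise SimulationError("rmr must be positive")
        for r in (self.rer_light, self.rer_dark):
            if not 0.5 <= r <= 1.3:
                raise SimulationError("rer values must lie in [0.5, 1.3]")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if self.sampling_interval <= 0 or self.n_days < 1:
            raise SimulationError("invalid sampling grid")


@dataclass
class CohortSimParams:
    """Two-group cohort: group B's RMR is shifted by ``group_effect`` and every
    animal's RMR scales with body mass around the cohort mean."""

    n_per_group: int = 8
    group_effect: float = 0.0      # kJ/h added to group B
    mass_slope: float = 0.2        # kJ/h per g of body mass
    mass_mean: float = 25.0        # g
    mass_sd: float = 2.0           # g
    animal_sd: float = 0.3         # kJ/h between-animal RMR jitter
    photoperiod: Photoperiod = field(default_factory=Photoperiod)
    template: AnimalSimParams = field(default_factory=AnimalSimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SimulationError("n_per_group must be at least 2")


def _dark_indicator(zt: np.ndarray, dark_onset: float, tau_h: float) -> np.ndarray:
    """Smoothed dark indicator on the ZT axis: ramps up after dark onset and
    back down after lights-on, linearly over ``tau_h`` hours."""
    s = np.zeros_like(zt)
    if tau_h <= 0:
        return np.where(zt >= dark_onset, 1.0, 0.0)
    s = np.where(zt < tau_h, 1.0 - zt / tau_h, s)
    ramp = (zt - dark_onset) / tau_h
    s = np.where((zt >= dark_onset) & (zt < dark_onset + tau_h),
                 np.minimum(ramp, 1.0), s)
    s = np.where(zt >= dark_onset + tau_h, 1.0, s)
    return s


def simulate_animal(
    params: AnimalSimParams,
    photoperiod: Photoperiod | None = None,
    animal_id: str = "A1",
    cohort_id: str = "sim",
    start: str | pd.Timestamp | None = None,
) -> tuple[CalorimetryFrame, dict]:
    """Simulate one animal; returns the frame and its ground-truth record."""
    photoperiod = photoperiod or Photoperiod()
    if start is None:
        start = pd.Timestamp("2024-01-01").normalize() + pd.Timedelta(
            hours=photoperiod.lights_on.hour, minutes=photoperiod.lights_on.minute)
    start = pd.Timestamp(start)

    ss = np.random.SeedSequence(params.seed)
    rng_noise, rng_burst, rng_act, rng_food, rng_water = (
        np.random.default_rng(c) for c in ss.spawn(5))

    n = int(round(params.n_days * 24 * 60 / params.sampling_interval))
    t_hours = np.arange(n) * params.sampling_interval / 60.0
    # whole-second grid: instruments log at second resolution
    timestamps = start + pd.to_timedelta(
        np.round(t_hours * 3600.0).astype("int64"), unit="s")
    zt = t_hours % 24.0  # start is at lights-on, so ZT == hours mod 24
    dark_onset = photoperiod.dark_onset_zt
    tau_h = params.transition_minutes / 60.0
    s = _dark_indicator(zt, dark_onset, tau_h)

    # dark-phase activity bursts with exponential decay
    burst_ee = np.zeros(n)
    dark_hours_per_day = 24.0 - dark_onset
    for day in range(params.n_days):
        n_events = rng_burst.poisson(params.burst_rate * dark_hours_per_day)
        event_zts = rng_burst.uniform(dark_onset, 24.0, size=n_events)
        for ez in np.sort(event_zts):
            et = day * 24.0 + ez
            mask = t_hours >= et
            burst_ee[mask] += params.burst_amplitude * np.exp(
                -(t_hours[mask] - et) * 60.0 / params.burst_decay)

    eps = rng_noise.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 \
        else np.zeros(n)
    ee = params.rmr + params.dark_increment * s + burst_ee + eps
    if (ee <= 0).any():
        raise SimulationError("simulated EE fell to zero or below; reduce noise")
    rer = params.rer_light + (params.rer_dark - params.rer_light) * s
    vo2 = ee / ((HELDMAIER_INTERCEPT + HELDMAIER_SLOPE * rer) * MW_TO_KJ_PER_H)
    vco2 = rer * vo2

    activity_mean = 2.0 + 5.0 * burst_ee  # counts per interval, burst-driven
    activity_x = rng_act.poisson(activity_mean).astype(float)
    activity_y = rng_act.poisson(activity_mean).astype(float)
    food = np.where(s > 0.5, rng_food.poisson(0.3, size=n), 0) * 0.05  # g
    water = np.where(s > 0.5, rng_water.poisson(0.4, size=n), 0) * 0.05  # g

    data = pd.DataFrame({
        "animal_id": animal_id,
        "cohort_id": cohort_id,
        "timestamp": timestamps,
        "vo2": vo2,
        "vco2": vco2,
        "activity_x": activity_x,
        "activity_y": activity_y,
        "food": food,
        "water": water,
        "temp_ambient": 23.0,
    })
    truth = {
        "animal_id": animal_id,
        "rmr": params.rmr,
        "dark_increment": params.dark_increment,
        "rer_light": params.rer_light,
        "rer_dark": params.rer_dark,
        "body_mass": params.body_mass,
        "ee_true": ee,
        "mean_ee_true": float(ee.mean()),
    }
    return CalorimetryFrame(data), truth


def _draw_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Per-animal ground-truth draw shared by the time-series and the
    summary-level cohort simulators."""
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    for group in ("A", "B"):
        for i in range(params.n_per_group):
            mass = rng.normal(params.mass_mean, params.mass_sd)
            jitter = rng.normal(0.0, params.animal_sd)
            rmr = (params.template.rmr
                   + (params.group_effect if group == "B" else 0.0)
                   + params.mass_slope * (mass - params.mass_mean)
                   + jitter)
            rows.append({
                "animal_id": f"{group}{i + 1:02d}",
                "group": group,
                "body_mass": mass,
                "rmr_true": rmr,
            })
    return pd.DataFrame(rows)


def simulate_cohort(
    params: CohortSimParams, cohort_id: str = "cohort1",
) -> tuple[CalorimetryFrame, MetadataTable, pd.DataFrame]:
    """Simulate a full two-group cohort with per-sample time series."""
    truth = _draw_cohort(params)
    animal_seeds = np.random.SeedSequence(params.seed).spawn(len(truth) + 1)[1:]
    frames = []
    for (_, row), aseed in zip(truth.iterrows(), animal_seeds):
        ap = replace(params.template,
                     rmr=float(row["rmr_true"]),
                     body_mass=float(row["body_mass"]),
                     seed=int(aseed.generate_state(1)[0] % (2 ** 31)))
        fr, _ = simulate_animal(ap, params.photoperiod,
                                animal_id=row["animal_id"], cohort_id=cohort_id)
        frames.append(fr.data)
    frame = CalorimetryFrame(pd.concat(frames, ignore_index=True))
    meta = MetadataTable(
        truth[["animal_id", "group", "body_mass"]].assign(cohort_id=cohort_id),
        photoperiod=params.photoperiod)
    return frame, meta, truth


def simulate_cohort_summary(params: CohortSimParams) -> pd.DataFrame:
    """Summary-level shortcut: the per-animal analysis table implied by the
    cohort draw (response = true per-animal RMR), for statistical
    calibration at scale without generating time series."""
    truth = _draw_cohort(params)
    return truth.rename(columns={"rmr_true": "response"})


def write_fixture(frame: CalorimetryFrame, dialect: DialectSpec | str, path) -> list:
    """Write a frame as files conforming exactly to a registered dialect.

    Returns the list of files written. Channels the dialect cannot represent
    are dropped from the file with a warning.
    """
    from pathlib import Path
    if isinstance(dialect, str):
        dialect = REGISTRY[dialect]
    path = Path(path)
    dropped = unrepresentable_channels(frame, dialect)
    if dropped:
        warnings.warn(
            f"dialect {dialect.name!r} cannot represent channel(s) {dropped}; "
            "dropped from the file", stacklevel=2)
    written = []
    if dialect.per_animal_files:
        path.mkdir(parents=True, exist_ok=True)
        for animal, sub in frame.data.groupby("animal_id", observed=True):
            f = path / f"{animal}.csv"
            write_dialect_file(sub, dialect, f, header_meta=frame.header_meta,
                               subject=str(animal))
            written.append(f)
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = dict(frame.header_meta)
        meta.setdefault("cohort", frame.data["cohort_id"].iloc[0]
                        if len(frame.data) else "sim")
        write_dialect_file(frame.data, dialect, path, header_meta=meta)
        written.append(path)
    return written
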