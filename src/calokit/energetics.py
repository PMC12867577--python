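"""Energy expenditure, RER, RMR/AEE, substrate oxidation, activity maps.

Energy expenditure is reconstructed from gas exchange with the Heldmaier
caloric-equivalent equation

    EE [kJ/h] = (4.44 + 1.43 · RER) · V̇O2 [ml/h] · 3.6 / 1000

where ``4.44 + 1.43·RER`` is the caloric equivalent of oxygen in mW per
(ml O2/h) and 3.6/1000 converts mW to kJ/h. A Weir-type alternative is
registered alongside it. Resting metabolic rate is extracted from the
low-variability segments of the EE trace: a window of fixed length slides
over the series sample-by-sample, and among windows whose coefficient of
variation stays below a threshold the one with the smallest mean defines
RMR. When no window is calm enough the mean of the lowest percentile of EE
samples serves as a fallback. Activity energy expenditure is the remainder
AEE = TEE − 24·RMR of total daily EE.

Substrate oxidation uses Frayn-type non-protein stoichiometry:
fat  = 1.67·(V̇O2 − V̇CO2)   [g/h, gases in l/h]
cho  = 4.55·V̇CO2 − 3.21·V̇O2
Negative rates (RER outside the non-protein range) are flagged, never
clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frame import CalorimetryFrame, COUNT_CHANNELS
from .metadata import Photoperiod, phase_of, zeitgeber_time

# Heldmaier caloric equivalent: mW per (ml O2 / h), linear in RER.
HELDMAIER_INTERCEPT = 4.44
HELDMAIER_SLOPE = 1.43
MW_TO_KJ_PER_H = 3.6 / 1000.0

# Frayn-type non-protein stoichiometric coefficients, g per litre of gas.
FRAYN_FAT_COEF = 1.67          # · (VO2 − VCO2)
FRAYN_CHO_VCO2 = 4.55
FRAYN_CHO_VO2 = 3.21

# Oxidation energy densities used for the closure consistency check, kJ/g.
ENERGY_DENSITY_FAT = 39.6
ENERGY_DENSITY_CHO = 16.7

# Physiological flagging band for RER (never a filter).
RER_BAND = (0.5, 1.3)

# kcal -> kJ
_KCAL = 4.184


class EnergeticsError(ValueError):
    pass


def _ee_heldmaier(vo2, rer):
    return (HELDMAIER_INTERCEPT + HELDMAIER_SLOPE * rer) * vo2 * MW_TO_KJ_PER_H


def _ee_weir(vo2, rer):
    # Weir (1949): kcal/h = 3.941·VO2[l/h] + 1.106·VCO2[l/h]; VCO2 = RER·VO2.
    return (3.941 * vo2 / 1000.0 + 1.106 * rer * vo2 / 1000.0) * _KCAL


#: Registry of caloric-equivalent equations: name -> f(vo2_mlh, rer) -> kJ/h.
EE_EQUATIONS = {
    "heldmaier": _ee_heldmaier,
    "weir": _ee_weir,
}


def compute_rer(vo2, vco2):
    """Respiratory exchange ratio V̇CO2/V̇O2 with a physiological-range flag.

    Returns ``(rer, flag)``; ``rer`` is NaN (and flagged) where vo2 <= 0.
    Scalar or array inputs.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(vo2 > 0, vco2 / vo2, np.nan)
    flag = ~((rer >= RER_BAND[0]) & (rer <= RER_BAND[1]))
    if rer.ndim == 0:
        return float(rer), bool(flag)
    return rer, flag


def compute_ee(vo2, rer, equation: str = "heldmaier"):
    """Energy expenditure in kJ/h from V̇O2 (ml/h) and RER."""
    if equation not in EE_EQUATIONS:
        raise EnergeticsError(
            f"unknown equation {equation!r}; registered: {sorted(EE_EQUATIONS)}")
    vo2 = np.asarray(vo2, dtype=float)
    rer = np.asarray(rer, dtype=float)
    ee = EE_EQUATIONS[equation](vo2, rer)
    if ee.ndim == 0:
        return float(ee)
    return ee


def substrate_oxidation(vo2, vco2):
    """Fat and carbohydrate oxidation rates in g/h (gases in ml/h).

    Returns ``(fat_ox, cho_ox, flag)`` where ``flag`` marks physiologically
    impossible negative rates (left unclamped).
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    fat = FRAYN_FAT_COEF * (vo2 - vco2) / 1000.0
    cho = (FRAYN_CHO_VCO2 * vco2 - FRAYN_CHO_VO2 * vo2) / 1000.0
    flag = (fat < 0) | (cho < 0)
    if fat.ndim == 0:
        return float(fat), float(cho), bool(flag)
    return fat, cho, flag


def energy_trace(frame: CalorimetryFrame, photoperiod: Photoperiod,
                 equation: str = "heldmaier") -> pd.DataFrame:
    """Per-sample derived series: ZT, phase, RER, EE, substrate oxidation.

    Covariate channels of the input frame are carried along so photoperiod
    aggregation can sum them.
    """
    df = frame.data.copy()
    zt = zeitgeber_time(df["timestamp"], photoperiod)
    df["zt"] = zt
    df["phase"] = phase_of(zt, photoperiod)
    rer, rer_flag = compute_rer(df["vo2"].to_numpy(), df["vco2"].to_numpy())
    df["rer"] = rer
    df["rer_flag"] = rer_flag
    df["ee"] = compute_ee(df["vo2"].to_numpy(), rer, equation)
    fat, cho, sub_flag = substrate_oxidation(df["vo2"].to_numpy(),
                                             df["vco2"].to_numpy())
    df["fat_ox"] = fat
    df["cho_ox"] = cho
    df["substrate_flag"] = sub_flag
    return df


# ---------------------------------------------------------------------------
# resting metabolic rate
# ---------------------------------------------------------------------------

@dataclass
class RMRConfig:
    """Parameters of the variability-based RMR extraction."""

    window_length: float = 30.0      # minutes
    cov_threshold: float = 0.05      # CoV = sd/mean within a window
    fallback_percentile: float = 0.05
    restrict_phase: str | None = None  # "light" | "dark" | None

    def __post_init__(self) -> None:
        if self.cov_threshold <= 0:
            raise EnergeticsError("cov_threshold must be positive")
        if not 0 < self.fallback_percentile <= 1:
            raise EnergeticsError("fallback_percentile must be in (0, 1]")
        if self.restrict_phase not in (None, "light", "dark"):
            raise EnergeticsError("restrict_phase must be light, dark or None")


def _rmr_one_animal(sub: pd.DataFrame, config: RMRConfig):
    ee_all = sub["ee"].to_numpy(dtype=float)
    tee = 24.0 * float(np.nanmean(ee_all))

    series = sub
    if config.restrict_phase is not None:
        series = sub[sub["phase"] == config.restrict_phase]
    ts = series["timestamp"].reset_index(drop=True)
    ee = series["ee"].reset_index(drop=True).astype(float)
    interval = ts.diff().median()
    if pd.isna(interval) or interval <= pd.Timedelta(0):
        raise EnergeticsError("cannot infer sampling interval")
    window = pd.Timedelta(minutes=config.window_length)
    if window < 3 * interval:
        raise EnergeticsError(
            f"window_length {window} shorter than 3x sampling interval {interval}")
    span = ts.iloc[-1] - ts.iloc[0]
    if span < 2 * window:
        raise EnergeticsError(
            f"trace span {span} shorter than twice the window {window}")
    k = int(round(window / interval))

    mean = ee.rolling(k).mean()
    sd = ee.rolling(k).std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sd / mean
    # disqualify windows whose samples are not contiguous in time
    width = ts.diff(k - 1)
    contiguous = width <= (k - 1) * interval * 1.5
    ok = (cov <= config.cov_threshold) & contiguous & mean.notna()
    if ok.any():
        means = mean[ok]
        i_end = means.idxmin()
        rmr = float(means.loc[i_end])
        window_start = ts.iloc[i_end - k + 1]
        method = "cov_window"
    else:
        n_low = max(1, int(np.ceil(config.fallback_percentile * len(ee))))
        rmr = float(np.sort(ee.to_numpy())[:n_low].mean())
        window_start = pd.NaT
        method = "percentile_fallback"

    aee = tee - 24.0 * rmr
    if aee < 0:
        warnings.warn(
            f"negative AEE ({aee:.3g} kJ/day) for animal "
            f"{sub['animal_id'].iloc[0]!r}: RMR exceeds mean EE", stacklevel=3)
    return {
        "animal_id": sub["animal_id"].iloc[0],
        "rmr": rmr,
        "window_start": window_start,
        "method_used": method,
        "tee": tee,
        "aee": aee,
        "aee_negative": aee < 0,
    }


def estimate_rmr(trace: pd.DataFrame, config: RMRConfig | None = None) -> pd.DataFrame:
    """Per-animal RMR (kJ/h), TEE and AEE (kJ/day) from an energy trace.

    The trace must come from :func:`energy_trace` (needs ``ee`` and
    ``phase``). TEE is 24x the mean EE of the supplied (already
    day-selected) trace; AEE = TEE − 24·RMR, negative values flagged.
    """
    config = config or RMRConfig()
    rows = [
        _rmr_one_animal(sub.reset_index(drop=True), config)
        for _, sub in trace.groupby("animal_id", observed=True)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiles and aggregates
# ---------------------------------------------------------------------------

def windowed_profile(trace: pd.DataFrame, window_hours: float = 1.0,
                     statistic: str = "mean", channel: str = "ee") -> pd.DataFrame:
    """Tumbling-window profile over zeitgeber time, folded across days.

    Returns one row per (animal, window) with the window-start ZT and the
    requested statistic of the channel; empty windows are simply absent.
    """
    if statistic not in ("mean", "min"):
        raise EnergeticsError("statistic must be 'mean' or 'min'")
    df = trace[["animal_id", "zt", channel]].dropna(subset=[channel])
    bins = np.floor(df["zt"] / window_hours).astype(int)
    grouped = df.groupby(["animal_id", bins], observed=True)[channel]
    out = (grouped.mean() if statistic == "mean" else grouped.min()).reset_index()
    out = out.rename(columns={"zt": "window", channel: "value"})
    out["zt_start"] = out["window"] * window_hours
    return out[["animal_id", "zt_start", "value"]]


def aggregate_photoperiod(trace: pd.DataFrame) -> pd.DataFrame:
    """Light/dark summary per animal: mean EE and RER, summed food, water
    and activity (when those channels exist)."""
    agg: dict[str, tuple[str, str]] = {
        "ee_mean": ("ee", "mean"),
        "rer_mean": ("rer", "mean"),
    }
    for ch in COUNT_CHANNELS:
        if ch in trace.columns:
            agg[f"{ch}_sum"] = (ch, "sum")
    out = trace.groupby(["animal_id", "phase"], observed=True).agg(**agg)
    return out.reset_index()


def locomotion_density(frame: CalorimetryFrame, bins: tuple[int, int] = (10, 10)):
    """Per-animal occupancy histogram of the (activity_x, activity_y) plane,
    normalised to unit mass.

    Each sample with any beam-break activity contributes one count at its
    (x, y) coordinate; inactive samples carry no mass. Returns
    ``{animal_id: (hist, x_edges, y_edges)}``.
    """
    df = frame.data
    for ch in ("activity_x", "activity_y"):
        if ch not in df.columns:
            raise EnergeticsError(f"activity channel {ch!r} absent")
    out = {}
    for animal, sub in df.groupby("animal_id", observed=True):
        x = sub["activity_x"].to_numpy(dtype=float)
        y = sub["activity_y"].to_numpy(dtype=float)
        w = ((x + y) > 0).astype(float)
        if w.sum() <= 0:
            raise EnergeticsError(f"animal {animal!r} has no activity")
        # degenerate ranges: pad so a single position still forms one bin
        def _edges(v, n):
            lo, hi = np.nanmin(v), np.nanmax(v)
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            return np.linspace(lo, hi, n + 1)
        hist, xe, ye = np.histogram2d(
            x, y, bins=[_edges(x, bins[0]), _edges(y, bins[1])], weights=w)
        hist = hist / hist.sum()
        out[animal] = (hist, xe, ye)
    return out
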