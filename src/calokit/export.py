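"""Standardized, re-ingestable exports and static figures.

Tables go out as UTF-8 CSV with ISO-8601 timestamps and "." decimals so
every export re-imports losslessly; consolidated bundles go to a
multi-sheet XLSX workbook; figures render deterministically to SVG/PDF/PNG
via the matplotlib Agg backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd

from .curation import CurationReport
from .frame import CalorimetryFrame, MANDATORY_COLUMNS
from .metadata import HarmonizationMap, MetadataTable
from .synthetic import write_fixture

_FLOAT_FMT = "%.12g"
FIGURE_KINDS = ("timeseries", "box", "bar", "density_map", "profile", "silhouette")


class ExportError(ValueError):
    pass


@dataclass
class ExportBundle:
    """Everything one analysis run produced, ready for serialization."""

    frame: CalorimetryFrame
    energy_trace: pd.DataFrame | None = None
    rmr_results: pd.DataFrame | None = None
    stats_tables: dict = field(default_factory=dict)
    curation_report: CurationReport | None = None
    harmonization_map: HarmonizationMap | None = None
    metadata: MetadataTable | None = None
    config_snapshot: dict = field(default_factory=dict)


def write_long_csv(obj, path: str | Path) -> Path:
    """Serialise any tabular artifact (frame, trace, report, ...) to CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, CalorimetryFrame):
        df = obj.data
    elif isinstance(obj, CurationReport):
        df = obj.to_frame()
    elif isinstance(obj, MetadataTable):
        df = obj.data
    elif isinstance(obj, HarmonizationMap):
        df = obj.entries
    else:
        df = obj
    df.to_csv(path, index=False, float_format=_FLOAT_FMT,
              date_format="%Y-%m-%dT%H:%M:%S")
    return path


def read_long_csv(path: str | Path, as_frame: bool = False):
    """Inverse of :func:`write_long_csv` for canonical tables."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col == "timestamp" or col == "window_start":
            df[col] = pd.to_datetime(df[col])
    if as_frame:
        return CalorimetryFrame(df)
    return df


def write_calr_csv(frame: CalorimetryFrame, path: str | Path) -> Path:
    """Export in the repo's documented ``calr_csv`` interchange dialect; the
    ingest reader recovers the frame from it."""
    missing = [c for c in MANDATORY_COLUMNS
               if c not in frame.data.columns]
    if missing:
        raise ExportError(f"frame lacks mandatory channel(s): {missing}")
    write_fixture(frame, "calr_csv", path)
    return Path(path)


def write_consolidated_workbook(bundle: ExportBundle, path: str | Path) -> Path:
    """One XLSX workbook: Data, EnergyTrace, RMR, Stats, Curation, Metadata,
    Config sheets."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pd.ExcelWriter(path, engine="openpyxl") as xw:
        bundle.frame.data.to_excel(xw, sheet_name="Data", index=False)
        if bundle.energy_trace is not None:
            bundle.energy_trace.to_excel(xw, sheet_name="EnergyTrace", index=False)
        if bundle.rmr_results is not None:
            bundle.rmr_results.to_excel(xw, sheet_name="RMR", index=False)
        if bundle.stats_tables:
            pd.concat(
                [t.assign(table=name) for name, t in bundle.stats_tables.items()],
                ignore_index=True,
            ).to_excel(xw, sheet_name="Stats", index=False)
        if bundle.curation_report is not None:
            bundle.curation_report.to_frame().to_excel(
                xw, sheet_name="Curation", index=False)
        if bundle.metadata is not None:
            bundle.metadata.data.to_excel(xw, sheet_name="Metadata", index=False)
        cfg = pd.DataFrame(
            {"key": list(bundle.config_snapshot),
             "value": [json.dumps(v, default=str)
                       for v in bundle.config_snapshot.values()]})
        cfg.to_excel(xw, sheet_name="Config", index=False)
    return path


def render_text_report(result, assumptions=None) -> str:
    """Plain-text model report with assumption check-marks and starred
    post-hoc contrasts."""
    assumptions = assumptions or result.assumptions
    lines = [f"Model: {result.spec.formula()}", ""]
    lines.append(result.model_table.to_string(index=False))
    if assumptions is not None:
        def mark(passed):
            return "n/a" if passed is None else ("✓" if passed else "✗")
        lines += ["", "Assumptions (alpha = 0.05):",
                  f"  Shapiro-Wilk residual normality: {mark(assumptions.shapiro_passed)}"
                  + (f" (p={assumptions.shapiro_p:.4g})" if assumptions.shapiro_p is not None else ""),
                  f"  Levene variance homogeneity:     {mark(assumptions.levene_passed)}"
                  + (f" (p={assumptions.levene_p:.4g})" if assumptions.levene_p is not None else "")]
    if result.posthoc_table is not None and len(result.posthoc_table):
        lines += ["", f"Post-hoc ({result.correction}):",
                  result.posthoc_table.to_string(index=False)]
    return "\n".join(lines) + "\n"


def render_figure(kind: str, data, path: str | Path, **kwargs) -> Path:
    """Render one static figure. ``data`` depends on the kind:

    - timeseries / silhouette: energy trace (per-animal EE over time)
    - box / bar: per-animal analysis table with ``group`` and value columns
    - density_map: output of :func:`calokit.energetics.locomotion_density`
    - profile: output of :func:`calokit.energetics.windowed_profile`
    """
    if kind not in FIGURE_KINDS:
        raise ExportError(f"unknown figure kind {kind!r}; known: {FIGURE_KINDS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    value = kwargs.get("value", "ee")

    if kind in ("timeseries", "silhouette"):
        animals = sorted(data["animal_id"].unique())
        n = len(animals)
        fig, axes = plt.subplots(n if kind == "silhouette" else 1, 1,
                                 figsize=(8, 2 * n if kind == "silhouette" else 4),
                                 sharex=True, squeeze=False)
        if kind == "timeseries":
            ax = axes[0][0]
            for animal in animals:
                sub = data[data["animal_id"] == animal]
                ax.plot(sub["timestamp"], sub[value], lw=0.8, label=str(animal))
            ax.set_ylabel(f"{value}")
            ax.legend(fontsize=6)
        else:
            for ax_row, animal in zip(axes, animals):
                sub = data[data["animal_id"] == animal]
                ax_row[0].fill_between(sub["timestamp"], sub[value], alpha=0.6)
                ax_row[0].set_ylabel(str(animal), fontsize=7)
        fig = plt.gcf()
    elif kind in ("box", "bar"):
        groups = sorted(data[kwargs.get("group", "group")].astype(str).unique())
        series = [data.loc[data[kwargs.get("group", "group")].astype(str) == g,
                           value].to_numpy(dtype=float) for g in groups]
        fig, ax = plt.subplots(figsize=(4, 4))
        if kind == "box":
            ax.boxplot(series, tick_labels=groups)
        else:
            means = [np.mean(s) for s in series]
            sems = [np.std(s, ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0
                    for s in series]
            ax.bar(groups, means, yerr=sems, capsize=4)
        stars = kwargs.get("stars")
        if stars:
            ax.set_title(stars)
        ax.set_ylabel(value)
    elif kind == "density_map":
        animals = sorted(data)
        fig, axes = plt.subplots(1, len(animals), figsize=(3 * len(animals), 3),
                                 squeeze=False)
        for ax, animal in zip(axes[0], animals):
            hist, xe, ye = data[animal]
            ax.imshow(hist.T, origin="lower", aspect="auto",
                      extent=(xe[0], xe[-1], ye[0], ye[-1]))
            ax.set_title(str(animal), fontsize=8)
    else:  # profile
        fig, ax = plt.subplots(figsize=(6, 4))
        for animal, sub in data.groupby("animal_id", observed=True):
            ax.step(sub["zt_start"], sub["value"], where="post", label=str(animal))
        ax.set_xlabel("zeitgeber time [h]")
        ax.set_ylabel("value")
        ax.legend(fontsize=6)

    fig.savefig(path, dpi=kwargs.get("dpi", 120))
    plt.close(fig)
    return path
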