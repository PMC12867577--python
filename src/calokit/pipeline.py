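"""End-to-end analysis pipeline driven by a single YAML-style config.

Stages run in the fixed workflow order — ingest → metadata → curation →
energetics → statistics → export — each logging its parameters and row
counts. Identical config + inputs yield byte-identical table outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curation as cur
from . import energetics as en
from . import export as ex
from . import ingest
from . import metadata as md
from . import stats as st

log = logging.getLogger("calokit")


class ConfigError(ValueError):
    """Config/schema violation (CLI exit code 2)."""


class DataError(ValueError):
    """Data-level failure inside a stage (CLI exit code 3)."""


_TOP_LEVEL_KEYS = {
    "inputs", "metadata", "synonyms", "photoperiod", "curation", "rmr",
    "equation", "model", "posthoc", "export", "seed",
}


@dataclass
class PipelineConfig:
    """Validated analysis configuration (see ``calokit defaults`` for the
    full schema with defaults)."""

    inputs: list[dict]
    metadata: str | None = None
    synonyms: str | None = None
    photoperiod: dict | None = None
    curation: dict = field(default_factory=dict)
    rmr: dict = field(default_factory=dict)
    equation: str = "heldmaier"
    model: dict | None = None
    posthoc: dict = field(default_factory=dict)
    export: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - _TOP_LEVEL_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "inputs" not in raw or not isinstance(raw["inputs"], list) or not raw["inputs"]:
            raise ConfigError("config requires a non-empty 'inputs' list")
        for item in raw["inputs"]:
            if not isinstance(item, dict) or "path" not in item:
                raise ConfigError("each input needs at least a 'path'")
            extra = set(item) - {"path", "dialect", "cohort_id"}
            if extra:
                raise ConfigError(f"unknown input key(s): {sorted(extra)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        # fail fast on nested validation
        try:
            cur.CurationConfig(**cfg.curation)
            en.RMRConfig(**cfg.rmr)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid curation/rmr config: {exc}") from exc
        if cfg.equation not in en.EE_EQUATIONS:
            raise ConfigError(f"unknown equation {cfg.equation!r}")
        if cfg.model is not None:
            try:
                st.ModelSpec(**cfg.model)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid model spec: {exc}") from exc
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _photoperiod_from(cfg: PipelineConfig, meta: md.MetadataTable | None):
    if cfg.photoperiod:
        return md.Photoperiod(md._parse_clock(cfg.photoperiod["lights_on"]),
                              md._parse_clock(cfg.photoperiod["lights_off"]))
    if meta is not None and meta.photoperiod is not None:
        return meta.photoperiod
    return md.default_photoperiod_with_warning()


def _stage(name: str, **params):
    log.info("stage=%s %s", name,
             " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> ex.ExportBundle:
    """Run the full workflow and write the export bundle under ``out_dir``.

    Outputs are staged in a temporary directory and moved into place only on
    success, so a failing stage leaves no partial bundle behind.
    """
    out_dir = Path(out_dir)
    tmp = Path(tempfile.mkdtemp(prefix=".calokit-", dir=out_dir.parent
                                if out_dir.parent.exists() else None))
    try:
        bundle = _run_stages(cfg, tmp)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    out_dir.mkdir(parents=True, exist_ok=True)
    for f in tmp.iterdir():
        shutil.move(str(f), out_dir / f.name)
    tmp.rmdir() if tmp.exists() else None
    return bundle


def _run_stages(cfg: PipelineConfig, out: Path) -> ex.ExportBundle:
    # --- ingest ---------------------------------------------------------
    frames = []
    for item in cfg.inputs:
        dialect = item.get("dialect", "auto")
        try:
            spec = (ingest.detect_dialect(item["path"]) if dialect == "auto"
                    else ingest.get_dialect(dialect))
            frames.append(ingest.read_dataset(item["path"], spec,
                                              cohort_id=item.get("cohort_id")))
        except (OSError, ValueError) as exc:
            raise DataError(f"ingest: {exc}") from exc
    frame = ingest.merge_cohorts(frames) if len(frames) > 1 else frames[0]
    _stage("ingest", files=len(frames), rows=frame.n_rows)

    # --- metadata -------------------------------------------------------
    meta = None
    hmap = None
    if cfg.metadata:
        try:
            sheet = md.load_metadata_sheet(cfg.metadata)
            synonyms = md.load_synonyms(cfg.synonyms) if cfg.synonyms else None
            meta, hmap = md.harmonize_labels([sheet], synonyms=synonyms)
            frame = md.apply_metadata(frame, meta)
        except ValueError as exc:
            raise DataError(f"metadata: {exc}") from exc
    photoperiod = _photoperiod_from(cfg, meta)
    _stage("metadata", animals=len(frame.animals),
           factors=meta.factors if meta else [])

    # --- curation -------------------------------------------------------
    try:
        curation_config = cur.CurationConfig(**cfg.curation)
        frame, report = cur.curate(frame, curation_config, photoperiod)
    except ValueError as exc:
        raise DataError(f"curation: {exc}") from exc
    _stage("curation", rows=frame.n_rows, removed=report.total_removed)

    # --- energetics -----------------------------------------------------
    try:
        trace = en.energy_trace(frame, photoperiod, cfg.equation)
        rmr = en.estimate_rmr(trace, en.RMRConfig(**cfg.rmr))
    except ValueError as exc:
        raise DataError(f"energetics: {exc}") from exc
    _stage("energetics", equation=cfg.equation, animals=len(rmr))

    # --- statistics -----------------------------------------------------
    stats_tables: dict[str, pd.DataFrame] = {}
    result = None
    if cfg.model is not None and meta is not None:
        try:
            spec = st.ModelSpec(**cfg.model)
            table = st.build_analysis_table(trace, rmr, meta, spec.response)
            result = st.fit_model(table, spec)
            ph_method = cfg.posthoc.get(
                "method", "tukey" if len(spec.factors) == 1 else "pairwise_t")
            ph_corr = cfg.posthoc.get("correction", "holm")
            st.posthoc(result, method=ph_method, correction=ph_corr)
            stats_tables["model"] = result.model_table
            stats_tables["posthoc"] = result.posthoc_table
            stats_tables["analysis_table"] = table
        except ValueError as exc:
            raise DataError(f"stats: {exc}") from exc
        _stage("stats", model=spec.formula())

    # --- export ---------------------------------------------------------
    snapshot = dataclasses.asdict(cfg)
    bundle = ex.ExportBundle(
        frame=frame, energy_trace=trace, rmr_results=rmr,
        stats_tables=stats_tables, curation_report=report,
        harmonization_map=hmap, metadata=meta, config_snapshot=snapshot)

    ex.write_long_csv(frame, out / "curated_frame.csv")
    ex.write_long_csv(trace, out / "energy_trace.csv")
    ex.write_long_csv(rmr, out / "rmr_results.csv")
    ex.write_long_csv(report, out / "curation_report.csv")
    if meta is not None:
        ex.write_long_csv(meta, out / "metadata.csv")
    if hmap is not None:
        ex.write_long_csv(hmap, out / "harmonization_map.csv")
    for name, table in stats_tables.items():
        ex.write_long_csv(table, out / f"stats_{name}.csv")
    if result is not None:
        (out / "stats_report.txt").write_text(
            ex.render_text_report(result), encoding="utf-8")
    (out / "config_snapshot.json").write_text(
        json.dumps(snapshot, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")
    if cfg.export.get("calr"):
        ex.write_calr_csv(frame, out / "consolidated_calr.csv")
    if cfg.export.get("workbook"):
        ex.write_consolidated_workbook(bundle, out / "consolidated.xlsx")
    for kind in cfg.export.get("figures", []):
        if kind in ("timeseries", "silhouette"):
            ex.render_figure(kind, trace, out / f"figure_{kind}.svg")
        elif kind == "profile":
            prof = en.windowed_profile(trace)
            ex.render_figure(kind, prof, out / f"figure_{kind}.svg")
    _stage("export", out=str(out))
    return bundle
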