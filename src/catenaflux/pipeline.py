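"""Pipeline orchestration: simulate -> fluxes -> segment -> summarize -> upscale.

Each stage reads the previous stage's files, so any stage can equally be fed
real field data in the documented schemas.  A manifest records the outputs,
their SHA-256 checksums, the seed and the package version; re-running with
the same configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fluxes import QcPolicy, estimate_fluxes
from .io import (FLUXES_SCHEMA, RAINFALL_SCHEMA, SENSORS_SCHEMA,
                 SOIL_CHEM_SCHEMA, read_table, read_traces, write_json,
                 write_table, write_traces)
from .periodstats import anova_two_way, assign_periods, hot_moments, summarize
from .segmentation import SegmentationConfig, segment_moisture
from .synthetic import (CatenaConfig, FluxRegimeSpec, MalfunctionSpec,
                        PERIODS, RegimeSpec, generate_chamber_traces,
                        generate_rainfall, generate_sensor_series,
                        generate_soil_chem)
from .upscaling import (UpscalingConfig, ch4_offset, flux_summaries,
                        run_monte_carlo)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "fluxes", "segment", "summarize", "upscale")


@dataclass
class PipelineConfig:
    """End-to-end configuration; every stage derives its RNG from ``seed``."""

    out_dir: Path
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES})
    # synthetic-campaign scale (days of chamber operation, closures/day);
    # the full campaign is 12 closures/day on ~150 days
    trace_days: int = 60
    closures_per_day: int = 4
    sample_interval_s: float = 10.0
    catena: CatenaConfig = field(default_factory=CatenaConfig)
    malfunctions: MalfunctionSpec = field(default_factory=MalfunctionSpec)
    qc: QcPolicy = field(default_factory=QcPolicy)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    upscaling: UpscalingConfig = field(default_factory=UpscalingConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None,
                  seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "catena" in raw:
            c = dict(raw["catena"])
            for k in ("start_date", "end_date"):
                if k in c:
                    c[k] = pd.Timestamp(c[k]).date()
            if "breakpoint_dates" in c:
                c["breakpoint_dates"] = tuple(
                    pd.Timestamp(d).date() for d in c["breakpoint_dates"])
            kwargs["catena"] = CatenaConfig(**c)
        for key, cls_ in (("malfunctions", MalfunctionSpec), ("qc", QcPolicy),
                          ("segmentation", SegmentationConfig),
                          ("upscaling", UpscalingConfig)):
            if key in raw:
                kwargs[key] = cls_(**raw[key])
        for key in ("stages", "trace_days", "closures_per_day",
                    "sample_interval_s", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if seed is not None:
            kwargs["seed"] = seed
        out = out_dir if out_dir is not None else raw.get("out_dir", ".")
        return cls(out_dir=Path(out), **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _period_names(n_breaks: int) -> list[str]:
    if n_breaks == 3:
        return list(PERIODS)
    return [f"segment_{i + 1}" for i in range(n_breaks + 1)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "stages": {}, "outputs": {}}

    def _record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    if config.stages.get("simulate", True):
        cat = config.catena
        rng = np.random.default_rng(config.seed)
        sensors, truth = generate_sensor_series(cat, RegimeSpec.default(cat),
                                                rng=rng)
        study, baseline, clim = generate_rainfall(cat, rng=rng)
        # stratify chamber days across periods so every period gets coverage
        per_period = max(1, config.trace_days // len(cat.period_bounds()))
        days = []
        for _, start, end in cat.period_bounds():
            span = pd.date_range(start, end, freq="D", inclusive="left")
            pick = np.sort(rng.choice(len(span), min(per_period, len(span)),
                                      replace=False))
            days.extend(d.date() for d in span[pick])
        traces, trace_truth = generate_chamber_traces(
            cat, FluxRegimeSpec.default(), config.malfunctions, rng=rng,
            dates=sorted(days),
            closures_per_day=config.closures_per_day,
            sample_interval_s=config.sample_interval_s)
        chem = generate_soil_chem(cat, rng=rng)
        p_sensors = write_table(sensors, out / "sensors.csv", SENSORS_SCHEMA)
        p_rain = write_table(study, out / "rainfall.csv", RAINFALL_SCHEMA)
        p_base = write_table(baseline, out / "rainfall_baseline.csv",
                             RAINFALL_SCHEMA)
        write_traces(traces, out / "traces")
        p_chem = write_table(chem, out / "soil_chem.csv", SOIL_CHEM_SCHEMA)
        truth["flux_regimes"] = (FluxRegimeSpec.default().cells.reset_index()
                                 .to_dict(orient="records"))
        truth["interpolated_flux_cells"] = sorted(
            FluxRegimeSpec.default().interpolated)
        p_truth = write_json(truth, out / "truth.json")
        trace_truth_p = write_table(trace_truth, out / "trace_truth.csv")
        _record("simulate", p_sensors, p_rain, p_base, p_chem, p_truth,
                trace_truth_p, out / "traces" / "manifest.csv")
    else:
        manifest["stages"]["simulate"] = "skipped"

    if config.stages.get("fluxes", True):
        traces = read_traces(out / "traces")
        flux_df = estimate_fluxes(traces, config.qc)
        p = write_table(flux_df, out / "fluxes.csv", FLUXES_SCHEMA)
        _record("fluxes", p)
    else:
        manifest["stages"]["fluxes"] = "skipped"

    if config.stages.get("segment", True):
        sensors = read_table(out / "sensors.csv", SENSORS_SCHEMA)
        seg = segment_moisture(sensors, config.segmentation,
                               rng=np.random.default_rng(config.seed + 10))
        names = _period_names(seg.chosen_n_breaks)
        edges = [pd.Timestamp(sensors["timestamp"].min()).normalize(),
                 *seg.breakpoint_dates,
                 pd.Timestamp(sensors["timestamp"].max()).normalize()]
        p = write_json({
            "breakpoints": seg.breakpoints,
            "breakpoint_dates": [d.date().isoformat()
                                 for d in seg.breakpoint_dates],
            "bic_table": {str(k): v for k, v in seg.bic_table.items()},
            "chosen_n_breaks": seg.chosen_n_breaks,
            "supF": seg.supF, "p_value": seg.p_value,
            "periods": [{"name": nm, "start": edges[i].date().isoformat(),
                         "end": edges[i + 1].date().isoformat()}
                        for i, nm in enumerate(names)],
        }, out / "segments.json")
        _record("segment", p)
    else:
        manifest["stages"]["segment"] = "skipped"

    if config.stages.get("summarize", True):
        import json

        seg_meta = json.loads((out / "segments.json").read_text())
        bps = [pd.Timestamp(d) for d in seg_meta["breakpoint_dates"]]
        names = [p["name"] for p in seg_meta["periods"]]
        flux_df = read_table(out / "fluxes.csv", FLUXES_SCHEMA)
        flux_df = assign_periods(flux_df, bps, period_names=names)
        retained = flux_df[flux_df["retained"]]
        summaries = pd.concat([
            summarize(retained[retained["gas"] == g], "flux",
                      by=["period", "zone"]).assign(gas=g)
            for g in ("co2", "ch4")], ignore_index=True)
        p_sum = write_table(summaries, out / "summaries.csv")
        anova_out = {}
        for gas, log in (("co2", True), ("ch4", False)):
            sub = retained[retained["gas"] == gas]
            res = anova_two_way(sub, "flux", repeated=True, log_transform=log)
            anova_out[gas] = {
                "design": res.design, "log_transformed": res.log_transformed,
                "table": res.table.reset_index()
                          .rename(columns={"index": "factor"})
                          .to_dict(orient="records"),
                "n_dropped_nonpositive": res.n_dropped_nonpositive,
                "tukey": {k: v.to_dict(orient="records")
                          for k, v in res.tukey.items()},
            }
        p_anova = write_json(anova_out, out / "anova.json")
        ch4 = retained[retained["gas"] == "ch4"]
        thresholds, flagged = hot_moments(ch4, "flux")
        p_hot = write_table(
            flagged[flagged["hot"]][["chamber_id", "zone", "closure_start",
                                     "period", "flux", "threshold"]],
            out / "hot_moments.csv")
        p_thr = write_table(thresholds, out / "hot_moment_thresholds.csv")
        _record("summarize", p_sum, p_anova, p_hot, p_thr)
    else:
        manifest["stages"]["summarize"] = "skipped"

    if config.stages.get("upscale", True):
        flux_df = read_table(out / "fluxes.csv", FLUXES_SCHEMA)
        import json

        seg_meta = json.loads((out / "segments.json").read_text())
        bps = [pd.Timestamp(d) for d in seg_meta["breakpoint_dates"]]
        names = [p["name"] for p in seg_meta["periods"]]
        flux_df = assign_periods(flux_df, bps, period_names=names)
        cells = flux_summaries(flux_df)
        result = {}
        rng = np.random.default_rng(config.seed + 20)
        for scenario in ("observed", "baseline"):
            mc = run_monte_carlo(cells, config.upscaling, scenario, rng=rng)
            result[scenario] = {
                gas: {"total_kg_co2e_ha": e.total, "ci_low": e.ci_low,
                      "ci_high": e.ci_high, "per_period": e.per_period,
                      "window_days": e.window_days}
                for gas, e in mc.items()}
            if scenario == "observed":
                off = ch4_offset(mc["ch4"])
                result["offset"] = {
                    "sink_kg_co2e_ha": off.sink,
                    "rebound_kg_co2e_ha": off.rebound,
                    "offset_pct": off.offset_pct,
                    "ci_low_pct": off.ci_low_pct,
                    "ci_high_pct": off.ci_high_pct,
                    "n_excluded": off.n_excluded}
        p = write_json(result, out / "emissions.json")
        _record("upscale", p)
    else:
        manifest["stages"]["upscale"] = "skipped"

    write_json(manifest, out / "pipeline_manifest.json")
    return manifest
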