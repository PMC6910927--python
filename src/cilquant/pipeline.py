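"""End-to-end orchestration: config → transitions → (simulate | read)
→ peak processing → quantification → group comparison, with a run
manifest for provenance.

A pipeline config is a single YAML/JSON document::

    seed: 1
    panel: default            # or a panel CSV path
    snr_min: 3.0
    rt_tol_min: 0.1
    weighting: "1/x"
    contrasts: [[SPF, SPF-RF], [SPF, GF], [SPF-RF, GF-RF]]
    simulate:                 # exactly one of simulate / inputs
      study: default          # or an inline/file study design
      config: {noise_sd: 2.0}
      chromatogram_format: null   # csv | mzml to also dump raw traces
    # inputs:
    #   chromatograms: path/to/run.mzML
    #   format: mzml
    calibration:              # optional absolute-quantification stage
      analytes: [Propanoic acid, Butyric acid]
      levels: [0.1, 0.22, 0.46, 1.0, 2.2, 4.6, 10.0]
      is_concentration: 10.0

All numeric artifacts are TSVs at full precision; the manifest records
the config hash, seed, stage timings, and output paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .compare import DEFAULT_CONTRASTS, build_comparison_report
from .errors import ConfigurationError
from .chromio import read_chromatograms, write_chromatograms_csv, \
    write_chromatograms_mzml
from .panel import internal_standard_for, load_default_panel
from .peaks import DEFAULT_SNR_MIN, PeakPair, integrate_pair, \
    integrate_transition
from .quantify import fit_calibration, replicate_ratio_summary
from .simulate import (
    GroupStudy,
    SimulationConfig,
    default_study_design,
    design_from_dict,
    simulate_calibration_series,
    simulate_group_study,
)
from .transitions import (
    HEAVY_2PA,
    LIGHT_2PA,
    build_transition_table,
    derivative_precursor_mz,
    read_panel_csv,
    write_transition_tsv,
)

logger = logging.getLogger("cilquant")


@dataclass
class RunManifest:
    """Provenance record emitted for every pipeline invocation."""

    run_id: str
    tool_version: str
    seed: int
    config_hash: str
    input_paths: list[str]
    panel_size: int
    stage_timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def config_hash(config: Mapping) -> str:
    """Stable SHA-256 of the canonicalized config content."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return payload


def _validate_config(config: Mapping) -> None:
    has_sim = "simulate" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise ConfigurationError(
            "config must contain exactly one of 'simulate' or 'inputs'"
        )


def _load_panel(spec) -> list:
    if spec in (None, "default"):
        return load_default_panel()
    return read_panel_csv(spec)


def _sim_config(config: Mapping, seed: int) -> SimulationConfig:
    overrides = dict(config.get("simulate", {}).get("config", {}))
    allowed = {f.name for f in dc_fields(SimulationConfig)}
    unknown = set(overrides) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown simulation config keys: {sorted(unknown)}"
        )
    overrides["seed"] = seed
    return SimulationConfig(**overrides)


def measure_study(
    study: GroupStudy,
    snr_min: float = DEFAULT_SNR_MIN,
    rt_tol_min: float = 0.1,
) -> tuple[dict[tuple[str, str, str], list[float] | None], pd.DataFrame]:
    """Integrate every replicate run of a study.

    Returns the measurements mapping consumed by
    :func:`cilquant.compare.build_comparison_report` (``None`` marks an
    ND cell) and a long-format ratios table with one row per
    (group, matrix, analyte) replicate summary.
    """
    measurements: dict[tuple[str, str, str], list[float] | None] = {}
    rows = []
    rt_tol_s = rt_tol_min * 60.0
    for (group, matrix), runs in study.runs.items():
        pairs_by_analyte: dict[str, list[PeakPair]] = {}
        for run in runs:
            for name, (light, heavy) in run.traces.items():
                pairs_by_analyte.setdefault(name, []).append(
                    integrate_pair(light, heavy, snr_min, rt_tol_s)
                )
        for analyte in study.panel:
            pairs = pairs_by_analyte[analyte.name]
            summary = replicate_ratio_summary(pairs)
            ratios = [p.ratio for p in pairs if p.ratio is not None]
            measurements[(group, matrix, analyte.name)] = (
                None if summary.nd else ratios
            )
            rows.append(
                {
                    "analyte": analyte.name,
                    "precursor_light": round(
                        derivative_precursor_mz(analyte, LIGHT_2PA), 4
                    ),
                    "precursor_heavy": round(
                        derivative_precursor_mz(analyte, HEAVY_2PA), 4
                    ),
                    "rt_min": analyte.expected_rt,
                    "group": group,
                    "matrix": matrix,
                    "mean_ratio": summary.mean,
                    "sd_ratio": summary.sd,
                    "n": summary.n,
                    "nd_flag": summary.nd,
                }
            )
    return measurements, pd.DataFrame(rows)


def _peaks_table(traces, snr_min: float) -> pd.DataFrame:
    rows = []
    for trace in traces:
        peak = integrate_transition(trace, snr_min)
        name, channel = trace.transition_id.rsplit("|", 1)
        rows.append(
            {
                "name": name,
                "channel": channel,
                "apex_min": peak.apex_time / 60.0,
                "area": peak.area if peak.detected else None,
                "height": peak.height if peak.detected else None,
                "snr": peak.snr,
                "detected": peak.detected,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> RunManifest:
    """Execute the configured workflow and write all artifacts under
    ``outdir``.  Deterministic given the config seed: the data artifacts
    of two identical invocations are byte-identical."""
    input_paths = []
    if isinstance(config, (str, Path)):
        input_paths.append(str(config))
        config = load_config(config)
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    snr_min = float(config.get("snr_min", DEFAULT_SNR_MIN))
    rt_tol_min = float(config.get("rt_tol_min", 0.1))
    weighting = config.get("weighting", "1/x")
    contrasts = [
        tuple(pair) for pair in config.get("contrasts", DEFAULT_CONTRASTS)
    ]
    manifest = RunManifest(
        run_id=f"cilquant-{config_hash(config)[:12]}-s{seed}",
        tool_version=__version__,
        seed=seed,
        config_hash=config_hash(config),
        input_paths=input_paths,
        panel_size=0,
    )

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                manifest.stage_timings[name] = round(dt, 4)
                if exc is None:
                    logger.info("stage %s: done in %.2fs", name, dt)
                else:
                    logger.error("stage %s: failed: %s", name, exc)
                return False

        return _Timer()

    try:
        with stage("transitions"):
            panel = _load_panel(config.get("panel", "default"))
            manifest.panel_size = len(panel)
            transitions = build_transition_table(panel)
            path = outdir / "transitions.tsv"
            write_transition_tsv(transitions, path)
            manifest.outputs["transitions"] = str(path)

        study = None
        traces = None
        if "simulate" in config:
            with stage("simulate"):
                sim_cfg = _sim_config(config, seed)
                design_spec = config["simulate"].get("study", "default")
                if design_spec in (None, "default"):
                    design = default_study_design(panel)
                elif isinstance(design_spec, Mapping):
                    design = design_from_dict(design_spec)
                else:
                    input_paths.append(str(design_spec))
                    design = design_from_dict(load_config(design_spec))
                study = simulate_group_study(design, panel, sim_cfg)
                fmt = config["simulate"].get("chromatogram_format")
                if fmt:
                    raw_dir = outdir / "chromatograms"
                    raw_dir.mkdir(exist_ok=True)
                    writer = (write_chromatograms_mzml if fmt == "mzml"
                              else write_chromatograms_csv)
                    suffix = ".mzML" if fmt == "mzml" else ".csv"
                    for (group, matrix), runs in study.runs.items():
                        for i, run in enumerate(runs):
                            writer(
                                run.all_traces(),
                                raw_dir / f"{group}_{matrix}_rep{i}{suffix}",
                            )
                    manifest.outputs["chromatograms"] = str(raw_dir)
        else:
            with stage("read"):
                inputs = config["inputs"]
                path = Path(inputs["chromatograms"])
                input_paths.append(str(path))
                traces = read_chromatograms(
                    path, transitions, inputs.get("format")
                )

        with stage("peaks"):
            if study is not None:
                all_traces = [
                    t
                    for runs in study.runs.values()
                    for run in runs
                    for t in run.all_traces()
                ]
            else:
                all_traces = traces
            peaks_df = _peaks_table(all_traces, snr_min)
            path = outdir / "peaks.tsv"
            peaks_df.to_csv(path, sep="\t", index=False)
            manifest.outputs["peaks"] = str(path)

        with stage("quantify"):
            if study is not None:
                measurements, ratios_df = measure_study(
                    study, snr_min, rt_tol_min
                )
            else:
                measurements, ratios_df = _measure_single_run(
                    traces, panel, snr_min, rt_tol_min
                )
            path = outdir / "ratios.tsv"
            ratios_df.to_csv(path, sep="\t", index=False)
            manifest.outputs["ratios"] = str(path)
            if "calibration" in config:
                cal_df = _calibration_stage(
                    config["calibration"], panel, seed, weighting, snr_min
                )
                path = outdir / "calibration.tsv"
                cal_df.to_csv(path, sep="\t", index=False)
                manifest.outputs["calibration"] = str(path)

        if study is not None:
            with stage("compare"):
                report = build_comparison_report(
                    measurements, panel, study.design.matrices, contrasts
                )
                path = outdir / "comparison.tsv"
                report.to_csv(path, sep="\t", index=False)
                manifest.outputs["comparison"] = str(path)
    finally:
        manifest.input_paths = input_paths
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n",
                                              encoding="utf-8")
    return manifest


def _measure_single_run(traces, panel, snr_min, rt_tol_min):
    """Ratios for one externally supplied differential run."""
    by_id = {t.transition_id: t for t in traces}
    measurements = {}
    rows = []
    for analyte in panel:
        light = by_id.get(f"{analyte.name}|light")
        heavy = by_id.get(f"{analyte.name}|heavy")
        if light is None or heavy is None:
            continue
        pair = integrate_pair(light, heavy, snr_min, rt_tol_min * 60.0)
        summary = replicate_ratio_summary([pair])
        measurements[("run", "run", analyte.name)] = (
            None if summary.nd else [pair.ratio]
        )
        rows.append(
            {
                "analyte": analyte.name,
                "precursor_light": round(
                    derivative_precursor_mz(analyte, LIGHT_2PA), 4
                ),
                "precursor_heavy": round(
                    derivative_precursor_mz(analyte, HEAVY_2PA), 4
                ),
                "rt_min": analyte.expected_rt,
                "group": "run",
                "matrix": "run",
                "mean_ratio": summary.mean,
                "sd_ratio": summary.sd,
                "n": summary.n,
                "nd_flag": summary.nd,
            }
        )
    return measurements, pd.DataFrame(rows)


def _calibration_stage(cal_config, panel, seed, weighting, snr_min):
    by_name = {a.name: a for a in panel}
    levels = [float(v) for v in cal_config["levels"]]
    is_conc = float(cal_config.get("is_concentration", 10.0))
    sim_cfg = SimulationConfig(seed=seed)
    rows = []
    for name in cal_config["analytes"]:
        if name not in by_name:
            raise ConfigurationError(f"calibration analyte {name!r} not in panel")
        analyte = by_name[name]
        runs = simulate_calibration_series(
            analyte, levels, is_conc, sim_cfg,
            internal_standard_for(name), run_key=f"cal|{name}",
        )
        pts = []
        for run in runs:
            a_peak = integrate_transition(run.analyte_trace, snr_min)
            is_peak = integrate_transition(run.is_trace, snr_min)
            if a_peak.detected and is_peak.detected:
                pts.append((run.concentration, a_peak.area / is_peak.area))
        curve = fit_calibration(pts, weighting, analyte=name)
        rows.append(
            {
                "analyte": name,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r": curve.r,
                "weighting": curve.weighting,
                "n_levels": curve.n_levels,
            }
        )
    return pd.DataFrame(rows)
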