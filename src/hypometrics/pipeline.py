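"""End-to-end orchestration: config -> synthetic inputs -> QC -> analysis
-> GroupTable -> summary report.

A run is fully described by a RunConfig (YAML-serializable); every
stochastic stage takes its seed from the config, so two runs of the same
config produce byte-identical tables. The bundled demo config exercises
every generator/analysis pairing at desk scale: activity suppression to
~50%, OCR suppression to one-third, MVO2 of treated vs vehicle grafts,
ratiometric ratio decline, ECG metrics, TEER/ddCT/binding assay math.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import assays, cardiac, perfusion, ratiometric, respirometry, synthio, video_activity
from .types import GROUP_TABLE_COLUMNS, active_rows, make_group_table


class ConfigError(ValueError):
    """The run configuration violates the schema; message names the field."""


ALL_STAGES = ("activity", "heartrate", "ecg", "respirometry", "perfusion", "ratiometric", "assays")

# stage -> parameter name -> default; unknown keys are rejected by path
CONFIG_SCHEMA: dict[str, dict] = {
    "activity": {
        "treated_level": 0.25,
        "vehicle_level": 0.5,
        "n_frames": 60,
        "n_organisms": 5,
        "bin_s": 2.0,
    },
    "heartrate": {"treated_bpm": 30.0, "vehicle_bpm": 60.0, "duration_s": 30.0},
    "ecg": {"bpm": 80.0, "qrs_width_s": 0.08, "st_offset_mv": 0.05, "fs_hz": 500.0},
    "respirometry": {
        "baseline_rate": 2.0,
        "treated_fold": 1 / 3,
        "n_treated": 9,
        "n_vehicle": 7,
        "noise_sd": 0.5,
        "duration_min": 60.0,
    },
    "perfusion": {
        "treated_mvo2": 2.39,
        "vehicle_mvo2": 4.28,
        "hb_g_dl": 3.0,
        "flow_ml_min": 500.0,
        "weight_g": 300.0,
        "temp_c": 21.0,
        "n_timepoints": 5,
    },
    "ratiometric": {"n_cells": 12, "treated_ratio": 1.0, "vehicle_ratio": 1.8, "noise_sd": 5.0},
    "assays": {"binding_ic50_nm": 3470.0, "binding_hill": 1.0, "ddct_shift": 1.0},
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "hypometrics_run"
    stages: tuple = ALL_STAGES
    params: dict = field(default_factory=dict)
    make_figures: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"seed", "out_dir", "stages", "params", "make_figures"}
        for key in raw:
            if key not in known_top:
                raise ConfigError(f"unknown config key: {key!r}")
        params = raw.get("params", {})
        for stage, stage_params in params.items():
            if stage not in CONFIG_SCHEMA:
                raise ConfigError(f"unknown config key: params.{stage}")
            for p in stage_params:
                if p not in CONFIG_SCHEMA[stage]:
                    raise ConfigError(f"unknown config key: params.{stage}.{p}")
        stages = tuple(raw.get("stages", ALL_STAGES))
        for s in stages:
            if s not in ALL_STAGES:
                raise ConfigError(f"unknown config key: stages entry {s!r}")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "hypometrics_run")),
            stages=stages,
            params=params,
            make_figures=bool(raw.get("make_figures", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def stage_params(self, stage: str) -> dict:
        merged = dict(CONFIG_SCHEMA[stage])
        merged.update(self.params.get(stage, {}))
        return merged


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stage runners: each returns (group table rows DataFrame, stage result dict)


def _run_activity(cfg: RunConfig):
    p = cfg.stage_params("activity")
    tables, res = [], {}
    for group, level in (("treated", p["treated_level"]), ("vehicle", p["vehicle_level"])):
        video, truth = synthio.gen_swim_video(
            n_organisms=p["n_organisms"],
            activity_level=level,
            n_frames=p["n_frames"],
            seed=_stage_seed(cfg.seed, f"activity.{group}"),
        )
        trace = video_activity.movement_index(video)
        tab = video_activity.summarize_activity(
            trace, p["bin_s"], group=group, replicate_id=f"{group}-0",
            provenance=f"gen_swim_video(level={level})",
        )
        tables.append(tab)
        res[group] = {"mean_index": float(trace.index.mean()), "true_level": level}
    rel = video_activity.relative_activity(
        tables[0].reset_index(drop=True), tables[1].reset_index(drop=True)
    )
    res["relative_activity_mean"] = float(np.nanmean(rel["relative_activity"]))
    return pd.concat(tables, ignore_index=True), res


def _run_heartrate(cfg: RunConfig):
    p = cfg.stage_params("heartrate")
    rows, res = [], {}
    for group, bpm in (("treated", p["treated_bpm"]), ("vehicle", p["vehicle_bpm"])):
        video, truth = synthio.gen_heart_video(
            bpm=bpm, duration=p["duration_s"], seed=_stage_seed(cfg.seed, f"hr.{group}")
        )
        trace = cardiac.roi_trace(video, truth.params["roi"])
        est = cardiac.count_beats(trace)
        rows.append(
            {
                "group": group, "replicate_id": f"{group}-0", "timepoint": 0.0,
                "metric": "heart_rate", "value": est.bpm, "unit": "beats/min",
                "qc_flag": "", "provenance": f"gen_heart_video(bpm={bpm})",
            }
        )
        res[group] = {"bpm": est.bpm, "n_peaks": est.n_peaks, "true_bpm": bpm}
    return make_group_table(rows), res


def _run_ecg(cfg: RunConfig):
    p = cfg.stage_params("ecg")
    trace, truth = synthio.gen_ecg(
        bpm=p["bpm"], qrs_width=p["qrs_width_s"], st_offset=p["st_offset_mv"],
        duration=30.0, fs=p["fs_hz"], seed=_stage_seed(cfg.seed, "ecg"),
    )
    m = cardiac.ecg_metrics(trace, 0.0)
    rows = [
        {
            "group": "native", "replicate_id": "ecg-0", "timepoint": 0.0,
            "metric": k, "value": v, "unit": u, "qc_flag": ";".join(m.flags),
            "provenance": f"gen_ecg(bpm={p['bpm']})",
        }
        for k, v, u in (
            ("ecg_amplitude", m.mean_amplitude, "mV"),
            ("qrs_interval", m.qrs_interval, "s"),
            ("st_height", m.st_height, "mV"),
            ("pulse_rate", m.pulse_rate, "beats/min"),
        )
    ]
    res = dataclasses.asdict(m)
    return make_group_table(rows), res


def _run_respirometry(cfg: RunConfig):
    p = cfg.stage_params("respirometry")
    rows = []
    for group, fold, n in (
        ("treated", p["treated_fold"], p["n_treated"]),
        ("vehicle", 1.0, p["n_vehicle"]),
    ):
        for k in range(n):
            trace, truth = synthio.gen_o2_trace(
                baseline_rate=p["baseline_rate"] * fold,
                fold_change=1.0,
                duration=p["duration_min"],
                noise_sd=p["noise_sd"],
                seed=_stage_seed(cfg.seed, f"resp.{group}.{k}"),
            )
            respirometry.qc_trace(trace)
            flag = "excluded" if trace.excluded else ""
            value = np.nan
            if not trace.excluded:
                value = respirometry.fit_ocr(trace).rate
            rows.append(
                {
                    "group": group, "replicate_id": f"{group}-{k}", "timepoint": 0.0,
                    "metric": "ocr", "value": value, "unit": f"{trace.unit}/min",
                    "qc_flag": flag, "provenance": f"gen_o2_trace(rate={p['baseline_rate'] * fold})",
                }
            )
    table = make_group_table(rows)
    fc = respirometry.group_fold_change(
        table, "treated", "vehicle", seed=_stage_seed(cfg.seed, "resp.boot")
    )
    res = {
        "fold_change": fc.value, "ci": [fc.ci_low, fc.ci_high],
        "true_fold": p["treated_fold"], "n_treated": fc.n_treated, "n_reference": fc.n_reference,
    }
    return table, res


def _run_perfusion(cfg: RunConfig):
    p = cfg.stage_params("perfusion")
    tables, res = [], {}
    for group, mvo2 in (("treated", p["treated_mvo2"]), ("vehicle", p["vehicle_mvo2"])):
        records, truth = synthio.gen_perfusion_records(
            true_mvo2=mvo2, hb=p["hb_g_dl"], q=p["flow_ml_min"], weight=p["weight_g"],
            temp=p["temp_c"], n_timepoints=p["n_timepoints"],
            seed=_stage_seed(cfg.seed, f"perf.{group}"),
        )
        tab = perfusion.mvo2_timecourse(records, group=group, replicate_id=f"{group}-0")
        tables.append(tab)
        res[group] = {"mean_mvo2": float(tab["value"].mean()), "true_mvo2": mvo2}
    res["mvo2_ratio"] = res["treated"]["mean_mvo2"] / res["vehicle"]["mean_mvo2"]
    return pd.concat(tables, ignore_index=True), res


def _run_ratiometric(cfg: RunConfig):
    p = cfg.stage_params("ratiometric")
    rows, res = [], {}
    for group, ratio in (("treated", p["treated_ratio"]), ("vehicle", p["vehicle_ratio"])):
        imgset, truth = synthio.gen_cell_images(
            n_cells=p["n_cells"], true_ratios=[ratio] * p["n_cells"],
            noise_sd=p["noise_sd"], seed=_stage_seed(cfg.seed, f"ratio.{group}"),
        )
        chans = imgset.channels[0]
        nuclei = ratiometric.segment_nuclei(chans["RFP"])
        cells = ratiometric.expand_cells(nuclei)
        meas = ratiometric.measure_cells(cells, chans["YFP"], chans["CFP"])
        mean_ratio, n_cells = ratiometric.image_summary(meas)
        rows.append(
            {
                "group": group, "replicate_id": f"{group}-0", "timepoint": 0.0,
                "metric": "yfp_cfp_ratio", "value": mean_ratio, "unit": "",
                "qc_flag": "", "provenance": f"gen_cell_images(ratio={ratio});n_cells={n_cells}",
            }
        )
        res[group] = {"mean_ratio": mean_ratio, "n_cells": n_cells, "true_ratio": ratio}
    return make_group_table(rows), res


def _run_assays(cfg: RunConfig):
    p = cfg.stage_params("assays")
    res = {}
    pair = assays.ImpedancePair("chip-1", 0.0, 2000.0, 500.0)
    res["teer_ohm"] = assays.teer(pair).tissue_impedance
    shift = p["ddct_shift"]
    records = [
        assays.QpcrRecord("t1", "treated", 25.0 + shift, 18.0),
        assays.QpcrRecord("t2", "treated", 25.2 + shift, 18.2),
        assays.QpcrRecord("c1", "control", 25.0, 18.0),
        assays.QpcrRecord("c2", "control", 25.2, 18.2),
    ]
    dd = assays.ddct_fold_change(records, "treated", "control")
    res["ddct_fold_change"] = dd.fold_change
    conc, binding, truth = synthio.gen_binding_series(
        ic50=p["binding_ic50_nm"], hill=p["binding_hill"], noise_sd=2.0,
        seed=_stage_seed(cfg.seed, "assays.binding"),
    )
    fit = assays.fit_binding(assays.BindingSeries(conc, binding))
    res["binding"] = {
        "ic50_nm": fit.ic50, "hill_slope": fit.hill_slope,
        "converged": fit.converged, "true_ic50_nm": p["binding_ic50_nm"],
    }
    rows = [
        {
            "group": "assay", "replicate_id": "assay-0", "timepoint": 0.0,
            "metric": m, "value": v, "unit": u, "qc_flag": "", "provenance": "assay demo",
        }
        for m, v, u in (
            ("teer", res["teer_ohm"], "ohm"),
            ("ddct_fold_change", dd.fold_change, ""),
            ("binding_ic50", fit.ic50 if fit.ic50 else np.nan, "nM"),
        )
    ]
    return make_group_table(rows), res


_RUNNERS = {
    "activity": _run_activity,
    "heartrate": _run_heartrate,
    "ecg": _run_ecg,
    "respirometry": _run_respirometry,
    "perfusion": _run_perfusion,
    "ratiometric": _run_ratiometric,
    "assays": _run_assays,
}


def summarize(table: pd.DataFrame, by: tuple = ("group", "metric")) -> pd.DataFrame:
    """Per-cell mean, sample SD (n-1) and n over non-excluded rows.

    Cells with a single value keep n=1 and an undefined (NaN) SD; empty
    cells are omitted.
    """
    df = active_rows(table)
    df = df[np.isfinite(df["value"])]
    if not len(df):
        return pd.DataFrame(columns=[*by, "mean", "sd", "n"])
    g = df.groupby(list(by))["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write a reproducible run directory.

    Emits: grouptable.csv, summary.csv, per-stage JSON under stages/,
    report.md (mean +/- SD per group and fold changes), manifest.json with
    SHA-256 of every table, run.log, and the resolved config as YAML.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "stages").mkdir(exist_ok=True)
    log_lines: list[str] = []

    def log(event: str, **kv):
        log_lines.append(json.dumps({"event": event, **kv}, default=str))

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    tables = []
    stage_results = {}
    for stage in config.stages:
        log("stage_start", stage=stage)
        tab, res = _RUNNERS[stage](cfg=config)
        tables.append(tab)
        stage_results[stage] = res
        with open(out / "stages" / f"{stage}.json", "w") as fh:
            json.dump(res, fh, indent=2, default=str, sort_keys=True)
        log("stage_done", stage=stage, rows=len(tab))
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=GROUP_TABLE_COLUMNS)
    table.to_csv(out / "grouptable.csv", index=False)
    summary = summarize(table)
    summary.to_csv(out / "summary.csv", index=False)
    report = _render_report(summary, stage_results)
    (out / "report.md").write_text(report)
    manifest = {
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in ("grouptable.csv", "summary.csv", "report.md")
        },
        "stages": list(config.stages),
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    if config.make_figures:
        _make_figures(table, out)
    return out


def _render_report(summary: pd.DataFrame, stage_results: dict) -> str:
    lines = ["# hypometrics run report", "", "## Group summaries (mean +/- SD, n)", ""]
    for _, row in summary.iterrows():
        sd = "undefined" if not np.isfinite(row["sd"]) else f"{row['sd']:.4g}"
        lines.append(
            f"- {row['group']} / {row['metric']}: {row['mean']:.4g} +/- {sd} (n={int(row['n'])})"
        )
    lines += ["", "## Fold changes and stage results", ""]
    if "respirometry" in stage_results:
        r = stage_results["respirometry"]
        lines.append(
            f"- OCR fold change treated/vehicle: {r['fold_change']:.4g} "
            f"(95% CI {r['ci'][0]:.4g}-{r['ci'][1]:.4g}; generating value {r['true_fold']:.4g})"
        )
    if "activity" in stage_results:
        a = stage_results["activity"]
        lines.append(f"- Relative activity treated/vehicle: {a['relative_activity_mean']:.4g}")
    if "perfusion" in stage_results:
        pr = stage_results["perfusion"]
        lines.append(
            f"- MVO2 treated/vehicle: {pr['treated']['mean_mvo2']:.4g} / "
            f"{pr['vehicle']['mean_mvo2']:.4g} mL O2/min/100 g (ratio {pr['mvo2_ratio']:.3g})"
        )
    if "assays" in stage_results:
        b = stage_results["assays"]["binding"]
        if b["converged"]:
            lines.append(f"- Binding IC50: {b['ic50_nm']:.4g} nM (Hill {b['hill_slope']:.3g})")
    lines.append("")
    return "\n".join(lines)


def _make_figures(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    act = table[table["metric"] == "movement_index"]
    if len(act):
        fig, ax = plt.subplots(figsize=(5, 3))
        for group, grp in act.groupby("group"):
            ax.plot(grp["timepoint"], grp["value"], marker="o", label=group)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("movement index")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "activity.png", dpi=100)
        plt.close(fig)
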