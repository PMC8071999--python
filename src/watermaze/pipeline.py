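"""One-command orchestration: simulate or ingest a dataset, then compute
metrics, cue weighting, cognitive screening, and the full statistics report.

Every analysis logs the aggregation unit and the n per cell, because with
trial-level data either subjects or trials could serve as the random unit;
this pipeline always aggregates to subject level before group statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cueweight, dataio, inference, metrics, screening, synthetic

DEFAULT_TOGGLES = {
    "acquisition_anova": True,
    "delayed_probe_anova": True,
    "moved_mountain": True,
    "metric_comparisons": True,
}

# delayed-probe matched-pair scheme: overall trial indices analysed as the
# repeated-viewpoint ('same') pair and their matched novel ('different') pair
DEFAULT_MATCHED_PAIRS = {"same": [65, 70], "different": [66, 67]}


@dataclass
class PipelineConfig:
    mode: str = "simulate"                      # 'simulate' | 'ingest'
    out_dir: str = "watermaze_out"
    seed: int = 0
    # simulate mode
    n_subjects: dict = field(default_factory=lambda: dict(synthetic.DEFAULT_N_SUBJECTS))
    sigma: dict = field(default_factory=lambda: {"young": 0.6, "old": 0.9})
    w: dict = field(default_factory=lambda: {"young": 0.46, "old": 0.40})
    speed: float = 0.5
    sample_rate: float = 10.0
    include_trajectories: bool = True
    env_seed: Optional[int] = None              # defaults to seed
    # ingest mode
    trials_path: Optional[str] = None
    trajectories_path: Optional[str] = None
    zscores_path: Optional[str] = None
    # analysis settings
    toggles: dict = field(default_factory=lambda: dict(DEFAULT_TOGGLES))
    matched_pairs: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MATCHED_PAIRS.items()})
    rotation_window: str = "trial"
    rotation_baseline: str = "initial_turn"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                default.update(value)
            else:
                setattr(cfg, key, value)
        if cfg.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if cfg.mode == "ingest" and not cfg.trials_path:
            raise ValueError("ingest mode requires trials_path")
        return cfg


class ValidationFailure(RuntimeError):
    """Raised when an ingested dataset violates schema invariants."""

    def __init__(self, findings):
        super().__init__("dataset validation failed:\n" + "\n".join(findings))
        self.findings = findings


def _ttest_entry(name, res: inference.TTestResult, bf: inference.BFResult, n_note: str):
    return {
        "analysis": name, "kind": res.kind, "t": res.t, "df": res.df,
        "p": res.p, "d": res.d, "bf10": bf.bf10, "bf01": bf.bf01,
        "bf_label": inference.interpret_bf(bf), "units": n_note,
    }


def _anova_entries(name, res: inference.AnovaResult, n_note: str):
    out = []
    for eff in (res.between, res.within, res.interaction):
        out.append({
            "analysis": name, "effect": eff.name, "F": eff.F,
            "df1": eff.df1, "df2": eff.df2, "p": eff.p,
            "partial_eta_sq": eff.partial_eta_sq, "units": n_note,
        })
    return out


def load_dataset(cfg: PipelineConfig):
    """Build (simulate) or read (ingest) the dataset plus z-score table."""
    if cfg.mode == "simulate":
        env_seed = cfg.seed if cfg.env_seed is None else cfg.env_seed
        env = synthetic.build_environment(seed=env_seed)
        schedule = synthetic.build_schedule(env, seed=cfg.seed)
        params = {g: synthetic.AgentParams(sigma=cfg.sigma[g], w=cfg.w[g],
                                           speed=cfg.speed, sample_rate=cfg.sample_rate)
                  for g in cfg.n_subjects}
        ds = synthetic.simulate_responses(env, schedule, params, cfg.n_subjects,
                                          seed=cfg.seed,
                                          include_trajectories=cfg.include_trajectories)
        zscores = synthetic.simulate_zscores(ds.subjects, seed=cfg.seed)
        return ds, zscores, env
    trials = dataio.read_trial_table(cfg.trials_path)
    trajectories = (dataio.read_trajectories(cfg.trajectories_path)
                    if cfg.trajectories_path else {})
    subjects = sorted({(r.subject_id, r.group) for r in trials})
    ds = dataio.Dataset(subjects=subjects, trials=trials, trajectories=trajectories)
    zscores = dataio.read_zscore_table(cfg.zscores_path) if cfg.zscores_path else None
    env_seed = cfg.seed if cfg.env_seed is None else cfg.env_seed
    env = synthetic.build_environment(seed=env_seed)
    return ds, zscores, env


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; writes the output bundle and returns it.

    Outputs: metrics.csv, weighting.csv, screening.csv, stats_report.json,
    stats_report.md, and run_log.json (seed, config hash, per-analysis n).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, zscores, env = load_dataset(cfg)
    findings = dataio.validate_dataset(ds)
    if findings:
        raise ValidationFailure(findings)

    mtab = metrics.metrics_table(ds, cfg.rotation_window, cfg.rotation_baseline)
    mtab.to_csv(out / "metrics.csv", index=False, float_format="%.12g")

    report: list[dict] = []
    log: dict = {"seed": cfg.seed, "mode": cfg.mode, "cells": {}}

    def cell_note(desc, counts):
        log["cells"][desc] = counts
        return desc

    # acquisition ANOVA: group x start type on subject-mean distance error
    if cfg.toggles.get("acquisition_anova"):
        acq = mtab[mtab.phase.isin(["acquisition", "acquisition_probe"])]
        subj = (acq.groupby(["subject_id", "group", "start_type"])["distance_error"]
                   .mean().reset_index())
        note = cell_note("acquisition: subject-mean distance error per start type",
                         subj.groupby(["group", "start_type"]).size().to_dict().__str__())
        res = inference.mixed_anova_2x2(subj, dv="distance_error", between="group",
                                        within="start_type", subject="subject_id")
        report += _anova_entries("acquisition_anova", res, note)

    # delayed-probe ANOVA on the matched same/different trial pairs
    if cfg.toggles.get("delayed_probe_anova"):
        pairs = cfg.matched_pairs
        rows = []
        for label, indices in (("same", pairs["same"]), ("different", pairs["different"])):
            sel = mtab[mtab.trial_index.isin(indices)]
            subj = sel.groupby(["subject_id", "group"])["distance_error"].mean().reset_index()
            subj["start_type"] = label
            rows.append(subj)
        paired = pd.concat(rows, ignore_index=True)
        note = cell_note(
            f"delayed probes: matched pairs same={pairs['same']} vs different={pairs['different']}",
            paired.groupby(["group", "start_type"]).size().to_dict().__str__())
        res = inference.mixed_anova_2x2(paired, dv="distance_error", between="group",
                                        within="start_type", subject="subject_id")
        report += _anova_entries("delayed_probe_anova", res, note)
        # median containment radius over all probe responses, per group
        probes = mtab[mtab.phase.isin(["acquisition_probe", "delayed_probe", "moved_mountain"])]
        for group, cell in probes.groupby("group"):
            report.append({
                "analysis": "probe_median_containment_radius", "group": group,
                "median_radius_m": metrics.median_containment_radius(cell.distance_error),
                "n_responses": int(len(cell)),
            })

    # moved-mountain cue weighting
    if cfg.toggles.get("moved_mountain"):
        wrows = cueweight.trial_weightings(ds.trials, env)
        wdf = pd.DataFrame(wrows)
        if len(wdf):
            subj_w = wdf.groupby(["subject_id", "group"])["w"].mean().reset_index()
            wdf = wdf.merge(subj_w.rename(columns={"w": "subject_mean_w"}),
                            on=["subject_id", "group"])
            wdf.to_csv(out / "weighting.csv", index=False, float_format="%.12g")
            groups = sorted(subj_w.group.unique())
            for group in groups:
                vals = subj_w[subj_w.group == group]["w"].to_numpy()
                res = inference.one_sample_t(vals, mu0=0.5)
                bf = inference.jzs_bayes_factor(res.t, len(vals))
                report.append(_ttest_entry(
                    f"weighting_vs_0.5[{group}]", res, bf,
                    cell_note(f"weighting[{group}]: subject-mean W over moved trials",
                              {"n_subjects": int(len(vals))}.__str__())))
            if len(groups) == 2:
                a = subj_w[subj_w.group == groups[0]]["w"].to_numpy()
                b = subj_w[subj_w.group == groups[1]]["w"].to_numpy()
                res = inference.welch_two_sample_t(a, b)
                bf = inference.jzs_bayes_factor(res.t, len(a), len(b))
                report.append(_ttest_entry(
                    f"weighting_between_groups[{groups[0]} vs {groups[1]}]", res, bf,
                    f"subject-mean W; n={len(a)}/{len(b)}"))

    # Table-2-style metric comparisons (delayed probe + visible), subject level
    if cfg.toggles.get("metric_comparisons"):
        for phase, label in (("delayed_probe", "probe"), ("visible", "visible")):
            sel = mtab[mtab.phase == phase]
            if not len(sel):
                continue
            for measure in ("total_path", "total_rotation", "excess_path",
                            "excess_rotation", "total_time", "response_time"):
                subj = (sel.groupby(["subject_id", "group"])[measure]
                           .mean().reset_index().dropna())
                groups = sorted(subj.group.unique())
                if len(groups) != 2:
                    continue
                a = subj[subj.group == groups[0]][measure].to_numpy()
                b = subj[subj.group == groups[1]][measure].to_numpy()
                res = inference.welch_two_sample_t(a, b)
                rs = inference.wilcoxon_rank_sum(a, b)
                report.append({
                    "analysis": f"{measure}_{label}",
                    "kind": "welch+ranksum", "t": res.t, "df": res.df, "p": res.p,
                    "d": res.d, "W": rs.w, "p_ranksum": rs.p,
                    "units": f"subject means, {phase}; n={len(a)}/{len(b)}",
                })

    # cognitive screening
    if zscores is not None:
        dataio.write_zscore_table(zscores, out / "zscores.csv")
        sc = screening.screen_table(zscores)
        sc.to_csv(out / "screening.csv", index=False)
        log["screening"] = sc.status.value_counts().to_dict()

    if cfg.mode == "simulate":
        dataio.write_trial_table(ds.trials, out / "trials.csv")
        if ds.trajectories:
            dataio.write_trajectories(ds.trajectories, out / "trajectories.csv")

    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_markdown_report(report, out / "stats_report.md")

    cfg_dict = asdict(cfg)
    cfg_dict.pop("out_dir")  # the hash identifies the analysis, not its destination
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    log["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    log["n_trials"] = len(ds.trials)
    log["n_subjects"] = len(ds.subjects)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return {"dataset": ds, "metrics": mtab, "report": report, "out_dir": str(out)}


def _write_markdown_report(report: list[dict], path) -> None:
    lines = ["# Statistics report", ""]
    anova = [r for r in report if "effect" in r]
    tt = [r for r in report if r.get("kind") in ("one_sample", "welch_two_sample")]
    other = [r for r in report if r not in anova and r not in tt]
    if anova:
        lines += ["## Mixed ANOVAs", "",
                  "| analysis | effect | F | df | p | partial eta^2 |", "|---|---|---|---|---|---|"]
        for r in anova:
            lines.append(f"| {r['analysis']} | {r['effect']} | {r['F']:.3f} | "
                         f"({r['df1']}, {r['df2']}) | {r['p']:.4f} | {r['partial_eta_sq']:.3f} |")
        lines.append("")
    if tt:
        lines += ["## t tests", "",
                  "| analysis | t | df | p | d | BF10 | BF01 | label |", "|---|---|---|---|---|---|---|---|"]
        for r in tt:
            lines.append(f"| {r['analysis']} | {r['t']:.3f} | {r['df']:.2f} | {r['p']:.4f} | "
                         f"{r['d']:.3f} | {r['bf10']:.3f} | {r['bf01']:.3f} | {r['bf_label']} |")
        lines.append("")
    if other:
        lines += ["## Other measures", "", "```json",
                  json.dumps(other, indent=2, sort_keys=True), "```", ""]
    Path(path).write_text("\n".join(lines))
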