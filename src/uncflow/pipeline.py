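"""Config-driven end-to-end run: synthetic generation -> behaviour ->
time-frequency/CBPT -> beamforming -> effective connectivity.

Every stage derives its seed from the master seed through a fixed
(master, stage-index) counter scheme, so stages are independently
reproducible and a re-run with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beamform, behavior, cbpt, ncreann, synthetic, timefreq

__all__ = ["RunConfig", "load_config", "run_all", "stage_seed"]

_STAGE_INDEX = {
    "behavior": 0,
    "eeg": 1,
    "cbpt": 2,
    "beamform": 3,
    "connectivity": 4,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([master, stage_index])."""
    return int(
        np.random.SeedSequence([master_seed, _STAGE_INDEX[stage]]).generate_state(1)[0]
    )


@dataclass
class BehaviorStageConfig:
    n_subjects: int = 12
    accuracy_jitter_sd: float = 0.03
    rt_jitter_sd_ms: float = 20.0


@dataclass
class EEGStageConfig:
    n_subjects: int = 10
    n_trials: int = 16
    n_channels: int = 30
    n_effect_channels: int = 12
    effect_preset: str = "paper_like"  # or "null"
    n_permutations: int = 500


@dataclass
class BeamformStageConfig:
    n_sources: int = 40
    n_channels: int = 30
    n_trials: int = 40
    n_samples: int = 256
    source_coupling: float = 0.0  # coherent sources cancel under beamforming; keep the localization demo uncorrelated
    top_percent: float = 5.0


@dataclass
class ConnectivityStageConfig:
    enabled: bool = True
    n_subjects: int = 4
    n_trials: int = 30
    trial_samples: int = 256
    order: int = 5
    hidden_units: int = 10
    cv_folds: int = 2
    max_epochs: int = 40
    n_surrogates: int = 0  # 0 disables surrogate thresholding in the pipeline


@dataclass
class RunConfig:
    seed: int = 0
    behavior: BehaviorStageConfig = field(default_factory=BehaviorStageConfig)
    eeg: EEGStageConfig = field(default_factory=EEGStageConfig)
    beamform: BeamformStageConfig = field(default_factory=BeamformStageConfig)
    connectivity: ConnectivityStageConfig = field(default_factory=ConnectivityStageConfig)


def _from_dict(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys are rejected, defaults logged."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        warnings.warn(
            "empty config file: using all defaults "
            f"({json.dumps(dataclasses.asdict(RunConfig()), default=str)})",
            stacklevel=2,
        )
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known_sections = {"behavior", "eeg", "beamform", "connectivity"}
    unknown = set(raw) - known_sections - {"seed"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(seed=int(raw.get("seed", 0)))
    for section, cls in [
        ("behavior", BehaviorStageConfig),
        ("eeg", EEGStageConfig),
        ("beamform", BeamformStageConfig),
        ("connectivity", ConnectivityStageConfig),
    ]:
        if section in raw:
            setattr(cfg, section, _from_dict(cls, raw[section] or {}, section))
    return cfg


def _log(handle, stage: str, **payload) -> None:
    handle.write(json.dumps({"stage": stage, **payload}) + "\n")
    handle.flush()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _run_behavior(cfg: RunConfig, outdir: Path, log) -> dict:
    seed = stage_seed(cfg.seed, "behavior")
    rng = np.random.default_rng(seed)
    design = synthetic.DesignSpec(seed=seed)
    base = synthetic.default_behavior_params()
    tables: dict[str, pd.DataFrame] = {}
    for s in range(cfg.behavior.n_subjects):
        params = {}
        for cell, cp in base.items():
            acc_hit = float(np.clip(cp.hit_rate + rng.normal(0, cfg.behavior.accuracy_jitter_sd),
                                    0.05, 0.99))
            acc_fa = float(np.clip(cp.fa_rate + rng.normal(0, cfg.behavior.accuracy_jitter_sd),
                                   0.01, 0.95))
            rt = float(np.clip(cp.rt_median_ms + rng.normal(0, cfg.behavior.rt_jitter_sd_ms),
                               150, 1500))
            params[cell] = synthetic.CellParams(hit_rate=acc_hit, fa_rate=acc_fa,
                                                rt_median_ms=rt, rt_sigma=cp.rt_sigma)
        tables[f"sub{s:02d}"] = synthetic.generate_trial_table(
            design, params, seed=int(rng.integers(2**31))
        )
    retained, screen_log = behavior.screen_participants(tables)
    summaries = []
    for subject in retained:
        summ = behavior.subject_summary(tables[subject])
        summ.insert(0, "subject", subject)
        summaries.append(summ)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(outdir / "behavioural_summary.csv", index=False)
    screen_log.to_csv(outdir / "screening_log.csv", index=False)

    anova_out = {}
    for dv in ("d_prime", "mean_rt", "accuracy"):
        res = behavior.rm_anova(summary, dv=dv)
        res.table.to_csv(outdir / f"anova_{dv}.csv", index=False)
        anova_out[dv] = res.table.to_dict(orient="records")

    cellmap = summary.set_index(["subject", "condition", "validity"])["d_prime"]
    contrasts = {}
    for label, (ca, cb) in {
        "valid_high_vs_low": (("high_uc", "valid"), ("low_uc", "valid")),
        "invalid_high_vs_low": (("high_uc", "invalid"), ("low_uc", "invalid")),
    }.items():
        va = [cellmap[(s, *ca)] for s in retained]
        vb = [cellmap[(s, *cb)] for s in retained]
        c = behavior.paired_contrasts(va, vb)
        contrasts[label] = dataclasses.asdict(c)
    (outdir / "contrasts.json").write_text(json.dumps(contrasts, indent=1))
    _log(log, "behavior", seed=seed, n_retained=len(retained))
    return {
        "n_subjects": cfg.behavior.n_subjects,
        "n_retained": len(retained),
        "cells": summary.groupby(["condition", "validity"], sort=False)["d_prime"]
        .mean()
        .reset_index()
        .to_dict(orient="records"),
        "anova": anova_out,
        "contrasts": contrasts,
    }


_PRESETS = {
    # theta burst amplitudes per (condition, validity); alpha flat except high_uc valid
    "paper_like": {
        ("high_uc", "valid"): {"theta": 0.8, "alpha": 1.6},
        ("high_uc", "invalid"): {"theta": 0.6, "alpha": 0.8},
        ("low_uc", "valid"): {"theta": 0.8, "alpha": 1.0},
        ("low_uc", "invalid"): {"theta": 1.6, "alpha": 1.0},
        ("low_uc_difficult", "valid"): {"theta": 0.8, "alpha": 1.4},
        ("low_uc_difficult", "invalid"): {"theta": 1.5, "alpha": 0.8},
    },
    "null": {
        (cond, validity): {"theta": 1.0, "alpha": 1.0}
        for cond in synthetic.DEFAULT_CONDITIONS
        for validity in ("valid", "invalid")
    },
}


def _run_eeg_cbpt(cfg: RunConfig, outdir: Path, log) -> dict:
    seed = stage_seed(cfg.seed, "eeg")
    rng = np.random.default_rng(seed)
    e = cfg.eeg
    model = synthetic.make_sensor_model(n_channels=e.n_channels, n_sources=10, seed=seed)
    effects = _PRESETS[e.effect_preset]
    effect_channels = np.arange(e.n_effect_channels)
    design = synthetic.DesignSpec(seed=seed)
    spec = timefreq.MorletSpec(sfreq=design.sfreq)

    # per-subject band/window-averaged power maps per cell
    maps: dict[tuple[str, str], list[np.ndarray]] = {cell: [] for cell in effects}
    for _s in range(e.n_subjects):
        epochs = synthetic.generate_band_power_epochs(
            design, effects, model,
            n_trials=e.n_trials, effect_channels=effect_channels,
            seed=int(rng.integers(2**31)),
        )
        for cell, arr in epochs.items():
            tf = timefreq.morlet_power(arr, spec)
            tf = timefreq.baseline_correct(tf)
            for band_name, band in (("theta", timefreq.THETA_BAND),
                                    ("alpha", timefreq.ALPHA_BAND)):
                vals = timefreq.band_window_average(tf, band, (0.0, 1.0)).mean(axis=0)
                maps.setdefault((band_name, *cell), []).append(vals)

    graph = cbpt.build_neighbors(model.channel_coords)
    results = {}
    for band_name in ("theta", "alpha"):
        pvals = []
        for cond in design.conditions:
            a = np.vstack(maps[(band_name, cond, "valid")])
            b = np.vstack(maps[(band_name, cond, "invalid")])
            res = cbpt.cluster_test(a, b, graph, n_perm=e.n_permutations,
                                    seed=int(rng.integers(2**31)))
            best_p = min((c.p for c in res.clusters), default=1.0)
            pvals.append(best_p)
            topo = pd.DataFrame({
                "channel": np.arange(e.n_channels),
                "t": res.t_map,
                "cluster_id": res.channel_labels(),
            })
            topo.to_csv(outdir / f"cbpt_topography_{band_name}_{cond}.csv", index=False)
            results[f"{band_name}_{cond}_valid_vs_invalid"] = {
                "n_clusters": len(res.clusters),
                "min_p_uncorrected": best_p,
            }
        corrected = cbpt.bonferroni(pvals, m=len(pvals))
        for cond, pc in zip(design.conditions, corrected):
            results[f"{band_name}_{cond}_valid_vs_invalid"]["p_bonferroni"] = float(pc)
        # condition contrast on invalid trials (high vs low uncertainty)
        a = np.vstack(maps[(band_name, "high_uc", "invalid")])
        b = np.vstack(maps[(band_name, "low_uc", "invalid")])
        res = cbpt.cluster_test(a, b, graph, n_perm=e.n_permutations,
                                seed=int(rng.integers(2**31)))
        best_p = min((c.p for c in res.clusters), default=1.0)
        results[f"{band_name}_invalid_high_vs_low"] = {
            "n_clusters": len(res.clusters),
            "min_p_uncorrected": best_p,
            "p_bonferroni": float(cbpt.bonferroni([best_p], m=2)[0]),
        }
    (outdir / "cbpt_results.json").write_text(json.dumps(results, indent=1))
    _log(log, "cbpt", seed=seed)
    return results


def _run_beamform(cfg: RunConfig, outdir: Path, log) -> dict:
    seed = stage_seed(cfg.seed, "beamform")
    b = cfg.beamform
    model = synthetic.make_sensor_model(
        n_channels=b.n_channels, n_sources=b.n_sources, seed=seed
    )
    # two coupled narrowband sources placed on existing grid points
    rng = np.random.default_rng(seed)
    src_idx = np.array([0, b.n_sources // 2])
    theta = 2 * np.pi * 5.5 / 256.0
    r = 0.95
    A = np.zeros((2, 2, 2))
    A[0] = [[2 * r * np.cos(theta), 0.0], [b.source_coupling, 2 * r * np.cos(theta)]]
    A[1] = [[-(r**2), 0.0], [0.0, -(r**2)]]
    spec = synthetic.CouplingSpec(M=2, p=2, A=A, noise_sd=0.3)
    sources = synthetic.simulate_sources(spec, b.n_trials, b.n_samples,
                                         seed=int(rng.integers(2**31)))
    full = np.zeros((b.n_trials, b.n_sources, b.n_samples))
    full[:, src_idx, :] = sources
    model_noisy = synthetic.SensorModel(
        leadfield=model.leadfield, channel_coords=model.channel_coords, sensor_noise_sd=0.05
    )
    epochs = synthetic.project_to_sensors(full, model_noisy, seed=int(rng.integers(2**31)))

    csd = beamform.estimate_csd(epochs, band=timefreq.THETA_BAND, window=(0.0, 0.6))
    power = beamform.dics_source_power(csd, model.leadfield)
    mask = beamform.top_percent_mask(power, percent=b.top_percent)
    cov = beamform.sensor_covariance(epochs)
    filters = beamform.lcmv_filters(cov, model.leadfield)
    rois = {"roiA": [int(src_idx[0])], "roiB": [int(src_idx[1])]}
    tcs = beamform.extract_roi_timecourses(epochs, filters, rois)

    out = pd.DataFrame({
        "source_id": np.arange(b.n_sources),
        "x": model.leadfield.source_coords[:, 0],
        "y": model.leadfield.source_coords[:, 1],
        "z": model.leadfield.source_coords[:, 2],
        "power": power,
        "mask": mask.astype(int),
    })
    out.to_csv(outdir / "source_power.csv", index=False)
    recovered = bool(mask[src_idx].all())
    corr = float(abs(np.corrcoef(tcs["roiA"].ravel(), sources[:, 0, :].ravel())[0, 1]))
    _log(log, "beamform", seed=seed, truth_in_mask=recovered)
    return {
        "true_sources_in_top_mask": recovered,
        "roiA_truth_correlation": corr,
        "n_masked": int(mask.sum()),
    }


def _run_connectivity(cfg: RunConfig, outdir: Path, log) -> dict:
    seed = stage_seed(cfg.seed, "connectivity")
    c = cfg.connectivity
    rng = np.random.default_rng(seed)
    nspec = ncreann.NMVARSpec(order=c.order, hidden_units=c.hidden_units,
                              cv_folds=c.cv_folds, max_epochs=c.max_epochs)

    def coupling(strength: float) -> synthetic.CouplingSpec:
        A = np.zeros((c.order, 2, 2))
        A[0] = [[0.6, 0.0], [strength, 0.6]]
        A[1] = [[-0.2, 0.0], [0.0, -0.2]]
        return synthetic.CouplingSpec(M=2, p=c.order, A=A, noise_sd=0.5)

    stacks = {"high": [], "low": []}
    r2s = []
    for _s in range(c.n_subjects):
        for cond, strength in (("high", 0.2), ("low", 0.45)):
            src = synthetic.simulate_sources(
                coupling(strength), c.n_trials, c.trial_samples,
                seed=int(rng.integers(2**31)),
            )
            res, net = ncreann.estimate_connectivity(src, nspec,
                                                     seed=int(rng.integers(2**31)))
            stacks[cond].append(res.lc)
            r2s.append(net.train_r2)
    lc_high = np.stack(stacks["high"])
    lc_low = np.stack(stacks["low"])
    comp = ncreann.group_compare(lc_high, lc_low, kind="linear")
    np.savetxt(outdir / "lc_high_mean.csv", lc_high.mean(axis=0), delimiter=",")
    np.savetxt(outdir / "lc_low_mean.csv", lc_low.mean(axis=0), delimiter=",")
    (outdir / "connectivity_group_stats.json").write_text(json.dumps(comp, indent=1))
    _log(log, "connectivity", seed=seed)
    return {
        "mean_train_r2": float(np.mean(r2s)),
        "group_stats": comp,
        "lc_high_mean_0to1": float(lc_high.mean(axis=0)[0, 1]),
        "lc_low_mean_0to1": float(lc_low.mean(axis=0)[0, 1]),
    }


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, persist artifacts, and return the JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    with open(outdir / "log.jsonl", "w") as log:
        _log(log, "start", seed=config.seed, config=dataclasses.asdict(config))
        stages = [
            ("behavior", _run_behavior),
            ("cbpt", _run_eeg_cbpt),
            ("beamform", _run_beamform),
        ]
        if config.connectivity.enabled:
            stages.append(("connectivity", _run_connectivity))
        for name, fn in stages:
            t0 = time.perf_counter()
            try:
                summary[name] = fn(config, outdir, log)
            except Exception as err:
                _log(log, name, error=str(err))
                (outdir / "summary_partial.json").write_text(
                    json.dumps(summary, indent=1, default=str)
                )
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            _log(log, name, elapsed_s=round(time.perf_counter() - t0, 3))
    text = json.dumps(summary, indent=1, sort_keys=True, default=str)
    (outdir / "summary.json").write_text(text)
    summary["summary_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return summary
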