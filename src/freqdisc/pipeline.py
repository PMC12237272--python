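"""End-to-end pipeline: simulate -> analyze -> decode -> report.

Stages operate on files with the schemas defined by the analysis modules,
so each can also be run standalone (see :mod:`freqdisc.cli`).  Every stage
is a pure function of (inputs, configuration, seed); a JSON manifest
records produced files, seeds, package version and per-stage record
counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import read_spike_table, write_spike_table
from .decoder import (
    WT_SUMMARY,
    run_discrimination_experiment,
    scaled_summary,
    summary_from_recordings,
)
from .fra import extract_fra_metrics, metrics_to_frame
from .psychophysics import fa_by_octave_band, psychometric_from_trials
from .rlf import build_cf_rlf, filter_fits, fit_rlf, fits_to_frame
from .spikedist import delta_distance_vs_cf
from .synth import (
    KO_ACX_LIKE,
    WT_LIKE,
    BehaviorGenParams,
    GenotypeRegime,
    gen_behavior_session,
    gen_tuning_matrix,
    gen_unit_population,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "behavior", "rlf", "fra", "spikedist", "decode", "report")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "freqdisc_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_units: int = 6
    regimes: dict = field(
        default_factory=lambda: {
            "WT": {"spont_scale": 1.0, "evoked_scale": 1.0, "width_scale": 1.0},
            "KO": {"spont_scale": 1.5, "evoked_scale": 1.3, "width_scale": 1.4},
        }
    )
    n_behavior_sessions: int = 5
    decoder_n_trials: int = 1000
    decoder_n_runs: int = 5
    decoder_go_freqs: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0)
    decoder_source: str = "config"  # config | recordings
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        if self.n_units <= 0 or self.decoder_n_trials <= 0 or self.decoder_n_runs <= 0:
            raise ValueError("counts must be positive")
        if self.decoder_source not in ("config", "recordings"):
            raise ValueError("decoder_source must be 'config' or 'recordings'")
        return self


def _spike_path(out: Path, label: str) -> Path:
    return out / f"spikes_{label}.csv"


def _stage_simulate(cfg: RunConfig, out: Path, manifest: dict):
    rng_root = np.random.SeedSequence(cfg.seed)
    reg_seqs = rng_root.spawn(len(cfg.regimes) + 1)
    files = []
    n_rows = 0
    for (label, scales), seq in zip(cfg.regimes.items(), reg_seqs):
        regime = GenotypeRegime(label, n_units=cfg.n_units, **scales)
        unit_seq, *mat_seqs = seq.spawn(cfg.n_units + 1)
        params = gen_unit_population(regime, np.random.default_rng(unit_seq))
        matrices = [
            gen_tuning_matrix(
                p,
                seed=np.random.default_rng(s),
                unit_id=f"{label}_u{i:03d}",
                genotype_label=label,
                animal_id=f"{label}_a0",
                penetration_id=f"{label}_p0",
            )
            for i, (p, s) in enumerate(zip(params, mat_seqs))
        ]
        path = _spike_path(out, label)
        write_spike_table(matrices, path)
        files.append(str(path))
        n_rows += sum(
            ts.total_spikes() for m in matrices for ts in m.cells.values()
        )
    beh_seq = reg_seqs[-1]
    beh_rows = []
    for i, s in enumerate(beh_seq.spawn(2 * cfg.n_behavior_sessions)):
        mode = "detection" if i < cfg.n_behavior_sessions else "discrimination"
        beh_rows.append(
            gen_behavior_session(
                BehaviorGenParams(), mode=mode,
                seed=np.random.default_rng(s), session_id=f"{mode[:3]}{i:02d}",
            )
        )
    beh = pd.concat(beh_rows, ignore_index=True)
    beh_path = out / "behavior.csv"
    beh.to_csv(beh_path, index=False)
    files.append(str(beh_path))
    manifest["stages"]["simulate"] = {
        "files": files, "n_spikes": n_rows, "n_behavior_trials": len(beh)
    }


def _load_matrices(cfg: RunConfig, out: Path):
    matrices = []
    for label in cfg.regimes:
        path = _spike_path(out, label)
        if not path.exists():
            raise FileNotFoundError(f"missing upstream spike table {path}")
        matrices.extend(read_spike_table(path))
    return matrices


def _fra_for(matrices, cache: dict):
    for m in matrices:
        if m.unit_id not in cache:
            cache[m.unit_id] = extract_fra_metrics(m)
    return [cache[m.unit_id] for m in matrices]


def _stage_behavior(cfg: RunConfig, out: Path, manifest: dict):
    path = out / "behavior.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing upstream behavior table {path}")
    beh = pd.read_csv(path)
    reports = {}
    fa_frames = []
    for sid, g in beh.groupby("session_id"):
        if (g["trial_type"] == "catch").any():
            psy = psychometric_from_trials(g)
            reports[sid] = {
                "mode": "detection",
                "levels_db": psy.levels_db.tolist(),
                "d_prime": [round(v, 4) for v in psy.d_prime],
                "threshold_db": psy.threshold_db,
            }
        else:
            go_freq = float(g.loc[g["trial_type"] == "go", "freq_khz"].iloc[0])
            fa = fa_by_octave_band(g, go_freq)
            reports[sid] = {
                "mode": "discrimination",
                "go_freq_khz": go_freq,
                "bands": {k: {"n": v[0], "fa_rate": v[1]} for k, v in fa.bands.items()},
            }
            fa_frames.append(fa.per_step.assign(session_id=sid))
    with open(out / "behavior_report.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    if fa_frames:
        pd.concat(fa_frames, ignore_index=True).to_csv(out / "fa_by_step.csv", index=False)
    manifest["stages"]["behavior"] = {
        "files": [str(out / "behavior_report.json"), str(out / "fa_by_step.csv")],
        "n_sessions": len(reports),
    }


def _stage_fra(cfg: RunConfig, out: Path, manifest: dict, fra_cache: dict):
    matrices = _load_matrices(cfg, out)
    metrics = _fra_for(matrices, fra_cache)
    df = metrics_to_frame(metrics)
    path = out / "fra_metrics.csv"
    df.to_csv(path, index=False)
    manifest["stages"]["fra"] = {
        "files": [str(path)],
        "n_units": len(df),
        "n_resolved": int(df["cf_khz"].notna().sum()),
    }


def _stage_rlf(cfg: RunConfig, out: Path, manifest: dict, fra_cache: dict):
    matrices = _load_matrices(cfg, out)
    metrics = _fra_for(matrices, fra_cache)
    fits = []
    for m, fm in zip(matrices, metrics):
        if not fm.resolved:
            continue
        fits.append(fit_rlf(build_cf_rlf(m, fm.cf_khz)))
    kept, excl_report = filter_fits(fits)
    df = fits_to_frame(fits)
    path = out / "rlf_fits.csv"
    df.to_csv(path, index=False)
    manifest["stages"]["rlf"] = {
        "files": [str(path)],
        "n_fits": len(fits),
        "n_admitted": len(kept),
        "exclusions": excl_report.drop(columns="excluded_units").to_dict("records"),
    }


def _stage_spikedist(cfg: RunConfig, out: Path, manifest: dict, fra_cache: dict):
    matrices = _load_matrices(cfg, out)
    metrics = _fra_for(matrices, fra_cache)
    frames = []
    skipped = []
    for m, fm in zip(matrices, metrics):
        if not fm.resolved:
            skipped.append(m.unit_id)
            continue
        frames.append(delta_distance_vs_cf(m, fm))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    path = out / "spike_distance.csv"
    df.to_csv(path, index=False)
    manifest["stages"]["spikedist"] = {
        "files": [str(path)], "n_units": len(frames), "skipped_units": skipped
    }


def _stage_decode(cfg: RunConfig, out: Path, manifest: dict, fra_cache: dict):
    summaries = {}
    if cfg.decoder_source == "recordings":
        matrices = _load_matrices(cfg, out)
        metrics = _fra_for(matrices, fra_cache)
        for label in cfg.regimes:
            ms = [m for m in matrices if m.genotype_label == label]
            fs = [f for m, f in zip(matrices, metrics) if m.genotype_label == label]
            summaries[label] = summary_from_recordings(ms, fs)
    else:
        for label, scales in cfg.regimes.items():
            summaries[label] = scaled_summary(
                WT_SUMMARY,
                spont_scale=scales.get("spont_scale", 1.0),
                evoked_scale=scales.get("evoked_scale", 1.0),
                width_scale=scales.get("width_scale", 1.0),
            )
    frames = []
    for i, (label, summary) in enumerate(summaries.items()):
        res = run_discrimination_experiment(
            summary,
            go_freqs_khz=cfg.decoder_go_freqs,
            n_trials=cfg.decoder_n_trials,
            n_runs=cfg.decoder_n_runs,
            seed=cfg.seed + 1000 + i,
            label=label,
        )
        frames.append(res.results.assign(population=label))
    df = pd.concat(frames, ignore_index=True)
    path = out / "decoder_errors.csv"
    df.to_csv(path, index=False)
    manifest["stages"]["decode"] = {
        "files": [str(path)],
        "n_rows": len(df),
        "summaries": {
            k: {"amplitude": s.amplitude, "sigma_oct": s.sigma_oct, "baseline": s.baseline}
            for k, s in summaries.items()
        },
    }


def _stage_report(cfg: RunConfig, out: Path, manifest: dict):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []

    def save(fig, name):
        path = out / name
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        files.append(str(path))

    fa_path = out / "fa_by_step.csv"
    if fa_path.exists():
        fa = pd.read_csv(fa_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        curve = fa.groupby("octave_distance")["fa_rate"].mean()
        ax.plot(curve.index, curve.values, "o-", color="k")
        ax.set_xlabel("octave distance from Go tone")
        ax.set_ylabel("FA rate")
        ax.set_title("False alarms vs tonal distance")
        save(fig, "report_fa_by_octave.png")

    fra_path = out / "fra_metrics.csv"
    if fra_path.exists():
        fra = pd.read_csv(fra_path)
        qcols = [c for c in fra.columns if c.startswith("q")]
        if qcols and len(fra):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            labels = [lab for lab in fra["genotype"].unique() if len(fra[fra["genotype"] == lab])]
            width = 0.8 / max(len(labels), 1)
            for li, lab in enumerate(labels):
                sub = fra[fra["genotype"] == lab]
                means = [sub[c].dropna().mean() for c in qcols]
                ax.bar(
                    np.arange(len(qcols)) + li * width, means, width,
                    label=str(lab),
                )
            ax.set_xticks(np.arange(len(qcols)) + 0.2, [c.upper() for c in qcols])
            ax.set_ylabel("Q value")
            ax.legend()
            ax.set_title("Tuning sharpness above threshold")
            save(fig, "report_q_values.png")

    sd_path = out / "spike_distance.csv"
    if sd_path.exists():
        sd = pd.read_csv(sd_path)
        if len(sd):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            sd["absd"] = sd["octave_distance"].abs().round(2)
            for lab, sub in sd.groupby("genotype"):
                curve = sub.groupby("absd")["delta_distance"].mean()
                ax.plot(curve.index, curve.values, "o-", label=str(lab))
            ax.set_xlabel("octave distance from CF")
            ax.set_ylabel("Delta SPIKE-distance")
            ax.legend()
            ax.set_title("Neural discriminability vs frequency separation")
            save(fig, "report_delta_spike_distance.png")

    dec_path = out / "decoder_errors.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        if len(dec):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            dec["absoff"] = dec["offset_twelfths"].abs()
            for lab, sub in dec.groupby("population"):
                curve = sub.groupby("absoff")["error"].mean()
                ax.plot(curve.index / 12.0, curve.values, "o-", label=str(lab))
            ax.set_xlabel("octave distance from Go tone")
            ax.set_ylabel("decoder error rate")
            ax.legend()
            ax.set_title("Population decoder performance")
            save(fig, "report_decoder_error.png")

    rlf_path = out / "rlf_fits.csv"
    if rlf_path.exists():
        fits = pd.read_csv(rlf_path)
        if len(fits):
            from .rlf import rlf_curve

            fig, ax = plt.subplots(figsize=(5, 3.5))
            grid = np.linspace(0, 90, 91)
            colors = {lab: f"C{i}" for i, lab in enumerate(fits["genotype"].unique())}
            for _, row in fits.iterrows():
                if not row["converged"]:
                    continue
                ax.plot(
                    grid,
                    rlf_curve(grid, row["a"], row["b"], row["c"], row["d"], row["e"], row["f"]),
                    color=colors[row["genotype"]], alpha=0.4, lw=1,
                )
            for lab, c in colors.items():
                ax.plot([], [], color=c, label=str(lab))
            ax.set_xlabel("level (dB SPL)")
            ax.set_ylabel("driven rate (spikes/s)")
            ax.legend()
            ax.set_title("Fitted rate-level functions at CF")
            save(fig, "report_rlf_overlays.png")

    manifest["stages"]["report"] = {"files": files}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
    }
    fra_cache: dict = {}
    runners = {
        "simulate": lambda: _stage_simulate(cfg, out, manifest),
        "behavior": lambda: _stage_behavior(cfg, out, manifest),
        "fra": lambda: _stage_fra(cfg, out, manifest, fra_cache),
        "rlf": lambda: _stage_rlf(cfg, out, manifest, fra_cache),
        "spikedist": lambda: _stage_spikedist(cfg, out, manifest, fra_cache),
        "decode": lambda: _stage_decode(cfg, out, manifest, fra_cache),
        "report": lambda: _stage_report(cfg, out, manifest),
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.time()
        logger.info("stage %s ...", stage)
        try:
            runners[stage]()
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            _write_manifest(out, manifest)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage]["seconds"] = round(time.time() - t0, 2)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)


def report_from_manifest(manifest_path) -> dict:
    """Regenerate the report stage from an existing manifest (idempotent)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg = RunConfig(**{
        k: v for k, v in manifest["config"].items()
        if k in RunConfig.__dataclass_fields__
    })
    out = Path(cfg.out_dir)
    _stage_report(cfg, out, manifest)
    _write_manifest(out, manifest)
    return manifest
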