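"""End-to-end pipeline: simulate -> preprocess -> cluster -> backfit ->
parameters -> statistics -> report.

Every stage reads only files written by earlier stages and writes its own
artifacts into the run directory, so any stage can be re-run from disk.
A single seed in the config fans out deterministically to per-stage child
seeds; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .canonical import canonical_maps
from .containers import Montage
from .exceptions import (InsufficientDataError, InvalidArgumentError,
                         MissingArtifactError)
from .microstates import backfit, find_gfp_peaks, gev, gfp, label_templates, \
    two_level_cluster
from .parameters import PARAMETERS, cohort_parameters
from .preprocess import bandpass, epoch_recording, reject_epochs
from .simulate import SimSpec, generate_cohort
from .stats import class_mean_maps, clinical_correlations, compare_parameters, \
    tanova_by_class

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "cluster", "backfit", "params", "stats")

_COND_GROUP = {"HC": "HC", "PD_OFF": "PD_OFF", "PD_ON": "PD_ON"}


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults follow standard clinical practice
    (2-s epochs, 1-40 Hz cleaning band, 2-20 Hz clustering band, four
    microstate classes, significance at 0.05 and 0.01 for correlations)."""

    data_dir: str = "data"
    out_dir: str = "run"
    epoch_length: float = 2.0
    clean_band: Tuple[float, float] = (1.0, 40.0)
    cluster_band: Tuple[float, float] = (2.0, 20.0)
    K: int = 4
    reject_uv: float = 100.0
    min_peak_distance_ms: float = 10.0
    max_maps_per_subject: int = 1000
    exclude_channels: List[str] = field(default_factory=list)
    n_permutations: int = 5000
    alpha: float = 0.05
    alpha_clinical: float = 0.01
    fdr_method: str = "fdr_bh"
    gev_at_peaks: bool = True
    seed: int = 0
    #: overrides for SimSpec; None disables the simulate stage
    simulate: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise InvalidArgumentError("K must be >= 2")
        self.clean_band = tuple(self.clean_band)  # type: ignore[assignment]
        self.cluster_band = tuple(self.cluster_band)  # type: ignore[assignment]
        for band in (self.clean_band, self.cluster_band):
            if not (0 < band[0] < band[1]):
                raise InvalidArgumentError(f"invalid band {band}")
        if self.epoch_length <= 0 or self.reject_uv <= 0:
            raise InvalidArgumentError("epoch length and threshold must be positive")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["clean_band"] = list(self.clean_band)
        d["cluster_band"] = list(self.cluster_band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1)[0] % (2 ** 31))


# ------------------------------------------------------------------ helpers

def _discover_subjects(data_dir: Path) -> List[Tuple[str, str]]:
    pairs = []
    for p in sorted(data_dir.glob("*_eeg.csv")):
        stem = p.name[:-len("_eeg.csv")]
        sid, _, cond = stem.partition("_")
        pairs.append((sid, cond))
    if not pairs:
        raise MissingArtifactError(f"no *_eeg.csv recordings in {data_dir}")
    return pairs


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"required artifact missing: {path}")
    return path


def _load_preprocessed(run_dir: Path, sid: str, cond: str,
                       montage: Montage) -> Tuple[np.ndarray, float, np.ndarray]:
    path = _require(run_dir / "preprocessed" / f"{sid}_{cond}.csv")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return data, float(sidecar["fs"]), np.array(sidecar["epoch_edges"], dtype=int)


def _epochwise_cluster_band(data: np.ndarray, fs: float, edges: np.ndarray,
                            band: Tuple[float, float]) -> np.ndarray:
    """2-20 Hz filter applied per epoch (no bleed across boundaries)."""
    from scipy.signal import butter, sosfiltfilt
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    out = np.empty_like(data)
    for a, b in zip(edges[:-1], edges[1:]):
        out[:, a:b] = sosfiltfilt(sos, data[:, a:b], axis=-1)
    return out - out.mean(axis=0, keepdims=True)


def _collect_peak_maps(data: np.ndarray, fs: float, edges: np.ndarray,
                       min_distance_ms: float) -> np.ndarray:
    maps = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = data[:, a:b]
        pk = find_gfp_peaks(gfp(seg), fs, min_distance_ms)
        if pk.size:
            maps.append(seg[:, pk].T)
    if not maps:
        raise InsufficientDataError("no GFP peaks found in any epoch")
    return np.vstack(maps)


def _subsample(maps: np.ndarray, max_maps: int) -> np.ndarray:
    if len(maps) <= max_maps:
        return maps
    idx = np.linspace(0, len(maps) - 1, max_maps).astype(int)
    return maps[idx]


# ------------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> None:
    if cfg.simulate is None:
        logger.info("simulate: no spec in config, skipping")
        return
    overrides = dict(cfg.simulate)
    overrides.setdefault("seed", cfg.stage_seed("simulate"))
    spec = SimSpec(**overrides)
    generate_cohort(spec, out_dir=Path(cfg.data_dir))
    logger.info("simulate: wrote cohort to %s", cfg.data_dir)


def stage_preprocess(cfg: PipelineConfig) -> None:
    data_dir = Path(cfg.data_dir)
    montage = io.read_montage(_require(data_dir / "montage.txt"))
    if cfg.exclude_channels:
        keep = [n for n in montage.channel_names if n not in cfg.exclude_channels]
        montage = Montage(tuple(keep), montage.positions[montage.index_of(keep)])
    out = Path(cfg.out_dir) / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    for sid, cond in _discover_subjects(data_dir):
        rec = io.read_recording(data_dir / f"{sid}_{cond}_eeg.csv", montage)
        rec = bandpass(rec, *cfg.clean_band)
        ep = epoch_recording(rec, cfg.epoch_length)
        ep = reject_epochs(ep, cfg.reject_uv)
        if ep.n_kept == 0:
            raise InsufficientDataError(
                f"{sid}/{cond}: every epoch exceeded {cfg.reject_uv} uV")
        data = ep.concatenate()
        n_len = data.shape[1] // ep.n_kept
        edges = np.arange(ep.n_kept + 1) * n_len
        np.savetxt(out / f"{sid}_{cond}.csv", data, fmt="%.4f", delimiter=",")
        sidecar = {"fs": rec.fs, "epoch_edges": [int(e) for e in edges],
                   "subject_id": sid, "condition": cond,
                   "n_epochs_total": int(ep.n_epochs),
                   "n_epochs_kept": int(ep.n_kept)}
        (out / f"{sid}_{cond}.json").write_text(json.dumps(sidecar, indent=1))
    logger.info("preprocess: done")


def stage_cluster(cfg: PipelineConfig) -> None:
    run_dir = Path(cfg.out_dir)
    montage = io.read_montage(_require(Path(cfg.data_dir) / "montage.txt"))
    subjects = _discover_subjects(Path(cfg.data_dir))
    canon = canonical_maps(montage, cfg.K)
    for group in sorted({cond for _, cond in subjects}):
        group_maps = []
        for sid, cond in subjects:
            if cond != group:
                continue
            data, fs, edges = _load_preprocessed(run_dir, sid, cond, montage)
            filt = _epochwise_cluster_band(data, fs, edges, cfg.cluster_band)
            maps = _collect_peak_maps(filt, fs, edges, cfg.min_peak_distance_ms)
            group_maps.append(_subsample(maps, cfg.max_maps_per_subject))
        templates = two_level_cluster(group_maps, cfg.K)
        templates = label_templates(templates, canon)
        io.write_templates(templates, run_dir / f"templates_{group}.csv")
        logger.info("cluster: %s templates GEV=%.3f", group, templates.gev)


def stage_backfit(cfg: PipelineConfig) -> None:
    run_dir = Path(cfg.out_dir)
    montage = io.read_montage(_require(Path(cfg.data_dir) / "montage.txt"))
    labels_dir = run_dir / "labels"
    labels_dir.mkdir(parents=True, exist_ok=True)
    gev_rows = []
    for sid, cond in _discover_subjects(Path(cfg.data_dir)):
        templates = io.read_templates(_require(run_dir / f"templates_{cond}.csv"))
        data, fs, edges = _load_preprocessed(run_dir, sid, cond, montage)
        filt = _epochwise_cluster_band(data, fs, edges, cfg.cluster_band)
        seq = backfit(filt, templates, fs, cfg.min_peak_distance_ms, edges)
        io.write_labels(seq, labels_dir / f"{sid}_{cond}.csv")
        g = gev(filt, seq, templates, at_peaks=cfg.gev_at_peaks,
                min_distance_ms=cfg.min_peak_distance_ms)
        gev_rows.append({"subject_id": sid, "condition": cond, "gev": g})
    pd.DataFrame(gev_rows).to_csv(run_dir / "gev.csv", index=False,
                                  float_format="%.6f")
    logger.info("backfit: done")


def stage_params(cfg: PipelineConfig) -> None:
    run_dir = Path(cfg.out_dir)
    sequences = {}
    for sid, cond in _discover_subjects(Path(cfg.data_dir)):
        seq = io.read_labels(_require(run_dir / "labels" / f"{sid}_{cond}.csv"))
        sequences[(sid, cond)] = seq
    params = cohort_parameters(sequences)
    params.to_csv(run_dir / "params.csv", index=False, float_format="%.6f")
    logger.info("params: wrote %d rows", len(params))


def stage_stats(cfg: PipelineConfig) -> None:
    run_dir = Path(cfg.out_dir)
    montage = io.read_montage(_require(Path(cfg.data_dir) / "montage.txt"))
    params = pd.read_csv(_require(run_dir / "params.csv"))
    conditions = set(params["condition"])

    # per-parameter comparison tables (layout: one table per parameter)
    if {"HC", "PD_OFF", "PD_ON"} <= conditions:
        comp = compare_parameters(params, alpha=cfg.alpha)
        for i, param in enumerate(PARAMETERS, start=1):
            tab = comp[comp["parameter"] == param].drop(columns="parameter")
            tab.to_csv(run_dir / f"table{i}_{param}.csv", index=False,
                       float_format="%.6g")

        # TANOVA on subject-level class-mean maps
        subject_maps: Dict[str, Dict[str, list]] = {}
        for sid, cond in _discover_subjects(Path(cfg.data_dir)):
            seq = io.read_labels(run_dir / "labels" / f"{sid}_{cond}.csv")
            data, fs, edges = _load_preprocessed(run_dir, sid, cond, montage)
            filt = _epochwise_cluster_band(data, fs, edges, cfg.cluster_band)
            means = class_mean_maps(filt, seq)
            for k, cls in enumerate(seq.class_labels):
                if np.all(np.isfinite(means[k])):
                    subject_maps.setdefault(cond, {}).setdefault(cls, []).append(
                        means[k])
        stacked = {g: {c: np.vstack(v) for c, v in d.items()}
                   for g, d in subject_maps.items()}
        tan = tanova_by_class(stacked, n_permutations=cfg.n_permutations,
                              seed=cfg.stage_seed("stats"))
        tan.to_csv(run_dir / "tanova.csv", index=False, float_format="%.6g")

    clinical_path = Path(cfg.data_dir) / "clinical.csv"
    if clinical_path.exists() and "PD_OFF" in conditions:
        clinical = io.read_clinical(clinical_path)
        corr = clinical_correlations(params, clinical, condition="PD_OFF",
                                     alpha=cfg.alpha_clinical)
        if "PD_ON" in conditions:
            corr = pd.concat([corr, clinical_correlations(
                params, clinical, condition="PD_ON",
                alpha=cfg.alpha_clinical)], ignore_index=True)
        corr.to_csv(run_dir / "correlations.csv", index=False,
                    float_format="%.6g")

    meta = {"version": __version__, "seed": cfg.seed,
            "stats_seed": cfg.stage_seed("stats"),
            "n_permutations": cfg.n_permutations,
            "alpha": cfg.alpha, "alpha_clinical": cfg.alpha_clinical,
            "fdr_method": cfg.fdr_method,
            "fdr_family": "classes x one parameter type x one score",
            "settings": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in dataclasses.asdict(cfg).items()}}
    (run_dir / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    logger.info("stats: done")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages in order; on failure the failing stage is named and
    partial outputs are preserved."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    stage_fns = {"simulate": stage_simulate, "preprocess": stage_preprocess,
                 "cluster": stage_cluster, "backfit": stage_backfit,
                 "params": stage_params, "stats": stage_stats}
    for name in STAGES:
        try:
            stage_fns[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    report(run_dir)
    return run_dir


# ------------------------------------------------------------------- report

def report(run_dir) -> str:
    """Human-readable summary of a completed run (also written to report.txt)."""
    run_dir = Path(run_dir)
    params = pd.read_csv(_require(run_dir / "params.csv"))
    gev_df = pd.read_csv(_require(run_dir / "gev.csv"))
    lines = ["Microstate analysis summary", "=" * 29, ""]
    by_cond = params.groupby("condition")
    for cond, sub in by_cond:
        per_subj = sub.groupby("subject_id").agg(
            duration=("duration_s", "mean"), occurrence=("occurrence_hz", "sum"),
            coverage=("coverage", "mean"))
        gv = gev_df[gev_df["condition"] == cond]["gev"]
        lines.append(
            f"{cond}: mean duration {per_subj['duration'].mean():.4f} s, "
            f"occurrence {per_subj['occurrence'].mean():.2f} /s, "
            f"GEV {100 * gv.mean():.1f}% (SD {100 * gv.std(ddof=1):.1f}%), "
            f"n={len(per_subj)}")
    lines.append("")
    for i, param in enumerate(PARAMETERS, start=1):
        path = run_dir / f"table{i}_{param}.csv"
        if not path.exists():
            continue
        tab = pd.read_csv(path)
        sig = []
        for _, row in tab.iterrows():
            for tag in ("HC_vs_PD_OFF", "HC_vs_PD_ON", "PD_OFF_vs_PD_ON"):
                if row.get(f"{tag}_significant", False):
                    sig.append(f"{row['class']} {tag} (p={row[f'{tag}_p']:.3g})")
        lines.append(f"{param}: significant: {', '.join(sig) if sig else 'none'}")
    tan_path = run_dir / "tanova.csv"
    if tan_path.exists():
        tan = pd.read_csv(tan_path)
        lines.append("")
        lines.append("TANOVA p-values per class:")
        for _, row in tan.iterrows():
            lines.append(f"  {row['contrast']} {row['class']}: "
                         f"p={row['p_value']:.4g} ({row['design']})")
    corr_path = run_dir / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        sig = corr[corr["significant"]]
        lines.append("")
        lines.append(f"Clinical correlations: {len(sig)} significant "
                     f"(FDR-adjusted) of {len(corr)} tests")
        for _, row in sig.iterrows():
            lines.append(f"  {row['condition']} {row['class']} "
                         f"{row['parameter']} vs {row['score']}: r={row['r']:.2f} "
                         f"(p_fdr={row['p_fdr']:.3g})")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
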