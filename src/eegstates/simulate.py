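"""Synthetic resting-state EEG cohorts with known microstate structure.

The generator emulates a three-condition study — healthy controls (HC) and
Parkinson's disease patients with deep-brain stimulation off (PD_OFF) and on
(PD_ON) — in which brain dynamics are slowed in disease: PD conditions get a
longer mean microstate dwell time and therefore fewer state changes per
second.  Each subject's EEG is built from K fixed scalp topographies that
switch according to a semi-Markov sequence (i.i.d. dwell times per class,
uniform choice among the other classes), amplitude-modulated by a rectified
alpha-band carrier so that global field power (GFP) peaks occur at
predictable instants, plus spatially correlated Gaussian sensor noise at a
controlled SNR.  A clinical table links motor impairment (UPDRS-III) to
each subject's true mean dwell time, so that the dynamics/symptom
correlation the analysis should detect exists by construction.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io
from .canonical import CLASS_NAMES, raw_shapes
from .containers import LabelSequence, Montage, Recording, TemplateSet
from .exceptions import GenerationError, InvalidArgumentError

GROUPS = ("HC", "PD_OFF", "PD_ON")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a synthetic cohort.

    Dwell-time targets default to the slowed-dynamics pattern of the study
    conditions: mean microstate duration 0.068 s in HC vs 0.075 / 0.076 s in
    PD_OFF / PD_ON, with matched UPDRS-III group means of 46.5 (OFF) and
    17.1 (ON).
    """

    n_hc: int = 21
    n_pd: int = 20
    n_channels: int = 32
    fs: float = 250.0
    record_length: float = 300.0
    K: int = 4
    #: mean dwell time (s) per group; scalar applies to every class, or a
    #: length-K sequence gives per-class targets
    mean_dwell: Dict[str, Union[float, Sequence[float]]] = field(
        default_factory=lambda: {"HC": 0.068, "PD_OFF": 0.075, "PD_ON": 0.076})
    #: between-subject SD (s) of the per-subject dwell offset
    dwell_subject_sd: float = 0.008
    dwell_distribution: str = "gamma"  # "gamma" | "lognormal"
    dwell_shape: float = 2.0
    #: optional (K, K) successor matrix (rows sum to 1, zero diagonal);
    #: None = uniform among the K-1 other classes
    transition_matrix: Optional[np.ndarray] = None
    carrier_freq: float = 10.0
    snr_db: float = 10.0
    noise_spatial_corr: float = 0.3
    signal_amplitude_uv: float = 15.0
    #: clinical model: updrs = intercept[group] + slope * (dwell - group target) + noise
    clinical_slope: float = 800.0
    clinical_noise_sd: float = 6.0
    clinical_intercepts: Dict[str, float] = field(
        default_factory=lambda: {"PD_OFF": 46.5, "PD_ON": 17.1})
    ledd_mean: float = 900.0
    ledd_sd: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise InvalidArgumentError("K must be >= 2")
        if self.n_channels < 8:
            raise InvalidArgumentError("n_channels must be >= 8")
        if self.K > self.n_channels:
            raise InvalidArgumentError("K cannot exceed n_channels")
        if self.fs < 4 * self.carrier_freq:
            raise InvalidArgumentError(
                f"fs={self.fs} must be >= 4 x carrier_freq={self.carrier_freq}")
        if not (0.0 <= self.noise_spatial_corr <= 1.0):
            raise InvalidArgumentError("noise_spatial_corr must lie in [0, 1]")
        if self.record_length <= 0 or self.dwell_subject_sd < 0:
            raise InvalidArgumentError("durations must be positive")
        if self.dwell_distribution not in ("gamma", "lognormal"):
            raise InvalidArgumentError(
                f"unknown dwell distribution {self.dwell_distribution!r}")
        for g in GROUPS:
            if g not in self.mean_dwell:
                raise InvalidArgumentError(f"mean_dwell lacks group {g!r}")
            if np.any(np.asarray(self.mean_dwell[g], dtype=float) <= 0):
                raise InvalidArgumentError("mean dwell targets must be positive")
        if self.transition_matrix is not None:
            T = np.asarray(self.transition_matrix, dtype=float)
            if T.shape != (self.K, self.K):
                raise InvalidArgumentError("transition matrix must be K x K")
            if np.any(np.abs(np.diag(T)) > 1e-12) or np.any(T < 0):
                raise InvalidArgumentError(
                    "transition matrix needs zero diagonal and non-negative rates")
            if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidArgumentError("transition matrix rows must sum to 1")

    def class_dwell(self, group: str) -> np.ndarray:
        """Per-class mean dwell targets (s) for one group."""
        target = np.asarray(self.mean_dwell[group], dtype=float)
        if target.ndim == 0:
            return np.full(self.K, float(target))
        if target.size != self.K:
            raise InvalidArgumentError("per-class dwell targets must have length K")
        return target


@dataclass(frozen=True)
class GroundTruth:
    """True generating quantities attached to a synthetic cohort."""

    montage: Montage
    templates: TemplateSet
    label_sequences: Dict[Tuple[str, str], LabelSequence]  # (subject, condition)
    subject_dwell: pd.DataFrame  # subject_id, condition, mean_dwell_s
    clinical: pd.DataFrame


# ----------------------------------------------------------------- montage

def generate_montage(n_channels: int, seed: int) -> Montage:
    """Quasi-uniform electrode positions on the upper unit hemisphere.

    A Fibonacci lattice supplies the base layout; a seed-dependent global
    rotation plus small angular jitter make distinct seeds produce distinct
    (but equally regular) montages.
    """
    if n_channels < 8:
        raise InvalidArgumentError(f"need >= 8 channels, got {n_channels}")
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels          # heights in (0, 1): upper hemisphere
    theta = np.arccos(z)                # polar angle from vertex
    phi = i * _GOLDEN_ANGLE + rng.uniform(0, 2 * np.pi)
    theta = np.clip(theta + rng.normal(0, 0.02, n_channels), 1e-3, np.pi / 2 - 1e-3)
    phi = phi + rng.normal(0, 0.02, n_channels)
    pos = np.column_stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])
    names = tuple(f"E{k + 1:03d}" for k in range(n_channels))
    return Montage(names, pos)


# --------------------------------------------------------------- templates

def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def _deflate_pair(mj: np.ndarray, mi: np.ndarray, target: float) -> np.ndarray:
    """Remove just enough of ``mi`` from ``mj`` to bring |corr| down to ``target``.

    Both maps are zero-mean and unit-norm; the minimal-change root of the
    quadratic in the deflation coefficient is used, so the map keeps its
    canonical character.
    """
    r = _corr(mj, mi)
    t = np.sign(r) * target
    c = r - t * np.sqrt(max((1 - r ** 2), 0.0) / (1 - t ** 2))
    out = mj - c * mi
    return out / np.linalg.norm(out)


def generate_templates(K: int, montage: Montage, seed: int,
                       max_corr: float = 0.5, max_retries: int = 20) -> TemplateSet:
    """K average-referenced, unit-GFP template maps with |r| <= ``max_corr``.

    Shapes start from the canonical A-D patterns, get seed-dependent smooth
    perturbations, and are then pairwise deflated until every absolute
    spatial correlation is at or below the separation bound.
    """
    if K > montage.n_channels:
        raise InvalidArgumentError("K cannot exceed the number of channels")
    base = raw_shapes(montage, K)
    n_ch = montage.n_channels
    rng = np.random.default_rng(seed)
    target = 0.9 * max_corr  # aim below the bound, leave slack for round-off
    for _ in range(max_retries):
        maps = base + 0.25 * rng.standard_normal((K, n_ch)) * base.std(axis=1,
                                                                       keepdims=True)
        maps = maps - maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        for _ in range(50):
            worst = 0.0
            for j in range(1, K):
                for i in range(j):
                    r = abs(_corr(maps[j], maps[i]))
                    worst = max(worst, r)
                    if r > target:
                        maps[j] = _deflate_pair(maps[j], maps[i], target)
                        maps[j] -= maps[j].mean()
                        maps[j] /= np.linalg.norm(maps[j])
            if worst <= target:
                break
        corrs = [abs(_corr(maps[j], maps[i])) for j in range(1, K) for i in range(j)]
        if max(corrs) <= max_corr:
            maps = maps - maps.mean(axis=1, keepdims=True)
            maps /= maps.std(axis=1, keepdims=True)  # unit GFP
            labels = list(CLASS_NAMES[:min(K, 4)]) + [f"X{j}" for j in range(4, K)]
            return TemplateSet(maps, tuple(labels), level="group")
    raise GenerationError(
        f"could not reach pairwise |r| <= {max_corr} after {max_retries} draws")


# ----------------------------------------------------------- state sequence

def _draw_dwell(rng: np.random.Generator, mean: float, spec: SimSpec) -> float:
    if spec.dwell_distribution == "gamma":
        return float(rng.gamma(spec.dwell_shape, mean / spec.dwell_shape))
    # lognormal parameterized by shape sigma with the requested mean
    sigma = 1.0 / np.sqrt(spec.dwell_shape)
    mu = np.log(mean) - 0.5 * sigma ** 2
    return float(rng.lognormal(mu, sigma))


def generate_state_sequence(spec: SimSpec, group: str, seed: int,
                            mean_dwell_override: Optional[np.ndarray] = None,
                            ) -> LabelSequence:
    """Semi-Markov microstate label sequence for one subject.

    Dwell times are drawn i.i.d. from the spec's distribution per class
    (default gamma with shape 2, so durations are unimodal and ultrashort
    runs are rare); the successor class is uniform among the other K-1
    classes unless a transition matrix is supplied.
    """
    if group not in GROUPS:
        raise InvalidArgumentError(f"unknown group {group!r}")
    targets = (np.asarray(mean_dwell_override, dtype=float)
               if mean_dwell_override is not None else spec.class_dwell(group))
    if targets.shape != (spec.K,) or np.any(targets <= 0):
        raise InvalidArgumentError("dwell targets must be K positive values")
    rng = np.random.default_rng(seed)
    n = int(round(spec.record_length * spec.fs))
    labels = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.integers(spec.K))
    T = spec.transition_matrix
    while pos < n:
        dwell = max(1, int(round(_draw_dwell(rng, targets[state], spec) * spec.fs)))
        end = min(n, pos + dwell)
        labels[pos:end] = state
        pos = end
        if T is not None:
            state = int(rng.choice(spec.K, p=np.asarray(T, dtype=float)[state]))
        else:
            step = int(rng.integers(spec.K - 1))
            state = step if step < state else step + 1
    names = list(CLASS_NAMES[:min(spec.K, 4)]) + [f"X{j}" for j in range(4, spec.K)]
    return LabelSequence(labels, spec.fs, tuple(names))


# ------------------------------------------------------------- EEG synthesis

def _noise_mixing(montage: Montage, rho: float) -> np.ndarray:
    """Cholesky factor of a distance-decaying channel covariance.

    rho = 0 gives white sensor noise; rho -> 1 gives noise fully dominated by
    a smooth spatial profile (correlation exp(-d^2) between electrodes).
    """
    if rho == 0.0:
        return np.eye(montage.n_channels)
    d2 = np.sum((montage.positions[:, None, :] - montage.positions[None, :, :]) ** 2,
                axis=-1)
    C = (1.0 - rho) * np.eye(montage.n_channels) + rho * np.exp(-d2)
    return np.linalg.cholesky(C + 1e-9 * np.eye(montage.n_channels))


def synthesize_eeg(templates: TemplateSet, labels: LabelSequence, spec: SimSpec,
                   seed: int, montage: Optional[Montage] = None,
                   subject_id: Optional[str] = None,
                   condition: Optional[str] = None,
                   return_parts: bool = False):
    """Render a label sequence as multichannel EEG.

    signal(t) = amplitude * template[label(t)] * a(t), where a(t) is a
    rectified sinusoid at the carrier frequency with per-half-cycle amplitude
    jitter; Gaussian spatially correlated noise is added at ``spec.snr_db``
    and the result is average-referenced.
    """
    if templates.K < len(labels.class_labels):
        raise InvalidArgumentError("template set and label legend disagree")
    if montage is None:
        montage = generate_montage(templates.n_channels, seed=0)
    rng = np.random.default_rng(seed)
    n = labels.n_samples
    t = np.arange(n) / spec.fs
    phase = 2 * np.pi * spec.carrier_freq * t + rng.uniform(0, 2 * np.pi)
    half_cycle = np.floor(phase / np.pi).astype(int)
    half_cycle -= half_cycle[0]
    gains = np.clip(1.0 + 0.1 * rng.standard_normal(half_cycle[-1] + 1), 0.3, None)
    a = np.abs(np.sin(phase)) * gains[half_cycle]
    signal = spec.signal_amplitude_uv * templates.maps[labels.labels].T * a
    signal -= signal.mean(axis=0, keepdims=True)

    if np.isinf(spec.snr_db):
        noise = np.zeros_like(signal)
    else:
        L = _noise_mixing(montage, spec.noise_spatial_corr)
        noise = L @ rng.standard_normal(signal.shape)
        noise -= noise.mean(axis=0, keepdims=True)
        p_sig = float(np.mean(signal ** 2))
        p_noise = float(np.mean(noise ** 2))
        scale = np.sqrt(p_sig / (10 ** (spec.snr_db / 10.0) * p_noise))
        noise *= scale
    data = signal + noise
    rec = Recording(data, spec.fs, montage, subject_id, condition)
    if return_parts:
        return rec, signal, noise
    return rec


# ------------------------------------------------------------------ cohort

def _subject_ids(spec: SimSpec) -> Tuple[list, list]:
    hc = [f"hc{k + 1:02d}" for k in range(spec.n_hc)]
    pd_ = [f"pd{k + 1:02d}" for k in range(spec.n_pd)]
    return hc, pd_


def generate_cohort(spec: SimSpec, out_dir: Optional[Path] = None,
                    ) -> Tuple[Dict[Tuple[str, str], Recording], GroundTruth]:
    """Generate the full synthetic cohort (HC once; PD in OFF and ON states).

    PD subjects are paired across conditions: a shared subject-level dwell
    offset plus a condition-specific offset (both Gaussian) produce the
    between-subject spread the clinical correlation needs, while group means
    stay on their targets.  UPDRS-III is an affine function of each
    subject's true mean dwell plus noise; LEDD is independent.

    Returns recordings keyed by (subject_id, condition) and the ground
    truth.  If ``out_dir`` is given, recordings, montage, true templates,
    true label sequences and the clinical table are also written there.
    """
    root = np.random.SeedSequence(spec.seed)
    s_montage, s_templates, s_subjects, s_clinical = root.spawn(4)
    montage = generate_montage(spec.n_channels, _seed_int(s_montage))
    templates = generate_templates(spec.K, montage, _seed_int(s_templates))

    hc_ids, pd_ids = _subject_ids(spec)
    rng_cl = np.random.default_rng(s_clinical)
    recordings: Dict[Tuple[str, str], Recording] = {}
    sequences: Dict[Tuple[str, str], LabelSequence] = {}
    dwell_rows = []

    plan = [(sid, "HC") for sid in hc_ids]
    plan += [(sid, cond) for sid in pd_ids for cond in ("PD_OFF", "PD_ON")]

    # per-subject dwell offsets (s): HC independent; PD shared + per-condition
    offsets: Dict[Tuple[str, str], float] = {}
    rng_off = np.random.default_rng(root.spawn(1)[0])
    for sid in hc_ids:
        offsets[(sid, "HC")] = rng_off.normal(0.0, spec.dwell_subject_sd)
    for sid in pd_ids:
        shared = rng_off.normal(0.0, spec.dwell_subject_sd * 0.7)
        for cond in ("PD_OFF", "PD_ON"):
            offsets[(sid, cond)] = shared + rng_off.normal(
                0.0, spec.dwell_subject_sd * 0.7)

    child_seeds = s_subjects.spawn(len(plan))
    for (sid, cond), child in zip(plan, child_seeds):
        targets = np.clip(spec.class_dwell(cond) + offsets[(sid, cond)], 0.02, None)
        s_seq, s_eeg = child.spawn(2)
        seq = generate_state_sequence(spec, cond, _seed_int(s_seq),
                                      mean_dwell_override=targets)
        rec = synthesize_eeg(templates, seq, spec, _seed_int(s_eeg),
                             montage=montage, subject_id=sid, condition=cond)
        recordings[(sid, cond)] = rec
        sequences[(sid, cond)] = seq
        dwell_rows.append({"subject_id": sid, "condition": cond,
                           "mean_dwell_s": float(np.mean(targets))})
    subject_dwell = pd.DataFrame(dwell_rows)

    clinical = _clinical_table(spec, subject_dwell, hc_ids, pd_ids, rng_cl)
    gt = GroundTruth(montage, templates, sequences, subject_dwell, clinical)

    if out_dir is not None:
        _write_cohort(out_dir, recordings, gt)
    return recordings, gt


def _clinical_table(spec: SimSpec, subject_dwell: pd.DataFrame,
                    hc_ids, pd_ids, rng: np.random.Generator) -> pd.DataFrame:
    dwell = subject_dwell.set_index(["subject_id", "condition"])["mean_dwell_s"]
    rows = []
    for sid in hc_ids:
        rows.append({"subject_id": sid, "group": "HC",
                     "updrs_off": np.nan, "updrs_on": np.nan, "ledd": np.nan})
    base_off = float(np.mean(spec.class_dwell("PD_OFF")))
    base_on = float(np.mean(spec.class_dwell("PD_ON")))
    for sid in pd_ids:
        u_off = (spec.clinical_intercepts["PD_OFF"]
                 + spec.clinical_slope * (dwell[(sid, "PD_OFF")] - base_off)
                 + rng.normal(0.0, spec.clinical_noise_sd))
        u_on = (spec.clinical_intercepts["PD_ON"]
                + spec.clinical_slope * (dwell[(sid, "PD_ON")] - base_on)
                + rng.normal(0.0, spec.clinical_noise_sd))
        ledd = max(150.0, rng.normal(spec.ledd_mean, spec.ledd_sd))
        rows.append({"subject_id": sid, "group": "PD",
                     "updrs_off": max(5.0, u_off), "updrs_on": max(1.0, u_on),
                     "ledd": ledd})
    return pd.DataFrame(rows)


def _write_cohort(out_dir: Path, recordings, gt: GroundTruth) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_montage(gt.montage, out_dir / "montage.txt")
    io.write_templates(gt.templates, out_dir / "templates_true.csv")
    io.write_clinical(gt.clinical, out_dir / "clinical.csv")
    gt.subject_dwell.to_csv(out_dir / "subject_dwell_true.csv", index=False,
                            float_format="%.6f")
    for (sid, cond), rec in recordings.items():
        stem = f"{sid}_{cond}"
        io.write_recording(rec, out_dir / f"{stem}_eeg.csv")
        io.write_labels(gt.label_sequences[(sid, cond)],
                        out_dir / f"{stem}_labels_true.csv")


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))
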