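"""Reading and writing recordings, montages, templates, labels and tables.

On-disk formats are deliberately plain:

* recordings — delimited matrix (channels x samples, microvolts, ``.csv`` or
  ``.tsv``) with a JSON sidecar ``{fs, channel_names, ...}``; EDF and
  BrainVision files are read through :mod:`mne`.
* montage — whitespace-delimited ``name x y z`` text;
* templates — CSV (rows = channels, columns = classes) plus JSON metadata;
* label sequences — per-sample integer CSV plus a JSON legend;
* clinical table — CSV with header ``subject_id,group,updrs_off,updrs_on,ledd``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import LabelSequence, Montage, Recording, TemplateSet
from .exceptions import ChannelMismatchError, InvalidArgumentError, SidecarError

PathLike = Union[str, Path]

CLINICAL_COLUMNS = ["subject_id", "group", "updrs_off", "updrs_on", "ledd"]


# ---------------------------------------------------------------- montage

def write_montage(montage: Montage, path: PathLike) -> None:
    path = Path(path)
    lines = [
        f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
        for name, p in zip(montage.channel_names, montage.positions)
    ]
    path.write_text("\n".join(lines) + "\n")


def read_montage(path: PathLike) -> Montage:
    names: list[str] = []
    pos: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise InvalidArgumentError(
                f"montage line needs 'name x y z', got {line!r}")
        names.append(parts[0])
        pos.append([float(v) for v in parts[1:]])
    return Montage(tuple(names), np.array(pos))


# -------------------------------------------------------------- recordings

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: PathLike) -> None:
    """Write a recording as a delimited matrix plus JSON sidecar."""
    path = Path(path)
    if path.suffix not in (".csv", ".tsv"):
        raise InvalidArgumentError(
            f"matrix recordings must end in .csv or .tsv, got {path.suffix!r}")
    delim = "," if path.suffix == ".csv" else "\t"
    np.savetxt(path, rec.data, fmt="%.4f", delimiter=delim)
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.montage.channel_names),
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_matrix(path: Path, montage: Montage) -> Recording:
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise SidecarError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("fs", "channel_names"):
        if key not in sidecar:
            raise SidecarError(f"sidecar {sidecar_path} lacks required key {key!r}")
    delim = "," if path.suffix == ".csv" else "\t"
    data = np.loadtxt(path, delimiter=delim, ndmin=2)
    names = list(sidecar["channel_names"])
    if data.shape[0] != len(names):
        raise ChannelMismatchError(
            f"{data.shape[0]} rows vs {len(names)} sidecar channels in {path}")
    return _as_recording(data, names, float(sidecar["fs"]), montage,
                         sidecar.get("subject_id"), sidecar.get("condition"))


def _read_mne(path: Path, montage: Montage) -> Recording:
    import mne  # heavy import kept local

    if path.suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:  # .vhdr
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne works in volts
    return _as_recording(data_uv, list(raw.ch_names), float(raw.info["sfreq"]),
                         montage, None, None)


def _as_recording(data: np.ndarray, names: list[str], fs: float,
                  montage: Montage, subject_id, condition) -> Recording:
    if set(names) != set(montage.channel_names):
        missing = set(montage.channel_names) - set(names)
        extra = set(names) - set(montage.channel_names)
        raise ChannelMismatchError(
            f"channel mismatch vs montage (missing {sorted(missing)}, "
            f"extra {sorted(extra)})")
    order = [names.index(n) for n in montage.channel_names]
    return Recording(data[order], fs, montage, subject_id, condition)


def read_recording(path: PathLike, montage: Union[Montage, PathLike]) -> Recording:
    """Read EDF, BrainVision or matrix+sidecar EEG, ordered per the montage."""
    path = Path(path)
    if not isinstance(montage, Montage):
        montage = read_montage(montage)
    if path.suffix in (".csv", ".tsv"):
        return _read_matrix(path, montage)
    if path.suffix in (".edf", ".vhdr"):
        return _read_mne(path, montage)
    raise InvalidArgumentError(f"unsupported recording format {path.suffix!r}")


# --------------------------------------------------------------- templates

def write_templates(templates: TemplateSet, path: PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(templates.maps.T, columns=list(templates.class_labels))
    df.to_csv(path, index=False, float_format="%.8f")
    meta = {"class_labels": list(templates.class_labels),
            "level": templates.level, "gev": templates.gev}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_templates(path: PathLike) -> TemplateSet:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path)
    labels = meta["class_labels"]
    return TemplateSet(df[labels].to_numpy().T, tuple(labels),
                       meta.get("level", "group"), meta.get("gev"))


# ------------------------------------------------------------------ labels

def write_labels(seq: LabelSequence, path: PathLike) -> None:
    path = Path(path)
    np.savetxt(path, seq.labels[:, None], fmt="%d")
    meta = {"fs": seq.fs, "class_labels": list(seq.class_labels),
            "epoch_edges": [int(e) for e in seq.epoch_edges]}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_labels(path: PathLike) -> LabelSequence:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    labels = np.loadtxt(path, dtype=int, ndmin=1)
    return LabelSequence(labels, float(meta["fs"]), tuple(meta["class_labels"]),
                         np.array(meta["epoch_edges"], dtype=int))


# ---------------------------------------------------------- clinical table

def write_clinical(table: pd.DataFrame, path: PathLike) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"clinical table lacks columns {missing}")
    table[CLINICAL_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def read_clinical(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"clinical table lacks columns {missing}")
    return table
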