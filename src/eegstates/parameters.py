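"""Temporal microstate parameters: duration, occurrence and coverage.

All three derive from the run-length structure of a label sequence:
duration is the mean dwell time of a class, occurrence the number of its
runs per second of labeled time, and coverage the fraction of labeled
samples it occupies.  In the default (inclusive) mode the identity
coverage = duration x occurrence holds exactly; ``trim_edges`` mode drops
each epoch's first and last (truncated) run from duration and occurrence.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from .containers import UNASSIGNED, LabelSequence
from .exceptions import InsufficientDataError, InvalidArgumentError

PARAMETERS = ("duration_s", "occurrence_hz", "coverage")


def segment_runs(seq: LabelSequence) -> List[Tuple[int, int, int]]:
    """Maximal same-class runs as (class_index, start_sample, length).

    Runs never span an epoch boundary; unassigned stretches are skipped.
    """
    runs: List[Tuple[int, int, int]] = []
    lab = seq.labels
    for a, b in zip(seq.epoch_edges[:-1], seq.epoch_edges[1:]):
        seg = lab[a:b]
        if seg.size == 0:
            continue
        change = np.flatnonzero(np.diff(seg)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [seg.size]])
        for s, e in zip(starts, ends):
            if seg[s] != UNASSIGNED:
                runs.append((int(seg[s]), int(a + s), int(e - s)))
    return runs


def temporal_parameters(seq: LabelSequence, mode: str = "inclusive") -> pd.DataFrame:
    """Per-class duration (s), occurrence (1/s) and coverage (fraction).

    Classes that never occur get NaN duration, zero occurrence and zero
    coverage.  Occurrence uses labeled time as its denominator so rejected
    or unassigned stretches do not deflate rates.
    """
    if mode not in ("inclusive", "trim_edges"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    runs = segment_runs(seq)
    if not runs:
        raise InsufficientDataError("no labeled runs in sequence")
    K = len(seq.class_labels)
    labeled_samples = int(np.sum(seq.labels != UNASSIGNED))
    labeled_time = labeled_samples / seq.fs

    counted = runs
    if mode == "trim_edges":
        counted = []
        by_epoch: dict[int, list] = {}
        edges = seq.epoch_edges
        for run in runs:
            e = int(np.searchsorted(edges, run[1], side="right") - 1)
            by_epoch.setdefault(e, []).append(run)
        for epoch_runs in by_epoch.values():
            counted.extend(epoch_runs[1:-1])

    rows = []
    for k, name in enumerate(seq.class_labels):
        lengths = np.array([r[2] for r in counted if r[0] == k], dtype=float)
        samples_k = int(np.sum(seq.labels == k))
        duration = float(lengths.mean() / seq.fs) if lengths.size else np.nan
        occurrence = lengths.size / labeled_time
        coverage = samples_k / labeled_samples
        rows.append({"class": name, "duration_s": duration,
                     "occurrence_hz": occurrence, "coverage": coverage})
    return pd.DataFrame(rows)


def transition_counts(seq: LabelSequence) -> np.ndarray:
    """Raw K x K counts of run-to-run transitions (utility only; transition
    probabilities are not part of the results surface)."""
    K = len(seq.class_labels)
    counts = np.zeros((K, K), dtype=int)
    runs = segment_runs(seq)
    edges = seq.epoch_edges
    for (ka, sa, la), (kb, sb, _) in zip(runs[:-1], runs[1:]):
        same_epoch = (np.searchsorted(edges, sa, side="right")
                      == np.searchsorted(edges, sb, side="right"))
        if same_epoch and sa + la == sb:
            counts[ka, kb] += 1
    return counts


def cohort_parameters(sequences: dict, mode: str = "inclusive") -> pd.DataFrame:
    """Long-format parameter table for many subjects.

    ``sequences`` maps (subject_id, condition) to a LabelSequence; the
    result has columns subject_id, condition, class, duration_s,
    occurrence_hz, coverage — one row per subject x condition x class.
    """
    frames = []
    for (sid, cond), seq in sequences.items():
        df = temporal_parameters(seq, mode=mode)
        df.insert(0, "condition", cond)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def subject_means(params: pd.DataFrame) -> pd.DataFrame:
    """Across-class means per subject x condition.

    Duration and coverage are averaged over classes; occurrence is summed
    (total state changes per second), matching how whole-recording dynamics
    are usually summarised.
    """
    grouped = params.groupby(["subject_id", "condition"])
    out = grouped.agg(duration_s=("duration_s", "mean"),
                      occurrence_hz=("occurrence_hz", "sum"),
                      coverage=("coverage", "mean")).reset_index()
    out.insert(2, "class", "mean")
    return out
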