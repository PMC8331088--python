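"""Microstate segmentation: GFP, AAHC clustering, backfitting and GEV.

The segmentation model treats resting EEG as a sequence of a few recurring
scalp topographies.  Moments of maximal global field power (GFP) carry the
most reliable topography, so the maps at GFP peaks are clustered — here with
the atomize-and-agglomerate hierarchical clustering (AAHC) rule, ignoring
map polarity — into K template maps.  Templates are computed per subject and
then re-clustered across subjects (two-level clustering), labeled A-D
against canonical references, and backfitted to the data by spatial
correlation; global explained variance (GEV) quantifies the fit.

Maps are 1-D voltage vectors over channels and must be average-referenced;
polarity-invariant similarity is the absolute spatial (Pearson)
correlation.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .containers import UNASSIGNED, LabelSequence, Recording, TemplateSet
from .exceptions import InvalidArgumentError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

_EPS = 1e-15


# ------------------------------------------------------------------- GFP

def gfp(frames: Union[np.ndarray, Recording]) -> np.ndarray:
    """Global field power: population SD across channels at each sample.

    Accepts a (channels, samples) array, a single frame, or a Recording.
    """
    if isinstance(frames, Recording):
        frames = frames.data
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 1:
        return float(arr.std())
    return arr.std(axis=-2)


def find_gfp_peaks(values: np.ndarray, fs: float,
                   min_distance_ms: float = 10.0) -> np.ndarray:
    """Indices of strict local GFP maxima, >= min_distance_ms apart.

    Plateaus (runs of equal values higher than both neighbours) count as a
    single peak at their earliest sample; the first and last samples are
    never peaks.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_distance_ms * fs / 1000.0)))
    peaks, props = sps.find_peaks(values, distance=distance,
                                  plateau_size=(1, None))
    return props["left_edges"].astype(int)


# ---------------------------------------------------------- correlations

def _check_map(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float).ravel()
    if m.std() < _EPS:
        raise UndefinedCorrelationError(f"{name} is constant; correlation undefined")
    return m


def spatial_correlation(m1: np.ndarray, m2: np.ndarray,
                        polarity_invariant: bool = True) -> float:
    """Pearson correlation between two maps across channels.

    With ``polarity_invariant`` (the spontaneous-EEG convention) the absolute
    value is returned, so a map and its sign-flipped copy are identical.
    """
    m1 = _check_map(m1, "m1")
    m2 = _check_map(m2, "m2")
    if m1.size != m2.size:
        raise InvalidArgumentError("maps must share the channel count")
    a = m1 - m1.mean()
    b = m2 - m2.mean()
    r = float(a @ b / np.sqrt((a @ a) * (b @ b)))
    return abs(r) if polarity_invariant else r


def _unit_rows(maps: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows (so row dot products are Pearson r)."""
    m = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms < _EPS):
        raise UndefinedCorrelationError("constant map encountered")
    return m / norms


# ------------------------------------------------------------------ AAHC

def _principal_map(members: np.ndarray, first_member: np.ndarray) -> np.ndarray:
    """Polarity-invariant cluster centroid: dominant eigenvector of the
    members' outer-product sum, sign-oriented to its first member."""
    S = members.T @ members
    vals, vecs = np.linalg.eigh(S)
    w = vecs[:, -1]
    w = w - w.mean()  # members are zero-mean, so this is a numerical guard
    w /= np.linalg.norm(w)
    orient = float(w @ first_member)
    if orient < 0:
        w = -w
    elif orient == 0.0:
        nz = np.flatnonzero(np.abs(w) > _EPS)
        if nz.size and w[nz[0]] < 0:
            w = -w
    return w


def aahc(peak_maps: np.ndarray, K: int, return_assignment: bool = False):
    """Atomize-and-agglomerate hierarchical clustering of GFP-peak maps.

    Every map starts as its own cluster.  At each step the cluster whose
    members contribute least to the global explained variance is dissolved
    ("atomized") and each of its members is re-assigned to the surviving
    cluster whose centroid it correlates with best (polarity ignored);
    centroids of the receiving clusters are then recomputed as the dominant
    eigenvector of their members' covariance.  The procedure stops at K
    clusters.

    ``peak_maps`` is (n_maps, n_channels), average-referenced, in original
    units: each map's own GFP weights its GEV contribution.  The result is
    deterministic for a given input order (no random initialisation; ties
    go to the lowest index).
    """
    maps = np.asarray(peak_maps, dtype=float)
    if maps.ndim != 2:
        raise InvalidArgumentError("peak_maps must be (n_maps, n_channels)")
    n, n_ch = maps.shape
    if K < 1 or K > n:
        raise InvalidArgumentError(f"K={K} must lie in [1, {n}]")
    if np.max(np.abs(maps.mean(axis=1))) > 1e-6 * max(1.0, np.abs(maps).max()):
        raise InvalidArgumentError("peak maps must be average-referenced")

    g = maps.std(axis=1)
    if np.any(g < _EPS):
        raise InvalidArgumentError("constant peak map cannot be clustered")
    U = _unit_rows(maps)                  # unit directions
    w2 = (g ** 2)                         # GEV weights
    denom = float(w2.sum())

    members: list[list[int]] = [[i] for i in range(n)]
    centroids = U.copy()                  # each map is its own centroid
    r = np.ones(n)                        # |corr| of each map to its centroid

    def contribution(c: int) -> float:
        idx = members[c]
        return float(np.sum(w2[idx] * r[idx] ** 2))

    contrib = [contribution(c) for c in range(n)]

    while len(members) > K:
        worst = int(np.argmin(contrib))
        orphans = members.pop(worst)
        contrib.pop(worst)
        centroids = np.delete(centroids, worst, axis=0)
        # re-assign orphans to the best surviving cluster
        R = U[orphans] @ centroids.T      # (n_orphans, n_clusters)
        best = np.argmax(np.abs(R), axis=1)
        touched = set()
        for o, b in zip(orphans, best):
            members[int(b)].append(o)
            touched.add(int(b))
        # recompute centroids and member correlations where membership changed
        for c in sorted(touched):
            idx = sorted(members[c])
            members[c] = idx
            centroids[c] = _principal_map(maps[idx], U[idx[0]])
            r[idx] = np.abs(U[idx] @ centroids[c])
            contrib[c] = contribution(c)

    total_gev = float(sum(contrib)) / denom
    # stable presentation: order clusters by descending GEV contribution,
    # ties by lowest member index
    order = sorted(range(len(members)),
                   key=lambda c: (-contrib[c], members[c][0]))
    out_maps = np.stack([centroids[c] * np.sqrt(n_ch) for c in order])  # unit GFP
    labels = tuple(f"T{j + 1}" for j in range(K))
    templates = TemplateSet(out_maps, labels, level="individual",
                            gev=min(1.0, total_gev))
    if return_assignment:
        assign = np.empty(n, dtype=int)
        for new_c, c in enumerate(order):
            assign[members[c]] = new_c
        return templates, assign
    return templates


def two_level_cluster(per_subject_peak_maps: Sequence[np.ndarray], K: int,
                      return_individual: bool = False):
    """Two-level clustering: AAHC per subject, then AAHC across subjects.

    Each subject's GFP-peak maps are reduced to K individual templates;
    the pooled individual templates (unit GFP, so every subject weighs
    equally) are clustered again into K group templates.
    """
    if len(per_subject_peak_maps) == 0:
        raise InvalidArgumentError("need at least one subject")
    individual = [aahc(np.asarray(m, dtype=float), K) for m in per_subject_peak_maps]
    pooled = np.vstack([ts.maps for ts in individual])
    group = aahc(pooled, K)
    group = TemplateSet(group.maps, group.class_labels, level="group",
                        gev=group.gev)
    if return_individual:
        return group, individual
    return group


def label_templates(templates: TemplateSet, canonical: TemplateSet) -> TemplateSet:
    """Assign canonical class labels (A-D, ...) to estimated templates.

    Solves the optimal one-to-one assignment maximising total
    polarity-invariant correlation with the canonical maps, reorders the
    templates into canonical label order, and flips signs so each template
    correlates positively with its canonical partner.
    """
    if templates.K != canonical.K:
        raise InvalidArgumentError("template sets must share K")
    T = _unit_rows(templates.maps)
    C = _unit_rows(canonical.maps)
    R = T @ C.T
    rows, cols = linear_sum_assignment(-np.abs(R))
    order = np.empty(canonical.K, dtype=int)
    signs = np.empty(canonical.K)
    for r_i, c_i in zip(rows, cols):
        order[c_i] = r_i
        signs[c_i] = 1.0 if R[r_i, c_i] >= 0 else -1.0
    maps = templates.maps[order] * signs[:, None]
    return TemplateSet(maps, canonical.class_labels, templates.level,
                       templates.gev)


# -------------------------------------------------------------- backfitting

def _fill_between_peaks(seg_len: int, peaks: np.ndarray,
                        peak_labels: np.ndarray) -> np.ndarray:
    """Spread peak labels over a whole epoch by the nearest-peak rule.

    Each inter-peak interval is split at its midpoint; when the gap is odd
    the extra sample goes to the earlier peak.  Samples before the first /
    after the last peak inherit that peak's label.
    """
    out = np.empty(seg_len, dtype=int)
    cuts = np.empty(peaks.size + 1, dtype=int)
    cuts[0] = 0
    for j in range(peaks.size - 1):
        gap = peaks[j + 1] - peaks[j] - 1
        cuts[j + 1] = peaks[j] + 1 + (gap + 1) // 2
    cuts[-1] = seg_len
    for j in range(peaks.size):
        out[cuts[j]:cuts[j + 1]] = peak_labels[j]
    return out


def backfit(rec: Union[Recording, np.ndarray], templates: TemplateSet,
            fs: Optional[float] = None, min_distance_ms: float = 10.0,
            epoch_edges: Optional[np.ndarray] = None) -> LabelSequence:
    """Label every sample with the best-fitting template class.

    GFP-peak frames are assigned to the template with the highest
    polarity-invariant spatial correlation; all other samples inherit the
    label of their nearest peak in time (midpoint rule).  Epochs (given by
    ``epoch_edges``) are processed independently — labels never bleed across
    an epoch boundary, and an epoch without any GFP peak is left entirely
    unassigned.
    """
    if isinstance(rec, Recording):
        data = rec.data
        fs = rec.fs
    else:
        data = np.asarray(rec, dtype=float)
        if fs is None:
            raise InvalidArgumentError("fs is required when passing a plain array")
    if np.max(np.abs(data.mean(axis=0))) > 1e-6 * max(1.0, np.abs(data).max()):
        raise InvalidArgumentError("backfit expects average-referenced data")
    n = data.shape[1]
    edges = (np.array([0, n]) if epoch_edges is None
             else np.asarray(epoch_edges, dtype=int))
    Tn = _unit_rows(templates.maps)
    labels = np.full(n, UNASSIGNED, dtype=int)
    for a, b in zip(edges[:-1], edges[1:]):
        seg = data[:, a:b]
        g = gfp(seg)
        peaks = find_gfp_peaks(g, fs, min_distance_ms)
        if peaks.size == 0:
            logger.warning("epoch [%d, %d) has no GFP peaks; left unassigned", a, b)
            continue
        frames = seg[:, peaks].T
        F = _unit_rows(frames)
        R = F @ Tn.T
        peak_labels = np.argmax(np.abs(R), axis=1)
        labels[a:b] = _fill_between_peaks(b - a, peaks, peak_labels)
    return LabelSequence(labels, fs, templates.class_labels, edges)


# --------------------------------------------------------------------- GEV

def gev(rec: Union[Recording, np.ndarray], labels: LabelSequence,
        templates: TemplateSet, at_peaks: bool = True,
        min_distance_ms: float = 10.0) -> float:
    """Global explained variance of a labeling.

    GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2 with r_t the
    polarity-invariant spatial correlation between the frame at t and the
    template of its label; the sum runs over labeled samples — by default
    restricted to GFP peaks, or over all labeled samples with
    ``at_peaks=False``.
    """
    data = rec.data if isinstance(rec, Recording) else np.asarray(rec, dtype=float)
    if data.shape[1] != labels.n_samples:
        raise InvalidArgumentError("data and labels disagree on sample count")
    fs = labels.fs
    if at_peaks:
        idx_parts = []
        for a, b in zip(labels.epoch_edges[:-1], labels.epoch_edges[1:]):
            p = find_gfp_peaks(gfp(data[:, a:b]), fs, min_distance_ms)
            idx_parts.append(p + a)
        idx = np.concatenate(idx_parts) if idx_parts else np.array([], dtype=int)
    else:
        idx = np.arange(labels.n_samples)
    idx = idx[labels.labels[idx] != UNASSIGNED]
    if idx.size == 0:
        raise InvalidArgumentError("no labeled samples to evaluate GEV on")
    frames = data[:, idx].T
    g = frames.std(axis=1)
    ok = g > _EPS
    frames, g, lab = frames[ok], g[ok], labels.labels[idx][ok]
    F = _unit_rows(frames)
    Tn = _unit_rows(templates.maps)
    r = np.abs(np.einsum("ij,ij->i", F, Tn[lab]))
    return float(np.sum((g * r) ** 2) / np.sum(g ** 2))
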