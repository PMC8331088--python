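"""Epoching, filtering, re-referencing, artifact rejection and channel repair.

The cleaning chain mirrors standard resting-state practice: cut the record
into non-overlapping 2-s epochs, band-pass 1-40 Hz with a zero-phase
4th-order Butterworth, reject epochs whose peak absolute voltage exceeds a
threshold (a deterministic stand-in for visual artifact marking), and
repair bad channels by inverse-distance-weighted interpolation from their
nearest neighbours.  A narrower 2-20 Hz band and an average reference are
applied before microstate clustering.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence, Union

import numpy as np
from scipy import signal as sps

from .containers import Epochs, Recording
from .exceptions import InvalidArgumentError


def epoch_recording(rec: Recording, epoch_length: float = 2.0) -> Epochs:
    """Split into non-overlapping epochs; a trailing remainder is discarded."""
    n_len_f = epoch_length * rec.fs
    n_len = int(round(n_len_f))
    if abs(n_len_f - n_len) > 1e-9 or n_len <= 0:
        raise InvalidArgumentError(
            f"epoch_length {epoch_length}s is not an integer number of samples "
            f"at fs={rec.fs}")
    n_epochs = rec.n_samples // n_len
    data = rec.data[:, :n_epochs * n_len]
    epochs = data.reshape(rec.data.shape[0], n_epochs, n_len).transpose(1, 0, 2)
    return Epochs(epochs.copy(), rec.fs, epoch_length, rec.montage,
                  subject_id=rec.subject_id, condition=rec.condition)


def _band_sos(lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    if not (0.0 < lo < hi < fs / 2):
        raise InvalidArgumentError(
            f"band ({lo}, {hi}) Hz invalid for fs={fs} (need 0 < lo < hi < fs/2)")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Union[Recording, Epochs], lo: float, hi: float,
             order: int = 4) -> Union[Recording, Epochs]:
    """Zero-phase Butterworth band-pass (forward-backward; DC removed).

    Epochs are filtered independently so no signal bleeds across epoch
    boundaries.
    """
    sos = _band_sos(lo, hi, rec.fs, order)
    if isinstance(rec, Recording):
        return rec.with_data(sps.sosfiltfilt(sos, rec.data, axis=-1))
    filtered = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=filtered)


def average_reference(obj: Union[Recording, Epochs, np.ndarray]):
    """Subtract the instantaneous mean across channels (channel axis = -2).

    For a plain array the channel axis is the first of the last two
    dimensions, so (channels, samples) and (epochs, channels, samples) both
    work; a 1-D array is treated as a single frame.
    """
    if isinstance(obj, Recording):
        return obj.with_data(obj.data - obj.data.mean(axis=0, keepdims=True))
    if isinstance(obj, Epochs):
        return replace(obj, data=obj.data - obj.data.mean(axis=1, keepdims=True))
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        return arr - arr.mean()
    return arr - arr.mean(axis=-2, keepdims=True)


def reject_epochs(ep: Epochs, abs_threshold_uv: float = 100.0) -> Epochs:
    """Mark epochs whose peak |voltage| exceeds the threshold as rejected."""
    if abs_threshold_uv <= 0:
        raise InvalidArgumentError("rejection threshold must be positive")
    peak = np.abs(ep.data).max(axis=(1, 2))
    kept = ep.kept & (peak <= abs_threshold_uv)
    return replace(ep, kept=kept)


def interpolate_bad_channels(rec: Recording, bad_names: Sequence[str],
                             k: int = 4, power: float = 2.0) -> Recording:
    """Replace bad channels by inverse-distance-weighted means of good ones.

    Each bad channel is rebuilt from its ``k`` nearest good channels with
    weights 1 / d**power.  Good channels are untouched.
    """
    if not bad_names:
        return rec
    names = rec.montage.channel_names
    unknown = [n for n in bad_names if n not in names]
    if unknown:
        raise InvalidArgumentError(f"bad channels not in montage: {unknown}")
    bad_idx = rec.montage.index_of(list(bad_names))
    good_idx = np.array([i for i in range(len(names)) if i not in set(bad_idx)],
                        dtype=int)
    if good_idx.size == 0:
        raise InvalidArgumentError("cannot interpolate: every channel is bad")
    k_eff = min(k, good_idx.size)
    data = rec.data.copy()
    pos = rec.montage.positions
    for b in bad_idx:
        d = np.linalg.norm(pos[good_idx] - pos[b], axis=1)
        nearest = good_idx[np.argsort(d)[:k_eff]]
        dn = np.linalg.norm(pos[nearest] - pos[b], axis=1)
        w = 1.0 / np.maximum(dn, 1e-12) ** power
        w /= w.sum()
        data[b] = w @ rec.data[nearest]
    return rec.with_data(data)
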