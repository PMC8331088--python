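"""Canonical microstate map shapes (classes A-D) on an arbitrary montage.

Resting-state EEG literature consistently reports four dominant map classes:
A and B with mirrored diagonal (left-posterior/right-anterior and
right-posterior/left-anterior) field gradients, C with an anterior-posterior
gradient, and D with a fronto-central focal extremum.  These idealized
shapes serve two purposes: they seed the synthetic-template generator and
act as the fixed reference against which estimated templates are given their
A-D labels.
"""

from __future__ import annotations

import numpy as np

from .containers import Montage, TemplateSet

CLASS_NAMES = ("A", "B", "C", "D")

_SQRT2 = np.sqrt(2.0)


def _average_reference(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def _unit_gfp(maps: np.ndarray) -> np.ndarray:
    gfp = maps.std(axis=-1, keepdims=True)
    if np.any(gfp < 1e-15):
        raise ValueError("cannot normalize a constant map to unit GFP")
    return maps / gfp


def raw_shapes(montage: Montage, K: int = 4) -> np.ndarray:
    """Idealized class shapes (K x channels), before any decorrelation.

    Classes beyond D (K > 4) are smooth low-order polynomial patterns in the
    sensor coordinates, provided so simulations with more than four states
    remain possible.
    """
    x, y, z = montage.positions.T
    shapes = [
        (x + y) / _SQRT2,            # A: left-posterior <-> right-anterior
        (y - x) / _SQRT2,            # B: right-posterior <-> left-anterior
        -y,                          # C: anterior-negative / posterior-positive
        np.exp(-(x ** 2 + (y - 0.3) ** 2 + (z - 0.95) ** 2) / 0.4),  # D: fronto-central focus
    ]
    extras = [x * y, x * z, y * z, x ** 2 - y ** 2, z ** 2]
    for j in range(4, K):
        shapes.append(extras[(j - 4) % len(extras)])
    return np.stack(shapes[:K])


def canonical_maps(montage: Montage, K: int = 4) -> TemplateSet:
    """Average-referenced, unit-GFP canonical templates for labeling.

    Deterministic (no noise, no decorrelation pass): this is the fixed
    labeling reference, not a simulation draw.
    """
    shapes = _unit_gfp(_average_reference(raw_shapes(montage, K)))
    labels = list(CLASS_NAMES[:min(K, 4)]) + [f"X{j}" for j in range(4, K)]
    return TemplateSet(shapes, tuple(labels), level="group")
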