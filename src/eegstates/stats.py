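"""Group-level inference: TANOVA, t-tests on temporal parameters, and
clinical correlations with FDR control.

TANOVA (topographic ANOVA) is a nonparametric randomization test on the
global map dissimilarity (GMD) between group-mean scalp maps: group labels
are permuted (between-subject design) or conditions swapped within subjects
(within-subject design) to build the null.  Temporal parameters are
compared with independent / paired t-tests, and their association with
motor scores (UPDRS-III) and medication load (LEDD) with Pearson
correlations, Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .containers import LabelSequence
from .exceptions import InvalidArgumentError, UndefinedCorrelationError
from .parameters import PARAMETERS, subject_means

logger = logging.getLogger(__name__)


# -------------------------------------------------------------------- GMD

def _unit_gfp_map(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float).ravel()
    m = m - m.mean()
    s = m.std()
    if s < 1e-15:
        raise UndefinedCorrelationError("constant map has no topography")
    return m / s


def gmd(m1: np.ndarray, m2: np.ndarray) -> float:
    """Global map dissimilarity: RMS difference of unit-GFP maps.

    Related to spatial correlation by GMD^2 = 2 - 2r; ranges from 0
    (identical topography) to 2 (sign-flipped copy).  Polarity is *not*
    collapsed — group-mean maps carry consistent polarity.
    """
    u1 = _unit_gfp_map(m1)
    u2 = _unit_gfp_map(m2)
    if u1.size != u2.size:
        raise InvalidArgumentError("maps must share the channel count")
    return float(np.sqrt(np.mean((u1 - u2) ** 2)))


def class_mean_maps(data: np.ndarray, labels: LabelSequence) -> np.ndarray:
    """Subject-level mean map per class: average of the frames assigned to
    each class (K x channels; NaN rows for classes that never occur)."""
    K = len(labels.class_labels)
    out = np.full((K, data.shape[0]), np.nan)
    for k in range(K):
        sel = labels.labels == k
        if sel.any():
            out[k] = data[:, sel].mean(axis=1)
    return out


# ----------------------------------------------------------------- TANOVA

@dataclass(frozen=True)
class TanovaResult:
    observed_gmd: float
    p_value: float
    n_permutations: int
    design: str  # "between" | "within"
    seed: Optional[int]
    exhaustive: bool


def _gmd_rows(mean1: np.ndarray, mean2: np.ndarray) -> np.ndarray:
    """Row-wise GMD between two stacks of maps (vectorized)."""
    def unit(m):
        m = m - m.mean(axis=1, keepdims=True)
        return m / m.std(axis=1, keepdims=True)
    return np.sqrt(np.mean((unit(mean1) - unit(mean2)) ** 2, axis=1))


def tanova(maps_a: np.ndarray, maps_b: np.ndarray, design: str = "between",
           n_permutations: int = 5000, seed: Optional[int] = None) -> TanovaResult:
    """Randomization test on the GMD between two group-mean maps.

    ``maps_a`` and ``maps_b`` are (n_subjects, n_channels) subject-level
    maps.  Between-subject design permutes group membership of the pooled
    subjects; within-subject design (paired: equal n, subjects aligned)
    randomly swaps each subject's pair.  When the number of distinct
    relabelings does not exceed ``n_permutations`` the null is enumerated
    exhaustively; otherwise Monte-Carlo sampling with the add-one estimator
    p = (1 + #{perm >= obs}) / (1 + n_permutations) is used.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise InvalidArgumentError("subject maps must be 2-D with equal channels")
    if min(len(A), len(B)) < 2:
        raise InvalidArgumentError("need >= 2 subjects per cell")
    observed = gmd(A.mean(axis=0), B.mean(axis=0))
    rng = np.random.default_rng(seed)

    if design == "between":
        X = np.vstack([A, B])
        n, n1 = len(X), len(A)
        from math import comb
        total = comb(n, n1)
        if total <= n_permutations:
            stats = np.array([
                _split_gmd(X, np.array(idx, dtype=int), n1)
                for idx in combinations(range(n), n1)])
            p = float(np.mean(stats >= observed - 1e-15))
            logger.info("tanova: exhaustive enumeration of %d splits", total)
            return TanovaResult(observed, p, total, design, seed, True)
        picks = rng.random((n_permutations, n)).argsort(axis=1)[:, :n1]
        masks = np.zeros((n_permutations, n), dtype=bool)
        np.put_along_axis(masks, picks, True, axis=1)
        mean1 = masks @ X / n1
        mean2 = (~masks) @ X / (n - n1)
        stats = _gmd_rows(mean1, mean2)
    elif design == "within":
        if len(A) != len(B):
            raise InvalidArgumentError("within design requires paired subjects")
        n = len(A)
        if 2 ** n <= n_permutations:
            stats_list = []
            for code in range(2 ** n):
                flip = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
                A2 = np.where(flip[:, None], B, A)
                B2 = np.where(flip[:, None], A, B)
                stats_list.append(gmd(A2.mean(axis=0), B2.mean(axis=0)))
            stats = np.array(stats_list)
            p = float(np.mean(stats >= observed - 1e-15))
            logger.info("tanova: exhaustive enumeration of %d swap patterns", 2 ** n)
            return TanovaResult(observed, p, 2 ** n, design, seed, True)
        flips = rng.integers(0, 2, size=(n_permutations, n)).astype(bool)
        mean1 = np.where(flips[:, :, None], B[None], A[None]).mean(axis=1)
        mean2 = np.where(flips[:, :, None], A[None], B[None]).mean(axis=1)
        stats = _gmd_rows(mean1, mean2)
    else:
        raise InvalidArgumentError(f"unknown design {design!r}")

    p = (1.0 + float(np.sum(stats >= observed - 1e-15))) / (1.0 + n_permutations)
    return TanovaResult(observed, p, n_permutations, design, seed, False)


def _split_gmd(X: np.ndarray, idx: np.ndarray, n1: int) -> float:
    mask = np.zeros(len(X), dtype=bool)
    mask[idx] = True
    return gmd(X[mask].mean(axis=0), X[~mask].mean(axis=0))


def tanova_by_class(subject_maps: Dict[str, Dict[str, np.ndarray]],
                    pairs=(("HC", "PD_OFF", "between"),
                           ("HC", "PD_ON", "between"),
                           ("PD_OFF", "PD_ON", "within")),
                    n_permutations: int = 5000,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """TANOVA per microstate class for each requested group contrast.

    ``subject_maps[group][class]`` is an (n_subjects, n_channels) stack of
    subject-level class-mean maps.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for (ga, gb, design) in pairs:
        classes = sorted(set(subject_maps[ga]) & set(subject_maps[gb]))
        children = ss.spawn(len(classes))
        for cls, child in zip(classes, children):
            child_seed = int(child.generate_state(1)[0] % (2 ** 31))
            res = tanova(subject_maps[ga][cls], subject_maps[gb][cls],
                         design=design, n_permutations=n_permutations,
                         seed=child_seed)
            rows.append({"contrast": f"{ga}_vs_{gb}", "class": cls,
                         "design": design, "observed_gmd": res.observed_gmd,
                         "p_value": res.p_value,
                         "n_permutations": res.n_permutations,
                         "exhaustive": res.exhaustive, "seed": child_seed})
    return pd.DataFrame(rows)


# ------------------------------------------------------- parameter t-tests

def _safe_t(stat: float, p: float, x: np.ndarray, y: np.ndarray,
            paired: bool) -> tuple[float, float]:
    if np.isfinite(stat):
        return float(stat), float(p)
    # zero-variance degenerate cases: identical data -> no effect
    diff = (np.mean(x) - np.mean(y))
    if abs(diff) < 1e-12:
        return 0.0, 1.0
    return np.inf * np.sign(diff), 0.0


def compare_parameters(params: pd.DataFrame, alpha: float = 0.05,
                       mean_row: bool = True) -> pd.DataFrame:
    """Group comparisons of duration/occurrence/coverage per class.

    ``params`` is the long-format table (subject_id, condition, class,
    duration_s, occurrence_hz, coverage) with conditions HC, PD_OFF, PD_ON.
    HC vs each PD state uses an independent-samples t-test; PD_OFF vs
    PD_ON a paired t-test on subjects present in both states.  A "mean"
    row per parameter summarises across classes.
    """
    df = params.copy()
    if mean_row:
        df = pd.concat([df, subject_means(params)], ignore_index=True)
    rows = []
    for cls in list(dict.fromkeys(df["class"])):
        sub = df[df["class"] == cls]
        for param in PARAMETERS:
            by = {c: sub[sub["condition"] == c].set_index("subject_id")[param]
                  for c in ("HC", "PD_OFF", "PD_ON")}
            entry = {"class": cls, "parameter": param}
            for cond in ("HC", "PD_OFF", "PD_ON"):
                entry[f"{cond}_mean"] = float(by[cond].mean())
                entry[f"{cond}_sd"] = float(by[cond].std(ddof=1))
            for (ca, cb, kind) in (("HC", "PD_OFF", "independent_t"),
                                   ("HC", "PD_ON", "independent_t"),
                                   ("PD_OFF", "PD_ON", "paired_t")):
                x, y = by[ca].dropna(), by[cb].dropna()
                with warnings.catch_warnings():
                    # degenerate (near-constant) inputs are resolved by
                    # _safe_t below
                    warnings.simplefilter("ignore", RuntimeWarning)
                    if kind == "independent_t":
                        t, p = sstats.ttest_ind(x, y)
                    else:
                        common = x.index.intersection(y.index)
                        x, y = x[common], y[common]
                        t, p = sstats.ttest_rel(x, y)
                t, p = _safe_t(t, p, x.to_numpy(), y.to_numpy(),
                               kind == "paired_t")
                tag = f"{ca}_vs_{cb}"
                entry[f"{tag}_t"] = t
                entry[f"{tag}_p"] = p
                entry[f"{tag}_kind"] = kind
                entry[f"{tag}_significant"] = p < alpha
            rows.append(entry)
    return pd.DataFrame(rows)


# ------------------------------------------------------ clinical correlation

def clinical_correlations(params: pd.DataFrame, clinical: pd.DataFrame,
                          condition: str = "PD_OFF", alpha: float = 0.01,
                          mean_row: bool = True) -> pd.DataFrame:
    """Pearson correlations of temporal parameters with UPDRS-III and LEDD.

    Parameters from ``condition`` are correlated with the matching UPDRS
    state (updrs_off for PD_OFF, updrs_on for PD_ON) and with LEDD.
    Benjamini-Hochberg adjustment is applied within each family of tests —
    all classes of one parameter type against one clinical score — and
    significance flagged at adjusted p < ``alpha``.
    """
    score_col = {"PD_OFF": "updrs_off", "PD_ON": "updrs_on"}.get(condition)
    if score_col is None:
        raise InvalidArgumentError(f"no clinical score for condition {condition!r}")
    df = params[params["condition"] == condition]
    if mean_row:
        means = subject_means(params)
        df = pd.concat([df, means[means["condition"] == condition]],
                       ignore_index=True)
    clin = clinical.set_index("subject_id")
    rows = []
    for score in (score_col, "ledd"):
        for param in PARAMETERS:
            family = []
            for cls in list(dict.fromkeys(df["class"])):
                sub = df[df["class"] == cls].set_index("subject_id")
                common = sub.index.intersection(clin.index)
                x = sub.loc[common, param].astype(float)
                y = clin.loc[common, score].astype(float)
                ok = x.notna() & y.notna()
                x, y = x[ok], y[ok]
                if len(x) < 3:
                    raise InvalidArgumentError(
                        f"too few subjects for correlation ({len(x)})")
                if float(np.std(y)) < 1e-12:
                    raise UndefinedCorrelationError(
                        f"clinical score {score!r} is constant; r undefined")
                if float(np.std(x)) < 1e-12:
                    # algebraically constant parameter (e.g. mean coverage
                    # is 1/K for every subject): no correlation exists
                    r, p = np.nan, np.nan
                else:
                    r, p = sstats.pearsonr(x, y)
                family.append({"condition": condition, "score": score,
                               "class": cls, "parameter": param,
                               "r": float(r), "p_raw": float(p), "n": len(x)})
            defined = [f for f in family if np.isfinite(f["p_raw"])]
            if defined:
                p_adj = multipletests([f["p_raw"] for f in defined],
                                      method="fdr_bh")[1]
                for f, pa in zip(defined, p_adj):
                    f["p_fdr"] = float(pa)
                    f["significant"] = bool(pa < alpha)
            for f in family:
                f.setdefault("p_fdr", np.nan)
                f.setdefault("significant", False)
            rows.extend(family)
    return pd.DataFrame(rows)
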