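# eegstates

Resting-state EEG microstate analysis for clinical group studies, with a
ground-truth-labeled synthetic-cohort simulator.

## What problem this addresses

Spontaneous EEG does not wander continuously between scalp topographies:
it dwells in one quasi-stable map for ~80–120 ms and then switches
abruptly. These recurring maps — *microstates*, canonically four classes
A–D — give a sub-second-resolution description of whole-brain dynamics.
Slowed microstate dynamics (longer dwell, fewer switches per second) have
been reported in Parkinson's disease and related to motor impairment,
with deep-brain stimulation partially restoring them. Testing such
hypotheses requires a chain of steps that are easy to get subtly wrong:
polarity-invariant clustering, two-level template estimation, backfitting,
dwell statistics on epoched data, and randomization tests on topographies.
This package implements that chain as a tested library for researchers who
want to run or audit microstate analyses, plus a simulator that generates
cohorts with *known* microstate structure so every stage can be validated
end to end.

## The model in brief

* **GFP** (global field power) at time *t* is the SD across channels of
  the average-referenced map `u_t`; maps at GFP peaks are the most
  reliable and are what gets clustered.
* **AAHC** (atomize-and-agglomerate hierarchical clustering): start with
  every peak map as a cluster; repeatedly dissolve the cluster with the
  smallest GEV contribution and re-assign its members by highest |spatial
  correlation| (polarity ignored); stop at K = 4. Centroids are dominant
  eigenvectors (polarity-safe means). Applied per subject, then across
  subjects (two-level), separately per group.
* **Backfitting**: each GFP-peak frame takes the template with the highest
  `|corr(u_t, T_k)|`; other samples inherit the nearest peak's label.
* **GEV** = `Σ_t (GFP_t · r_t)² / Σ_t GFP_t²` — the fraction of
  GFP-weighted topographic variance the labeled templates explain.
* **Temporal parameters** per class: mean duration (s), occurrence (1/s),
  coverage (fraction), with `coverage = duration × occurrence`.
* **Statistics**: TANOVA (randomization test on global map dissimilarity
  `GMD = √(2 − 2r)` between group-mean maps), independent/paired t-tests
  on the temporal parameters, and FDR-corrected Pearson correlations with
  clinical scores (UPDRS-III, LEDD).

The simulator generates a three-condition cohort (healthy controls, and
patients recorded with stimulation OFF and ON) as a semi-Markov template
sequence (gamma dwell times; group mean dwell 0.068 / 0.075 / 0.076 s)
modulated by a rectified 10-Hz carrier plus spatially correlated noise at
a set SNR, with UPDRS-III scores generated as a linear function of each
subject's true dwell (group means calibrated to 46.5 OFF / 17.1 ON).

## Worked example

`python examples/02_segment_single_subject.py` simulates one 300-s,
32-channel subject at 10 dB SNR, clusters its GFP-peak maps, and scores
the segmentation against the generating truth:

```
9292 GFP peaks in 300 s (mean spacing 32.3 ms)
AAHC on 1000 peak maps: templates ('A', 'B', 'C', 'D'), GEV on its own input 0.954
template |r| vs ground truth per class: {'A': 0.9998, 'B': 0.9999, 'C': 0.9997, 'D': 0.9996}
GFP-peak label accuracy vs ground truth: 99.8%
GEV of the backfit (at peaks): 0.953
```

Reading: the four estimated templates are topographically identical to
the generating maps (|r| ≈ 1), 99.8% of GFP-peak samples get the correct
class, and the four templates explain 95% of the GFP-weighted variance of
this (synthetic, low-artifact) recording. The other examples cover cohort
simulation, temporal parameters, group statistics, and the on-disk
pipeline (`eegstates run-all --config …`), whose stages can also be run
individually (`simulate`, `preprocess`, `cluster`, `backfit`, `params`,
`stats`, `report`).

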