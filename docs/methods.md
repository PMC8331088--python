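# Methods

## The model

Resting-state EEG is modeled as a sequence of microstates: quasi-stable
scalp topographies that persist for roughly 80–120 ms and then switch
abruptly. The analysis estimates K = 4 template maps (classes A–D) and
describes each recording by which template is active when. Three
temporal parameters summarise the dynamics per class k:

* **duration** `d_k` — mean dwell time of class k (s),
* **occurrence** `f_k` — number of class-k appearances per second of
  labeled time (1/s),
* **coverage** `c_k` — fraction of labeled samples assigned to class k.

In inclusive mode these satisfy `c_k = d_k · f_k` exactly, and
`Σ_k c_k = 1`.

### Segmentation chain

1. **GFP and peaks.** Global field power is the population standard
   deviation across channels of the average-referenced map at each
   sample. Topographies are most reliable at GFP maxima, so strict local
   maxima (plateaus keep their earliest sample; ≥ 10 ms apart) supply the
   maps to cluster.
2. **AAHC.** Atomize-and-agglomerate hierarchical clustering starts with
   every peak map as its own cluster and repeatedly dissolves the cluster
   contributing least global explained variance, re-assigning each orphan
   to the surviving cluster with the highest absolute spatial correlation
   (polarity is ignored throughout, the convention for spontaneous EEG).
   The cluster centroid is the dominant eigenvector of the members' outer
   product sum — a polarity-safe mean — sign-oriented to the member with
   the lowest index and scaled to unit GFP. The procedure has no random
   initialisation; ties go to the lowest index, so results are a pure
   function of the input order.
3. **Two-level clustering.** AAHC reduces each subject to K individual
   templates; the pooled individual templates (unit GFP, so every subject
   weighs equally) are clustered again into K group templates, separately
   per group/condition.
4. **Labeling.** Estimated templates get their A–D names by optimal
   one-to-one assignment (Hungarian algorithm) against fixed canonical
   shapes: mirrored diagonal gradients (A, B), an anterior–posterior
   gradient (C) and a fronto-central focal map (D).
5. **Backfitting.** Each GFP-peak frame takes the label of the template
   with the highest absolute spatial correlation; every other sample
   inherits the label of its nearest peak, splitting each inter-peak
   interval at its midpoint (the extra sample of an odd gap goes to the
   earlier peak). Epochs are processed independently — labels never cross
   an epoch boundary, and an epoch without peaks stays unassigned.
6. **GEV.** The fit quality of a labeling is
   `GEV = Σ_t (GFP_t · r_t)² / Σ_t GFP_t²` with `r_t` the absolute
   spatial correlation between the frame at `t` and its assigned
   template. By default the sum runs over GFP peaks (where the assignment
   is actually made); a flag evaluates all labeled samples instead.

### Group statistics

* **TANOVA.** Topographic differences between groups are tested with a
  randomization test on the global map dissimilarity
  `GMD = RMS(u₁ − u₂)` between group-mean maps after unit-GFP scaling
  (`GMD² = 2 − 2r`; polarity is kept, since group means carry consistent
  polarity). Between-subject designs permute group membership;
  within-subject designs swap each subject's condition pair. The subject-
  level map entering the test is the subject's mean map over the samples
  assigned to the class. When the number of distinct relabelings is at
  most the requested permutation count the null is enumerated
  exhaustively; otherwise Monte-Carlo sampling uses the add-one estimator
  `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, which never returns 0.
* **Parameter tests.** Independent-samples t-tests compare healthy
  controls with each patient state; a paired t-test compares the two
  patient states. Significance threshold 0.05.
* **Clinical correlations.** Pearson correlations of each class ×
  parameter with the motor score (UPDRS-III, state-matched) and
  medication load (LEDD), Benjamini–Hochberg adjusted within each family
  (all classes of one parameter type against one score), flagged at
  adjusted p < 0.01.

## The synthetic cohort

The generator emulates a three-condition study — healthy controls (HC,
n = 21) and Parkinson's patients with deep-brain stimulation off/on
(PD_OFF / PD_ON, n = 20, paired) — in which disease slows brain dynamics.

* **State sequence.** A semi-Markov chain: dwell times i.i.d. gamma
  (shape 2) with group mean targets 0.068 s (HC), 0.075 s (PD_OFF),
  0.076 s (PD_ON); the successor class is uniform among the other K − 1
  classes (a transition-matrix parameter exists, but no empirical values
  are adopted as defaults — published studies of this design report the
  temporal parameters, not the transition probabilities). Gamma shape 2
  gives unimodal dwell distributions in the 80–120 ms band without
  ultrashort runs; a lognormal option exists.
* **Between-subject spread.** Each subject receives a dwell offset
  (SD 0.008 s; for patients a shared component plus a condition-specific
  component, so OFF and ON are correlated within subject). This matches
  the ~0.010 s between-subject SDs typical of such cohorts and is what
  makes a dynamics–symptom correlation possible at all.
* **EEG synthesis.** `x(t) = A · template[label(t)] · a(t) + noise(t)`,
  with `a(t)` a rectified 10-Hz sinusoid (eyes-closed alpha surrogate)
  with per-half-cycle amplitude jitter — GFP maxima therefore occur at
  predictable instants — and Gaussian sensor noise with distance-decaying
  channel correlation, scaled to the requested SNR (default 10 dB),
  everything average-referenced. Templates are canonical A–D shapes with
  seed-dependent smooth perturbations, pairwise deflated until all
  absolute correlations are ≤ 0.5.
* **Clinical model.** `UPDRS = intercept_group + slope · (subject dwell −
  group target) + N(0, 6)`, intercepts 46.5 (OFF) and 17.1 (ON), slope
  800 points/s. Group means land on the calibrated values, the relative
  improvement (OFF − ON)/OFF is ≈ 0.63, and longer dwell implies worse
  motor score by construction (r ≈ 0.7 at these settings). LEDD is drawn
  independently.

What the generator does **not** emulate: 1/f background spectra, ocular or
cardiac artifacts, stimulation artifacts, volume-conduction forward
physics, or topographic differences between groups (all conditions share
one template set, so TANOVA contrasts are null by construction). Passing
recovery tests therefore show that the estimation chain is correct and
well-calibrated under the stated dynamics, not that it is robust to every
artifact of real recordings.

## Two analysis modes for synthetic data, and a known bias

On real recordings the pipeline band-passes 2–20 Hz before clustering and
backfitting. On synthetic data both modes are informative:

* **Direct mode** (`band=None`): the average-referenced signal as
  generated. Template recovery (|r| ≈ 1.0), GFP-peak label accuracy
  (≈ 99.9%) and GEV are sharpest here. But GFP maxima occur only every
  ~30–50 ms (the carrier plus noise), so dwells shorter than the peak
  spacing contain no peak, vanish from the segmentation, and inflate the
  measured mean duration by roughly 20% at the default conditions. This
  is the segmentation-resolution bias inherent to peak-based backfitting,
  not an implementation defect; group *differences* and correlations are
  attenuated far less than the scale (measured-vs-true slope ≈ 0.85).
* **Clustering-band mode** (`band=(2, 20)`): band-limited noise adds GFP
  peaks between carrier maxima, raising the temporal resolution — mean
  durations land within a few percent of their targets — at the cost of
  peak-label accuracy (≈ 89–90%, low-amplitude peaks are noise-dominated)
  and slightly blended templates (|r| ≈ 0.94–0.97). This mode mirrors
  what the pipeline does on real data.

Recovery checks use the mode each quantity is best defined in: identity
of templates/labels against ground truth in direct mode, temporal-
parameter recovery in clustering-band mode. Both are reported by the
acceptance script.

## Numerical choices

* GFP uses the population SD (divisor = n channels); fixed and documented
  because only consistency matters.
* Peak ties (plateaus) keep the earliest sample; minimum inter-peak
  distance 10 ms suppresses noise doublets.
* Filters are 4th-order Butterworth applied forward–backward (zero phase,
  so topography timing is preserved); cleaning band 1–40 Hz, clustering
  band 2–20 Hz, applied per epoch so nothing bleeds across boundaries.
* Artifact rejection is a deterministic absolute-amplitude threshold
  (default 100 µV) standing in for manual marking; bad channels are
  repaired by inverse-distance weighting over the k = 4 nearest good
  channels (simpler and better conditioned than spherical splines at
  8–64 channels).
* Occurrence uses labeled time as denominator, so rejected epochs do not
  deflate rates. Inclusive mode (all runs counted) is the default because
  it preserves the `c = d · f` identity; `trim_edges` drops each epoch's
  first and last (truncated) runs from duration and occurrence.
* Degenerate statistics are resolved explicitly: identical groups give
  t = 0, p = 1; an algebraically constant parameter (mean coverage is
  1/K for every subject) yields an undefined (NaN) correlation rather
  than an error, while a constant clinical score is an error.

## Problem sizes

Simulation studies in the test-suite and acceptance script use the study
conditions (300-s records at 250 Hz, 32 channels, 10 dB SNR, 20–21
subjects per group) with per-subject AAHC running on an evenly spaced
subsample of at most 1000 GFP-peak maps — standard practice, since the
~9000 peak maps of a 5-min record are heavily redundant. The TANOVA
calibration uses 200 null replicates of 10 + 10 subject maps with 1000
permutations; the directional-effect study uses 5 cohort replicates.

## Known limitations

* Measured durations depend on segmentation resolution (see above); with
  a 10-Hz carrier, direct-mode durations are upward-biased. Comparisons
  between groups analyzed the same way remain valid.
* The power of the group comparison at the built-in effect (dwell
  0.068 vs 0.075 s, between-subject SD 0.008 s) is ≈ 0.75 per cohort at
  n ≈ 20/group — deliberately comparable to the marginal significance such
  cohort sizes yield in practice, so a minority of simulated cohorts will
  not reach p < 0.05.
* EDF and BrainVision files are read (via mne) but recordings are written
  only in the delimited-matrix + JSON-sidecar format.
* Transition probabilities are available as a raw count matrix utility
  but are not part of the results surface.
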