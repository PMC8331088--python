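"""Group-level statistics on a scaled-down simulated cohort.

Runs the whole inferential surface: TANOVA on class topographies,
independent/paired t-tests on duration, occurrence and coverage, and
FDR-corrected Pearson correlations with the motor score.  The cohort is
small (8 + 8 subjects, 60-s records), so expect direction but not always
significance.
"""

import numpy as np

import eegstates as es
from eegstates.evaluation import match_against_truth, segment_group

spec = es.SimSpec(n_hc=8, n_pd=8, record_length=60.0, seed=2)
recordings, truth = es.generate_cohort(spec)

sequences, subject_maps = {}, {}
for group in ("HC", "PD_OFF", "PD_ON"):
    items = [(k, r) for k, r in sorted(recordings.items()) if k[1] == group]
    seg = segment_group([r for _, r in items], K=4, band=None)
    relabeled, _ = match_against_truth(seg.templates, truth.templates)
    for key, data in zip((k for k, _ in items), seg.analysis_data):
        lab = es.backfit(data, relabeled, spec.fs)
        sequences[key] = lab
        means = es.class_mean_maps(data, lab)
        for k, cls in enumerate(lab.class_labels):
            subject_maps.setdefault(group, {}).setdefault(cls, []).append(means[k])

params = es.cohort_parameters(sequences)
comp = es.compare_parameters(params)
mean_dur = comp[(comp["class"] == "mean")
                & (comp["parameter"] == "duration_s")].iloc[0]
print("mean duration (s): "
      f"HC {mean_dur['HC_mean']:.4f} vs PD_OFF {mean_dur['PD_OFF_mean']:.4f} "
      f"(independent t-test p = {mean_dur['HC_vs_PD_OFF_p']:.3f})")

stacked = {g: {c: np.vstack(v) for c, v in d.items()}
           for g, d in subject_maps.items()}
tan = es.tanova_by_class(stacked, n_permutations=1000, seed=0)
print("\nTANOVA (all groups share one template set, so these are null tests):")
print(tan[["contrast", "class", "observed_gmd", "p_value"]]
      .round(3).to_string(index=False))

corr = es.clinical_correlations(params, truth.clinical, condition="PD_OFF")
dur = corr[(corr["score"] == "updrs_off") & (corr["parameter"] == "duration_s")]
print("\nduration vs UPDRS-III (OFF), FDR-adjusted within the family:")
print(dur[["class", "r", "p_raw", "p_fdr", "significant"]]
      .round(3).to_string(index=False))
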