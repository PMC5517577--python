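"""Detecting early sleep in short scans without any sleep scoring.

Typical resting-state runs last only minutes, so sessions are truncated
to 7 minutes and windowed with sliding (step-1) windows to keep enough
samples for clustering.  The wakefulness state can then be identified
label-free: its occurrence probability is higher at the beginning of
the scan than at the end.
"""

import numpy as np

import dfcstates as d

cohort = d.truncate_cohort(d.wake_n1_cohort(n_subjects=24, n_regions=20, seed=3),
                           420.0)
subjects = d.prepare_windows(cohort)
print(f"windowing mode: {subjects[0].spec.mode} "
      f"({len(subjects[0].vectors)} windows per subject)")

curve, _ = d.sample_size_curve(subjects, sizes=[10, 20], iterations=20, k=2,
                               seed=3, replicates=50)
print(curve.to_string(index=False))

# label-free identification of the wakefulness state on the full sample
vectors = np.vstack([s.vectors for s in subjects])
model = d.cluster_states(vectors, k=2, replicates=50, seed=3)
splits = np.cumsum([len(s.vectors) for s in subjects])[:-1]
profiles = d.occurrence_profile(
    [c.tolist() for c in np.split(model.assignments, splits)], labels=range(2)
)
wake = d.identify_wake_heuristic(profiles)
print(f"cluster {wake} identified as wakefulness "
      f"(occurrence falls from scan start to end)")
# Mean accuracy rises with sample size; even 10-subject subsets stay
# well above the 50% chance level.
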