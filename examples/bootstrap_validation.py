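"""Bootstrap validation of the staging accuracy against its null.

Random 8-subject subsets are re-clustered and scored repeatedly; the
same procedure with each subject's window-stage labels permuted gives
the null distribution, which concentrates at the 1/k chance level.
"""

import dfcstates as d

cohort = d.sleep_cohort(n_subjects=16, n_regions=20, seed=2)
subjects = d.prepare_windows(cohort, d.WindowSpec(50),
                             collapse=d.WAKE_SLEEP_COLLAPSE)

boot = d.bootstrap_accuracy(subjects, subset_size=8, iterations=30, k=2,
                            seed=2, replicates=50)
null = d.bootstrap_accuracy(subjects, subset_size=8, iterations=30, k=2,
                            seed=2, replicates=50, randomize_labels=True)

print(f"intact labels:    mode {boot.mode:.3f}  mean {boot.mean:.3f} "
      f"+- {boot.sd:.3f}")
print(f"permuted labels:  mode {null.mode:.3f}  mean {null.mean:.3f} "
      f"+- {null.sd:.3f}")
print(f"chance level 100%/k = {100 * d.chance_accuracy(2):.0f}%")
# The intact distribution should peak far above 0.5 while the permuted
# one peaks at the chance level, showing the accuracy is carried by the
# correspondence between connectivity states and sleep stages.
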