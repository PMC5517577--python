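"""Generate a small synthetic EEG-fMRI sleep cohort and inspect it.

Each subject gets a hypnogram (Markov stage sequence: wakefulness
declines over the session, N1 peaks before N2/N3) and a BOLD matrix
whose covariance switches with the active stage (band-passed to the
ultra-slow 0.01-0.1 Hz band).
"""

from collections import Counter

import dfcstates as d

cohort = d.sleep_cohort(n_subjects=10, n_regions=20, seed=1)

ts, hyp = cohort[0]
print(f"subject {ts.subject}: {ts.n_volumes} volumes x {ts.n_regions} regions "
      f"at TR {ts.tr} s ({hyp.duration / 60:.0f} min)")

counts = Counter(s for _, h in cohort for s in h.stages)
total = sum(counts.values())
print("cohort stage prevalence (fraction of 30-s epochs):")
for stage in ("W", "N1", "N2", "N3"):
    print(f"  {stage:3s} {counts[stage] / total:5.1%}")
# Expect roughly 48% W / 23% N1 / 19% N2 / 10% N3: the occupancy the
# stage model was calibrated to.
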