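# Methods

## The staging model

The pipeline assumes that whole-brain functional connectivity, measured
over windows of tens of volumes, occupies a small number of discrete
patterns that track the level of wakefulness. Staging is therefore
posed as unsupervised clustering: window correlation matrices from all
subjects are pooled, their upper triangles vectorized (row-major above
the diagonal), and grouped into k clusters. k is fixed by the question,
not estimated: 2 for wake-vs-sleep, 4 for the NREM cycle (W/N1/N2/N3),
5 when REM is expected.

**Correlation-distance k-means.** Windows should group by the *shape*
of their connectivity pattern, not its amplitude, so the metric is
d(u, v) = 1 − Pearson(u, v). This is implemented exactly by mapping
every vector to zero mean and unit norm and running Lloyd iterations in
Euclidean space (for standardized x, y: ‖x − y‖² = 2 d(x, y)), with
centroids re-standardized after each mean update. Each fit uses
k-means++ initialization and is repeated (100 replicates by default);
the replicate with the lowest total within-cluster correlation distance
wins. An emptied cluster is re-seeded from the point farthest from its
centroid. Iterations stop when assignments are stable or after 300
rounds. Tie-breaks (equal inertia) keep the earliest replicate, making
results a pure function of the seed.

**Matching clusters to stages.** Two fMRI-only criteria are computed
and cross-checked. (1) Occurrence profiles: P(label, t) is the fraction
of subjects carrying the label at window index t; clusters and stages
are matched by the bijection maximizing the summed Pearson correlation
between profiles. (2) Matrix similarity: clusters and stages are
matched on the Pearson correlation of their mean connectivity
matrices. Both assignments are solved exactly by enumerating all k!
bijections (k ≤ 5 ⇒ ≤ 120 candidates); a Hungarian solver reproduces
the same optimum in tests. When the two matchers disagree the pipeline
logs a warning rather than arbitrating — on the well-separated cohorts
used here they agree. Constant profiles (an absent stage) contribute 0
similarity, which keeps the assignment bijective on subsets where not
every stage occurs. A third, label-free heuristic for EEG-free data
declares the cluster whose occurrence drops most from the first half to
the second half of the session to be wakefulness.

**Scoring.** Accuracy is the fraction of correctly staged volumes:
every volume inherits the cluster→stage label of its window (with
sliding windows, the majority over covering windows; ties go to the
lighter stage under the order W < N1 < N2 < N3 < REM). Volumes after
the last full window are excluded from the denominator. Window-level
stage truth is the majority stage of the window's volumes with the same
lighter-stage tie-break. Because k-means partitions the pooled cloud
approximately evenly, chance accuracy is 1/k independent of stage
prevalence; the label-permutation bootstrap (below) verifies this
empirically rather than assuming it.

**Bootstrap validation.** Each iteration draws a subject subset without
replacement (10 of 58 by default), re-clusters only that subset's
windows, re-matches by occurrence profile, and scores volume accuracy;
100 iterations give the accuracy distribution. The null variant
permutes each subject's window-stage sequence before matching and
scoring (truth is then the permuted labels expanded to volumes). The
distribution "peak" is the center of the fullest of 20 histogram bins
on [0, 1] — a deliberately coarse, assumption-free mode estimator.

**Short scans.** With sessions of ~7 minutes, non-overlapping windows
leave too few samples, so windowing switches to sliding (step 1)
windows; `prepare_windows` does this automatically for sessions of
≤ 420 s. Everything downstream is unchanged.

## Network characterization

Stage-wise networks are per-participant means of the (non-overlapping)
window matrices whose majority stage matches; the diagonal is zeroed
and negative correlations are kept (fully connected signed networks).

**Signed modularity.** Q_W separates positive and negative weights,
each with its own configuration null e±ᵢⱼ = s±ᵢ s±ⱼ / v±, where
s±ᵢ are signed strengths and v± the totals over all ordered pairs. With
that convention Σᵢⱼ(w − e) telescopes to zero, so any single-module
partition of a positive network scores exactly 0, and for all-positive
weights Q_W reduces to classical weighted Newman modularity (verified
against networkx to 1e-12). The negative term is normalized by
v⁺ + v⁻, down-weighting negative-weight violations.

**Maximization.** A Louvain-style algorithm: greedy single-node moves
using the exact signed gain, then aggregation of communities into
super-nodes — with the positive and negative layers aggregated
*separately*, since re-splitting a net-weight aggregate by sign
corrupts the objective. The best of 100 restarts is kept; restarts
after the first start from random partitions, which explores the
rugged landscape of small dense signed networks far better than
varying the node-visit order alone. The returned Q_W is always
re-evaluated on the original network with the direct formula, and the
single-module partition is a floor (hence Q_W ≥ 0 for positive
networks). On random signed networks of up to 8 nodes the best-of-100
result matches exhaustive enumeration over all partitions.

**Coupling and contrasts.** SC–FC coupling is the Pearson correlation
of vectorized upper triangles over a common node subset (e.g. cortical
regions only). Node-level structural matrices aggregate to regions by
summing all weights between region pairs. Stage contrasts use a paired
t-test per edge across participants with Benjamini–Hochberg FDR at
α = 0.05 (the test family is the set of unique edges); with region→RSN
labels, edges aggregate into within/between-network blocks reported
both as mean differences and as counts of significant edges.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the biophysics of fMRI.

**Hypnograms** follow a time-inhomogeneous first-order Markov chain
over 30-s epochs with three rate regimes (session thirds). The default
sleep model was calibrated by exact occupancy propagation to ~48/23/19/10 %
W/N1/N2/N3 over a 52-minute session started awake, with monotonically
declining wakefulness and N1 peaking before N2/N3; the narcolepsy-like
model (adds REM, abrupt transitions) targets ~28/19/14/23/16 %. A
two-stage W/N1 model (wake probability decaying towards 0.625) serves
the short-scan scenario. Durations quantize to whole epochs; volume
counts to floor(duration/TR), so 52 min at TR 2.08 s gives exactly 1500
volumes.

**Stage covariance templates** are convex combinations of valid
correlation matrices — a stage-specific random signature (Wishart-
derived, fixed weight 0.35), a shared block-modular component (4
modules, within-block r = 0.6) scaled by the stage's modularity grade,
a structural template in correlation form scaled by the stage's
SC-coupling grade, and a uniform compound-symmetry filler (r = 0.3)
absorbing the remainder. Convexity makes every template a valid
correlation matrix with no projection step. Three choices keep the two
planted gradings identifiable and mutually orthogonal: signatures are
orthogonalized against the block and structural edge patterns (at
R = 20 chance alignment would otherwise dominate); the synthetic
structural template uses index-independent lognormal weights (60 %
density), because a banded, distance-decaying template carries
intrinsic community structure (Q ≈ 0.3–0.4) that leaks into the
modularity grading; and the filler is uniform rather than identity,
since a globally constant edge weight is both integration-promoting
(Q ≈ 0) and invisible to Pearson coupling, whereas a stage-varying
identity weight silently rescales the other components. The shared
fraction of the signatures is calibrated by bisection so the mean
pairwise correlation of vectorized templates hits a target
(default 0.5); a coupling grade of exactly 1 returns the structural
template itself in correlation form. Default grades — modularity
W 0.05 < N1 0.30 < N2 0.50 < N3 0.70; coupling N1 0.15 < W 0.30 <
N2 0.55 < N3 0.75 — were spaced so the planted ordering survives the
estimation-noise attenuation of the cohort analysis (rare stages
average fewer windows, which dilutes their measured SC–FC r most);
the ordering recovery was verified across independent seeds at cohort
level before freezing. A `signature_rank` knob controls signature
granularity: full rank for subtle patterns, low rank (R/3, used for the
wake/N1 short-scan cohort) for the coarse, well-separated states that
scenario posits.

**BOLD signals** are volume-wise Gaussian draws from the active stage's
template (Cholesky), plus isotropic noise of standard deviation
`noise_sd` (default 0.5 — a "clean" regime; the within-stage
variability of real connectivity is not modeled and this knob is free),
then band-pass filtered 0.01–0.1 Hz with an order-6 Butterworth applied
zero-phase (forward–backward), per region over the concatenated
session as a continuous recording would be. No hemodynamic convolution
is applied: the analysis consumes window correlations, which a shared
linear filter leaves essentially intact, and filtering already imposes
the ultra-slow spectral content. Per-subject seeds derive as
master + index.

**What passing tests do and do not show.** The synthetic cohorts have
exactly piecewise-stationary, Gaussian, stage-locked connectivity with
subject-exchangeable templates. Real data add head motion,
physiological noise, hemodynamic variability, inter-subject template
variability and within-stage dynamics; accuracy measured here is
therefore an upper bound on, not an estimate of, real-data accuracy.
What the tests do establish is that the pipeline's machinery —
windowing, correlation-distance clustering, exact matching, bootstrap
and null construction, signed modularity and its maximization —
recovers planted structure correctly and reproduces the analytic
chance levels.

## Numerical choices and problem sizes

- Degenerate inputs: zero-variance regions correlate as 0 with a logged
  warning; constant vectors are errors where correlation is essential
  (distance, SC–FC); an all-zero network has Q_W = 0 with a warning;
  fewer pooled windows than clusters flags the sweep entry as
  degenerate (NaN accuracy) instead of fitting nonsense.
- PSD repairs (signature orthogonalization, user-supplied structural
  templates) clip eigenvalues at 1e-10 and renormalize to unit
  diagonal; Cholesky factors add 1e-9 jitter.
- Comparisons use strict tolerances: partition/assignment equalities at
  1e-12; Louvain move gains must exceed 1e-12 to act, so zero-gain
  relabeling cannot cycle.
- Default problem sizes keep every analysis tractable on one CPU:
  cohorts of 58 subjects × 1500 volumes at R = 20 regions for the
  bootstrap experiments, 16 subjects for the stage-network analyses,
  and windows of 50 volumes throughout. R = 116 (the whole-brain
  parcellation the defaults emulate) is a default region count for the
  data types, not a constant; all analyses are dimension-agnostic.

## Known limitations

- The matching report flags matcher disagreement but has no arbitration
  rule; on poorly separated real data the two criteria can differ.
- The wake heuristic presumes subjects start awake; recordings begun
  mid-sleep violate it.
- Louvain with random-init restarts is exhaustive only in expectation;
  global optimality is guaranteed nowhere beyond the enumerable sizes
  the tests cover.
- The generator's noise_sd and signature_rank are free knobs: they set
  how hard the synthetic problem is and have no empirical calibration
  against real EEG-fMRI variability.
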