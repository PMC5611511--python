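# Methods

## Problem setting and model

A fixed-point network responds to a sustained input with a transient that
approaches a stable population firing-rate pattern. Supervised sampling
gives, per stimulus *S_i*, a collection of trials of nonnegative N × T
firing-rate matrices (PSTHs). The package constructs a low-dimensional
classification state space in which each of the m training stimuli owns one
axis, projects trajectories into it, and classifies/recognizes novel
responses by how long they dwell inside a target hyperellipse.

The pipeline assumes:

* responses are approximately rank-one per stimulus — a dominant spatial
  pattern modulated by a temporal envelope — so the first SVD mode of the
  trial-averaged matrix is a faithful stimulus signature;
* each node is *predominantly* associated with one stimulus (the exclusive
  assignment of ETR is meaningful even when tuning is broad);
* mixtures are approximately superpositions of their constituents'
  patterns, so they project near the sum of the constituent fixed points.

## Pipeline stages and their numerical choices

**PSTH conversion.** Spike trains are binned at `dt` (default 10 ms) and
optionally smoothed with a Gaussian kernel (default width 50 ms) evaluated
at bin centers, truncated at the recording boundaries and renormalized per
spike. Renormalization makes the time-integrated rate of every node equal
its spike count exactly, including for spikes near the edges.

**Library.** Trials are averaged per stimulus before the SVD (per-trial
concatenation is available behind a flag). Node-space singular vectors are
the patterns; each library column is unit-norm and sign-oriented so its
entry sum is nonnegative — the dominant singular vector of a nonnegative
matrix always admits such a representative, and the orientation is required
for the row-max rule to be meaningful. Singular-value ties keep the solver
order.

**ETR.** Row rule: keep the strictly-largest entry of each row when it
exceeds τ (default 0), zero the rest; ties go to the lowest stimulus index
(deterministic). Columns of the output have disjoint supports, hence
O ᵀO is diagonal with zero tolerance. ETR is scale-equivariant:
etr(cL, cτ) = c·etr(L, τ).

**OETR.** The objective ‖LᵀDʷO − I‖_Fr is linear in the diagonal weights
w and, because O's columns have disjoint supports, separates into one
least-squares block per stimulus cluster: entry (i, j) of LᵀDʷO is
Σ_{n∈cluster j} L[n,i]·L[n,j]·w_n. Each block is solved exactly
(`numpy.linalg.lstsq`); rank-deficient blocks take the minimum-norm
solution, which coincides with the global minimum-norm solution since the
blocks share no variables. Unassigned nodes (row max ≤ τ) get w = 0 — they
never enter the objective, and pinning them makes runs reproducible. A
stimulus with no assigned node makes its identity column unreachable; the
solver warns and still returns the minimizer over the remaining entries
(that column contributes 1 to the squared residual). Weights are
unconstrained in sign.

**ICA comparison.** The library transpose is whitened (without centering,
so the unmixed components stay inside span L) and unmixed with the plain
Bell–Sejnowski Infomax algorithm (`mne.preprocessing.infomax_`,
`extended=False`), seeded. Plain Infomax's logistic nonlinearity suits the
super-Gaussian sources relevant here and recovers mixed heavy-tailed
sources to correlation > 0.99 in the package's tests; non-convergence is
flagged on the result rather than raised.

**Recognition.** The Rec score counts the fraction of ON-window samples of
a projected trajectory inside the target region; the boundary (q = 0)
counts as inside. The default region is a sphere of radius 0.65. For a
stimulus that is an axis of an ETR/OETR space the center is its fixed
point's coordinates (row of LᵀDʷO); for mixtures — whose fixed-point
coordinates are not defined by the construction — the center is the mean
projected training trajectory over the ON window. Classification
normalizes per-stimulus mean scores by their maximum, thresholds strictly
above d = (mean + 1)/2 (a score exactly at d is non-behavioral), and
reports precision × recall, with empty denominators reported as 0.
Single-trial recognition uses a threshold fraction of the target's own Rec
(default 0.7, configurable). Confidence intervals on per-trial Rec are
Student-t by default (exactly zero-width for constant scores) with a
seeded percentile bootstrap as an option; classes are called separable
when all pairwise intervals are disjoint. The radius sweep covers
0.50–0.85 in steps of 0.01 and reports the widest contiguous interval with
perfect precision.

**Baselines.** Featurization turns every ON-window time sample of every
trial into one node-space point (per-trial flattened vectors behind a
flag); all baselines and any external comparison consume this same
featurization. The SVM is the regularized hinge-loss classifier
(scikit-learn, C = 1/λ; linear or Gaussian kernel) evaluated on a
trial-stratified held-out split — trials never straddle the split.
RUSBoost under-samples the majority class to balance each round (weighted,
seeded), fits a depth-limited decision tree, and applies the AdaBoost.M2
pseudo-loss update ε_t = Σᵢ D_t(i)·(1 − h_t(xᵢ,yᵢ) + h_t(xᵢ,ȳ))/2,
α_t = ε_t/(1 − ε_t), with final hypothesis argmax_y Σ_t h_t(x,y)·log 1/α_t.
The ½ factor keeps ε ∈ [0,1] so α is well-defined; rounds with ε ≥ 0.5 are
discarded and resampled (bounded retries).

## Synthetic generator

The generator emulates the structure of a multi-unit olfactory benchmark:
N = 106 nodes, m = 8 mono stimuli, 5 trials, 1 s recordings at dt = 10 ms
with the stimulus ON during [0, 0.5) s — 17 stimuli × 5 trials = 85
response matrices with the default mixture roster.

* **Patterns.** Every node has a primary stimulus (balanced assignment)
  with dominant weight U(0.5, 1); a `support_overlap` fraction of nodes
  (default 0.3 — projection neurons are broadly tuned but with a dominant
  odorant) additionally carries weaker weights U(0.05, 0.45) for all other
  stimuli. Columns are unit-norm.
* **Dynamics.** The noiseless response is pattern × envelope with a
  saturating rise 1 − exp(−t/τ_rise) (τ_rise = 100 ms, so trajectories
  approach the vicinity of the fixed point within a realistic 200–400 ms)
  and exponential decay (τ_decay = 150 ms) after stimulus OFF.
* **Noise.** I.i.d. Gaussian per sample, clipped at zero, with variance
  set so that time-averaged signal power over the ON window (per node,
  averaged over support nodes and mono stimuli) divided by the noise
  variance equals `snr` (default 3, the noisy regime of multi-unit
  recordings). The same σ applies to all stimuli including the blank
  control — noise is a property of the recording, not the stimulus.
* **Scale.** Rates are emitted in normalized units with ON-plateau
  amplitude 1 and unit-norm patterns, so projected trajectories live on
  the scale where ETR/OETR fixed points are unit vectors — the scale on
  which hyperellipse radii (0.5–0.85) are expressed. Physical firing rates
  only rescale both trajectories and radii jointly.
* **Mixtures.** Linear superpositions by default. B1 = S1+S2+S3 at equal
  weights; B2 and B3 perturb the ratios (behavioral mixtures share
  constituents at effective ratios and project close to B1). E1 = S1+S2
  (dropping the third constituent abolishes the behavioral response),
  E2 = S1+S2+S4 (substituting it does not restore it), E3–E5 combine
  unrelated odorants, E6 is a blank control (noise only).
* **Seeding.** Patterns derive from the config seed; each (stimulus,
  trial) noise stream derives from (seed, crc32(stimulus), trial), so
  collections are bit-reproducible and trials share the signal component.

What the generator does **not** emulate: temporally correlated noise
(real PSTHs are smoothed spike-rate estimates, so their noise is low-pass;
here noise is white per bin), trial-to-trial gain drift and adaptation,
sublinear mixture suppression (a knob exists but is off by default), and
Poisson spiking statistics (a Poisson-spikes-then-PSTH path exercises the
conversion but is not the default). Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical structure, not
performance on any particular biological dataset. External recordings can
be used by converting them to the native directory layout
(`collection.json` + one CSV per stimulus/trial).

## Known limitations

* When supports overlap, the OETR weights must cancel cross-terms and the
  weighted basis columns grow large (norms ~5–10 at overlap 0.3), which
  amplifies white per-bin noise; at SNR ≲ 3 absolute Rec scores shrink even
  though max-normalized classification still works. With temporally smooth
  noise (realistic PSTHs) the effect is much weaker. Consequently,
  OETR-vs-ETR confidence-interval separability dominance is exhibited in
  the easy-noise regime (SNR 10) rather than at every noise level of the
  white-noise generator.
* The ETR row rule presumes sign-oriented, nonnegatively-summed library
  columns; libraries whose dominant patterns are genuinely signed need a
  different orientation convention.
* Rec normalization uses ON-window samples only; scoring the full
  recording would dilute the score with post-stimulus decay samples.
* The convex-hull generalization of the recognition region is not
  implemented — only its hyperellipse simplification.

## Problem sizes in tests and reproduction script

Tests and `scripts/acceptance.py` use the generator's default sizes
(106 nodes, 17 stimuli, 5 trials, 100 samples) throughout; the degradation
curve averages 20 independent collections per SNR level, which keeps the
whole reproduction run around five seconds on one CPU while leaving the
study conditions at full benchmark scale.
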