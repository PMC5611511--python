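# fpnet

Supervised classification spaces for **fixed-point network dynamics** from
multi-node timeseries.

Many neural circuits encode stimuli as attractors: a sustained input drives
the population toward a stable firing-rate pattern (a fixed point). Given
supervised recordings — for each stimulus *S_i*, trials of a nonnegative
nodes × time firing-rate matrix *F_{S_i}* (a PSTH) — the task is to find a
low-dimensional state space in which the fixed points and the transient
trajectories approaching them are maximally separated, so that novel
responses (including *mixtures* of stimuli) can be classified and
recognized. The motivating system is the insect antennal lobe, whose
projection-neuron population discriminates odorants and their behaviorally
meaningful blends, but nothing in the package is specific to olfaction.

`fpnet` is for computational neuroscientists and systems biologists who
have (or simulate) such population recordings and want a classification
pipeline that is robust at the low signal-to-noise ratios typical of
multi-unit data.

## Method

1. **Library construction.** For each stimulus, the trial-averaged response
   matrix is decomposed by SVD (*SVDSep*); the dominant node-space pattern
   *PC¹_{S_i}* of each stimulus becomes a unit-norm column of the library
   matrix **L** (N nodes × m stimuli). Relative pattern weights are the
   energies H_k = σ_k² / Σᵢ σᵢ². (Decomposing the time-wise concatenation
   instead — *SVDCon* — mixes the stimuli into ambiguous modes; both are
   available for comparison.)
2. **ETR (exclusive threshold reduction).** Library columns come from
   independent decompositions and are not orthogonal. ETR keeps, in each
   node's row of **L**, only the maximal entry (if it exceeds a threshold
   τ, default 0), producing a matrix **O** whose columns have disjoint node
   supports — each node is assigned to exactly one stimulus with its
   library value as the weight. **O** is an exactly orthogonal basis.
3. **OETR (optimal ETR).** Node contributions are re-scaled by a diagonal
   matrix **D**ʷ solving the convex problem
   min_w ‖**L**ᵀ**D**ʷ**O** − **I**‖_Fr, so the projected fixed points
   (rows of **L**ᵀ**D**ʷ**O**) become orthonormal — one unit vector per
   stimulus. The objective is linear in *w* and block-separable over ETR
   clusters; the solver computes the exact least-squares minimizer.
4. **Recognition.** A projected trajectory *x(t)* is scored against an
   m-dimensional hyperellipse (by default a sphere of radius 0.65) centered
   at a target's fixed point via
   q = Σᵢ ((xᵢ − cᵢ)/rᵢ)² − 1, s_t = 1 iff q ≤ 0, and
   **Rec** = Σ_t s_t / T over the stimulus-ON window. Per-stimulus mean
   scores are normalized by their maximum and thresholded at the decision
   line d = (⟨{⟨Rec⟩}⟩ + 1)/2; performance is precision × recall.

Baselines operating directly in node space (hinge-loss SVM, RUSBoost for
class imbalance, Infomax ICA of **L**ᵀ) are included for comparison, along
with a synthetic fixed-point-network simulator that emulates the structure
of a 106-neuron, 17-stimulus, 5-trial olfactory benchmark (8 odorants,
3 behavioral + 5 non-behavioral mixtures, 1 control).

## Worked example

```python
from fpnet import (SyntheticConfig, generate_benchmark_like, build_space,
                   evaluate_classification)

config = SyntheticConfig(snr=10.0, seed=1)
collection, truth = generate_benchmark_like(config)   # 17 stimuli x 5 trials
space = build_space(collection, method="oetr",
                    stimuli=[f"S{i}" for i in range(1, 9)])
print(f"OETR objective = {space.objective:.3e}")
result = evaluate_classification(collection, space,
                                 target_stimulus="B1", radius=0.65)
print(f"decision line d = {result.decision_line:.3f}")
print(f"precision = {result.precision:.2f}, recall = {result.recall:.2f}, "
      f"accuracy (P x R) = {result.accuracy:.2f}")
```

prints

```
OETR objective = 8.901e-15
decision line d = 0.582
precision = 1.00, recall = 1.00, accuracy (P x R) = 1.00
```

The near-zero objective says the eight mono-stimulus fixed points were made
exactly orthonormal; the three planted behavioral mixtures (B1–B3, blends
of S1–S3) are the only stimuli whose normalized mean Rec scores
(0.78, 1.00, 0.97) exceed the decision line, so behavioral classification
is perfect at this noise level.

The same pipeline is available from the shell:

```bash
fpnet simulate --out coll --seed 1 --snr 10
fpnet build-space --collection coll --out space --method oetr
fpnet classify --collection coll --space space --target B1 --out result
fpnet evaluate --collection coll --methods oetr,etr --dims 1-8 --out tables
```

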