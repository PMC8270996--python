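# Methods

## Model and objective

The classifier f_ω is a small 1-D convolutional network: same-padded conv
blocks (conv → ReLU → max-pool), global average pooling over time, a single
inverted-dropout site on the penultimate feature vector, and one linear
softmax head per task (class-incremental scenario) or a single shared head
(all other scenarios).  Heads are zero-initialised, so an untrained head
returns the uniform distribution.  Optimisation is Adam.  Forward and
backward passes are written in NumPy (float64): the models involved are small
enough that this is fast, exactly reproducible from a seed, and free of
framework nondeterminism.  The backward pass is verified element-by-element
against central finite differences in the test suite.

A mini-batch while training task k contains B instances of the current task
and, once a replay pool exists, B_r replayed instances.  The loss is

    L = (1/B_k) Σ_i [ β_ik · L_ik + λ(β_ik − 1)² ]  +  (1/B_r) Σ_j Σ_i L_ij

with cross-entropy L_ik.  The regulariser sits inside the averaged sum, so
the β gradient, (1/B_k)(L_ik + 2λ(β_ik − 1)), is per-instance and independent
of batch-size rescaling; the sign property (positive loss pushes β down when
λ = 0) is preserved.  β is updated by plain gradient descent with rate η
each step, recorded at every epoch boundary with β(0) = 1 prepended, so a
τ-epoch trajectory has τ+1 points and a constant-1 trajectory integrates to
exactly s = τ under the trapezoidal rule.

Replayed instances are deliberately unweighted: their coefficient is fixed at
1/B_r, and β is frozen for a task once its training ends.

## Buffer mechanics

At the end of task k the ⌈b·N_k⌉ training instances with the largest s are
stored in that task's slot (ties broken lexicographically by instance id —
every selection in the package is deterministic under the run seed).  Slots
are per task and never evict one another, so total capacity is Σ_k ⌈b·N_k⌉;
capacity is induced by the fraction b rather than fixed a priori, since each
task is allotted its own fixed portion.  Ceiling conversion guarantees b > 0
stores at least one instance.

On every global epoch ≥ τ_MC the whole buffer is rescored with BALD over
T Monte-Carlo dropout passes (natural-log entropies; the base is immaterial
because the score is only used for ranking).  On every global epoch ≥ τ_S the
per-task pools are refreshed with the ⌈a·slot⌉ highest-BALD instances.  The
defaults τ_MC = τ+1 and τ_S = τ+2 satisfy the required ordering
τ_S ≥ τ_MC > τ and make replay active from the second epoch after the first
task; each refresh is a fresh ranking (no memory of previous pools).  Since
the dropout site sits on the penultimate features, the trunk is evaluated
once per rescoring and T masks are applied to the head input — identical in
distribution to T full stochastic passes, at a fraction of the cost.

Strategy variants: `fine_tuning` (plain mean loss, no buffer), `mtl` (all
tasks pooled, shared head over the class union — in the class-incremental
scenario this becomes a single multi-class problem), `random_storage` /
`random_acquisition` / `random_both` (the corresponding mechanism replaced by
a uniform draw of identical cardinality; the β loss-weighting is kept, since
these ablate only the buffer mechanics), and `loss_area_storage` (stores the
instances with the *smallest* area under the per-instance loss trajectory,
i.e. the consistently easy ones, the loss-curve analogue of top-s storage).

## Evaluation

R_j^i is the test AUC of task j immediately after the last epoch of task i
(no extra fine-tuning), evaluated with task j's own head in the per-task-head
scenario and the shared head otherwise.  Binary tasks use standard ROC AUC;
multi-class tasks use macro one-vs-rest AUC over the classes present in the
test split (restricting and renormalising the probability columns when the
head covers absent classes).  From the matrix: average AUC (mean final
column), BWT (final minus diagonal), BWT_t (t-step deltas) and BWT_λ (mean
over all horizons).  MTL fills only the final column, so only average AUC is
defined for it.

## Task difficulty, similarity, curricula

Per task, a Gaussian N(μ_k, σ_k²) is fitted to the storage scores (sample
mean; sample sd with ddof = 1; zero variance or zero mean is rejected as
degenerate rather than smoothed).  Difficulty is d_k = 1/μ_k.  Similarity is
S(j,k) = 1 − √(1 − BC) with the closed-form Bhattacharyya coefficient of two
Gaussians; the test suite checks this against numerical integration of
∫√(p_j p_k).  A curriculum starts at the easiest task and repeatedly appends
the unvisited task most similar to the most recently added one (matching the
chain construction, not similarity to the whole prefix); the anti-curriculum
starts at the hardest task; ties break on the smaller task id.  Curriculum
orders are derived from a pilot run of the same configuration in the stream's
native order.

## Synthetic data

Each segment is a sum of Gaussian wavelets (P, Q, R, S, T) per beat on a flat
baseline: beat onsets follow the configured heart rate with Gaussian RR
jitter (refractory floor at 20% of the mean RR), a smooth ST plateau between
the S and T wavelets implements ST shift, and white noise of configurable sd
is added.  Sample index is 0-based; time = index/fs seconds.  The default
12-class palette is organised as six confusable pairs sharing heart rate and
differing in exactly one feature (ST level, P-wave presence, QRS width, RR
regularity, T amplitude) — mirroring how real arrhythmia label sets are
confusable, and ensuring sequential binary tasks compete for the same learned
features, which is the regime in which forgetting occurs at all.  Default
generator conditions: L = 2500 samples at 250 Hz (10 s), noise sd 0.25,
24/8/32 train/val/test segments per class per task, two segments per
synthetic patient with patients never straddling splits.

Scenario construction: class-incremental = consecutive disjoint class pairs
(per-task heads); time-incremental = three terms with largest-remainder
allocation of drifting prevalence vectors and noise sd (0.06/0.10/0.14);
domain-incremental = 12 scalar-gain projections (cosine lead gains, sign
flips included) of one latent noise-free trace plus per-lead noise;
institute-incremental = three sites with disjoint label vocabularies,
sampling rates ×{1.0, 1.4, 0.8} and noise ×{1.0, 1.5, 0.75}, linearly
resampled to the common grid.

What the generator does *not* emulate: real inter-patient morphology
variability, baseline wander and electrode artefacts, multi-label
comorbidity, class imbalance beyond the configured prevalences, and genuine
12-lead vector electrocardiography.  Passing the package's studies therefore
shows the mechanisms behave as designed under controlled shift, not that the
exact clinical effect sizes transfer.

## Scaled-down study conditions

The multi-seed studies (`clops.experiments`) run on a 4-task
class-incremental stream of 4-second segments at 100 Hz (L = 400), 48
training instances per task, with a two-block trunk (8 and 16 channels,
kernel 7, pool 4, dropout 0.3), τ = 20 epochs per task, batch size 8,
learning rate 1e-2 (the small trunk takes few optimizer steps per task, so it
trains hotter than a full-scale model), λ = 10, b = 0.25, a = 0.5, T = 20,
and 16 training seeds.  The difficulty-recovery study uses a single easily
learnable binary task (normal rhythm vs tachycardia) with 20% of training
labels flipped, so the flip is the only source of instance difficulty; the
flipped-vs-clean comparison of mean storage scores is assessed with a
one-sided sign test across seeds.

Observed margins under these conditions: fine-tuning BWT ≈ −0.04 (clear
forgetting) and replay BWT higher by ≈ +0.03 are solid across seed sets
(across-seed sd of BWT ≈ 0.03).  The guided-vs-random average-AUC gap is
+0.015 at the suite's fixed seeds but shrinks toward zero when averaged over
further seed sets: with only ⌈0.25·48⌉ = 12 slots per task, top-s storage is
often dominated by the easier class of a binary pair (occasionally all 12
from one class), which makes that task's replay one-sided — an artefact of
small slots that the large-data regime, where slots hold hundreds of
instances of both classes, does not share.  The curriculum-vs-random BWT gap
(+0.002 to +0.012 depending on seed set) is likewise directional-but-noisy.
The fixed-seed test suite is exactly reproducible.

## Numerical and design choices

- Entropies in BALD use natural log; x·log x is defined as 0 at x = 0;
  posterior tensors are validated to the simplex within 1e-6.
- The Bhattacharyya coefficient is clipped at 1 before 1 − √(1 − BC) to guard
  rounding for identical Gaussians.
- β is not clamped; the regulariser controls decay.  With η·2λ/B_k ≥ 1 the
  scalar β dynamics overshoot and oscillate around the fixed point
  1 − L/(2λ); the package's defaults are far from this regime.
- Replay draws are uniform without replacement from the flattened pool,
  capped at the pool size; task order within the draw is deterministic.
- The stream container is a CSV manifest plus an NPZ array; round-trips are
  byte-identical.  The WFDB adapter reads text headers with format-16
  little-endian int16 data and applies (adc − baseline)/gain.
- Early stopping is not used; every task trains exactly τ epochs and R is
  measured immediately afterwards.

## Known limitations

- Directional comparisons at desk scale carry the seed noise quantified
  above; conclusions about real clinical streams require the full-scale
  external corpora.
- The MTL baseline reuses τ epochs over the pooled data; no per-strategy
  budget equalisation is attempted.
- GEM- and MIR-style comparators and supplementary storage/acquisition
  variants are out of scope.
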