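# Methods

`pathdistill` implements a deployment-optimization pipeline for multitask
classification of free-text cancer pathology reports: a hard-label
baseline classifier, a seed-diversified ensemble, a distilled student
trained on ensemble soft labels, softmax-threshold abstention calibrated
to a target accuracy, and vote-profile analyses of overconfidence and
label/data noise. The real registry corpora behind this problem are
restricted, so the package ships a synthetic corpus generator that
reproduces the problem's statistical structure and makes every stage
testable end to end.

## The classifier

The base model is a multitask word-level text CNN (MtCNN). Token indices
pass through a trainable embedding (reference profile: 300 dimensions),
then three parallel 1-d convolutions over time with filter widths of 3,
4 and 5 consecutive words (300 filters each in the reference profile),
ReLU, and global max-pooling over time. The pooled features concatenate
(3 × 300 = 900 dimensions) and feed one dense softmax head per task; the
reference task set is site (70 classes), subsite (326), laterality (7),
histology (639) and behavior (4).

The loss is the unweighted sum over tasks of the mean categorical
cross-entropy `-Σ_k y_k log ŷ_k` with probabilities clipped at 1e-7.
Targets may be one-hot (hard labels) or arbitrary probability vectors
(soft labels); one-hot soft targets reproduce hard-label training
batch-for-batch, which the tests assert exactly.

The network is implemented directly on NumPy with hand-written gradients
and a minibatch Adam optimizer. The global max-pool routes gradients
only to each filter's argmax window, so the backward pass is cheap, and
all sampling (initialization, batch order) flows from integer seeds
through `numpy.random.Generator`, which makes training bit-reproducible
for a fixed configuration and seed. Optimizer choice, learning rate
(default 1e-3), batch size and the epoch cap are configuration
parameters with logged defaults; embeddings are trained from scratch
(no pretrained vectors), and no dropout or weight decay is used —
overfitting control is early stopping only.

Early stopping monitors validation loss with a patience of 5 epochs by
default: training stops when the best value has not strictly improved
for `patience` consecutive epochs, and the weights of the best epoch are
restored. A plateau counts as no improvement.

## Ensemble, soft labels, student

The ensemble is a pool of T members with identical architecture and
data but different initialization seeds (`base_seed + i`); there is no
bagging, because members should see the full training set. The
canonical ensemble decision is the arithmetic mean of the member softmax
vectors (summing then normalizing); a softmax-of-sum variant exists as a
non-default flag but re-warps the probabilities and is not used for
distillation.

Soft labels for distillation are exactly the ensemble means over the
training documents — a deterministic function of the pool. The student
is a fresh MtCNN trained with those vectors as targets; its early
stopping monitors the soft-target validation loss by default (teacher
labels on the validation split), with hard-label monitoring available.
Temperature is fixed at 1: the method distills raw softmax averages, so
no temperature knob is exposed. Label smoothing (`1-α` on the annotated
class, `α/(K-1)` elsewhere) is provided as the uninformed soft-label
baseline; the pipeline can optionally train a smoothing contrast arm
whose α is matched to the mean confidence of the ensemble soft labels,
so smoothing and distillation are compared at equal average target
confidence. Smoothing flattens every target identically and carries no
information about which documents are noisy, which is why it is not
expected to recover the abstention benefit; the comparison is reported,
not asserted.

Vote profiles tally member argmax votes per document and task. Two
flagging rules operate on them:

* **Label noise** — unanimous votes (agreement exactly 1.0 by default,
  relaxable) on a class different from the annotation.
* **Data noise (mixed specimens)** — votes split almost equally over
  k ∈ {2, 3} classes: each top-k share within `1/k ± δ` and jointly
  covering at least `1-δ` of the votes, smallest k reported; δ defaults
  to 0.1 because "almost equal" has no canonical width, and it is
  configurable.

## Abstention

Per task and per model independently, calibration scans the fixed grid
0.001, 0.002, …, 0.999 on validation data and returns the smallest
threshold whose retained set (confidence = max softmax of that task's
head, retention rule `confidence ≥ τ`) is non-empty and at least 97%
accurate (the target registries impose before deployment). If no grid
value qualifies the calibrator returns an abstain-all sentinel and
warns. Test-time reporting uses the retention proportion
RP = 100·X̂/X (= 100 − abstention rate) and retained-set accuracy;
document counts derived from percentage tables use truncation
(`floor(rp/100·N)`), which reproduces the published counts exactly where
rounding would not. Uncertainty is reported as percentile intervals
over the member pool (for per-model metrics) and bootstrap-over-
documents intervals (for accuracies).

Overconfidence diagnostics: histograms of confidence over wrong
predictions (left-closed bins, last bin closed), counts of wrong
predictions with confidence strictly above 0.97, and the curve of that
count versus ensemble size, obtained by averaging R random subsets of m
distinct members per size (without replacement by default; a
with-replacement option exists). At m = T there is no sampling freedom,
so the full ensemble is evaluated once.

## Synthetic corpus generator

The generator emulates the statistical features of the registry problem
rather than clinical language:

* **Class imbalance** — rank r of a task's classes receives probability
  ∝ r^(−s), ranks assigned to class indices by a seeded permutation.
  One exponent per task reproduces both a heavy head and a sparse tail;
  `calibrate_imbalance` finds by bisection the exponent whose top-k mass
  matches a requested value (e.g. a top-2 mass of 41% for a 639-class
  task, the observed head mass of the real histology coding task).
* **Lexical structure** — each (task, class) owns a token vocabulary; a
  fifth of each class's tokens are shared with each ring neighbour, so
  adjacent classes are confusable while classes remain separable by
  construction (a bag-of-words nearest-centroid classifier exceeds 99%
  held-out accuracy on clean corpora, which the tests assert).
* **Cross-task coupling** — task 0 plays the "site" role; task 1's
  ("subsite") classes are partitioned among site classes round-robin
  and sampled conditionally; later tasks are tilted per site. This
  mirrors the nested ontology that makes multitask learning meaningful.
* **Mixed-specimen noise** — with probability `mix_rate` a document
  blends 2–3 label tuples with flat-Dirichlet weights; tokens are drawn
  from the component vocabularies in proportion to the weights, and the
  hard label comes from the heaviest component. This directly produces
  the split-vote signature the ensemble analysis looks for.
* **Label noise** — a Bernoulli(ρ) fraction of documents has one task's
  label swapped to a ring neighbour (a lexically confusable class).
  Truth metadata records the original labels, the mixing structure and
  the noise flag, so noise recovery is exactly measurable. ρ has no
  empirical estimate for the real data and is a free parameter.
* **Registry shift** — per-registry multiplicative tilts
  (`exp(shift·z)`) of every class distribution and of the background
  token distribution, so a held-out registry is genuinely out of
  distribution.

What the generator does **not** emulate: clinical language and
section structure, document-length pathology, inter-annotator
idiosyncrasies, and real ontology semantics. Passing benchmarks here
demonstrates that the pipeline's machinery behaves as designed under
the stated statistical structure, not that the reported real-registry
numbers transfer.

## Profiles and problem sizes

Two named profiles exist. The *reference profile* carries the full
published hyperparameters (300-dim embeddings, 3/4/5 × 300 filters,
patience 5, pool T = 1000, five tasks with 70/326/7/639/4 classes); it
is exercised structurally (initialization, head shapes, checkpoint
round-trips). The *desk benchmark* is the package's own sizing for
single-CPU runs: 3 tasks with 10/25/4 classes, 6 registries × 800
documents (~4800 total), sequence length 48, embedding 16, 16 filters
per width, batch 64, learning rate 2e-3, at most 15 epochs with
patience 3, pool T = 20, three replicate seeds. Benchmark conditions are
mixed-specimen rate 0.2 with label-noise rate 0.05 (for the abstention
and overconfidence comparisons) and mix 0 with ρ = 0.1 on ~3000
documents (for noise-flag precision).

## Numerical and design notes

* Ties in the vocabulary (equal frequency) break lexicographically;
  majority-vote ties break to the smallest class index; truncation
  keeps the head of a document.
* The threshold grid is exact integer thousandths; calibration is
  verified against an exhaustive brute-force scan.
* Aggregation is convex: every ensemble probability lies inside the
  members' min–max envelope, and member order is irrelevant.
* Degenerate inputs: empty retained sets report an undefined accuracy
  marker; an all-wrong validation task calibrates to the abstain-all
  sentinel with a warning; a pool of size 1 aggregates to the identity.
* The validation split is a seeded random fraction (default 0.1) of the
  non-held-out registries; stratified splitting is not implemented.

## Known limitations and observed behavior

On the desk benchmark the central overconfidence claim reproduces
directionally: the student makes no more wrong predictions with
confidence > 0.97 than the hard-label baseline on the largest task in
all three replicates, and the overconfident-wrong count declines with
ensemble size (summed over tasks and averaged over replicates; single
task/seed curves jitter by ±1 count at the tail because the counts
themselves are ~10). Retained accuracy on the held-out registry falls
below the 0.97 calibration target for most tasks, reproducing the
out-of-distribution generalization gap. The retention-proportion gain
of the student over the baseline, by contrast, is seed-dependent at
this scale and is reported rather than asserted — at T = 20 and ~4000
training documents, threshold calibration noise on a 400-document
validation split dominates the coverage effect that the full-scale
deployment observed.
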