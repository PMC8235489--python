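# Methods

This note records the modeling assumptions, numerical choices, and known
limitations behind `fgmi`. The README describes the pipeline itself; here
we explain *why* it is built the way it is.

## The pipeline and its assumptions

The method is stacked generalization driven by confusion structure. It
assumes (i) base classifiers whose errors concentrate on a small set of
visually similar classes per true class, and (ii) enough training images
per class for the per-class prediction distribution to identify that set.
Everything downstream — subsets, banks, the stacked representation — is a
deterministic function of the training data and the configuration; no
stage uses randomness (see *Determinism* below).

**Confusion estimation.** Following the training procedure, confusion is
estimated by resubstitution: the base models predict their own training
data (default, `confusion_cv=0`). A base model that fits its training
data perfectly yields a degenerate profile (all mass on the true class);
two mitigations exist. First, `confusion_cv=V` (V ≥ 2) replaces
resubstitution with stratified out-of-fold predictions. Second, when
fewer than `K` classes carry nonzero misclassification mass, the
remaining slots are filled by the *mean score* the class-`c` images
assign to each candidate class — the natural soft analogue of the count
distribution — with ties broken toward the lower class index. Whether the
sorted per-class distribution is a count or a frequency does not affect
the ranking; proportions are used so profiles sum to 1.

**Self-exclusion.** The true class `c` is excluded from the top-`K`
ranking (it typically dominates its own prediction distribution and is
always added back as a subset member), so no selection slot is wasted.

**Subset classifiers.** Each of the `K+1` member-vs-rest classifiers is
trained *only* on its subset's images: restricting negatives to the
mutually confusable classes is the point of subset construction.
Training is independent per `(c, k)` pair and may be parallelized; since
every fit is deterministic in its inputs, the result is independent of
execution order.

**Representation semantics.** The bank outputs concatenated into the
stacked representation are raw decision values (margins), not hard
labels: hard labels would discard the ranking information the final
stage needs. `bank_output="label"` switches to hard ±1 outputs for
comparison. Every image is scored by every bank classifier — not just
subset members — because a small `K` cannot cover all confused classes
and scoring each image `C(K+1)` times is what makes the representation
robust.

**Final stage.** Per base model, `C` one-vs-all linear classifiers
minimize the unweighted L2-regularized hinge objective with binary ±1
encoding. A constant-1 column is appended to the representation so the
bias is regularized with the weights — this single convention keeps the
brute-force optimization oracle well defined. The representation is
standardized per column (training-split statistics, default on) before
the final stage, since a single regularization strength `α` presumes
comparable column scales. Per-(model, class) fusion weights default to
`λ = 1/M` exactly — the mean of the per-model scores; any positive
constant gives the same argmax. At test time the stored subsets, banks,
scalers and final classifiers are applied directly; confusion is never
re-estimated on test data (that would require test labels).

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `K` | confused classes per class (unitless count, global) | 3 | block size − 1 of the reference synthetic benchmark; in general a `K/C` of 0.1–0.2 is a sensible operating range |
| `alpha` | final-stage L2 strength | 1.0 | middle of the stable 0.1–10 range; too small leaves the objective unregularized, too large degenerates it |
| `subset_alpha` | subset-classifier L2 strength | 1.0 | same family and scale as the final stage |
| `confusion_cv` | out-of-fold confusion folds | 0 (resubstitution) | matches the training procedure; set ≥ 2 for strongly fit base models |
| `standardize` | z-score the representation | on | comparable column scales for the single `α` |
| `bank_output` | margins vs hard labels | `margin` | keeps ranking information |

**Default base model.** The "prelearned" base classifier is the user's
to supply; the built-in default is a one-vs-all linear hinge classifier —
the same family as the subset and final stages, emulating the margin
outputs of prelearned linear SVMs. Margin outputs are deliberately *not*
calibrated across classes; this cross-class miscalibration is the raw
material the pipeline exploits, and the stacked final stage is what
corrects it. With a perfectly calibrated base (e.g. multinomial logistic
regression), averaging base scores is already near-optimal on synthetic
Gaussian data and the stacked stage has nothing left to add — see
*Limitations*.

## The hinge solver

The binary problem `min_w Σ_n max(0, 1 − y_n w·x_n) + α‖w‖²` is a linear
SVM with box constant `1/(2α)`; it is solved by cyclic dual coordinate
descent. The solver is entirely order-deterministic (fixed sample order,
no shuffling), so identical inputs give bitwise-identical weights — this
is what makes the `K = C−1` reduction to plain one-vs-all classification
an *exact* equality rather than a numerical approximation. After each
epoch the primal objective is evaluated and the best iterate so far is
retained; the reported objective trace is therefore non-increasing, while
the monotone dual ascent underneath guarantees convergence. Iteration
stops when the relative primal-dual gap falls below `tol` (default 1e-6,
certifying the suboptimality of the returned weights) or after
`max_iter` epochs (default 1000).

Base and subset classifier fits z-score their features internally and
fold the affine transform back into raw-space weights. This is purely a
conditioning device — feature tables with large offsets (such as
far-apart cluster centers) otherwise slow coordinate descent down
badly — and does not change the stored-weight interface. The final stage
does not need it because its input is already standardized.

Ties in argmax predictions, sorted confusion orders, top-`K` selection
and no-NIR voting all break toward the lowest class index.

## Synthetic benchmark

`make_confusable_dataset` draws a hierarchical Gaussian model:
`B` block centers along random orthogonal directions scaled to mutual
distance `δ_b·√2 ≥ δ_b`; `C` class means jittered at radius `δ_w/√2`
around their block center (so same-block means sit ≈ `δ_w` apart);
images as class mean + isotropic noise `σ`; and per model `m` an
independent Gaussian perturbation `τ` of the shared image features, so
different base models err on different images and fusion is non-trivial.
Defaults (C=12, B=3, n=40 images/class, d=10, `δ_w=2σ`, `δ_b=20σ`,
`τ=σ`) put within-block classification in the heavily confusable regime
while keeping blocks essentially never confused — the biased
misclassification structure of real fine-grained data. All randomness
flows from the config seed through named `SeedSequence` streams;
`sample_from_truth(stream=...)` draws fresh (e.g. test) samples from the
same planted truth.

What the generator does *not* emulate: non-Gaussian class-conditional
densities, heteroscedastic or correlated noise, label noise, class
imbalance, and the nonlinear feature geometry of real CNN embeddings.
Consequences: in this linear-Gaussian world a *global* linear model
already attains the information ceiling, so the stacked representation
cannot dominate base-score averaging by a large margin the way it can on
real image features — passing ordering tests here demonstrates the
machinery is correct and directionally effective, not the magnitude of
real-world gains.

## Test problem sizes

Unit and acceptance tests run the pipeline at desk scale: C ≤ 30 for
dimension laws, C = 12 / N = 480 per model for the recovery and ablation
studies (20 and 10 replicate datasets respectively), held-out test draws
of 100 images per class, and 4-point two-feature toys for the
grid-search solver oracle (grid step 0.01 over `[−5, 5]²`). The whole
suite completes in well under a minute on one CPU; `scripts/acceptance.py`
in ~10 s.

## Limitations

* **Unweighted hinge under imbalance.** With `C` classes, each final
  one-vs-all problem is 1:(C−1) imbalanced. When the positive class is
  not close to separable in representation space, the unweighted hinge
  optimum degenerates toward "score everything negative" (verified
  against an independent SVM solver — it is the true optimum, not a
  solver artifact). The method targets regimes where classes are nearly
  separable in representation space; far outside that regime the
  ablation that simply averages base scores can match or beat the full
  method, and the margin between them shrinks.
* **Resubstitution optimism.** Default confusion estimates and bank/final
  training reuse the same training data; `confusion_cv` mitigates the
  selection step only. Out-of-fold *representations* are not implemented.
* **Global `K`.** One `K` for all classes and models; no per-class
  adaptive subset size, no semantic or taxonomic priors on confusability.
* **Linear stages only.** Subset and final classifiers are linear; kernel
  or deep subset classifiers are out of scope.
* Fusion weights are fixed (equal); no learned fusion, no probability
  calibration of final scores.
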