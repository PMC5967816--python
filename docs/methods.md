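# Methods

`strainclass` reimplements, as a reusable pipeline, a concussion-classification
study design in which voxel-wise white-matter (WM) fiber-strain image volumes
from simulated head impacts are classified as concussion vs non-injury by
feature-based learners and benchmarked against scalar injury metrics under
cross-validation. This note records the models, the parameters that matter,
the numerical conventions, and what the synthetic data generator does and
does not emulate.

## Data model

All cases share one `VolumeGrid`: a 3D voxel grid with a brain mask, a WM
mask and an ROI label volume (0 non-WM, 1 CC, 2 SLF-R, 3 SLF-L, 4 EC-L,
5 EC-R, 6 brainstem, 7 other-WM; the WM mask is exactly `labels > 0`).
Because all strain fields come from one head model on one subject's DTI
grid, volumes are voxel-aligned by construction and no registration is
performed. The canonical feature order is the ascending linear index of WM
voxels with the x axis fastest (Fortran ravel); a feature index therefore
denotes the same voxel in every case, fold and selection mask.

A `StrainCase` holds a peak fiber-strain volume (zero outside WM), a peak
maximum-principal-strain (MPS) volume (zero outside the brain mask), the
per-axis peak angular-velocity magnitudes (rad/s) and a binary injury label.
Fiber strain is a projection of the strain tensor onto the local fiber
direction, so `fiber <= MPS` voxel-wise is enforced as a validation
invariant. Volumes are stored as 32-bit-float NIfTI — standard neuroimaging
practice and ample precision for strains of order 0.1.

## Synthetic data generator

The original 58 reconstructed football impacts are not publicly available,
so the package generates datasets with the statistical structure the
analysis assumes, plus known ground truth:

* **Geometry.** Brain and WM masks are smoothed ellipsoids (a seeded smooth
  wobble field perturbs the boundary); six named ROI blobs are spheres at
  fixed anatomical-ish positions inside the WM shell; remaining WM voxels
  get the catch-all label. The default 32^3 grid yields ~3.5k WM voxels;
  a full-scale preset (82^3, ~64k WM voxels) exists for configuration
  parity with the original feature count.
* **Strain fields.** Latent severity `s ~ exp(N(0, 0.4))` scales a fixed
  smooth positive baseline pattern (median MPS 0.08) times a per-case
  positive spatially correlated field, `exp(0.35 * G)` with `G` white noise
  smoothed by a Gaussian kernel of width 2 voxels and standardized. This is
  strictly positive, smooth and cheap. Fiber strain is MPS times a per-voxel
  attenuation drawn uniformly from (0.5, 0.9).
* **Labels.** The planted discriminative feature is the mean fiber strain
  over the SLF-R and EC-L blobs. Labels are drawn from a logistic model on
  the standardized regional mean (slope = `effect_size`, intercept
  calibrated by bisection to the 25/58 prevalence) and rejection-resampled
  until the class counts are exactly 25/33, matching the fixed study design.
  A logistic draw on a fixed unit-variance feature cannot realize
  standardized separations much above ~2.7 at this prevalence, so the
  generator then lifts the concussed cases' planted-ROI strains by a
  per-case multiplicative factor chosen so every concussed case's regional
  mean shifts by the same additive delta; this leaves within-class SDs
  untouched and makes the realized separation equal `effect_size` exactly.
  MPS is co-scaled at those voxels so `fiber <= MPS` survives. With
  `effect_size = 0` no lift is applied and labels are independent of strain
  (a clean null). The default `effect_size = 3` makes the planted signal
  clearly recoverable, which is the regime the study reports (held-out
  accuracies well above 0.8 for feature-based classifiers).
* **Kinematics.** The log peak angular speed is a `kinematics_coupling`-
  weighted mix of standardized log severity and independent noise
  (median 22 rad/s, log-SD 0.35), split across the three axes by a random
  positive direction. Severity drives both the strain fields and (noisily)
  the kinematics, so BrIC carries genuine but weaker class signal than the
  planted voxels — reproducing the qualitative ordering in which scalar
  metrics trail feature-based classifiers.

What the generator does **not** emulate: biofidelic strain physics,
anatomically accurate tract geometry, heteroscedastic reconstruction error,
inter-subject variability, or any relationship between impact direction and
strain localization. Passing tests therefore demonstrate that the pipeline
recovers structure of this specified form, not that the classifiers would
perform identically on real reconstructed impacts.

## Scalar injury metrics

* **BrIC** `= sqrt((wx/wxc)^2 + (wy/wyc)^2 + (wz/wzc)^2)` with critical
  velocities 30.4/35.6/23.5 rad/s (the values tuned for the head model the
  strain fields come from). The 3-vector input is interpreted as per-axis
  peak magnitudes of the angular-velocity change, which is the only
  documented convention available; it is recorded here because peak-change
  vs peak-magnitude is ambiguous in parts of the literature.
* **CSDM** over a region = fraction of region voxels with MPS strictly
  greater than the threshold (default 0.2). Strict inequality is an
  arbitrary but fixed convention; it only matters for synthetic constant
  fields, where boundary voxels are not measure-zero.
* **Peak-CC** = max fiber strain over the corpus callosum label.
* **Univariate logistic regression** turns each metric into a probabilistic
  classifier. Fitting is maximum likelihood (statsmodels' Newton/IRLS);
  complete separation — likely at small n with strong effects — is detected
  by a threshold scan and handled by a small ridge penalty (default 1e-2)
  instead of diverging, and flagged on the model. A zero-variance metric
  yields the intercept-only model exactly.

## Classifiers

All three classifiers implement one contract: fit on a training matrix of
(possibly pre-selected) voxel features, emit a per-case concussion
probability p1, decide concussion when p1 >= 0.5. A fitted classifier stores
its selection mask and applies it internally, so callers always pass
full-length vectors — this prevents accidental train/test index mismatches.

**Deep network.** Five fully connected layers halving in width
(full scale 2000-1000-500-250-2 on 64272 inputs, ~1.31e8 parameters;
reduced 500-250-125-60-2 on 643 selected inputs, ~4.85e5 weight entries;
desk scale 48-24-12-6-2). Activation schedule: ReLU with batch normalization
on layer 1 (batch statistics during training, running statistics at
inference; the affine output is normalized then rectified), plain ReLU on
layers 2-3, Sigmoid on layer 4 (bounding the features feeding the decision
layer to [0,1]), identity on the two-unit output, followed by Softmax. The
implementation is plain NumPy: forward, backprop (including the batch-norm
gradient) and the ADAM update are a few hundred lines and fully seeded.

Training: softmax cross-entropy, ADAM (beta1 0.9, beta2 0.999, eps 1e-8),
batch size 5 with short final batches topped up by resampling, a stratified
10% internal validation split. Early stopping: the best-validation
parameters are kept; training stops at the first epoch past the admissible
minimum with no validation improvement for `patience` epochs (paper scale:
patience 200 within the admissible range [1000, 5000]; desk scale: patience
15, range [30, 100]). A probe (300 epochs full scale, 10 desk) detects bad
initializations: if validation error has not decreased from its initial
value by the probe epoch the attempt restarts with a fresh initialization,
at most 5 times. When every attempt fails the probe the trainer keeps the
best attempt and records a warning rather than raising (a hard error would
make the randomized-label protocol — which trains on pure noise by design —
impossible to run); `strict_restarts=True` restores the hard error. A
`momentum` field exists for configuration compatibility but is a documented
no-op: the ADAM beta values fully specify the update.

Learning rates are scale-specific: 2e-8 (full net), 1e-6 (reduced net) —
appropriate to ~64k-dimensional strain inputs — and 1e-3 for the desk net,
retuned once for ~10^2-dimensional inputs so that separable desk data fits
within the desk epoch range.

**Linear SVM.** scikit-learn SVC with a linear kernel (C = 1 by default; the
cost parameter is otherwise undocumented for the original study).
Probabilities come from a univariate logistic calibration of the training
decision values (Platt-style, reusing the metrics module's fitter, whose
separation guard keeps coefficients finite on separable training sets); the
calibration is monotone, so decisions agree with the raw margin.

**Random forest.** Because a single forest depends on its random
initialization, a prediction is an ensemble of `n_trials` independently
seeded forests (100 at paper scale, 5 desk). The reported probability is the
mean per-trial vote fraction; the full per-trial distribution is retained so
reporting layers can quote percentile CIs over trials. Tree count/depth:
45/64 without selection and 75/8 (F-score) or 75/12 (RF-voting) at paper
scale; 25/8 at desk scale.

## Feature selection

* **F-score**: per voxel,
  `F = ((m1-m)^2 + (m0-m)^2) / (s1^2 + s0^2)` with class means m1/m0,
  overall mean m and within-class sample variances. Voxels constant overall
  score 0; voxels constant within both classes but differing between them
  get the maximum-score convention. Default retention: the top 4% (rounded),
  the fraction recommended for linear SVMs on high-dimensional inputs. The
  original study's count of 2566 voxels (3.99% of 64272) is treated as an
  empirically tuned constant and is available as an override, not the rule.
* **RF voting**: `n_runs` independently seeded forests (5000 paper scale,
  200 desk) each rank voxels by mean impurity decrease; the top 1% per run
  receive one unweighted vote; the final mask is the top 1% by votes. Vote
  and score ties break toward the lowest voxel index (stable sort), a fixed
  convention since the original tie rule is undocumented. The voting
  forests reuse the downstream RF classifier's tree count/depth.
* Selection always happens inside the cross-validation fold, from the
  training cases only. Aggregating per-fold masks gives the per-voxel
  selection frequency map; the display convention shows voxels with
  frequency strictly greater than 0.5.

## Evaluation protocols

* **LOOCV**: n folds; fold k selects features and fits on the other n-1
  cases, predicts case k. Held-out probabilities over all folds give one
  testing AUC; each fold's classifier also scores its own n-1 training cases
  for a training AUC (the deep net's internal validation split is part of
  the fold's training set for this purpose), summarized as mean, percentile
  95% CI, best and worst. Several classifier configs evaluated together
  share each fold's selection mask — selection depends only on the fold's
  training data and seed, so this is a runtime optimization, not a protocol
  change. Fold failures are recorded and surfaced, never silently dropped.
* **AUC** uses the Mann-Whitney convention (ties 1/2), verified in tests
  against an exhaustive pairwise-concordance oracle.
* **Out-of-bootstrap**: each of `n_boot` (default 100) trials draws n cases
  with replacement (redrawn, bounded, until the bag has >= 2 cases per class
  and the out-of-bag set is nonempty), selects features and fits on the bag,
  and evaluates out of bag. Summaries are means with percentile 95% CIs
  (the original CI method is unnamed). Sensitivity/specificity/AUC are NaN
  for trials whose out-of-bag set lacks a class and are nan-aggregated.
* **.632+ error**: with apparent error `err_train` from the full-data fit
  and out-of-bag error `err_oob`, the no-information error is
  `gamma = p(1-q) + (1-p)q`; `err_oob` is clamped to gamma; the relative
  overfitting rate `R = (err_oob - err_train)/(gamma - err_train)` is
  clipped to [0,1]; the result is `(1-w) err_train + w err_oob` with
  `w = .632/(1 - .368 R)`.
* **Randomized-label validation**: labels are permuted (class counts
  preserved) and the full LOOCV re-run, 50 trials by default; mean accuracy,
  sensitivity and specificity are tested against 0.5 by two-tailed
  one-sample t-tests. LOOCV (not bootstrap) is used here, matching the
  protocol used for the headline numbers. Under permutation the classifiers
  drift toward majority-class voting, which depresses sensitivity and
  inflates specificity; accuracy is the quantity the null check is about.
  With an imbalanced design (25/33) a small, early-stopped network retains a
  mild majority lean even in accuracy (a point or two above 0.5 on average),
  so at 50 trials the t-test sits near its rejection boundary and its
  verdict can vary with the permutation stream; the per-trial distributions
  are reported so this can be inspected.

## Problem sizes and determinism

The desk preset (32^3 grid, 48-24-12-6-2 net, 25/8 forests with 5 trials,
200 voting runs, F-score selection inside the 50-trial null protocol) is the
package's default study size, chosen so a complete campaign — LOOCV with
RF-voting selection, bootstrap, and the 50-trial randomized-label run — fits
in minutes on a single CPU while exercising every structural property of the
protocol. Paper-scale configurations are constructed by the same code paths
(`presets.classifier_suite("paper", ...)`) and are validated structurally
(parameter counts, selection arithmetic) rather than by retraining.

Every stochastic stage draws a child seed derived by hashing the master seed
with a stage tag, so stages are independently reproducible and report
bundles are bit-identical across reruns with the same seed.

## Known limitations

* The desk-scale learning rate and epoch range were retuned once for the
  small net; loss-curve shapes are not comparable across scales.
* The reduced/full networks at paper scale are runnable but not routinely
  trained in the test suite; their correctness is covered by the shared
  implementation and structural checks.
* The generator's distributional choices (log-normal severity, exponential
  Gaussian fields, uniform attenuation) are stand-ins chosen for
  testability; no distributional claims about real strain fields attach to
  them.
* With 58 cases, percentile CIs over folds/trials are coarse; they quantify
  protocol variability, not population uncertainty.
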