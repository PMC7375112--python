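# Methods

## Phase metrics

Instantaneous phases are obtained from the analytic signal
`x_a = x + iH[x]` computed with the discrete Hilbert transform per
region; the first and last 10 frames are dropped to suppress the
transform's border effects. The input must be narrowband for the phase
to be physically meaningful (Bedrosian's condition), which is why the
band-pass stage is mandatory and zero-phase.

The Kuramoto order parameter is implemented as the **modulus** of the
mean unit phasor. The defining property — R between 0 (incoherent) and
1 (locked) — requires the modulus; a signed or complex variant is never
used. Metastability is the **population** SD (ddof 0) of R(t), which
keeps the analytic bound metastability ≤ 0.5 (the SD of any quantity
confined to [0, 1]); synchrony is the time mean. A worked consequence:
two oscillators at a fixed π/2 phase lag have R(t) ≡ cos(π/4) ≈ 0.707
at every frame — constant, hence metastability exactly 0. (Prose
descriptions of this configuration sometimes quote "synchrony 0.5";
the formula gives 0.707 and the formula is authoritative here.)

Interaction matrices evaluate the metric over each network's regions
(diagonal) and over the union of regions of each network pair
(off-diagonal). Because the order parameter of a union is determined by
the two networks' phasor sums, the implementation reduces each frame to
14 complex sums; a brute-force recomputation that rebuilds every union
from scratch is kept in the test suite as the oracle (agreement to
1e-12). A single-region network (the thalamus) has synchrony 1 and
metastability 0 on its diagonal by construction — one phasor always has
unit modulus.

Order of operations: nuisance regression → band-pass → z-score →
Hilbert → trim → (for tasks) concatenation of task-block frames →
metrics. Filtering and the Hilbert transform always run on the
continuous series; block concatenation happens afterwards, on phases,
to avoid transform artefacts at block seams.

## Preprocessing

* Framewise displacement: FD_t = Σ|Δtranslation| + 50 mm · Σ|Δrotation|
  (rotations converted to arc length on a 50 mm sphere, the standard
  head-radius convention). Subjects are excluded when *strictly more*
  than 20% of rest frames exceed FD > 0.5 mm (both inequalities
  strict); no frame censoring is performed, because removing frames
  would corrupt the temporal structure the phase metrics need.
* Nuisance design: 6 rigid-body parameters, the supplied mean nuisance
  series (e.g. white-matter/ventricle analogues), an intercept, and
  backward-difference derivatives with a zero-padded first row.
  Rank-deficient designs are rejected with the collinear columns named.
* Band-pass: Butterworth of order 2 per pass, applied forward-backward
  (`sosfiltfilt`), passband 0.06–0.125 Hz at TR = 0.72 s. Zero phase is
  non-negotiable for a phase-based analysis; the test suite checks an
  in-band tone's phase shifts < 0.01 rad through the full conditioning
  chain. The filter's squared magnitude response is exposed
  (`bandpass_gain`) and used as its own oracle in tests.
* Task-block selection uses the frame-midpoint rule (a frame belongs to
  a block iff its midpoint time falls inside), which is unambiguous
  when block durations are not multiples of TR. Rest series are
  truncated to the task length so rest/task metrics are compared on
  equal data.
* Global signal regression is available but off by default.

## Synthetic cohort generator

The generator's purpose is to emulate the *analysis-relevant* structure
of a multi-condition fMRI study, not the physics of BOLD. Regions are
noisy Kuramoto phase oscillators:

    dθ_k/dt = 2π f_k + Σ_j K_kj sin(θ_j − θ_k) + σ ξ(t),

with K = k_w/N within a network and k_b/N between networks (N = total
regions), integrated by Euler–Maruyama at dt = TR/10 with stroboscopic
sampling every 10 steps (stable at band frequencies). An optional
burn-in discards the relaxation from the random initial state — the
transient otherwise inflates short-window metastability estimates, and
the stationarity-dependent checks use it.

Defaults and why:

* geometry: 14 labelled networks with a single-region thalamus. The
  default desk-scale parcellation has 4 regions per network
  (53 regions) so that simulation-driven tests run in seconds;
  `gordon_like_network_sizes()` provides the full 334-region geometry
  (per-network counts there are plausible inventions — only the totals
  are constrained).
* TR 0.72 s, 400 frames per condition, intrinsic frequencies uniform in
  0.06–0.125 Hz — inside the analysis band so the read-out survives the
  band-pass.
* coupling: rest at (k_w, k_b) = (4.0, 0.4) 1/s sits just below the
  between-network synchronisation transition, giving global
  metastability ≈ 0.12 at the default geometry with phase-noise
  0.8 rad/√s. Tasks multiply within-network coupling by 1.75 in
  cognitive-control networks (fronto-parietal, dorsal attention,
  cingulo-opercular, thalamus), by 0.75 in unimodal sensory networks
  (visual, motor hand/mouth, auditory), and raise k_b by 1.25×, with a
  small per-task tilt. Under these settings tasks show higher global
  and between-network metastability than rest (≈ 0.14–0.17 vs
  ≈ 0.12–0.14 measured through the pipeline) with a control-up /
  sensory-down contrast structure — the qualitative regime the analysis
  is designed to detect.
* intrinsic frequencies and a per-network lognormal coupling jitter
  (sd 0.25, unit mean) are sampled **once per subject** and shared
  across conditions: dynamics are trait-like, which is what lets rest
  metastability carry subject-level information.
* observation: x_k = sin θ_k + white noise (sd 0.1) + a weighted common
  nuisance mixture (two smoothed random-walk confound series,
  weight 0.2). No haemodynamic convolution — the analysis operates in a
  narrow band where the HRF acts approximately as a fixed gain and
  phase shift common to regions, which the metrics are invariant to.
* motion: a 6-column random walk (translation steps sd 0.02 mm;
  rotational steps arc-length-equivalent, i.e. divided by the 50 mm
  radius) plus persistent single-axis translation jumps of 0.6 mm at
  rate 0.005/frame. A persistent step registers in FD exactly once.
* behaviour: score = a + b·m + ε with b = 0.5 on the ground-truth rest
  metastability of the fronto-parietal–dorsal-attention connection and
  ε sd 0.004 — about half the between-subject signal sd (b × sd of m
  under the default jitter), i.e. a clearly detectable but noisy trait
  association. A flag switches the target from true to measured
  metastability to include estimator error.

Seeding: every random draw is keyed on (seed, purpose, subject,
condition) so cohorts are reproducible element-wise and subjects can be
simulated in any batch split with identical results.

What the generator does **not** emulate: haemodynamic convolution and
its regional variability, scanner noise spectra (1/f, physiological
aliasing), spatial autocorrelation between neighbouring regions, and
distance-dependent motion artefacts. Tests passing on this generator
therefore demonstrate correctness of the *estimators and statistics*,
not robustness to every property of real fMRI.

Cheap matrix-level fixtures (`synthetic_paired_stacks`,
`synthetic_matrix_classes`) bypass the oscillator model for stages that
only consume interaction matrices (NBS calibration, classification):
symmetric Gaussian baselines with subject effects, planted additive
edge effects, and class-specific patterns (dense, or sparse
"increase-only" effects on a few connections — the regime where
saliency-based occlusion is meaningful).

## Network-based statistic

Connection-wise paired t on (task − rest) over the 105 unique
connections; threshold t > 3.0 by default (the threshold is
intentionally a free parameter — on real data it is an analysis
choice), separate one-sided runs per tail. Supra-threshold off-diagonal
entries form edges of a 14-node graph; supra-threshold diagonal entries
attach to their node as self-loops, counting toward component size but
never merging nodes. The null permutes task/rest labels independently
per subject (sign flips of the difference matrices); since sign flips
leave Σd² invariant, all permutation t statistics are computed in one
matrix product, and component sizes come from a small union-find. The
FWER p value is (1 + #{null ≥ observed}) / (1 + n_perm), never zero.
The observed-component path uses an independent graph-library
implementation; the two component-search routes are cross-checked in
tests. Permutation tests on discrete statistics are conservative: the
measured false-positive rate at α = 0.05 over null cohorts is typically
0.005–0.03.

## Task-general architecture

Per subject, the 7 task matrices are vectorized (upper triangle +
diagonal, 105 entries), centered across tasks, and decomposed by SVD.
The PC1 pattern is reported in data units (σ₁-scaled right singular
vector); the variance fraction is σ₁²/Σσ². Centering makes the left
singular vectors exactly zero-mean, so loadings are instead defined as
the unit-normalised projections of the *uncentered* task vectors onto
the PC1 axis — for near-identical tasks these approach the equal-
loading value 1/√7 ≈ 0.378, the behaviour expected of a task-general
component. Sign convention: mean loading positive; ties broken by
orienting along the data mean, then by the dominant pattern entry.
The cohort exemplar averages per-subject patterns after aligning each
subject's sign to the first subject (antipodal patterns must reinforce,
not cancel). The high/low decomposition applies the same PCA to
task-minus-rest contrasts and splits connections by the sign of the
PC1 pattern. A pooled (all-subjects-stacked) PCA variant is provided.

The subject's task-general architecture *in metastability units* — the
quantity correlated with the rest matrix for update efficiency — is the
component shared by all tasks, which under task-centering is the task
mean; the centered PC1 describes the dominant mode of deviation around
it.

## Association

Update efficiency: Pearson r between the vectorized rest and
task-general matrices, Fisher z = atanh(r) with r clamped to
±(1 − 1e-12) so z stays finite. Connection-wise behaviour association
runs one OLS per unique connection (closed form, verified against
statsmodels), two-sided p from the t distribution, Benjamini–Hochberg
step-up at q = 0.01 over the **105 unique** connections — testing the
196 redundant entries of the full matrix would double-count identical
tests and distort the FDR. The efficiency–performance regression adds
the control covariate (global metastability) and reports the partial
correlation via double residualisation.

## Connectome CNN

Architecture: E2E (cross-shaped row+column filter) → ReLU → E2N
(weighted edge sums per node) → ReLU → N2G (weighted node sum) → ReLU →
FC → ReLU → FC → ReLU → FC → softmax over 8 states. Default widths
16/32/64 maps and FC 64→32→8 (widths are exposed; the test suite and
acceptance script train at 8/16/32, FC 32→16→8, which reaches the same
accuracy on the synthetic benchmarks in a fraction of the time).
Training: cross-entropy, Adam with learning rate 0.001 and first-moment
decay β₁ = 0.9 ("momentum 0.9"), batch 128, inputs z-scored per entry
on the training set. Dropout 0.6 is applied on the dense head (N2G
output and first FC output); at that rate on the narrow E2E/E2N feature
maps the forward signal is starved and the network demonstrably fails
to train at these widths. Early stopping on validation loss
(patience 20, cap 300 epochs). Evaluation uses 5-fold cross-validation
with disjoint stratified test folds and a 0.6/0.2/0.2
train/validation/test partition; reported accuracy is the mean over
test folds, with a row-normalized confusion matrix (rows = true class).

The forward and backward passes are written directly in numpy; the
backward pass is verified against finite differences in the tests. At
14×14 inputs this is fast (a full 5-fold run on 400 samples takes well
under a minute) and keeps the guided-backpropagation rule — propagate
only positive gradients through positively activated units — explicit.
Saliency maps are gradients of the winning class score w.r.t. the
standardized input. Consensus occlusion is class-wise: per class, each
subject's top 10% most positive saliency entries are binarized,
averaged, and entries exceeding 90% consensus (strict) form that
class's mask; the class's inputs are occluded (set to zero) with their
own mask and the pre-trained model re-evaluated. Occlusion collapses
accuracy only when class information is concentrated (the sparse-edge
benchmark); with dense class differences, removing 10% of entries
barely matters — which is itself informative about where the signal
lives.

## Numerical and testing choices

* "Exactly 0/1" claims about R are asserted at 1e-12; float rounding of
  means makes literal equality meaningless.
* Problem sizes: simulation-backed tests use the 53-region geometry,
  150–1,200 frames, and up to 200 subjects; the NBS calibration uses
  200 null cohorts × 1,000 permutations (fully vectorized, seconds);
  classifier runs use 400 samples at reduced widths. These sizes make
  the full suite run in a few minutes while leaving every statistical
  check well-powered.
* Seeded stochastic tests assert properties with explicit Monte-Carlo
  slack (binomial intervals, CI coverage counts) rather than point
  values.
* Degenerate inputs are errors, not silent results: zero-variance
  regions (z-score, Hilbert, efficiency), rank-deficient designs,
  empty networks, too-few subjects/frames, invalid bands and p-values.

## Known limitations

* The oscillator read-out is sinusoidal; amplitude dynamics and
  envelope–phase coupling present in real BOLD are absent, so
  amplitude-based confounds of phase estimation are not exercised.
* The NBS threshold is on the paired-t scale and results depend on it,
  as in any NBS analysis; no threshold-free variant is implemented.
* The classifier is desk-scale: no GPU, no hyperparameter search; it is
  a faithful, testable implementation of the architecture rather than a
  performance-tuned model.
* Update efficiency compares matrices through Pearson correlation,
  which is insensitive to uniform offsets/scalings of the architecture;
  alternative similarity measures are not provided.
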