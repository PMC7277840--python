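# Methods

## What the package models

`echoview` is a tested re-implementation of an echocardiographic
view-classification pipeline and of its downstream question: how much
view-mislabeling can a left-ventricular ejection-fraction (LVEF)
regressor's training data tolerate?  The clinical cohorts the original
analysis used are not available, so the package ships a first-class
synthetic cine-loop generator that reproduces the *statistical structure*
the pipeline assumes, and every quantitative claim the test suite makes
is about this synthetic substrate.

The pipeline stages are:

1. **Simulation** (`echoview.synthetic`) — stratified patient cohorts,
   five views per patient, cardiac motion encoding LVEF, speckle,
   vendor variation, burned-in peripheral metadata.
2. **Preprocessing** (`echoview.preprocess`) — metadata removal by fan
   masking and intensity windowing, optional rigid registration
   (translation + isotropic scale by normalized cross-correlation),
   crop/resample to an 18.07 × 18.07 cm, 120 × 120 px field, cardiac-cycle
   detection, and selection of 10 equally spaced frames per cycle.
3. **View classification** (`echoview.viewnet`) — a small CNN trained
   under two input strategies (cycle-averaged image vs the 10 frames),
   patient-level 5-fold cross-validation, min-validation-loss
   checkpointing, and softmax-probability ensembling over the 5 per-fold
   weight sets.
4. **Evaluation** (`echoview.evaluate`) — 5 × 5 contingency table,
   overall accuracy, weighted Cohen's kappa with a delta-method standard
   error, and a misclassification report ordered so that adjacent-apical
   confusions (AP3 ↔ AP2/AP4) come first.
5. **Label-noise experiment** (`echoview.labelnoise`) — corrupt an EF
   training set by swapping in same-patient wrong-view clips at a fixed
   rate, retrain a surrogate conv regressor, and compare Pearson
   correlations against the clean baseline with the Fisher z test.

## The synthetic generator

Each view is a distinct stylized chamber layout inside a sector fan:
PLAX two stacked elongated cavities, PSAX an annular cavity, AP2/AP3/AP4
two/three/four elliptical cavities in apical orientation.  All views
share the same end-diastolic total cavity area (one heart, different
cross-sections): what distinguishes them is layout, not aggregate dark
area.  Chambers carry a per-patient anatomical size factor, uniform on
[0.80, 1.25].  Cavity area oscillates sinusoidally over the cardiac
cycle; the end-diastolic to end-systolic fractional area change (FAC)
is linear in LVEF,

    FAC = 0.01 · LVEF · m_view,

with motion factors m = 1.0 for the apical views, 0.7 for PLAX and 0.5
for PSAX (longitudinal vs radial function).  The linear map is a
modeling convention — real FAC–EF relations are view- and
geometry-dependent — chosen so that pixel-count oracles can verify
strict monotonicity exactly.

On top of the deterministic geometry:

* **Apparent-EF error.** The motion amplitude of each clip encodes
  `LVEF + ε_view` with per-patient ε ~ N(0, σ_view²), σ = 1.5 (AP4),
  5 (AP2/AP3), 9 (PLAX), 11 (PSAX) EF points.  This mirrors the clinical
  fact that EF read from a non-designated cross-section is a degraded
  measurement, and it is what makes the label-noise experiment
  non-vacuous: without it, a wrong-view clip is a perfectly clean EF
  signal and corruption has no measurable cost.
* **Speckle**: multiplicative Rayleigh noise (σ = 0.35, unit mean), the
  standard first-order ultrasound texture model.
* **Vendors**: three styles differing in fan half-angle (33–42°), depth
  (18–21 cm, hence pixel spacing), mean gain (further ±15% per clip),
  and baseline cardiac period (24–34 frames/cycle) with ±3 frames
  per-patient jitter — this exercises the cycle-normalizing frame
  selector.
* **Metadata**: text-like high-intensity blocks confined to a 14-px
  peripheral margin outside every vendor's fan.

Reproducibility: each patient's parameters come from an RNG stream keyed
by (cohort seed, patient index), so cohort composition is independent of
render order and bit-reproducible.

What the generator does **not** emulate: physical wave propagation,
anisotropic point-spread, shadowing/dropout, probe motion, arrhythmia,
3D geometry, Doppler.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its claims hold under the
stated statistical structure — not that the trained networks would
transfer to clinical images.

## Preprocessing decisions

* Registration estimates one translation + isotropic scale from the
  clip's *temporal-mean* image (one shared transform for all frames) by
  NCC over a geometric grid of scales with per-scale phase correlation;
  rotation is off by default since probe fan orientation is canonical.
  A configurable NCC floor turns silent failures into errors.
* Cycle detection restricts to the top-10% temporal-variance pixels
  (the moving cavity boundary), centers them over time and takes the
  lag-averaged autocorrelation of the resulting frame vectors; the
  period is the highest non-zero-lag peak and the start is the first
  local extremum of the motion-region mean-intensity series.  The
  motion-region statistic (rather than the global frame mean) keeps the
  peak sharp when the oscillation is weak relative to speckle, e.g.
  PSAX at low LVEF.  A manual `(period, start)` override is a
  first-class input — the "semi-automatic" contract — and the pipeline
  falls back to the simulator's ground-truth period when detection
  fails.
* Frame selection uses the closed-form rule `start + floor(i·P/k)`,
  i = 0..k−1, k = 10; ties and rounding are thereby deterministic.
* Averaging rounds half-up back to 8-bit so FrameSets remain valid
  images; downsampling is anti-aliased linear interpolation.
* Coordinates are 0-based, origin top-left.

## Networks and training

No deep-learning framework is used: `echoview.nn` is a self-contained
NumPy CNN engine (3×3 same-padded convolutions via one matrix product
per kernel offset in channels-last layout, ReLU, 2×2 max-pool, dense
layers, softmax cross-entropy, MSE, Adam with standard defaults).
Gradients are exact and verified against finite differences.  Float32
throughout; pixel intensities are scaled to [0, 1].

The full-protocol classifier is 5 conv blocks with 64–128 channels,
50 epochs, batch 32 — these are the package defaults (`ModelConfig`).
Desk-scale experiments (tests, acceptance script) shrink channels to
(8, 12, 16, 24, 32) and epochs to 2 (per-frame input) or 8 (averaged
input); on the strongly separable phantoms both strategies converge
within these budgets, and the reduced problem sizes (60–120 training
studies, 30–40 test studies) keep a full run on one CPU in minutes.

Fold design is patient-level: all clips of a patient share a fold, so
near-duplicate frames never straddle the train/test boundary.  For fold
f the fold itself is held out, fold (f+1) mod k is the validation set
for min-loss checkpointing, and the rest train.

The surrogate EF regressor is a 3-block conv net (16, 24, 32 channels,
leaky ReLU) on the 2x-block-averaged cycle-averaged AP4 image, with a
**global-average-pooling** head, a scalar output and squared-error
loss, trained 50 epochs with Adam.  The GAP head is deliberate: the
model reads the motion-blur *texture* that encodes LVEF rather than the
chamber *layout* that identifies the view — the way a fixed
EF-measurement procedure reads wall excursion without re-deciding which
view it was handed.  A spatially flattened head at this scale either
memorizes each view's cluster (making view-mislabeling invisibly cheap)
or trains unstably; the GAP variant converges reproducibly across
seeds.  The surrogate stands in for the separately published EF model
the original analysis reused; all label-noise claims are statements
about this surrogate.

Open modeling choices resolved here: softmax *probabilities* (not
logits) are averaged across frames and weight sets, as the ensembling
is described; argmax ties break toward the canonical view order
(PLAX, PSAX, AP3, AP4, AP2); batch size, ReLU and max-pooling are
conventional fills for unstated details.

## Statistics

Weighted kappa uses disagreement weights w_ij ∈ {1−δ_ij, |i−j|/(k−1),
((i−j)/(k−1))²}; κ = 1 − Σw·o / Σw·e with marginal-product expectation.
Views are nominal, so the weighting (linear by default) and the class
ordering it acts on are reporting conventions; every result records the
weighting used.  The standard error is the classical large-sample
delta-method formula for weighted kappa (validated against bootstrap
resampling within 15% relative), and the 95% CI is κ ± 1.96·SE.
Correlations are Pearson's r; two independent correlations are compared
with the two-sided Fisher z test.  The label-noise experiment is run as
several independently seeded retrainings; the per-retraining Fisher z
statistics are combined with Stouffer's method (sum of z over sqrt(k)),
the standard aggregation for replicate experiments — a single
retraining at desk-scale n has too little power to resolve the modest
r differences corruption produces.  Corruption counts round half-up:
exactly round(rate · n) records are swapped.

Why corruption degrades r here at all deserves a note: a converged
regressor that can identify the input's view simply learns one
calibration per view, and wrong-view training clips then cost nothing —
Pearson r is also invariant to any monotone-linear bias, so deterministic
mis-calibration alone cannot reduce it.  The degradation that the
experiment measures comes from estimation error: per-patient anatomical
size (and gain) act as nuisance variables whose compensation must be
learned from clean designated-view data, and corruption replaces half
of that data at the 50% rate while injecting conflicting
texture-to-target pairs into the shared feature space.

## Known limitations

* Synthetic geometry is stylized; no claim of visual realism.
* The FAC–LVEF map and apparent-EF error scales are conventions, not
  fitted to clinical data.
* The headline clinical numbers of the original analysis (98.1%
  accuracy, κ = 0.98, r = 0.82/0.80) are properties of non-public data
  and are deliberately not targets; the package reproduces the
  *qualitative* findings (both input strategies learn the task; ≲2%
  mislabeling does not measurably degrade the EF model, gross
  mislabeling does).
* Registration assumes the fan dominates the image; clips with little
  fan content need the manual override path.
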