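# echoview

Echocardiographic view classification and label-noise robustness on
synthetic cine loops.

A proper echo study records short ultrasound videos from several
standard probe positions — parasternal long/short axis (PLAX, PSAX) and
apical 2-/3-/4-chamber (AP2, AP3, AP4) — but archives rarely label them
reliably, so identifying the view is the first step of any automated
analysis.  `echoview` implements that step end to end and then asks the
downstream question: if an imperfect view classifier lets a small
fraction of wrong-view clips into the training data of an ejection-
fraction (LVEF) regressor, how much does the regressor's accuracy
suffer?

Because the clinical cohorts behind the original analysis are not
public, the package includes a first-class synthetic generator: cohorts
of five-view cine loops with stratified LVEF (40 patients at 10–20%, 50
per decade up to 80%; 340 patients, 17,000 labeled frames in the full
design), sector-fan geometry with burned-in metadata, cardiac motion
whose fractional cavity-area change is linear in LVEF, Rayleigh speckle,
and vendor variation in fan angle, depth, gain and frame rate.

## Method

* **Preprocessing** — clips are rigidly registered (translation +
  isotropic scale, by normalized cross-correlation on the temporal-mean
  image), cropped to an 18.07 × 18.07 cm field at 120 × 120 px, stripped
  of peripheral metadata by fan masking and intensity windowing, and
  normalized in time: the cardiac period P is detected from the
  autocorrelation of the frame-mean intensity (manual override
  supported), and k = 10 frames are taken at indices
  `start + ⌊i·P/k⌋`, plus their pixel-wise average.
* **Classifier** — a small CNN (5 conv blocks, 64–128 channels by
  default) with 5-way softmax, trained with Adam on cross-entropy under
  patient-level 5-fold cross-validation, keeping the minimum-
  validation-loss epoch per fold.  Two input strategies: the averaged
  image, or the 10 frames individually with the 10 softmax vectors
  averaged.  At test time the 5 per-fold weight sets form an ensemble:
  probabilities are averaged and the argmax (ties broken by the
  canonical order PLAX, PSAX, AP3, AP4, AP2) is the predicted view.
* **Evaluation** — 5 × 5 contingency table; accuracy = trace/total;
  weighted Cohen's kappa `κ = 1 − Σw·o / Σw·e` (linear weights by
  default, unweighted/quadratic selectable) with a large-sample SE and
  κ ± 1.96·SE confidence interval.
* **Label-noise experiment** — exactly `round(rate·n)` records of the
  EF training set get a same-patient clip from a different view (the
  LVEF target is untouched), a surrogate conv regressor is retrained,
  and Pearson r on a clean held-out split is compared with the clean
  baseline via the two-sided Fisher z test.

No deep-learning framework is required: `echoview.nn` is a compact
NumPy CNN engine with exact, finite-difference-verified gradients.
See `docs/methods.md` for modeling assumptions and design choices.

## Worked example

```sh
python examples/04_noise_study.py
```

simulates a 60-patient cohort, corrupts the EF training set at
0%/2%/50% view-mislabeling, retrains the regressor per rate and prints:

```
 rate        r  n  n_corrupted  p_vs_baseline
 0.00 0.957817 18            0            NaN
 0.02 0.957060 18            1       0.980143
 0.50 0.910964 18           21       0.290937

r = Pearson correlation between estimated and reference LVEF on the
never-corrupted test split; p_vs_baseline = Fisher z test against the
0% row (NaN for the baseline itself).
```

At 2% corruption (1 of 42 training records) the correlation is
unchanged; at 50% it visibly drops, though a single retraining at
n = 18 cannot call that drop significant — the robustness tests
replicate the experiment over 12 independently seeded retrainings and
combine the Fisher z statistics, where it is.  The other examples cover
cohort simulation and I/O (`01`), preprocessing (`02`), and the full
view-classification study, which prints accuracy 0.933 and linear
weighted kappa 0.897 (95% CI 0.756–1.000) on 30 test clips at its small
default scale (`03`).  A thin CLI wraps the same pipeline for shell use
(`echoview --help`): `simulate`, `preprocess`, `train`, `predict`,
`evaluate`, and the two end-to-end drivers `view-study` and
`noise-study`.

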