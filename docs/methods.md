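# Methods

## Model and protocol

swathnet treats sample classification from raw LC–MS/MS data as a two-stage
problem: (1) make variable-length centroided spectra commensurable, and
(2) classify at scan granularity, then aggregate to a sample verdict.

**Feature swath extraction.** The m/z axis over `[mz_min, mz_max]` is tiled
with `J` contiguous equal-width windows; within each scan all peak intensities
falling in one window are summed, giving one length-`J` vector per scan
(`IM`). Each row is divided by its own maximum (`NIM`), making the features
invariant to any multiplicative intensity factor that is constant within a
scan — in particular per-run instrument response and injection-amount
differences. Windows are half-open `[lo, hi)` with the last window closed at
`mz_max` (standard histogram convention), so a peak exactly on an interior
edge belongs to the window starting there. Peaks outside the grid range are
dropped and counted in the log rather than clamped into edge windows;
clamping would distort the edge bins, and with a shared inferred range drops
are rare. Empty scans are retained as all-zero rows, and all-zero rows pass
through normalization unchanged (0/0 ≡ 0), so the matrix keeps one row per
acquired scan. Square window specs `"N×N"` denote `N²` one-dimensional bins;
the 2-D arrangement is purely a heat-map display convention, and the
classifier always consumes the flat vector.

One grid is shared by all runs of an experiment (training and test must live
in one feature space). By default its range is the floor/ceiling of the
pooled min/max m/z over all runs, inferred per MS level; explicit bounds can
be supplied instead. The default spec is 32×32 = 1024 windows, within the
resolution band (≈800–1000 windows) where window-size sweeps on DDA data
plateau; much coarser grids blur class-specific loci into shared bins and
much finer grids spread single peaks over many near-empty columns.

**Classifier.** The default network is three dense layers; on 1024 inputs:
1024 → 56 (ReLU) → 41 (ReLU) → 1 (sigmoid), 59,779 trainable parameters
(weights + biases, counted in closed form as Σ n_in·n_out + n_out). Multiclass
problems replace the output by `n_classes` softmax units. Other input widths
scale both hidden sizes proportionally (rounded, floored at one unit); the
parameter count is then reported, not asserted. Training uses minibatch Adam
on cross-entropy: 30 epochs, batch 128, learning rate 1e-3, no early
stopping, with a 10% held-out split whose accuracy is recorded in the
training log. These defaults suit cohorts of a few thousand scans; with only
a few hundred rows the number of gradient updates (epochs × rows/batch) is
small, and more epochs are warranted. All stochastic choices (initialisation,
shuffling, the validation split) derive from one integer seed, and training
is bit-reproducible within an environment. The optimizer/backprop machinery
is scikit-learn's multilayer perceptron; the architecture, parameter
accounting, determinism contract and decision rules are owned by this
package. Class imbalance is left untouched by default; deterministic
minority-class oversampling is available behind `TrainingConfig.balance_classes`.

**Prediction rules.** Binary: positive class iff its probability ≥ 0.5, ties
to the positive class — the same boundary-inclusive convention as the sample
verdict. Multiclass: argmax of the softmax row (ties to the lowest class
index, as produced by argmax).

**Leave-one-out cross prediction.** Each run is held out once; a fresh model
(no warm start) is trained on the remaining runs with seed
`master_seed + iteration`, giving reproducibility with inter-iteration
independence. The binary sample verdict is by scan vote with a
boundary-inclusive threshold: correct iff the fraction of scans predicted as
the true label is ≥ 0.5. Multiclass verdicts use the argmax of scan-averaged
class probabilities, matching how per-sample class-probability heat maps are
read. Cohort accuracy is the fraction of correct verdicts. Precision, recall
and F1 are computed over sample verdicts (that is the granularity at which
benchmark tables are reported); ROC and AUC are computed over the per-scan
positive-class probabilities pooled across iterations, because scans are the
unit at which the classifier emits calibrated scores. Zero-denominator
precision/recall are reported as 0 with a logged warning, preventing NaN
propagation into F1. AUC is the trapezoidal area under the threshold-sweep
ROC (ties grouped into single steps), which equals the concordant-pair
probability with ties counted one half.

## Synthetic cohorts

The generator emulates centroided DDA runs: scans on a jittered RT grid
across the gradient; per scan a Poisson number (mean 60) of background peaks
uniform in m/z 350–1350 with log-normal intensities (σ = 0.5); plus up to 8
class-signature peaks. Signatures are built from *shared* base loci: class
`c` displaces locus `l` by `signature_shift · N(0, 5 Th)` and rescales its
amplitude by `exp(signature_shift · N(0, 0.5))`, so at `signature_shift = 0`
every class draws from literally the same distribution — a built-in negative
control. Signature peaks fire in 80% of scans, wobble by 0.25 Th, and sit
about 8× above the background median. Each run carries a global intensity
factor drawn from [0.5, 2.0], which row-max normalization must cancel — this
is asserted end-to-end in the tests. Optional MS2 runs fragment the brightest
loci into 12 fixed-offset fragment peaks with 1.5× the intensity noise, so
the fragment level carries a degraded copy of the class signal. Defaults
(2 classes × 5 runs, 300 scans/run) complete a full leave-one-out analysis in
a few minutes on one CPU.

What the generator does **not** emulate: isotope envelopes, charge states,
chromatographic peak shapes, detector saturation, batch effects beyond a
scalar run factor, or retention-time drift between runs. Passing tests
therefore show that the pipeline recovers m/z-encoded class structure robust
to scale variation — not that it handles every artefact of real instrument
data.

## Null behaviour of the vote threshold

A property worth knowing before interpreting cohort accuracy: under
leave-one-out, the held-out sample's class is underrepresented in its
training fold (4 runs vs 5 in the default cohort). On data with *no* class
signal a trained classifier drifts toward the training prior, so per-scan
correct ratios concentrate near 4/9 ≈ 0.44 — just below the 0.5 vote
threshold — and the sample-level accuracy of a null cohort collapses toward
0 rather than 0.5 (with 300 scans per run, P(ratio ≥ 0.5) ≈ 3%). Scan-level
accuracy stays at chance (~0.44), which is the correct place to look for
train/test leakage: contamination would push it toward 1. The test suite
asserts the scan-level chance band; the sample-level pessimism is inherent to
majority voting under leave-one-out with no class reweighting and disappears
only if training folds are rebalanced (`balance_classes`).

## Numerical and design notes

- Window assignment uses `searchsorted` on the exact `linspace` edge array;
  the brute-force per-peak oracle in the tests pins the convention.
- Row sums of the unnormalized matrix conserve total in-range intensity to
  1e-9 relative (float associativity only).
- `infer_mz_range` floors/ceils to whole Th and widens a degenerate range to
  1 Th so a valid grid always exists.
- Retention times are normalized to seconds on read regardless of the source
  unit (mzXML ISO durations, mzML minute/second cvParams).
- mzXML 3.x is parsed with pyteomics. mzML 1.1 is handled by a deliberately
  minimal reader/writer (base64 32/64-bit float arrays, zlib or none;
  spectrum-level ms level and scan start time); precursor metadata,
  chromatograms and indexed wrappers are out of scope. The writer exists so
  synthetic cohorts can be round-tripped through a real file format in
  integration tests.
- Manifest paths resolve relative to the manifest file; duplicates and
  missing files fail fast, a single-class manifest only warns at load and
  errors at training time.
- Double normalization is refused rather than silently idempotent: per-scan
  division is defined on raw summed intensities only.
- The `5×5 … 32×32` sweep utility reuses one master seed across window specs
  so accuracy differences reflect resolution, not training noise; a failing
  spec reports its error and the sweep continues.
- Problem sizes in the test suite: structural properties run on randomized
  small fixtures; simulation-recovery checks run at the full default cohort
  conditions (10 runs × 300 scans, 1024 windows), once for the
  strong-separation cohort and over 10 seeds for the null control.

## Known limitations

- Only MS levels 1 and 2 and centroided (or centroid-like) peak lists are
  supported; profile spectra are binned as stored, without centroiding.
- Hidden activations other than ReLU are declared in the model spec but not
  trainable with the current backend.
- Multiclass precision/recall/F1 are one-vs-rest with macro averaging — an
  extension beyond the binary contract, labelled as such in the report.
- No automatic window-size selection: the sweep reports accuracy per spec and
  the choice stays with the analyst.
- Leave-one-out retrains one model per sample; cohorts of hundreds of runs
  would need a cheaper split strategy (not provided).
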