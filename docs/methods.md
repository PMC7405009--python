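# Methods

## The analysis problem

Five truffle species (white: *T. magnatum*, *T. borchii*; black:
*T. aestivum*, *T. melanosporum*, *T. indicum*) must be told apart from
FT-NIR absorbance spectra of freeze-dried, powdered fruiting bodies,
recorded in triplicate over 11550–3950 cm⁻¹. The discriminating signal
lies in broad overtone/combination bands of proteins and carbohydrates;
the nuisance structure is (a) particle-size scattering, which acts
approximately affinely on each spectrum, (b) a strongly variable additive
offset above 9000 cm⁻¹ (near-visible region, lyophilisate colour), and
(c) measurement noise. The package implements the full chain from raw
replicate spectra to cross-validated accuracy tables.

## Pre-processing model

Each operator acts row-wise on the absorbance matrix over a shared
wavenumber axis (stored ascending; derivative signs follow d/dν).

* **cut(threshold)** retains ν ≤ threshold. On the default 3732-point grid
  the 9000 cm⁻¹ cut keeps 2480 points, and 10-point binning then yields
  248 variables; the grid size was chosen so this convention holds
  exactly, since the true instrument grid (4 cm⁻¹ nominal resolution) is
  not recoverable from the study's report.
* **MSC** fits xᵢ ≈ aᵢ + bᵢ·r by OLS and corrects to (xᵢ − aᵢ)/bᵢ. The
  reference is the mean of the *current working subset*: subset analyses
  (black-only, white-only, one-species-by-origin) therefore rescope the
  reference automatically. Matching the study's protocol, pre-processing
  runs on the full working set *before* cross-validation; this leaks the
  subset mean across folds, which is deliberate reproduction, and a
  train-scoped reference can be passed explicitly (`reference=` vector)
  by anyone wanting the leakage-safe variant. Degenerate references
  (zero variance) and near-zero slopes (|bᵢ| < 1e−12) are errors.
* **Order rule.** cut must precede MSC. With active offsets above
  9000 cm⁻¹ the retained-region variance after cut→MSC is orders of
  magnitude below MSC→cut (the acceptance script reports the ratio);
  `PipelineSpec` rejects the wrong order unless `allow_unsafe_order=True`.
* **Smoothing** is a centred moving average (span 5, must be odd) with
  windows truncated at the edges — truncation invents no data, and no
  padding convention is implied by the design.
* **Derivatives** are plain finite differences on the (equally spaced,
  tolerance 1e−6 relative) axis: np.gradient-style central/one-sided
  stencils for order 1, and the direct 3-point second-difference stencil
  for order 2, with the nearest interior stencil reused at the edges. The
  direct stencil is exact on quadratics at every interior point, which is
  the behaviour the unit oracle asserts; iterating the first-difference
  operator twice would contaminate points adjacent to the boundary.
  Savitzky–Golay derivatives (scipy) are available behind
  `savitzky_golay=True` but are not the default, because the named
  approaches apply smoothing as an explicit separate step.
* **Detrending** subtracts each row's least-squares polynomial (default
  order 1) in the wavenumber, computed on a centred/scaled axis for
  conditioning; it is idempotent and leaves residuals orthogonal to the
  basis.
* **Binning** block-averages `width`=10 adjacent points (axis and
  absorbance alike), dropping a trailing incomplete block; with the
  declared grid no block is dropped. **Replicate averaging** collapses to
  one arithmetic-mean spectrum per sample and drops the replicate column;
  inconsistent species labels within a sample are an error.

The seven named approaches are: i cut9000+MSC; ii +1st derivative; iii
+2nd derivative; iv +detrend(1); v smooth+MSC+1st; vi cut6000+smooth+
MSC+2nd; vii smooth+MSC+detrend(1); all ending in bin(10) then replicate
averaging.

## Classifiers

Commodity algorithms (scikit-learn) pinned to the study configuration:
LDA (SVD solver, tolerant of p ≫ n rank deficiency; optional shrinkage),
SVC with polynomial kernel (γ = 1/scale², coef0 = 1, C = box constraint 1;
one-vs-one multiclass by default, one-vs-rest optional), a random-subspace
ensemble of LDAs (30 learners, ⌈p/2⌉ features each by default — the
subspace dimension is not fixed by the design and is configurable), a
random forest (Gini, `max_leaf_nodes = splits + 1 = 101`, 30 trees — tree
count unstated in the design, configurable) and 1-NN (Euclidean, equal
weights). Ensemble randomness is a pure function of the spec seed. No
internal standardisation is applied by default, so classifier inputs are
exactly the pre-processed features; note that a polynomial kernel at
scale 1 degenerates towards a constant on derivative-magnitude features
(~1e−4), which is why the quadratic SVM can collapse to majority-class
prediction there — `standardize=True` is the remedy when that
configuration is wanted.

## Validation protocol

Outer stratified 4-fold CV (per class, fold sizes differ by ≤ 1); each
training partition runs an inner stratified 10-fold CV over an optional
hyperparameter grid, ties resolved by grid order. Because the study design
fixes all hyperparameters, the default grid is a singleton and the inner
loop is skipped unless a validation estimate is requested
(`compute_inner_validation=True`) — supplying a real grid activates
genuine nested selection. The whole procedure repeats `repetitions` times
with folds re-randomised (both loops) per repetition; a master seed spawns
one independent stream per (repetition, approach, model) cell so any
sub-grid reruns identically in isolation. Reported: mean and sd (ddof 1)
over repetitions of the balanced accuracy, plus the accumulated confusion
matrix whose row sums equal repetitions × class counts (a conservation
law the tests assert). With one repetition the sd is reported as 0 and
flagged undefined.

Metric definitions: sensitivity = 100·diag/row-sum; balanced accuracy =
unweighted mean sensitivity (chosen over overall accuracy because class
sizes range from 5 to 29); predictive value = 100·diag/column-sum. The
latter is deliberately *not* called specificity: the published tables
label it "specificity" but print diag/column-sum values (e.g.
999/1025 = 97.5 %), i.e. a precision, not a true-negative rate. The strict
metric functions error on empty rows/columns; the evaluation summary
reports NaN predictive value for never-predicted classes so a degenerate
model doesn't abort a grid run.

## Synthetic generator

Per replicate j of sample i:
x = aᵢⱼ + bᵢⱼ·[baseline(ν) + Σₖ Aₖ·mₖ(class)·exp(−(ν−μₖ)²/2σₖ²) +
origin(ν)] + offsetᵢ·1[ν>9000] + ε(ν), with bᵢⱼ = exp N(0, 0.08),
aᵢⱼ ~ N(0, 0.02), ε ~ N(0, 0.003), all reproducible from one seed. The
baseline rises linearly towards low wavenumbers (0.15 → 0.60 absorbance).
Band centres sit at the assigned protein/amide (6667, 6318, 4859, 4687,
4600 cm⁻¹) and carbohydrate/C–H (4338, 4257, 5760, 5742 cm⁻¹) positions;
widths default to σ = 60 cm⁻¹ for the broad bands and 15–30 cm⁻¹ for the
doublets (invented, configurable). The 6318 cm⁻¹ protein-band multipliers
are proportional to reported soluble-protein contents
8.7 : 11 : 13 : 24 (melanosporum : aestivum : borchii : magnatum), with
indicum set equal to melanosporum at that band; the other bands carry
small invented contrasts sized so that all five classes — including the
5-sample *T. borchii* — are recoverable at ≥ 95 % balanced accuracy by
approach ii + LDA, the generator's documented design condition. 30 % of
samples receive a half-normal (sd 0.5) additive offset above 9000 cm⁻¹.
The 20 *T. magnatum* samples split 14 Italian / 6 non-Italian; the
non-Italian origins share one extra band (5150 cm⁻¹, σ 30, amplitude
0.15), sized once so that origin authentication after approach vi with a
random forest lands imperfect (~80–85 %) — origin is meant to be a much
weaker signal than species.

What the generator does **not** emulate: real between-class covariance,
correlated (pink) instrument noise, water-band interference, wavelength
miscalibration, or absolute absorbance levels. Passing tests therefore
demonstrate that the pipeline machinery is correct and calibrated, not
that real truffle spectra reach these accuracies.

## Numerical and design choices

* Axis stored ascending; descending (instrument-order) input is flipped
  with its columns on construction and on read.
* CSV is the only required dialect (UTF-8, comma, "." decimal, full-repr
  floats → round trips to ~1e−16, asserted at 1e−12); no vendor binary
  formats, no resampling onto a common axis.
* Missing origin is the literal string "unknown".
* PCA is the SVD of the mean-centred matrix (not a covariance
  eigendecomposition — better conditioned for p ≫ n); a unit oracle
  bridges the two to 1e−8. Sign convention: each loading's
  largest-magnitude element is positive. Component indices in
  `score_plane` are 1-based (PC1, PC2, …).
* Statistical checks involving chance level average over independent
  generated datasets, because repetitions on one dataset share its
  sampling noise: the null-calibration check draws 8 independent null
  datasets and uses the between-dataset standard error.
* Problem sizes in the shipped checks: 10 CV repetitions for accuracy
  estimates and 100 repetitions where only counting conservation is
  asserted (1-NN), keeping every check cheap while exercising the full
  machinery; the protocol itself defaults to the study's 100 repetitions.

## Known limitations

* The leakage-reproducing MSC scope (full working set before CV) follows
  the modelled protocol; accuracies under a train-scoped reference will
  be slightly lower on real data.
* The inner CV with a singleton grid is a validation estimate, not a
  selection step; what the original inner loop optimised over is not
  specified in the design and is left to the user via `inner_grid`.
* Quadratic/linear SVMs at kernel scale 1 are sensitive to absolute
  feature magnitude (see above); results for those cells are only
  meaningful with comparable feature scales or `standardize=True`.
* The generator's effect sizes are design knobs, not estimates of real
  truffle spectra.
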