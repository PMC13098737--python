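# Methods

## Scope and model

The package analyzes single-cell spontaneous Raman spectra acquired at
785 nm over 300–1800 cm⁻¹ (1024 detector bins, 10 accumulations of 10 s
averaged per cell) from three cell populations: normal pyramidal neurons,
dysmorphic neurons (FCD type IIa and IIb) and balloon cells (IIb only).
The analysis assumes each preprocessed spectrum is well described by a sum
of Gaussian bands on a residual-free background, and that diagnostic
information lives in the relative band intensities. Two binary questions
are posed: lesion vs normal cortex, and subtype IIa vs IIb.

## Preprocessing chain

Order: accumulation averaging → dark subtraction → response correction →
wavenumber calibration → Savitzky–Golay smoothing → baseline removal →
truncation → SNV. SNV is deliberately last; the suite asserts mean 0 / SD 1
(sample SD, tolerance 1e-9) for every spectrum after the full chain.

- **Dark subtraction** removes the laser-off detector offset; negative
  values are permitted (noise).
- **Response correction** divides by the relative instrument sensitivity,
  estimated as smoothed(measured standard)/certified curve and rescaled to
  unit mean, which makes the correction invariant to the standard's
  exposure. The smoothing reuses the Savitzky–Golay settings of the
  smoothing step (parsimony; one smoother in the whole chain).
- **Wavenumber calibration** least-squares fits a polynomial (degree 3,
  requiring ≥ 4 reference pairs) from measured to known positions of a
  reference compound, remaps the axis and linearly re-interpolates onto a
  uniform 1.1 cm⁻¹ grid anchored so a grid point falls exactly on
  700 cm⁻¹. After truncation to [700, 1700] this grid has 910 bins. The
  reference-peak table is an input file, not hard-coded, since reference
  band lists differ between instrument installations.
- **Savitzky–Golay** (order 3, window 11) replaces each point with the
  centered local least-squares cubic; edge points use the polynomial
  fitted to the truncated one-sided window (no reflection), so cubics are
  reproduced exactly everywhere.
- **Baseline removal** is a custom adaptation of the rolling-ball idea:
  a robust polynomial trend (degree 7, points more than 1 SD *above* the
  fit iteratively excluded, 12 iterations) first absorbs the steep smooth
  fluorescence decay; a morphological opening (erosion + dilation with a
  ball-shaped element, radius 120 cm⁻¹ in (cm⁻¹, scaled-intensity) space)
  then corrects the flattened residual; the sum is smoothed with the same
  SG settings and subtracted. The pre-flattening exists because a plain
  opening's error necessarily depends on the background's steepness and
  amplitude: with it, the final SNV spectrum changes by ~1% RMS when the
  baseline amplitude is quadrupled; without it, by ~6%. The radius default
  (120 cm⁻¹) sits well above the largest band FWHM (bounded at 60 cm⁻¹)
  and well below the baseline scale; it is exposed in `PreprocessConfig`.
- **Truncation** keeps the closed interval [700, 1700] cm⁻¹.
- **SNV** divides each centered spectrum by its sample SD; constant
  spectra raise a degenerate-input error.

## Peak features

Detection: local maxima separated by ≥ 8 cm⁻¹ whose prominence exceeds
3 × a robust noise estimate (MAD of successive differences / √2) and 5% of
the spectrum's peak-to-peak range. The absolute floor keeps near-noiseless
spectra from yielding microscopic candidates; the 3σ rule governs
realistic noise levels.

Fitting: nonlinear least squares of h·exp(−4 ln 2 (x−μ)²/w²) + c over a
window of ±15 cm⁻¹ around each candidate, truncated at half the distance
to the nearest neighboring candidate so blended doublets do not drag each
other's fits. Bounds: h ≥ 0, w ∈ [2, 60] cm⁻¹, μ within ±5 cm⁻¹ of the
candidate. The constant offset c absorbs the SNV shift (SNV spectra are
negative between bands); heights are therefore local band amplitudes in
SNV units. Non-converged fits fall back to the candidate position, the
local amplitude and a moment-based width, and are flagged.

Consensus: single-linkage clustering of all fitted positions (1-D: sorted
positions split where the gap exceeds the ±5 cm⁻¹ tolerance); clusters
present in ≥ 80% of spectra are kept, represented by their median
position. The feature matrix has 3 columns (position, height, FWHM) per
consensus peak; a spectrum without a matched fit gets a constrained refit
at the consensus position, so missing bands appear as ≈ 0 heights and the
matrix has no gaps. Tolerance (±5 cm⁻¹, half a typical FWHM) and the 0.8
prevalence threshold are configuration, not constants of nature.

## Classification

20% of spectra are held out up front (stratified by class; test size =
round(0.2·n), i.e. 294 of 1470). A `--group-by-patient` split mode keeps
all spectra of a patient on one side; the spectrum-level split remains the
default because it mirrors a random-spectrum holdout, but patient leakage
is a real optimism risk on clinical data and the grouped mode plus the
`analysis/05` sensitivity band exist to quantify it.

Feature selection uses an L1-penalized linear SVM purely as a ranker: the
selector strength is raised by bisection until at least the target count
of coefficients is nonzero, and the top-|coefficient| features are kept.
The final classifier is a standard L2 linear SVM — the two-stage design
keeps the sparsity device separate from the decision rule. Grid search
covers C ∈ {0.01, 0.1, 1, 10, 100} × retained features ∈ {4, 8, 13, 24,
48, 72} with fivefold stratified CV scored by ROC AUC; standardization and
selection are refitted inside every training fold. Ties break toward fewer
features, then smaller C.

Evaluation: ROC over all unique decision thresholds (±∞ endpoints), AUC by
the trapezoidal rule (the suite cross-checks it against the Mann–Whitney
U statistic), operating point = ROC point nearest (FPR 0, TPR 1) with ties
resolved toward higher TPR, and sensitivity/specificity/accuracy read off
the confusion matrix at that threshold. Note the operating point is chosen
on the test ROC; on finite test sets this carries a small optimistic bias
(~+0.06 accuracy at n≈30 under the null), which is why the null-calibration
test uses a test set large enough to keep the bias inside the chance band.

## Synthetic cohort: what it emulates, and what it does not

Each class profile lists 25 bands: the 17 catalogue bands (758–1657 cm⁻¹,
with literature assignments) plus 8 shared nuisance bands at {720, 880,
960, 1070, 1160, 1390, 1490, 1690} cm⁻¹, placed ≥ 27 cm⁻¹ from every
catalogue band. Class contrasts follow the observed mean-spectrum
directions (lesion model: FCD higher at 758, 827, 852, 933, 1263, 1337,
1554, 1602, 1657; normal higher at 1002, 1031, 1302, 1447; subtype model:
IIb higher at 852, 1031, 1101, 1124, 1201, 1263, 1302, 1447, 1554, 1593;
IIa higher at 1002). At every contrasted band the between-class mean
height difference equals `effect_scale` × the within-class height SD
(log-normal jitter, CV 0.15, mean-preserving); `effect_scale` defaults
to 3.

Instrument model: 1024 bins over 300–1800 cm⁻¹; bell-shaped response
curve; gentle monotone cubic wavenumber distortion (|shift| ≲ 3 cm⁻¹) —
the generated reference-peak table lies exactly on this cubic, so the
calibration fit must recover its coefficients; dark level 100 counts
(noise SD 5); Gaussian noise with variance dark² + signal (the standard
CCD dark + shot model) per accumulation; counts clipped at zero (dark
level ≫ noise SD, so the bias is negligible); 10 accumulations averaged.
Baseline: A·exp(−(x−300)/τ) with τ = 700 cm⁻¹ and A defaulting to 10× the
mean band height, so baseline removal is genuinely exercised. Cosmic-ray
spikes are off by default (available as a stressor flag). Patients carry a
log-normal per-band offset (SD 0.05) shared by their spectra, giving mild
intra-patient correlation; default hierarchy: 2 specimens per patient,
18/9/9 patients per class, counts 700/396/374.

Band widths default to 12 cm⁻¹ FWHM; the 1593/1602 pair gets 6 cm⁻¹
(sharp aromatic bands). Even so, at 1.1 cm⁻¹ resolution this 9 cm⁻¹
doublet blends in a fraction of spectra, and those single blended fits
bridge the two position clouds under single-linkage at ±5 cm⁻¹ — so the
pair contributes one consensus peak (~1597 cm⁻¹). The default conditions
therefore yield 16 resolved catalogue clusters + 1 blended pair + 8
nuisance bands = 24 consensus peaks and 72 features. Both diagnostic
directions survive on the blended feature, since 1593 carries only the
subtype contrast and 1602 only the lesion contrast.

What the generator does **not** emulate: paraffin residues and
deparaffinization artifacts, non-Gaussian line shapes, wavenumber-
dependent noise correlation, instrument drift between cells, cell-type
mixtures within a spectrum, or any real biological covariance structure
between bands (band heights jitter independently). Passing the end-to-end
tests therefore demonstrates that the pipeline recovers the structure this
generator plants at realistic noise levels — not that real FFPE cohorts
will reach the same figures. In particular, with independent band noise
and a 3-SD effect at ≥ 11 discriminative bands, both models saturate
(accuracy and AUC ≈ 1.0 on the held-out set); the configured effect size
is the dial that makes the problem as easy or hard as desired, and
`effect_scale=0` is the built-in negative control (chance-level accuracy).

## Numerical choices and degenerate inputs

Axes must be strictly increasing within [100, 4000] cm⁻¹; descending
files are sorted on read with a notice. The distortion inverse is computed
by interpolation plus three Newton steps (machine precision). Tolerances:
SNV invariant 1e-9; calibration-coefficient recovery is exact on exact
pairs up to conditioning (~1e-13 residual RMS in practice). Grid search is
an explicit loop (not a framework call) so the tie-break order is exact
and selection provably happens inside folds. Constant spectra, empty
truncations, single-class test sets, too-few calibration pairs and
non-monotone fitted maps all raise typed validation errors naming the
offending spectrum.

## Problem sizes used in the checks

The default verification cohort in the test suite uses 70 spectra
(30/20/20) end to end; the acceptance computation uses the full
700/396/374 design. The null-calibration check uses one 144-spectrum
two-class cohort over 20 split seeds; the Monte-Carlo averaging check uses
200 replicates. These sizes were chosen so each check's statistical margin
is comfortable at desk scale.

## Known limitations

Single consensus peak set per dataset (not per model); linear kernels
only; no probability calibration; no multiclass (3-way) model; no
despiking (spikes are a generator stressor, not handled in preprocessing);
the 1.1 cm⁻¹ resampling makes the 910-bin grid the package's canonical
fingerprint axis, and bin counts quoted elsewhere for the same interval
may differ by a few bins depending on endpoint conventions.
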