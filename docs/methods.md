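# Methods

## Scope and model of the data

The package analyzes SERS chip maps acquired for quantifying meropenem in
serum. One *map* is a grid of pixel spectra over a nanostructured silver
substrate; pixel intensities vary because plasmonic hotspots are unevenly
distributed. A calibration run measures a concentration series (replicate
maps per level), each map is collapsed to one representative spectrum, and
a latent-variable regression maps spectra to concentration. Validation
follows clinical practice: small held-out groups, permutation nulls, and
Bland–Altman agreement against a reference method.

## Synthetic-data generator

Because no spectra ship with the package, `synthgen` emulates the
statistical structure the analysis relies on. One pixel spectrum is

```
I(ν) = B(ν) + g · [ r · c · Σ_k a_k L_k(ν) + s · Σ_j b_j L_j(ν) ] + ε(ν)
```

* `L` — unit-peak Lorentzian profiles (Gaussian selectable). Raman-type
  bands are well approximated by Lorentzians; no line-shape information
  beyond band positions and relative intensities is emulated.
* Analyte bands `a_k` at 1559 (response 1.00 per μM), 1387 (0.55),
  1052 (0.30), 890 (0.35), 771 (0.22), 709 (0.18), 670 (0.15) cm⁻¹,
  FWHM 12–18 cm⁻¹. The 1559 cm⁻¹ β-lactam C=C stretch dominates and is
  the quantification band throughout. Relative responses are chosen to
  mirror the qualitative intensity ordering of the meropenem SERS
  spectrum; absolute units are arbitrary instrument counts.
* Interferent bands `b_j`: uric acid at 640 cm⁻¹ (amplitude 180) and a
  broad residual-matrix band at 1450 cm⁻¹ (amplitude 60).
* `B(ν)` — quadratic substrate baseline (coefficients 120, −60, 40 on the
  axis normalized to [0, 1]).
* `ε` — additive homoscedastic Gaussian channel noise, default SD 4
  (≈ SNR 25 at 100 μM); the noise model is a deliberate simplification
  (no shot-noise heteroscedasticity, no cosmic-ray spikes).
* `g` — per-pixel enhancement, log-normal with mean 1 and log-sigma 0.25
  (default), emulating hotspot heterogeneity while keeping the expected
  band height linear in concentration: E[height] = response · c.
* Cleanup method effects (`r`, `s`, noise scale): protein precipitation
  (PP), ultrafiltration (UF, 3k/10k cutoffs) and mono-spin solid-phase
  extraction (ms-SPE) differ in how much serum matrix survives. This is
  modelled as three coupled factors — interferent scale (PP 1.0, UF3k
  0.8, UF10k 0.45, ms-SPE 0.1), noise-floor scale (2.0/1.8/1.4/1.0) and
  analyte recovery (0.6/0.7/0.85/1.0) — so that ms-SPE shows both the
  weakest 640 cm⁻¹ interferent band and the best SNR, UF beats PP, as the
  assay development observed. The specific numbers are plausibility
  choices, not fitted values.
* Concentration–response is linear through the origin; adsorption
  saturation (Langmuir behaviour) is deliberately not simulated, so the
  generator cannot exercise nonlinear-calibration failure modes.

Default calibration design: levels {25, 50, 100, 250, 500, 750} μM × 5
replicate maps of 64 pixels on a 696-channel axis spanning 600–1800 cm⁻¹,
giving the 30 × 696 matrix the multivariate stages expect. The exact level
set between the named end points is a design choice. The paired patient
cohort draws truths uniformly from the 20–450 μM therapeutic window
(n = 27 by default) with reference noise SD 5 μM, test noise SD 30.8 μM
and test bias −14.55 μM (test − reference), matching the agreement
statistics such an assay reports. All randomness flows through one integer
seed; the pipeline fans a global seed out to stages by fixed offsets.

What passing tests on these data do **not** show: robustness to wavenumber
miscalibration between instruments, matrix effects beyond band-amplitude
scaling, heteroscedastic or correlated noise, and calibration
nonlinearity. They do show that the algorithmic chain is correct under its
stated assumptions (linearity, additive noise, multiplicative pixel
heterogeneity).

## Preprocessing

* **Crop** keeps channels inside a closed wavenumber range (default
  600–1800 cm⁻¹, covering all modelled bands).
* **Background correction** uses asymmetric least squares: minimize
  Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²z)² with wᵢ = p above the baseline and 1−p below,
  iterated to convergence (λ = 10⁴, p = 0.02, ≤ 20 iterations). The
  spectrum is linearly extrapolated by 30 channels at both ends before
  solving, because the free boundary of the second-difference penalty
  otherwise flattens the baseline at the spectrum edges. The banded
  normal equations are solved with a symmetric banded Cholesky, O(n) per
  iteration. Defaults were set against three recovery contracts: a pure
  smooth polynomial is removed to < 1 % of its range, peak heights over a
  linear baseline are recovered within 5 %, and correction of an already
  baseline-free noisy spectrum moves the net peak height by less than the
  noise SD.
* **Map reduction**: each pixel is cropped and background-corrected,
  pixels are ranked by their maximum corrected intensity inside
  1559 ± 10 cm⁻¹, and the channelwise mean of the top ⌈0.20 · n⌉ pixels
  (minimum 1) is returned with the scalar mean peak height. Ranking uses
  corrected heights; ties break toward the lower pixel index, making the
  reduction deterministic and permutation-invariant.
* **SNR** = net peak height at the band over the SD of corrected
  intensities in a band-free noise window (default 1700–1800 cm⁻¹,
  ≥ 5 channels); a zero SD raises instead of returning infinity.
* **Scaling**: min–max (training columns to [0, 1]; constant column → 0),
  autoscaling (zero-variance column raises), mean centering, row-wise
  vector normalization, Savitzky–Golay first derivative (window 9, order
  2), and log1p after clipping negatives. Column statistics are stored on
  fit and applied unchanged to prediction rows. Min–max is the pipeline
  default, the variant found most effective for this kind of data.

## Calibration

* **Univariate curve**: OLS of the 1559 cm⁻¹ net band height against
  concentration with per-level replicate SD (the classical error-bar
  calibration plot).
* **PCA**: mean-centered, full SVD. The suggested component count is the
  elbow of a venetian-blinds cross-validated reconstruction RMSE (first
  component whose marginal improvement falls below 1 %); this is a
  heuristic read-out, not a model-selection rule the regression depends
  on.
* **PLSR**: single-response NIPALS. With one response the weight vector
  per component is X'y normalized, so the algorithm is exact, not
  iterative. The regression vector at A components is
  b = W(P'W)⁻¹q; at full rank and maximal A it reproduces ordinary least
  squares, which the tests assert against `numpy.linalg.lstsq` and
  scikit-learn's NIPALS as independent oracles.
* **Cross-validation**: venetian blinds with 5 splits; replicates of the
  same concentration level are assigned to the same fold (no replicate
  leakage). Scaling and the decomposition are refit inside every fold.
* **Latent-variable count**: smallest A whose RMSECV lies within one
  standard error (over folds, at the RMSECV minimum) of the global
  minimum — the usual parsimony rule when only calibration/CV error
  curves are available.
* **Figures of merit**: instrumental noise is estimated by projecting
  blank (0 μM) replicate spectra through the fitted model; the SD of the
  resulting pseudo-concentrations is σ_c. Then γ⁻¹ = σ_c, γ = 1/σ_c,
  LoD = 3.3 σ_c, LoQ = 10 σ_c, and SEN = 1/‖b_raw‖ where b_raw is the
  regression vector mapped back to raw intensity units (defined for
  column-linear scalings). This is algebraically the pseudounivariate
  3.3 σₓ‖b‖ form with σₓ = σ_c/‖b‖; the leverage-corrected,
  sample-specific LoD variant is out of scope. The identity
  RMSEP² = bias² + SEP²(n−1)/n holds by construction and is asserted.
  Negative predictions are reported as-is with a flag, never truncated.

## Validation

* **Fold plans**: a random partition of n samples into groups of size 2
  or 3 (feasible iff 2f ≤ n ≤ 3f); 27 samples in 12 folds always yields
  nine pairs and three triples. Group sizes and memberships are shuffled
  from the seed.
* **Leave-group-out PLSR** refits scaling, decomposition and the LV count
  inside every fold, so each sample is predicted exactly once by a model
  that never saw it; pooled R² and RMSEP are computed from the aggregated
  out-of-fold predictions.
* **Permutation test**: concentrations are shuffled B times (default 999;
  the pipeline default is 199 to keep runs short) and the entire pipeline
  — scaling, LV selection, CV — is re-run per shuffle, so model selection
  cannot leak into the null. p = (1 + #{null ≥ observed})/(B + 1) for R²
  (≤ for RMSECV), hence p ≥ 1/(B+1) and the test is valid (super-uniform
  under the null), which the acceptance suite checks empirically at
  B = 199 over 100 pure-noise repetitions.

## Agreement

Differences are test − reference. bias = mean(d), sd = SD(d, n−1),
limits of agreement bias ± 1.96 sd, MDC = 1.96 sd. z is fixed at 1.96
rather than a small-sample t quantile because that is the convention the
reported agreement numbers follow; MDC is defined as the half-width of
the limits-of-agreement interval (the alternative 1.96·√2·SEM definition
is inconsistent with that arithmetic and was rejected). Conversion to
mg/L uses the meropenem free-acid molar mass 383.46 g/mol. The scatter
regression is OLS of test on reference with a mean-response 95 %
confidence band (statsmodels); a prediction band is not provided.

## Numerical and design choices

* All randomness uses `numpy.random.default_rng` seeded per call; a rerun
  of the pipeline with the same configuration is bit-identical (no
  timestamps in artifacts; files are stamped with the seed and a config
  hash instead).
* Top-fraction count is ⌈fraction · n⌉ with minimum 1; fraction ∈ (0, 1].
* "~1559 cm⁻¹" is interpreted as the window maximum within ±10 cm⁻¹
  (configurable); a zero halfwidth degenerates to the nearest channel.
* Degenerate inputs fail loudly: constant y, zero blank spread, empty
  crop intersection, infeasible fold plans and sub-minimal cohort sizes
  all raise with explicit messages rather than returning NaN.
* Problem sizes used by the shipped study and acceptance script — 30
  calibration rows (6 × 5) of 64-pixel maps on 696 channels, 12 test
  rows, 8 blanks, B = 199 permutations, 27-patient cohort — keep a full
  run in a few seconds while preserving the design's structure
  (row-to-channel ratio, replicate grouping, fold sizes).

## Known limitations

* The generator's linear response cannot probe saturation-induced
  calibration bias; LoD/LoQ estimates inherit the pseudounivariate
  assumption of homoscedastic blank noise.
* PCA component suggestion is a heuristic elbow, sensitive to the 1 %
  threshold on smooth CV curves.
* `b_raw` (hence SEN) is only meaningful under column-linear scalings;
  for derivative/log/vector-norm pipelines the scaled-space norm is
  reported instead.
* Transfer of calibration between instruments (different axes) is not
  supported; predictions require the training axis up to column
  permutation.
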