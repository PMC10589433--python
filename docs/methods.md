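# Methods

## Signal model and CVR estimator

The ROI-mean BOLD series S(t_k), k = 0..n−1, acquired every TR seconds
during an alternating air/CO2 breathing paradigm, is modelled as a linear
response to the end-tidal CO2 partial pressure x(t) delayed by a
hemodynamic lag δ, plus a linear scanner drift:

    y_k = β · x(t_k − δ) + γ · k + α + ε_k,
    y_k = 100 · (S_k − mean(S)) / mean(S)

β is the CVR in % BOLD per mmHg. For each candidate δ on a grid the model
is fitted by ordinary least squares; the reported fit is the one with the
smallest sum of squared residuals (SSR). Ties on SSR are broken toward the
smallest |δ|, then the smaller δ, so the estimator prefers the least
extreme physiological interpretation.

Choices that were genuinely open, and how they were settled:

- **Normalization baseline.** Percent change is taken about the series'
  own temporal mean. An intercept-based baseline is confounded with drift;
  the temporal mean is well-defined for every series and makes the
  estimator exactly scale-invariant. The algebraically near-equivalent
  alternative (fit raw signal, divide by mean) differs only through the
  regression intercept and is not separately exposed.
- **Delay grid.** Default −5 s to +60 s in 1 s steps. White matter lags in
  small vessel disease can exceed 30 s; the small negative margin lets the
  estimator flag series where the "response" precedes the stimulus (a sign
  of artefact). Configurable everywhere it appears.
- **Regressor construction per delay.** Each candidate regressor is
  re-interpolated from the breath-resolved EtCO2 trace at the delayed
  volume timestamps rather than shifting an already volume-sampled vector,
  so no temporal resolution is lost at any shift. Edges are extended with
  constant values so every fit uses all n volumes and SSRs are comparable
  across delays.
- **Volume timestamps.** Mid-TR (k·TR + TR/2) by default, on a symmetric
  sampling argument; volume-start timestamps are available via
  `volume_timing="start"`. The two differ only by a constant half-TR shift
  of the recovered delay.
- **Drift units.** The drift regressor is the 0-based volume index; the
  reported `drift_pct_per_scan` rescales the coefficient by n for
  readability.

Degenerate inputs: a constant regressor (e.g. an all-air paradigm) raises a
degenerate-design error at every delay and an estimation error overall; a
non-positive temporal mean raises a signal error; an ROI that is empty
after mask conditioning is omitted from a subject's results with a logged
reason rather than failing the subject.

## Mask conditioning

Order of operations: erode SGM and NAWM by 1 mm in all directions → dilate
the ventricles by 5 mm left/right and 4 mm along the other four directions
→ subtract the dilated ventricles from NAWM and WMH → subtract the optional
manually drawn large-vessel mask from all tissue ROIs. WMH masks are not
eroded: they are often only a voxel or two thick and erosion would empty
them.

Structuring elements are axis-aligned boxes, because the specification of
the operation is per-direction millimetre extents, which map directly onto
box half-widths. Millimetres convert to voxels with ceil, guaranteeing at
least the stated physical margin on anisotropic grids. The anatomical
(LR/AP/SI) to array-axis mapping is derived from the NIfTI affine's
dominant direction cosines; oblique acquisitions use the dominant axis with
a logged warning. Mask registration into BOLD space is out of scope: masks
are consumed already resampled to the BOLD grid.

## Cohort models

One OLS model per (ROI, predictor) pair, with regional CVR as outcome.
Adjusted models add age, sex, mean arterial pressure, smoking history (two
indicator contrasts — current/recent and ex-smoker >1 year — against
never), and diagnoses of hypertension, diabetes and hypercholesterolaemia:
10 parameters including the intercept. Confidence intervals use the t
distribution with residual degrees of freedom. Complete-case analysis per
model; models with fewer than 10 complete cases are refused. WMH volume
enters as log10(%ICV), so its coefficient is % BOLD/mmHg per ten-fold
volume increase; zero volumes are excluded from log models with a logged
count (an additive-offset policy is deliberately not the default, since it
changes the coefficient's meaning). No multiple-comparison correction is
applied; no significance threshold is enforced.

Standardized coefficients default to the both-variable z-score convention,
B · sd(x)/sd(y), which is what a forest plot comparing predictors across
ROIs needs; predictor-only scaling is available. Collinearity is screened
by the condition number of the z-scored design (threshold 30, warning
only); the raw-scale condition number is not used because covariates in
native units (age in years, pressure in mmHg) always exceed such a
threshold regardless of actual collinearity. Residual diagnostics are
Shapiro–Wilk (normality) and Breusch–Pagan (heteroscedasticity), advisory
at α = 0.05 with no automatic refitting.

## Synthetic-data generator

The generator's defaults encode the study conditions the package targets:
a 12-minute paradigm alternating 2 min air with 3 min 6% CO2, TR 1.55 s
(464 volumes), EtCO2 baseline 38 mmHg stepping 8 mmHg under hypercapnia,
and cohorts of 182 subjects.

- **EtCO2 dynamics.** The underlying level follows a first-order
  exponential response (default τ = 15 s) to the block stimulus — the
  simplest physiologically plausible shape that still exercises delay
  estimation — computed piecewise-exactly from the block-boundary
  recursion. Breaths are sampled every 4 s with Gaussian timing jitter
  (SD 0.3 s), forcing the resampling logic downstream.
- **BOLD forward model.** S_k = S0·(1 + c/100·x̃_k + d/100·r̃_k) + noise,
  where x̃ is the delayed EtCO2 regressor and r̃ the linear ramp, both
  centred at their temporal means. Centring makes mean(S) = S0 in the
  noiseless case, so the generating c is exactly the slope the
  percent-of-mean estimator recovers — the round-trip identity the test
  suite and acceptance checks rely on. Noise is i.i.d. Gaussian at a
  configurable percentage of S0 (0.2% is typical of ROI means).
- **Phantoms.** Nested ellipsoid brain, central ventricles, a WMH rim
  adjacent to the ventricles (guaranteeing the ventricle-dilation
  subtraction is exercised), lateral SGM blobs and an NAWM shell — all
  pairwise disjoint and deterministic per seed.
- **Cohorts.** Covariates are drawn to match the published population
  marginals (log-normal WMH volume with median 0.51 %ICV; geometric lacune
  counts with median 1; zero-inflated microbleeds with 80% zeros;
  Binomial(6, ½) atrophy scores; categorical Fazekas/PVS/SVD scores).
  Regional CVR is intercept + Σ B_j·x_j + Gaussian residual. Residual SDs
  for recovery experiments are back-solved from published CI half-widths:
  σ = (half-width / t_{0.975,df}) · sd(x) · √n, with the focal predictor
  drawn independently of the adjustment covariates so the multivariable SE
  matches the univariable formula. The default missingness pattern mirrors
  the study (7 missing WMH CVR, 3 missing MoCA, 6 missing PVS volumes).

What the generator does **not** emulate: voxel-wise fMRI noise structure
(spatial autocorrelation, physiological noise spectra), head motion,
registration error, correlated covariates (e.g. age–WMH volume), or
non-Gaussian CVR residuals. Passing tests therefore demonstrate estimator
correctness and calibration under the stated model, not robustness to
every artefact of real acquisitions.

## Problem sizes and reproducibility

Recovery experiments use 182-subject cohorts, 200 replicates in the
acceptance script and 400 in the CI-coverage test — enough for Monte-Carlo
standard errors of 2–4% of the smallest effect studied. Every stochastic
routine takes an explicit seed, and identical configuration plus seed gives
bit-identical output; the acceptance script derives all replicate seeds
from its single `--seed` argument via seed sequences.

## Known limitations

- Temporal realignment (motion correction) of the BOLD series is an input
  contract, not a processing step.
- Voxel-wise CVR and delay maps are out of scope by design; the estimator
  operates on ROI means only.
- Cortical grey matter CVR is not computed (cortical thinning and surface
  vessels make it unreliable in this population).
- Associations estimated by the cohort stage are cross-sectional;
  nothing here supports causal claims.
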