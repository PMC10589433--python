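# cvrkit

Cerebrovascular reactivity (CVR) quantifies how much cerebral blood vessels
dilate in response to a vasodilatory stimulus. In small vessel disease (SVD)
research it is measured by having patients breathe 6% CO2-enriched air in
alternating blocks while acquiring BOLD fMRI: the end-tidal CO2 (EtCO2)
partial pressure tracks the arterial stimulus, and the BOLD signal tracks
the vascular response.

`cvrkit` is a tested pipeline for this analysis, aimed at imaging
researchers studying SVD. It covers:

- **Physio processing** — end-tidal peak extraction from raw capnograph
  recordings, resampling of the EtCO2 trace to the BOLD volume grid, and
  delay-shifted regressors with constant-edge extension.
- **ROI conditioning** — erosion of subcortical grey matter (SGM) and
  normal-appearing white matter (NAWM) masks by 1 mm against partial-volume
  contamination; anisotropic ventricle dilation (5 mm left/right, 4 mm
  anterior/posterior/superior/inferior) and subtraction from the NAWM and
  white matter hyperintensity (WMH) masks to exclude periventricular veins;
  optional large-vessel exclusion masks.
- **CVR estimation** — per ROI, ordinary least squares of the
  percent-normalised mean BOLD signal on the shifted EtCO2 regressor plus a
  linear drift term:

      %ΔBOLD(t) = β·EtCO2(t − δ) + γ·t + ε

  The hemodynamic delay δ is chosen on a grid (default −5 s to +60 s, 1 s
  steps) to minimise the sum of squared residuals; β is the CVR in
  **% BOLD per mmHg**.
- **Cohort statistics** — univariable and covariate-adjusted linear models
  with regional CVR as outcome and SVD features (WMH volume as log10 %ICV,
  lacune and microbleed counts, Fazekas/PVS/atrophy/SVD scores, cognition)
  as predictors; standardized coefficients for forest plots; paired
  inter-region contrasts; residual normality and heteroscedasticity
  diagnostics.
- **Synthetic data** — gas paradigms, EtCO2 traces, BOLD series, phantom
  mask volumes and patient cohorts with known ground truth, so every stage
  is verifiable without patient data.

## Worked example

Simulate a 12-minute scan (2 min air / 3 min 6% CO2 blocks, TR 1.55 s) with
a known NAWM-like CVR of 0.042 %/mmHg, a 10 s hemodynamic delay and
realistic ROI-level noise, then estimate both back:

```python
from cvrkit.model import DelayGrid, normalize_percent, optimize_delay
from cvrkit.synthetic import (SimulationConfig, make_gas_paradigm,
                              simulate_etco2, simulate_bold_roi)

paradigm = make_gas_paradigm(2, 3, 12)
config = SimulationConfig(true_cvr_pct_per_mmHg=0.042, true_delay_s=10.0,
                          noise_sd_pct=0.2, seed=1)
trace = simulate_etco2(paradigm, config)
bold = simulate_bold_roi(trace, config)
result = optimize_delay(normalize_percent(bold), trace, DelayGrid(), config.tr_s)
print(f"CVR   = {result.cvr_pct_per_mmHg:.4f} %/mmHg")
print(f"delay = {result.delay_s:.0f} s")
print(f"R^2   = {result.r_squared:.3f}")
```

prints

```
CVR   = 0.0419 %/mmHg
delay = 9 s
R^2   = 0.419
```

The estimated CVR sits within the Monte-Carlo error of the generating
0.042 %/mmHg; the delay lands one grid step from the truth because noise at
0.2% of the baseline signal makes neighbouring shifts nearly equivalent,
and R² ≈ 0.42 is typical for ROI-mean series at this noise level. In the
noiseless limit the recovery is exact (to <1e-6 %/mmHg).

## Command line

```bash
cvrkit simulate  --out-dir sim --seed 1 --n-subjects 182 --n-imaging 2
cvrkit roi-prep  --mask nawm nawm.nii.gz --mask ventricles vent.nii.gz --out-dir prep
cvrkit cvr       --bold bold.nii.gz --mask nawm prep/mask_nawm.nii.gz \
                 --physio physio.csv --out cvr.csv
cvrkit cohort    --cohort cohort.csv --out-dir stats
cvrkit run-all   --config pipeline.yaml
```

Every run writes a JSON provenance manifest (versions, seeds, parameters,
per-subject inclusion/exclusion reasons) next to its outputs.

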