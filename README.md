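# coformkin

Tools for assessing the magnitude and decline of **pesticide co-formulant
residues** — the surfactants, solvents and carriers that plant protection
products (PPPs) contain besides the active substance — on vegetables and
fruit. Regulation and monitoring focus on active substances; co-formulants
are rarely measured, so screening-level estimates of their residues at
harvest must be built from PPP composition data, residue-trial statistics
for active substances, and simple dissipation kinetics. `coformkin`
implements that whole chain for residue scientists and regulatory exposure
assessors:

- **Trial data & QC** (`coformkin.trial_data`): residue time series with
  analytical replicates, recovery / replicate-precision / storage-stability
  statistics, and LOQ censoring (a time point enters fitting only if *every*
  replicate exceeds the limit of quantification; pre-treatment controls are
  always excluded).
- **Application model** (`coformkin.application`): per-substance application
  rate, `rate [g/ha] = content [g/kg] × PPP rate [kg/ha]`, and normalization
  of day-0 residues to a unit rate, `C₀,norm = C₀ / (rate / 1000)` in mg/kg
  per kg/ha.
- **Initial residues** (`coformkin.initial_residues`): the generic
  crop-filter model
  `C₀,gen = coverage × rate / (plant weight × plants per ha) × 10⁶` (mg/kg),
  and lookups of published scaled day-0 residues (median / 90th percentile
  at 1 kg/ha) per crop group.
- **Kinetics** (`coformkin.kinetics`): single-first-order decline
  `C(t) = C₀ e^(−kt)` with `DT50 = ln 2 / k`, and the bi-phasic DFOP model
  `C(t) = C₀ [g e^(−k₁t) + (1−g) e^(−k₂t)]` with a numerically derived
  overall DT50 (time to 50% of fitted C₀). Fitters are scikit-learn
  estimators (`SFODeclineModel`, `BiphasicDeclineModel`) with
  series-level wrappers `fit_sfo` / `fit_biphasic`.
- **Exposure tiers** (`coformkin.tiers`): screening predictions
  `C(PHI) = C₀-estimate × e^(−ln2·PHI/DT50)` at a pre-harvest interval PHI,
  with a *median* tier (median day-0 residue, DT50 = 5 d) and a *worst-case*
  tier (90th-percentile day-0 residue, DT50 = 12 d).
- **Synthetic trials** (`coformkin.synthetic`): a seeded generator of
  realistic trial datasets (default sampling days −1, 0, 1, 2, 3, 7, 14, 21;
  two replicates; 15% measurement CV; rain-pulse wash-off events) plus
  Monte-Carlo DT50 recovery studies.
- **CLI** (`coformkin.cli`): `coformkin fit | estimate | simulate | generate`.

## Worked example

```python
import numpy as np
import coformkin as ck

# per-substance rate and unit-rate normalization (solvent in parsley)
rate = ck.substance_application_rate(396, 1.25)       # 495.0 g/ha
c0n = ck.round_sig(ck.normalize_day0(9.0, rate), 2)   # 18.0 mg/kg at 1 kg/ha

# worst-case screening estimate for lettuce, 1 kg/ha, 7-day PHI
pred = ck.predict_residue("lettuce", 1.0, 7.0, "worst_case")
print(rate, c0n, round(pred.residue_mg_per_kg, 1))
```

prints

```
495.0 18.0 46.7
```

meaning: the solvent was applied at 495 g/ha; its measured day-0 residue
of 9.0 mg/kg corresponds to 18 mg/kg at a 1 kg/ha reference rate; and the
worst-case tier (70 mg/kg day-0 at the 90th percentile, declining with a
12-day half-life) predicts 46.7 mg/kg one week after a 1 kg/ha application.

Fitting kinetics to a synthetic trial:

```python
scenario = ck.TrialScenario(truth_params=ck.SfoParams(c0=10, k=np.log(2)/2), seed=42)
fit = ck.fit_sfo(ck.generate_trial(scenario))
print(round(fit.dt50_days, 2))   # 1.94  (true half-life: 2 days, 15% noise)
```

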