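# Methods

## Scope and model chain

`coformkin` estimates residues of PPP co-formulants on edible crops along a
four-stage chain: (1) QC and LOQ censoring of supervised residue-trial time
series, (2) application-rate arithmetic and normalization of day-0 residues
to a 1 kg/ha reference rate, (3) dissipation kinetics (SFO and bi-phasic)
with half-life derivation, and (4) tiered prediction of the residue at an
arbitrary pre-harvest interval. A seeded synthetic-trial generator makes
the fitting and prediction stages testable end to end without field data.

## Trial data and censoring

Concentrations are mg/kg fresh weight; time is days after treatment as a
float, with the sample taken ~1 h after spraying represented as t = 0
exactly and pre-treatment controls as negative days. Replicate counts are
not fixed (n ≥ 1; two analytical replicates is the common design).
Replicate precision is reported as the maximum relative deviation from the
replicate mean, in percent; it is 0 by definition for a single replicate,
and defined as 0 (with a warning) when all replicates are zero.

Censoring keeps a time point only when **every** replicate exceeds the
LOQ, mirroring how quantifiable decline data are displayed and avoiding
the bias of substituting LOQ/2 for non-detects near the tail. Censored
tail points are excluded, not imputed; substitution can be layered on by
the user for sensitivity analysis. Pre-treatment samples are stored but
never fitted; a control above 10% of the day-0 mean raises a warning
(typical trials report controls at least an order of magnitude below
day-0 residues).

## Application rates and normalization

The per-substance rate is always *derived* (content × PPP rate, g/ha).
Published composition tables occasionally print a measured tank-mix rate
that disagrees with the product of the printed content and PPP rate; an
explicit `rate_override_g_per_ha` field reproduces such printed values and
logs the discrepancy rather than silently choosing one. Normalization is
exact internally; the printed 2-significant-figure convention is applied
only at the reporting layer (`round_sig`). The packaged day-0 table flags
rows (`consistent`) where the printed normalized value is recovered from
the printed inputs after rounding; the remainder were evidently computed
from unrounded raw measurements and are excluded from regression checks.

## Initial residues

The crop-filter model treats a downward-sprayed field crop as a flat
filter: the intercepted dose (coverage × rate) is diluted into the
standing biomass (plant weight × planting density), with 10⁶ converting
kg/kg to mg/kg. It is linear in rate and coverage and inversely linear in
biomass, and is gated by a `whole_plant_commodity` flag: it applies only
where the consumable commodity is essentially the entire plant (leafy
vegetables and herbs), not to fruiting vegetables whose fruit is shielded
by foliage.

The scaled day-0 lookup table ships as editable YAML with the published
median / 90th-percentile values for leek (5.1 / 6.9 mg/kg), lettuce
(19 / 70) and apples (0.8 / 2.6) at 1 kg/ha. Parsley has no published
entry and is mapped to lettuce as a surrogate; the lookup logs the
surrogacy. Celery is omitted from the defaults because only verbal bounds
(confidence-interval midpoint and highest value) are published without
numbers; users can extend the YAML. The packaged crop parameters
(`crop_parameters_synthetic.csv`) are a synthetic stand-in: agronomically
plausible coverage/weight/density values chosen to be consistent with the
reported magnitudes of generic day-0 estimates for leafy crops
(~15–41 mg/kg at 1 kg/ha), since the original per-crop measurements are
not public.

## Kinetics

SFO fits run by nonlinear least squares on replicate means in linear
concentration space (residuals in concentration weight the early, large
residues most; a `log_space` flag switches to log residuals for
ill-conditioned tails). Initialization: c₀ from the day-0 mean via a
log-linear regression intercept, k from its slope. Convergence tolerance
is 1e−10 on the RSS change; the optimizer is deterministic, so identical
inputs give identical fits. Non-convergence falls back to the log-linear
estimate with `converged=False`. A fit needs at least free-parameters + 1
retained points and a day-0 point.

The bi-phasic model is double-first-order-in-parallel (DFOP), the standard
bi-phasic form in degradation-kinetics guidance: a fast phase (weight g,
rate k₁) in parallel with a slow phase (1−g, k₂), k₁ ≥ k₂ enforced by
post-fit relabeling since the phases are exchangeable. Fitting multi-starts
over g ∈ {0.2, 0.5, 0.8} with k₂ initialized at k/10; the best converged
start by RSS wins. A boundary-stuck g (within 1e−3 of 0 or 1) flags the
fit degenerate, i.e. effectively single-phase, and an SFO fit is
preferable. Because DFOP nests SFO (g = 1), the bi-phasic RSS is never
above the SFO RSS where both converge — kept as a test invariant.

The **overall DT50** of a DFOP fit is defined as the time at which the
fitted curve reaches half of the fitted c₀ — consistent with the SFO limit
ln 2 / k — and found by bracketing plus Brent root-finding to well below
1e−6 d (the root lies in [ln2/k₁, ln2/k₂] for interior g). A curve whose
non-degrading slow phase retains ≥ 50% of c₀ has no overall DT50 and
raises. No goodness-of-fit criterion beyond RSS is imposed; model
selection statistics are out of scope.

## Exposure tiers

A tier pairs a day-0 percentile with a default half-life:
median tier = median scaled day-0 with DT50 = 5 d; worst-case tier =
90th-percentile day-0 with DT50 = 12 d. The 5 and 12-day values are the
median and 80th percentile of foliar-dissipation half-life compilations
used in regulatory guidance; they live in code as `MEDIAN_TIER` /
`WORST_CASE_TIER` and can be replaced by custom `TierConfig` objects
(whether the p90 × p80 pairing is the right degree of conservatism is a
policy choice left to configuration). Predictions are linear in
application rate, and the worst-case tier dominates the median tier at
every PHI by construction. For crops without a lookup entry the predictor
falls back to the crop-filter model when crop parameters are supplied,
otherwise it errors — no silent surrogacy beyond the parsley→lettuce
mapping above.

## Synthetic trials

The generator emulates the design of a close-to-harvest residue trial:
sampling at days −1, 0, 1, 2, 3, 7, 14, 21; two replicates; LOQ
0.001 mg/kg (0.01 mg/kg is typical for an SDS-like analyte and is
configurable); replicate noise with a 15% CV by default, the middle of
the 1–25% precision range of LC–MS/MS residue methods. Noise is
multiplicative lognormal with a **mean-one** parameterization
(σ² = ln(1+CV²), mean correction e^(−σ²/2)) so the expected generated
concentration equals the truth curve times the wash-off factor — verified
to within 1% at CV 25% with 10⁴ draws. Rain wash-off is modelled as
instantaneous fractional removal between sampling days (a rain pulse
between days 2 and 3 is the motivating case); continuous rain-rate
modelling, volatilization and growth dilution are not mechanistically
separated — they are phenomenologically absorbed into the decline rate.
Day −1 samples are generated as zeros. All randomness derives from one
integer seed; `recovery_study` spawns per-simulation seeds reproducibly
from it and counts estimator failures instead of raising.

What passing tests on synthetic data do **not** show: real decline curves
mix processes (wash-off, volatilization, growth dilution) that SFO only
approximates, real noise can exceed the modelled CV for difficult
analytes, and real day-0 residues vary with growth stage and plant
architecture beyond the filter model. The recovery studies quantify
estimator behaviour under the stated noise model only.

## Problem sizes and numerical choices

Monte-Carlo recovery studies use 200 simulated trials at 15% CV on the
default schedule, enough to pin the median relative DT50 error to a few
percent while keeping the suite fast; the bisection-oracle comparison for
the overall DT50 uses 100 random DFOP parameter sets. Reported tolerance
choices: machine-level (≤1e−6) agreement on noise-free recovery, 1e−6 d
on the overall-DT50 root, 2 significant figures for normalized day-0
reporting.

## Known limitations

- The default scaled day-0 table covers three crop groups plus one
  surrogate; everything else needs user-supplied config or crop
  parameters.
- DBNS-like analytes quantified against a technical mixture are
  semi-quantitative; the package carries their numbers without extra
  uncertainty handling.
- No dietary-intake integration (consumption, body weight, hazard
  quotients): the pipeline stops at residue magnitude.
- No χ²-error-level or information-criterion model selection; users
  compare SFO vs bi-phasic fits via RSS and the degenerate flag.
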