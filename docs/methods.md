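# Methods

`fluxpam` processes long-term, in-situ measurements of leaf/shoot
photosynthesis acquired by two loosely coupled instruments: an automated
gas-exchange chamber sampled by an infrared gas analyser (IRGA), and a
miniature pulse-amplitude-modulated (PAM) fluorometer. This note records
the models implemented, the defaults and their rationale, the synthetic
campaign the test suite runs against, and the known limitations.

## Gas-exchange from chamber closures

The chamber (volume *V*, enclosing leaf area *S*) closes for 60 s every
20 min; CO₂ and H₂O concentrations are logged at 5-s intervals during
closure. Net assimilation and transpiration follow from the rate of
concentration change:

- The first 10 s (2 samples) of each closure are discarded as a
  fan-mixing transient. This is configurable (`lag_discard_s`); no
  published convention exists for this chamber, so the default is a
  judgment call and the diagnostics (`*_n`, `*_r2`) expose its effect.
- The default estimator is the ordinary least-squares slope of
  concentration vs. time over the retained samples (≥ 4 required), with
  slope standard error, R² and sample count reported per gas.
- CO₂ slopes (ppm s⁻¹ = µmol per mol of chamber air per second) convert
  to flux via the chamber air content *n* = *PV*/(*RT*ₖ) (ideal gas,
  *R* = 8.314 J mol⁻¹ K⁻¹, chamber air temperature and site pressure at
  closure): A_NET = −slope · *n* / *S*, so drawdown means positive
  uptake. H₂O is accepted either as molar density (mol m⁻³, flux =
  slope · *V* / *S*) or as mole fraction with the same ideal-gas
  conversion; the unit is declared per file.
- The chamber is non-hermetic. An opt-in mass-balance estimator fits the
  first-order solution *c*(*t*) = *c*₀ + *s·τ*(1 − e^(−t/τ)) of
  d*c*/d*t* = *s* + (*c*_amb − *c*)/τ and reports the initial rate *s*;
  if the nonlinear fit fails it falls back to the linear slope with a
  flag. The linear default matches how such closures are conventionally
  analysed; under genuine inflow it underestimates the flux (the test
  suite demonstrates both behaviours).

## Vapour pressure and stomatal conductance

Saturation vapour pressure uses the Magnus–Tetens form
SVP = 0.61078·exp(17.27·T/(T + 237.3)) kPa with T the **chamber air**
temperature (°C). Actual vapour pressure comes from the ideal gas law,
VP = (n/V)·R·Tₖ/1000 kPa, with n/V the water molar density; the pipeline
takes n/V from the fitted intercept of the closure H₂O trace at t = 0 —
the extrapolated pre-closure ambient — because the first *retained*
sample is already enriched by ~10 s of transpiration. VPD = SVP − VP,
clipped at zero with a supersaturation flag (dawn sensor noise near
saturation is expected, not an error). Stomatal conductance is
g_s = E/VPD·P (mmol m⁻² s⁻¹); below VPD = 0.05 kPa the division is
numerically meaningless and g_s is withheld with a low-VPD flag.

No leaf temperature is measured, so VPD is computed at air temperature;
when the leaf runs warmer, VPD is underestimated and g_s overestimated.
This bias is documented, not corrected.

## Fluorescence: Y(II), ETR, Fv/Fm

Y(II) = 1 − F′/F_M′. Records with F′ > F_M′ indicate saturating-pulse
failure and are flagged missing rather than clipped (clipping would bias
the nightly maxima). ETR = PAR_CH · Y(II) · Abs · α_II with the
generalized constants Abs = 0.84 and α_II = 0.5 as campaign-level
configuration; the chamber PAR sensor is used (the PAM unit's own PAR
sensor is reserved for quality control). Nightly Fv/Fm is the maximum
dark-acclimated Y(II) per night; a record is dark when PAR < 5 µmol m⁻²
s⁻¹ (a small positive cutoff robust to sensor offset), and nights are
counted noon-to-noon because boreal nights straddle midnight. All three
quantities are invariant to common multiplicative rescaling of F′ and
F_M′, which is why gain drift and step artifacts do not disturb them.

## Pairing and quality control

The fluorometer logger clock drifts relative to the chamber controller
(up to ~8 min over a campaign), so records are matched by nearest
timestamp within a 600-s tolerance, one-to-one (nearest wins; the
earlier gas record wins exact ties). Interpolation is deliberately
avoided: both streams share one cadence and interpolating F_M′ has no
physical meaning. Unmatched records on either side are emitted with a
`no_match` code.

Pairs measured under diverging illumination are detected by the ratio
PAR_CH/PAR_MICRO: outside 0.5–2.0 (inclusive bounds; strict variant
0.75–1.5) the pair is excluded. Pairs with both sensors below the dark
threshold bypass the filter (`dark_pair` tag — the ratio is undefined at
night); pairs with exactly one dark sensor are treated as genuine
mismatches and judged by the ratio.

## The ETR/A_NET diagnostic

ETR/A_NET counts electrons transported per molecule of net CO₂ fixed.
Its theoretical floor is 4 (four electrons → two NADPH → one CO₂);
photorespiration, day respiration and alternative electron sinks raise
it, and 8–10 is typical of unstressed C₃ leaves. The ratio is reported
for A_NET > 0; |A_NET| < 0.5 µmol m⁻² s⁻¹ sets a low-denominator flag
but the value is still reported, because extreme ratios at near-zero net
uptake are precisely the stress signal of interest. At A_NET ≤ 0 the
ratio loses its meaning and is suppressed with a sign flag. Daily
summaries report noon means over the half-open local window
[11:00, 15:00) using qc-passing daylight records only, each mean with
its record count; timestamps are interpreted in a single local zone with
no DST arithmetic.

## The synthetic campaign

The simulator exists so every stage is testable by parameter recovery;
its defaults are the study conditions: chamber volume 2.1 dm³, leaf area
42.5 cm², 60-s closures at 5-s sampling every 20 min, midday PAR up to
1700 µmol m⁻² s⁻¹, a 13–25 °C diurnal temperature sinusoid (minimum at
03:00, maximum at 15:00) and a 6-h dark window emulating a boreal
July.

- **Leaf:** ETR follows a one-parameter saturating exponential of PAR,
  ETR = Abs·α_II·Y(II)_dark·PAR_sat·(1 − e^(−PAR/PAR_sat)) with
  PAR_sat = 450 µmol m⁻² s⁻¹ and dark yield 0.82, chosen so the implied
  Y(II) falls from 0.82 in darkness to ~0.27 at full light and noon
  A_NET lands near 18 µmol m⁻² s⁻¹ under the default sink fractions —
  field-typical for a healthy top-canopy birch leaf. Gross assimilation
  is ETR/4 scaled by (1 − photoresp − alt_sink); net assimilation
  additionally by (1 − resp). Hence ETR/A_NET =
  4/((1 − photoresp − alt_sink)(1 − resp)) ≥ 4 with equality iff all
  fractions vanish — the analytic oracle the recovery tests use. Default
  fractions (0.35 photorespiration, 0.10 alternative sinks, 0.15 day
  respiration) put the ratio near 8.6, inside the normal C₃ band.
- **Stomata and humidity:** absolute humidity is constant at 90% RH of
  the nightly temperature minimum; g_s = g_max·f(PAR)/(1 + 0.6·VPD)
  with a small (5%) residual nocturnal conductance, and E inverts
  g_s = E/VPD·P so conductance recovery is exact by construction.
- **Closures:** noise-free traces are exact lines (or exact first-order
  exponentials when an inflow time constant is set), so integrating a
  trace recovers the imposed flux to machine precision; Gaussian sensor
  noise (defaults 0.2 ppm CO₂, 0.002 mol m⁻³ H₂O, instrument-class
  placeholder values — the campaign itself reports none) is added per
  sample.
- **PAM:** F_M′ = gain·2.5 and F′ = F_M′(1 − Y(II)) before noise, with
  an optional (time, factor) gain-step artifact; clock drift is a linear
  0 → `clock_drift_s` ramp applied to the *recorded timestamps only*
  (the measurement still happens on the cycle), matching a logger-clock
  drift. Light-mismatch injections shade PAR_MICRO of k randomly chosen
  well-lit cycles by a factor of 0.2, with the injection log stored in
  the ground truth.
- Identical scenario + seed ⇒ byte-identical serialized streams
  (per-stage RNG substreams spawned from the scenario seed).

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: leaf temperature departing from
air temperature, water-vapour condensation and wall adsorption, NPQ
kinetics beyond the Y(II) light response, realistic cloud fields
(illumination mismatch is injected, not emergent), canopy radiative
transfer, and instrument drifts other than the modelled gain step and
clock ramp.

## Problem sizes

The default test campaign spans 3 days (216 cycles); the QC-exactness
and noisy-recovery checks use 14 days (1008 cycles) and 1000 closures
respectively. These sizes make every statistical check well-resolved
(noon windows of ~12 cycles/day, ~95% coverage estimated from 1000
replicates) while keeping the whole suite fast.

## Known limitations

- PSI fluorescence contamination of F₀/F′ and possible F_M′
  undersaturation are not corrected; both bias Y(II) (and hence
  ETR/A_NET) downward on real instruments.
- Abs and α_II are campaign constants; seasonal variation is not
  modelled.
- Clock-drift *correction* (e.g. by cross-correlation) is out of scope;
  the package only tolerates drift through pairing.
- The noon window uses local clock time, not solar time.
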