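# Methods

## The estimation problem

On veno-arterial ECMO the native lung and the membrane oxygenator compete
for one venous return. If both exchangers see the same inflow gas content
and raise (or lower) it by the same amount per unit flow, the fraction of
total gas exchange each performs equals the fraction of blood flow each
receives, so native pulmonary blood flow follows from the measured ECMO
blood flow and the exchange ratio:

    Q_lung = Q_ecmo * |Vdot_lung| / |Vdot_ecmo|.

The package implements this estimator in five variants, distinguished by
the gas (O2 or CO2) and the measurement route (blood contents × measured
flow, or gas-phase integration). Production and elimination have opposite
signs across the two gases; magnitudes are used throughout.

### Gas-phase measurement

At the oxygenator, the exhaust flow is not measured directly. Nitrogen is
insoluble, so all nitrogen entering through the air mass-flow controller
(fraction 0.79 of the air line) leaves through the exhaust; the outlet flow
is `air_inflow * 0.79 / (1 - F_PE_O2 - F_PE_CO2)` (the Haldane
transformation). The transformation degrades as the exhaust nitrogen
fraction shrinks; below a nitrogen fraction of 0.05 the implementation
refuses to compute it. CO2 elimination is outlet flow × exhaust CO2
fraction; O2 uptake is O2 inflow minus O2 outflow.

At the airway, V̇CO2 and V̇O2 come from integrating tidal gas flow against
the fraction traces (positive flow = expiration), averaged over a 3-minute
window. The side-stream O2 signal lags the mainstream CO2 signal by a
transport delay; it is aligned by maximizing the cross-correlation of the
inverted O2 trace with the CO2 trace over lags of 0–5 s at one-sample
resolution. Breath detection uses a 0.1 L/min hysteresis on the flow sign.
Waveform pairs with different sample rates are linearly interpolated onto
the higher rate before integration. All simulator gas volumes are generated
and consumed in STPD, so no BTPS conversion is applied internally; an
optional conversion factor can be applied when ingesting real data.

### V/Q normalization of lung CO2 elimination

CO2 elimination depends on the ventilation/perfusion ratio as

    V(x) = V1 * x * (1 + c) / (x + c),     x = V/Q,

where V1 is the elimination the exchanger would achieve at x = 1 and
c = sigma_CO2 * R * T * (1 + Kc), Kc = 10^(pH − pK'), evaluated on a venous
sample (ECMO drainage by default; configurable to the pulmonary artery).
Multiplying a measured lung V̇CO2 by f(x) = (x + c)/((1 + c) x) therefore
recovers the flow-proportional V1 exactly when the measured x is right —
the normalization is the exact inverse of the model's V/Q dependence, and
f(1) = 1. The lung x is estimated from the O2 mass balance: contents in
mL/mL divided by the inspired-minus-mixed-expired O2 fraction difference.
The printed form of that ratio in the source literature is dimensionally
the reciprocal-and-negated mass balance; this package implements the
mass-balance-consistent orientation (ca − cv)/(FI − FE), which is positive
for an oxygen-taking lung and yields values near 1 under matched
ventilation. Normalization is applied per window, with that window's V/Q
estimate. The membrane lung is run at V/Q = 1 by protocol and never
normalized.

### Blood-phase measurement and hemoglobin pooling

Blood-phase exchange rates are content differences times the measured
flows (flow probes), mirroring how such validation datasets are analyzed.
Within a window the five site samples are drawn from the same circulating
blood within minutes, so hemoglobin is physically common to them; by
default the estimator uses the mean Hb of the window's samples for all
content calculations (`pool_hb=False` restores per-sample Hb). Pooling
removes analyzer Hb noise — which would otherwise dominate the O2
content-difference error — without touching the saturation and tension
measurements that carry the signal.

## Content models

* **O2 content**: 1.36 · Hb · SO2/100 + 0.003 · PO2 (mL/dL). The 1.36
  binding capacity is used verbatim for porcine blood; 1.34–1.39 variants
  exist and the coefficient is a plain constant in the code.
* **CO2 content**: the Douglas–Stapp–Fenn whole-blood formulation —
  plasma dissolved + bicarbonate CO2 from Henderson–Hasselbalch with
  pH/temperature-dependent solubility and pK', scaled to whole blood by
  1 − 0.0289·Hb/((3.352 − 0.456·SO2)(8.142 − pH)). The saturation term is
  the Haldane effect. The model is strictly increasing in PCO2 and
  decreasing in SO2, and evaluates to ≈47 mL/dL at PCO2 40, pH 7.4, Hb 15,
  SO2 97.5%. It stands behind a stable function interface; any whole-blood
  CO2 model passing the same monotonicity and range tests could be
  substituted.
* **Dissociation curve**: Hill curve 100·PO2ⁿ/(PO2ⁿ + P50ⁿ); porcine
  defaults P50 = 35 mmHg, n = 2.8.
* **Species saturation correction**: CO-oximeters are calibrated for human
  hemoglobin; porcine blood needs recalibration. Implemented as a monotone
  odds-power map preserving 0 and 100 (identity by default). The porcine
  default parameters are provisional placeholders for a published
  recalibration whose coefficients are not reproduced here.

Unit conventions: contents in mL gas (STPD)/dL blood, 1 mmol CO2 =
22.26 mL, flows in mL/min, fractions dimensionless.

## The circuit simulator

The simulator provides ground truth where no public dataset exists. It is
a lumped, steady-state model solved by fixed-point iteration on arterial
contents (tolerance 1e-8 mL/dL, limit 10,000 iterations, diagnostics on
failure):

1. **Body**: fixed VO2 (200 mL/min) and VCO2 (160 mL/min, respiratory
   exchange ratio 0.8 — reported total VO2 and VCO2 in comparable animals
   are not mutually consistent with RER 0.8, so the O2 figure is kept and
   VCO2 derived from the RER); mixed venous content = arterial ∓
   100·Vdot/Q_total.
2. **Venous split**: the return divides into ECMO drainage (RA) and
   pulmonary flow (PA). An optional O2-content offset between the two
   streams (`venous_streaming_delta`, mL/dL, applied mass-conservingly
   about the flow-weighted mean) reproduces the venous-side inflow
   heterogeneity seen in vivo; PCO2 streaming is not modeled.
3. **Native lung**: a shunt fraction of pulmonary flow bypasses exchange
   entirely. The exchanging compartment runs at an effective V/Q of
   `lung_vq / (1 − occluded_fraction)`: balloon occlusion of a pulmonary
   artery branch removes perfusion from ventilated units while the
   ventilator keeps total ventilation, raising the ventilation available
   per unit of exchanging perfusion. This is a deliberate single-
   compartment idealization — no multi-compartment V/Q distribution is
   modeled — chosen so that the gas-side V/Q estimate recovers the
   effective V/Q exactly on noiseless data.
4. **Membrane lung**: complete oxygenation (outlet SO2 100%) below a rated
   blood flow, with outlet PO2 = FdO2·713 − PCO2 − gradient (default
   gradient 40 mmHg); above rated flow, saturation declines linearly. CO2
   removal is anchored at V/Q = 1 by an equilibration factor (outlet PCO2
   = k_eq × inlet PCO2) and scaled across V/Q by the same V(x) model the
   normalization inverts. k_eq = 0.87 was calibrated once so the baseline
   circuit sits at the protocol's stated operating point (sweep titrated
   to arterial pH 7.4–7.5; realized pH 7.41, PaCO2 38 mmHg).
5. **Mixing**: aortic content is the flow-weighted mix of lung and ECMO
   outflow; acid–base follows a log-linear acute-respiratory pH(PCO2)
   relation around 7.40 at 40 mmHg.

Gas-side signals (sweep blend at FdO2 0.6, exhaust fractions, lung FI/FE
and minute ventilation) are generated consistently with the blood-side
exchange, which makes every estimator exact on noiseless data — the
parameter-recovery property the test suite leans on. Ventilator waveforms
(square-wave flow with I:E 1:1.6, CO2/O2 fraction traces, configurable
side-stream delay) are synthesized so their integrals reproduce the
configured transfer rates.

**Protocol emulation**: six phases (baseline ×2, shunt ×2 at
shunt_fraction 0.3, dead space ×2 at occluded_fraction 0.3, with two
ventilator V/Q settings per condition) × the ECMO ladder 4, 3, 2, 1 L/min
at constant total cardiac output 5 L/min — 24 measurement periods per
simulated animal, five blood-gas draws (one per site) per period.

**Noise model**: accuracy bounds quoted for the devices are interpreted as
95% intervals (SD = bound/1.96): mainstream capnograph ±2 mmHg below
41 mmHg and ±5% of reading above; side-stream module ±(0.2 vol% + 2% of
reading) for CO2 and ±(1 vol% + 2%) for O2. Blood-gas analyzer SDs: PO2
2 mmHg, PCO2 1 mmHg, SO2 0.5%, Hb 0.2 g/dL (pH noise not modeled).
Saturations are clipped to [0, 100] and pressures to ≥ 0. One seeded
generator per dataset; the seed is recorded in `meta.txt`.

## Agreement statistics

Bias = mean(test − reference); limits of agreement = bias ± 1.96 SD of the
differences (normal multiplier, no t-quantile); least-squares regression
of difference on pair mean flags proportional bias. Percentage error =
100·1.96·SD/mean reference. Least significant change = 1.96·√2·SD_within,
with SD_within pooled as the RMS of per-subject replicate SDs; replicates
are the repeated phases at the same (animal, condition, ladder step).
Trending concordance counts sign agreement of ladder-step changes outside
a central exclusion zone defaulting to the method's LSC. Outlier rule:
calculated flows < 0 or > 10 L/min are excluded (flagged, logged, order
preserved). Limits of agreement are pooled over all windows; no
repeated-measures correction is applied by default.

## What the simulator does and does not show

Passing tests demonstrate internal consistency: the estimator recovers
known flows under the ideal-circuit premise, degrades in the documented
directions under shunt, V/Q mismatch and venous streaming, and the
precision ordering of the variants under device-spec noise matches what
animal experiments report (blood-O2 most precise, gas-phase O2 least).
They do not demonstrate accuracy on real animals or patients: the
simulator enforces a steady state (CO2 body stores equilibrate over hours
in vivo, so real CO2-based estimates see non-steady-state drift the model
deliberately omits), uses a single-compartment lung, a phenomenological
membrane CO2 model, and no pH streaming, recirculation, pulsatility or
temperature effects. The V-V ECMO configuration is out of scope.

## Numerical notes

* Fixed-point iteration is a contraction under physiological parameters;
  convergence is typically 300–450 iterations at 1e-8 mL/dL.
* Content → blood-gas inversion uses scipy's Brent root-finder at xtol
  1e-10 over PO2 ∈ (0, 1500] and PCO2 ∈ (0, 400]; contents above the
  model ceiling pin to the bracket edge.
* Degenerate inputs raise ValueError with a named cause: equal content
  differences (denominator < 1e-9 mL/dL), zero membrane exchange, equal
  FI/FE, nitrogen fraction ≤ 0.05, flat waveforms, windows shorter than
  one breath. Per-method failures are isolated: the other estimators of a
  window still report.
* Seeds: every random stream derives from `config.seed` (per-animal seeds
  are offset by 1000·animal); identical configuration and seed reproduce
  all outputs byte-for-byte.
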