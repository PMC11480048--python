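# Methods

This note documents the models, numerical choices and defaults behind
`rqcontrol`: what the digital twin simulates, how the soft sensors and
controllers are defined, how the adaptive gain is learned, and what the
package's tests do and do not demonstrate about a physical bioreactor.

## 1. The digital twin

### 1.1 Two-reaction black-box metabolism

The culture is described per C-mol of glucose by two lumped reactions
whose coefficients are *solved*, not tabulated, from four inputs: the
oxidative biomass yield `Y_XS_ox` (default 0.50 g/g), the fermentative
yield `Y_XS_ferm` (0.25 g/g), the biomass elemental formula
(CH1.761O0.636N0.143, a literature-typical yeast composition — the
organism's measured composition is not published) and the by-product
carbon split (ethanol 0.85, arabitol 0.10, succinate 0.05).

* Oxidative: `CH2O + b O2 → Yc_ox X + (1−Yc_ox) CO2`, with `b` fixed by
  the degree-of-reduction balance (γ convention C=+4, H=+1, O=−2, N=−3;
  ammonia as N source). With the defaults this gives an oxidative
  respiratory quotient `RQ_ox = 1.021`.
* Fermentative: `CH2O → Yc_f X + B·(by-products) + c CO2`, no oxygen,
  with the total by-product carbon `B` fixed by the electron balance and
  `c` by the carbon balance.

Both balances therefore close *exactly by construction*, which is what
makes the downstream consistency checks meaningful. The oxidative RQ is
a derived quantity, validated at construction to fall in the
physiological 1.0–1.1 window; configurations that cannot close (e.g. a
by-product pool too oxidised to absorb the fermentative electron
surplus) are rejected at construction.

The instantaneous metabolic state is a convex mix of the two reactions:
oxygen uptake is `qO2 = min(demand, OTR_capacity/X)`, where `demand` is
the fully-oxidative requirement of the current glucose flux; whatever
fraction of the flux cannot be respired runs fermentatively. RQ is then
a strictly decreasing function of the oxidative fraction, which makes
steady-state RQ monotone in agitation speed — the property every
controller in the package relies on.

### 1.2 Feeding, uptake and growth

The feed is the exponential profile
`F(t) = F0·exp(µ_set·t)`, `F0 = X0·V0·µ_set/(Y_XS_ox·S_feed)`, with
µ_set = 0.10 h⁻¹, X0 = 25 g/L, V0 = 2 L, S_feed = 400 g/L. Residual
glucose stays ≈ 0 (carbon limitation); uptake saturates at a
configurable `qS_max` (0.30 g/g/h), above which glucose accumulates —
the twin's representation of the instability seen at very high biomass
and feed. Because hypoxic growth yields less biomass than the oxidative
yield assumed by the feed law, the realised µ settles slightly below
µ_set and the realised qS slightly above µ_set/Y_XS_ox, as observed in
practice. Product formation is growth-associated, `qP = Y_PX·µ` with
Y_PX = 3.8 kAU/g.

### 1.3 Oxygen transfer

`kLa = a·N^b` with b = 2 and a = 5.0391e-4 h⁻¹·rpm⁻², frozen by
calibrating the steady twin so that the batch-end state (X0, µ_set)
sits exactly at RQ = 1.4 when stirred at 575 rpm — i.e. the set-point
lies in the 550–600 rpm window where the experimental fed-batches
started. `calibrate_kla_coefficient` reproduces this number by
root-finding.

The driving force uses Henry's law against the *mean* of inlet and
off-gas O2 partial pressure (the usual single-tank approximation for a
measurably depleted gas phase), so enriching the inlet from 20.97% to
28.87% O2 raises the transfer capacity by the partial-pressure ratio,
and uptake is additionally hard-capped at 98% of the molar O2 supply —
without this cap a fast-growing culture could formally consume more
oxygen than the gas stream carries. Dissolved oxygen is quasi-steady:
zero when transfer-limited, otherwise the value balancing uptake.

### 1.4 Gas phase, analyser dynamics and noise

True dry off-gas fractions follow from the instantaneous gas-phase mole
balance (molar volume 24.466 L/mol at 1 atm, 25 °C). The analyser and
headspace are lumped into one first-order lag, τ = 7 min by default,
bounded by the empirically observed 5–10 min response window. The
*inlet reference* used by the soft sensor passes through the same lag:
the analysed off-gas corresponds to inlet gas from roughly τ earlier, so
reconciling an instantly-switched inlet composition with lagged outlet
readings would manufacture phantom respiration rates at every blend
change.

Measurement noise is multiplicative Gaussian on the respiration
*signals* — the inlet–outlet O2 depletion and CO2 enrichment — with RSD
1.5% per channel (plus 2% on the humidity channel). Noise sized this
way propagates to ≈1.5% RSD on OUR/CER and ≈2% on RQ, matching the
reported precision of the calculated respirometric parameters; the same
RSD applied to the raw fractions instead would swamp the depletion
signal (2% of y_O2 ≈ 0.2 is several times the early-fed-batch signal)
and contradict that precision. Noise is applied only to measured
channels; the true state is integrated deterministically and logged
alongside, which is what enables exact-balance tests and ground-truth
supervision.

### 1.5 Integration

Explicit per-minute stepping with 4 sub-steps (15 s). The control clock
is 1 min and the fastest dynamic is the 7-min lag, so this resolves all
time constants comfortably; because every state increment in a sub-step
derives from the same closed rate vector, carbon and electron
inventories are conserved to floating-point accuracy over arbitrary
horizons (asserted at 1e-6 relative in the tests, observed ~1e-12).

## 2. Soft sensors

Outlet molar flow comes from the inert (N2) balance,
`F_out = F_in·(1−y_O2_in−y_CO2_in)/(1−y_O2_out−y_CO2_out)`; OUR and CER
from the O2/CO2 mole balances normalised by broth volume; RQ = CER/OUR.
The inert balance — rather than the naive ratio of fraction differences,
which is also provided for comparison — is required for correctness as
soon as RQ ≠ 1, and especially across the O2-enrichment step. Readings
are first span/offset-calibrated and converted from wet to dry basis via
the humidity channel (`y_dry = y_wet/(1−humidity/100)`).

Below a configurable OUR floor (2e-3 mol/L/h) RQ is reported as
undefined (NaN) rather than as a number: in the early fed-batch both gas
signals are small and their quotient amplifies analyser error. All
downstream consumers (controllers, metrics, training-set construction)
treat undefined RQ explicitly.

## 3. Controllers

All three policies share a protocol: called once per minute with the
current smoothed RQ and a snapshot of process variables, they return a
(possibly empty) agitation action carrying its provenance (rule, ε,
K_P). Controllers consume a 3-sample moving average of the per-minute
soft-sensed RQ; performance statistics are computed on the raw trace.

* **MHC** (initial N = 600 rpm): checks every 30 min; if RQ > 1.6,
  steps up by a time-scheduled amount, default +50 rpm before 5 h and
  +100 rpm after; never steps down. The escalating default keeps the
  step at roughly N/8 as agitation grows from 600 toward 1200 rpm — a
  constant-magnitude step merely chases the exponentially growing oxygen
  demand and leaves RQ riding at the threshold. An overshoot-graded
  "expertise" rule was evaluated and performs *worse* (small overshoots
  trigger small steps, reinforcing the chase), so the deterministic time
  schedule is kept as the reproducible stand-in for the operator.
* **BLC** (initial N = 550 rpm): every 10 min; +Δrpm1 when RQ > 1.4
  (Δrpm1 scheduled 10/15/25 rpm at 0/7/14 h), −10 rpm when RQ < 1.3,
  nothing in the deadband. The down-rule is checked first; the
  thresholds make the rules mutually exclusive, so the order is stated
  only for determinism.
* **AI-APC** (initial N = 550 rpm): every minute computes
  ε = RQ − 1.4 and a gain K_P from the forest (below); the action
  Δrpm = ε·K_P is applied only if ≥7 min have passed since the last
  applied action *and* |Δrpm| ≥ 2 rpm (symmetric deadband — the only
  self-consistent reading of the action-suppression rule given that
  Δrpm may be negative). Without a model the controller records a
  warning and holds.

## 4. The adaptive gain model

A scikit-learn random-forest regressor (100 trees, bootstrap, √p
features per split, min-leaf 2, seeded) predicts the **agitation speed
required to hold RQ = 1.4** from nine features: time, current agitation,
smoothed RQ, OUR, CER, feed rate, cumulative glucose fed, inlet O2
fraction, and total biomass.

*Training corpus.* Closed-loop twin runs of the two simpler strategies
(MHC, BLC) at µ = 0.08/0.10/0.12 h⁻¹, one replicate each, no gas
disturbances — emulating a historical record of plain hypoxic
fed-batches. One row per 10-min control instant, skipping undefined-RQ
and glucose-accumulation rows (~670 rows).

*Supervision.* The target of each row is the twin's ground-truth
inversion of the steady kLa/OTR/metabolic-split map at the row's state
(closed form; cross-checked against a bisection oracle to 0.5 rpm).
This supervision is observable only in simulation; it stands in for the
operator-action labels a physical plant would provide, and nothing
downstream depends on its specific provenance.

*Gain derivation.* K_P = |N_predicted − N_current| / |ε|, clamped to a
configurable non-negative range (default 0–600 rpm per RQ unit), with
the *direction* of the move always taken from ε. When the prediction
and the error agree in sign — the normal, in-envelope case — the
proportional law reproduces the predicted correction exactly. When the
model extrapolates (e.g. after the inlet O2 enrichment, a condition
absent from the corpus, the forest keeps predicting from demand
covariates and lands on the wrong side of the error), the controller
still moves in the direction the error demands with the model-implied
magnitude. A signed derivation clamped at zero was evaluated first and
deadlocks in exactly that scenario. The upper clamp brackets the
plant's own steady-state sensitivity — from the twin's RQ(N) map,
|dN/dRQ| ≈ 0.55·N ≈ 300–660 rpm per RQ unit over the operating range —
so a near-zero ε cannot be amplified into arbitrarily large moves.

## 5. Performance statistics

Accuracy: `MRE = (1/n)·Σ|y_i − y_sp|/y_sp`. Precision:
`RMSD = sqrt(Σ(y_i − ȳ)²/n)` (population form). Both are computed on
the per-minute soft-sensed RQ trace with undefined-RQ samples dropped;
the evaluation window is configurable (the set-point-band statistic
excludes the first 2 h, during which the controllers are still finding
the initial operating point). Recovery time after a disturbance is the
first instant from which the trace stays inside a band (default
1.3–1.5) for a 10-min dwell — without the dwell a single in-band noise
sample would count as recovery.

## 6. Data reconciliation

The seven specific rates (product formation excluded as negligible for
both balances) are subject to two linear constraints — carbon and
degree-of-reduction closure — built from a packaged per-C-mol
composition table. Measured rates `m` with standard deviations σ are
adjusted by the standard weighted-least-squares projection
`r = m − Σ Aᵀ(A Σ Aᵀ)⁻¹ A m` (Σ = diag σ²), and
`χ² = (A m)ᵀ(A Σ Aᵀ)⁻¹(A m)` is compared with the χ² quantile at the
chosen confidence (default 95%, dof = 2). The projection is idempotent,
reconciled rates close both balances to ~1e-10, and on clean data
perturbed at the configured RSDs (biomass and gas rates 5%, HPLC species
2%) the test rejects ≈5% of datasets — the calibration property checked
at 1000 replicates.

## 7. Study protocol and problem sizes

The benchmark used by the acceptance script and the end-to-end tests:
train the gain model on the 6-run corpus, then per seed run 20-h
closed loops of the three strategies at 1-min sampling (MHC and BLC
undisturbed, as in the original fermentations; AI-APC with the inlet
switch 2.0 L/min air → 1.8 L/min air + 0.2 L/min O2 at t = 13.3 h),
averaged over 5 seeds. This is ~21 simulations of 1200 control steps
each and completes in about half a minute on one CPU; the problem sizes
were chosen to mirror the experimental campaign (20-h fed-batches,
duplicate-scale replication extended to 5 seeds for stable means).

## 8. What the twin does and does not show

The generator reproduces: the monotone RQ–agitation map, exponential
demand growth, gas-side O2 depletion, analyser lag, calibrated
measurement noise, undefined-RQ low-signal behaviour, glucose-uptake
saturation, and exact elemental closure. It does **not** model pH or
temperature excursions, CO2 dissolution/bicarbonate buffering, analyser
drift beyond span/offset, hydrodynamic or viscosity effects on kLa,
foaming, the hypoxia-dependent boost of specific product formation (qP
is purely growth-associated), or biological variability between
replicates beyond measurement noise and seeds. Passing tests therefore
demonstrate the correctness and internal consistency of the control and
analysis chain under the stated model, not performance guarantees on a
physical reactor; on real equipment the gain model would be trained on
plant data and the calibration of `kLa = a·N^b` re-identified.

## 9. Known limitations

* The forest cannot learn the inlet-O2 dependence from a corpus in
  which that variable never moves; after the enrichment step the
  adaptive controller relies on the proportional fallback direction and
  tracks with a visible (~0.05–0.1) RQ offset for a while — consistent
  with the weaker out-of-envelope control reported for the original
  system.
* MRE/RMSD are computed on measured RQ, so they carry the sensor noise
  floor (~1.7% MRE at the default noise); controllers cannot score
  below it.
* The MHC emulation is deliberately simple (deterministic schedule);
  real operator behaviour spans a wide performance range, and the
  emulation sits near the middle of the reported spread.
* Linear reconciliation only; no gross-error localisation beyond the
  global χ² verdict.
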