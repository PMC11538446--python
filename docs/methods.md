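# Methods

This note documents the models, defaults and design choices behind
`capnosvo`: what is being computed, what the synthetic experiment does and
does not emulate, and where the genuinely open decisions were made.

## 1. Gas-exchange arithmetic (`capnosvo.physiology`)

Oxygen content is `C = Hb·k·S + α·PO₂` with Hüfner's capacity
`k = 1.34 ml g⁻¹` and plasma solubility `α = 0.03 ml L⁻¹ mmHg⁻¹` — common
clinical values, both configurable, since published capnodynamic work names
the constants without printing values. Alveolar PO₂ uses the alveolar gas
equation `PAO₂ = FiO₂(Pb − PH₂O) − PaCO₂/RQ` with Pb = 760, PH₂O = 47 mmHg
and RQ = 0.97 (a value measured in a comparable porcine cohort; RQ shifts
the SvO₂ level but not its spread, so a fixed value is the standard
operating assumption).

The dissociation curve is the Severinghaus human-blood formulation
`S = (1 + 23400/(P³+150P))⁻¹`, rescaled along the PO₂ axis to a
configurable P50 (default ≈ 26.9 mmHg; a porcine preset with P50 = 35 mmHg
is provided); a Hill curve (n = 2.7) is available as a fallback. No
temperature/pH Bohr corrections and no dyshemoglobins — out of scope by
design. The inverse curve is closed-form (Cardano), so the
content→saturation inversion — solving `CvO₂ = Hb·k·S + α·PO₂(S)` on
[0, 1] with PO₂ capped at alveolar PO₂ — is implemented as a vectorized
damped fixed-point iteration (the dissolved term is a small contraction);
it converges below 1e−12, and contents at or below zero / at or above the
capacity ceiling clamp to 0 / 1. The clamps are deliberate: the real
method briefly reads zero during hemodynamic collapse, and we preserve
that behavior with quality flags rather than dropping rows.

Blood CO₂ content uses a linearized dissociation relation
`C_CO₂ = 5.0·PCO₂ + 280 ml L⁻¹`, adequate over the 25–80 mmHg range the
estimator operates in; it lives in `PhysioConstants` because the estimator
and the simulator must share it.

## 2. The capnodynamic estimator (`capnosvo.estimator`)

The commercial capnodynamic EPBF equation is not public. This module is a
reconstruction of the standard single-compartment breath-by-breath CO₂
mass balance: over each of the trailing nine breaths (one full
6-normal + 3-pause cycle),

    ELV·(FAₙ − FAₙ₋₁) = EPBF·Δtₙ·(CvCO₂ − CcCO₂(FAₙ)) − VTCO₂ₙ,

linear in the three unknowns (ELV, EPBF, EPBF·CvCO₂) and solved by least
squares, re-estimated at every breath. Both a full refit per breath and a
mode that carries CvCO₂ between windows are provided (default: refit; with
no statement available on which the commercial device uses, refit is the
more conservative choice and the two agree on steady states). Degenerate
windows (no CO₂ signal, singular system, non-positive flow) carry the last
valid EPBF forward with a `degenerate` flag.

VCO₂ is a trailing 20-min moving mean of per-breath elimination
(Σ VTCO₂ / Σ duration); before the window fills the partial-window mean is
used and flagged `vco2_warmup` rather than emitting NaNs. Alveolar PaCO₂
for the alveolar gas equation is taken as `FetCO₂·(Pb − PH₂O)` — end-tidal
gas approximates alveolar gas in this lung model. The displayed output is
additionally smoothed by a 50 s trailing moving mean (`svo2_filt_pct`),
the less-reactive presentation appropriate for unstable phases; both raw
and filtered series are emitted.

Pattern timing: the 6+3 cycle spans 45 s (normal breath ≈ 4.17 s,
expiratory pause 2.5 s — the midpoint of the 2–3 s range used clinically).

## 3. The virtual endotoxemia experiment (`capnosvo.simulate`)

**Hemodynamic truth.** State variables (cardiac output, shunt fraction,
VO₂, Hb) relax first-order (τ = 120 s by default) toward targets that
protocol events move, mostly multiplicatively so paired start/stop events
reverse cleanly. LPS ramps CO toward ×0.66 and shunt toward 0.20 with
τ = 1800 s (an hour-long accelerating deterioration); a stabilization
event then partially restores baseline (τ = 900 s). Intervention
magnitudes: crystalloid bolus Hb ×0.90 and CO ×1.04 (net slight SvO₂
decrease); PEEP reduces the CO target by 1.7%/cmH₂O (venous return);
dobutamine CO ×1.35 and VO₂ ×1.05; norepinephrine CO ×1.08; hemorrhage CO
×0.70 with Hb unchanged (whole-blood loss), reversed by retransfusion.
FiO₂ and PEEP switch instantaneously as ventilator settings.

True SvO₂ is the self-consistent whole-body Fick solution with venous
admixture. Writing EPBF = CO·(1 − shunt), the mixing identities collapse
to `CvO₂ = CcO₂ − VO₂/EPBF`, which is closed-form given the state; every
emitted state satisfies the content balance to float precision (tested to
1e−8), so estimator error can be attributed unambiguously.

Baseline defaults — 31.5 kg animal, CO 3.5 L·min⁻¹, shunt 0.10, Hb
100 g·L⁻¹, VO₂ 180 ml·min⁻¹, PaCO₂ 40 mmHg — are plausible juvenile-pig
values chosen once so that baseline true SvO₂ sits near 60% and the sepsis
nadir near 40%, the directional anchors of this protocol; per-animal
variability jitters baselines (CV 6%) and response magnitudes (CV 15%).
All ten virtual animals complete the full FiO₂ sequence including the 1.0
step (a simplification: in comparable animal work the 1.0 step was a late
protocol addition).

**Breath synthesis.** A single alveolar CO₂ store (ELV = 900 ml) is
perfused by the true EPBF; each breath updates the alveolar fraction
implicitly through the same mass balance the estimator assumes (linear,
closed-form per breath), with alveolar tidal ventilation set so that
steady-state elimination equals VO₂·RQ at the target PaCO₂. Pause breaths
accumulate more CO₂, producing the EPBF-identifying fluctuation. Because
forward model and estimator share the compartment physics, noise-free
recovery is exact; the recovery tests therefore validate the estimator's
identification machinery, not the realism of a richer lung. Features of
real capnography that are *not* emulated: airway dead-space dynamics,
ventilation-perfusion heterogeneity, sensor drift, and cardiogenic
oscillations — so passing tests bound algorithmic error, not device error
on real animals.

**Measurement streams.** Noise is multiplicative (CV-based, matching the
CV-defined precision statistic). CO-oximetry: spot readings,
CV 5.85% — calibrated so that 2×CV of five baseline draws averages ≈ 11%
(the expectation of a 5-sample SD is 0.94σ, hence 0.11/(2·0.94)).
Capno stream: estimator output plus CV 3.2% (→ precision ≈ 6%).
Fiberoptic: first-order lag 45 s, reading CV 3.7% (→ ≈ 7%), and a relative
drift of −8%/h since the last calibration, reset at the initial and
mid-protocol calibrations — emulating the gradual underestimation of
reflectance oximetry between calibrations. Blood-gas hemoglobin reaches
the estimator as a 5-min step function of the true Hb, emulating frequent
gas draws under a goal-directed protocol.

Recording slots follow the protocol cadence: five precision baselines
5 min apart, an induction baseline, sepsis readings every 10 min for one
hour, then pre/post slots bracketing each intervention (~29 slots/animal;
290 paired points for a 10-animal cohort).

## 4. Method comparison (`capnosvo.comparison`)

*Precision* is 2×CV of the five baseline repeats, averaged over animals.
*LSC* is precision × √2 (reported rounded to integer percent; 11% → 16%).
The concordance *exclusion zone* is the reference LSC (relative %) times
the mean baseline reference SvO₂, rounded to integer percentage points,
with a direct override available.

*Bland–Altman corrected for repeated measurements* uses the
multiple-observations-per-individual variant for a varying true value:
one-way variance components of the differences with the unequal-n divisor
`m0 = (N − Σnᵢ²/N)/(I − 1)`, total SD² = between + within, LoA = bias ±
1.96·SD. A negative between-animal component is clamped at zero. CIs are
the standard approximations (bias via t with I−1 df and variance
σ²_b/I + σ²_w/N; LoA via Var(bias) + z²·SD²/(2(N−1))). Single-animal (or
one-pair-per-animal) inputs fall back to simple Bland–Altman with a
warning flag. The concordance CI is a Wilson score interval; other
published intervals for this statistic are not reproducible from their
descriptions, so only the rate itself should be compared across sources.

Exclusion-zone membership tests the *reference* change only — the
conventional reading of four-quadrant methodology.

## 5. Numerical and reporting conventions

Saturations are fractions internally and percentage points (0–100) in all
CSVs and reports. Rates and LSC are reported both unrounded and rounded to
integer percent. All randomness flows from one seed through per-animal
`SeedSequence` spawns; identical seeds reproduce CSV bytes exactly. The
flat `key = value` config file round-trips losslessly and its SHA-256
hash is recorded in every output manifest.

Problem sizes used by the test suite and the acceptance script — 10-animal
cohorts, ~3 900 breaths/animal at 1 Hz state resolution, 600 s steady-state
runs for recovery checks — were chosen as the smallest sizes at which the
statistics stabilize; a full cohort simulates in well under a minute.

## 6. Known limitations

* The EPBF equation is a reconstruction; absolute agreement with the
  proprietary implementation is not claimed, only with the simulator's
  ground truth.
* The simulator's Fick truth and the estimator share the oxygen-content
  arithmetic, so end-to-end tests validate the chain's internal
  consistency plus the measurement model — not ODC mis-specification on
  real blood.
* Desk-scale limits of agreement are narrower than animal data (the noisy
  cohort produces LoA of roughly ±7 points for the capno stream): the
  simulator omits the between-method response-time mismatches and
  biological variability that dominate the spread in vivo.
* The high-SvO₂ mitochondrial-dysfunction sepsis phenotype is outside the
  simulated model, as is the closed-loop rescue protocol (emulated only as
  a fixed stabilization event).
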