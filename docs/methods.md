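# Methods

This note records the model, its assumptions, the parameter choices that
matter, and the numerical decisions — in enough detail that a reader can
judge what the package's results do and do not show.

## Model structure

The whole-body model is a perfusion-limited (flow-limited) PBPK system:
venous blood → lung → arterial blood → twelve parallel tissue compartments
(liver, kidney, muscle, adipose, skin, brain, heart, gut, spleen, bone, a
rest-of-body lumping compartment, and the lung in series). Gut and spleen
drain into the portal vein, so liver inflow is hepatic-arterial plus
portal. For each tissue,

    dA_t/dt = Q_t · (C_art − C_t · B:P / Kp_t),

on a whole-blood concentration basis, with `Kp_t` the tissue:plasma
partition coefficient (times the group Kp scalar) and B:P the
blood:plasma ratio (1.2). Amounts are mg, volumes L, flows L/h, time h.
Plasma concentration — the reporting scale throughout, because the
toxicity threshold and clinical data are plasma-based — is venous blood
concentration divided by B:P.

Elimination:

* **Hepatic (saturable).** Whole-liver capacity is scaled from cytosolic
  kinetics: `Vmax_total = Vmax_invitro · CPPGL · liver_mass · 11 · f_ADH`,
  converted from nmol/min to mg/h. Elimination follows Michaelis–Menten
  kinetics driven by the unbound plasma-equivalent concentration leaving
  the well-stirred liver, `Cu = fu_p · C_liver / Kp_liver`, against
  `Km = 25.1 mM × 76.06 = 1909.1 mg/L`. Km is treated as an unbound
  aqueous value (fu in the cytosol incubation ≈ 1, consistent with
  fu_p = 0.99). No extrahepatic ADH metabolism.
* **Renal (linear).** Adults: a fixed plasma clearance of 3.3 L/h (45% of
  the literature total systemic clearance), scaled per subject by a
  sampled kidney-function multiplier and allometrically by weight^0.75.
  Neonates: filtration only — `rate = GFR · fu_B · C_blood`, with GFR from
  the quadratic polynomial in body surface area
  `GFR = −19.8 + 89.04·BSA − 7.16·BSA²` (mL/min), clamped at zero. The
  polynomial is a local fit to neonatal data; its positive root sits at
  BSA ≈ 0.228 m², essentially on top of the reference term neonate, which
  is why sampled neonatal renal clearances are enormously dispersed (our
  populations show ~160% CV) and some subjects have zero filtration.

Dosing: IV doses default to a 0.5-h zero-order infusion into the venous
pool. The source analyses say only "given intravenously"; bolus vs
infusion changes Cmax and therefore threshold screening, so the duration
is an explicit, configurable default. Oral doses enter a gut-lumen depot
with first-order absorption (ka = 7.56 /h) and fraction fa = 0.99 into the
portal inflow. The state vector carries cumulative metabolized, excreted
and unabsorbed amounts so mass balance is checkable at every output time.

## Key parameters

| parameter | value | note |
|---|---|---|
| MW | 76.06 g/mol | |
| log P | **−0.92** | PG is water-miscible; a positive 0.92 (as sometimes printed) gives adipose Kp ≈ 7 and Vss ≈ 1.9 L/kg, incompatible with the literature 0.80 L/kg |
| fu_p / B:P | 0.99 / 1.2 | fu_B = 0.825 |
| Vmax, Km (cytosol) | 1.57 nmol/min/mg, 25.1 mM | assay: 8 PG levels 0–1000 mM, triplicate, 0.5 mg/mL cytosol, 200 µL, 20 min, 340 nm; ALDH blocked by disulfiram, so NADH formation = PG disappearance (1:1) |
| CPPGL | 80.7 mg/g | standard literature scalar, adults and neonates alike (no maturation data for it); configurable |
| liver tissue scalar | 11 | recovers whole-organ activity per unit enzyme vs the cytosol preparation |
| ADH ontogeny | F_birth 0.18, F_max 1, Age₅₀ 0.9 y, n 1.4 | f(0) = 0.18; adults evaluate to ≈0.994 at age 30 |
| Kp scalar | 1.0 adult / 0.44 neonate | uniform across tissues |
| PLAT | 580 mg/L | plasma level associated with toxicity (osmolar-gap signal) |
| dose grid | 0.75–7500 mg/kg per event | the printed example doses, so threshold statements are evaluable on-grid |

## Reference physiology and variability

Commercial simulators ship proprietary virtual populations; here the
reference physiology is explicit, ICRP-style, and editable YAML
(`src/pgpbpk/data/physiology.yaml`): adult 30 y / 81 kg / 177 cm, cardiac
output 390 L/h, liver 1.80 L (1890 g at 1.05 g/mL); term neonate age 0 /
3.5 kg / 51 cm (WHO median length), CO 36 L/h, liver 130 g. BSA uses the
Haycock formula (valid from neonates to adults with one expression).
Organ volumes scale with weight; flows scale with weight^0.75.

Interindividual variability is lognormal on weight, height, liver size,
CPPGL and (adults) kidney function. The generating CVs are not reported by
typical sources — only output CVs are — so they were calibrated once so the
simulated systemic-clearance CVs bracket the published 28% (adult) / 53%
(neonate): weight 0.15/0.12, height 0.03/0.035, liver 0.25, CPPGL 0.30,
adult renal 0.25. With all CVs zero, sampling returns the reference
subject exactly (a tested contract).

Resulting low-dose behaviour (0.75 mg/kg IV q24h, geometric means over 200
subjects): adult systemic CL ≈ 9.0 L/h (hepatic ≈ 5.5, renal ≈ 3.3),
half-life ≈ 4 h; neonate systemic CL ≈ 0.09 L/h, half-life ≈ 10 h. The
well-stirred closed form `Q_h·fu_B·CLu_int/(Q_h + fu_B·CLu_int)` is used
as an independent cross-check of the ODE's hepatic extraction (agreement
within 5% at low dose), never as the implementation.

A scale caveat: clearances here are plasma-referenced (dose / plasma AUC).
Back-calculated *blood*-scale hepatic clearances (≈4.9 adult, ≈0.064 L/h
neonate) sit 20% lower than the plasma-scale ones; published tables that
mix the two scales will disagree with one or the other. With renal
clearance fixed at 3.3 L/h on plasma, the adult renal mass fraction
computes to ≈38% (hepatic ≈62%) rather than the often-quoted 45/55 split —
that split is only reachable on a blood-referenced hepatic scale.

## Analyses

**Observed clearance.** CL = dose per interval / plasma AUC over the final
dosing interval at steady state (linear trapezoid; the grid is dense, 0.1 h).
Steady state is verified by <1% change in interval AUC between the last
two intervals; heavily saturated doses never reach it and are flagged.
"AUC/dose" phrasing in the source is dimensionally inverted; units force
dose/AUC. Population summaries are geometric means (matching how such
tables report) with arithmetic %CV.

**Saturation onset.** Scans simulate each grid dose to steady state
(run-in 5 days adult, 10 days neonate — ≥5 half-lives) and detect onset
as: linear phase = maximal low-dose prefix of the (dose, CL) points whose
OLS line attains r² ≥ 0.98 (flat data counts as perfectly linear); onset =
first dose beyond that phase, confirmed by >1% absolute deviation from the
phase line. This is one defensible operationalization of "1% deviation
from linearity (r² = 0.98)"; the criterion as printed underdetermines the
rule, and alternatives (deviation from the phase *mean*; deviation below
the line inside the phase) move onsets by one to several grid points. Both
thresholds are configurable, and the detector is verified exactly against
a brute-force reimplementation on synthetic hyperbolic clearance curves.
Note that this model's clearance–dose curves decline smoothly from low
doses (at 800 mg/kg q6h in adults the average plasma level is already
~0.7 × Km), so a strictly literal 1% criterion would place onsets near
50–100 mg/kg — in line with clinical/EMA saturation estimates of
75–200 mg/kg/day, and well below some published model-based thresholds.

**PLAT screening.** A regimen "reaches PLAT" if the steady-state peak of
the population-mean plasma profile is ≥ 580 mg/L. Screening is monotone in
dose at fixed frequency; the daily-dose recommender flags, per candidate
total daily dose and frequency, PLAT exceedance (and saturation if scan
onsets are supplied) and reports the largest candidate safe at all
frequencies.

**Validation workflow.** The synthetic-data module generates sparse noisy
observation sets from the model itself (multiplicative lognormal residual
error — the standard choice for concentration data; default 6 samples per
subject over one interval, emulating opportunistic neonatal sampling). The
2-fold check compares per-subject observed AUC and CL against the
prediction population's geometric means; the VPC check computes coverage
of the predicted 5th–95th percentile band. Model-generated noise-free
observations score 100% on both (a tested identity); a 3-fold clearance
mismatch fails the 2-fold check.

## What the synthetic data does and does not emulate

Plates: true Michaelis–Menten rates through a known linear standard curve
with multiplicative well noise. Not emulated: substrate depletion at low S
over the 20-min incubation, instrument drift, ALDH leakage past
disulfiram, isoform heterogeneity. Observations: model-consistent
kinetics with residual error only. Not emulated: model misspecification,
covariate effects, inducible renal clearance after repeated dosing,
ethanol co-exposure competing for ADH. Passing the round-trip and
self-consistency tests therefore demonstrates internal correctness of the
pipeline, not clinical predictive performance on real data.

## Numerical choices

* Stiff-capable adaptive integration (LSODA), rtol 1e-8, atol 1e-10 mg,
  integrated piecewise between dose events; halving tolerances moves AUC
  by <0.1% (tested). Output grid 0.1 h.
* Mass balance |dosed − (in body + eliminated + unabsorbed)| stays below
  1e-6 of the administered dose in the tests.
* Michaelis–Menten fits: unweighted nonlinear least squares with
  asymptotic t-based 95% CIs from the covariance; a Km collapsing onto the
  boundary (saturated plates) or beyond 10× the top substrate level is
  flagged unreliable. Blank correction subtracts the 0 mM-well rate.
* GFR is clamped at zero below the polynomial's root; negative
  blank-corrected assay rates clip to zero with a warning.
* Degenerate configurations used as oracles: a single-tissue model with
  very large perfusion reproduces the one-compartment closed form
  `C0·exp(−CL·t/V)` to 0.1%.

## Problem sizes

Population summaries use 200 subjects per group (the conventional
simulation size for this kind of analysis); dose scans run on the
reference individual over the 13-dose printed grid at the bounding
frequencies (q6h, q24h); the noisy in-vitro recovery uses 100 seeded
plates. The acceptance script completes in about two minutes on one core.

## Known limitations

* Perfusion-limited tissues only; no permeability-limited liver, no
  enterohepatic recirculation, no transporter or metabolite
  (lactaldehyde/lactate) disposition, no osmolar-gap pharmacodynamics.
* No preterm neonates or intermediate pediatric ages; ontogeny is
  evaluated, not validated, between those anchors.
* No ethanol–PG excipient–excipient interaction, although formulations
  often contain both and they compete for ADH.
* The neonatal renal model is pure glomerular filtration; tubular
  processes and postnatal maturation within the first weeks are not
  represented.
* The saturation-onset dose is detector-dependent (see above); the
  clearance curves themselves are the robust output.
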