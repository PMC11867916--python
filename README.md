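# pgpbpk

Physiologically based pharmacokinetic (PBPK) modelling of **propylene
glycol (PG)** — a ubiquitous pharmaceutical excipient with GRAS status but
well-documented concentration-dependent toxicity — in **adults and term
neonates**.

PG is cleared roughly half by hepatic alcohol dehydrogenase (ADH) and half
renally in adults. Both routes are compromised in neonates: ADH activity at
birth is ~18% of the adult level and glomerular filtration is barely
developed, so PG accumulates (half-life 10–31 h vs 2–5 h in adults) and the
saturable ADH pathway can tip from first- to zero-order kinetics at
clinically used doses. This package implements the whole chain needed to
study that problem quantitatively, for pharmacometricians and clinical
pharmacologists:

* **In-vitro kinetics** — NADH-coupled plate-assay processing and
  Michaelis–Menten fitting (v = V·S/(Kₘ+S)); the shipped defaults are
  Vmax = 1.57 nmol/min/mg cytosolic protein, Kₘ = 25.1 mM.
* **IVIVE** — whole-liver capacity
  Vmax,total = Vmax · CPPGL · liver mass · tissue scalar · f_ADH(age), with
  hepatic elimination driven by the unbound plasma-equivalent concentration
  leaving a well-stirred liver.
* **Ontogeny** — sigmoid ADH maturation
  f(age) = F_birth + (F_max−F_birth)·ageⁿ/(Age₅₀ⁿ+ageⁿ) and a quadratic
  GFR(BSA) polynomial for neonatal renal function (clamped at zero).
* **Distribution** — tissue:plasma partition coefficients for a neutral
  solute from tissue composition (neutral lipid / phospholipid / water,
  oil:water surrogate partitioning), with a uniform neonatal Kp scalar 0.44.
* **Virtual populations** — documented reference adults (81 kg) and term
  neonates (3.5 kg) with lognormal interindividual variability.
* **Whole-body ODE engine** — 12 perfusion-limited tissues, lung in series,
  portal drainage into the liver, IV infusion/bolus and first-order oral
  dosing, mass balance asserted at every output time.
* **Analyses** — non-compartmental "observed" clearance (dose/AUC),
  dose-vs-clearance saturation scans with an onset detector
  (linear phase at r² ≥ 0.98, >1% deviation from linearity), and screening
  of regimens against the plasma level associated with toxicity
  (PLAT = 580 mg/L, the exposure linked to an increased osmolar gap).

## Worked example

```python
from pgpbpk import (DoseRegimen, reference_subject, screen_plat,
                    simulate, subject_model)
from pgpbpk.nca import steady_state_metrics
from pgpbpk.saturation import steady_state_duration

neo = reference_subject("term_neonate")
model = subject_model(neo)

reg = DoseRegimen(route="iv_infusion", dose_per_event=0.75, interval=24.0,
                  n_doses=11)
res = simulate(model, reg, duration=11 * 24.0 + 48.0)
nca = steady_state_metrics(res, reg, dose_mg=0.75 * neo.weight)
print(f"neonate systemic CL = {nca.cl_observed:.4f} L/h, t1/2 = {nca.t_half:.1f} h")

for tau in (24.0, 6.0):
    n, _ = steady_state_duration("term_neonate", tau)
    screen = screen_plat([neo], DoseRegimen(route="iv_infusion",
                         dose_per_event=100.0, interval=tau, n_doses=n))
    print(f"100 mg/kg q{tau:.0f}h: steady-state Cmax = {screen.max_ss_conc:.0f} mg/L"
          f" -> {'reaches' if screen.exceeds else 'below'} PLAT (580 mg/L)")
```

prints

```
neonate systemic CL = 0.0765 L/h, t1/2 = 10.1 h
100 mg/kg q24h: steady-state Cmax = 417 mg/L -> below PLAT (580 mg/L)
100 mg/kg q6h: steady-state Cmax = 1413 mg/L -> reaches PLAT (580 mg/L)
```

The reference neonate clears PG at ~0.08 L/h — roughly a hundredfold below
the adult ~9 L/h — and the same 100 mg/kg dose that is safe once daily
accumulates past the toxicity threshold when given 6-hourly: toxicity is a
property of the *regimen*, not the dose alone.

The same stages are scriptable from the shell:

```bash
pgpbpk simulate --config examples/neonate.yaml --out out/profile.csv
pgpbpk scan --group term_neonate --interval 6 --out out/
pgpbpk screen --group adult --daily-dose 200 --out out/
pgpbpk report --n-subjects 50 --out out/
```

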