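# hdlturnover

Tracer-kinetic analysis of HDL cholesteryl-ester (CE) turnover in plasma,
built for two-group animal studies (e.g. sham-operated vs. partially
nephrectomized rabbits): compartmental modeling of radiolabeled CE decay,
fractional catabolic rate (FCR) and production rate (PR) estimation,
CE mass-flux accounting, HDL-subclass quantification from gradient-gel
densitograms, and exact nonparametric group comparison at small n.

## The model

After an intravenous bolus of HDL-[³H]-CE, plasma radioactivity is followed
in two pools — HDL (compartment 1, where the label enters) and VLDL/LDL
(compartment 2) — over eleven samples between 5 and 300 min, normalized so
the 5-min draw reads 100% (HDL) and 0% (VLDL/LDL).  Four first-order
transfer coefficients (min⁻¹) connect the pools:

    dq₁/dt = −(K(1,0) + K(1,2))·q₁ + K(2,1)·q₂        q₁(0) = 100
    dq₂/dt =   K(1,2)·q₁ − (K(2,1) + K(2,0))·q₂        q₂(0) = 0

where K(1,2) is CE transfer HDL → VLDL/LDL, K(2,1) the return transfer,
and K(1,0), K(2,0) irreversible removal from each pool.  The package
provides the analytic solution (`solve_model`), two FCR estimators —
a constrained biexponential fit `y(t) = 100(Ae^{−αt} + Be^{−βt})`, A+B=1,
with FCR = 60/(A/α + B/β) h⁻¹ (reciprocal area under the normalized
fraction-remaining curve), and a full two-pool fit whose closed-form FCR
is `60·[K(1,0) + K(1,2)K(2,0)/(K(2,1)+K(2,0))]` — plus:

* **PR** = FCR × CE concentration (mg/L) × plasma volume (0.0328 L/kg ×
  body weight) / body weight, in mg·kg⁻¹·h⁻¹;
* **mass fluxes** = rate constant × source-pool CE concentration
  (μmol·L⁻¹·min⁻¹), with total outflow = K(1,0)- plus K(2,0)-flux;
* **HDL subclasses** 2b/2a/3a/3b/3c as percent AUC of the stained-gel
  densitogram over the diameter windows 10.58–13.59 / 9.94–10.58 /
  8.98–9.94 / 8.45–8.98 / 7.94–8.45 nm (marker-protein calibration,
  log-diameter linear in migration distance);
* **group statistics**: median (IQR) summaries and the exact two-sided
  Mann–Whitney U test (full enumeration for tie-free groups up to n = 10).

A seeded synthetic-cohort generator emulates the full study design
(log-normal between-animal spread matched to published median/IQR targets,
3% proportional counting noise, five-Gaussian densitograms), so the whole
pipeline is testable without any data download.

## Worked example

```python
import hdlturnover as h

rates = h.KineticRateSet(k_hdl_to_vldl=0.002, k_vldl_to_hdl=0.002,
                         k_hdl_out=0.003, k_vldl_out=0.002)   # min^-1
curve = h.solve_model(rates, h.SHIFTED_TIMES_MIN)             # noiseless decay
params, report = h.fit_biexponential(curve, seed=0)
print(h.fcr_from_biexponential(params))   # 0.240 h^-1
print(h.fcr_closed_form(rates))           # 0.240 h^-1 (same, by construction)

print(h.production_rate(0.24, 698.7, body_weight_kg=3.2))   # 5.50 mg/kg/h

fluxes = h.mass_fluxes(h.KineticRateSet(0, 0, 0.02, 0.01),
                       h.PoolConcentrations(hdl_ce=590, vldl_ce=341))
print(fluxes.total_outflow)               # 15.21 umol/L/min
```

The fitted biexponential for this sham-like rate set is A = 0.621,
α = 0.00656 min⁻¹, B = 0.379, β = 0.00244 min⁻¹; both FCR routes agree at
0.240 h⁻¹ because the model's HDL curve is exactly biexponential and the
closed form is the reciprocal of its area.  A full synthetic 6-vs-6 run:

```python
bundle = h.run_pipeline(h.RunConfig(seed=11, synthetic=True))
print(bundle.markdown)
```

prints the group-comparison table, e.g.

```
| Variable | Sham | Ntx | U | p |
| --- | --- | --- | --- | --- |
| fcr_biexp_per_h | 0.19 (0.15-0.35) | 0.14 (0.13-0.19) | 11 | 0.3095 |
| fcr_compartmental_per_h | 0.17 (0.14-0.30) | 0.13 (0.13-0.19) | 12 | 0.3939 |
...
```

each cell being the group median (interquartile range) of the per-animal
estimates, `U` and `p` the exact Mann–Whitney statistics, and `*` marking
p < 0.05.  The same pipeline runs from CSV inputs (time-activity curves,
lipid panels, densitograms, marker calibration) via the `hdlturnover`
command line: `simulate-cohort`, `fit`, `fluxes`, `subclasses`, `report`,
all driven by a YAML config.

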