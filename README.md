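# nanopartchar

Standardized particle characterization for food-grade titanium dioxide
(E171) and similar particulate additives. The package implements, as
tested and reusable code, the computational side of a combined
TEM + single-particle ICP-MS characterization workflow:

- **spICP-MS processing** (`nanopartchar.spicpms`): time-resolved
  counts-per-dwell traces are separated into baseline and particle events by
  an iterative mean + 5σ discrimination; net event counts are converted
  through an ionic calibration and the transport efficiency into analyte
  mass per particle, then into an **equivalent spherical diameter** (ESD)
  via `d = (6m / πρ)^{1/3}`; event counts and masses over the effectively
  analyzed volume `V_eff = η·q·t` give number and mass concentrations;
  background statistics give size detection/quantification limits. The
  transport efficiency η is calibrated by the particle-frequency method with
  monodisperse reference particles (e.g. 30 nm gold at 12.5 ng/L).
- **TEM particle sizing** (`nanopartchar.tem_sizing`): minimum/maximum
  Feret (caliper) diameters by rotating calipers on the convex hull,
  moments-equivalent ellipse fitting and watershed splitting of touching
  particles for image input, ISO 9276-style number-weighted distribution
  summaries (median, quartiles, KDE mode), quantification-window gating
  (LLOQ = 10 × pixel size, ULOQ = field width / 10), and the EC
  nanomaterial classification (median Fmin < 100 nm, with or without the
  expanded measurement uncertainty).
- **Metrology** (`nanopartchar.metrology`): one-way ANOVA decomposition of a
  day × replicate precision study into repeatability (s_r) and between-day
  (s_d) relative SDs, and the combined standard uncertainty of a routine
  result `u_c = sqrt(s_r²/n_rep + s_d²/n_days + u_Δ²)` with expansion
  `U = k·u_c` (k = 2).
- **Protocol design** (`nanopartchar.protocol_design`): Stokes-law
  centrifugal sedimentation calculator
  `v = Δρ·g_eff·d²/(18η)` for dimensioning centrifugation steps, plus the
  six standard sample-preparation presets P1–P6.
- **Synthetic ground truth** (`nanopartchar.synth`): seeded generators for
  spICP-MS traces (Poisson baseline + lognormal particle populations),
  rasterized particle images, and precision tables, each with an exact truth
  table for estimator validation.

## Worked example

Simulate a 2-minute trace of a 90 nm-median TiO₂ population in the
single-particle regime and run the full pipeline:

```python
from nanopartchar import spicpms as sp, synth

acq = sp.AcquisitionConfig(duration=120.0)           # 0.47 mL/min, η=4.8%, 3 ms dwell
pop = synth.PopulationSpec(size_median=90.0)         # lognormal, GSD 1.3, 2.5e7 /L
trace, truth = synth.simulate_trace(pop, synth.TraceSimConfig(seed=1, acquisition=acq))

w_unit = acq.transport_efficiency * (acq.flow_rate / 60) * acq.dwell_time * 1e6
cal = sp.fit_ionic_calibration([(0.0, 0.0), (1.0, 200.0 * w_unit)])
result = sp.summarize_spicpms(trace, cal, acq)
print(result.n_events, round(result.median_esd_nm, 1), round(result.size_lod_nm, 1))
```

This prints `1102 89.1 24.7`: 1102 detected events (of 1139 injected), a
recovered median ESD of 89.1 nm against the true 90 nm, and a 24.7 nm size
detection limit from the 4-count intensity floor at this sensitivity.
The analysis drivers under `analysis/` (numbered in workflow order) run the
same machinery over the published study inputs — the Stokes sedimentation
table, the imaging quantification windows, the synthetic recovery study,
the 15-material EC classification (12 nanomaterials, 11 significantly below
100 nm), and the three uncertainty budgets — writing their tables under
`results/`.

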