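# ecoforcing

Multiscale warming/cooling diagnostics for nutrient-manipulation
experiments observed with paired eddy-covariance and radiometric towers.

Nitrogen (and phosphorus) addition changes a grassland–savanna surface
gradually: the vegetation gets slightly brighter (higher albedo α), takes
up a little more CO₂ (more negative NEE), and repartitions its energy
budget between latent (LE), sensible (H) and soil (G) heat. `ecoforcing`
quantifies what those non-abrupt changes do to climate at two scales:

* **Globally**, as top-of-atmosphere radiative forcing per m² of treated
  surface. The albedo term propagates the monthly treated-minus-control
  albedo difference through an ensemble of albedo radiative kernels,
  RF_Δα = −K̄αs · Δα · A_site / A_Earth. The CO₂ term converts the
  cumulative NEE difference into a global mole-fraction perturbation,
  Δχ_CO₂ = β · ΔNEE_cum · A_site · (M_a/M_c) / m_a (airborne fraction
  β = 0.44, atmospheric mass m_a = 5.15×10²¹ g), and then into forcing,
  RF_ΔNEE = 5.35 · Δχ/χ₀ with χ₀ = 399.4 ppm. Both are reported in
  10⁻¹⁴ W m⁻² (global) m⁻² (surface); a GWP hook converts the albedo
  forcing into a sustained CO₂-equivalent emission (kg CO₂e ha⁻¹ yr⁻¹).
* **Locally**, as surface-temperature change. Ts is retrieved from
  outgoing longwave via LWUR = σ ε Ts⁴ with ε = −0.16 α + 0.99, and the
  daily treated-minus-control ΔTs is decomposed by a first-order Taylor
  expansion of the surface energy budget into contributions (in °C) from
  Δα, ΔSWDR, ΔLWDR, ΔLE, ΔH, ΔG, the residual imbalance ΔI and Δε, all
  divided by 4 σ ε Ts³.
* **Mechanistically**, via daily water-use efficiency, evaporative
  fraction, bulk aerodynamic conductance Ga = [u/u*² + 6.2 u*^(−2/3)]⁻¹,
  Penman–Monteith-inverted surface conductance Gs, and the
  Jarvis–McNaughton decoupling coefficient Ω — and by ranking which
  decomposition components track ΔTs in time using dynamic time warping,
  with seasonal between-site ANOVA/Kruskal–Wallis tests.

The package targets two observation layers per site — the whole
tree–grass ecosystem (15 m towers) and the grass understory (1.6 m) —
for a control (CT), an N-added (NT) and an N+P-added (NPT) site. A
first-class synthetic generator emulates the three co-located sites with
known injected treatment effects, so every stage of the pipeline can be
validated by parameter recovery.

## Worked example

```python
import ecoforcing as ef
from ecoforcing import radiative_forcing as rf

scenario = ef.ScenarioSpec(seed=1)            # 2 years, 3 sites, 2 layers
records = ef.generate_halfhourly(scenario)    # half-hourly tower records
calendar = ef.synthetic_towers.calendar_for(scenario)
kernels = rf.synthetic_kernel_ensemble()      # 4-member kernel climatology

results = ef.run_pipeline(records, ef.AnalysisConfig(), calendar, kernels)

t = results["monthly_rf"]
nt = t[(t.site_pair == "NT-CT") & (t.layer == "ecosystem")]
print("mean RF_dalpha :", round(nt["rf_delta_alpha"].mean(), 3))
print("final RF_dNEE  :", round(nt["rf_delta_nee_cum"].iloc[-1], 3))
d = results["decomposition_daily"]
sel = d[(d.site_pair == "NT-CT") & (d.layer == "ecosystem") & d.kept]
print("mean dTs_obs   :", round(sel["dTs_obs"].mean(), 2), "degC")
```

prints

```
mean RF_dalpha : -0.333
final RF_dNEE  : -0.041
mean dTs_obs   : -0.41 degC
```

i.e. for the N-added site the ecosystem-scale brightening of +0.015
albedo units produces a mean monthly cooling of −0.33 ×10⁻¹⁴ W m⁻² m⁻²
at the top of the atmosphere, the extra CO₂ uptake adds a small
cumulative cooling, and the surface itself is 0.41 °C cooler than
control — the injected effect the generator planted, recovered by the
full chain of filtering, retrieval and decomposition.

The same pipeline is scriptable from a shell:

```
ecoforcing synth --out towers/
ecoforcing run --towers towers/ --out outdir/
```

which writes `daily_albedo.csv`, `day_flags.csv`, `monthly_rf.csv`,
`decomposition_daily.csv`, `ecophys_daily.csv`, `dtw_report.csv`,
`seasonal_tests.csv` and `closure.csv`.

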