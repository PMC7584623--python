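# floatbloom

Phytoplankton biomass cycles, bloom phenology and division-rate sensitivity from
BGC-Argo-style profiling-float data.

## The problem

Seasonal phytoplankton blooms are usually explained "bottom-up": more light and
nutrients, faster cell division, more biomass. But the net biomass-specific rate of
change is always a balance,

    r = (1/P) dP/dt = mu - l,

between the division rate mu and the summed loss rate l (grazing, viruses,
sinking). In the Southern Ocean, in situ float records show blooms *starting* in
late winter while mu is still near its minimum — intelligible only if losses track
growth with a short time lag, so that r follows d(mu)/dt rather than mu itself
(the disturbance-recovery view of blooms). `floatbloom` implements the full
analysis chain that extracts this signal from vertical float profiles:

* **biomass** — particulate backscatter to carbon: `POC = 3.12e4 * bbp(700) + 3.0`
  (mg m⁻³), `C_phyto = 0.19 * POC`, with a 900–2000 m deep-offset correction and
  negative screening;
* **growth** — a carbon-based productivity model (CbPM):
  `mu(z) = mu_max * NSI(z) * LSI(z)` with the nutrient saturation index read from
  the Chl:C ratio, `LSI(z) = 1 - exp(-5 PAR(z))`, and scalar PAR attenuated by a
  chlorophyll-dependent Kd;
* **rates** — the switching centered-difference for r: concentration-based during
  mixed-layer shoaling, inventory-based during deepening, so dilution and
  detrainment contribute exactly zero;
* **phenology** — bloom initiation/termination as sign changes of the r
  climatology, the autumn r-minimum, summer-minus-winter bloom magnitude, and
  Southern Ocean zone bookkeeping (STZ/SAZ/PAZ/SIZ, under-ice weeks);
* **sensitivity** — the climatology-perturbation experiment: losses modeled as mu
  lagged by a fitted number of days, seasonal mu contrast damped by 10–60%, biomass
  re-integrated and bloom magnitude / NPP responses tabulated;
* **synthetic** — a float-array generator (Argo vertical grid, 5/10-day cadence,
  seasonal mixed layer and light, lagged-loss ecology, entrainment dilution,
  under-ice gaps, optical noise) whose construction contracts make every stage
  testable without downloading anything.

Readers for flat-CSV and Argo-like NetCDF profile dialects, same-day nearest-pixel
PAR matchups and 500-km/same-month dissolved-iron matchups, and a thin `floatbloom`
CLI round out the pipeline.

## Worked example

```python
from floatbloom import phenology, pipeline, synthetic

cfg = synthetic.TruthConfig(n_floats=6, n_years=2, seed=12)
truth = synthetic.simulate_truth(cfg)
profiles = synthetic.emit_float_profiles(truth, cfg)
derived, rate_series, clim = pipeline.run_pipeline(profiles)

events = phenology.detect_bloom_events(clim["r"])
print(events.bi_day, events.bt_day, events.rm_day)
```

Running `python examples/bloom_phenology.py` (the same computation with reporting)
prints:

```
438 casts from 6 floats over 2 years
r observations: 432 (49% concentration branch)
bloom initiation  (BI): day 168
bloom termination (BT): day 67
r minimum         (rM): day 130
blooming days per year: 265
bloom magnitude: 9.7 mg C m-3 (summer minus winter mixed-layer biomass)
```

Bloom initiation on day 168 is mid-June — austral winter, near the division-rate
minimum and months before the mu maximum — while the bloom terminates (day 67,
early March) with division rates still high: the hallmark of loss rates lagging
growth. The other scripts in `examples/` walk each capability separately
(backscatter-to-carbon, the CbPM, the switching rule, matchups, the perturbation
sweep).

The `floatbloom` CLI chains the same stages from a shell:

```bash
floatbloom --out-dir run simulate
floatbloom --out-dir run process --profiles run/profiles.csv --par run/par.nc
floatbloom --out-dir run climatology --derived run/derived.csv --rates run/rates.csv
floatbloom --out-dir run phenology --climatology run/climatology.csv
floatbloom --out-dir run sensitivity --climatology run/climatology.csv
```

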