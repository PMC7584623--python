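"""Bloom phenology of a synthetic Southern Ocean float array.

Runs the full pipeline (simulate -> process -> rates -> climatology), detects
bloom initiation/termination and the autumn r-minimum, and reports the bloom
magnitude (summer-minus-winter mixed-layer biomass).
"""

import numpy as np

from floatbloom import phenology, pipeline, synthetic

cfg = synthetic.TruthConfig(n_floats=6, n_years=2, seed=12)
truth = synthetic.simulate_truth(cfg)
profiles = synthetic.emit_float_profiles(truth, cfg)
derived, rate_series, clim = pipeline.run_pipeline(profiles)

events = phenology.detect_bloom_events(clim["r"])
doy = derived.cast_time.dt.dayofyear.to_numpy()
magnitude = phenology.bloom_magnitude(doy, derived.pbar.to_numpy())

print(f"{len(profiles)} casts from {cfg.n_floats} floats over {cfg.n_years} years")
print(f"r observations: {len(rate_series)} "
      f"({(rate_series.branch == 'concentration').mean():.0%} concentration branch)")
print(f"bloom initiation  (BI): day {events.bi_day}")
print(f"bloom termination (BT): day {events.bt_day}")
print(f"r minimum         (rM): day {events.rm_day}")
print(f"blooming days per year: {int(np.sum(events.blooming_mask))}")
print(f"bloom magnitude: {magnitude:.1f} mg C m-3 (summer minus winter mixed-layer biomass)")
print()
print("Initiation lands in austral winter near the division-rate minimum - biomass")
print("starts accumulating while growth conditions are still poor, because losses")
print("lag growth; that is the disturbance-recovery signature the r cycle encodes.")
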