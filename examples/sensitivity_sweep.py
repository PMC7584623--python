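"""Perturb the seasonal division-rate cycle and watch the bloom respond.

Fits the loss lag (losses = division rates delayed a few days), damps the
seasonal mu contrast by 0-60%, re-integrates the biomass cycle and reports the
response of bloom magnitude and annual NPP.
"""

from floatbloom import pipeline, sensitivity, synthetic

cfg = synthetic.TruthConfig(n_floats=6, n_years=2, seed=12)
truth = synthetic.simulate_truth(cfg)
profiles = synthetic.emit_float_profiles(truth, cfg)
_, _, clim = pipeline.run_pipeline(profiles)

lag, table = sensitivity.fit_loss_lag(clim["mu"], clim["r"])
print("loss-lag fit (RMSE of r = mu(t) - mu(t-L) against the observed r cycle):")
for _, row in table.iterrows():
    marker = "  <- best" if row.lag_days == lag else ""
    print(f"  L = {int(row.lag_days):2d} d   rmse = {row.rmse:.2e}{marker}")

results, response = sensitivity.run_sensitivity_sweep(clim, loss_lag=lag)
print("\nperturbation sweep (s damps the seasonal mu contrast):")
print(response.to_string(index=False, float_format=lambda v: f"{v:10.2f}"))
print()
print("Bloom magnitude shrinks steadily with s: damping the seasonal growth contrast")
print("flattens the biomass cycle. The annual NPP column moves the other way here -")
print("the lagged-loss model pins biomass to the local division rate, so a damped")
print("cycle lifts winter biomass under a deep winter mixed layer (see docs/methods.md).")
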