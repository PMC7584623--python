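"""Diagnose a division-rate profile with the carbon-based productivity model.

mu(z) = mu_max * NSI(z) * LSI(z): nutrient stress read from the Chl:C ratio,
light limitation from PAR attenuated through the chlorophyll profile.
"""

import numpy as np

from floatbloom import growth, pipeline, synthetic

cfg = synthetic.TruthConfig(n_floats=1, n_years=1, seed=3)
truth = synthetic.simulate_truth(cfg)
casts = synthetic.emit_float_profiles(truth, cfg)

summer, winter = casts[0], casts[18]  # January vs mid-year cast
for cast in (summer, winter):
    d = pipeline.process_cast(cast)
    print(f"{cast.cast_time.date()}  MLD {d.mld:6.1f} m  surface PAR {cast.par0:5.1f} E m-2 d-1")
    print(f"  mixed-layer mean PAR {d.par_ml:6.2f} E m-2 d-1  -> LSI {d.lsi_ml:.3f}")
    print(f"  nutrient saturation NSI {d.nsi_ml:.3f}")
    print(f"  division rate mu {d.mu_ml:.3f} d-1   NPP {d.npp:.0f} mg C m-2 d-1")

kd = growth.attenuation_from_chl(np.array([0.0, 0.25, 1.0]))
print()
print("Kd(chl=0, 0.25, 1.0 mg m-3) =", np.round(kd, 4), "m-1")
print("The light saturation index saturates above roughly 1 E m-2 d-1, so at these")
print("latitudes the seasonal mu contrast is carried mostly by the Chl:C-diagnosed")
print("nutrient term; LSI takes over only in very deep, dark winter mixed layers")
print("(seasonal-ice-zone conditions).")
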