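"""Noiseless phantom round trip: build ground truth, synthesise complex
signals, phase-correct, fit DKI by WLS and check that the global scalar
metrics come back at the construction targets.
"""

import numpy as np

from cardiodki import build_protocol, fit_image
from cardiodki.metrics import scalar_maps_from_fit
from cardiodki.phantom import PhantomSpec, build_ground_truth, synthesize_series
from cardiodki.preprocessing import phase_correct_real

spec = PhantomSpec(snr_at_b100=None)   # noiseless
scheme = build_protocol(30, 6, seed=1)
truth = build_ground_truth(spec)
series = synthesize_series(truth, scheme, spec)
real = phase_correct_real(series)

fit = fit_image(real.data, scheme, real.mask, model="dki")
maps = scalar_maps_from_fit(fit)
m = real.mask

def lv(v):
    vv = v[m]
    return np.mean(vv[np.isfinite(vv)])

print(f"LV mask: {m.sum()} voxels over {spec.n_slices} short-axis slices")
print(f"          target   recovered")
print(f"MD (e-3)   {spec.target_md*1e3:.2f}      {lv(maps.md)*1e3:.4f}")
print(f"FA         {spec.target_fa:.2f}      {lv(maps.fa):.4f}")
print(f"MK         {spec.target_mk:.2f}      {lv(maps.mk):.4f}")
print(f"AK         {spec.target_ak:.2f}      {lv(maps.ak):.4f}")
print(f"RK         {spec.target_rk:.2f}      {lv(maps.rk):.4f}")
print("\nNoiseless recovery is exact to fitting precision: the linear WLS "
      "estimator inverts the forward model it was built from.")
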