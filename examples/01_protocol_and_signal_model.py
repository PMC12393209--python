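"""Build the 5-shell cardiac DKI protocol and evaluate the forward model.

Prints the shell table and the predicted signal decay of a myocardium-like
voxel along one encoding direction, showing the kurtosis-driven deviation
from mono-exponential decay at high b-values.
"""

import numpy as np

from cardiodki import build_protocol
from cardiodki.model import (DiffusionTensor, KurtosisTensor,
                             VoxelSignalModel, predict_signal)
from cardiodki.acquisition import AcquisitionScheme

scheme = build_protocol(directions_per_shell=30, repeats=6, seed=1)
print(f"protocol: {len(scheme)} measurements")
for b in np.unique(scheme.bvals):
    sel = scheme.bvals == b
    ndir = len(np.unique(np.round(scheme.bvecs[sel], 6), axis=0))
    print(f"  b = {b:6.0f} s/mm^2: {ndir:2d} directions x "
          f"{sel.sum() // ndir} repeats")

# isotropic voxel with the study's global MD and MK
D = DiffusionTensor(np.eye(3) * 1.66e-3)
w = np.zeros(15)
w[:3] = 0.32
w[9:12] = 0.32 / 3.0
model = VoxelSignalModel(1.0, D, KurtosisTensor(w))

bvals = np.array([0.0, 100.0, 450.0, 900.0, 1200.0, 1350.0])
n = np.array([0.0, 0.0, 1.0])
one_dir = AcquisitionScheme(bvals, np.tile(n, (len(bvals), 1)),
                            np.arange(len(bvals)), np.zeros(len(bvals), int))
s = predict_signal(model, one_dir)
mono = np.exp(-bvals * 1.66e-3)
print("\n   b     S/S0 (DKI)   mono-exponential")
for b, sk, sm in zip(bvals, s, mono):
    print(f"{b:6.0f}   {sk:10.5f}   {sm:10.5f}")
print("\nThe DKI signal sits above the mono-exponential curve at high b "
      "(positive kurtosis = slower decay); at b=1350 the gap is "
      f"{100 * (s[-1] - mono[-1]) / mono[-1]:.0f}%.")
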