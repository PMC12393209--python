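"""DTI fits to b-value pairs {100, bmax}: the fitted mean diffusivity
declines as bmax grows because the (positive-kurtosis) signal decays slower
than mono-exponentially, while a full DKI fit keeps MD stable.
"""

from cardiodki import build_protocol
from cardiodki.phantom import PhantomSpec, build_ground_truth, synthesize_series
from cardiodki.preprocessing import phase_correct_real
from cardiodki.study import run_bmax_subset_analysis, run_dti_dki_subset_comparison

spec = PhantomSpec(snr_at_b100=None)
scheme = build_protocol(30, 6, seed=1)
truth = build_ground_truth(spec)
real = phase_correct_real(synthesize_series(truth, scheme, spec))

tab = run_bmax_subset_analysis(real)
print("DTI subset fits (noiseless phantom):")
print(tab[["bmax", "md_mean_e3", "fa_mean"]].round(4).to_string(index=False))
print("\nMD falls from ~1.58 to ~1.44 x1e-3 mm^2/s as bmax goes 450 -> 1350,"
      "\nthe two-point slope D - ((b1+b2)/6) D^2 K in closed form.")

tab2 = run_dti_dki_subset_comparison(real, n_dirs_mk=2000)
print("\nDTI vs DKI on growing b-value sets:")
cols = ["subset", "model", "md_mean_e3", "fa_mean", "mk_mean"]
print(tab2[cols].round(4).to_string(index=False))
print("\nDKI-estimated MD is identical across the sets (the kurtosis term "
      "absorbs the curvature); DTI-estimated MD keeps dropping.")
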