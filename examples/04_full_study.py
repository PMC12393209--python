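"""Simulate a 10-subject synthetic cohort at the study SNR ladder and print
the group table: MD/FA/MK/AK/RK means, the RK-AK contrast with its exact
Wilcoxon signed-rank p-value, and the E2A summary.

Runtime: about a minute on one CPU.
"""

from cardiodki.study import StudyConfig, run_full_study

report = run_full_study(StudyConfig(seed=1))

print("per-subject global means:")
cols = ["subject", "md_mean_e3", "fa_mean", "mk_mean", "ak_mean", "rk_mean",
        "rk_minus_ak"]
print(report["subjects"][cols].round(4).to_string(index=False))

g = report["group"]
print("\ngroup summary (mean +- SD over 10 subjects):")
for label, key in (("MD (e-3 mm^2/s)", "md_mean_e3"), ("FA", "fa_mean"),
                   ("MK", "mk_mean"), ("AK", "ak_mean"), ("RK", "rk_mean")):
    print(f"  {label:16s} {g[key]['mean']:.3f} +- {g[key]['sd']:.3f}")

rka = report["rk_vs_ak"]
print(f"\nRK - AK = {rka['mean']:.3f} +- {rka['sd']:.3f}, "
      f"Wilcoxon p = {rka['wilcoxon']['p']:.4g} ({rka['wilcoxon']['method']})")
print(f"E2A median of medians: {report['e2a']['median_of_medians']:.1f} deg "
      "(ground truth 0: the phantom models no sheetlet tilt)")
print("\nRadial kurtosis exceeds axial kurtosis because cross-myocyte "
      "restrictions dominate; the paired contrast survives the study noise.")
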