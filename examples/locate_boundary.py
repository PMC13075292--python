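"""Localize a migrating boundary in a timed synthetic scan series.

Generates a four-scan experiment (first scan at 7 min, then every 2 min) for
a 10 mM sample, runs the signal chain (baseline subtraction, moving-average
filter, trough localization) and fits the boundary velocity V_MRB.
"""

from mrbscan import ExperimentConfig, fit_velocity, fixes_from_scan_series, generate_experiment

cfg = ExperimentConfig(concentrations_mM=(10.0,), seed=1)
exp = generate_experiment(cfg)

fixes = fixes_from_scan_series(
    exp.traces[10.0], exp.baseline, method="trough", filter_window=251
)
print("scan clock (min)   boundary fix (mm)   true position (mm)")
for fix, truth in zip(fixes, exp.truth.positions_mm[10.0]):
    print(f"{fix.clock_min:14.2f}   {fix.x_boundary_mm:15.2f}   {truth:16.2f}")

est = fit_velocity(fixes)
true_u = exp.truth.velocities_mm_min[10.0]
print(f"\nfitted V_MRB = {est.v_mrb:.4f} mm/min (r2 = {est.r2:.5f}); "
      f"true U = {true_u:.4f} mm/min")
print("the fixes carry a constant geometric offset from the true boundary, "
      "which cancels in the velocity (the quantitative signal).")
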