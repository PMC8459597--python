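"""Calibrate a cantilever: thermal spring constant + glass-curve sensitivity.

The spring constant comes from equipartition on a thermal deflection
series; the deflection sensitivity from the contact slope of an approach
curve on glass, where piezo travel equals cantilever deflection.
"""

import cellelast as ce

series, truth = ce.gen_thermal_series(
    ce.ThermalSimConfig(seed=3, k_true=0.1, temperature=310.15, n_samples=100_000)
)
result = ce.spring_constant_thermal(series, temperature=310.15)
print(f"thermal spring constant: {result.spring_constant:.4f} N/m "
      f"(true {truth['k_true']} N/m, n = {result.sample_count})")

glass, gtruth = ce.gen_glass_curve(seed=3, sensitivity_nm_per_v=50.0)
glass = ce.baseline_correct(glass)
sens = ce.deflection_sensitivity_from_hard_curve(glass)
print(f"deflection sensitivity: {sens:.2f} nm/V "
      f"(true {gtruth['sensitivity_nm_per_v']} nm/V)")
# With k and the sensitivity set, a raw volt-signal curve converts to
# force in nN via F = k * sensitivity * signal.
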