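"""Summarize tumor growth kinetics from caliper data and necrosis areas.

Simulates a control vs twice-daily-treated cohort (treatment halves the
growth rate), converts diameters to ellipsoid volumes, and reports fold
changes, the treated/control ratio, and a necrosis percentage.
"""

import cellelast as ce

ms, truth = ce.gen_tumor_cohort(
    ce.TumorSimConfig(seed=8, growth_rate_per_day=0.15, treatment_effect=0.5)
)
out = ce.growth_summary(ms)

last = out.groups[out.groups["day"] == out.groups["day"].max()]
for _, row in last.iterrows():
    print(f"day {row['day']:2d} {row['group']:12s}: "
          f"mean volume {row['mean_volume']:6.1f} mm^3, "
          f"fold change {row['mean_fold']:.2f} +/- {row['sem_fold']:.2f}")

ratio = out.ratio_vs_control
print(f"treated/control volume ratio, day {int(ratio['day'].max())}: "
      f"{ratio[ratio['day'] == ratio['day'].max()]['volume_ratio'].iloc[0]:.2f}")
# A ratio below 1 means treatment slowed growth (true rate reduction: 50%).

aon = ce.aon_percent(necrotic_area=50.0, total_area=250.0)
print(f"necrosis fraction for a (50, 250) area pair: AON% = {aon:.0f}%")
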