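"""Simulate a full 23-subject study and run the group analysis.

Generates hemoglobin time courses, cardiac intervals and VAS ratings
under the default (study-calibrated) effect profiles, then produces the
per-period paired comparisons and the repeated-measures ANOVA. The
creative-vs-simple oxyhemoglobin contrast should emerge during the task
and peak in the post-task rest periods of channel 1.
"""

from nirtrs.pipeline import run_full_pipeline
from nirtrs.simulate import SimulationConfig, simulate_experiment

experiment = simulate_experiment(SimulationConfig(seed=1, n_subjects=23))
bundle = run_full_pipeline(experiment)

t3 = bundle.table_oxy
ch1 = t3[t3.channel == "ch1"]
print("oxy-Hb change rate, channel 1 (creative vs simple):")
print(
    ch1[["period", "mean_creative", "mean_simple", "t", "p", "d", "power"]]
    .to_string(index=False, float_format=lambda v: f"{v:.3f}")
)

aov = bundle.table_anova
row = aov[(aov.chromophore == "oxy") & (aov.channel == "ch1")].iloc[0]
print(f"\nRM-ANOVA (oxy, ch1): condition F = {row.F_condition:.2f} "
      f"(p = {row.p_condition:.3f}), interaction F = {row.F_interaction:.2f} "
      f"(GG-corrected p = {row.p_interaction:.4f}, "
      f"epsilon = {row.epsilon_gg_period:.2f})")
print("A significant interaction says the condition difference grows over "
      "the 13 periods, as the calibrated profiles prescribe.")
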