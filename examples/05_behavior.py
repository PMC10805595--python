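"""Behavioural fixtures and their link to echo information.

Generates two-alternative forced-choice trial tables at the observed
per-condition accuracies (15 trials per condition), summarizes them with
exact binomial tests against chance, and averages decisive walking
trajectories after mirroring right-side trials.
"""

from echodome import (
    gen_choice_trials,
    gen_trajectories,
    normalize_trajectories,
    summarize_choices,
)

table = gen_choice_trials(n_per_condition=15, n_bats=3, seed=42)
summary = summarize_choices(table)
print("per-condition summary (pooled over bats):")
print(summary.per_condition.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nT2/T5 (strong occlusion edits) sit near 100%; T3 hovers near "
      "chance -- the pattern the echo analysis explains.")

fixtures = gen_trajectories(20, condition="T1vT4", decision_profile="DECISIVE", seed=7)
mean_path = normalize_trajectories(fixtures)
y_end = mean_path.mean[-1, 1]
print(f"\nmean decisive path: starts near the centreline, ends at lateral "
      f"{y_end:.0f} mm (T1 corridor centred at -60 mm after mirroring); "
      f"mid-path spread {mean_path.sd[50, 1]:.0f} mm.")
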