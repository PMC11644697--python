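"""Watch the drift statistic J react to a weather-regime change.

Builds a monitor from a dry-weather reference window, then feeds it
sliding one-day windows across a dry→rain transition and prints J (the
MI-weighted relative change of the KDE expectations, in %) per day.
"""

import numpy as np

from bodsense import (
    DriftMonitorState,
    ScenarioConfig,
    compute_mi_profile,
    generate,
    should_reconstruct,
    weights_from_mi,
)

cfg = ScenarioConfig(seed=3, n_days=8, regime_schedule=[("dry", 5), ("rain", 3)])
ds = generate(cfg)
ref = ds.slice_rows(0, 288)  # 3-day dry reference

profile = compute_mi_profile(ref, k=3, threshold_lambda=0.3)
sel = profile.selected
weights = weights_from_mi({v: profile.mi_values[v] for v in sel})
print("monitor weights (from MI):",
      {k: round(w, 3) for k, w in weights.items()})

state = DriftMonitorState.from_reference(
    {v: ref.column(v) for v in sel}, weights, threshold_delta=5.0)

print(f"\nthreshold delta = {state.threshold_delta}% on |J|\n")
for day in range(3, 8):
    window = ds.slice_rows((day - 2) * 96, (day + 1) * 96)  # trailing 3 days
    regime = ds.regime_labels[day * 96]
    decision, J = should_reconstruct(state, {v: window.column(v) for v in sel})
    flag = "RECONSTRUCT" if decision else "hold"
    print(f"day {day} ({regime:>4}): J = {J:+6.2f}%  -> {flag}")
    if decision:
        state.commit({v: window.column(v) for v in sel})

print("\nJ stays within a couple of percent while the weather is stable and "
      "jumps past the threshold as rain shifts the input distribution; "
      "committing the window resets the reference so J relaxes afterwards.")
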