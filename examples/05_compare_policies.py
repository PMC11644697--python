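"""Compare static, moving-window and drift-triggered retraining policies.

Runs all three policies over the same 9-day test stream (dry → rain →
storm) and prints one summary row each: the drift-triggered policy
should approach the moving window's accuracy with far fewer retrains,
and both should beat the never-retrained model once the weather turns.
"""

from bodsense import compute_mi_profile
from bodsense.pipeline import PolicyConfig, compare_policies
from bodsense.study import STUDY_LAMBDA, drift_scenario, split_train_test, study_model_cfg

train_ds, test_ds = split_train_test(drift_scenario(seed=3))
profile = compute_mi_profile(train_ds, k=3, threshold_lambda=STUDY_LAMBDA)

table, traces = compare_policies(
    train_ds, test_ds, profile, study_model_cfg(seed=3),
    PolicyConfig(window_length=288, stride=96, delta=5.0))

print(table.drop(columns="retrain_seconds").to_string(index=False,
                                                      float_format="%.4f"))

print("\nper-cycle drift statistic (mpdar policy):")
for r in traces["mpdar"].records:
    print(f"  cycle {r.cycle}: J = {r.J:+6.2f}%  "
          f"{'retrained' if r.reconstructed else 'held'}")

print("\nReading the table: 'static' degrades in the wet regimes, 'mw' "
      "retrains every cycle (9x), and 'mpdar' retrains only on the cycles "
      "where J crossed 5% - similar accuracy to mw at a fraction of the "
      "retraining effort.")
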