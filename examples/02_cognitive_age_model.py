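"""Fit the cognitive age model and compute bias-corrected CAG scores.

Trains PLS1 (5 components) on every training-cohort session, predicts age in
the held-out test cohort, reports accuracy before bias correction, then shows
that the correction removes the age-dependent bias in the CAG.
"""

import numpy as np

from cogage import (
    SimulationConfig, accuracy, apply_bias_correction, fit_age_model,
    fit_bias_correction, generate_cohort, predict_age,
)

cohort = generate_cohort(SimulationConfig(seed=1))
train = cohort.sessions_for("train")
test = cohort.sessions_for("test")

model = fit_age_model(train, n_components=5)
train_age = train["age_at_session"].to_numpy()
test_age = test["age_at_session"].to_numpy()

acc_train = accuracy(predict_age(model, train), train_age)
acc_test = accuracy(predict_age(model, test), test_age)
print(f"training accuracy: r={acc_train.r:.2f}, R2={acc_train.r2:.2f}, "
      f"MAE={acc_train.mae:.2f} years")
print(f"test accuracy:     r={acc_test.r:.2f}, R2={acc_test.r2:.2f}, "
      f"MAE={acc_test.mae:.2f} years")

# Raw CAG = predicted − chronological age is biased: positive for the young,
# negative for the old. The linear offset fitted on the training cohort
# removes it; the corrected CAG is what SA classification uses.
bias = fit_bias_correction(predict_age(model, train) - train_age, train_age)
print(f"bias correction: offset = {bias.alpha:.3f} * age + {bias.beta:.2f}")

res = apply_bias_correction(bias, predict_age(model, test), test_age)
raw_slope = np.polyfit(test_age, res.cag_raw, 1)[0]
cor_slope = np.polyfit(test_age, res.cag_corrected, 1)[0]
print(f"CAG-vs-age slope: raw {raw_slope:.3f} → corrected {cor_slope:.3f} "
      f"(≈0 means the age bias is gone)")
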