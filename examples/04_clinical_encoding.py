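"""Encode clinical metadata: z-scores for continuous fields, one-hot for
categoricals, with the fitted state reusable on new records.

The scaler is fitted on the training table only, so validation/test data
never leak into the statistics.
"""

import pandas as pd

from dermapatch import SynthConfig, generate_cohort, fit_encoder, transform

cohort = generate_cohort(SynthConfig(n_images=50, seed=9))
table = pd.DataFrame([s.clinical for s in cohort])

encoder = fit_encoder(table)
print(f"fitted encoder: {encoder.dim} features -> {encoder.feature_names}")
age = encoder.continuous["age"]
print(f"age: mu={age['mean']:.1f}, sigma={age['std']:.1f} (population convention)")

record = {"age": 64.0, "symptom_duration": 12.0, "gender": "F",
          "skin_type": "III", "history_flag": 1}
vector = transform(record, encoder)
print(f"encoded record (length {len(vector)}):")
for name, value in zip(encoder.feature_names, vector):
    print(f"  {name:>22s} = {value:+.3f}")
# the age z-score is (64 - mu)/sigma; each one-hot block has exactly one 1
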