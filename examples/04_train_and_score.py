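"""Train a small patch classifier and Monte-Carlo-score held-out fields.

A scaled-down version of the full workflow: simulate a labelled field set,
hold out two acquisition batches, train the three-class patch CNN, then
score each held-out field by 100-round 4-patch Monte-Carlo averaging.
Takes a couple of minutes on one CPU.
"""

import numpy as np

from mitoscore import benchmark

fields = benchmark.make_field_set(seed=0, n_per_class=15)
train_fields, test_fields, _ = benchmark.grouped_split(fields, seed=0, test_folds=(0,))
print(f"{len(train_fields)} training fields, {len(test_fields)} held-out fields")

model = benchmark.train_task_model(train_fields, task="CCCP-FL3-NC", seed=0, epochs=8)
print("final training accuracy:", round(model.curves["accuracy"].iloc[-1], 3))

scores = benchmark.score_fields(model, test_fields, rounds=100, k=4, seed=0)
score_cols = [f"score_{c}" for c in model.class_order]
pred = [model.class_order[i] for i in scores[score_cols].to_numpy().argmax(axis=1)]
acc = float(np.mean(np.asarray(pred) == scores["label"].to_numpy()))
print(scores[["field_id", "label", *score_cols]].head(6).to_string(index=False))
print(f"held-out field accuracy: {acc:.2f}")

# Each row's three probabilities are the field's CCCP-/FL3-/NC-scores; the
# argmax is the predicted morphology class of the whole field.
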