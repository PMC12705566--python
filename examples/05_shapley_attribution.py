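"""Explain the peak-feature classifier with exact Shapley values.

Every prediction is decomposed into per-feature contributions by enumerating
all 2^7 feature coalitions against a calibration-mean background. The mean
|Shapley value| ranking identifies which fluorophore regions drive the model.
"""

import numpy as np

from eemstress import (
    AttentionConfig,
    build_peak_table,
    exact_shapley,
    generate_dataset,
    importance_summary,
    preprocess_dataset,
    split_dataset,
    train_attention_classifier,
)

dataset, _ = generate_dataset(n_per_group=10, seed=4)
table = build_peak_table(preprocess_dataset(dataset))
sel = (table["polymer"] == "PS") | (table["polymer"] == "CONTROL")
X = table.loc[sel, list("AMCDBTN")].to_numpy()
y = table.loc[sel, "concentration_mg_per_L"].to_numpy()
split = split_dataset(y, k_folds=0, seed=0)

cfg = AttentionConfig(seed=0, epochs=60, early_stopping=False)
clf = train_attention_classifier(X[split.calibration], y[split.calibration], cfg, view="features")
background = X[split.calibration].mean(axis=0)

atts, labels = [], []
for i in split.validation[:15]:
    atts.append(exact_shapley(clf, X[i], background, target_class=int(y[i]), feature_names=list("AMCDBTN")))
    labels.append(int(y[i]))
eff = max(abs(a.base_value + a.values.sum() - a.full_value) for a in atts)
print(f"efficiency residual across {len(atts)} explanations: {eff:.2e} (exact mode)")

summary = importance_summary(atts, labels)
overall = summary[summary["class"] == "overall"].sort_values("rank")
print(overall[["feature", "mean_abs_shap", "rank"]].round(4).to_string(index=False))
print(
    "The efficiency residual confirms base value + contributions = prediction\n"
    "exactly. All seven peaks carry dose information in this simulation, so the\n"
    "ranking shows which of the redundant features this particular trained model\n"
    "actually leans on when assigning the class probability."
)
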