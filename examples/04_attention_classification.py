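"""Classify stress concentration with the patch-attention model and baselines.

For the PET task (control vs 10 vs 100 mg/L), three views of the same data are
classified: the 7 peak features (one attention token), the emission spectrum
at Ex 350 nm (1-D windows) and, for comparison, KNN/RF on the peak features.
"""

import numpy as np

from eemstress import (
    AttentionConfig,
    build_peak_table,
    class_metrics,
    confusion,
    generate_dataset,
    preprocess_dataset,
    split_dataset,
    train_attention_classifier,
    train_baseline,
)

dataset, _ = generate_dataset(n_per_group=12, seed=3)
clean = preprocess_dataset(dataset)
table = build_peak_table(clean)

sel = (table["polymer"] == "PET") | (table["polymer"] == "CONTROL")
X_peaks = table.loc[sel, list("AMCDBTN")].to_numpy()
y = table.loc[sel, "concentration_mg_per_L"].to_numpy()
split = split_dataset(y, k_folds=0, seed=0)

cfg = AttentionConfig(seed=0, epochs=60, early_stopping=False)
attn = train_attention_classifier(X_peaks[split.calibration], y[split.calibration], cfg, view="features")
pred = attn.predict(X_peaks[split.validation])
m = class_metrics(confusion(y[split.validation], pred))
print(f"attention on peak features: validation accuracy {m.accuracy:.2f}%")
print("confusion matrix (rows = true 0/10/100 mg/L):")
print(confusion(y[split.validation], pred).to_frame().to_string())

slices = clean.to_tensor()[np.flatnonzero(sel.to_numpy())][:, clean.grid.ex_index(350), :]
attn1d = train_attention_classifier(slices[split.calibration], y[split.calibration], cfg, view="sequence")
acc1d = 100 * np.mean(attn1d.predict(slices[split.validation]) == y[split.validation])
print(f"attention on the Ex 350 nm emission spectrum: {acc1d:.2f}%")

for kind in ("KNN", "RF"):
    base = train_baseline(X_peaks[split.calibration], y[split.calibration], kind, seed=0)
    acc = 100 * np.mean(base.predict(X_peaks[split.validation]) == y[split.validation])
    print(f"{kind} baseline on peak features: {acc:.2f}%")
print(
    "On well-separated synthetic effects every view resolves the three doses;\n"
    "per-class sensitivity/specificity come from the one-vs-rest confusion counts."
)
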