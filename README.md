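# eemstress

Chemometrics pipeline for diagnosing microplastics stress in plants from
excitation–emission matrix (EEM) fluorescence spectra of root exudates.

Plants under abiotic stress change the composition of the organic compounds
their roots release. The fluorescent fraction of those exudates — humic-like,
fulvic-like and protein-like (tyrosine/tryptophan) fluorophores — shows up as
characteristic peaks in an EEM, the 2-D landscape of fluorescence intensity
over every excitation/emission wavelength pair. This package implements the
full analysis chain for a hydroponic study design in which rice seedlings are
exposed to PET, PS or PVC microplastics at 0, 10 or 100 mg/L (seven treatment
groups, 48 spectra each, 336 in total, on an Ex 220–550 nm / 5 nm × Em
240–750 nm / 1 nm grid):

- **`eemstress.core`** — EEM domain types, self-describing CSV I/O, dataset
  manifests, wavelength-grid validation.
- **`eemstress.preprocess`** — Rayleigh/Raman scatter masking
  (|em − ex| ≤ w₁, |em − 2ex| ≤ w₂, water Raman band at
  1/λ_em = 1/λ_ex − 3400·10⁻⁷ nm⁻¹), linear interpolation along emission
  rows, moving-average smoothing, zeroing of the anti-Stokes triangle
  em < ex.
- **`eemstress.peaks`** — the seven conventional peak regions
  (A, M, C, D, B, T, N) reduced to regional mean intensities.
- **`eemstress.parafac`** — non-negative PARAFAC (CP) decomposition
  X_ijk ≈ Σ_f a_if b_jf c_kf by multi-start alternating least squares with
  exact per-row NNLS, plus CORCONDIA and split-half rank diagnostics.
- **`eemstress.attention` / `eemstress.models`** — a small
  vision-transformer-style classifier (patch embedding, additive positional
  encoding, pre-norm encoder blocks with multi-head scaled dot-product
  attention softmax(QKᵀ/√d_k)V, MLP head with dropout) for 2-D EEMs, 1-D
  emission spectra and short feature vectors; KNN and random-forest
  baselines with the same probability contract.
- **`eemstress.evaluation`** — stratified splits, confusion matrices,
  one-vs-rest sensitivity/specificity/accuracy, per-excitation-wavelength
  model sweep.
- **`eemstress.shapley`** — exact (coalition-enumeration) and sampled
  (permutation) Shapley attribution of predictions to features.
- **`eemstress.synthetic`** — a generator producing the full labelled study
  from Gaussian-profile fluorophore components with dose-dependent loadings,
  scatter ridges and measurement noise, together with its ground truth.
- **`eemstress.pipeline` / `eemstress.cli`** — end-to-end orchestration and
  a thin `eemstress` command-line front-end
  (`simulate`, `preprocess`, `peaks`, `parafac`, `train`, `evaluate`,
  `sweep`, `explain`-via-`reproduce`).

## Worked example

`examples/` holds one short script per capability. Rank selection
(`python examples/03_parafac_rank_selection.py`) prints:

```
tensor: (84, 67, 128) (emission decimated 4x for desk-scale ALS)
 n_components  fit_error  core_consistency  split_half_similarity
            3      0.033            95.968                 99.990
            4      0.005            97.956                 99.789
            5      0.003            91.587                 99.965
            6      0.003          -869.856                 99.943
chosen rank: 5
```

The residual fit error flattens once five components are allowed (the
generator used five fluorophores), core consistency collapses at six
(over-factoring), and split-half similarity above 95 % certifies that both
random sample halves recover the same excitation/emission loadings — so rank
5 is selected. Classification on the extracted features
(`python examples/04_attention_classification.py`) then reaches 100 %
validation accuracy on the well-separated synthetic effects, and
`examples/05_shapley_attribution.py` decomposes each prediction into
per-peak contributions whose efficiency residual is at machine precision.

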