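"""Simulate a small EEM study and remove scatter from one spectrum.

Builds a 7-group synthetic study (control + 3 polymers x 2 doses), then shows
what preprocessing does to the emission spectrum at Ex 350 nm: the Rayleigh
ridge at 350 nm and the water Raman band near 397 nm are masked and filled,
and the anti-Stokes region (em < ex) is zeroed.
"""

import numpy as np

from eemstress import extract_emission_slice, generate_dataset, preprocess

dataset, truth = generate_dataset(n_per_group=4, seed=0)
print(f"simulated {len(dataset)} spectra on a {dataset.grid.n_ex} x {dataset.grid.n_em} grid")

raw = dataset[0]
clean = preprocess(raw)
for em_nm in (340, 350, 398, 500):
    j = int(em_nm - 240)
    print(
        f"Ex 350 / Em {em_nm} nm: raw {extract_emission_slice(raw, 350)[j]:8.1f}"
        f" -> preprocessed {extract_emission_slice(clean, 350)[j]:8.1f}"
    )
print(
    "Raw values at 350 and 398 nm are dominated by Rayleigh/Raman scatter; after\n"
    "preprocessing they drop to the underlying fluorophore level, Em 340 < Ex 350\n"
    "is zeroed (anti-Stokes), and Em 500 nm is essentially unchanged."
)
assert not np.isnan(clean.intensities).any()
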