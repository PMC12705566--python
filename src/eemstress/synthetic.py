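"""Synthetic EEM study generator with known ground truth.

Emulates a 7-group stress study (control + {PET, PS, PVC} x {10, 100} mg/L,
48 spectra each by default, 336 total): every sample is a non-negative sum of
Gaussian-profile fluorophore components (separable in excitation x emission,
so the noise-free data cube is exactly trilinear), plus first/second-order
Rayleigh and water-Raman scatter ridges and additive Gaussian measurement
noise. Treatment acts multiplicatively on component loadings: low dose pushes
loadings below control, high dose above, with PS > PVC > PET effect strength
at high dose. Between-sample biological scatter is log-normal per sample and
component.

The generator returns the ground truth (true loadings, true scores, and a way
to rebuild each scatter-free clean EEM), so every downstream stage can be
tested against what was actually put in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_GRID, EEMDataset, EEMSample, Polymer, WavelengthGrid, make_grid
from .preprocess import raman_emission_nm

__all__ = [
    "FluorophoreComponent",
    "TreatmentEffect",
    "NoiseModel",
    "default_component_catalog",
    "default_treatment_effects",
    "render_component",
    "generate_dataset",
    "GroundTruth",
    "generate_worked_fixtures",
]

GROUPS = [
    (Polymer.CONTROL, 0),
    (Polymer.PET, 10),
    (Polymer.PET, 100),
    (Polymer.PS, 10),
    (Polymer.PS, 100),
    (Polymer.PVC, 10),
    (Polymer.PVC, 100),
]


@dataclass(frozen=True)
class FluorophoreComponent:
    """One separable Gaussian fluorophore (peak value = base_amplitude)."""

    name: str
    ex_center: float
    ex_sigma: float
    em_center: float
    em_sigma: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.ex_sigma <= 0 or self.em_sigma <= 0:
            raise ValueError(f"{self.name}: sigmas must be positive")
        if self.em_center <= self.ex_center:
            raise ValueError(f"{self.name}: Stokes shift requires em_center > ex_center")


def default_component_catalog() -> list[FluorophoreComponent]:
    """Five components at the resolved C1-C5 peak positions.

    C1 305/425 (tryptophan-derived humic-like), C2 285/355 (protein-like),
    C3 375/475 (humic acid), C4 360/430 (fulvic acid) and a broad
    long-wavelength stand-in for the composite C5 component.
    """
    return [
        FluorophoreComponent("C1", 305, 18, 425, 26, 900.0),
        FluorophoreComponent("C2", 285, 15, 355, 22, 800.0),
        FluorophoreComponent("C3", 375, 20, 475, 28, 650.0),
        FluorophoreComponent("C4", 360, 17, 430, 24, 700.0),
        FluorophoreComponent("C5", 420, 30, 545, 45, 400.0),
    ]


@dataclass
class TreatmentEffect:
    """Multiplicative loading factors per (component, polymer, concentration).

    Control factor is fixed at 1. Defaults: low dose (10 mg/L) in [0.6, 0.9]
    (below control), high dose (100 mg/L) in [1.2, 1.8] (above control), with
    high-dose strength ordered PS > PVC > PET.
    """

    factors: dict = field(default_factory=dict)

    def factor(self, component: str, polymer: Polymer, concentration: int) -> float:
        if polymer is Polymer.CONTROL or concentration == 0:
            return 1.0
        key = (component, Polymer(polymer).value, int(concentration))
        if key not in self.factors:
            raise KeyError(f"missing treatment factor for {key}")
        f = self.factors[key]
        if f <= 0:
            raise ValueError(f"treatment factor for {key} must be positive")
        return f

    def validate(self, component_names) -> None:
        missing = [
            (c, p.value, conc)
            for c in component_names
            for p, conc in GROUPS
            if p is not Polymer.CONTROL and (c, p.value, conc) not in self.factors
        ]
        if missing:
            raise ValueError(f"treatment effect table is missing cells: {missing}")


_LOW_BASE = {"PET": 0.80, "PS": 0.68, "PVC": 0.72}
_HIGH_BASE = {"PET": 1.30, "PS": 1.70, "PVC": 1.50}
_COMP_OFFSETS = (0.0, 0.03, -0.03, 0.02, -0.02, 0.01, -0.01)


def default_treatment_effects(catalog=None) -> TreatmentEffect:
    catalog = catalog if catalog is not None else default_component_catalog()
    factors = {}
    for i, comp in enumerate(catalog):
        off = _COMP_OFFSETS[i % len(_COMP_OFFSETS)]
        for polymer in ("PET", "PS", "PVC"):
            factors[(comp.name, polymer, 10)] = float(np.clip(_LOW_BASE[polymer] + off, 0.6, 0.9))
            factors[(comp.name, polymer, 100)] = float(
                np.clip(_HIGH_BASE[polymer] + 2 * off, 1.2, 1.8)
            )
    return TreatmentEffect(factors)


@dataclass(frozen=True)
class NoiseModel:
    """Between-sample scatter, measurement noise, and scatter-ridge amplitudes."""

    sample_lognormal_sigma: float = 0.10
    additive_gaussian_sigma: float = 2.0
    rayleigh1_amp: float = 1500.0
    rayleigh2_amp: float = 400.0
    raman_amp: float = 250.0
    ridge_width_nm: float = 6.0
    raman_shift_cm1: float = 3400.0

    def __post_init__(self) -> None:
        vals = (
            self.sample_lognormal_sigma,
            self.additive_gaussian_sigma,
            self.rayleigh1_amp,
            self.rayleigh2_amp,
            self.raman_amp,
            self.ridge_width_nm,
        )
        if any(v < 0 for v in vals):
            raise ValueError("noise model parameters must be >= 0")


def _gauss(axis: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / sigma) ** 2)


def render_component(component: FluorophoreComponent, grid: WavelengthGrid) -> np.ndarray:
    """Outer product of Gaussian ex/em profiles; peak value = base_amplitude."""
    ex_prof = _gauss(grid.ex_axis, component.ex_center, component.ex_sigma)
    em_prof = _gauss(grid.em_axis, component.em_center, component.em_sigma)
    return component.base_amplitude * np.outer(ex_prof, em_prof)


def _scatter_ridges(grid: WavelengthGrid, noise: NoiseModel) -> np.ndarray:
    ex = grid.ex_axis[:, None]
    em = grid.em_axis[None, :]
    w = max(noise.ridge_width_nm, 1e-9)
    ridges = noise.rayleigh1_amp * np.exp(-0.5 * ((em - ex) / w) ** 2)
    ridges += noise.rayleigh2_amp * np.exp(-0.5 * ((em - 2 * ex) / w) ** 2)
    raman = raman_emission_nm(grid.ex_axis, noise.raman_shift_cm1)[:, None]
    ridges += noise.raman_amp * np.exp(-0.5 * ((em - raman) / w) ** 2)
    return ridges


@dataclass
class GroundTruth:
    """What the generator actually put into each sample."""

    components: list[FluorophoreComponent]
    ex_loadings: np.ndarray  # n_ex x F, unit-norm columns
    em_loadings: np.ndarray  # n_em x F, unit-norm columns
    scores: np.ndarray  # n_samples x F, scaled so scores @ loadings^T rebuilds the clean EEM
    grid: WavelengthGrid

    def clean_sample(self, i: int) -> np.ndarray:
        """Scatter-free, noise-free EEM of sample i."""
        return np.einsum("f,jf,kf->jk", self.scores[i], self.ex_loadings, self.em_loadings)


def generate_dataset(
    component_catalog=None,
    effects: TreatmentEffect | None = None,
    noise: NoiseModel | None = None,
    n_per_group: int = 48,
    grid: WavelengthGrid = DEFAULT_GRID,
    seed: int = 0,
    include_scatter: bool = True,
) -> tuple[EEMDataset, GroundTruth]:
    """Generate the full labelled study with its ground-truth bundle.

    Each sample is sum_f score_if * component_f + scatter ridges + additive
    Gaussian noise, clipped at 0, where score_if = treatment factor x
    log-normal sample effect. Deterministic given ``seed``.
    """
    catalog = list(component_catalog) if component_catalog is not None else default_component_catalog()
    effects = effects if effects is not None else default_treatment_effects(catalog)
    noise = noise if noise is not None else NoiseModel()
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    effects.validate([c.name for c in catalog])

    rng = np.random.default_rng(seed)
    F = len(catalog)
    renders = np.stack([render_component(c, grid) for c in catalog])  # F x n_ex x n_em
    ex_load = np.stack([_gauss(grid.ex_axis, c.ex_center, c.ex_sigma) for c in catalog], axis=1)
    em_load = np.stack([_gauss(grid.em_axis, c.em_center, c.em_sigma) for c in catalog], axis=1)
    ex_norm = np.linalg.norm(ex_load, axis=0)
    em_norm = np.linalg.norm(em_load, axis=0)
    ex_load /= ex_norm[None, :]
    em_load /= em_norm[None, :]

    ridges = _scatter_ridges(grid, noise) if include_scatter else 0.0
    samples: list[EEMSample] = []
    scores = np.zeros((n_per_group * len(GROUPS), F))
    i = 0
    for polymer, conc in GROUPS:
        for r in range(n_per_group):
            raw = np.array(
                [
                    effects.factor(c.name, polymer, conc)
                    * rng.lognormal(mean=0.0, sigma=noise.sample_lognormal_sigma)
                    for c in catalog
                ]
            )
            eem = np.einsum("f,fjk->jk", raw, renders)
            eem = eem + ridges
            if noise.additive_gaussian_sigma > 0:
                eem = eem + rng.normal(0.0, noise.additive_gaussian_sigma, grid.shape)
            eem = np.clip(eem, 0.0, None)
            tag = "CTRL" if polymer is Polymer.CONTROL else polymer.value
            samples.append(
                EEMSample(
                    sample_id=f"{tag}-{conc:03d}-{r:03d}",
                    intensities=eem,
                    grid=grid,
                    polymer=polymer,
                    concentration_mg_per_L=conc,
                    replicate_index=r,
                )
            )
            # scale scores so that scores @ (unit-norm loadings) reproduces the clean EEM
            scores[i] = raw * np.array([c.base_amplitude for c in catalog]) * ex_norm * em_norm
            i += 1
    truth = GroundTruth(
        components=catalog, ex_loadings=ex_load, em_loadings=em_load, scores=scores, grid=grid
    )
    return EEMDataset(samples), truth


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=np.float64).tobytes()).hexdigest()


def generate_worked_fixtures() -> dict:
    """Deterministic mini-fixtures shared across the test suite.

    Returns rank-1 and 3-component tensors with their generating factors, a
    toy EEM sample on a small grid, and SHA-256 checksums of every array.
    """
    rng = np.random.default_rng(20250101)
    a1 = rng.uniform(0.5, 2.0, 12)
    b1 = rng.uniform(0.5, 2.0, 8)
    c1 = rng.uniform(0.5, 2.0, 10)
    rank1 = np.einsum("i,j,k->ijk", a1, b1, c1)

    A = rng.uniform(0.2, 1.5, (20, 3))
    B = np.stack([_gauss(np.arange(10.0), c, 2.0) for c in (2.0, 5.0, 8.0)], axis=1)
    C = np.stack([_gauss(np.arange(15.0), c, 2.5) for c in (3.0, 7.5, 12.0)], axis=1)
    three = np.einsum("if,jf,kf->ijk", A, B, C)

    toy_grid = make_grid(220, 245, 5, 240, 260, 1)
    toy = EEMSample(
        "toy-000",
        rng.uniform(0.0, 10.0, toy_grid.shape),
        toy_grid,
    )
    fixtures = {
        "rank1_tensor": rank1,
        "rank1_factors": (a1, b1, c1),
        "three_component_tensor": three,
        "three_component_factors": (A, B, C),
        "toy_sample": toy,
    }
    fixtures["checksums"] = {
        "rank1_tensor": _checksum(rank1),
        "three_component_tensor": _checksum(three),
        "toy_sample": _checksum(toy.intensities),
    }
    return fixtures
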