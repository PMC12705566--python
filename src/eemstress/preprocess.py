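"""Scatter correction and smoothing for raw EEMs.

Raw EEMs carry three chemically uninformative ridges: first-order Rayleigh
scatter along em = ex, second-order Rayleigh along em = 2*ex, and the water
Raman band at a fixed wavenumber shift (~3400 cm^-1, the O-H stretch) from the
excitation line. The pipeline masks those ridges, fills them by linear
interpolation along each emission row, applies a centered moving average, and
finally zeroes the non-physical triangle em < ex (emission cannot carry more
energy than excitation).

Order is fixed as mask -> interpolate -> smooth -> zero so that interpolation
never leaks intensity into the non-physical region; negatives are clipped to 0
at the end (fluorescence is non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EEMDataset, EEMSample, WavelengthGrid

__all__ = [
    "ScatterConfig",
    "PreprocessError",
    "raman_emission_nm",
    "scatter_mask",
    "interpolate_masked",
    "smooth_emission",
    "zero_nonphysical",
    "preprocess",
    "preprocess_dataset",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class ScatterConfig:
    """Geometry of the scatter ridges and smoothing parameters.

    Halfwidths are in nm; ``raman_shift_cm1`` is the Raman shift in cm^-1
    (3400 for the water O-H stretch). ``smoothing_window`` is an odd number of
    emission-axis points. ``nonphysical_margin`` widens the zeroed triangle:
    cells with em < ex + margin are set to zero.
    """

    rayleigh1_halfwidth: float = 15.0
    rayleigh2_halfwidth: float = 15.0
    raman_shift_cm1: float = 3400.0
    raman_halfwidth: float = 10.0
    smoothing_window: int = 11
    nonphysical_margin: float = 0.0

    def __post_init__(self) -> None:
        if min(self.rayleigh1_halfwidth, self.rayleigh2_halfwidth, self.raman_halfwidth) <= 0:
            raise PreprocessError("scatter halfwidths must be positive")
        if self.raman_shift_cm1 <= 0:
            raise PreprocessError("raman_shift_cm1 must be positive")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise PreprocessError("smoothing_window must be odd and >= 3")


def raman_emission_nm(ex_nm, shift_cm1: float = 3400.0):
    """Emission wavelength of the Raman band for excitation ``ex_nm``.

    1/lambda_em = 1/lambda_ex - shift, with the shift converted from cm^-1 to
    nm^-1 (factor 1e-7). For Ex 350 nm and 3400 cm^-1 this is ~397.3 nm.
    """
    ex_nm = np.asarray(ex_nm, dtype=float)
    return 1.0 / (1.0 / ex_nm - shift_cm1 * 1e-7)


def scatter_mask(grid: WavelengthGrid, config: ScatterConfig | None = None) -> np.ndarray:
    """Boolean n_ex x n_em mask, True where a cell lies on a scatter ridge."""
    config = config or ScatterConfig()
    ex = grid.ex_axis[:, None]
    em = grid.em_axis[None, :]
    mask = np.abs(em - ex) <= config.rayleigh1_halfwidth
    mask |= np.abs(em - 2.0 * ex) <= config.rayleigh2_halfwidth
    raman = raman_emission_nm(grid.ex_axis, config.raman_shift_cm1)[:, None]
    mask |= np.abs(em - raman) <= config.raman_halfwidth
    return mask


def interpolate_masked(sample: EEMSample, mask: np.ndarray) -> EEMSample:
    """Fill masked cells by linear interpolation along each emission row.

    Runs touching a row edge are filled by nearest-value extension. A fully
    masked row cannot be filled and raises, naming its excitation wavelength.
    """
    if mask.shape != sample.intensities.shape:
        raise PreprocessError("mask shape does not match sample")
    out = sample.intensities.copy()
    idx = np.arange(sample.grid.n_em)
    for r in range(sample.grid.n_ex):
        row_mask = mask[r] | ~np.isfinite(out[r])
        if not row_mask.any():
            continue
        if row_mask.all():
            raise PreprocessError(
                f"emission row at excitation {sample.grid.ex_axis[r]:g} nm is fully masked"
            )
        good = ~row_mask
        out[r, row_mask] = np.interp(idx[row_mask], idx[good], out[r, good])
    return sample.with_intensities(out)


def smooth_emission(sample: EEMSample, window: int | None = None) -> EEMSample:
    """Centered moving average along each emission row.

    Windows shrink near the row edges (the average runs over the cells that
    exist), so output length equals input length and each output value stays
    within the row's [min, max].
    """
    window = 11 if window is None else window
    if window % 2 == 0:
        raise PreprocessError(f"smoothing window must be odd, got {window}")
    if window > sample.grid.n_em:
        raise PreprocessError("smoothing window exceeds emission axis length")
    x = sample.intensities
    kernel = np.ones(window)
    sums = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, x)
    counts = np.convolve(np.ones(x.shape[1]), kernel, mode="same")
    return sample.with_intensities(sums / counts[None, :])


def zero_nonphysical(sample: EEMSample, margin: float = 0.0) -> EEMSample:
    """Zero every cell with em < ex + margin (anti-Stokes triangle)."""
    ex = sample.grid.ex_axis[:, None]
    em = sample.grid.em_axis[None, :]
    out = sample.intensities.copy()
    out[em < ex + margin] = 0.0
    return sample.with_intensities(out)


def preprocess(sample: EEMSample, config: ScatterConfig | None = None) -> EEMSample:
    """Full pipeline: mask -> interpolate -> smooth -> zero -> clip negatives."""
    config = config or ScatterConfig()
    mask = scatter_mask(sample.grid, config)
    out = interpolate_masked(sample, mask)
    out = smooth_emission(out, config.smoothing_window)
    out = zero_nonphysical(out, config.nonphysical_margin)
    return out.with_intensities(np.clip(out.intensities, 0.0, None))


def preprocess_dataset(dataset: EEMDataset, config: ScatterConfig | None = None) -> EEMDataset:
    config = config or ScatterConfig()
    if not len(dataset):
        return EEMDataset([])
    # mask depends only on the shared grid; compute once
    mask = scatter_mask(dataset.grid, config)
    out = []
    for s in dataset:
        t = interpolate_masked(s, mask)
        t = smooth_emission(t, config.smoothing_window)
        t = zero_nonphysical(t, config.nonphysical_margin)
        out.append(t.with_intensities(np.clip(t.intensities, 0.0, None)))
    return EEMDataset(out)
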