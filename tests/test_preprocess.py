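"""Scatter masking geometry, interpolation, smoothing and the full pipeline."""

import numpy as np
import pytest

from eemstress.core import DEFAULT_GRID, EEMSample
from eemstress.preprocess import (
    PreprocessError,
    ScatterConfig,
    interpolate_masked,
    preprocess,
    raman_emission_nm,
    scatter_mask,
    smooth_emission,
    zero_nonphysical,
)
from eemstress.synthetic import FluorophoreComponent, NoiseModel, generate_dataset
from conftest import random_sample


def em_idx(em_nm):
    return int(em_nm - 240)


class TestScatterMask:
    def test_raman_wavenumber_arithmetic(self):
        # 1/lambda_em = 1/lambda_ex - 3400e-7 nm^-1
        assert raman_emission_nm(350.0) == pytest.approx(397.3, abs=0.1)
        assert raman_emission_nm(300.0) == pytest.approx(1 / (1 / 300 - 3.4e-4), rel=1e-12)

    def test_ex350_ridges_where_expected(self):
        mask = scatter_mask(DEFAULT_GRID)
        row = mask[DEFAULT_GRID.ex_index(350)]
        assert row[em_idx(350)]  # 1st-order Rayleigh near 350
        assert row[em_idx(398)]  # Raman band near 397-400
        assert row[em_idx(700)]  # 2nd-order Rayleigh near 700
        assert not row[em_idx(500)]  # far from every ridge
        assert not row[em_idx(450)]

    def test_band_edges_symmetric(self):
        cfg = ScatterConfig(rayleigh1_halfwidth=15)
        mask = scatter_mask(DEFAULT_GRID, cfg)
        row = mask[DEFAULT_GRID.ex_index(350)]
        assert row[em_idx(335)] and row[em_idx(365)]
        assert not row[em_idx(334)] and not row[em_idx(366)]

    @pytest.mark.parametrize("attr", ["rayleigh1_halfwidth", "rayleigh2_halfwidth", "raman_halfwidth"])
    def test_masked_fraction_monotone_in_halfwidth(self, attr):
        fractions = []
        for hw in (5, 10, 20, 40):
            cfg = ScatterConfig(**{attr: hw})
            fractions.append(scatter_mask(DEFAULT_GRID, cfg).mean())
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_config_validation(self):
        with pytest.raises(PreprocessError):
            ScatterConfig(rayleigh1_halfwidth=-1)
        with pytest.raises(PreprocessError):
            ScatterConfig(smoothing_window=4)


class TestInterpolation:
    def make(self, rows, small_grid):
        x = np.tile(np.asarray(rows, dtype=float), (small_grid.n_ex, 1))
        pad = np.zeros((small_grid.n_ex, small_grid.n_em))
        pad[:, : x.shape[1]] = x
        return EEMSample("t", pad, small_grid)

    def test_linear_ramp_and_constant_fill(self, small_grid):
        s = self.make([0] * small_grid.n_em, small_grid)
        s.intensities[0, :4] = [1, np.nan, np.nan, 4]
        s.intensities[1, :3] = [5, np.nan, 5]
        mask = ~np.isfinite(s.intensities)
        out = interpolate_masked(s, mask)
        np.testing.assert_allclose(out.intensities[0, :4], [1, 2, 3, 4])
        np.testing.assert_allclose(out.intensities[1, :3], [5, 5, 5])

    def test_gap_over_linear_trend_recovered_exactly(self, small_grid, rng):
        slope, icpt = 0.7, 3.0
        row = icpt + slope * np.arange(small_grid.n_em)
        s = self.make(row, small_grid)
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[:, 20:27] = True  # 7-point gap
        out = interpolate_masked(s, mask)
        np.testing.assert_allclose(out.intensities, s.intensities, rtol=1e-12)

    def test_edge_runs_extend_nearest_value(self, small_grid):
        s = self.make(np.arange(small_grid.n_em, dtype=float), small_grid)
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[:, :3] = True
        mask[:, -2:] = True
        out = interpolate_masked(s, mask)
        assert np.all(out.intensities[:, :3] == out.intensities[:, [3]])
        assert np.all(out.intensities[:, -2:] == out.intensities[:, [-3]])

    def test_fully_masked_row_names_excitation(self, small_grid, rng):
        s = random_sample(small_grid, rng)
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[2] = True
        with pytest.raises(PreprocessError, match=str(int(small_grid.ex_axis[2]))):
            interpolate_masked(s, mask)

    def test_unmasked_cells_unchanged(self, small_grid, rng):
        s = random_sample(small_grid, rng)
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[:, 10:15] = True
        out = interpolate_masked(s, mask)
        np.testing.assert_array_equal(out.intensities[~mask], s.intensities[~mask])


class TestSmoothing:
    def test_constant_row_invariant(self, small_grid):
        s = EEMSample("c", np.full(small_grid.shape, 7.0), small_grid)
        np.testing.assert_allclose(smooth_emission(s, 5).intensities, 7.0)

    def test_spike_window3(self, small_grid):
        x = np.zeros(small_grid.shape)
        x[0, :5] = [0, 0, 3, 0, 0]
        out = smooth_emission(EEMSample("s", x, small_grid), 3)
        np.testing.assert_allclose(out.intensities[0, :5], [0, 1, 1, 1, 0])

    def test_variance_reduced_and_bounds_kept(self, small_grid, rng):
        s = random_sample(small_grid, rng)
        out = smooth_emission(s, 11)
        assert out.intensities.var(axis=1).mean() < s.intensities.var(axis=1).mean()
        assert np.all(out.intensities.min(axis=1) >= s.intensities.min(axis=1) - 1e-12)
        assert np.all(out.intensities.max(axis=1) <= s.intensities.max(axis=1) + 1e-12)

    def test_even_window_rejected(self, small_grid, rng):
        with pytest.raises(PreprocessError, match="odd"):
            smooth_emission(random_sample(small_grid, rng), 4)


class TestZeroNonphysical:
    def test_triangle_zeroed(self, rng):
        s = random_sample(DEFAULT_GRID, rng)
        out = zero_nonphysical(s)
        row350 = out.intensities[DEFAULT_GRID.ex_index(350)]
        assert np.all(row350[: em_idx(350)] == 0)
        assert np.all(row350[em_idx(350) :] != 0)
        # ex 220: whole emission axis (240-750) is Stokes-shifted, nothing zeroed
        np.testing.assert_array_equal(out.intensities[0], s.intensities[0])

    def test_margin_widens_triangle(self, rng):
        s = random_sample(DEFAULT_GRID, rng)
        out = zero_nonphysical(s, margin=10)
        row300 = out.intensities[DEFAULT_GRID.ex_index(300)]
        assert np.all(row300[: em_idx(310)] == 0)
        assert row300[em_idx(310)] != 0

    def test_idempotent(self, rng):
        s = random_sample(DEFAULT_GRID, rng)
        once = zero_nonphysical(s)
        twice = zero_nonphysical(once)
        np.testing.assert_array_equal(once.intensities, twice.intensities)


class TestFullPipeline:
    def test_all_zero_in_all_zero_out(self, small_grid):
        s = EEMSample("z", np.zeros(small_grid.shape), small_grid)
        np.testing.assert_array_equal(preprocess(s).intensities, 0.0)

    def test_output_clean(self, rng):
        s = random_sample(DEFAULT_GRID, rng)
        out = preprocess(s)
        assert np.isfinite(out.intensities).all()
        assert (out.intensities >= 0).all()
        ex = DEFAULT_GRID.ex_axis[:, None]
        em = DEFAULT_GRID.em_axis[None, :]
        assert np.all(out.intensities[em < ex] == 0)

    def test_recovers_scatter_free_truth(self):
        """RMSE to the generator's scatter-free EEM stays below 1.5x the noise sd,
        outside a guard band around the scatter ridges."""
        noise = NoiseModel(additive_gaussian_sigma=2.0)
        dataset, truth = generate_dataset(n_per_group=1, seed=5, noise=noise)
        cfg = ScatterConfig()
        from eemstress.preprocess import scatter_mask as sm

        guard = sm(
            dataset.grid,
            ScatterConfig(
                rayleigh1_halfwidth=cfg.rayleigh1_halfwidth + 5,
                rayleigh2_halfwidth=cfg.rayleigh2_halfwidth + 5,
                raman_halfwidth=cfg.raman_halfwidth + 5,
            ),
        )
        ex = dataset.grid.ex_axis[:, None]
        em = dataset.grid.em_axis[None, :]
        physical = ~guard & (em >= ex)
        for i, s in enumerate(dataset):
            out = preprocess(s, cfg)
            clean = truth.clean_sample(i)
            resid = (out.intensities - clean)[physical]
            assert np.sqrt((resid**2).mean()) < 1.5 * noise.additive_gaussian_sigma
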