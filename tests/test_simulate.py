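"""Synthetic campaign generator: grid, profiles, forward model, outliers."""

import numpy as np
import pytest

from nirsel.pls import fit_pls, predict
from nirsel.simulate import (DEFAULT_ANALYTES, SATURATED_REGION,
                             SimulationConfig, build_full_grid,
                             concentration_profiles, plant_outliers,
                             pure_spectrum, simulate_dataset)
from nirsel.spectra import exclude_region


class TestGrid:
    def test_uniform_spacing(self):
        g = build_full_grid().values
        d = np.diff(g)
        assert np.allclose(d, d[0], rtol=1e-9)

    def test_exclusion_retains_2032(self):
        grid = build_full_grid()
        v = grid.values
        keep = ~((v >= SATURATED_REGION.low) & (v <= SATURATED_REGION.high))
        assert keep.sum() == 2032

    def test_excluded_points_all_inside_window(self):
        v = build_full_grid().values
        excluded = [x for x in v if 5078.0 <= x <= 5235.0]
        assert len(excluded) == len(v) - 2032
        assert all(5078.0 <= x <= 5235.0 for x in excluded)


class TestProfiles:
    def test_monotone_decline_without_jitter(self):
        cfg = SimulationConfig(seed=2, concentration_jitter_sigma=0.0,
                               n_outliers=0)
        ds, gt = simulate_dataset(cfg)
        meta = ds.sample_meta
        for b, grp in meta.groupby("batch_id"):
            order = grp["time_min"].argsort(kind="stable")
            for col in gt.true_concentrations.columns:
                c = gt.true_concentrations[col].to_numpy()[grp.index[order]]
                assert np.all(np.diff(c) <= 1e-12)

    def test_values_within_admissible_ranges(self):
        cfg = SimulationConfig(seed=3, n_outliers=0)
        _, gt = simulate_dataset(cfg)
        for a in DEFAULT_ANALYTES:
            c = gt.true_concentrations[a.name]
            lo, hi = a.concentration_range
            assert c.min() >= lo and c.max() <= hi

    def test_analytes_strongly_correlated(self):
        _, gt = simulate_dataset(SimulationConfig(seed=4, n_outliers=0))
        c = gt.true_concentrations
        r = np.corrcoef(c.iloc[:, 0], c.iloc[:, 1])[0, 1]
        assert r > 0.8


class TestForwardModel:
    def test_default_config_gives_101_samples(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=0))
        assert ds.n_samples == 101

    def test_fixed_seed_is_bit_reproducible(self):
        a, _ = simulate_dataset(SimulationConfig(seed=13))
        b, _ = simulate_dataset(SimulationConfig(seed=13))
        assert np.array_equal(a.absorbance, b.absorbance)
        assert a.references.equals(b.references)

    def test_noiseless_beer_lambert_is_exactly_linear(self, noiseless_dataset):
        ds, _ = noiseless_dataset
        ds = exclude_region(ds, SATURATED_REGION)
        for a in ds.references.columns:
            model = fit_pls(ds.absorbance, ds.references[a].to_numpy(), 2)
            res = predict(model, ds.absorbance) - ds.references[a].to_numpy()
            assert np.sqrt(np.mean(res ** 2)) < 1e-8

    def test_doubling_concentration_doubles_contribution(self):
        grid = build_full_grid()
        a = DEFAULT_ANALYTES[0]
        assert np.allclose(2.0 * pure_spectrum(a, grid),
                           pure_spectrum(a, grid) * 2.0)
        # forward model linearity through the mixture sum
        cfg = SimulationConfig(seed=1, noise_sd_base=0, scatter_slope_sd=0,
                               noise_sd_low_wn_region=0, offset_sd=0,
                               tilt_sd=0, concentration_jitter_sigma=0,
                               n_outliers=0)
        ds, gt = simulate_dataset(cfg)
        pures = {n.name: pure_spectrum(n, ds.grid) for n in DEFAULT_ANALYTES}
        solvent = ds.absorbance[0] - sum(
            gt.true_concentrations[n].iloc[0] * p for n, p in pures.items())
        recon = solvent + sum(
            gt.true_concentrations[n].iloc[5] * p for n, p in pures.items())
        # linearity holds everywhere except inside the clipped plateau
        nu = ds.grid.values
        free = (nu < SATURATED_REGION.low - 60) | \
               (nu > SATURATED_REGION.high + 60)
        assert np.allclose(recon[free], ds.absorbance[5][free], atol=1e-10)

    def test_low_wavenumber_noise_elevated(self):
        cfg = SimulationConfig(seed=6, n_outliers=0,
                               concentration_jitter_sigma=0.0,
                               scatter_slope_sd=0.0, offset_sd=0.0,
                               tilt_sd=0.0)
        ds, gt = simulate_dataset(cfg)
        clean, _ = simulate_dataset(SimulationConfig(
            seed=6, n_outliers=0, concentration_jitter_sigma=0.0,
            scatter_slope_sd=0.0, offset_sd=0.0, tilt_sd=0.0,
            noise_sd_base=0.0, noise_sd_low_wn_region=0.0))
        resid = ds.absorbance - clean.absorbance
        nu = ds.grid.values
        low = resid[:, (nu <= 4413) & (nu >= 4000)].std()
        high = resid[:, (nu <= 9000) & (nu >= 8000)].std()
        assert low > 2 * high

    def test_saturated_plateau_is_flat_across_samples(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=8, n_outliers=0))
        nu = ds.grid.values
        sat = ds.absorbance[:, (nu >= SATURATED_REGION.low)
                            & (nu <= SATURATED_REGION.high)]
        assert np.all(sat == sat.max())

    def test_informative_indices_cover_band_centers_only(self):
        _, gt = simulate_dataset(SimulationConfig(seed=9, n_outliers=0))
        grid = build_full_grid()
        for a in DEFAULT_ANALYTES:
            p = pure_spectrum(a, grid)
            idx = gt.informative_variable_indices[a.name]
            assert len(idx) > 0
            assert np.all(p[idx] >= 0.1 * p.max())
            rest = np.setdiff1d(np.arange(len(p)), idx)
            assert np.all(p[rest] < 0.1 * p.max())


class TestOutliers:
    def test_empty_indices_is_identity(self):
        ds, gt = simulate_dataset(SimulationConfig(seed=1, n_outliers=0))
        out = plant_outliers(ds, gt, [], "concentration_shift")
        assert out is ds

    def test_out_of_range_index_rejected(self):
        ds, gt = simulate_dataset(SimulationConfig(seed=1, n_outliers=0))
        with pytest.raises(IndexError):
            plant_outliers(ds, gt, [500], "concentration_shift")

    def test_shift_outlier_has_largest_linear_fit_residual(self):
        cfg = SimulationConfig(seed=21, noise_sd_base=0,
                               noise_sd_low_wn_region=0, scatter_slope_sd=0,
                               offset_sd=0, tilt_sd=0,
                               concentration_jitter_sigma=0, n_outliers=0)
        ds, gt = simulate_dataset(cfg)
        ds = plant_outliers(ds, gt, [30], "concentration_shift", cfg=cfg)
        ds = exclude_region(ds, SATURATED_REGION)
        y = ds.references["geniposide"].to_numpy()
        model = fit_pls(ds.absorbance, y, n_lv=3)
        resid = np.abs(predict(model, ds.absorbance) - y)
        assert int(np.argmax(resid)) == 30

    def test_spectral_artifact_alters_spectrum_not_reference(self):
        ds, gt = simulate_dataset(SimulationConfig(seed=2, n_outliers=0))
        out = plant_outliers(ds, gt, [7], "spectral_artifact")
        assert not np.array_equal(out.absorbance[7], ds.absorbance[7])
        assert out.references.iloc[7].equals(ds.references.iloc[7])
        assert 7 in gt.outlier_indices
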