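"""Pretreatments: SG smoothing, SNV, MSC, normalization and the screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsel.preprocess import (PretreatmentConfig, apply_pretreatment, msc,
                               normalize, pretreatment_screen, sg_smooth,
                               snv)


class TestSG:
    def test_reproduces_quadratic_exactly(self):
        x = np.linspace(0, 1, 60)
        row = 3.0 - 2.0 * x + 5.0 * x ** 2
        out = sg_smooth(row[None, :], window=11, polyorder=2)
        assert np.allclose(out[0], row, atol=1e-10)

    def test_constant_row_unchanged(self):
        out = sg_smooth(np.full((2, 30), 0.7), window=7, polyorder=2)
        assert np.allclose(out, 0.7)

    def test_interior_point_matches_local_polyfit_oracle(self, rng):
        row = rng.normal(size=41)
        w, d = 9, 2
        out = sg_smooth(row[None, :], window=w, polyorder=d)[0]
        for center in (10, 20, 30):
            seg = row[center - w // 2: center + w // 2 + 1]
            t = np.arange(-(w // 2), w // 2 + 1)
            coef = np.polynomial.polynomial.polyfit(t, seg, d)
            assert out[center] == pytest.approx(coef[0], abs=1e-10)

    def test_reduces_white_noise_variance(self, rng):
        smooth = np.sin(np.linspace(0, 4, 300))
        noisy = smooth + 0.05 * rng.normal(size=300)
        out = sg_smooth(noisy[None, :], window=11, polyorder=2)[0]
        assert np.var(out - smooth) < np.var(noisy - smooth)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            sg_smooth(np.zeros((1, 20)), window=8, polyorder=2)
        with pytest.raises(ValueError):
            sg_smooth(np.zeros((1, 20)), window=5, polyorder=7)


class TestSNV:
    def test_rows_standardized(self, rng):
        out = snv(rng.normal(2.0, 3.0, size=(6, 40)))
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(3, 25))
        assert np.allclose(snv(1.7 + 0.3 * x), snv(x), atol=1e-10)

    def test_matches_per_row_oracle(self, rng):
        X = rng.normal(size=(5, 7))
        out = snv(X)
        for i in range(5):
            r = X[i]
            assert np.allclose(out[i], (r - r.mean()) / r.std(ddof=1))

    def test_constant_row_reported(self):
        X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            snv(X)


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.normal(size=30)
        X = np.vstack([ref, ref * 2 + 1])
        out = msc(X, reference=ref)
        assert np.allclose(out[0], ref, atol=1e-10)

    def test_constructed_scatter_removed(self, rng):
        ref = np.abs(rng.normal(size=40)) + 1
        row = 0.3 + 1.7 * ref
        out = msc(row[None, :], reference=ref)
        assert np.allclose(out[0], ref, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(4, 20))
        ref = X.mean(axis=0)
        out = msc(X)
        A = np.vstack([np.ones(20), ref]).T
        for i in range(4):
            a, b = np.linalg.lstsq(A, X[i], rcond=None)[0]
            assert np.allclose(out[i], (X[i] - a) / b, atol=1e-10)


class TestNormalize:
    def test_vector_norm_unit_rows(self, rng):
        out = normalize(rng.normal(size=(5, 12)), "vector_norm")
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0)

    def test_max_abs_peak_is_one(self, rng):
        out = normalize(np.abs(rng.normal(size=(4, 9))), "max_abs")
        assert np.allclose(out.max(axis=1), 1.0)

    def test_area_matches_l1_oracle(self, rng):
        X = rng.normal(size=(6, 15))
        out = normalize(X, "area")
        assert np.allclose(np.abs(out).sum(axis=1), 1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros((1, 5)), "max_abs")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_pretreatments_preserve_shape(seed):
    rng = np.random.default_rng(seed)
    X = np.abs(rng.normal(0.5, 0.2, size=(4, 31))) + 0.05
    for cfg in (PretreatmentConfig("raw"), PretreatmentConfig("snv"),
                PretreatmentConfig("msc"),
                PretreatmentConfig("normalization"),
                PretreatmentConfig("sg_smoothing", sg_window=7)):
        assert apply_pretreatment(X, cfg).shape == X.shape


class TestScreen:
    def test_identical_configs_identical_rows(self, rng):
        X = rng.normal(size=(20, 10))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        cfgs = [PretreatmentConfig("raw", label="a"),
                PretreatmentConfig("raw", label="b")]
        t = pretreatment_screen(X, y, cfgs, max_lv=3)
        assert np.allclose(t.iloc[0][["Rcv", "RMSECV", "RPDCV"]].astype(float),
                           t.iloc[1][["Rcv", "RMSECV", "RPDCV"]].astype(float))

    def test_all_methods_near_exact_on_noiseless_data(self, noiseless_dataset):
        from nirsel.simulate import SATURATED_REGION
        from nirsel.spectra import exclude_region
        ds, _ = noiseless_dataset
        ds = exclude_region(ds, SATURATED_REGION)
        # thin the grid for speed; linearity is column-subset invariant
        X = ds.absorbance[:, ::8]
        y = ds.references["geniposide"].to_numpy()
        cfgs = [PretreatmentConfig(m) for m in
                ("raw", "snv", "msc", "normalization", "sg_smoothing")]
        t = pretreatment_screen(X, y, cfgs, max_lv=6)
        # row-ratio transforms (SNV, MSC) divide by a concentration-
        # dependent scale, so exact linearity is only approximate there
        linear = t["Pretreatment"].isin(["raw", "normalization",
                                         "sg_smoothing"])
        assert (t.loc[linear, "RMSECV"] < 1e-6).all()
        assert (t["RMSECV"] < 1e-3).all()

    def test_sg_ranks_at_or_above_raw_under_heteroscedastic_noise(self):
        # mirrors the screening outcome: smoothing beats raw spectra
        # when the low-wavenumber noise region is informative
        from nirsel.simulate import SATURATED_REGION, SimulationConfig, \
            simulate_dataset
        from nirsel.spectra import exclude_region
        wins = 0
        for seed in range(10):
            ds, _ = simulate_dataset(SimulationConfig(
                seed=100 + seed, n_outliers=0))
            ds = exclude_region(ds, SATURATED_REGION)
            X = ds.absorbance[:, ::4]
            y = ds.references["geniposide"].to_numpy()
            t = pretreatment_screen(
                X, y, [PretreatmentConfig("raw"),
                       PretreatmentConfig("sg_smoothing")], max_lv=10)
            raw = float(t.loc[t.Pretreatment == "raw", "RMSECV"].iloc[0])
            sg = float(t.loc[t.Pretreatment == "sg_smoothing",
                             "RMSECV"].iloc[0])
            wins += sg <= raw
        assert wins >= 8
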