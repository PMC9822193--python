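"""Dataset container, CSV round-trips, replicate averaging, exclusion."""

import numpy as np
import pandas as pd
import pytest

from nirsel.spectra import (ExclusionInterval, SpectralDataset,
                            WavenumberGrid, average_replicates,
                            exclude_region, read_dataset, write_dataset)


class TestGrid:
    def test_rejects_ascending(self):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array([4000.0, 5000.0, 6000.0]))

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array([6000.0, 5000.0, 5000.0]))

    def test_rejects_out_of_region(self):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array([13000.0, 5000.0]))

    def test_exclusion_interval_order(self):
        with pytest.raises(ValueError):
            ExclusionInterval(high=5000.0, low=6000.0)


class TestIO:
    def test_round_trip(self, small_dataset, tmp_path):
        sp, rp = tmp_path / "s.csv", tmp_path / "r.csv"
        write_dataset(small_dataset, sp, rp)
        back = read_dataset(sp, rp)
        assert back.absorbance.shape == (3, 5)
        assert np.array_equal(back.absorbance, small_dataset.absorbance)
        assert np.array_equal(back.grid.values, small_dataset.grid.values)
        pd.testing.assert_frame_equal(back.references,
                                      small_dataset.references)

    def test_large_random_round_trip_to_text_precision(self, rng, tmp_path):
        grid = WavenumberGrid(np.linspace(11000, 4100, 200))
        n = 15
        ds = SpectralDataset(
            absorbance=rng.normal(0.5, 0.2, size=(n, 200)),
            grid=grid,
            sample_meta=pd.DataFrame({
                "sample_id": [f"S{i}" for i in range(n)],
                "batch_id": "B1", "time_min": np.arange(n, dtype=float)}))
        sp = tmp_path / "s.csv"
        write_dataset(ds, sp)
        back = read_dataset(sp)
        assert np.allclose(back.absorbance, ds.absorbance, rtol=1e-9)
        assert np.allclose(back.grid.values, ds.grid.values, rtol=1e-9)

    def test_spectra_only_when_no_references(self, small_dataset, tmp_path):
        ds = SpectralDataset(
            absorbance=small_dataset.absorbance, grid=small_dataset.grid,
            sample_meta=small_dataset.sample_meta)
        sp, rp = tmp_path / "s.csv", tmp_path / "r.csv"
        write_dataset(ds, sp, rp)
        assert sp.exists() and not rp.exists()

    def test_ascending_header_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("sample_id,batch_id,time_min,4000,5000\nA,B1,0,1,2\n")
        with pytest.raises(ValueError, match="decreasing"):
            read_dataset(f)

    def test_non_numeric_cell_located(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("sample_id,batch_id,time_min,5000,4000\n"
                     "A,B1,0,1,2\nB,B1,10,oops,2\n")
        with pytest.raises(ValueError, match="row 1"):
            read_dataset(f)

    def test_sample_id_mismatch(self, small_dataset, tmp_path):
        sp, rp = tmp_path / "s.csv", tmp_path / "r.csv"
        write_dataset(small_dataset, sp, rp)
        refs = pd.read_csv(rp)
        refs["sample_id"] = ["A", "B", "ZZZ"]
        refs.to_csv(rp, index=False)
        with pytest.raises(ValueError, match="mismatch"):
            read_dataset(sp, rp)


class TestAverageReplicates:
    def test_identical_replicates_collapse(self, small_dataset):
        ds = small_dataset
        meta = ds.sample_meta.copy()
        meta["sample_id"] = ["G1", "G1", "G1"]
        four = SpectralDataset(
            absorbance=np.tile(ds.absorbance[0], (3, 1)), grid=ds.grid,
            sample_meta=meta)
        out = average_replicates(four, "sample_id")
        assert out.n_samples == 1
        assert np.allclose(out.absorbance[0], ds.absorbance[0], rtol=1e-15)

    def test_mean_of_01_pairs(self, small_dataset):
        grid = small_dataset.grid
        ab = np.array([[0.0] * 5, [0.0] * 5, [1.0] * 5, [1.0] * 5])
        meta = pd.DataFrame({"sample_id": ["G"] * 4, "batch_id": "B1",
                             "time_min": 0.0})
        out = average_replicates(
            SpectralDataset(absorbance=ab, grid=grid, sample_meta=meta))
        assert np.allclose(out.absorbance, 0.5)

    def test_matches_columnwise_mean_oracle(self, rng):
        grid = WavenumberGrid(np.linspace(9000, 5000, 5))
        ab = rng.normal(size=(8, 5))
        groups = ["a", "a", "b", "a", "b", "b", "a", "b"]
        meta = pd.DataFrame({"sample_id": groups, "batch_id": "B1",
                             "time_min": 0.0})
        out = average_replicates(
            SpectralDataset(absorbance=ab, grid=grid, sample_meta=meta))
        ga = ab[[0, 1, 3, 6]].mean(axis=0)
        gb = ab[[2, 4, 5, 7]].mean(axis=0)
        assert np.allclose(out.absorbance, np.vstack([ga, gb]))

    def test_unknown_key_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            average_replicates(small_dataset, "nope")


class TestExcludeRegion:
    def test_toy_membership(self):
        grid = WavenumberGrid(np.array([10000.0, 9000.0, 8000.0, 7000.0,
                                        6000.0]))
        meta = pd.DataFrame({"sample_id": ["A"], "batch_id": "B1",
                             "time_min": 0.0})
        ds = SpectralDataset(absorbance=np.arange(5.0)[None, :], grid=grid,
                             sample_meta=meta)
        out = exclude_region(ds, ExclusionInterval(high=9000.0, low=7000.0))
        # brute-force closed-interval membership: 9000, 8000, 7000 removed
        assert out.grid.values.tolist() == [10000.0, 6000.0]
        assert out.column_origin.tolist() == [0, 4]

    def test_outside_span_is_noop(self, small_dataset):
        out = exclude_region(small_dataset,
                             ExclusionInterval(high=4600.0, low=4500.0))
        assert np.array_equal(out.grid.values, small_dataset.grid.values)

    def test_idempotent(self, small_dataset):
        iv = ExclusionInterval(high=7500.0, low=5500.0)
        once = exclude_region(small_dataset, iv)
        twice = exclude_region(once, iv)
        assert np.array_equal(once.grid.values, twice.grid.values)
        assert np.array_equal(once.column_origin, twice.column_origin)

    def test_refuses_to_remove_almost_everything(self, small_dataset):
        with pytest.raises(ValueError):
            exclude_region(small_dataset,
                           ExclusionInterval(high=9500.0, low=5500.0))

    def test_commutes_with_average_replicates(self, rng):
        grid = WavenumberGrid(np.linspace(9000, 5000, 6))
        ab = rng.normal(size=(4, 6))
        meta = pd.DataFrame({"sample_id": ["a", "a", "b", "b"],
                             "batch_id": "B1", "time_min": 0.0})
        ds = SpectralDataset(absorbance=ab, grid=grid, sample_meta=meta)
        iv = ExclusionInterval(high=8000.0, low=6000.0)
        one = exclude_region(average_replicates(ds), iv)
        two = average_replicates(exclude_region(ds, iv))
        assert np.allclose(one.absorbance, two.absorbance)
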