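import numpy as np
import pandas as pd
import pytest

from singulor import (
    bin_axis,
    cell_type_bin_matrix,
    filter_low_count_cells,
    gene_bin_profile,
    log_normalize,
    or_density_map,
    project_to_axis,
    spatial_high_dominance_summary,
)

from conftest import make_count_matrix


class TestLowCountFilter:
    def test_boundary_eleven_removed_twelve_kept(self):
        cm = make_count_matrix([[11, 0], [12, 0], [5, 8]])
        out, report = filter_low_count_cells(cm)
        assert list(report["kept"]) == [False, True, True]
        assert out.n_cells == 2

    def test_empty_input(self):
        import scipy.sparse as sp
        from singulor import CountMatrix

        cm = CountMatrix(np.array([], dtype=object), np.array(["g"], dtype=object),
                         sp.csr_matrix((0, 1), dtype=np.int64))
        out, report = filter_low_count_cells(cm)
        assert out.n_cells == 0 and len(report) == 0


class TestAxisProjection:
    POLY = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0]])

    def test_vertex_arc_lengths(self):
        s = project_to_axis(self.POLY, self.POLY)
        np.testing.assert_allclose(s, [0.0, 0.5, 1.0])

    def test_straight_axis_midpoint(self):
        s = project_to_axis(np.array([[50.0, 30.0]]), np.array([[0.0, 0.0], [100.0, 0.0]]))
        assert s[0] == pytest.approx(0.5)

    def test_dense_sampling_oracle(self):
        rng = np.random.default_rng(0)
        poly = np.array([[0, 0], [100, 50], [180, 40], [300, 120]], float)
        pts = rng.uniform([0, -20], [310, 140], size=(150, 2))
        s = project_to_axis(pts, poly)
        # oracle: nearest of 200k points sampled densely along the axis
        t = np.linspace(0, 1, 200_001)
        seg = np.diff(poly, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        arc = t * cum[-1]
        seg_idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seg_len) - 1)
        frac = (arc - cum[seg_idx]) / seg_len[seg_idx]
        dense = poly[seg_idx] + frac[:, None] * seg[seg_idx]
        d2 = ((pts[:, None, :] - dense[None, :, :]) ** 2).sum(-1)
        oracle = t[np.argmin(d2, axis=1)]
        assert np.abs(s - oracle).max() < 1e-3

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            project_to_axis(np.array([[1.0, 1.0]]), np.array([[0.0, 0.0], [0.0, 0.0]]))


class TestBinAxis:
    @pytest.mark.parametrize("s,expected", [(0.0, 1), (1.0, 50), (0.5, 26), (0.019, 1), (0.02, 2)])
    def test_half_open_bins_closed_top(self, s, expected):
        assert bin_axis(np.array([s]), 50)[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_axis(np.array([1.2]))

    def test_partition_conserves_cells(self):
        rng = np.random.default_rng(1)
        s = rng.random(1000)
        bins = bin_axis(s, 50)
        assert np.bincount(bins, minlength=51)[1:].sum() == 1000


class TestCellTypeBins:
    def test_row_scaling_by_max(self):
        bins = np.array([1, 2, 2, 3, 3, 3])  # one type: counts (1, 2, 3) over 3 bins
        types = np.array(["A"] * 6, dtype=object)
        raw, scaled = cell_type_bin_matrix(bins, types, n_bins=3)
        np.testing.assert_allclose(scaled.loc["A"], [1 / 3, 2 / 3, 1.0])

    def test_all_zero_row_stays_zero(self):
        raw, scaled = cell_type_bin_matrix(np.array([1]), np.array(["A"], dtype=object), n_bins=3)
        raw.loc["B"] = 0
        m = raw.max(axis=1).replace(0, 1)
        assert (raw.div(m, axis=0).loc["B"] == 0).all()

    def test_raw_total_equals_cells(self):
        rng = np.random.default_rng(0)
        bins = rng.integers(1, 51, size=400)
        types = rng.choice(["A", "B", "C"], size=400)
        raw, _ = cell_type_bin_matrix(bins, types)
        assert raw.to_numpy().sum() == 400

    def test_z_scale_option(self):
        bins = np.array([1, 2, 2, 3, 3, 3])
        types = np.array(["A"] * 6, dtype=object)
        _, scaled = cell_type_bin_matrix(bins, types, n_bins=3, scale="z")
        assert scaled.loc["A"].mean() == pytest.approx(0.0)


class TestGeneBinProfile:
    def make_norm(self, dense, gene_ids):
        return log_normalize(make_count_matrix(dense, gene_ids=gene_ids))

    def test_constant_gene_flat_profile(self):
        norm = self.make_norm([[5, 5]] * 4, ["g1", "g2"])
        prof = gene_bin_profile(norm, np.array([1, 1, 2, 2]), ["g1"], n_bins=2)
        assert prof.loc["g1", 1] == pytest.approx(prof.loc["g1", 2])

    def test_restricted_gene_nonzero_only_high_bins(self):
        dense = [[1, 0], [1, 0], [1, 5], [1, 5]]
        norm = self.make_norm(dense, ["hk", "marker"])
        prof = gene_bin_profile(norm, np.array([1, 1, 2, 2]), ["marker"], n_bins=2)
        assert prof.loc["marker", 1] == 0.0
        assert prof.loc["marker", 2] > 0

    def test_empty_bin_is_nan(self):
        norm = self.make_norm([[1, 1]], ["g1", "g2"])
        prof = gene_bin_profile(norm, np.array([1]), ["g1"], n_bins=3)
        assert np.isnan(prof.loc["g1", 2])

    def test_metagene_linearity(self):
        rng = np.random.default_rng(3)
        dense = rng.integers(0, 6, size=(20, 3))
        norm = self.make_norm(dense, ["a", "b", "c"])
        bins = rng.integers(1, 5, size=20)
        prof = gene_bin_profile(norm, bins, ["a", "b"], n_bins=4)
        summed = prof.loc["a"] + prof.loc["b"]
        # mean of a sum = sum of means at fixed bin membership
        vals = np.asarray(norm.values[:, [0, 1]].todense()).sum(axis=1)
        expected = pd.Series(
            {b: vals[bins == b].mean() if (bins == b).any() else np.nan for b in range(1, 5)}
        )
        np.testing.assert_allclose(summed.to_numpy(float), expected.to_numpy(float))

    def test_unknown_gene_rejected(self):
        norm = self.make_norm([[1]], ["g1"])
        with pytest.raises(KeyError):
            gene_bin_profile(norm, np.array([1]), ["nope"], n_bins=1)


class TestDensityMap:
    def test_single_cell_single_pixel(self):
        dm = or_density_map(np.array([[10.0, 10.0]]), np.array([5.0]), pixel_size=20.0)
        assert dm.grid.sum() == pytest.approx(5.0)
        assert (dm.grid > 0).sum() == 1

    def test_unsmoothed_conserves_total(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 200, size=(100, 2))
        tot = rng.integers(0, 10, size=100).astype(float)
        dm = or_density_map(pos, tot, pixel_size=10.0)
        assert dm.grid.sum() == pytest.approx(tot.sum())

    def test_smoothing_conserves_interior_mass(self):
        # mass far from the boundary: Gaussian smoothing keeps it in-grid
        pos = np.array([[500.0, 500.0]])
        pad = np.concatenate([pos, [[0.0, 0.0]], [[1000.0, 1000.0]]])
        tot = np.array([100.0, 0.0, 0.0])
        dm = or_density_map(pad, tot, pixel_size=10.0, bandwidth=20.0)
        assert dm.grid.sum() == pytest.approx(100.0, rel=1e-3)

    def test_nonpositive_pixel_rejected(self):
        with pytest.raises(ValueError):
            or_density_map(np.array([[0.0, 0.0]]), np.array([1.0]), pixel_size=0.0)

    def test_empty_or_panel_all_zero(self):
        dm = or_density_map(np.array([[0.0, 0.0], [5.0, 5.0]]), np.zeros(2), pixel_size=1.0)
        assert dm.grid.sum() == 0


class TestSpatialDominanceSummary:
    def make_summary(self, scores):
        return pd.DataFrame({"dominance_score": scores})

    def test_no_cell_exceeds_threshold(self):
        out = spatial_high_dominance_summary(
            self.make_summary([1.0, 2.0]), np.array(["A", "B"], dtype=object), threshold=3.0
        )
        assert (out == 0).all()

    def test_threshold_zero_counts_positive_scores(self):
        out = spatial_high_dominance_summary(
            self.make_summary([0.0, 0.5, 2.0]), np.array(["A", "A", "A"], dtype=object),
            threshold=0.0,
        )
        assert out["A"] == 2

    def test_partition_additivity(self):
        scores = self.make_summary([4.0, 4.0, 4.0, 4.0])
        types = np.array(["A", "A", "B", "B"], dtype=object)
        left = np.array([True, True, False, False])
        full = spatial_high_dominance_summary(scores, types)
        a = spatial_high_dominance_summary(scores, types, domain_mask=left)
        b = spatial_high_dominance_summary(scores, types, domain_mask=~left)
        assert ((a + b) == full).all()
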