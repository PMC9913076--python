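"""Texture-matrix constructors against brute-force enumeration, plus the
bookkeeping invariants of the aggregation algebra."""

import numpy as np
import pytest

from texagg import texmat
from texagg.features import glcm_features
from texagg.phantom import fixture_grid

from _oracles import bf_glcm, bf_glrlm, bf_ngldm, bf_ngtdm, bf_zones


def zones_to_matrix(zones, n_bins, kind):
    col = 1 if kind == "size" else 2
    width = max(z[col] for z in zones)
    M = np.zeros((n_bins, width))
    for z in zones:
        M[z[0] - 1, z[col] - 1] += 1
    return M


def roi_slices(voi):
    return [z for z in range(voi.mask.shape[0]) if voi.mask[z].any()]


class TestDirections:
    def test_in_plane_set(self):
        dirs = texmat.directions_2d()
        assert len(dirs) == 4
        assert all(d.offset[0] == 0 for d in dirs)
        full = {d.offset for d in dirs} | {tuple(-c for c in d.offset) for d in dirs}
        assert len(full) == 8

    def test_three_d_set(self):
        dirs = texmat.directions_3d()
        assert len(dirs) == 13
        offs = {d.offset for d in dirs}
        assert len(offs | {tuple(-c for c in o) for o in offs}) == 26
        assert not any(tuple(-c for c in o) in offs for o in offs)

    def test_chebyshev_norm_enforced(self):
        with pytest.raises(ValueError):
            texmat.Direction((0, 0, 2))


class TestOracleEquivalence:
    """Every constructor must agree exactly with naive enumeration."""

    def test_glcm(self, rand_voi):
        for z in roi_slices(rand_voi):
            for d in texmat.directions_2d():
                got = texmat.glcm_unit(rand_voi, z, d)
                ref = bf_glcm(rand_voi.grey[z : z + 1], rand_voi.mask[z : z + 1], d.offset, rand_voi.n_bins)
                np.testing.assert_array_equal(got.counts, ref)
        for d in texmat.directions_3d():
            got = texmat.glcm_unit(rand_voi, None, d)
            ref = bf_glcm(rand_voi.grey, rand_voi.mask, d.offset, rand_voi.n_bins)
            np.testing.assert_array_equal(got.counts, ref)

    def test_glrlm(self, rand_voi):
        for z in roi_slices(rand_voi):
            for d in texmat.directions_2d():
                got = texmat.glrlm_unit(rand_voi, z, d)
                ref = bf_glrlm(rand_voi.grey[z : z + 1], rand_voi.mask[z : z + 1], d.offset, rand_voi.n_bins)
                np.testing.assert_array_equal(got.counts[:, : ref.shape[1]], ref)
                assert got.counts[:, ref.shape[1] :].sum() == 0
        for d in texmat.directions_3d():
            got = texmat.glrlm_unit(rand_voi, None, d)
            ref = bf_glrlm(rand_voi.grey, rand_voi.mask, d.offset, rand_voi.n_bins)
            np.testing.assert_array_equal(got.counts[:, : ref.shape[1]], ref)

    @pytest.mark.parametrize("kind", ["size", "distance"])
    def test_zone_matrices(self, rand_voi, kind):
        ctor = texmat.glszm_unit if kind == "size" else texmat.gldzm_unit
        for z in roi_slices(rand_voi):
            zones = bf_zones(rand_voi.grey[z : z + 1], rand_voi.mask[z : z + 1], two_d=True)
            ref = zones_to_matrix(zones, rand_voi.n_bins, kind)
            got = ctor(rand_voi, z).counts
            np.testing.assert_array_equal(got[:, : ref.shape[1]], ref)
        zones = bf_zones(rand_voi.grey, rand_voi.mask, two_d=False)
        ref = zones_to_matrix(zones, rand_voi.n_bins, kind)
        got = ctor(rand_voi, None).counts
        np.testing.assert_array_equal(got[:, : ref.shape[1]], ref)

    def test_ngtdm(self, rand_voi):
        for z in roi_slices(rand_voi):
            ref = bf_ngtdm(rand_voi.grey[z : z + 1], rand_voi.mask[z : z + 1], True, rand_voi.n_bins)
            got = texmat.ngtdm_unit(rand_voi, z).counts
            np.testing.assert_allclose(got, ref, atol=1e-12)
        ref = bf_ngtdm(rand_voi.grey, rand_voi.mask, False, rand_voi.n_bins)
        np.testing.assert_allclose(texmat.ngtdm_unit(rand_voi, None).counts, ref, atol=1e-12)

    def test_ngldm(self, rand_voi):
        for z in roi_slices(rand_voi):
            ref = bf_ngldm(rand_voi.grey[z : z + 1], rand_voi.mask[z : z + 1], True, rand_voi.n_bins)
            got = texmat.ngldm_unit(rand_voi, z).counts
            np.testing.assert_array_equal(got[:, : ref.shape[1]], ref)
        ref = bf_ngldm(rand_voi.grey, rand_voi.mask, False, rand_voi.n_bins)
        got = texmat.ngldm_unit(rand_voi, None).counts
        np.testing.assert_array_equal(got[:, : ref.shape[1]], ref)

    def test_fixtures_match_oracle_too(self, fixture_voi):
        for d in texmat.directions_3d():
            np.testing.assert_array_equal(
                texmat.glcm_unit(fixture_voi, None, d).counts,
                bf_glcm(fixture_voi.grey, fixture_voi.mask, d.offset, fixture_voi.n_bins),
            )


class TestHandExamples:
    def test_glcm_row112(self):
        voi, _ = fixture_grid("row-112")
        tm = texmat.glcm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        assert tm.counts[0, 0] == 2 and tm.counts[0, 1] == 1 and tm.counts[1, 0] == 1
        assert tm.total() == 4

    def test_glcm_constant_3x3(self):
        voi, _ = fixture_grid("constant-3x3")
        tm = texmat.glcm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        assert tm.counts[0, 0] == 12 and tm.total() == 12

    def test_glcm_empty_unit_flagged(self):
        voi, _ = fixture_grid("single-voxel")
        assert texmat.glcm_unit(voi, 0, texmat.Direction((0, 0, 1))).empty

    def test_glrlm_row112(self):
        voi, _ = fixture_grid("row-112")
        tm = texmat.glrlm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        assert tm.counts[0, 1] == 1 and tm.counts[1, 0] == 1

    def test_glrlm_mask_breaks_run(self):
        grey = np.array([[[1, 1, 1, 1]]], dtype=np.int32)
        mask = np.array([[[1, 1, 0, 1]]], dtype=bool)
        grey[~mask] = 0
        from texagg.image import DiscretizedVOI

        voi = DiscretizedVOI(grey, mask, 1, 0, 1)
        tm = texmat.glrlm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        assert tm.counts[0, 1] == 1 and tm.counts[0, 0] == 1

    def test_glszm_l_shape(self):
        from texagg.image import DiscretizedVOI

        grid = np.array([[[1, 1], [1, 2]]], dtype=np.int32)
        voi = DiscretizedVOI(grid, grid > 0, 2, 0, 1)
        tm = texmat.glszm_unit(voi, 0)
        assert tm.counts[0, 2] == 1 and tm.counts[1, 0] == 1

    def test_checkerboard_diagonal_zones(self):
        voi, _ = fixture_grid("checkerboard-2x2")
        tm = texmat.glszm_unit(voi, 0)
        # 8-connectivity joins the diagonals: one zone of size 2 per grey
        assert tm.counts[0, 1] == 1 and tm.counts[1, 1] == 1

    def test_gldzm_single_voxel_border_distance(self):
        voi, _ = fixture_grid("single-voxel")
        tm = texmat.gldzm_unit(voi, 0)
        assert tm.counts[0, 0] == 1  # one zone at distance 1

    def test_ngtdm_hand_means(self):
        from texagg.image import DiscretizedVOI

        grid = np.array([[[1, 1], [1, 2]]], dtype=np.int32)
        voi = DiscretizedVOI(grid, grid > 0, 2, 0, 1)
        tm = texmat.ngtdm_unit(voi, 0)
        np.testing.assert_allclose(tm.counts[:, 1], [1.0, 1.0])
        np.testing.assert_allclose(tm.counts[:, 0], [3.0, 1.0])

    def test_ngtdm_single_voxel_empty(self):
        voi, _ = fixture_grid("single-voxel")
        assert texmat.ngtdm_unit(voi, 0).empty

    def test_ngldm_constant_3x3_columns(self):
        voi, _ = fixture_grid("constant-3x3")
        tm = texmat.ngldm_unit(voi, 0)
        assert tm.counts[0, 3] == 4 and tm.counts[0, 5] == 4 and tm.counts[0, 8] == 1

    def test_ngldm_checkerboard_all_k1(self):
        voi, _ = fixture_grid("checkerboard-2x2")
        tm = texmat.ngldm_unit(voi, 0)
        assert tm.counts[:, 1].sum() == 4 and tm.total() == 4

    def test_ngldm_single_voxel(self):
        voi, _ = fixture_grid("single-voxel")
        tm = texmat.ngldm_unit(voi, 0)
        assert tm.counts[0, 0] == 1


class TestInvariants:
    def test_glcm_symmetry(self, rand_voi):
        for d in texmat.directions_3d():
            tm = texmat.glcm_unit(rand_voi, None, d)
            np.testing.assert_array_equal(tm.counts, tm.counts.T)

    def test_run_bookkeeping(self, rand_voi):
        """Sum of (length x count) equals the in-ROI voxel tally per direction."""
        for d in texmat.directions_3d():
            tm = texmat.glrlm_unit(rand_voi, None, d)
            lengths = np.arange(1, tm.counts.shape[1] + 1)
            assert (tm.counts * lengths).sum() == rand_voi.n_voxels

    def test_zone_bookkeeping(self, rand_voi):
        """GLSZM and GLDZM have identical grey-level marginals per unit."""
        s = texmat.glszm_unit(rand_voi, None)
        d = texmat.gldzm_unit(rand_voi, None)
        np.testing.assert_array_equal(s.counts.sum(axis=1), d.counts.sum(axis=1))

    def test_merge_conserves_totals(self, rand_voi):
        units = [texmat.glcm_unit(rand_voi, None, d) for d in texmat.directions_3d()]
        merged = texmat.merge(units)
        assert merged.total() == sum(u.total() for u in units)
        np.testing.assert_array_equal(merged.counts, merged.counts.T)

    def test_merge_singleton_and_linearity(self):
        voi, _ = fixture_grid("row-112")
        tm = texmat.glcm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        np.testing.assert_array_equal(texmat.merge([tm]).counts, tm.counts)
        np.testing.assert_array_equal(texmat.merge([tm, tm, tm]).counts, 3 * tm.counts)

    def test_merge_rejects_mixed_families(self):
        voi, _ = fixture_grid("row-112")
        a = texmat.glcm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        b = texmat.glrlm_unit(voi, 0, texmat.Direction((0, 0, 1)))
        with pytest.raises(ValueError):
            texmat.merge([a, b])


class TestAggregate:
    def test_two_slice_entropy_sensitivity(self):
        """Averaged 2D sees two constant slices (entropy 0); the merged 2.5D
        matrix holds two equal-mass grey levels (entropy 1 bit)."""
        voi, _ = fixture_grid("two-slice-constant")
        avg = texmat.aggregate(voi, "GLCM", "2D_averaged", glcm_features)
        merged = texmat.aggregate(voi, "GLCM", "2.5D_merged", glcm_features)
        assert avg["joint_entropy"] == 0.0
        assert merged["joint_entropy"] == pytest.approx(1.0)

    def test_single_slice_methods_coincide(self):
        voi, _ = fixture_grid("row-112")
        vals = [
            texmat.aggregate(voi, "GLCM", m, glcm_features)
            for m in ("2D_averaged", "2.5D_d_merged")
        ]
        per_slice = texmat.aggregate(voi, "GLCM", "2D_s_merged", glcm_features)
        for k in vals[0]:
            assert vals[0][k] == pytest.approx(vals[1][k])

    def test_identical_units_average_equals_merge(self):
        """With identical unit matrices the normalized merged matrix coincides
        with each unit, so averaged == merged for every feature."""
        voi, _ = fixture_grid("constant-3x3")
        a = texmat.aggregate(voi, "GLCM", "2D_averaged", glcm_features)
        m = texmat.aggregate(voi, "GLCM", "2.5D_merged", glcm_features)
        for k in a:
            assert a[k] == pytest.approx(m[k], abs=1e-12)

    def test_illegal_method_rejected(self):
        voi, _ = fixture_grid("row-112")
        with pytest.raises(ValueError):
            texmat.aggregate(voi, "GLSZM", "2D_averaged", glcm_features)

    def test_method_catalogue(self):
        assert len(texmat.methods_for_family("GLCM")) == 6
        assert len(texmat.methods_for_family("GLRLM")) == 6
        for fam in ("GLSZM", "GLDZM", "NGTDM", "NGLDM"):
            assert texmat.methods_for_family(fam) == ("2D", "2.5D", "3D")
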