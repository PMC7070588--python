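import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulescan import BinaryMap, GridGeometry, IndexMap, binarize, fuse, oversample


def _imap(values, pitch=2.0, kind="cia"):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(pitch=pitch, n_x=values.shape[1], n_y=values.shape[0])
    return IndexMap(values=values, geometry=geom, kind=kind)


def optimal_two_partition(values):
    """Exhaustive 1-D two-cluster split minimizing within-cluster variance.

    Independent oracle for the k-means binarization: sort, try every split
    point, return the boolean mask of the upper cluster.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    s = values[order]
    best_sse, best_k = np.inf, None
    for k in range(1, s.size):
        lo, hi = s[:k], s[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse - 1e-15:
            best_sse, best_k = sse, k
    mask = np.zeros(values.size, dtype=bool)
    mask[order[best_k:]] = True
    return mask


class TestOversample:
    def test_subpixel_count_matches_grid_arithmetic(self):
        # 378 native points at 6x oversampling -> 13,608 classified sub-pixels
        imap = _imap(np.random.default_rng(0).random((21, 18)))
        assert imap.geometry.n_points == 378
        over = oversample(imap, 6)
        assert over.values.size == 13608
        assert over.geometry.pitch == pytest.approx(2.0 / 6.0)

    def test_constant_map_stays_constant(self):
        over = oversample(_imap(np.full((4, 5), 0.37)), 6)
        np.testing.assert_allclose(over.values, 0.37)

    def test_bilinear_weights_by_hand(self):
        # native cells 0 and 1 along x; factor-2 sub-pixels sit 1/4 of a cell
        # either side of the midpoint: bilinear values 0.25 and 0.75
        over = oversample(_imap([[0.0, 1.0]]), 2)
        np.testing.assert_allclose(over.values,
                                   [[0.0, 0.25, 0.75, 1.0]] * 2)

    def test_nearest_replicates_blocks(self):
        over = oversample(_imap([[0.0, 1.0]]), 3, method="nearest")
        np.testing.assert_allclose(over.values, [[0, 0, 0, 1, 1, 1]] * 3)

    def test_block_average_recovers_native_interior(self):
        # for a smooth field, averaging the sub-pixels of each native cell
        # must give back the native value to interpolation accuracy
        jj, ii = np.mgrid[0:6, 0:7]
        imap = _imap(0.5 + 0.4 * np.sin(ii / 3.0) * np.cos(jj / 4.0))
        over = oversample(imap, 6)
        back = over.values.reshape(6, 6, 7, 6).mean(axis=(1, 3))
        np.testing.assert_allclose(back[1:-1, 1:-1], imap.values[1:-1, 1:-1],
                                   atol=0.02)

    def test_invalid_factor_raises(self):
        with pytest.raises(ValueError, match="factor"):
            oversample(_imap([[0.0, 1.0]]), 0)


class TestBinarize:
    def test_well_separated_values_split_as_oracle_says(self):
        values = np.array([[0.0, 0.01, 0.02, 0.8, 0.9]])
        bmap = binarize(_imap(values))
        np.testing.assert_array_equal(bmap.mask.ravel(),
                                      optimal_two_partition(values.ravel()))
        np.testing.assert_array_equal(bmap.mask, [[False, False, False, True, True]])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kmeans_matches_exhaustive_partition(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.normal(0.15, 0.05, 40),
                                 rng.normal(0.7, 0.08, 20)]).clip(0, 1)
        bmap = binarize(_imap(values.reshape(4, 15)))
        np.testing.assert_array_equal(bmap.mask.ravel(),
                                      optimal_two_partition(values))

    def test_constant_map_is_all_background(self):
        with pytest.warns(UserWarning, match="constant"):
            bmap = binarize(_imap(np.full((3, 4), 0.5)))
        assert not bmap.mask.any()

    def test_bimodal_mixture_threshold_and_misassignment(self):
        rng = np.random.default_rng(42)
        lo = rng.normal(0.1, 0.05, 500)
        hi = rng.normal(0.7, 0.05, 500)
        values = np.concatenate([lo, hi]).clip(0, 1).reshape(20, 50)
        truth = np.concatenate([np.zeros(500, bool), np.ones(500, bool)])
        km = binarize(_imap(values), method="kmeans")
        assert 0.25 < km.threshold < 0.55
        assert (km.mask.ravel() != truth).mean() < 0.01
        # Otsu places its threshold somewhere in the same inter-mode gap and
        # must classify the bimodal fixture identically
        otsu = binarize(_imap(values), method="otsu")
        np.testing.assert_array_equal(otsu.mask, km.mask)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="method"):
            binarize(_imap(np.random.default_rng(0).random((3, 4))), method="magic")


def _bmap(mask, pitch=1.0):
    mask = np.asarray(mask, dtype=bool)
    geom = GridGeometry(pitch=pitch, n_x=mask.shape[1], n_y=mask.shape[0])
    return BinaryMap(mask=mask, geometry=geom, source="test")


class TestFuse:
    def test_disjoint_masks(self):
        a = _bmap([[1, 0, 0]])
        b = _bmap([[0, 0, 1]])
        assert not fuse(a, b, "and").mask.any()
        np.testing.assert_array_equal(fuse(a, b, "or").mask, [[True, False, True]])

    def test_identical_masks_fixed_point(self):
        a = _bmap([[1, 0], [0, 1]])
        np.testing.assert_array_equal(fuse(a, a, "and").mask, a.mask)
        np.testing.assert_array_equal(fuse(a, a, "or").mask, a.mask)

    @given(st.integers(0, 2 ** 12 - 1), st.integers(0, 2 ** 12 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_lattice_property(self, bits_a, bits_b):
        a = _bmap(np.array([(bits_a >> k) & 1 for k in range(12)]).reshape(3, 4))
        b = _bmap(np.array([(bits_b >> k) & 1 for k in range(12)]).reshape(3, 4))
        land = fuse(a, b, "and").mask
        lor = fuse(a, b, "or").mask
        for m in (a.mask, b.mask):
            assert np.all(land <= m) and np.all(m <= lor)
        assert land.sum() <= min(a.mask.sum(), b.mask.sum())
        assert lor.sum() >= max(a.mask.sum(), b.mask.sum())

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError, match="geometry"):
            fuse(_bmap([[1, 0]]), _bmap([[1, 0]], pitch=2.0), "or")
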