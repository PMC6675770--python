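"""Luminance computation and luminance-matched sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromosep import luminance, luminance_matched_sample
from chromosep.base import ChromosepError, InfeasibleSamplingError
from chromosep.config import LUMINANCE_WEIGHTS
from chromosep.sampling import _largest_remainder

from chromosep import generate_lesion_image
from conftest import make_lesion_spec


class TestLuminance:
    @given(st.floats(min_value=0, max_value=255))
    def test_gray_identity(self, v):
        assert luminance((v, v, v)) == pytest.approx(v, abs=1e-9)

    def test_pure_red_under_bt601(self):
        assert luminance((255, 0, 0)) == pytest.approx(76.245, abs=1e-9)

    def test_black_is_zero(self):
        assert luminance((0, 0, 0)) == 0.0

    def test_out_of_range_component_rejected(self):
        with pytest.raises(ChromosepError):
            luminance((256, 0, 0))
        with pytest.raises(ChromosepError):
            luminance((-1, 0, 0))

    def test_bt709_weights_selectable(self):
        got = luminance((255, 0, 0), weights=LUMINANCE_WEIGHTS["bt709"])
        assert got == pytest.approx(0.2126 * 255, abs=1e-9)

    def test_vectorized_matches_scalar(self):
        arr = np.array([[10.0, 20.0, 30.0], [200.0, 100.0, 50.0]])
        got = luminance(arr)
        assert got.shape == (2,)
        assert got[0] == pytest.approx(luminance(arr[0]))


class TestLargestRemainder:
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2,
                    max_size=20).filter(lambda c: sum(c) > 0),
           st.data())
    @settings(deadline=None)
    def test_allocation_sums_and_respects_capacity(self, capacity, data):
        capacity = np.asarray(capacity)
        total = data.draw(st.integers(min_value=1,
                                      max_value=int(capacity.sum())))
        quotas = total * capacity / capacity.sum()
        alloc = _largest_remainder(quotas, total)
        assert alloc.sum() == total
        assert np.all(alloc <= capacity)
        assert np.all(alloc >= 0)

    def test_tie_breaks_to_lower_bin(self):
        # two equal remainders, one unit to distribute -> lower index wins
        alloc = _largest_remainder(np.array([1.5, 1.5]), 3)
        assert alloc.tolist() == [2, 1]


def _coords(n):
    return np.column_stack([np.arange(n), np.zeros(n, int)])


class TestLuminanceMatchedSample:
    def test_single_gray_value_fills_requested_counts(self):
        """Both classes concentrated at one luminance: the full 2000+2000
        protocol draw succeeds from a single bin (4000 pixels in total)."""
        c = np.full((2500, 3), 100.0)
        n = np.full((3000, 3), 100.0)
        sc, sn = luminance_matched_sample(c, _coords(2500), n, _coords(3000),
                                          n_per_class=2000, seed=0)
        assert sc.n == 2000 and sn.n == 2000
        assert sc.n + sn.n == 4000

    def test_disjoint_luminance_supports_are_infeasible(self):
        dark = np.full((500, 3), 10.0)
        bright = np.full((500, 3), 240.0)
        with pytest.raises(InfeasibleSamplingError) as exc:
            luminance_matched_sample(dark, _coords(500), bright, _coords(500),
                                     n_per_class=100, seed=0)
        assert exc.value.achievable == 0

    def test_error_reports_achievable_maximum(self):
        shared = np.full((50, 3), 100.0)
        c = np.vstack([shared, np.full((500, 3), 10.0)])
        n = np.vstack([shared, np.full((500, 3), 240.0)])
        with pytest.raises(InfeasibleSamplingError) as exc:
            luminance_matched_sample(c, _coords(550), n, _coords(550),
                                     n_per_class=100, seed=0)
        assert exc.value.achievable == 50

    def _random_classes(self, seed, n=3000):
        rng = np.random.default_rng(seed)
        c = np.clip(rng.normal((140, 90, 85), 15, (n, 3)), 0, 255)
        nn = np.clip(rng.normal((120, 100, 95), 15, (n, 3)), 0, 255)
        return c, nn

    def test_per_bin_counts_match_by_independent_recount(self):
        c, n = self._random_classes(1)
        sc, sn = luminance_matched_sample(c, _coords(len(c)), n,
                                          _coords(len(n)), n_per_class=100,
                                          n_bins=8, seed=5)
        edges = np.linspace(0, 255, 9)
        hist_c, _ = np.histogram(sc.luminances, bins=edges)
        hist_n, _ = np.histogram(sn.luminances, bins=edges)
        assert hist_c.tolist() == hist_n.tolist()
        assert hist_c.sum() == 100

    def test_mean_luminance_difference_within_bin_width(self):
        c, n = self._random_classes(2)
        sc, sn = luminance_matched_sample(c, _coords(len(c)), n,
                                          _coords(len(n)), n_per_class=500,
                                          n_bins=32, seed=5)
        assert abs(sc.luminances.mean() - sn.luminances.mean()) <= 255 / 32

    def test_no_replacement_within_class(self):
        spec = make_lesion_spec(image_size=(128, 128))
        image, mask = generate_lesion_image(spec)
        rows, cols = np.nonzero(mask == 255)
        c_rgb = image[rows, cols].astype(float)
        c_coords = np.column_stack([rows, cols])
        rows, cols = np.nonzero(mask == 0)
        n_rgb = image[rows, cols].astype(float)
        n_coords = np.column_stack([rows, cols])
        sc, sn = luminance_matched_sample(c_rgb, c_coords, n_rgb, n_coords,
                                          n_per_class=1000, seed=3)
        for s in (sc, sn):
            assert len({tuple(xy) for xy in s.coords}) == s.n

    def test_seed_determinism_and_sensitivity(self):
        c, n = self._random_classes(3)
        args = (c, _coords(len(c)), n, _coords(len(n)))
        a = luminance_matched_sample(*args, n_per_class=200, seed=7)
        b = luminance_matched_sample(*args, n_per_class=200, seed=7)
        other = luminance_matched_sample(*args, n_per_class=200, seed=8)
        assert np.array_equal(a[0].coords, b[0].coords)
        assert np.array_equal(a[1].rgb, b[1].rgb)
        assert not np.array_equal(a[0].coords, other[0].coords)

    def test_samples_property_materializes_records(self):
        c, n = self._random_classes(4)
        sc, _ = luminance_matched_sample(c, _coords(len(c)), n,
                                         _coords(len(n)), n_per_class=10,
                                         seed=0)
        records = sc.samples
        assert len(records) == 10
        assert records[0].luminance == pytest.approx(
            luminance(records[0].rgb))
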