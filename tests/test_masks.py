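import numpy as np
import pytest
from helpers import brute_expand
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroskin import (
    RasterMask,
    basement_membrane,
    derive_subepidermis,
    expand_mask,
    mask_area,
    resolve_overlap,
)
from conftest import straight_masks


def random_mask(seed, shape=(32, 32), density=0.1, pixel_size=1.0):
    rng = np.random.default_rng(seed)
    return RasterMask(rng.random(shape) < density, pixel_size)


class TestExpandMask:
    def test_zero_distance_is_identity(self):
        m = random_mask(0)
        out = expand_mask(m, 0.0)
        assert np.array_equal(out.grid, m.grid)

    def test_empty_mask_stays_empty(self):
        m = RasterMask(np.zeros((20, 20), bool), 1.0)
        assert expand_mask(m, 50.0).n_foreground == 0

    def test_single_pixel_becomes_lattice_disk(self):
        # lattice points with dx^2 + dy^2 <= 25 around one center: 81 pixels
        grid = np.zeros((21, 21), bool)
        grid[10, 10] = True
        out = expand_mask(RasterMask(grid, 1.0), 5.0)
        assert out.n_foreground == 81

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="distance"):
            expand_mask(random_mask(1), -1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), radius=st.sampled_from([0.0, 1.0, 2.5, 5.0]))
    def test_matches_bruteforce_distance_oracle(self, seed, radius):
        m = random_mask(seed)
        expected = brute_expand(m.grid, radius)
        assert np.array_equal(expand_mask(m, radius).grid, expected)

    def test_physical_units_respected(self):
        # 5 um at 0.61 um/px reaches 8.19 px: compare against the px oracle
        m = random_mask(3, pixel_size=0.61)
        expected = brute_expand(m.grid, 5.0 / 0.61)
        assert np.array_equal(expand_mask(m, 5.0).grid, expected)

    def test_monotone_in_distance(self):
        m = random_mask(5)
        small = expand_mask(m, 2.0).grid
        large = expand_mask(m, 4.0).grid
        assert not (small & ~large).any()


class TestSubepidermis:
    def test_vertical_band_geometry(self, straight_interface):
        epi, dermis = straight_interface
        band = derive_subepidermis(epi, dermis, 50.0)
        rows = np.where(band.grid.any(axis=1))[0]
        assert rows.min() == 10 and rows.max() == 59
        assert band.area_um2 == pytest.approx(5000.0)

    def test_empty_dermis_gives_empty_band(self, straight_interface):
        epi, _ = straight_interface
        empty = RasterMask(np.zeros_like(epi.grid), epi.pixel_size_um)
        assert derive_subepidermis(epi, empty, 50.0).n_foreground == 0

    def test_zero_distance_gives_empty_band(self, straight_interface):
        epi, dermis = straight_interface
        assert derive_subepidermis(epi, dermis, 0.0).n_foreground == 0

    def test_band_never_exceeds_dermis_nor_touches_epidermis(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            boundary = rng.integers(5, 20)
            epi, dermis = straight_masks(boundary=boundary)
            band = derive_subepidermis(epi, dermis, float(rng.integers(1, 80)))
            assert not (band.grid & ~dermis.grid).any()
            assert not (band.grid & epi.grid).any()

    def test_overlapping_inputs_rejected_with_count(self, straight_interface):
        epi, _ = straight_interface
        overlapping = RasterMask(np.ones_like(epi.grid), 1.0)
        with pytest.raises(ValueError, match=r"overlap in 1000 pixels"):
            derive_subepidermis(epi, overlapping)

    def test_resolve_overlap_makes_inputs_usable(self, straight_interface):
        epi, _ = straight_interface
        overlapping = RasterMask(np.ones_like(epi.grid), 1.0)
        epi2, dermis2 = resolve_overlap(epi, overlapping)
        assert not (epi2.grid & dermis2.grid).any()
        derive_subepidermis(epi2, dermis2)  # no longer raises

    def test_shape_mismatch_rejected(self, straight_interface):
        epi, _ = straight_interface
        other = RasterMask(np.zeros((10, 10), bool), 1.0)
        with pytest.raises(ValueError, match="shape"):
            derive_subepidermis(epi, other)


class TestBasementMembrane:
    def test_straight_interface_length(self, straight_interface):
        epi, dermis = straight_interface
        bm = basement_membrane(epi, dermis)
        assert bm.length_mm == pytest.approx(0.100, rel=1e-9)
        assert len(bm.polylines) == 1

    def test_rotation_invariance(self, straight_interface):
        epi, dermis = straight_interface
        ref = basement_membrane(epi, dermis).length_mm
        rot = basement_membrane(
            RasterMask(np.rot90(epi.grid).copy(), 1.0),
            RasterMask(np.rot90(dermis.grid).copy(), 1.0),
        ).length_mm
        assert rot == pytest.approx(ref)

    def test_translation_invariance(self):
        epi, dermis = straight_masks(height=60, boundary=10)
        ref = basement_membrane(epi, dermis).length_mm
        shifted_epi, shifted_dermis = straight_masks(height=60, boundary=25)
        assert basement_membrane(shifted_epi, shifted_dermis).length_mm == pytest.approx(ref)

    def test_length_scales_with_pixel_size(self):
        epi1, der1 = straight_masks(pixel_size=1.0)
        epi2, der2 = straight_masks(pixel_size=0.61)
        l1 = basement_membrane(epi1, der1).length_mm
        l2 = basement_membrane(epi2, der2).length_mm
        assert l2 == pytest.approx(0.61 * l1)

    def test_no_adjacency_is_an_error(self):
        e = np.zeros((50, 50), bool)
        d = np.zeros((50, 50), bool)
        e[:5, :5] = True
        d[45:, 45:] = True
        with pytest.raises(ValueError, match="no basement membrane"):
            basement_membrane(RasterMask(e, 1.0), RasterMask(d, 1.0))

    def test_band_lies_in_dermis_adjacent_to_epidermis(self, straight_interface):
        epi, dermis = straight_interface
        bm = basement_membrane(epi, dermis)
        assert not (bm.band.grid & epi.grid).any()
        assert (bm.band.grid & dermis.grid).sum() == bm.band.n_foreground


class TestMaskArea:
    def test_direct_count(self):
        g = np.zeros((10, 10), bool)
        g.flat[:10] = True
        assert mask_area(RasterMask(g, 1.0)) == pytest.approx(10.0)

    def test_pixel_size_squared(self):
        g = np.zeros((10, 10), bool)
        g.flat[:10] = True
        assert mask_area(RasterMask(g, 0.61)) == pytest.approx(10 * 0.61**2)

    def test_disjoint_roi_gives_zero(self):
        g = np.zeros((10, 10), bool)
        g[0] = True
        roi = np.zeros((10, 10), bool)
        roi[5] = True
        assert mask_area(RasterMask(g, 1.0), RasterMask(roi, 1.0)) == 0.0
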