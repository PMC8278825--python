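"""Dry-mass conversion, stain normalization, masks, histograms and overlaps."""

import numpy as np
import pytest

from picslim import quantify
from picslim.types import PhaseMap


def pm(arr, pitch=1.0):
    return PhaseMap(phi=np.asarray(arr, dtype=float), pixel_pitch=pitch)


class TestStainNormalize:
    def test_identity(self):
        p = pm(np.random.default_rng(0).uniform(0, 1, (4, 4)))
        out = quantify.stain_normalize(p, gain=1.0, offset=0.0)
        assert np.array_equal(out.phi, p.phi)

    def test_affine_matches_elementwise_oracle(self):
        arr = np.array([[0.3, -0.1], [0.8, 0.0]])
        out = quantify.stain_normalize(pm(arr), gain=0.8, offset=-0.05)
        assert np.allclose(out.phi, 0.8 * arr - 0.05)
        assert out.metadata["stain_normalization"] == {"gain": 0.8, "offset": -0.05}

    def test_zero_gain_rejected(self):
        with pytest.raises(ValueError):
            quantify.stain_normalize(pm(np.zeros((2, 2))), gain=0.0)


class TestDryMass:
    def test_closed_form(self):
        out = quantify.phase_to_dry_mass(pm(np.full((3, 3), 2 * np.pi)), 0.55, 0.2)
        assert np.allclose(out.density, 2.75)

    def test_zero_phase_zero_mass(self):
        out = quantify.phase_to_dry_mass(pm(np.zeros((3, 3))))
        assert np.all(out.density == 0.0)

    def test_linearity_and_commutes_with_gain(self):
        arr = np.random.default_rng(2).uniform(0, 2, (5, 5))
        rho1 = quantify.phase_to_dry_mass(pm(arr)).density
        rho2 = quantify.phase_to_dry_mass(pm(2 * arr)).density
        assert np.allclose(rho2, 2 * rho1)
        gained = quantify.stain_normalize(pm(arr), gain=1.7)
        assert np.allclose(quantify.phase_to_dry_mass(gained).density, 1.7 * rho1)

    def test_invalid_constants(self):
        with pytest.raises(ValueError):
            quantify.phase_to_dry_mass(pm(np.zeros((2, 2))), wavelength=-1)
        with pytest.raises(ValueError):
            quantify.phase_to_dry_mass(pm(np.zeros((2, 2))), refractive_increment=0)


class TestMyelinMask:
    def test_fixed_threshold_all_true(self):
        m = quantify.myelin_mask(pm(np.full((4, 4), 0.5)), method="fixed", threshold=0.2)
        assert m.mask.all() and m.threshold == 0.2

    def test_fixed_threshold_above_max(self):
        m = quantify.myelin_mask(pm(np.full((4, 4), 0.5)), method="fixed", threshold=0.9)
        assert not m.mask.any()

    def test_otsu_two_level_image(self):
        arr = np.concatenate([np.full((8, 4), 0.1), np.full((8, 4), 0.9)], axis=1)
        m = quantify.myelin_mask(pm(arr), method="otsu")
        assert 0.1 < m.threshold < 0.9
        assert np.array_equal(m.mask, arr >= 0.5)

    def test_otsu_matches_between_class_variance_scan(self):
        # brute-force oracle: maximize w0*w1*(mu0-mu1)^2 over candidate cuts
        rng = np.random.default_rng(7)
        arr = np.concatenate([rng.normal(0.2, 0.05, 500), rng.normal(1.0, 0.1, 500)])
        arr = arr.reshape(25, 40)
        m = quantify.myelin_mask(pm(arr), method="otsu")
        cands = np.linspace(arr.min(), arr.max(), 512)
        best, best_t = -1, None
        flat = arr.ravel()
        for t in cands:
            lo, hi = flat[flat < t], flat[flat >= t]
            if len(lo) == 0 or len(hi) == 0:
                continue
            v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if v > best:
                best, best_t = v, t
        assert abs(m.threshold - best_t) < 0.05

    def test_otsu_constant_image_all_false(self):
        m = quantify.myelin_mask(pm(np.full((4, 4), 0.3)), method="otsu")
        assert not m.mask.any()

    def test_fixed_requires_threshold(self):
        with pytest.raises(ValueError):
            quantify.myelin_mask(pm(np.zeros((2, 2))), method="fixed")


class TestMaskedStats:
    def test_hand_arithmetic(self):
        mass = quantify.phase_to_dry_mass(pm(np.zeros((4, 5))))
        mass.density[:] = 2.0
        mask_arr = np.zeros((4, 5), bool)
        mask_arr.ravel()[:10] = True
        stats = quantify.masked_dry_mass_stats(
            mass, quantify.MyelinMask(mask=mask_arr, threshold=0, method="fixed")
        )
        assert stats == {
            "total_mass_pg": 20.0, "mean_density": 2.0, "area_um2": 10.0, "pixel_count": 10,
        }

    def test_empty_mask(self):
        mass = quantify.phase_to_dry_mass(pm(np.ones((3, 3))))
        stats = quantify.masked_dry_mass_stats(
            mass, quantify.MyelinMask(mask=np.zeros((3, 3), bool), threshold=9, method="fixed")
        )
        assert stats["pixel_count"] == 0 and stats["total_mass_pg"] == 0.0

    def test_all_true_equals_sum_oracle(self):
        rng = np.random.default_rng(3)
        mass = quantify.phase_to_dry_mass(pm(rng.uniform(0, 1, (6, 6)), pitch=0.5))
        stats = quantify.masked_dry_mass_stats(
            mass, quantify.MyelinMask(mask=np.ones((6, 6), bool), threshold=0, method="fixed")
        )
        assert np.isclose(stats["total_mass_pg"], mass.density.sum() * 0.25)

    def test_shape_mismatch(self):
        mass = quantify.phase_to_dry_mass(pm(np.ones((3, 3))))
        with pytest.raises(ValueError):
            quantify.masked_dry_mass_stats(
                mass, quantify.MyelinMask(mask=np.ones((2, 2), bool), threshold=0, method="fixed")
            )


class TestHistogram:
    def test_constant_map(self):
        h = quantify.phase_histogram(pm(np.full((2, 2), 0.5)), [0.0, 1.0])
        assert list(h.counts) == [4] and list(h.normalized) == [1.0]

    def test_direct_binning(self):
        h = quantify.phase_histogram(pm(np.array([[0.1, 0.1], [0.6, 0.9]])), [0.0, 0.5, 1.0])
        assert list(h.counts) == [2, 2]

    def test_additivity_and_conservation(self):
        p = pm(np.random.default_rng(5).uniform(0, 1, (8, 8)))
        h1 = quantify.phase_histogram(p, np.linspace(0, 1, 11))
        h2 = quantify.phase_histogram([p, p], np.linspace(0, 1, 11))
        assert np.array_equal(h2.counts, 2 * h1.counts)
        assert h1.total == 64

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            quantify.phase_histogram(pm(np.zeros((2, 2))), [0.0, 1.0, 0.5])


class TestOverlap:
    def make_hist(self, counts, edges=None):
        edges = np.arange(len(counts) + 1, dtype=float) if edges is None else edges
        return quantify.PhaseHistogram(bin_edges=edges, counts=np.asarray(counts))

    def test_self_overlap_is_one(self):
        h = self.make_hist([3, 1, 6])
        assert quantify.histogram_overlap(h, h) == 1.0

    def test_disjoint_support_is_zero(self):
        assert quantify.histogram_overlap(self.make_hist([4, 0]), self.make_hist([0, 9])) == 0.0

    def test_binwise_min_fixture(self):
        v = quantify.histogram_overlap(self.make_hist([2, 2]), self.make_hist([1, 3]))
        assert np.isclose(v, 0.75)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(9)
        a = self.make_hist(rng.integers(0, 10, 8))
        b = self.make_hist(rng.integers(0, 10, 8))
        ab, ba = quantify.histogram_overlap(a, b), quantify.histogram_overlap(b, a)
        assert ab == ba and 0.0 <= ab <= 1.0

    def test_differing_edges_rejected(self):
        with pytest.raises(ValueError):
            quantify.histogram_overlap(
                self.make_hist([1, 2]), self.make_hist([1, 2], edges=np.array([0.0, 0.5, 1.0]))
            )


class TestGroupOverlaps:
    CLASSES = ("AGA-CON", "AGA-HF", "SGA-CON", "SGA-HF")

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(11)
        groups = {
            c: [pm(rng.normal(1.0, 0.2, (100, 100)))] for c in self.CLASSES
        }
        table = quantify.group_pairwise_overlaps(groups, np.linspace(0, 2, 65))
        assert len(table) == 6
        assert all(v >= 0.95 for v in table.values())

    def test_disjoint_ranges_zero(self):
        groups = {
            c: [pm(np.full((4, 4), 10.0 * i))] for i, c in enumerate(self.CLASSES)
        }
        table = quantify.group_pairwise_overlaps(groups, np.linspace(-1, 40, 42))
        assert all(v == 0.0 for v in table.values())

    def test_missing_class_named(self):
        groups = {c: [pm(np.zeros((2, 2)))] for c in self.CLASSES[:3]}
        with pytest.raises(ValueError, match="SGA-HF"):
            quantify.group_pairwise_overlaps(groups)
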