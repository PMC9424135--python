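import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from clauseg.metrics import (UndefinedDistanceError, compare_paired, dsc,
                             evaluate_pair, hd95, surface_distances,
                             volumetric_similarity, write_report_csv)
from clauseg.volume import BinaryMask, CompatibilityError
from conftest import random_blob_mask


def brute_force_border(mask):
    """Foreground voxels with a face-adjacent background neighbour
    (out-of-grid counts as background) — independent of the implementation."""
    border = np.zeros_like(mask, dtype=bool)
    fg = np.argwhere(mask)
    for x, y, z in fg:
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < mask.shape[0] and 0 <= ny < mask.shape[1]
                    and 0 <= nz < mask.shape[2]) or not mask[nx, ny, nz]:
                border[x, y, z] = True
                break
    return border


def brute_force_distances(m, p, spacing):
    bm = np.argwhere(brute_force_border(m)) * np.asarray(spacing)
    bp = np.argwhere(brute_force_border(p)) * np.asarray(spacing)
    d = cdist(bm, bp)
    return d.min(axis=1), d.min(axis=0)


class TestVolumetricSimilarity:
    def test_equal_volumes_100(self, rng):
        m = np.zeros((6, 6, 6), dtype=bool)
        p = np.zeros((6, 6, 6), dtype=bool)
        m[0, 0, :3] = True
        p[5, 5, 1:4] = True  # different location, same volume
        assert volumetric_similarity(m, p) == 100.0

    def test_known_value(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        p = np.zeros((10, 10, 10), dtype=bool)
        m.ravel()[:100] = True
        p.ravel()[:80] = True
        assert volumetric_similarity(m, p) == pytest.approx(100 * (1 - 20 / 180))

    def test_one_empty_zero(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1] = True
        assert volumetric_similarity(m, np.zeros_like(m)) == 0.0


class TestDSC:
    def test_identical_100(self, rng):
        m = random_blob_mask(rng, (8, 8, 8))
        assert dsc(m, m) == 100.0

    def test_half_overlap(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        p = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, :4] = True
        p[0, 0, 2:4] = True
        p[0, 1, :2] = True
        assert dsc(m, p) == pytest.approx(100 * 4 / 8)

    def test_disjoint_zero(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        p = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        p[3, 3, 3] = True
        assert dsc(m, p) == 0.0


class TestSurfaceDistances:
    def test_identical_masks_all_zero(self, rng):
        m = random_blob_mask(rng, (10, 10, 10))
        d1, d2 = surface_distances(m, m, (1, 1, 1))
        assert (d1 == 0).all() and (d2 == 0).all()

    def test_single_voxels_known_distance(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        p = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 0] = True
        p[2, 2, 2] = True
        d1, d2 = surface_distances(m, p, (0.5, 0.5, 0.5))
        np.testing.assert_allclose(d1, [1.0])
        np.testing.assert_allclose(d2, [1.0])

    def test_against_brute_force(self, rng):
        for _ in range(50):
            m = random_blob_mask(rng, (12, 12, 12))
            p = random_blob_mask(rng, (12, 12, 12))
            spacing = rng.uniform(0.3, 1.5, size=3)
            d1, d2 = surface_distances(m, p, spacing)
            b1, b2 = brute_force_distances(m, p, spacing)
            np.testing.assert_allclose(d1, np.sort(b1), atol=1e-9)
            np.testing.assert_allclose(d2, np.sort(b2), atol=1e-9)

    def test_empty_mask_raises(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        p = np.zeros((4, 4, 4), dtype=bool)
        p[0, 0, 0] = True
        with pytest.raises(UndefinedDistanceError):
            surface_distances(m, p, (1, 1, 1))


class TestHD95:
    def test_identical_zero(self, rng):
        m = random_blob_mask(rng, (9, 9, 9))
        assert hd95(m, m, (1, 1, 1)) == 0.0

    def test_percentile_interpolation(self):
        # nine zeros and one 10 -> 95th percentile by linear interpolation
        d = np.array([0.0] * 9 + [10.0])
        assert np.percentile(d, 95) == pytest.approx(5.5)

    def test_le_max_hausdorff(self, rng):
        for _ in range(100):
            m = random_blob_mask(rng, (10, 10, 10))
            p = random_blob_mask(rng, (10, 10, 10))
            d1, d2 = surface_distances(m, p, (1, 1, 1))
            full = max(d1.max(), d2.max())
            assert hd95(m, p, (1, 1, 1)) <= full + 1e-12

    def test_spacing_scaling(self, rng):
        m = random_blob_mask(rng, (10, 10, 10))
        p = random_blob_mask(rng, (10, 10, 10))
        h1 = hd95(m, p, (0.5, 0.7, 1.1))
        h2 = hd95(m, p, (1.0, 1.4, 2.2))
        assert h2 == pytest.approx(2 * h1)

    def test_symmetry(self, rng):
        for _ in range(20):
            m = random_blob_mask(rng, (8, 8, 8))
            p = random_blob_mask(rng, (8, 8, 8))
            assert hd95(m, p, (1, 1, 1)) == pytest.approx(hd95(p, m, (1, 1, 1)))

    def test_max_directed_variant(self, rng):
        m = random_blob_mask(rng, (8, 8, 8))
        p = random_blob_mask(rng, (8, 8, 8))
        d1, d2 = surface_distances(m, p, (1, 1, 1))
        expected = max(np.percentile(d1, 95), np.percentile(d2, 95))
        assert hd95(m, p, (1, 1, 1), method="max_directed") == pytest.approx(expected)


def exhaustive_wilcoxon(a, b):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    p_le = (ws <= w_obs).mean()
    p_ge = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestComparePaired:
    def test_identical_scores_degenerate(self):
        p, degenerate = compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and degenerate

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            p, degenerate = compare_paired(a, b)
            assert not degenerate
            assert p == pytest.approx(exhaustive_wilcoxon(a, b), abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert compare_paired(a, b)[0] == pytest.approx(compare_paired(b, a)[0])


class TestEvaluatePair:
    def test_perfect_pair(self, rng):
        m = random_blob_mask(rng, (8, 8, 8))
        rep = evaluate_pair(m, m, (0.5, 0.5, 0.5), "s1")
        assert (rep.vs_percent, rep.hd95_mm, rep.dsc_percent) == (100.0, 0.0, 100.0)

    def test_empty_prediction_conventions(self, rng):
        m = random_blob_mask(rng, (8, 8, 8))
        rep = evaluate_pair(m, np.zeros_like(m), (1, 1, 1), "s2")
        assert rep.vs_percent == 0.0 and rep.dsc_percent == 0.0
        assert not rep.hd95_defined and rep.p_empty and not rep.m_empty

    def test_both_empty_convention(self):
        z = np.zeros((4, 4, 4), dtype=bool)
        rep = evaluate_pair(z, z, (1, 1, 1))
        assert rep.vs_percent == 100.0 and rep.dsc_percent == 100.0
        assert not rep.hd95_defined

    def test_shape_mismatch(self):
        with pytest.raises(CompatibilityError):
            evaluate_pair(np.zeros((3, 3, 3), dtype=bool),
                          np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))

    def test_csv_report(self, tmp_path, rng):
        reports = [evaluate_pair(random_blob_mask(rng, (8, 8, 8)),
                                 random_blob_mask(rng, (8, 8, 8)),
                                 (1, 1, 1), f"s{i}") for i in range(5)]
        out = write_report_csv(reports, tmp_path / "metrics.csv")
        assert len(out) == 6  # 5 subjects + summary row
        assert (tmp_path / "metrics.csv").exists()


class TestMetricSymmetry:
    def test_all_three_symmetric(self, rng):
        for _ in range(20):
            m = random_blob_mask(rng, (9, 9, 9))
            p = random_blob_mask(rng, (9, 9, 9))
            assert volumetric_similarity(m, p) == volumetric_similarity(p, m)
            assert dsc(m, p) == dsc(p, m)
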