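import math

import numpy as np
import pytest
from scipy import ndimage, stats

from clauseg.metrics import dsc
from clauseg.phantom import (PhantomSpec, PhantomSpecError, RaterModel,
                             generate_cohort, generate_phantom, sheet_geometry,
                             simulate_rater, theta_to_weeks, tissue_intensities)


def cap_area_voxels(semi_axes, cap_half_angle_deg):
    """Numerical area of the two lateral caps of an ellipsoidal shell.

    Parametrise the ellipsoid around the x (left-right) axis and integrate
    the surface element on a fine grid — independent of voxelisation.
    """
    a, b, c = semi_axes
    alpha = math.radians(cap_half_angle_deg)
    t = np.linspace(0.0, alpha, 400)          # polar angle from +x axis
    ph = np.linspace(0.0, 2 * math.pi, 400)   # azimuth around x
    t_g, ph_g = np.meshgrid(t, ph, indexing="ij")
    # r(t, ph) = (a cos t, b sin t cos ph, c sin t sin ph)
    dt = t[1] - t[0]
    dp = ph[1] - ph[0]
    rt = np.stack([-a * np.sin(t_g), b * np.cos(t_g) * np.cos(ph_g),
                   c * np.cos(t_g) * np.sin(ph_g)])
    rp = np.stack([np.zeros_like(t_g), -b * np.sin(t_g) * np.sin(ph_g),
                   c * np.sin(t_g) * np.cos(ph_g)])
    cross = np.cross(rt, rp, axis=0)
    area_one = np.sqrt((cross ** 2).sum(axis=0)).sum() * dt * dp
    return 2.0 * area_one  # both hemispheres


@pytest.fixture(scope="module")
def default_grid_phantom():
    spec = PhantomSpec(grid=(96, 96, 96), maturity=1.0, sheet_thickness_vox=2)
    return spec, generate_phantom(spec)


class TestGeneratePhantom:
    def test_deterministic(self):
        spec = PhantomSpec(grid=(48, 48, 48), seed=3)
        v1, m1, a1 = generate_phantom(spec)
        v2, m2, a2 = generate_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert a1 == a2

    def test_background_zero_brain_nonzero(self, small_phantom):
        vol, mask, _ = small_phantom
        assert (vol.data == 0).any()
        assert (vol.data != 0).any()
        # mask lies fully inside the brain
        assert (vol.data[mask.data.astype(bool)] != 0).all()

    def test_mask_count_within_analytic_band(self, default_grid_phantom):
        spec, (_, mask, _) = default_grid_phantom
        geo = sheet_geometry(spec)
        expected = cap_area_voxels(geo["semi_axes_vox"], geo["cap_half_angle_deg"]) \
            * geo["thickness_vox"]
        count = mask.volume_voxels()
        # voxelisation of a thin curved shell is coarse; the analytic
        # surface-times-thickness estimate still brackets the count
        assert 0.5 * expected < count < 1.7 * expected

    def test_noise_free_phantom_has_discrete_levels(self, noise_free_phantom):
        vol, _, _ = noise_free_phantom
        brain_vals = np.unique(vol.data[vol.data != 0])
        levels = tissue_intensities(PhantomSpec(grid=(48, 48, 48), seed=7))
        assert set(np.round(brain_vals, 9)) == {round(v, 9) for v in levels.values()}

    def test_scan_age_map(self):
        assert theta_to_weeks(0.0) == pytest.approx(29.0)
        assert theta_to_weeks(1.0) == pytest.approx(42.0)

    def test_foreground_fraction_small(self, default_grid_phantom):
        # at the default grid the sheets are a sub-percent fraction of brain
        _, (vol, mask, _) = default_grid_phantom
        brain_vox = (vol.data != 0).sum()
        assert mask.volume_voxels() / brain_vox < 0.01

    def test_sheets_thin(self, small_phantom):
        _, mask, _ = small_phantom
        spec_thickness = 2.0
        half = ndimage.distance_transform_edt(mask.data).max()
        assert 2 * half - 1 <= spec_thickness + 1

    def test_t1_polarity_inverts_contrast(self):
        t2 = tissue_intensities(PhantomSpec(maturity=1.0))
        t1 = tissue_intensities(PhantomSpec(maturity=1.0, polarity="t1_like"))
        assert np.sign(t2["sheet"] - t2["white_matter"]) == \
            -np.sign(t1["sheet"] - t1["white_matter"])

    def test_too_small_grid_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(grid=(16, 16, 16))

    def test_bad_maturity_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(maturity=1.5)


class TestGenerateCohort:
    def test_deterministic_and_distinct(self):
        spec = PhantomSpec(grid=(48, 48, 48))
        c1 = generate_cohort(5, spec=spec, seed=9)
        c2 = generate_cohort(5, spec=spec, seed=9)
        for s1, s2 in zip(c1, c2):
            np.testing.assert_array_equal(s1.volume.data, s2.volume.data)
        assert len({s.volume.data.tobytes() for s in c1}) == 5

    def test_age_sampler_controls_gyrification(self):
        spec = PhantomSpec(grid=(48, 48, 48))
        old = generate_cohort(12, age_sampler=(0.85, 0.95), spec=spec, seed=1)
        young = generate_cohort(12, age_sampler=(0.05, 0.15), spec=spec, seed=2)
        amp_old = [s.info["gyrification_amplitude"] for s in old]
        amp_young = [s.info["gyrification_amplitude"] for s in young]
        assert stats.mannwhitneyu(amp_old, amp_young).pvalue < 1e-4
        assert np.mean(amp_old) > np.mean(amp_young)

    def test_ages_recorded(self):
        cohort = generate_cohort(4, age_sampler=(0.5, 1.0),
                                 spec=PhantomSpec(grid=(48, 48, 48)), seed=0)
        for s in cohort:
            assert 35.0 <= s.scan_age_weeks <= 42.0


class TestSimulateRater:
    def test_identity_when_unperturbed(self, small_phantom):
        _, mask, _ = small_phantom
        out = simulate_rater(mask, RaterModel(boundary_jitter_vox=0,
                                              erode_dilate_bias=0, seed=1))
        np.testing.assert_array_equal(out.data, mask.data)

    def test_jitter_decreases_dsc_monotonically(self, small_phantom):
        _, mask, _ = small_phantom
        med = []
        for jitter in (0.5, 1.5, 3.0):
            scores = [dsc(mask.data, simulate_rater(
                mask, RaterModel(boundary_jitter_vox=jitter, seed=s)).data)
                for s in range(10)]
            med.append(np.median(scores))
        assert med[0] > med[1] > med[2]
        assert med[0] < 100.0

    def test_interrater_below_intrarater(self, small_phantom):
        # two independent raters agree less with each other than either
        # does with the reference — the ordering seen in human reliability
        _, mask, _ = small_phantom
        diffs = []
        for s in range(10):
            r1 = simulate_rater(mask, RaterModel(boundary_jitter_vox=1.5, seed=100 + s))
            r2 = simulate_rater(mask, RaterModel(boundary_jitter_vox=1.5, seed=200 + s))
            intra = min(dsc(mask.data, r1.data), dsc(mask.data, r2.data))
            inter = dsc(r1.data, r2.data)
            diffs.append(inter - intra)
        assert np.median(diffs) <= 0

    def test_dilate_bias_grows_volume(self, small_phantom):
        _, mask, _ = small_phantom
        out = simulate_rater(mask, RaterModel(boundary_jitter_vox=0,
                                              erode_dilate_bias=1.0, seed=0))
        assert out.volume_voxels() > mask.volume_voxels()
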