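"""Ray integrals, forward projection, and Poisson noise."""

import numpy as np
import pytest

from vctdbt.geometry import DetectorSpec, make_conventional
from vctdbt.phantom import LabelVolume
from vctdbt.projector import (MaterialTable, ProjectionSet, add_noise,
                              forward_project, ray_integral)


def supersampled_integral(volume, materials, src, dst, n=20000):
    """Independent oracle: dense midpoint sampling along the ray."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    mu = materials.mu_volume(volume).astype(np.float64)
    o = volume.origin_mm()
    ts = (np.arange(n) + 0.5) / n
    pts = src + ts[:, None] * (dst - src)
    idx = np.floor((pts - o) / volume.voxel_mm).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
    vals = np.zeros(n)
    vals[ok] = mu[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return vals.sum() * np.linalg.norm(dst - src) / n


@pytest.fixture
def slab():
    return LabelVolume(np.ones((10, 10, 10), np.uint8), voxel_mm=1.0)


@pytest.fixture
def materials():
    return MaterialTable()


class TestRayIntegral:
    def test_vertical_ray_through_slab(self, slab, materials):
        li = ray_integral(slab, materials, (0, 5, 50), (0, 5, -10))
        assert li == pytest.approx(materials.mu_adipose * 10, rel=1e-6)

    def test_oblique_ray_slab_sec_theta(self, slab, materials):
        """At angle theta to vertical the path grows by 1/cos(theta)."""
        theta = np.deg2rad(30)
        dx = 60 * np.tan(theta)
        src, dst = (1.0 - dx, 5.0, 55.0), (1.0, 5.0, -5.0)
        li = ray_integral(slab, materials, src, dst)
        oracle = supersampled_integral(slab, materials, src, dst)
        assert li == pytest.approx(oracle, rel=1e-3)

    def test_missing_ray_is_zero(self, slab, materials):
        assert ray_integral(slab, materials, (50, 5, 50), (50, 5, -10)) == 0.0

    def test_source_inside_rejected(self, slab, materials):
        with pytest.raises(ValueError):
            ray_integral(slab, materials, (0.0, 5.0, 5.0), (0, 5, -10))

    def test_random_rays_match_supersampling(self, materials, rng):
        vol = LabelVolume(rng.integers(0, 3, (16, 16, 16)).astype(np.uint8),
                          voxel_mm=1.0)
        mu_max = materials.mu_dense * 16 * np.sqrt(3)
        for _ in range(30):
            src = np.array([rng.uniform(-20, 20), rng.uniform(-20, 36), 60.0])
            dst = np.array([rng.uniform(-10, 10), rng.uniform(2, 14), -10.0])
            li = ray_integral(vol, materials, src, dst)
            oracle = supersampled_integral(vol, materials, src, dst)
            assert abs(li - oracle) <= 1e-3 * mu_max


class TestForwardProject:
    def test_all_air_gives_zero(self, coarse_detector, materials):
        vol = LabelVolume(np.zeros((12, 12, 12), np.uint8), voxel_mm=1.0)
        p = forward_project(vol, make_conventional(detector=coarse_detector),
                            materials)
        assert np.all(p.images == 0)

    def test_single_voxel_shadow_is_unique_peak(self, fine_detector, materials):
        labels = np.zeros((24, 24, 24), np.uint8)
        labels[8, 10, 12] = 2
        vol = LabelVolume(labels, voxel_mm=1.0)
        geom = make_conventional(n=3, detector=fine_detector)
        p = forward_project(vol, geom, materials)
        for s, img in enumerate(p.images):
            src = geom.sources[s]
            # expected shadow: perspective projection of the voxel centre
            c = vol.origin_mm() + (np.array([8, 10, 12]) + 0.5) * vol.voxel_mm
            t = (-fine_detector.gap_mm - src[2]) / (c[2] - src[2])
            hit = src + t * (c - src)
            iu = hit[0] / 0.5 + 0.5 * fine_detector.n_u - 0.5
            iv = hit[1] / 0.5 - 0.5
            peak = np.unravel_index(np.argmax(img), img.shape)
            assert abs(peak[0] - iu) <= 1.0
            assert abs(peak[1] - iv) <= 1.0

    def test_linear_in_attenuation(self, coarse_detector, slab):
        geom = make_conventional(n=3, detector=coarse_detector)
        m1 = MaterialTable()
        m2 = MaterialTable(mu_air=0.0, mu_adipose=2 * m1.mu_adipose,
                           mu_dense=2 * m1.mu_dense)
        p1 = forward_project(slab, geom, m1)
        p2 = forward_project(slab, geom, m2)
        assert np.allclose(p2.images, 2 * p1.images, atol=1e-5)

    def test_disjoint_objects_superpose(self, coarse_detector, materials):
        a = np.zeros((16, 16, 16), np.uint8)
        b = np.zeros((16, 16, 16), np.uint8)
        a[2:5, 3:6, 2:5] = 1
        b[10:13, 8:11, 9:12] = 2
        geom = make_conventional(n=3, detector=coarse_detector)
        pa = forward_project(LabelVolume(a, 1.0), geom, materials)
        pb = forward_project(LabelVolume(b, 1.0), geom, materials)
        pab = forward_project(LabelVolume(a + b, 1.0), geom, materials)
        assert np.allclose(pab.images, pa.images + pb.images, atol=1e-5)

    def test_noiseless_non_negative(self, coarse_detector, slab, materials):
        p = forward_project(slab, make_conventional(detector=coarse_detector),
                            materials)
        assert p.images.min() >= 0

    def test_tiff_round_trip(self, tmp_path, coarse_detector, slab, materials):
        p = forward_project(slab, make_conventional(n=3, detector=coarse_detector),
                            materials)
        path = tmp_path / "proj.tiff"
        p.save(path)
        back = ProjectionSet.load(path)
        assert np.array_equal(back.images, p.images)
        assert back.geometry.name == p.geometry.name


class TestAddNoise:
    @pytest.fixture
    def pset(self, coarse_detector, slab):
        geom = make_conventional(n=2, detector=coarse_detector)
        return forward_project(slab, geom, MaterialTable())

    def test_same_seed_identical(self, pset):
        a = add_noise(pset, fluence=1e4, seed=5)
        b = add_noise(pset, fluence=1e4, seed=5)
        assert np.array_equal(a.images, b.images)

    def test_high_fluence_recovers_input(self, pset):
        noisy = add_noise(pset, fluence=1e10, seed=1)
        mask = pset.images > 0.1
        rel = np.abs(noisy.images[mask] - pset.images[mask]) / pset.images[mask]
        assert rel.max() < 1e-2

    def test_variance_scales_inversely_with_exposure(self):
        """6x exposure shrinks line-integral variance ~6-fold."""
        det = DetectorSpec(pixel_pitch_mm=1.0, n_u=100, n_v=100)
        geom = make_conventional(n=1, detector=det)
        images = np.full((1, 100, 100), 1.0, np.float32)
        p = ProjectionSet(images=images, geometry=geom)
        v1 = np.var(add_noise(p, 1e4, seed=2, exposure_scale=1.0).images)
        v6 = np.var(add_noise(p, 1e4, seed=3, exposure_scale=6.0).images)
        assert v1 / v6 == pytest.approx(6.0, rel=0.15)

    def test_zero_fluence_rejected(self, pset):
        with pytest.raises(ValueError):
            add_noise(pset, fluence=0.0, seed=0)
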