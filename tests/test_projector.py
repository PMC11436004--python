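"""Forward DRR model: quadrature, interpolation, Beer-Lambert compositing."""

import numpy as np
import pytest

import mufield as mf
from mufield.geometry import Ray, generate_rays
from mufield.projector import sample_uniform


def central_ray(length_before=200.0):
    return Ray(origin=(-length_before, 0.0, 0.0), direction=(1.0, 0.0, 0.0))


class TestSampleUniform:
    def test_midpoint_rule_positions(self):
        ray = Ray(origin=(0, 0, 0), direction=(1.0, 0, 0), t_near=0.0, t_far=1.0)
        t, delta = sample_uniform(ray, 4)
        assert delta == pytest.approx(0.25)
        assert np.allclose(t, [0.125, 0.375, 0.625, 0.875])

    def test_single_sample_at_midpoint(self):
        ray = Ray(origin=(0, 0, 0), direction=(1.0, 0, 0), t_near=2.0, t_far=4.0)
        t, delta = sample_uniform(ray, 1)
        assert t[0] == pytest.approx(3.0) and delta == pytest.approx(2.0)

    @pytest.mark.parametrize("n", [1, 3, 17])
    def test_partition_identity(self, n):
        ray = Ray(origin=(0, 0, 0), direction=(1.0, 0, 0), t_near=1.0, t_far=7.5)
        _, delta = sample_uniform(ray, n)
        assert n * delta == pytest.approx(6.5)

    def test_miss_ray_empty(self):
        t, delta = sample_uniform(Ray(origin=(0, 0, 0), direction=(1.0, 0, 0)), 8)
        assert len(t) == 0 and delta == 0.0

    def test_rejects_zero_samples(self):
        with pytest.raises(ValueError):
            sample_uniform(central_ray(), 0)


class TestInterpolateMu:
    def test_voxel_center_exact_and_midpoint_mean(self):
        vol = mf.VolumeGrid(np.arange(27, dtype=float).reshape(3, 3, 3))
        center_val = mf.interpolate_mu(vol, vol.index_to_world([1, 1, 1]))
        assert center_val[0] == pytest.approx(13.0)
        mid = 0.5 * (
            vol.index_to_world([0, 1, 1]) + vol.index_to_world([1, 1, 1])
        )
        assert mf.interpolate_mu(vol, mid)[0] == pytest.approx(0.5 * (4 + 13))

    def test_constant_region_and_outside(self):
        vol = mf.VolumeGrid(np.full((8, 8, 8), 0.7))
        inside = mf.interpolate_mu(vol, [[0.2, -0.3, 0.1]])
        assert inside[0] == pytest.approx(0.7)
        outside = mf.interpolate_mu(vol, [[100.0, 0, 0]])
        assert outside[0] == 0.0


class TestLineIntegral:
    def test_zero_volume(self, homogeneous_cube):
        empty = mf.VolumeGrid(np.zeros_like(homogeneous_cube.values), spacing=4.0)
        ray = central_ray()
        ray.t_near, ray.t_far = mf.volume_aabb_intersect(ray, empty)
        assert mf.line_integral(empty, ray, 64) == 0.0

    def test_homogeneous_closed_form(self, homogeneous_cube):
        """mu = 0.01 / mm over a 200 mm chord -> p = 2 within 0.5%."""
        ray = central_ray()
        ray.t_near, ray.t_far = mf.volume_aabb_intersect(ray, homogeneous_cube)
        p = mf.line_integral(homogeneous_cube, ray, 512)
        assert p == pytest.approx(2.0, rel=5e-3)

    def test_midpoint_rule_converges(self, tiny_phantom, rng):
        """Doubling n shrinks the error against a dense-march reference."""
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ray = Ray(origin=-100 * d + [0, 1.5, 0.5], direction=d)
        ray.t_near, ray.t_far = mf.volume_aabb_intersect(ray, tiny_phantom)
        dense = mf.line_integral(tiny_phantom, ray, 20000)  # ~0.003 mm steps
        errors = [abs(mf.line_integral(tiny_phantom, ray, n) - dense) for n in (64, 128, 256)]
        assert errors[2] < errors[0]

    def test_oracle_equivalence_random_rays(self, tiny_phantom, tiny_geometry):
        """n = 1024 quadrature within 1% of a dense march on real DRR rays."""
        rays = generate_rays(tiny_geometry, 0, tiny_phantom)
        hit_idx = np.flatnonzero(rays.hits)[::11][:100]
        sub = rays[hit_idx]
        p_fast = mf.line_integral(tiny_phantom, sub, 1024)
        p_dense = mf.line_integral(tiny_phantom, sub, 12000)  # ~0.005 mm steps
        mask = p_dense > 1e-3
        assert np.all(
            np.abs(p_fast[mask] - p_dense[mask]) <= 0.01 * p_dense[mask] + 1e-6
        )


class TestRenderDrr:
    def test_empty_volume_gives_i0(self, tiny_geometry):
        empty = mf.VolumeGrid(np.zeros((32, 32, 32)))
        proj = mf.render_drr(empty, tiny_geometry, n_samples=16)
        assert np.all(proj.stack() == tiny_geometry.i0)

    def test_beer_lambert_central_pixel(self, homogeneous_cube):
        """p = 2 on the central ray -> I / I0 = exp(-2) within 0.5%."""
        det_shape, det_spacing = mf.fit_detector(homogeneous_cube, n_pixels=33)
        geom = mf.ConeBeamGeometry.circular(
            1, sad=500, sdd=1000, detector_shape=det_shape, detector_spacing=det_spacing
        )
        proj = mf.render_drr(homogeneous_cube, geom, n_samples=512)
        central = proj.images[0].pixels[16, 16]
        assert central == pytest.approx(np.exp(-2.0), rel=5e-3)

    def test_deterministic_and_noise_validation(self, tiny_phantom, tiny_geometry):
        a = mf.render_drr(tiny_phantom, tiny_geometry, n_samples=32)
        b = mf.render_drr(tiny_phantom, tiny_geometry, n_samples=32)
        assert np.array_equal(a.stack(), b.stack())
        with pytest.raises(ValueError):
            mf.render_drr(tiny_phantom, tiny_geometry, n_samples=32, noise_sd=-0.1)
        noisy = mf.render_drr(tiny_phantom, tiny_geometry, n_samples=32, noise_sd=0.01, seed=3)
        assert not np.array_equal(a.stack(), noisy.stack())

    def test_monotone_in_attenuation(self, tiny_geometry, tiny_phantom, tiny_projections):
        """Adding attenuation anywhere never brightens any pixel."""
        denser = mf.VolumeGrid(
            tiny_phantom.values + 0.002, tiny_phantom.spacing, tiny_phantom.origin
        )
        proj2 = mf.render_drr(denser, tiny_geometry, n_samples=64)
        assert np.all(proj2.stack() <= tiny_projections.stack() + 1e-12)


class TestRepresentations:
    def test_round_trip_exact(self, tiny_projections):
        li = mf.to_line_integrals(tiny_projections)
        assert li.representation == "line_integral"
        assert np.all(li.stack() >= 0)
        back = mf.to_intensities(li)
        err = np.max(np.abs(back.stack() - tiny_projections.stack()))
        assert err < 1e-10

    def test_identity_values(self, tiny_geometry):
        from mufield.projector import ProjectionImage, ProjectionSet

        pix = np.full((4, 4), tiny_geometry.i0)
        pix[0, 0] = tiny_geometry.i0 * np.exp(-2.0)
        pset = ProjectionSet(
            tiny_geometry,
            [
                ProjectionImage(pix, "intensity", float(a))
                for a in tiny_geometry.angles
            ],
        )
        p = mf.to_line_integrals(pset).images[0].pixels
        assert p[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert p[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_pixel_rejected_with_view(self, tiny_geometry):
        from mufield.projector import ProjectionImage, ProjectionSet

        images = [
            ProjectionImage(np.ones((4, 4)), "intensity", float(a))
            for a in tiny_geometry.angles
        ]
        images[7].pixels[2, 2] = 0.0
        pset = ProjectionSet(tiny_geometry, images)
        with pytest.raises(ValueError, match="view 7"):
            mf.to_line_integrals(pset)
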