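"""DRR, semi-transparent, isosurface rendering, and polygon compositing."""

import numpy as np
import pytest

from ctsim.errors import InvalidParameterError
from ctsim.rendering import (
    BeamPolygon,
    Camera,
    RenderWarning,
    TransferFunction,
    composite_polygons,
    render_drr,
    render_isosurface,
    render_semitransparent,
)
from ctsim.volume import VoxelVolume


@pytest.fixture
def slab():
    """A 20 mm water slab along z (box extent 20 x 16 x 16 mm)."""
    return VoxelVolume(np.zeros((20, 8, 8)), spacing=(1.0, 2.0, 2.0))


@pytest.fixture
def cam_z():
    return Camera(direction=(1, 0, 0), shape=(4, 4), pitch=2.0)


def square_at_depth(frame, depth_mm, half_mm, color=5.0):
    base = frame.plane_center + frame.w * depth_mm
    u, v = frame.u, frame.v
    s = half_mm
    return BeamPolygon(
        np.array(
            [
                base - u * s - v * s,
                base + u * s - v * s,
                base + u * s + v * s,
                base - u * s + v * s,
            ]
        ),
        color=color,
    )


class TestDRR:
    def test_zero_attenuation_gives_I0(self, slab, cam_z):
        tf = TransferFunction(attenuation=[(-1024, 0.0), (3071, 0.0)])
        res = render_drr(slab, cam_z, tf, step=1.0, I0=2.5)
        assert np.allclose(res.image, 2.5)
        assert np.all(res.zbuffer == res.far)

    def test_homogeneous_slab_beer_lambert(self, slab, cam_z):
        K, D = 0.05, 20.0
        tf = TransferFunction.uniform_attenuation(K)
        res = render_drr(slab, cam_z, tf, step=D / 100)
        assert np.allclose(res.image, np.exp(-K * D), rtol=5e-3)

    def test_doubling_thickness_doubles_exponent(self, cam_z):
        K = 0.05
        tf = TransferFunction.uniform_attenuation(K)
        thin = VoxelVolume(np.zeros((20, 8, 8)), spacing=(1.0, 2.0, 2.0))
        thick = VoxelVolume(np.zeros((40, 8, 8)), spacing=(1.0, 2.0, 2.0))
        i1 = render_drr(thin, cam_z, tf, step=0.2).image[2, 2]
        i2 = render_drr(thick, cam_z, tf, step=0.2).image[2, 2]
        assert np.log(i2) / np.log(i1) == pytest.approx(2.0, rel=1e-9)

    def test_adding_attenuation_never_brightens(self, cam_z):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 500, (10, 8, 8))
        vol_lo = VoxelVolume(data, spacing=(2.0, 2.0, 2.0))
        vol_hi = VoxelVolume(data + 100.0, spacing=(2.0, 2.0, 2.0))
        tf = TransferFunction(attenuation=[(-1024, 0.0), (0, 0.0), (3071, 0.1)])
        lo = render_drr(vol_lo, cam_z, tf, step=1.0).image
        hi = render_drr(vol_hi, cam_z, tf, step=1.0).image
        assert np.all(hi <= lo + 1e-12)

    def test_step_halving_converges(self, slab, cam_z):
        tf = TransferFunction.uniform_attenuation(0.05)
        a = render_drr(slab, cam_z, tf, step=0.4).image
        b = render_drr(slab, cam_z, tf, step=0.2).image
        assert np.max(np.abs(a - b) / b) < 0.005

    def test_bad_step_rejected(self, slab, cam_z):
        tf = TransferFunction.uniform_attenuation(0.05)
        with pytest.raises(InvalidParameterError):
            render_drr(slab, cam_z, tf, step=0.0)


class TestSemiTransparent:
    def test_two_sample_hand_accumulation(self, cam_z):
        # layer 1: alpha 0.5, shade 1; layer 2: alpha 1, shade 1
        data = np.zeros((2, 4, 4))
        data[1] = 1000.0
        vol = VoxelVolume(data, spacing=(1.0, 2.0, 2.0))
        tf = TransferFunction(
            opacity=[(-1.0, 0.5), (1.0, 0.5), (999.0, 1.0), (1001.0, 1.0)],
            shade=[(-1024, 1.0), (3071, 1.0)],
        )
        res = render_semitransparent(vol, cam_z, tf, step=1.0)
        # 1*0.5*1 + 1*1*0.5 = 1.0 exactly
        assert np.allclose(res.image, 1.0)

    def test_full_occlusion_first_sample(self, cam_z):
        data = np.zeros((2, 4, 4))
        data[1] = 1000.0  # behind: would add shade 9 if visible
        vol = VoxelVolume(data, spacing=(1.0, 2.0, 2.0))
        tf = TransferFunction(
            opacity=[(-1024, 1.0), (3071, 1.0)],
            shade=[(-1.0, 0.7), (1.0, 0.7), (999.0, 9.0), (1001.0, 9.0)],
        )
        res = render_semitransparent(vol, cam_z, tf, step=1.0)
        assert np.allclose(res.image, 0.7)

    def test_all_transparent_gives_zero_and_far(self, slab, cam_z):
        tf = TransferFunction(opacity=[(-1024, 0.0), (3071, 0.0)])
        res = render_semitransparent(slab, cam_z, tf, step=1.0)
        assert np.allclose(res.image, 0.0)
        assert np.all(res.zbuffer == res.far)

    def test_energy_bound_with_unit_shades(self, cam_z):
        rng = np.random.default_rng(6)
        vol = VoxelVolume(rng.uniform(-1000, 1000, (12, 8, 8)), spacing=(1, 2, 2))
        tf = TransferFunction(
            opacity=[(-1000, 0.0), (1000, 0.9)],
            shade=[(-1024, 1.0), (3071, 1.0)],
        )
        res = render_semitransparent(vol, cam_z, tf, step=0.5)
        assert np.all(res.image <= 1.0 + 1e-9)

    def test_zbuffer_set_at_half_opacity(self, cam_z):
        data = np.zeros((4, 4, 4))
        vol = VoxelVolume(data, spacing=(1.0, 2.0, 2.0))
        tf = TransferFunction(opacity=[(-1024, 0.6), (3071, 0.6)])
        res = render_semitransparent(vol, cam_z, tf, step=1.0)
        # first sample reaches opacity 0.6 >= 0.5 -> depth of first sample
        assert np.all(res.zbuffer < res.far)


class TestIsosurface:
    def test_constant_volume_no_crossing(self, slab, cam_z):
        res = render_isosurface(slab, cam_z, isovalue=500.0, step=1.0)
        assert np.allclose(res.image, 0.0)
        assert np.all(res.zbuffer == res.far)

    def test_sphere_front_hemisphere_depths(self):
        n, sp = 64, 2.0
        c = (np.arange(n) + 0.5) * sp - n * sp / 2
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        R = 40.0
        data = np.where(zz**2 + yy**2 + xx**2 <= R**2, 1000.0, -1000.0)
        vol = VoxelVolume(data, spacing=(sp, sp, sp))
        cam = Camera(direction=(1, 0, 0), shape=(17, 17), pitch=4.0)
        res = render_isosurface(vol, cam, 0.0, step=1.0)
        frame = res.frame
        center = np.asarray(vol.origin) + np.asarray(vol.extent_mm()) / 2
        d_center = float((center - frame.plane_center) @ frame.w)
        for i, j in [(8, 8), (8, 10), (10, 8), (6, 8)]:
            du = (j - 8) * 4.0
            dv = (i - 8) * 4.0
            rho2 = du**2 + dv**2
            if rho2 >= R**2:
                continue
            analytic = d_center - np.sqrt(R**2 - rho2)
            assert res.zbuffer[i, j] == pytest.approx(analytic, abs=1.0)  # one step

    def test_sphere_gradient_is_radial(self):
        n, sp = 64, 2.0
        c = (np.arange(n) + 0.5) * sp - n * sp / 2
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        R = 40.0
        # smooth radial field so central differences see the true normal
        data = 1000.0 - 20.0 * (np.sqrt(zz**2 + yy**2 + xx**2) - R)
        vol = VoxelVolume(data, spacing=(sp, sp, sp))
        cam = Camera(direction=(1, 0, 0), shape=(9, 9), pitch=4.0)
        res = render_isosurface(vol, cam, 1000.0, step=1.0)
        # center pixel: normal is along the view -> |g . L| ~ 1
        assert res.image[4, 4] == pytest.approx(1.0, abs=0.01)


class TestCompositePolygons:
    @pytest.fixture
    def sphere_render(self):
        n, sp = 32, 4.0
        c = (np.arange(n) + 0.5) * sp - n * sp / 2
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        data = np.where(zz**2 + yy**2 + xx**2 <= 40.0**2, 1000.0, -1000.0)
        vol = VoxelVolume(data, spacing=(sp, sp, sp))
        cam = Camera(direction=(1, 0, 0), shape=(17, 17), pitch=6.0)
        return render_isosurface(vol, cam, 0.0, step=2.0)

    def test_no_polygons_is_identity(self, sphere_render):
        out = composite_polygons(sphere_render, [])
        assert np.array_equal(out, sphere_render.image)

    def test_polygon_behind_surface_hidden(self, sphere_render):
        frame = sphere_render.frame
        d_surf = sphere_render.zbuffer[8, 8]
        poly = square_at_depth(frame, d_surf + 30.0, 20.0)
        out = composite_polygons(sphere_render, [poly], w=1.0)
        # footprint lies entirely within the sphere silhouette -> all hidden
        assert np.array_equal(out, sphere_render.image)

    def test_polygon_in_front_takes_color_at_w1(self, sphere_render):
        frame = sphere_render.frame
        d_surf = sphere_render.zbuffer[8, 8]
        poly = square_at_depth(frame, d_surf - 30.0, 20.0, color=5.0)
        out = composite_polygons(sphere_render, [poly], w=1.0)
        assert out[8, 8] == 5.0

    def test_half_occluded_polygon_blends_exactly_the_visible_half(self):
        # slab occupying the left half of the image, polygon spanning both
        data = np.full((8, 16, 32), -1000.0)
        data[:, :, :16] = 1000.0  # high-HU half
        vol = VoxelVolume(data, spacing=(4.0, 4.0, 4.0))
        cam = Camera(direction=(1, 0, 0), shape=(16, 32), pitch=4.0,
                     up=(0.0, 1.0, 0.0))
        res = render_isosurface(vol, cam, 0.0, step=1.0)
        frame = res.frame
        d_face = float(np.min(res.zbuffer))  # slab face depth
        poly = square_at_depth(frame, d_face + 10.0, 60.0, color=3.0)
        out = composite_polygons(res, [poly], w=1.0)
        uc, vc, _ = frame.project(poly.vertices)
        cmin = max(0, int(np.ceil(uc.min())))
        cmax = min(31, int(np.floor(uc.max())))
        rmin = max(0, int(np.ceil(vc.min())))
        rmax = min(15, int(np.floor(vc.max())))
        inside_surface = res.zbuffer < res.far
        for r in range(rmin, rmax + 1):
            for c in range(cmin, cmax + 1):
                if inside_surface[r, c]:
                    assert out[r, c] == res.image[r, c]  # behind the slab face
                else:
                    assert out[r, c] == 3.0  # visible against far background

    def test_blend_weight(self, sphere_render):
        frame = sphere_render.frame
        poly = square_at_depth(frame, 1.0, 20.0, color=4.0)
        out = composite_polygons(sphere_render, [poly], w=0.25)
        expected = 0.75 * sphere_render.image[8, 8] + 0.25 * 4.0
        assert out[8, 8] == pytest.approx(expected)

    def test_edge_on_polygon_skipped_with_warning(self, sphere_render):
        frame = sphere_render.frame
        base = frame.plane_center + frame.w * 10.0
        poly = BeamPolygon(
            np.array([base, base + frame.w * 20.0, base + frame.w * 40.0 + frame.u * 1e-9])
        )
        with pytest.warns(RenderWarning):
            out = composite_polygons(sphere_render, [poly])
        assert np.array_equal(out, sphere_render.image)


class TestCameraAndTypes:
    def test_nonplanar_polygon_rejected(self):
        with pytest.raises(InvalidParameterError):
            BeamPolygon(np.array([[0, 0, 0], [0, 0, 10], [0, 10, 0], [7, 10, 10]]))

    def test_opacity_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransferFunction(opacity=[(-1024, 0.0), (3071, 1.5)])

    def test_negative_attenuation_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransferFunction(attenuation=[(-1024, -0.1), (3071, 0.0)])

    def test_perspective_rays_diverge(self):
        vol = VoxelVolume(np.zeros((8, 8, 8)), spacing=(2, 2, 2))
        cam = Camera(direction=(1, 0, 0), shape=(5, 5), pitch=2.0,
                     mode="perspective", focal=100.0)
        frame = cam.frame_for(vol)
        _, dirs = frame.rays()
        assert not np.allclose(dirs[0, 0], dirs[4, 4])
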