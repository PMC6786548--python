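import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from granulattice.cells import HIAPP_BCT_CELL, UnitCell
from granulattice.synthetic import (
    DisorderSpec,
    RenderSpec,
    TwinSpec,
    apply_disorder,
    apply_missing_wedge,
    build_twinned_assembly,
    build_unit_cell_points,
    extract_slab_projection,
    make_cyclic_twin,
    missing_wedge_mask,
    render_volume,
)
from conftest import BCT_MIN_SPACING


def brute_force_min_distance(points, n_max=400):
    pts = points[:n_max]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return d[d > 1e-9].min()


class TestBuildUnitCellPoints:
    def test_simple_cubic_grid(self):
        pts = build_unit_cell_points(UnitCell(1, 1, 1), box=(10, 10, 10))
        assert len(pts) == 1000  # half-open box convention: 10 sites per axis
        assert brute_force_min_distance(pts) == pytest.approx(1.0)

    def test_bct_point_count_tracks_density(self):
        """Count ~ box volume / primitive volume: < 5 % error for boxes at
        least ~10 cells per side; order of magnitude for the thin slab box
        (85 nm is only 2.6 c-repeats, so edge inclusion inflates the count)."""
        cell = HIAPP_BCT_CELL
        big = (600.0, 600.0, 600.0)
        # generic origin: avoids the systematic inclusion bias of a box whose
        # faces are commensurate with the lattice planes
        pts = build_unit_cell_points(cell, box=big, origin=(np.pi, np.e, np.sqrt(2)))
        assert len(pts) == pytest.approx(np.prod(big) / cell.primitive_volume, rel=0.05)

        slab_box = (600.0, 600.0, 85.0)
        pts = build_unit_cell_points(cell, box=slab_box)
        density_estimate = np.prod(slab_box) / cell.primitive_volume
        assert density_estimate == pytest.approx(2.4e3, rel=0.01)
        assert 0.5 * density_estimate < len(pts) < 1.5 * density_estimate

    def test_bct_min_pairwise_distance_closed_form(self, bct_points):
        # shortest lattice translation of BCT is the half body diagonal
        assert brute_force_min_distance(bct_points) == pytest.approx(
            BCT_MIN_SPACING, abs=1e-9
        )
        assert BCT_MIN_SPACING == pytest.approx(25.72, abs=0.01)

    @pytest.mark.parametrize("cell", [HIAPP_BCT_CELL, UnitCell(28.4, 26.5, 24.2, 78, 66, 61)])
    def test_shortest_neighbor_distances_match_metric_tensor(self, cell):
        """The three shortest realized distances equal the three shortest
        lattice-translation lengths from the metric tensor (brute force)."""
        from granulattice.cells import primitive_basis

        B = primitive_basis(cell)
        combos = np.array(
            [m for m in itertools.product(range(-3, 4), repeat=3) if m != (0, 0, 0)]
        )
        lens = np.sort(np.linalg.norm(combos @ B, axis=1))
        expected = np.unique(np.round(lens, 6))[:3]

        pts = build_unit_cell_points(cell, box=(150, 150, 150))
        sub = pts[:300]
        d = np.linalg.norm(sub[:, None] - pts[None, :], axis=-1)
        realized = np.unique(np.round(d[d > 1e-6], 6))[:3]
        assert np.allclose(realized, expected, atol=1e-5)

    def test_rotation_preserves_distances(self):
        rot = Rotation.from_euler("zyx", [30, 20, 10], degrees=True)
        pts = build_unit_cell_points(HIAPP_BCT_CELL, orientation=rot, box=(150, 150, 150))
        assert brute_force_min_distance(pts) == pytest.approx(BCT_MIN_SPACING, abs=1e-9)

    def test_degenerate_cell_rejected(self):
        from granulattice.cells import DegenerateCellError

        with pytest.raises(DegenerateCellError):
            UnitCell(10, 10, 10, alpha=1e-7)


class TestTwinnedAssembly:
    def test_every_point_in_its_labeled_sector(self, twin_points):
        """Brute-force azimuth check against the documented sector bounds."""
        pts, labels = twin_points
        spec = make_cyclic_twin(HIAPP_BCT_CELL, (76, 70, 71, 73, 69))
        bounds = spec.sector_bounds()
        center = np.array([300.0, 300.0, 42.5])
        rel = pts - center
        az = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
        on_axis = np.hypot(rel[:, 0], rel[:, 1]) < 1e-9
        for s in range(5):
            lo, hi = bounds[s]
            sel = (labels == s) & ~on_axis
            assert np.all((az[sel] >= lo) & (az[sel] < hi))

    def test_closure_policy_stretches_last_sector(self):
        spec = make_cyclic_twin(HIAPP_BCT_CELL, (76, 70, 71, 73, 69))
        bounds = spec.sector_bounds()
        assert bounds[-1, 1] == pytest.approx(360.0)
        assert bounds[-1, 1] - bounds[-1, 0] == pytest.approx(70.0)  # 69 + 1 deficit

    def test_gap_policy_leaves_deficit_unassigned(self):
        spec = make_cyclic_twin(HIAPP_BCT_CELL, (76, 70, 71, 73, 69), closure="gap")
        assert spec.sector_bounds()[-1, 1] == pytest.approx(359.0)

    def test_degenerate_twin_covers_plain_lattice(self):
        box = (200.0, 200.0, 66.0)
        full = TwinSpec(
            wedge_angles=(180.0, 180.0),
            sectors=((HIAPP_BCT_CELL, None), (HIAPP_BCT_CELL, None)),
        )
        pts, _ = build_twinned_assembly(full, box=box)
        center = np.array([100.0, 100.0, 33.0])
        plain = build_unit_cell_points(HIAPP_BCT_CELL, box=box, origin=center)
        assert len(pts) == len(plain)
        assert np.allclose(np.sort(pts, axis=0), np.sort(plain, axis=0))

    @pytest.mark.parametrize("bad", [(-10, 370), (200, 200)])
    def test_invalid_wedges_rejected(self, bad):
        with pytest.raises(ValueError):
            TwinSpec(wedge_angles=bad, sectors=((HIAPP_BCT_CELL, None),) * len(bad))


class TestDisorder:
    def test_zero_disorder_is_identity(self, bct_points):
        out = apply_disorder(bct_points, DisorderSpec(seed=0))
        assert np.array_equal(out, bct_points)

    def test_vacancy_survival_within_binomial_interval(self):
        pts = np.random.default_rng(0).uniform(0, 100, (2000, 3))
        out = apply_disorder(pts, DisorderSpec(vacancy_prob=0.1, seed=1))
        # binomial(2000, 0.9) central 95 % interval
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], 2000, 0.9)
        assert lo <= len(out) <= hi

    def test_jitter_rms_displacement(self):
        pts = np.zeros((4000, 3))
        out = apply_disorder(pts, DisorderSpec(jitter_sigma=0.5, seed=2))
        rms = np.sqrt(np.mean(np.sum(out**2, axis=1)))
        assert rms == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_bending_is_sinusoidal_in_z(self):
        z = np.linspace(0, 400, 50)
        pts = np.stack([np.zeros(50), np.zeros(50), z], axis=1)
        out = apply_disorder(pts, DisorderSpec(bend_amplitude=3.0, bend_wavelength=200.0))
        assert np.allclose(out[:, 0], 3.0 * np.sin(2 * np.pi * z / 200.0))

    def test_reproducible_under_seed(self, bct_points):
        spec = DisorderSpec(jitter_sigma=1.0, vacancy_prob=0.05, seed=7)
        a = apply_disorder(bct_points, spec)
        b = apply_disorder(bct_points, spec)
        assert np.array_equal(a, b)


class TestRender:
    def test_single_sphere_fwhm_equals_diameter(self):
        spec = RenderSpec(granule_diameter=20.1)
        vol = render_volume(np.array([[30.0, 30.0, 30.0]]), spec)
        k, j, i = np.unravel_index(np.argmax(vol.data), vol.shape)
        prof = vol.data[k, j, :].astype(float)
        above = np.where(prof >= prof.max() / 2)[0]
        fwhm = (above[-1] - above[0] + 1) * vol.voxel_size
        assert fwhm == pytest.approx(20.1, abs=vol.voxel_size)

    def test_linker_ridge_between_granules(self):
        pts = np.array([[30.0, 30.0, 30.0], [55.6, 30.0, 30.0]])
        spec = RenderSpec(linker_planes=((0.0, 0.0, 1.0),))
        vol = render_volume(pts, spec)
        mid_idx = vol.to_index([[42.8, 30.0, 30.0]])[0].round().astype(int)
        off_idx = vol.to_index([[42.8, 48.0, 30.0]])[0].round().astype(int)
        ridge = vol.data[tuple(mid_idx)]
        background = vol.data[tuple(off_idx)]
        assert ridge > 0.5  # linker amplitude
        assert background < 0.05

    def test_noise_render_bit_reproducible(self):
        pts = np.array([[30.0, 30.0, 30.0]])
        spec = RenderSpec(noise_sigma=0.2, seed=5)
        a = render_volume(pts, spec)
        b = render_volume(pts, spec)
        assert np.array_equal(a.data, b.data)

    def test_unresolvable_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            render_volume(np.zeros((1, 3)), RenderSpec(voxel_size=12.0, granule_diameter=20.0))


class TestMissingWedge:
    def test_mask_zero_inside_wedge_one_outside(self):
        mask = missing_wedge_mask((32, 32, 32), tilt_range=60.0, dual_axis=False)
        kz = np.fft.fftfreq(32)[:, None, None]
        kx = np.fft.fftfreq(32)[None, None, :]
        inside_missing = np.abs(kz) > np.abs(kx) * np.tan(np.radians(60.0))
        assert not mask[np.broadcast_to(inside_missing, mask.shape)].any()
        assert mask[~np.broadcast_to(inside_missing, mask.shape)].all()

    def test_dual_axis_mask_is_union_of_single_axis(self):
        shape = (24, 24, 24)
        dual = missing_wedge_mask(shape, dual_axis=True)
        single_y = missing_wedge_mask(shape, dual_axis=False)
        assert dual[single_y].all()  # dual samples everything single-axis does
        assert dual.sum() > single_y.sum()

    def test_filter_preserves_energy_outside_wedge(self):
        rng = np.random.default_rng(3)
        from granulattice.synthetic import Volume3D

        vol = Volume3D(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.1)
        out = apply_missing_wedge(vol, 60.0, dual_axis=True)
        mask = missing_wedge_mask(vol.shape, 60.0, True)
        ft_in = np.fft.fftn(vol.data)
        ft_out = np.fft.fftn(out.data)
        assert np.allclose(ft_out[mask], ft_in[mask], atol=1e-3)
        assert np.allclose(ft_out[~mask], 0.0, atol=1e-3)


class TestSlabProjection:
    def test_full_depth_slab_equals_z_projection(self, bct_volume):
        nz = bct_volume.shape[0]
        thickness = nz * bct_volume.voxel_size
        img = extract_slab_projection(bct_volume, (0, 0, 1), thickness=thickness)
        assert np.allclose(img, bct_volume.data.sum(axis=0))

    def test_empty_slab_is_uniform_background(self):
        pts = np.array([[50.0, 50.0, 10.0]])
        vol = render_volume(pts, RenderSpec(), box=((0, 100), (0, 100), (0, 100)))
        img = extract_slab_projection(vol, (0, 0, 1), anchor=(50, 50, 80), thickness=20)
        assert img.max() < 1e-4

    def test_slab_through_001_plane_shows_square_net(self, slab_volume):
        """Bright dots on a square net of side a in the (001) slab."""
        pts, vol = slab_volume
        img = extract_slab_projection(vol, (0, 0, 1), anchor=(150, 150, 49.5), thickness=20)
        plane = pts[np.abs(pts[:, 2] - 49.5) < 0.1]

        def sample(x, y):
            c = int(round((x - vol.origin[0]) / vol.voxel_size - 0.5))
            r = int(round((y - vol.origin[1]) / vol.voxel_size - 0.5))
            if 0 <= r < img.shape[0] and 0 <= c < img.shape[1]:
                return img[r, c]
            return None

        vals = [v for p in plane if (v := sample(p[0], p[1])) is not None]
        # background: clear of granule columns (any plane) and of the x/y
        # linker ridges of the square net
        mid = plane[len(plane) // 2]
        off = sample(mid[0] + 27.9 / 2, mid[1] + 27.9 / 4)
        assert np.median(vals) > 5 * abs(off)

    def test_out_of_volume_slab_rejected(self, bct_volume):
        with pytest.raises(ValueError):
            extract_slab_projection(bct_volume, (0, 0, 1), thickness=1e4)
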