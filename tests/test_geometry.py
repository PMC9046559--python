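"""Idealized stenosis profile, segment partition and grid generation."""

import numpy as np
import pytest

import hemoflow as hf
from hemoflow.geometry import _eta_faces


class TestStenosisProfile:
    def test_anchor_values(self, default_spec):
        # minimum lumen diameter at the lesion center, reference D at shoulders
        assert hf.stenosis_profile(default_spec, 0.0) == pytest.approx(default_spec.D_min)
        for x in (-0.0015, 0.0015):
            assert hf.stenosis_profile(default_spec, x) == pytest.approx(0.003)
        # quarter-lesion point: halfway between D_min and D (sin^2(pi/4) = 1/2)
        mid = default_spec.D_min + 0.5 * (0.003 - default_spec.D_min)
        assert hf.stenosis_profile(default_spec, 0.003 / 4) == pytest.approx(mid)

    def test_symmetry_and_smoothness(self, default_spec):
        x = np.linspace(-0.0015, 0.0015, 101)
        d = hf.stenosis_profile(default_spec, x)
        assert np.allclose(d, d[::-1])
        # C1 across the shoulder: numerical slope goes to zero there
        eps = 1e-7
        slope = (hf.stenosis_profile(default_spec, 0.0015) -
                 hf.stenosis_profile(default_spec, 0.0015 - eps)) / eps
        assert abs(slope) < 1e-3

    def test_outside_lesion_constant(self, default_spec):
        assert hf.stenosis_profile(default_spec, 0.01) == pytest.approx(0.003)

    def test_mld_conventions(self):
        lit = hf.StenosisSpec(mld_convention="paper_literal")
        cli = hf.StenosisSpec(mld_convention="clinical")
        assert lit.D_min == pytest.approx(0.0012)
        assert cli.D_min == pytest.approx(0.0018)

    def test_errors(self, default_spec):
        with pytest.raises(ValueError):
            hf.stenosis_profile(default_spec, np.nan)
        with pytest.raises(ValueError):
            hf.StenosisSpec(DS=0.0)
        with pytest.raises(ValueError):
            hf.StenosisSpec(DS=1.2)
        with pytest.raises(ValueError):
            hf.StenosisSpec(L_lesion=-1.0)


class TestPartition:
    def test_boundaries(self, default_geometry, default_spec):
        seg = default_geometry.segment
        x = default_geometry.x
        # segment 2 starts one diameter proximal of the proximal shoulder
        assert np.all(seg[x < -0.0045] == 1)
        # MLD station belongs to segment 2 (closed-left convention)
        assert seg[default_geometry.mld_index] == 2
        assert np.all(seg[x > 0.0045] == 4)
        # segment-2 axial extent = 1 D + L_lesion / 2 = 4.5 mm
        extent = x[seg == 2].max() - x[seg == 2].min()
        dx = x[1] - x[0]
        assert extent == pytest.approx(0.0045, abs=2 * dx)

    def test_segment_lengths_partition_domain(self, default_geometry):
        seg = default_geometry.segment
        n = len(default_geometry.x)
        assert sum(np.sum(seg == k) for k in (1, 2, 3, 4)) == n
        # labels are contiguous and ordered
        assert np.all(np.diff(seg) >= 0)

    def test_straight_vessel_rejected(self):
        geom = hf.straight_geometry()
        with pytest.raises(ValueError, match="no stenosis"):
            hf.partition_segments(geom, hf.StenosisSpec())

    def test_lesion_too_close_to_boundary(self):
        spec = hf.StenosisSpec(L_inlet=0.003, L_outlet=0.003)
        with pytest.raises(ValueError, match="L_inlet"):
            hf.build_geometry(spec, n_axial=128)


class TestMesh:
    def test_wall_layers_monotone(self):
        geom = hf.straight_geometry(n_axial=16)
        grid = hf.generate_mesh(geom, resolution=16, wall_layers=10)
        d = np.diff(grid.eta_faces)
        # 10 near-wall layers shrink monotonically toward the wall
        layers = d[-10:]
        assert np.all(np.diff(layers) < 0)
        assert len(d) == 16

    def test_resolution_doubling(self):
        geom = hf.straight_geometry(n_axial=16)
        g1 = hf.generate_mesh(geom, resolution=16, wall_layers=4)
        g2 = hf.generate_mesh(geom, resolution=32, wall_layers=4)
        assert len(g2.eta_centers) >= 2 * len(g1.eta_centers) - 4

    def test_min_cell_at_mld_wall(self, default_spec):
        geom = hf.build_geometry(default_spec, n_axial=128)
        grid = hf.generate_mesh(geom, resolution=20, wall_layers=8)
        # smallest physical spacing = innermost wall layer at the throat
        phys = np.diff(grid.eta_faces)[None, :] * grid.r_centers[:, None]
        i, j = np.unravel_index(np.argmin(phys), phys.shape)
        assert j == len(grid.eta_centers) - 1
        assert abs(grid.x_centers[i]) < 2 * grid.dx

    def test_mesh_independent_of_profile(self, default_spec):
        x = np.linspace(-0.001, 0.001, 11)
        d = hf.stenosis_profile(default_spec, x)
        hf.generate_mesh(hf.build_geometry(default_spec, n_axial=64),
                         resolution=12, wall_layers=4)
        assert np.allclose(hf.stenosis_profile(default_spec, x), d)

    def test_invalid_args(self):
        geom = hf.straight_geometry(n_axial=16)
        with pytest.raises(ValueError):
            hf.generate_mesh(geom, resolution=4)
        with pytest.raises(ValueError):
            hf.generate_mesh(geom, resolution=16, wall_layers=0)

    def test_eta_faces_cover_unit_interval(self):
        ef = _eta_faces(24, 10)
        assert ef[0] == 0.0 and ef[-1] == 1.0
        assert np.all(np.diff(ef) > 0)


def test_geometry_requires_positive_radius():
    with pytest.raises(ValueError):
        hf.VesselGeometry(x=np.array([0.0, 1.0]), r=np.array([1.0, -1.0]),
                          radius_fn=lambda x: np.asarray(x))
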