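"""Height-field geometry, curvature estimation and the shape index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromashade import surface_geometry as sg


class TestGenerateBumpyHeightfield:
    def test_zero_amplitude_is_flat(self):
        h = sg.generate_bumpy_heightfield(32, amplitude=0.0, seed=1)
        assert np.all(h.heights == 0.0)

    def test_same_seed_bit_identical(self):
        a = sg.generate_bumpy_heightfield(64, seed=7)
        b = sg.generate_bumpy_heightfield(64, seed=7)
        assert np.array_equal(a.heights, b.heights)
        c = sg.generate_bumpy_heightfield(64, seed=8)
        assert not np.array_equal(a.heights, c.heights)

    def test_band_limited_spectrum(self):
        """Fourier power above f = 2/correlation_length is negligible."""
        L, d = 2.0, 0.25
        h = sg.generate_bumpy_heightfield(64, correlation_length=L,
                                          spacing=d, seed=3)
        power = np.abs(np.fft.fft2(h.heights)) ** 2
        f = np.fft.fftfreq(64, d=d)
        fmag = np.sqrt(f[None, :] ** 2 + f[:, None] ** 2)
        assert power[fmag > 2.0 / L].sum() / power.sum() < 1e-6

    def test_amplitude_sets_rms(self):
        h = sg.generate_bumpy_heightfield(64, amplitude=0.7, seed=2)
        assert h.heights.std() == pytest.approx(0.7)

    @pytest.mark.parametrize("kwargs", [
        {"nx": 8}, {"amplitude": -1.0}, {"correlation_length": 0.1},
    ])
    def test_parameter_errors(self, kwargs):
        args = {"nx": 32, "amplitude": 0.5, "correlation_length": 2.0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            sg.generate_bumpy_heightfield(**args, seed=0)


class TestPrincipalCurvatures:
    def test_flat_plane_zero_curvature(self):
        pc = sg.principal_curvatures(sg.HeightField(np.zeros((32, 32)), 0.1))
        assert np.all(pc.k1[pc.mask] == 0)
        assert np.all(pc.k2[pc.mask] == 0)

    @pytest.mark.parametrize("r", [5.0, 10.0])
    def test_sphere_cap_matches_analytic(self, r):
        """Interior curvature of a spherical cap equals 1/r within 1%."""
        n, d = 129, r / 150.0
        x = (np.arange(n) - n // 2) * d
        X, Y = np.meshgrid(x, x)
        pc = sg.principal_curvatures(
            sg.HeightField(np.sqrt(r**2 - X**2 - Y**2), d))
        interior = pc.mask & (X**2 + Y**2 < (0.3 * r) ** 2)
        assert np.allclose(pc.k1[interior], 1.0 / r, rtol=0.01)
        assert np.allclose(pc.k2[interior], 1.0 / r, rtol=0.01)

    def test_cylinder_ridge_matches_analytic(self):
        r, n, d = 10.0, 129, 0.08
        x = (np.arange(n) - n // 2) * d
        X, Y = np.meshgrid(x, x)
        pc = sg.principal_curvatures(
            sg.HeightField(np.sqrt(r**2 - X**2), d))
        interior = pc.mask & (np.abs(X) < 0.3 * r)
        assert np.allclose(pc.k1[interior], 1.0 / r, rtol=0.01)
        assert np.allclose(pc.k2[interior], 0.0, atol=1e-4)

    def test_border_masked(self):
        pc = sg.principal_curvatures(sg.HeightField(np.zeros((8, 8)), 1.0))
        assert not pc.mask[0].any() and not pc.mask[-1].any()
        assert not pc.mask[:, 0].any() and not pc.mask[:, -1].any()

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            sg.principal_curvatures(sg.HeightField(np.zeros((2, 5)), 1.0))


class TestShapeIndex:
    def _si(self, k1, k2):
        k1 = np.atleast_2d(np.asarray(k1, dtype=float))
        k2 = np.atleast_2d(np.asarray(k2, dtype=float))
        pc = sg.PrincipalCurvatures(k1, k2, np.ones(k1.shape, dtype=bool))
        return sg.shape_index(pc).s

    @pytest.mark.parametrize("r", [0.1, 1.0, 10.0])
    def test_convex_sphere_is_minus_one_for_any_radius(self, r):
        assert self._si(1.0 / r, 1.0 / r)[0, 0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("r", [0.1, 1.0, 10.0])
    def test_concavity_is_plus_one(self, r):
        assert self._si(-1.0 / r, -1.0 / r)[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [0.2, 1.0, 7.0])
    def test_symmetric_saddle_is_zero(self, k):
        assert self._si(k, -k)[0, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        k2 = rng.normal(size=(20, 20))
        k1 = k2 + np.abs(rng.normal(size=(20, 20)))
        assert np.allclose(self._si(c * k1, c * k2), self._si(k1, k2))

    def test_bounded_on_generated_field(self, bumpy_field):
        si = sg.shape_index(sg.principal_curvatures(bumpy_field))
        assert np.all(si.s[si.mask] >= -1.0)
        assert np.all(si.s[si.mask] <= 1.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(k2=st.floats(-50, 50), dk=st.floats(0, 100),
           c=st.floats(1e-3, 1e3))
    def test_bounded_and_scale_invariant_for_any_curvature_pair(self, k2, dk,
                                                                c):
        """For every ordered pair k1 >= k2 the index stays in [-1, 1] and is
        unchanged by rescaling both curvatures."""
        k1 = k2 + dk
        s = self._si(k1, k2)[0, 0]
        assert -1.0 <= s <= 1.0
        assert self._si(c * k1, c * k2)[0, 0] == pytest.approx(s, abs=1e-9)

    def test_ordering_violation_rejected(self):
        pc = sg.PrincipalCurvatures.__new__(sg.PrincipalCurvatures)
        object.__setattr__(pc, "k1", np.array([[0.0]]))
        object.__setattr__(pc, "k2", np.array([[1.0]]))
        object.__setattr__(pc, "mask", np.array([[True]]))
        with pytest.raises(ValueError):
            sg.shape_index(pc)


class TestClassifyRegion:
    def test_anchor_classes_and_grays(self):
        s = np.array([[-1.0, 0.0, 1.0]])
        si = sg.ShapeIndexMap(s, np.ones_like(s, dtype=bool))
        rc = sg.classify_region(si)
        assert list(rc.classes[0]) == [sg.CONVEX, sg.SADDLE, sg.CONCAVE]
        # concave darkest (0), convex light (1), saddle midway
        assert rc.gray[0, 0] == pytest.approx(1.0)
        assert rc.gray[0, 1] == pytest.approx(0.5)
        assert rc.gray[0, 2] == pytest.approx(0.0)

    def test_thirds_thresholds(self):
        s = np.array([[-0.34, -0.32, 0.32, 0.34]])
        rc = sg.classify_region(sg.ShapeIndexMap(s, np.ones_like(s, bool)))
        assert list(rc.classes[0]) == [sg.CONVEX, sg.SADDLE, sg.SADDLE,
                                       sg.CONCAVE]


class TestMeshIO:
    def _quad_mesh(self):
        verts = np.array([[0, 0, 2.0], [1, 0, 2.0], [1, 1, 2.0], [0, 1, 2.0]])
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        return sg.TriMesh(verts, faces)

    def test_obj_round_trip_preserves_vertices(self, tmp_path):
        mesh = self._quad_mesh()
        path = tmp_path / "plane.obj"
        lines = [f"v {x} {y} {z}" for x, y, z in mesh.vertices]
        lines += [f"f {a+1} {b+1} {c+1}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
        loaded = sg.load_mesh_obj(path)
        assert len(loaded.vertices) == 4
        assert len(loaded.faces) == 2

    def test_flat_quad_resamples_to_constant(self):
        h = sg.resample_to_heightfield(self._quad_mesh(), nx=17)
        assert np.allclose(h.heights, 2.0, atol=1e-9)

    def test_resampled_heights_match_point_in_triangle_oracle(self):
        # slanted plane z = x + 2y: barycentric interpolation is exact
        verts = np.array([[0, 0, 0.0], [2, 0, 2.0], [2, 2, 6.0], [0, 2, 4.0]])
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        h = sg.resample_to_heightfield(sg.TriMesh(verts, faces), nx=21)
        ny, nx = h.heights.shape
        xs = h.spacing * np.arange(nx)
        ys = h.spacing * np.arange(ny)
        expected = xs[None, :] + 2.0 * ys[:, None]
        assert np.allclose(h.heights, expected, atol=1e-6)

    def test_empty_mesh_rejected(self, tmp_path):
        path = tmp_path / "empty.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\n")
        with pytest.raises(ValueError):
            sg.load_mesh_obj(path)

    def test_invalid_face_indices_rejected(self):
        with pytest.raises(ValueError):
            sg.TriMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))
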