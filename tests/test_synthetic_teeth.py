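"""Crown generator and wear operators against closed-form ground truth."""

import numpy as np
import pytest
import scipy.integrate
import trimesh
from scipy.sparse import coo_matrix

from occluwear import synthetic_teeth as st
from occluwear.mesh_core import SurfaceMesh


def crown_body_volume_oracle(spec, n_theta=2000, n_r=1500):
    """Numeric integration of the parametric crown body (no relief):
    wall of revolution with oval section plus the occlusal height field."""
    hw = st._wall_height(spec)
    rt = st._top_radius(spec)
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    shape = st.cross_section_shape(spec, theta)
    section = (shape ** 2).sum() * (2 * np.pi / n_theta) / 2.0
    wall = scipy.integrate.quad(
        lambda z: st.wall_radius(spec, z) ** 2, 0.0, hw)[0] * section
    cap = 0.0
    rr = (np.arange(n_r) + 0.5) / n_r
    for i in range(0, n_theta, 4):
        rmax = rt * shape[i]
        r = rr * rmax
        u = np.column_stack([r * np.cos(theta[i]), r * np.sin(theta[i])])
        h = st.cap_height(spec, u)
        cap += (h * r).sum() * (rmax / n_r) * (2 * np.pi / (n_theta / 4))
    return wall + cap


def count_local_maxima(mesh, mask):
    """Strict local maxima of z over masked vertices (graph neighbourhood)."""
    e = mesh.directed_edges()
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                     shape=(len(mesh.vertices),) * 2).tocsr()
    z = mesh.vertices[:, 2]
    n = 0
    for i in np.flatnonzero(mask):
        nb = adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
        if len(nb) and (z[i] > z[nb]).all():
            n += 1
    return n


def flat_topped_cylinder(radius=3.0, height=8.0, sections=128, rings=8):
    """Watertight cylinder with subdivided wall, flat top and bottom."""
    theta = 2 * np.pi * np.arange(sections) / sections
    rows = []
    for i in range(rings + 1):
        z = height * i / rings
        rows.append(np.column_stack([radius * np.cos(theta),
                                     radius * np.sin(theta),
                                     np.full(sections, z)]))
    v = np.concatenate(rows + [[[0, 0, 0]], [[0, 0, height]]])
    bot, top = len(v) - 2, len(v) - 1
    idx = np.arange(sections)
    nxt = (idx + 1) % sections
    faces = []
    for i in range(rings):
        a, b = i * sections + idx, i * sections + nxt
        c, d = (i + 1) * sections + idx, (i + 1) * sections + nxt
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    faces.append(np.column_stack([nxt, idx, np.full(sections, bot)]))
    r0 = rings * sections
    faces.append(np.column_stack([r0 + idx, r0 + nxt, np.full(sections, top)]))
    return SurfaceMesh(v, np.concatenate(faces))


# ---------------------------------------------------------------------------
# generate_crown
# ---------------------------------------------------------------------------


class TestGenerateCrown:
    def test_deterministic_for_fixed_spec(self):
        spec = st.premolar_spec(random_seed=1, mesh_resolution=2000)
        a, b = st.generate_crown(spec), st.generate_crown(spec)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    @pytest.mark.parametrize("maker", [st.premolar_spec, st.molar_spec])
    def test_watertight_oriented_with_planar_base(self, maker):
        crown = st.generate_crown(maker(random_seed=7, mesh_resolution=3000))
        assert crown.is_watertight
        assert crown.enclosed_volume() > 0
        base = crown.vertices[:, 2] <= 1e-12
        assert base.sum() > 10  # the gingival boundary ring plus centre
        assert np.all(crown.vertices[:, 2] >= -1e-12)

    def test_face_count_within_30_percent(self):
        for target in (1000, 6000, 17000):
            crown = st.generate_crown(
                st.premolar_spec(random_seed=1, mesh_resolution=target))
            assert abs(len(crown.faces) - target) <= 0.3 * target

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError, match="500"):
            st.generate_crown(st.premolar_spec(mesh_resolution=400))

    def test_molar_has_four_cusp_maxima(self, molar):
        occlusal = molar.vertex_normals[:, 2] > np.cos(np.deg2rad(30.0))
        assert count_local_maxima(molar, occlusal) == 4

    def test_premolar_has_two_cusp_maxima(self, premolar):
        occlusal = premolar.vertex_normals[:, 2] > np.cos(np.deg2rad(30.0))
        assert count_local_maxima(premolar, occlusal) == 2

    def test_smooth_body_volume_matches_numeric_integral(self):
        spec = st.premolar_spec(random_seed=1, mesh_resolution=8000,
                                surface_bumpiness=0.0)
        expected = crown_body_volume_oracle(spec)
        got = st.generate_crown(spec).enclosed_volume()
        assert got == pytest.approx(expected, rel=5e-3)

    def test_tilt_is_a_rigid_motion_of_the_upright_crown(self):
        up = st.generate_crown(st.premolar_spec(random_seed=5,
                                                mesh_resolution=2000))
        tilted = st.generate_crown(st.premolar_spec(random_seed=5,
                                                    mesh_resolution=2000,
                                                    axis_tilt_deg=10.0))
        assert tilted.enclosed_volume() == pytest.approx(
            up.enclosed_volume(), rel=1e-9)


# ---------------------------------------------------------------------------
# occlusal wear
# ---------------------------------------------------------------------------


class TestOcclusalWear:
    def test_zero_depth_is_identity(self, premolar):
        worn, removed = st.apply_occlusal_wear(premolar, 0.0, seed=1)
        assert removed == 0.0
        assert np.array_equal(worn.vertices, premolar.vertices)

    def test_cylinder_closed_form(self):
        cyl = flat_topped_cylinder(radius=3.0, height=8.0)
        worn, removed = st.apply_occlusal_wear(cyl, 1.0, seed=0,
                                               roughness=0.0)
        assert worn.is_watertight
        assert removed == pytest.approx(9 * np.pi, rel=2e-3)

    def test_monotone_in_depth(self, premolar):
        removed = [st.apply_occlusal_wear(premolar, d, seed=5)[1]
                   for d in (0.5, 1.0, 2.0)]
        assert removed[0] < removed[1] < removed[2]

    def test_depth_exceeding_height_rejected(self, premolar):
        with pytest.raises(ValueError, match="crown height"):
            st.apply_occlusal_wear(premolar, 99.0, seed=0)

    def test_ground_surface_is_rough_but_bounded(self, premolar):
        worn, _ = st.apply_occlusal_wear(premolar, 1.0, seed=3)
        z = worn.vertices[:, 2]
        cut = premolar.vertices[:, 2].max() - 1.0
        plateau = z > cut - 0.2
        # undulation present (not a perfect plane) yet within 50 um
        assert z[plateau].max() - cut <= 0.050 + 1e-9
        assert np.std(z[z > cut - 0.04]) > 1e-4


# ---------------------------------------------------------------------------
# lateral patch wear
# ---------------------------------------------------------------------------


class TestPatchWear:
    def test_zero_depth_is_identity(self, premolar):
        patch = st.PatchSpec(depth=0.0)
        worn, removed = st.apply_surface_patch_wear(premolar, patch)
        assert removed == 0.0
        assert np.array_equal(worn.vertices, premolar.vertices)

    def test_cosine_bump_matches_analytic_integral(self):
        # patch on the flat top of a watertight slab: removed volume is
        # the closed-form integral of the cosine bump, D*rho0^2*(pi/2-2/pi)
        depth, extent = 0.2, 4.0
        top = SurfaceMesh(*grid_slab(180))
        patch = st.PatchSpec(depth=depth, extent=extent)
        worn, removed = st.apply_surface_patch_wear(
            top, patch, center=np.array([0.0, 0.0, 2.0]),
            direction=np.array([0.0, 0.0, 1.0]))
        rho0 = extent / 2.0
        expected = depth * rho0 ** 2 * (np.pi / 2 - 2 / np.pi)
        assert worn.is_watertight
        assert removed == pytest.approx(expected, rel=0.01)

    def test_deeper_patch_removes_more(self, premolar):
        shallow = st.apply_surface_patch_wear(
            premolar, st.PatchSpec(depth=0.100, extent=4.0))[1]
        deep = st.apply_surface_patch_wear(
            premolar, st.PatchSpec(depth=0.250, extent=4.0))[1]
        assert deep > shallow

    def test_overlap_with_occlusal_region_rejected(self, premolar):
        high = st.PatchSpec(depth=0.2, extent=5.0, center_height_frac=0.9)
        with pytest.raises(ValueError, match="overlaps"):
            st.apply_surface_patch_wear(premolar, high,
                                        occlusal_exclusion_z=6.0)

    def test_invalid_spec_ranges_rejected(self):
        with pytest.raises(ValueError):
            st.PatchSpec(depth=0.7)
        with pytest.raises(ValueError):
            st.PatchSpec(extent=12.0)


def grid_slab(n=180, half=8.0, thickness=2.0):
    """Watertight slab with a finely gridded top face (for patch oracles)."""
    xs = np.linspace(-half, half, n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    top = np.column_stack([gx.ravel(), gy.ravel(),
                           np.full(n * n, thickness)])
    bottom = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
    v = np.vstack([top, bottom])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, c, d])
            faces.append([a, d, b])
            ab, bb, cb, db = a + n * n, b + n * n, c + n * n, d + n * n
            faces.append([ab, db, cb])
            faces.append([ab, bb, db])
    faces = np.asarray(faces)
    # stitch the four sides
    side = []
    for k in range(n - 1):
        pairs = [(k, k + 1), ((n - 1) * n + k + 1, (n - 1) * n + k),
                 ((k + 1) * n, k * n),
                 (k * n + n - 1, (k + 1) * n + n - 1)]
        for a, b in pairs:
            side.append([a, b, b + n * n])
            side.append([a, b + n * n, a + n * n])
    return v, np.vstack([faces, np.asarray(side)])


# ---------------------------------------------------------------------------
# crown pairs
# ---------------------------------------------------------------------------


class TestMakeCrownPair:
    def test_zero_wear_pair_is_displaced_copy(self):
        pair = st.make_crown_pair(
            st.premolar_spec(random_seed=3, mesh_resolution=2000),
            st.WearSpec(occlusal_depth=0.0, random_seed=1),
            displacement_seed=5)
        assert pair.true_occlusal_wear_volume == 0.0
        assert pair.true_buccolingual_wear_volume == 0.0
        t0 = st.generate_crown(st.premolar_spec(random_seed=3,
                                                mesh_resolution=2000))
        d = np.linalg.norm(pair.t1_aligned.vertices - t0.vertices, axis=1)
        assert d.max() < 1e-9

    def test_volume_bookkeeping_closes(self, worn_pair):
        diff = worn_pair.t0.enclosed_volume() \
            - worn_pair.t1_aligned.enclosed_volume()
        assert diff == pytest.approx(worn_pair.true_total_wear_volume,
                                     abs=1e-6)

    def test_deterministic(self):
        kwargs = dict(
            crown_spec=st.premolar_spec(random_seed=4, mesh_resolution=2000),
            wear_spec=st.WearSpec(occlusal_depth=1.0,
                                  buccal_patch=st.PatchSpec(),
                                  random_seed=2),
            displacement_seed=6)
        a, b = st.make_crown_pair(**kwargs), st.make_crown_pair(**kwargs)
        assert np.array_equal(a.t1.vertices, b.t1.vertices)
        assert a.true_occlusal_wear_volume == b.true_occlusal_wear_volume

    def test_unworn_vertices_congruent_under_true_alignment(self, worn_pair):
        spec = worn_pair.crown_spec
        t0 = st.generate_crown(spec)
        aligned = worn_pair.t1_aligned
        d = np.linalg.norm(aligned.vertices - t0.vertices, axis=1)
        untouched = d < 1e-9  # wear moved the rest
        assert untouched.mean() > 0.5

    def test_displacement_within_stated_bounds(self, worn_pair):
        t = worn_pair.true_alignment.inverse()
        assert np.rad2deg(t.rotation_angle()) <= 30.0 + 1e-9


class TestStudyReplica:
    def test_composition_and_determinism(self):
        replica = st.study_replica(n_teeth=12, seed=2, mesh_resolution=1500)
        types = [t.tooth_type for t in replica]
        assert types.count("premolar") == types.count("molar") == 6
        depths = sorted(t.nominal_depth for t in replica)
        assert depths.count(0.5) == depths.count(1.0) == depths.count(2.0)
        again = st.study_replica(n_teeth=12, seed=2, mesh_resolution=1500)
        assert np.array_equal(replica[5].pair.t1.vertices,
                              again[5].pair.t1.vertices)

    def test_patch_parameters_within_study_ranges(self):
        replica = st.study_replica(n_teeth=6, seed=3, mesh_resolution=1500)
        for tooth in replica:
            for patch in (tooth.pair.wear_spec.buccal_patch,
                          tooth.pair.wear_spec.lingual_patch):
                assert 3.0 <= patch.extent <= 5.0
                assert 0.100 <= patch.depth <= 0.250

    def test_ground_truth_conservation(self):
        replica = st.study_replica(n_teeth=4, seed=4, mesh_resolution=1500)
        for tooth in replica:
            pair = tooth.pair
            diff = pair.t0.enclosed_volume() \
                - pair.t1_aligned.enclosed_volume()
            assert diff == pytest.approx(pair.true_total_wear_volume,
                                         abs=1e-6)
            assert pair.t0.is_watertight and pair.t1.is_watertight
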