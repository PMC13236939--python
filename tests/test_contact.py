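import math

import numpy as np
import pytest

from ratknee.contact import (
    GapField,
    GeometryError,
    LoadCase,
    build_jcs,
    compartment_gap_field,
    pose_flexion,
    pose_varus,
    redistribute_load,
    solve_fraction_sweep,
    solve_indentation,
    solve_load_case_angle,
)
from ratknee.materials import MaterialSet, foundation_modulus
from ratknee.mesh import SurfaceMesh, directed_distances, rotation_matrix, spherical_band
from ratknee.cohort import generate_cohort

from conftest import zero_variance_config


def rigid_copy(specimen, R, t):
    out = specimen.copy()
    for body in out.bodies():
        body.vertices = body.vertices @ R.T + t
    return out


class TestJointCS:
    def test_axes_orthonormal_origin_at_midpoint(self, nominal):
        jcs = build_jcs(nominal)
        lm = nominal.landmarks
        assert np.allclose(jcs.origin, 0.5 * (lm["medial_epicondyle"] + lm["lateral_epicondyle"]))
        for a in (jcs.X, jcs.Y, jcs.Z):
            assert abs(np.linalg.norm(a) - 1) <= 1e-10
        for a, b in ((jcs.X, jcs.Y), (jcs.X, jcs.Z), (jcs.Y, jcs.Z)):
            assert abs(a @ b) <= 1e-10

    def test_equivariant_under_rigid_transform(self, nominal):
        rng = np.random.default_rng(2)
        R = rotation_matrix(rng.normal(size=3), 0.7)
        t = np.array([3.0, -2.0, 5.0])
        jcs0 = build_jcs(nominal)
        jcs1 = build_jcs(rigid_copy(nominal, R, t))
        assert np.allclose(jcs1.origin, R @ jcs0.origin + t, atol=1e-9)
        for a0, a1 in ((jcs0.X, jcs1.X), (jcs0.Z, jcs1.Z), (jcs0.Y, jcs1.Y)):
            assert np.allclose(a1, R @ a0, atol=1e-9)


class TestPosing:
    def test_zero_flexion_is_identity(self, nominal):
        posed = pose_flexion(nominal, build_jcs(nominal), 0.0)
        assert np.array_equal(posed.femur.vertices, nominal.femur.vertices)

    def test_flexion_inverts(self, nominal):
        jcs = build_jcs(nominal)
        there = pose_flexion(nominal, jcs, 80.0)
        back = pose_flexion(there, jcs, -80.0)
        assert np.max(np.abs(back.femur.vertices - nominal.femur.vertices)) <= 1e-10

    def test_flexion_is_rigid(self, nominal):
        jcs = build_jcs(nominal)
        posed = pose_flexion(nominal, jcs, 80.0)
        idx = np.arange(0, nominal.femur.n_vertices, 500)
        d0 = np.linalg.norm(nominal.femur.vertices[idx][:, None] - nominal.femur.vertices[idx], axis=2)
        d1 = np.linalg.norm(posed.femur.vertices[idx][:, None] - posed.femur.vertices[idx], axis=2)
        assert np.max(np.abs(d0 - d1)) <= 1e-10

    def test_varus_lowers_medial_condyle(self, nominal):
        jcs = build_jcs(nominal)
        tilted = pose_varus(nominal, jcs, 4.0)
        patch = nominal.cartilage_patch("femur", "medial")
        before = nominal.femur.face_centroids()[patch.face_indices].mean(0)
        after = tilted.femur.face_centroids()[patch.face_indices].mean(0)
        assert (after - before) @ jcs.Z > 0


class TestLoadRedistribution:
    @pytest.mark.parametrize("level,expected", [(0, (1.47, 1.47)), (50, (2.205, 0.735)),
                                                (100, (2.94, 0.0))])
    def test_varus_splits(self, level, expected):
        med, lat = redistribute_load(2.94, level)
        assert (med, lat) == pytest.approx(expected)
        assert med + lat == pytest.approx(2.94)

    def test_unsupported_level_rejected(self):
        with pytest.raises(ValueError):
            redistribute_load(2.94, 30)


class TestGapField:
    def test_sphere_over_plane_is_locally_parabolic(self):
        """Gap to a meshed sphere follows g0 + r^2/(2R) near the pole."""
        R, g0 = 2.0, 0.1
        cap = spherical_band(np.zeros(3), R, (-0.35, 0.35), 0.35, 60, 60, "other")
        xs = np.linspace(-0.5, 0.5, 11)
        X, Y = np.meshgrid(xs, xs)
        origins = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, R + g0)])
        d = directed_distances(cap, origins, np.array([0.0, 0.0, -1.0]))
        r2 = X.ravel() ** 2 + Y.ravel() ** 2
        expected = g0 + r2 / (2 * R)
        within = r2 <= 0.5**2  # lateral offsets up to 0.5 mm
        assert np.isfinite(d[within]).all()
        assert np.max(np.abs(d[within] - expected[within]) / expected[within]) <= 0.01

    def test_conforming_compartment_gap_matches_design_curvature(self, nominal):
        jcs = build_jcs(nominal)
        posed = pose_flexion(nominal, jcs, 80.0)
        f = compartment_gap_field(posed, jcs, "medial")
        cent = posed.tibia_fibula.face_centroids()[f.face_ids]
        r = np.sqrt((cent[:, 0] + 2.3) ** 2 + cent[:, 1] ** 2)
        expected = 0.5 * 0.00402 * r**2
        inner = r < 1.5
        assert np.max(np.abs(f.gaps[inner] - expected[inner])) <= 1.5e-3  # mm

    def test_axial_translation_shifts_gaps_linearly(self, nominal):
        jcs = build_jcs(nominal)
        posed = pose_flexion(nominal, jcs, 80.0)
        from ratknee.contact import translate_femur
        moved = translate_femur(posed, jcs.Z, 0.05)
        f0 = compartment_gap_field(posed, jcs, "medial")
        f1 = compartment_gap_field(moved, jcs, "medial")
        common = np.intersect1d(f0.face_ids, f1.face_ids)
        g0 = f0.gaps[np.isin(f0.face_ids, common)]
        g1 = f1.gaps[np.isin(f1.face_ids, common)]
        assert np.max(np.abs((g0 - g1) - 0.05)) <= 1e-9


def _analytic_sphere_field(R=2.0, h=0.05, extent=0.6):
    """Equal-area, low-discrepancy (sunflower) sampling of the contact disk.

    Elements are radius-ordered, so counting full element areas tracks the
    analytic contact-disk area to about one element at the 0.05 mm size.
    """
    import math as _m
    n = int(_m.pi * extent**2 / (h * h))
    r = extent * np.sqrt((np.arange(n) + 0.5) / n)
    gaps = r**2 / (2 * R)
    areas = np.full(n, h * h)
    return GapField(side="medial", gaps=gaps, areas=areas, face_ids=np.arange(n),
                    candidates=gaps <= 1e9, patch_area=float(areas.sum()))


class TestFoundationSolve:
    def test_zero_target_force_zero_field(self):
        u, res = solve_indentation(_analytic_sphere_field(), 102.6846, 0.5, 0.0)
        assert res.peak_pressure == 0.0 and res.contact_area == 0.0

    def test_sphere_on_foundation_closed_form(self):
        """F = pi E R u^2 / t for a rigid sphere on an elastic foundation."""
        E, t, R, F = foundation_modulus(6.0, 0.49), 0.5, 2.0, 1.47
        u, res = solve_indentation(_analytic_sphere_field(R=R), E, t, F)
        u_exact = math.sqrt(F * t / (math.pi * E * R))
        assert u == pytest.approx(u_exact, rel=0.02)
        assert res.peak_pressure == pytest.approx(E / t * u_exact, rel=0.02)
        assert res.contact_area == pytest.approx(2 * math.pi * R * u_exact, rel=0.02)
        assert res.achieved_force == pytest.approx(F, abs=1e-6)

    def test_doubling_force_scales_indentation_sqrt2(self):
        E, t = foundation_modulus(6.0, 0.49), 0.5
        u1, _ = solve_indentation(_analytic_sphere_field(), E, t, 1.47)
        u2, _ = solve_indentation(_analytic_sphere_field(), E, t, 2.94)
        assert u2 / u1 == pytest.approx(math.sqrt(2), rel=0.02)

    def test_empty_candidates_for_loaded_compartment_raises(self):
        field = _analytic_sphere_field()
        field = GapField("medial", field.gaps, field.areas, field.face_ids,
                         np.zeros(len(field.gaps), dtype=bool), field.patch_area)
        with pytest.raises(GeometryError):
            solve_indentation(field, 100.0, 0.5, 1.0)


class TestFractionMode:
    def test_total_force_conserved_at_every_level(self, nominal, materials):
        out = solve_fraction_sweep(nominal, materials, [0, 50, 100])
        for oc in out.values():
            total = oc.medial.achieved_force + oc.lateral.achieved_force
            assert abs(total - 2.94) <= 1e-4

    def test_medial_monotone_lateral_antitone(self, nominal, materials):
        out = solve_fraction_sweep(nominal, materials, [0, 50, 100])
        mp = [out[lv].medial.peak_pressure for lv in (0, 50, 100)]
        ma = [out[lv].medial.contact_area for lv in (0, 50, 100)]
        lp = [out[lv].lateral.peak_pressure for lv in (0, 50, 100)]
        la = [out[lv].lateral.contact_area for lv in (0, 50, 100)]
        assert mp == sorted(mp) and ma == sorted(ma)
        assert lp == sorted(lp, reverse=True) and la == sorted(la, reverse=True)

    def test_unloaded_lateral_compartment_at_full_varus(self, nominal, materials):
        oc = solve_fraction_sweep(nominal, materials, [100])[100]
        assert oc.lateral.peak_pressure == 0.0
        assert oc.lateral.contact_area == 0.0
        assert oc.lateral.near_contact_area > 0.0  # within-pinball diagnostic

    def test_results_invariant_under_whole_joint_rigid_motion(self, nominal, materials):
        R = rotation_matrix(np.array([0.3, 1.0, -0.2]), 0.5)
        moved = rigid_copy(nominal, R, np.array([4.0, 1.0, -2.0]))
        a = solve_fraction_sweep(nominal, materials, [50])[50]
        b = solve_fraction_sweep(moved, materials, [50])[50]
        assert b.medial.peak_pressure == pytest.approx(a.medial.peak_pressure, rel=1e-3)
        assert b.medial.contact_area == pytest.approx(a.medial.contact_area, rel=1e-3)

    def test_pressure_fields_nonnegative_area_bounded(self, nominal, materials):
        oc = solve_fraction_sweep(nominal, materials, [50])[50]
        for comp in (oc.medial, oc.lateral):
            assert np.all(comp.pressures >= 0)
            assert comp.contact_area <= comp.near_contact_area + 1e-9


@pytest.fixture(scope="module")
def symmetric():
    cfg = zero_variance_config(conformity_lateral=0.00402)
    return generate_cohort(cfg)[0]


class TestAngleMode:
    def test_neutral_angle_splits_evenly_on_symmetric_joint(self, symmetric, materials):
        case = LoadCase(mode="angle", varus_angle=0.0)
        oc = solve_load_case_angle(symmetric, materials, case)
        assert oc.medial.achieved_force == pytest.approx(oc.lateral.achieved_force, rel=0.01)

    def test_zero_stiffness_ligaments_conserve_applied_load(self, symmetric):
        slack = MaterialSet(ligament_table={k: (1e-9, 0.0) for k in ("ACL", "PCL", "MCL", "LCL")})
        oc = solve_load_case_angle(symmetric, slack, LoadCase(mode="angle", varus_angle=3.0))
        assert abs(oc.total_contact_force - 2.94) <= 1e-4

    def test_medial_fraction_monotone_in_angle(self, symmetric, materials):
        fracs = []
        for angle in (0.0, 3.0, 6.0):
            oc = solve_load_case_angle(symmetric, materials,
                                       LoadCase(mode="angle", varus_angle=angle))
            fracs.append(oc.medial_fraction)
        assert fracs[0] < fracs[1] <= fracs[2]
        assert fracs[0] == pytest.approx(0.5, abs=0.02)


class TestLoadCaseValidation:
    def test_invalid_cases_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(varus_level=30)
        with pytest.raises(ValueError):
            LoadCase(total_force=-1.0)
        with pytest.raises(ValueError):
            LoadCase(mode="angle", varus_angle=45.0)
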