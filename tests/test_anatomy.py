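"""Synthetic anatomy: determinism, watertightness, calibration, population."""

import numpy as np
import pytest

import mortisesim as ms
from mortisesim.anatomy import AnatomyParams, ParameterError, Population
from mortisesim.measurement import measure_incisura_depth

from conftest import COARSE


class TestSpecimenGeneration:
    def test_deterministic_for_fixed_params(self):
        p = AnatomyParams(seed=7)
        a = ms.generate_specimen(p, **COARSE)
        b = ms.generate_specimen(p, **COARSE)
        for bone in ("tibia_mesh", "fibula_mesh", "talus_mesh"):
            assert getattr(a, bone).vertices.tobytes() == \
                getattr(b, bone).vertices.tobytes()

    def test_different_draws_differ(self):
        pop = Population()
        c = ms.generate_cohort(2, pop, seed=1, **COARSE)
        d = ms.generate_cohort(2, pop, seed=2, **COARSE)
        assert c[0].fibula_mesh.vertices.tobytes() != d[0].fibula_mesh.vertices.tobytes()

    def test_meshes_watertight_default_resolution(self, specimen):
        for mesh in specimen.bones().values():
            assert mesh.is_watertight()
            assert mesh.volume() > 0

    def test_watertight_over_random_parameter_draws(self):
        pop = Population()
        rng = np.random.default_rng(42)
        for _ in range(100):
            spec = ms.generate_specimen(pop.sample_params(rng), **COARSE)
            for mesh in spec.bones().values():
                assert mesh.is_watertight()

    def test_no_self_intersections_random_draws(self):
        pop = Population()
        rng = np.random.default_rng(99)
        for _ in range(8):
            spec = ms.generate_specimen(pop.sample_params(rng), **COARSE)
            assert not spec.fibula_mesh.self_intersects()
            assert not spec.tibia_mesh.self_intersects()

    def test_no_tibiofibular_overlap_at_neutral(self, specimen):
        assert not ms.meshes_intersect(specimen.fibula_mesh, specimen.tibia_mesh)
        assert not ms.meshes_intersect(specimen.fibula_mesh, specimen.talus_mesh)

    def test_canal_landmarks_inside_fibula(self, specimen):
        pts = np.stack([specimen.landmarks["fibula_canal_distal"],
                        specimen.landmarks["fibula_canal_proximal"]])
        assert specimen.fibula_mesh.contains(pts).all()

    def test_fossa_wall_ring_lies_on_surface(self, specimen):
        """Ring points must sit on the carved fibular surface within 0.1 mm."""
        ring = specimen.landmarks["fossa_wall_ring"]
        tri = specimen.fibula_mesh.triangles()
        mids = tri.mean(axis=1)
        from scipy.spatial import cKDTree

        # distance from ring points to nearest triangle plane patch (approx:
        # distance to nearest facet centroid minus facet radius bound)
        d, idx = cKDTree(mids).query(ring)
        near = tri[idx]
        n = np.cross(near[:, 1] - near[:, 0], near[:, 2] - near[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        plane_dist = np.abs(np.einsum("ij,ij->i", ring - near[:, 0], n))
        assert plane_dist.max() < 0.1


class TestCalibration:
    def test_neutral_alpha_matches_offset_fraction(self, specimen):
        """Closed-loop: pipeline alpha at neutral equals the calibrated
        fraction, checked against a direct 3D computation of the three
        abscissae (no meshes, no rendering)."""
        _, meas = ms.measure_pose(specimen, 0.0)
        f = specimen.params.fossa_medial_offset_frac
        assert meas.alpha == pytest.approx(f, abs=0.02)

        # independent oracle: off-centre-circle silhouette + wall-ring level
        p = specimen.params
        v = np.radians(15.0)
        fx = specimen.landmarks["fibula_canal_distal"][0]
        R = p.malleolus_width / 2.0
        d = p.malleolus_offset
        u_cmal = (fx + d) * np.cos(v)  # malleolar centre, rotated by the view
        uA, uC = u_cmal - R, u_cmal + R
        ring = specimen.landmarks["fossa_wall_ring"]
        rot = np.array([[np.cos(v), -np.sin(v), 0], [np.sin(v), np.cos(v), 0], [0, 0, 1]])
        rv = ring @ rot.T
        level = specimen.landmarks["medial_malleolus_tip"][2]
        at_level = rv[np.isclose(rv[:, 2], level, atol=1e-6)]
        uB = at_level[:, 0].min()          # medial branch of the ring
        alpha_oracle = (uB - uA) / (uC - uA)
        assert meas.alpha == pytest.approx(alpha_oracle, abs=0.01)

    def test_flat_incisura_measures_zero(self):
        p = AnatomyParams(incisura_depth=0.0)
        spec = ms.generate_specimen(p)
        metrics = measure_incisura_depth(spec.tibia_mesh, p.plafond_z)
        assert abs(metrics.depth_mm) <= 0.1
        assert metrics.type == "shallow"

    @pytest.mark.parametrize("depth", [3.0, 4.8])
    def test_carved_sagitta_is_recovered(self, depth):
        spec = ms.generate_specimen(AnatomyParams(incisura_depth=depth))
        metrics = measure_incisura_depth(spec.tibia_mesh, 0.0)
        assert metrics.depth_mm == pytest.approx(depth, abs=0.1)


class TestMirrorSymmetry:
    def test_double_mirror_is_identity(self, coarse_specimen):
        back = ms.mirror_specimen(ms.mirror_specimen(coarse_specimen))
        assert np.allclose(back.fibula_mesh.vertices, coarse_specimen.fibula_mesh.vertices)
        assert back.side == coarse_specimen.side

    @pytest.mark.parametrize("angle", [-20.0, 15.0])
    def test_alpha_invariant_under_mirroring(self, specimen, angle):
        """A mirrored (left) ankle with the side-aware sign convention gives
        the same ratio alpha at the same internal-rotation angle."""
        _, m_right = ms.measure_pose(specimen, angle)
        _, m_left = ms.measure_pose(ms.mirror_specimen(specimen), angle)
        assert m_left.alpha == pytest.approx(m_right.alpha, abs=1e-9)


class TestPopulation:
    def test_concave_fraction_matches_configuration(self):
        pop = Population()
        rng = np.random.default_rng(2024)
        depths = pop.sample_incisura_depth(rng, 10_000)
        frac = float((depths >= 4.0).mean())
        assert abs(frac - pop.p_concave) < 0.02

    def test_cohort_concave_count_within_binomial_band(self):
        """n=96 at p=0.583: 3-sigma band around 56 is [45, 67]."""
        cohort = ms.generate_cohort(96, seed=0, **COARSE)
        n_concave = sum(s.params.incisura_depth >= 4.0 for s in cohort)
        assert 45 <= n_concave <= 67

    def test_single_specimen_cohort(self):
        cohort = ms.generate_cohort(1, seed=5, **COARSE)
        assert len(cohort) == 1

    def test_cohort_size_must_be_positive(self):
        with pytest.raises(ParameterError):
            ms.generate_cohort(0)


class TestRoster:
    def test_study_roster_accounting(self):
        roster = ms.generate_roster(120, 12, 7, 5, seed=0)
        included, acc = ms.apply_exclusions(roster)
        assert len(included) == 96
        assert acc["excluded_prior_fracture"] == 12
        assert acc["excluded_under_18"] == 7
        assert acc["excluded_poor_image_quality"] == 5

    def test_flags_mutually_exclusive(self):
        roster = ms.generate_roster(50, 10, 10, 10, seed=3)
        flagged = roster.records[list(roster.FLAGS)].sum(axis=1)
        assert flagged.max() <= 1
        assert (roster.records["age"] >= 0).all()
        under = roster.records[roster.records["under_18"] == 1]
        assert (under["age"] < 18).all()

    def test_no_flags_means_all_included(self):
        included, _ = ms.apply_exclusions(ms.generate_roster(10, 0, 0, 0, seed=1))
        assert len(included) == 10

    def test_counts_exceeding_total_rejected(self):
        with pytest.raises(ParameterError):
            ms.generate_roster(5, 3, 3, 0)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(fossa_medial_offset_frac=0.0), "fossa_medial_offset_frac"),
        (dict(fossa_medial_offset_frac=1.2), "fossa_medial_offset_frac"),
        (dict(malleolus_width=-1.0), "malleolus_width"),
        (dict(incisura_chord=40.0, tibia_radius=18.0), "incisura_chord"),
        (dict(sex="other"), "sex"),
    ])
    def test_invalid_parameters_named_in_error(self, kwargs, field):
        with pytest.raises(ParameterError, match=field):
            ms.generate_specimen(AnatomyParams(**kwargs))


class TestSpecimenIO:
    @pytest.mark.parametrize("fmt", ["stl", "obj"])
    def test_save_load_roundtrip(self, tmp_path, coarse_specimen, fmt):
        ms.save_specimen(coarse_specimen, tmp_path, fmt=fmt)
        back = ms.load_specimen(tmp_path, coarse_specimen.specimen_id, fmt=fmt)
        assert back.fibula_mesh.is_watertight()
        assert back.fibula_mesh.volume() == pytest.approx(
            coarse_specimen.fibula_mesh.volume(), rel=1e-5)
        for key in ("medial_malleolus_tip", "plafond_medial", "plafond_lateral"):
            assert np.allclose(back.landmarks[key], coarse_specimen.landmarks[key])

    def test_left_specimen_mirrored_at_load(self, tmp_path, coarse_specimen):
        left = ms.mirror_specimen(coarse_specimen, rename=False)
        ms.save_specimen(left, tmp_path / "left")
        back = ms.load_specimen(tmp_path / "left", left.specimen_id)
        assert back.side == "right"   # canonicalised on load
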