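"""Shape model: feature layout, PCA fit/synthesis, variance bookkeeping,
subcohort grouping, mean cases and disc-parameterization correspondence."""

import numpy as np
import pytest

from lvshapeflow.correspondence import (
    PatchTemplate,
    PatchTopologyError,
    correspond,
)
from lvshapeflow.geometry import CaseMetadata, LVGeometry, SurfaceMesh
from lvshapeflow.segments import SegmentMap, assign_segments, segment_aggregate
from lvshapeflow.ssm import (
    FeatureMatrix,
    ShapeVector,
    assemble_feature_vector,
    cohort_mean,
    cumulative_variance,
    fit_model,
    group_cases,
    load_model,
    modes_for_variance,
    save_model,
    shape_vector_to_geometry,
    synthesize,
)
from lvshapeflow.synthetic import make_cohort


class TestShapeVector:
    def test_toy_length(self):
        sv = ShapeVector(np.zeros((4, 3)), np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        assert len(sv.pack()) == 31  # 7*4 + 3

    def test_pack_unpack_roundtrip(self):
        rng = np.random.default_rng(0)
        sv = ShapeVector(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)),
                         rng.random(10), rng.normal(size=3))
        back = ShapeVector.unpack(sv.pack())
        np.testing.assert_array_equal(back.pack(), sv.pack())

    def test_rca_occupies_last_three_entries(self, default_lv):
        import copy

        a = assemble_feature_vector(default_lv).pack()
        other = copy.deepcopy(default_lv)
        other.ed_mesh.landmarks["rca_ostium"] = (
            other.ed_mesh.landmark_point("rca_ostium") + [1.0, 2.0, 3.0])
        b = assemble_feature_vector(other).pack()
        assert np.array_equal(a[:-3], b[:-3])
        assert not np.array_equal(a[-3:], b[-3:])


class TestFitModel:
    def test_identical_cases_collapse(self, default_lv):
        v = assemble_feature_vector(default_lv).pack()
        M = FeatureMatrix(np.column_stack([v, v, v]), ["a", "b", "c"])
        model = fit_model(M)
        assert model.eigenvalues.max() < 1e-12 * np.dot(model.mean, model.mean)
        np.testing.assert_allclose(model.mean, v)

    def test_rank_bound(self):
        spec = make_cohort(5, (4.0, 2.0, 1.0), noise=0.5, seed=5)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        significant = model.eigenvalues > 1e-10 * model.eigenvalues[0]
        assert significant.sum() <= 4

    def test_planted_modes_recovered(self):
        spec = make_cohort(40, (4.0, 2.0), noise=0.0, seed=3)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        cum = cumulative_variance(model)
        assert cum[1] >= 0.999
        s = np.linalg.svd(spec.mode_directions.T @ model.modes[:, :2],
                          compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, 0, 1)))
        assert angles.max() < 1.0

    def test_single_case_rejected(self, default_lv):
        v = assemble_feature_vector(default_lv).pack()
        with pytest.raises(ValueError):
            fit_model(FeatureMatrix(v[:, None], ["only"]))

    def test_orthonormal_modes_and_variance_trace(self):
        spec = make_cohort(12, (4.0, 2.0, 1.0), noise=0.3, seed=9)
        M = FeatureMatrix.from_cases(spec.cases)
        model = fit_model(M)
        G = model.modes.T @ model.modes
        np.testing.assert_allclose(G, np.eye(model.n_modes), atol=1e-8)
        centered = M.M - M.M.mean(axis=1, keepdims=True)
        total = np.sum(centered**2) / (M.n - 1)
        assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-8)


class TestSynthesize:
    def test_zero_weights_give_mean(self):
        spec = make_cohort(8, (3.0,), noise=0.2, seed=1)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        np.testing.assert_array_equal(synthesize(model, np.zeros(3)), model.mean)

    def test_training_case_reconstruction(self):
        spec = make_cohort(10, (4.0, 2.0, 1.0), noise=0.5, seed=2)
        M = FeatureMatrix.from_cases(spec.cases)
        model = fit_model(M)
        for j in (0, 4, 9):
            x = M.M[:, j]
            rec = synthesize(model, model.project(x))
            assert np.linalg.norm(rec - x) / np.linalg.norm(x) < 1e-8

    def test_single_mode_excursion_stays_on_mode(self):
        spec = make_cohort(10, (4.0, 2.0), noise=0.0, seed=4)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        b = np.zeros(2)
        b[0] = 3.0 * np.sqrt(model.eigenvalues[0])
        out = synthesize(model, b)
        delta = out - model.mean
        residual = delta - model.modes[:, 0] * (model.modes[:, 0] @ delta)
        assert np.linalg.norm(residual) < 1e-10

    def test_linearity(self):
        spec = make_cohort(10, (4.0, 2.0), noise=0.1, seed=6)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        b1, b2 = np.array([2.0, -1.0]), np.array([-0.5, 3.0])
        lhs = synthesize(model, b1 + b2) - model.mean
        rhs = (synthesize(model, b1) - model.mean) + (synthesize(model, b2) - model.mean)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_too_many_weights_rejected(self):
        spec = make_cohort(4, (3.0,), noise=0.0, seed=0)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        with pytest.raises(ValueError):
            synthesize(model, np.zeros(model.n_modes + 1))


class TestVariance:
    def test_printed_example(self):
        from lvshapeflow.ssm import SSModel

        model = SSModel(mean=np.zeros(10), modes=np.eye(10)[:, :4],
                        eigenvalues=np.array([4.0, 3.0, 2.0, 1.0]), n_train=5)
        assert modes_for_variance(model, 0.9) == 3
        assert modes_for_variance(model, 1.0) == 4

    def test_geometric_decay_closed_form(self):
        from lvshapeflow.ssm import SSModel

        ratio, k = 0.8, 30
        eig = ratio ** np.arange(k)
        model = SSModel(np.zeros(64), np.linalg.qr(
            np.random.default_rng(0).normal(size=(64, k)))[0], eig, k + 1)
        for target in (0.5, 0.8, 0.95):
            # cumsum of geometric series: (1 - r^j) / (1 - r^k)
            j = np.arange(1, k + 1)
            closed = int(j[(1 - ratio**j) / (1 - ratio**k) >= target - 1e-12][0])
            assert modes_for_variance(model, target) == closed


class TestGrouping:
    @pytest.mark.parametrize("aneurysm, mr, expected", [
        ("none", 1.0, ("A0ML",)),
        ("true", 2.0, ("A1MH", "A1T")),
        ("intermediate", 1.99, ("A1ML", "A1I")),
        ("hypokinetic", 2.5, ("A1MH", "A1HK")),
        ("unclassified", 2.0, ("A1MH",)),
    ])
    def test_rules(self, aneurysm, mr, expected):
        labels = group_cases([CaseMetadata(mr, aneurysm)])
        assert labels[0] == expected

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError):
            group_cases([None])


class TestCohortMean:
    def test_mean_of_two_sphere_like_cases(self):
        spec = make_cohort(2, (4.0,), noise=0.0, seed=8)
        vecs = [assemble_feature_vector(c) for c in spec.cases]
        mean = cohort_mean(vecs)
        np.testing.assert_allclose(
            mean.pack(), 0.5 * (vecs[0].pack() + vecs[1].pack()), atol=1e-12)

    def test_equals_model_mean(self):
        spec = make_cohort(9, (4.0, 2.0), noise=0.3, seed=12)
        vecs = [assemble_feature_vector(c) for c in spec.cases]
        M = FeatureMatrix.from_cases(spec.cases)
        np.testing.assert_allclose(cohort_mean(vecs).pack(), fit_model(M).mean,
                                   atol=1e-12)

    def test_mean_segmental_motion_within_cohort_envelope(self):
        spec = make_cohort(40, (3.0, 1.5), noise=0.2, seed=21)
        vecs = [assemble_feature_vector(c) for c in spec.cases]
        mean_geo = shape_vector_to_geometry(
            cohort_mean(vecs), spec.cases[0].ed_mesh.faces,
            landmarks=spec.cases[0].ed_mesh.landmarks)
        segmap = assign_segments(mean_geo.ed_mesh)
        per_case = np.array([
            segment_aggregate(segmap, np.linalg.norm(c.displacement, axis=1))
            for c in spec.cases])
        mean_agg = segment_aggregate(
            segmap, np.linalg.norm(mean_geo.displacement, axis=1))
        lo, hi = per_case.min(axis=0), per_case.max(axis=0)
        assert np.all(mean_agg >= lo - 1e-9)
        assert np.all(mean_agg <= hi + 1e-9)

    def test_empty_subcohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_mean([])


class TestTwoModelDiscipline:
    def test_aneurysm_model_first_mode_carries_thinning(self):
        """Separate models on aneurysmatic vs normal subcohorts: only the
        aneurysmatic model's dominant thickness-channel loadings mark a
        focal thin-walled region."""
        from lvshapeflow.synthetic import LVGenParams, make_lv

        def cohort(aneurysm, seed):
            cases = []
            for i in range(8):
                if aneurysm:
                    params = LVGenParams(aneurysm="true",
                                         bulge_amplitude=6.0 + 0.8 * i,
                                         thinning=0.30 + 0.04 * i, seed=seed + i)
                else:
                    params = LVGenParams(aneurysm="none",
                                         sphericity=0.60 + 0.012 * i, seed=seed + i)
                cases.append(make_lv(params))
            return cases

        m = cohort(True, 0)[0].ed_mesh.n_vertices
        model_a = fit_model(FeatureMatrix.from_cases(cohort(True, 0)))
        model_n = fit_model(FeatureMatrix.from_cases(cohort(False, 100)))

        def thickness_loading_peak(model):
            v_channel = model.modes[6 * m : 7 * m, 0]
            return np.abs(v_channel).max() / max(np.abs(model.modes[:, 0]).max(), 1e-30)

        assert thickness_loading_peak(model_a) > 5 * thickness_loading_peak(model_n)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        spec = make_cohort(6, (3.0, 1.0), noise=0.2, seed=17)
        model = fit_model(FeatureMatrix.from_cases(spec.cases))
        save_model(model, tmp_path / "model", faces=spec.cases[0].ed_mesh.faces)
        back, faces = load_model(tmp_path / "model")
        np.testing.assert_array_equal(back.mean, model.mean)
        np.testing.assert_array_equal(back.modes, model.modes)
        np.testing.assert_array_equal(back.eigenvalues, model.eigenvalues)
        assert back.n_train == model.n_train
        np.testing.assert_array_equal(faces, spec.cases[0].ed_mesh.faces)


class TestCorrespondence:
    def test_near_idempotent_on_source_mesh(self, default_lv):
        mesh = default_lv.ed_mesh
        segmap = assign_segments(mesh)
        res, _ = correspond(mesh, segmap)
        from lvshapeflow.geometry import closest_points_on_surface

        _, dist, _ = closest_points_on_surface(mesh, res.vertices)
        edge = np.linalg.norm(
            mesh.vertices[mesh.faces[:, 0]] - mesh.vertices[mesh.faces[:, 1]],
            axis=1).mean()
        assert dist.max() < edge

    def test_fixed_vertex_count(self, default_lv):
        template = PatchTemplate(n_radial=5, n_angular=16)
        segmap = assign_segments(default_lv.ed_mesh)
        res, _ = correspond(default_lv.ed_mesh, segmap, template)
        assert res.n_vertices == template.total_points == 17 * (5 * 16 + 1)

    def test_concentric_spheres_radial_offset(self, sphere_case_30, sphere_case_33):
        r30, _ = correspond(sphere_case_30, assign_segments(sphere_case_30))
        r33, _ = correspond(sphere_case_33, assign_segments(sphere_case_33))
        d = np.linalg.norm(r33.vertices - r30.vertices, axis=1)
        assert np.all(np.abs(d - 3.0) < 0.2)

    def test_field_interpolation_preserves_constant(self, default_lv):
        segmap = assign_segments(default_lv.ed_mesh)
        _, fields = correspond(default_lv.ed_mesh, segmap,
                               fields={"c": np.full(default_lv.ed_mesh.n_vertices, 2.5)})
        np.testing.assert_allclose(fields["c"], 2.5, atol=1e-12)

    def test_patch_with_hole_rejected(self):
        # flat annulus (square with a square hole) labeled as one patch
        n = 9
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        keep = ~((xs > 2) & (xs < 6) & (ys > 2) & (ys < 6))
        idx = -np.ones((n, n), int)
        idx[keep] = np.arange(keep.sum())
        verts = np.column_stack([xs[keep], ys[keep], np.zeros(keep.sum())])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                q = [idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]]
                if min(q) >= 0:
                    faces.append([q[0], q[1], q[2]])
                    faces.append([q[0], q[2], q[3]])
        mesh = SurfaceMesh(verts, np.array(faces))
        segmap = SegmentMap(labels=np.ones(len(verts), np.int64),
                            apex=np.array([4.0, 4.0, -10.0]),
                            base_point=np.array([4.0, 4.0, 10.0]),
                            axis=np.array([0.0, 0.0, -1.0]),
                            azimuth_ref=np.array([1.0, 0.0, 0.0]),
                            cap_fraction=0.1)
        template = PatchTemplate(n_patches=1)
        with pytest.raises(PatchTopologyError, match="segment 1"):
            correspond(mesh, segmap, template)
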