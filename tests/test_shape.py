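import numpy as np
import pytest

from ratknee.mesh import rotation_matrix
from ratknee.shape import (
    BlockLayout,
    ShapeAppearanceModel,
    build_ssam,
    cohort_matrix,
    fit_coefficients,
    from_shape_vector,
    gpa_align,
    loo_validate,
    reconstruct_specimen,
    sample_ssam,
    specimen_raw_vector,
    to_shape_vector,
)
from ratknee.cohort import generate_cohort

from conftest import coarse_config, zero_variance_config


def _aligned_target_points(bundle, target):
    from ratknee.shape import procrustes_align, specimen_raw_vector
    layout = bundle.layout
    x = specimen_raw_vector(target, layout)
    S = x[: layout.n_shape].reshape(layout.n_points, 3)
    return procrustes_align(S, bundle.model.alignment_ref_)


class TestVectorization:
    def test_round_trip_reproduces_specimen(self, coarse_cohort):
        s = coarse_cohort[0]
        layout = BlockLayout.from_specimen(s)
        vec = to_shape_vector(s, w_s=2.0, w_a=0.5, layout=layout)
        back = from_shape_vector(vec, s, w_s=2.0, w_a=0.5, layout=layout)
        for body in ("femur", "tibia_fibula", "patella"):
            assert np.max(np.abs(back.body(body).vertices - s.body(body).vertices)) <= 1e-12
            assert np.max(np.abs(back.body(body).vertex_density - s.body(body).vertex_density)) <= 1e-12

    def test_identical_specimens_identical_vectors(self, coarse_cohort):
        v1 = specimen_raw_vector(coarse_cohort[0])
        v2 = specimen_raw_vector(coarse_cohort[0].copy())
        assert np.array_equal(v1, v2)

    def test_nonpositive_weights_rejected(self, coarse_cohort):
        with pytest.raises(ValueError):
            to_shape_vector(coarse_cohort[0], w_s=1.0, w_a=0.0)


class TestProcrustes:
    def test_rigid_motion_copies_collapse(self, coarse_cohort):
        base = np.vstack([b.vertices for b in coarse_cohort[0].bodies()])
        rng = np.random.default_rng(0)
        sets = []
        for _ in range(4):
            R = rotation_matrix(rng.normal(size=3), rng.uniform(0, 2 * np.pi))
            sets.append(base @ R.T + rng.normal(scale=5.0, size=3))
        aligned, _ = gpa_align(np.stack(sets))
        for i in range(1, 4):
            rms = np.sqrt(np.mean((aligned[i] - aligned[0]) ** 2))
            assert rms <= 1e-8

    def test_idempotent_on_aligned_cohort(self, coarse_cohort):
        pts = np.stack([np.vstack([b.vertices for b in s.bodies()]) for s in coarse_cohort[:4]])
        once, _ = gpa_align(pts)
        twice, _ = gpa_align(once)
        assert np.max(np.abs(twice - once)) <= 1e-10

    def test_alignment_reduces_objective(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(50, 3))
        sets = []
        for _ in range(3):
            R = rotation_matrix(rng.normal(size=3), rng.uniform(0.2, 1.0))
            sets.append(base @ R.T + rng.normal(scale=0.05, size=(50, 3)))
        X = np.stack(sets)
        before = ((X - X.mean(0)) ** 2).sum()
        aligned, _ = gpa_align(X)
        after = ((aligned - aligned.mean(0)) ** 2).sum()
        assert after < before


def _random_model(rng, n=8, counts=(6, 4, 3)):
    layout = BlockLayout(counts)
    X = rng.normal(size=(n, layout.n_total))
    model = ShapeAppearanceModel(layout=layout, w_a=1.0, align=False)
    return model.fit(X), X


class TestPCA:
    def test_matches_explicit_covariance_eigendecomposition(self):
        """Brute-force oracle: eigenpairs of the explicit sample covariance."""
        rng = np.random.default_rng(3)
        model, X = _random_model(rng)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.sd_**2, evals[: model.n_components_], atol=1e-8)
        # components diagonalise the covariance
        proj = model.components_ @ cov @ model.components_.T
        assert np.allclose(proj, np.diag(model.sd_**2), atol=1e-8)

    def test_total_variance_equals_covariance_trace(self):
        rng = np.random.default_rng(4)
        model, X = _random_model(rng)
        trace = np.trace(np.cov(X, rowvar=False, ddof=1))
        assert model.total_variance_ == pytest.approx(trace, rel=1e-8)

    def test_rank_bound_nine_training_limbs(self):
        rng = np.random.default_rng(5)
        model, _ = _random_model(rng, n=9, counts=(30, 20, 10))
        assert model.n_components_ <= 8

    def test_component_signs_deterministic(self):
        rng = np.random.default_rng(6)
        model, X = _random_model(rng)
        model2 = ShapeAppearanceModel(layout=model.layout, w_a=1.0, align=False).fit(X)
        assert np.allclose(model.components_, model2.components_)
        for c in model.components_:
            assert c[np.argmax(np.abs(c))] > 0


class TestSpecimenModel:
    def test_zero_variance_training_reproduces_specimen(self):
        cohort = generate_cohort(zero_variance_config(seed=2))
        bundle = build_ssam(cohort)
        assert bundle.n_components == 0
        rebuilt = reconstruct_specimen(bundle, np.zeros(0))
        # reconstruction lives in the aligned frame: compare shapes centred
        ref = np.vstack([b.vertices for b in cohort[0].bodies()])
        out = np.vstack([b.vertices for b in rebuilt.bodies()])
        assert np.max(np.abs((out - out.mean(0)) - (ref - ref.mean(0)))) <= 1e-8

    def test_fit_of_mean_is_zero(self, coarse_cohort):
        bundle = build_ssam(coarse_cohort)
        mean_spec = reconstruct_specimen(bundle, np.zeros(bundle.n_components))
        b = fit_coefficients(bundle, mean_spec)
        assert np.max(np.abs(b)) <= 1e-8

    def test_fit_recovers_constructed_scores(self, coarse_cohort):
        bundle = build_ssam(coarse_cohort)
        b_true = np.zeros(bundle.n_components)
        b_true[0] = 2.0
        spec = reconstruct_specimen(bundle, b_true)
        b_hat = fit_coefficients(bundle, spec, clip=False)
        assert np.allclose(b_hat, b_true, atol=1e-6)

    def test_training_member_in_span(self, coarse_cohort):
        bundle = build_ssam(coarse_cohort)
        target = coarse_cohort[3]
        b = fit_coefficients(bundle, target, clip=False)
        pred = reconstruct_specimen(bundle, b)
        aligned = _aligned_target_points(bundle, target)
        out = np.vstack([bdy.vertices for bdy in pred.bodies()])
        rms = np.sqrt(np.mean((out - aligned) ** 2))
        assert rms <= 1e-8

    def test_reconstruction_is_affine(self, coarse_cohort):
        bundle = build_ssam(coarse_cohort)
        k = bundle.n_components
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=k), rng.normal(size=k)
        def verts(spec):
            return np.vstack([x.vertices for x in spec.bodies()])
        lhs = verts(reconstruct_specimen(bundle, a + b)) - verts(reconstruct_specimen(bundle, a))
        rhs = verts(reconstruct_specimen(bundle, b)) - verts(reconstruct_specimen(bundle, np.zeros(k)))
        assert np.max(np.abs(lhs - rhs)) <= 1e-10

    def test_reconstruction_error_monotone_in_components(self, coarse_cohort):
        X, layout = cohort_matrix(coarse_cohort)
        target = X[5]
        errs = []
        for k in (1, 3, 5, 8):
            model = ShapeAppearanceModel(layout=layout, n_components=k, clip=False).fit(X)
            b = model.transform(target[None, :], clip=False)
            rec = model.inverse_transform(b)[0]
            tgt = model._weighted_aligned(target[None, :])[0]
            w = np.concatenate([np.full(layout.n_shape, model.w_s_),
                                np.full(layout.n_points, model.w_a_)])
            errs.append(np.linalg.norm(rec * w - tgt))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))


class TestSampling:
    def test_twenty_resamples_per_component_within_three_sd(self, coarse_cohort):
        bundle = build_ssam(coarse_cohort)
        B = bundle.model.sample_coefficients(20, rng=np.random.default_rng(1))
        assert B.shape == (20 * bundle.n_components, bundle.n_components)
        assert np.max(np.abs(B)) <= 3.0
        # single-mode sampling: one nonzero coefficient per instance
        assert np.all((B != 0).sum(axis=1) <= 1)

    def test_zero_limit_returns_mean(self, coarse_cohort):
        bundle = build_ssam(coarse_cohort)
        specs = sample_ssam(bundle, n_per_component=2, limit_sd=0.0, seed=0)
        mean = reconstruct_specimen(bundle, np.zeros(bundle.n_components))
        for s in specs:
            assert np.max(np.abs(s.femur.vertices - mean.femur.vertices)) <= 1e-10


class TestLeaveOneOut:
    def test_zero_variance_cohort_has_zero_error(self):
        cohort = generate_cohort(zero_variance_config(seed=9))
        loo, _ = loo_validate(cohort)
        assert len(loo) == 10
        assert loo["rms_mm"].max() <= 1e-9

    def test_beats_mean_shape_baseline(self, coarse_cohort):
        loo, predicted = loo_validate(coarse_cohort)
        assert len(loo) == 10 and len(predicted) == 10
        assert loo["rms_mm"].mean() < loo["baseline_rms_mm"].mean()

    def test_requires_three_limbs(self, coarse_cohort):
        with pytest.raises(ValueError):
            loo_validate(coarse_cohort[:2])
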