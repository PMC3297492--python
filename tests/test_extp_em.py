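import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dysmorph import (
    PDM,
    BreakdownError,
    Configuration,
    InlierModel,
    ResidualField,
    TransformParams,
    apply_pdm,
    apply_rigid,
    e_step,
    extp_fit,
    inlier_belief,
    lambda_from_kappa,
    lss_fit,
    m_step,
    q_objective,
    nll,
)
from dysmorph.synthetic import (
    add_awgn,
    make_modes,
    make_template,
    pinocchio_pair,
    random_rigid,
)

positive = st.floats(0.05, 50.0, allow_nan=False)


class TestLambdaFromKappa:
    def test_closed_form_values(self):
        assert lambda_from_kappa(1.0, 2.0) == pytest.approx(0.05399096651318806, rel=1e-12)
        # kappa -> 0+ limit approaches the Gaussian prefactor
        assert lambda_from_kappa(1.0, 1e-9) == pytest.approx(1 / math.sqrt(2 * math.pi), rel=1e-9)

    @given(positive, positive)
    def test_halves_when_sigma_doubles(self, sigma, kappa):
        assert lambda_from_kappa(2 * sigma, kappa) == pytest.approx(
            lambda_from_kappa(sigma, kappa) / 2, rel=1e-12
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            lambda_from_kappa(0.0, 2.0)


class TestInlierBelief:
    @given(positive, positive)
    def test_belief_is_half_exactly_at_kappa_sigma(self, sigma, kappa):
        b = inlier_belief(kappa * sigma, InlierModel(sigma, kappa))
        assert abs(b - 0.5) < 1e-12

    def test_zero_residual_value(self):
        b = inlier_belief(0.0, InlierModel(1.0, 2.0))
        assert b == pytest.approx(1 / (1 + math.exp(-2)), rel=1e-12)

    def test_limits_and_monotonicity(self):
        m = InlierModel(0.7, 2.0)
        r = np.linspace(0, 20, 200)
        b = inlier_belief(r, m)
        assert np.all(np.diff(b) < 0)
        assert inlier_belief(1e6, m) == 0.0


class TestEStep:
    def test_matches_elementwise_belief(self, rng):
        res = ResidualField(rng.normal(0, 1, (10, 3)))
        m = InlierModel(0.8, 2.0)
        assert np.allclose(e_step(res, m), inlier_belief(res.magnitudes, m))

    def test_single_gross_outlier_flagged(self):
        m = InlierModel(1.0, 2.0)
        vecs = np.zeros((8, 3))
        vecs[3, 0] = 10 * m.kappa * m.sigma
        b = e_step(ResidualField(vecs), m)
        assert (b < 0.5).sum() == 1 and b[3] < 0.5


class TestQObjective:
    def test_all_inliers_equal_classical_nll(self, rng):
        res = ResidualField(rng.normal(0, 0.5, (12, 3)))
        m = InlierModel(0.5, 2.0)
        q = q_objective(res, np.ones(12), m)
        assert q == pytest.approx(nll(res, 0.5), rel=1e-12)

    def test_all_outliers_independent_of_residuals(self):
        m = InlierModel(1.0, 2.0)
        q_small = q_objective(ResidualField(np.ones((5, 3))), np.zeros(5), m)
        q_large = q_objective(ResidualField(100 * np.ones((5, 3))), np.zeros(5), m)
        assert q_small == pytest.approx(q_large, rel=1e-12)

    def test_hand_computed_two_landmark_case(self):
        sigma, kappa = 0.8, 2.0
        m = InlierModel(sigma, kappa)
        vecs = np.array([[0.3, 0.4, 0.0], [1.0, 2.0, 2.0]])
        b = np.array([0.9, 0.2])
        lam = math.exp(-0.5 * kappa**2) / (math.sqrt(2 * math.pi) * sigma)
        expected = 0.0
        for bj, r2 in zip(b, (0.25, 9.0)):
            expected += (
                bj * r2 / (2 * sigma**2)
                + bj * math.log(math.sqrt(2 * math.pi) * sigma)
                - (1 - bj) * math.log(lam)
            )
        assert q_objective(ResidualField(vecs), b, m) == pytest.approx(expected, abs=1e-12)


class TestMStep:
    def test_unit_beliefs_reduce_to_classical_fit(self, noisy_pinocchio):
        honest, lying, *_ = noisy_pinocchio
        b = np.ones(honest.n_landmarks)
        params, sigma = m_step(honest, lying, b)
        classic = lss_fit(lying, honest)
        assert np.allclose(params.rotation, classic.rotation, atol=1e-12)
        r2 = ((apply_rigid(lying, classic).coords - honest.coords) ** 2).sum(1)
        assert sigma == pytest.approx(math.sqrt(r2.mean()), rel=1e-12)

    def test_zero_belief_on_outliers_gives_exact_recovery(self, clean_pinocchio):
        honest, lying, _, regions, _ = clean_pinocchio
        nose = set(regions["nose_tip"])
        b = np.array([0.0 if l in nose else 1.0 for l in honest.labels])
        params, _ = m_step(honest, lying, b)
        resid = np.linalg.norm(apply_rigid(lying, params).coords - honest.coords, axis=1)
        assert resid[b > 0].max() < 1e-9

    def test_breakdown_guard(self, noisy_pinocchio):
        honest, lying, *_ = noisy_pinocchio
        with pytest.raises(BreakdownError, match="inlier mass"):
            m_step(honest, lying, np.full(honest.n_landmarks, 0.1))

    def test_pdm_update_matches_unregularized_least_squares(self, rng):
        template, _, _ = make_template(80, seed=11)
        modes = make_modes(template, 3, seed=12)
        base = template.centered()
        pdm_wide = PDM(base, modes, np.full(3, 1e9))  # penalty effectively off
        c_true = np.array([4.0, -2.0, 1.5])
        observed = Configuration(
            base.coords + (modes.T @ c_true).reshape(base.coords.shape), base.labels
        )
        params, _ = m_step(
            pdm_wide, observed, np.ones(base.n_landmarks), sigma=1.0, pdm_inner=5
        )
        # oracle: plain lstsq of the displacement onto the mode fields
        c_ls, *_ = np.linalg.lstsq(modes.T, observed.vec() - base.vec(), rcond=None)
        assert np.allclose(params.pdm_coeffs, c_ls, atol=1e-8)


class TestExtpFit:
    def test_pinocchio_alignment_and_flags(self, clean_pinocchio):
        honest, lying, _, regions, _ = clean_pinocchio
        res = extp_fit(lying, honest, kappa=2.0)
        nose = set(regions["nose_tip"])
        mask = np.array([l in nose for l in honest.labels])
        mags = res.residuals.magnitudes
        assert mags[~mask].max() < 1e-6  # perfect alignment of unaffected landmarks
        assert set(np.array(honest.labels)[res.flagged]) == nose

    def test_large_kappa_approaches_lss(self, clean_pinocchio):
        honest, lying, *_ = clean_pinocchio
        robust = extp_fit(lying, honest, kappa=6.0)
        classic = lss_fit(lying, honest)
        a = apply_rigid(lying, robust.params).coords
        b = apply_rigid(lying, classic).coords
        scale = math.sqrt((honest.centered().coords ** 2).sum(1).mean())
        assert math.sqrt(((a - b) ** 2).sum(1).mean()) / scale < 1e-3

    def test_parameter_recovery_under_pure_noise(self):
        template, _, _ = make_template(500, seed=21)
        noisy = add_awgn(template, 0.5, seed=22)
        truth = random_rigid(seed=23, max_angle=0.5, max_translation=20)
        observed = apply_rigid(noisy, truth)
        res = extp_fit(observed, template, kappa=2.0)
        Rerr = res.params.rotation @ truth.rotation
        angle = math.degrees(math.acos(np.clip((np.trace(Rerr) - 1) / 2, -1, 1)))
        assert angle < 0.5
        assert abs(res.sigma_per_coord - 0.5) / 0.5 < 0.1
        assert res.flagged.mean() < 0.1

    def test_objective_trace_total_decrease_and_stable_tail(self, noisy_pinocchio):
        honest, lying, *_ = noisy_pinocchio
        res = extp_fit(lying, honest, kappa=2.0)
        tr = np.array(res.objective_trace)
        assert res.converged and len(tr) == res.n_iter
        assert tr[-1] < tr[0]  # total decrease from initialization
        tail = np.diff(tr[-3:])
        assert np.all(tail <= 1e-6 * (1 + np.abs(tr[-3:-1])))

    def test_noiseless_trace_strictly_monotone(self, clean_pinocchio):
        honest, lying, *_ = clean_pinocchio
        tr = np.array(extp_fit(lying, honest).objective_trace)
        assert np.all(np.diff(tr) <= 1e-6 * (1 + np.abs(tr[:-1])))

    def test_equivariance_under_common_rotation(self, noisy_pinocchio):
        honest, lying, *_ = noisy_pinocchio
        common = random_rigid(seed=31, max_angle=1.0, max_translation=40)
        res0 = extp_fit(lying, honest)
        res1 = extp_fit(apply_rigid(lying, common), apply_rigid(honest, common))
        assert np.allclose(res0.beliefs, res1.beliefs, atol=1e-9)
        assert np.allclose(
            res0.residuals.magnitudes, res1.residuals.magnitudes, atol=1e-9
        )

    def test_redescending_influence(self):
        # equivalent rho-function: derivative rises near zero then decays to 0
        sigma, kappa = 1.0, 2.0
        m = InlierModel(sigma, kappa)
        d = np.linspace(1e-3, 12, 4000)
        rho = [
            q_objective(ResidualField(np.array([[x, 0.0, 0.0]])),
                        np.array([inlier_belief(x, m)]), m)
            for x in d
        ]
        drho = np.gradient(np.array(rho), d)
        peak = drho.argmax()
        assert 0 < peak < len(d) - 1
        assert abs(drho[-1]) < 1e-3 * drho[peak]

    def test_pdm_fit_of_in_model_face_recovers_coefficients(self):
        template, _, _ = make_template(150, seed=41)
        modes = make_modes(template, 3, seed=42)
        base = template.centered()
        pdm = PDM(base, modes, np.array([8.0, 5.0, 3.0]))
        c_true = np.array([6.0, -4.0, 2.0])
        face = Configuration(
            base.coords + (modes.T @ c_true).reshape(base.coords.shape), base.labels
        )
        face = apply_rigid(face, random_rigid(seed=43, max_angle=0.4, max_translation=10))
        res = extp_fit(face, pdm, kappa=2.0)
        assert np.allclose(res.params.pdm_coeffs, c_true, atol=0.05)
        neq = apply_pdm(pdm, res.params)
        assert np.linalg.norm(neq.coords - face.coords, axis=1).max() < 0.05
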