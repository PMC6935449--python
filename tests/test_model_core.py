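import math

import numpy as np
import pytest
from scipy.special import logsumexp

from gmhcrf.exceptions import InputError, ModelValidityError
from gmhcrf.gradcheck import random_model, random_sequence, random_spd
from gmhcrf.model_core import (
    ClassParams,
    FeatureSequence,
    GaussianComponent,
    GMHCRFModel,
    StateMixture,
    backward,
    brute_force_log_score,
    class_posterior,
    forward,
    log_emission_matrix,
    log_gaussian_density,
    log_mixture_density,
    predict,
)

from conftest import make_instance


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


class TestTypes:
    def test_sequence_rejects_nonfinite(self):
        with pytest.raises(InputError):
            FeatureSequence("s", np.array([[1.0, np.nan]]))

    def test_sequence_rejects_empty(self):
        with pytest.raises(InputError):
            FeatureSequence("s", np.zeros((0, 2)))

    def test_gaussian_rejects_asymmetric(self):
        with pytest.raises(ModelValidityError):
            GaussianComponent(np.zeros(2), np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_gaussian_rejects_non_spd(self):
        with pytest.raises(ModelValidityError):
            GaussianComponent(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_mixture_rejects_bad_weights(self):
        c = GaussianComponent(np.zeros(1), np.eye(1))
        with pytest.raises(ModelValidityError):
            StateMixture(np.array([0.5, 0.6]), [c, c])

    def test_class_params_rejects_plus_inf(self):
        c = GaussianComponent(np.zeros(1), np.eye(1))
        mix = StateMixture(np.array([1.0]), [c])
        with pytest.raises(ModelValidityError):
            ClassParams(np.array([np.inf]), np.zeros((1, 1)), [mix])

    def test_class_params_allows_minus_inf(self):
        # -inf potentials arise from the log of zero probabilities
        c = GaussianComponent(np.zeros(1), np.eye(1))
        mix = StateMixture(np.array([1.0]), [c])
        ClassParams(np.array([-np.inf]), np.zeros((1, 1)), [mix])

    def test_model_rejects_duplicate_labels(self, rng):
        m = random_model(rng, 2, 1, 1, 1)
        with pytest.raises(InputError):
            GMHCRFModel(["a", "a"], m.classes)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


class TestDensities:
    def test_standard_normal_at_mode(self):
        comp = GaussianComponent(np.zeros(1), np.eye(1))
        assert log_gaussian_density(np.zeros(1), comp) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-12
        )

    def test_identity_covariance_mode_2d(self):
        comp = GaussianComponent(np.ones(2), np.eye(2))
        assert log_gaussian_density(np.ones(2), comp) == pytest.approx(
            -math.log(2 * math.pi), abs=1e-12
        )

    def test_matches_explicit_inverse_oracle(self, rng):
        # oracle: closed-form quadratic with an explicitly inverted covariance
        for _ in range(25):
            D = 3
            S = random_spd(rng, D)
            mu = rng.normal(size=D)
            u = rng.normal(size=D)
            comp = GaussianComponent(mu, S)
            Sinv = np.linalg.inv(S)
            expected = -0.5 * (
                D * math.log(2 * math.pi)
                + math.log(np.linalg.det(S))
                + (u - mu) @ Sinv @ (u - mu)
            )
            got = log_gaussian_density(u, comp)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch(self):
        comp = GaussianComponent(np.zeros(2), np.eye(2))
        with pytest.raises(InputError):
            log_gaussian_density(np.zeros(3), comp)

    def test_single_component_mixture(self, rng):
        comp = GaussianComponent(rng.normal(size=2), random_spd(rng, 2))
        mix = StateMixture(np.array([1.0]), [comp])
        u = rng.normal(size=2)
        assert log_mixture_density(u, mix) == pytest.approx(
            log_gaussian_density(u, comp), rel=1e-12
        )

    def test_duplicate_components_collapse(self, rng):
        comp = GaussianComponent(rng.normal(size=2), random_spd(rng, 2))
        twin = GaussianComponent(comp.mean.copy(), comp.covariance.copy())
        mix = StateMixture(np.array([0.5, 0.5]), [comp, twin])
        u = rng.normal(size=2)
        assert log_mixture_density(u, mix) == pytest.approx(
            log_gaussian_density(u, comp), rel=1e-12
        )

    def test_matches_sum_then_log_oracle(self, rng):
        for _ in range(10):
            M, D = 3, 2
            w = rng.dirichlet(np.ones(M))
            comps = [
                GaussianComponent(rng.normal(size=D), random_spd(rng, D))
                for _ in range(M)
            ]
            mix = StateMixture(w, comps)
            u = rng.normal(size=D)
            naive = math.log(
                sum(
                    wi * math.exp(log_gaussian_density(u, c))
                    for wi, c in zip(w, comps)
                )
            )
            assert log_mixture_density(u, mix) == pytest.approx(naive, rel=1e-12)

    def test_zero_weight_component_dropped(self, rng):
        good = GaussianComponent(np.zeros(1), np.eye(1))
        far = GaussianComponent(np.full(1, 100.0), np.eye(1))
        mix = StateMixture(np.array([1.0, 0.0]), [good, far])
        u = np.zeros(1)
        assert log_mixture_density(u, mix) == pytest.approx(
            log_gaussian_density(u, good), rel=1e-12
        )


# ---------------------------------------------------------------------------
# forward / backward / brute force
# ---------------------------------------------------------------------------


class TestForwardBackward:
    def test_T1_no_transitions(self, rng):
        model, _ = make_instance(rng, Q=3, M=1, D=2, T=1)
        cp = model.classes[0]
        seq = random_sequence(rng, 1, 2)
        lm = log_emission_matrix(cp, seq)
        expected = logsumexp(cp.prior + lm[0])
        assert forward(cp, seq)[1] == pytest.approx(expected, rel=1e-12)

    def test_Q1_single_path(self, rng):
        model = random_model(rng, 1, Q=1, M=2, D=2)
        cp = model.classes[0]
        seq = random_sequence(rng, 6, 2)
        lm = log_emission_matrix(cp, seq)
        expected = cp.prior[0] + 5 * cp.transition[0, 0] + lm[:, 0].sum()
        assert forward(cp, seq)[1] == pytest.approx(expected, rel=1e-12)

    def test_backward_terminal_and_Q1(self, rng):
        model = random_model(rng, 1, Q=1, M=1, D=1)
        cp = model.classes[0]
        seq = random_sequence(rng, 5, 1)
        lb = backward(cp, seq)
        assert lb[-1, 0] == 0.0
        lm = log_emission_matrix(cp, seq)
        for t in range(5):
            expected = (4 - t) * cp.transition[0, 0] + lm[t + 1 :, 0].sum()
            assert lb[t, 0] == pytest.approx(expected, rel=1e-12)

    def test_forward_backward_agreement(self, rng):
        for _ in range(20):
            model, seq = make_instance(
                rng,
                n_classes=1,
                Q=int(rng.integers(1, 4)),
                M=int(rng.integers(1, 3)),
                D=2,
                T=int(rng.integers(1, 7)),
            )
            cp = model.classes[0]
            la, score = forward(cp, seq)
            lb = backward(cp, seq)
            lm = log_emission_matrix(cp, seq)
            seeded = logsumexp(cp.prior + lm[0] + lb[0])
            assert seeded == pytest.approx(score, rel=1e-10)

    def test_brute_force_guard(self, rng):
        model = random_model(rng, 1, Q=3, M=1, D=1)
        seq = random_sequence(rng, 20, 1)
        with pytest.raises(InputError):
            brute_force_log_score(model.classes[0], seq)

    @pytest.mark.parametrize("trial", range(20))
    def test_forward_equals_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        Q = int(rng.integers(1, 4))
        M = int(rng.integers(1, 3))
        D = int(rng.integers(1, 4))
        T = int(rng.integers(1, 6))
        model, seq = make_instance(rng, n_classes=1, Q=Q, M=M, D=D, T=T)
        cp = model.classes[0]
        bf = brute_force_log_score(cp, seq)
        fw = forward(cp, seq)[1]
        assert abs(fw - bf) <= 1e-10 * max(1.0, abs(bf))


# ---------------------------------------------------------------------------
# posterior / predict
# ---------------------------------------------------------------------------


class TestPosterior:
    def test_identical_blocks_symmetry(self, rng):
        m = random_model(rng, 1, 2, 1, 2)
        cp = m.classes[0]
        twin = ClassParams(cp.prior.copy(), cp.transition.copy(), cp.emissions)
        model = GMHCRFModel(["a", "b"], [cp, twin])
        seq = random_sequence(rng, 4, 2)
        post = class_posterior(model, seq)
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_additive_prior_shift_multiplies_odds(self, rng):
        model, seq = make_instance(rng, n_classes=2, T=4)
        post0 = class_posterior(model, seq)
        c = 0.7
        shifted = model.classes[0]
        shifted = ClassParams(
            shifted.prior + c, shifted.transition, shifted.emissions
        )
        model2 = GMHCRFModel(model.labels, [shifted, model.classes[1]])
        post1 = class_posterior(model2, seq)
        odds0 = post0[0] / post0[1]
        odds1 = post1[0] / post1[1]
        assert odds1 / odds0 == pytest.approx(math.exp(c), rel=1e-9)

    def test_posterior_matches_brute_force(self, rng):
        for _ in range(5):
            model, seq = make_instance(rng, n_classes=3, Q=2, M=1, D=2, T=3)
            scores = np.array(
                [brute_force_log_score(c, seq) for c in model.classes]
            )
            expected = np.exp(scores - logsumexp(scores))
            got = class_posterior(model, seq)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_posterior_sums_to_one(self, rng):
        for _ in range(10):
            model, seq = make_instance(rng, n_classes=4, T=5)
            assert class_posterior(model, seq).sum() == pytest.approx(1.0, abs=1e-12)

    def test_predict_tie_break_first_label(self, rng):
        m = random_model(rng, 1, 2, 1, 2)
        cp = m.classes[0]
        model = GMHCRFModel(["z_second", "a_first"], [cp, cp])
        seq = random_sequence(rng, 3, 2)
        assert predict(model, seq) == "z_second"

    def test_predict_prefers_shifted_class(self, rng):
        model, seq = make_instance(rng, n_classes=3, T=3)
        boosted = ClassParams(
            model.classes[1].prior + 10.0,
            model.classes[1].transition,
            model.classes[1].emissions,
        )
        model2 = GMHCRFModel(
            model.labels, [model.classes[0], boosted, model.classes[2]]
        )
        assert predict(model2, seq) == model.labels[1]

    def test_predict_agrees_with_brute_force(self, rng):
        for _ in range(5):
            model, seq = make_instance(rng, n_classes=3, Q=2, M=1, D=2, T=3)
            scores = [brute_force_log_score(c, seq) for c in model.classes]
            assert predict(model, seq) == model.labels[int(np.argmax(scores))]


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


class TestPropertyBased:
    """Hypothesis-driven invariants over raw parameter draws."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**31 - 1), shift=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_posterior_normalized_and_translation_invariant(self, seed, shift):
        rng = np.random.default_rng(seed)
        model, seq = make_instance(
            rng,
            n_classes=int(rng.integers(2, 4)),
            Q=int(rng.integers(1, 3)),
            M=int(rng.integers(1, 3)),
            D=int(rng.integers(1, 3)),
            T=int(rng.integers(1, 5)),
        )
        post = class_posterior(model, seq)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        shifted = GMHCRFModel(
            model.labels,
            [
                ClassParams(c.prior + shift, c.transition, c.emissions)
                for c in model.classes
            ],
        )
        np.testing.assert_allclose(
            class_posterior(shifted, seq), post, atol=1e-12
        )

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_forward_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model, seq = make_instance(
            rng,
            n_classes=1,
            Q=int(rng.integers(1, 4)),
            M=int(rng.integers(1, 3)),
            D=int(rng.integers(1, 4)),
            T=int(rng.integers(1, 6)),
        )
        cp = model.classes[0]
        bf = brute_force_log_score(cp, seq)
        fw = forward(cp, seq)[1]
        assert abs(fw - bf) <= 1e-10 * max(1.0, abs(bf))


class TestInvariances:
    def test_hidden_state_relabeling(self, rng):
        for _ in range(5):
            model, seq = make_instance(rng, n_classes=2, Q=3, M=2, D=2, T=4)
            cp = model.classes[0]
            perm = rng.permutation(3)
            permuted = ClassParams(
                cp.prior[perm],
                cp.transition[np.ix_(perm, perm)],
                [cp.emissions[i] for i in perm],
            )
            s0 = forward(cp, seq)[1]
            s1 = forward(permuted, seq)[1]
            assert s1 == pytest.approx(s0, rel=1e-10)

    def test_global_prior_translation_invariance(self, rng):
        model, seq = make_instance(rng, n_classes=3, T=4)
        post0 = class_posterior(model, seq)
        shifted = GMHCRFModel(
            model.labels,
            [
                ClassParams(c.prior + 3.21, c.transition, c.emissions)
                for c in model.classes
            ],
        )
        post1 = class_posterior(shifted, seq)
        np.testing.assert_allclose(post0, post1, atol=1e-12)
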