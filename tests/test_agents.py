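import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banditfit.agents import (
    GQLAgent,
    GQLParams,
    QLAgent,
    QLPAgent,
    QLPParams,
    QLParams,
    count_gql_params,
    gql_update,
    ql_update,
    softmax,
)


class TestSoftmax:
    def test_equal_logits_symmetric(self):
        assert softmax(np.zeros(2)).tolist() == [0.5, 0.5]

    def test_logistic_value(self):
        p = softmax(np.array([1.0, 0.0]))
        assert p[0] == pytest.approx(0.73106, abs=1e-5)

    def test_large_logits_no_overflow(self):
        p = softmax(np.array([1000.0, 0.0]))
        assert p[0] == pytest.approx(1.0)
        assert np.isfinite(p).all()

    def test_nan_rejected(self):
        with pytest.raises(FloatingPointError):
            softmax(np.array([np.nan, 0.0]))

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=5),
           st.floats(-100, 100))
    @settings(deadline=None)
    def test_sums_to_one_and_shift_invariant(self, logits, shift):
        logits = np.array(logits)
        p = softmax(logits)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p, softmax(logits + shift), atol=1e-12)


class TestQL:
    def test_update_arithmetic(self):
        Q = np.array([0.5, 0.0])
        assert ql_update(Q, 0, 1, 0.1)[0] == pytest.approx(0.55)
        assert ql_update(Q, 0, 1, 0.0).tolist() == [0.5, 0.0]  # phi = 0
        assert ql_update(Q, 0, 1, 1.0)[0] == 1.0               # phi = 1
        assert ql_update(Q, 0, 1, 0.1)[1] == 0.0               # other unchanged

    def test_value_converges_geometrically_under_constant_reward(self):
        agent = QLAgent(QLParams(phi=0.2, beta=1.0))
        for t in range(1, 51):
            agent.observe(0, 1)
            assert agent.Q[0] == pytest.approx(1 - 0.8**t)
        assert agent.Q[0] == pytest.approx(1.0, abs=1e-4)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            QLParams(phi=1.5, beta=1.0)
        with pytest.raises(ValueError):
            QLParams(phi=0.5, beta=0.0)


class TestQLP:
    def test_kappa_zero_reduces_to_ql(self, rng):
        ql = QLAgent(QLParams(phi=0.3, beta=2.0))
        qlp = QLPAgent(QLPParams(phi=0.3, beta=2.0, kappa=0.0))
        for _ in range(50):
            a, r = rng.integers(0, 2), rng.integers(0, 2)
            assert np.array_equal(ql.predict(), qlp.predict())
            ql.observe(a, r)
            qlp.observe(a, r)

    def test_perseveration_closed_form(self):
        agent = QLPAgent(QLPParams(phi=0.0, beta=1.0, kappa=2.0))
        agent.observe(0, 0)
        assert agent.predict()[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-4)

    def test_alternation_with_negative_kappa(self):
        agent = QLPAgent(QLPParams(phi=0.0, beta=1.0, kappa=-2.0))
        agent.observe(0, 0)
        assert agent.predict()[0] == pytest.approx(1 / (1 + np.exp(2)), abs=1e-4)

    def test_first_trial_has_no_kernel(self):
        agent = QLPAgent(QLPParams(phi=0.3, beta=2.0, kappa=5.0))
        assert agent.predict().tolist() == [0.5, 0.5]


class TestGQL:
    def test_d1_update_equals_ql(self):
        Q = np.array([[0.4], [0.1]])
        H = np.zeros((2, 1))
        Q2, _ = gql_update(Q, H, 0, 1, np.array([0.1]), np.array([0.5]))
        assert Q2[0, 0] == pytest.approx(ql_update(Q[:, 0].copy(), 0, 1, 0.1)[0])

    def test_psi_one_makes_history_the_last_action_indicator(self):
        H = np.array([[0.3], [0.7]])
        _, H2 = gql_update(np.zeros((2, 1)), H, 1, 0, np.array([0.5]), np.array([1.0]))
        assert H2.tolist() == [[0.0], [1.0]]

    def test_two_rate_worked_example(self):
        Phi = np.array([0.1, 0.05])
        Q, _ = gql_update(np.zeros((2, 2)), np.zeros((2, 2)), 0, 1, Phi,
                          np.array([0.5, 0.5]))
        assert Q[0].tolist() == [0.1, 0.05]
        assert Q[1].tolist() == [0.0, 0.0]

    def test_zero_weights_give_uniform_policy(self, rng):
        params = GQLParams(Phi=np.array([0.3, 0.1]), Psi=np.array([0.5, 0.1]),
                           B=np.zeros(2), K=np.zeros(2), C=np.zeros((2, 2)))
        agent = GQLAgent(params)
        for _ in range(20):
            assert agent.predict().tolist() == [0.5, 0.5]
            agent.observe(rng.integers(0, 2), rng.integers(0, 2))

    def test_negative_value_weight_lowers_stay_probability_after_reward(self):
        params = GQLParams(Phi=np.array([0.5]), Psi=np.array([0.5]),
                           B=np.array([-3.0]), K=np.array([0.0]),
                           C=np.zeros((1, 1)))
        agent = GQLAgent(params)
        before = agent.predict()[0]
        agent.observe(0, 1)  # rewarded L
        after = agent.predict()[0]
        assert after < before  # the post-reward switch 'dip'

    def test_param_count_formula(self):
        assert count_gql_params(1) == 5
        assert count_gql_params(2) == 12
        assert count_gql_params(10) == 140
        with pytest.raises(ValueError):
            count_gql_params(0)

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            GQLParams(Phi=np.array([0.1, 0.2]), Psi=np.array([0.1]),
                      B=np.zeros(2), K=np.zeros(2), C=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            GQLParams(Phi=np.array([1.2]), Psi=np.array([0.1]),
                      B=np.zeros(1), K=np.zeros(1), C=np.zeros((1, 1)))

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=80),
           st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=30)
    def test_history_stays_in_unit_interval(self, seq, psi1, psi2):
        params = GQLParams(Phi=np.array([0.3, 0.1]),
                           Psi=np.array([psi1, psi2]),
                           B=np.zeros(2), K=np.zeros(2), C=np.zeros((2, 2)))
        agent = GQLAgent(params)
        for a, r in seq:
            agent.observe(a, r)
            assert np.all(agent.H >= 0.0) and np.all(agent.H <= 1.0)
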