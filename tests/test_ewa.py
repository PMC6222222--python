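import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ohsmarket.ewa import LearnerState, choice_probabilities, sample_strategy, update
from ohsmarket.params import EWAParams


def make_state(attractions, experience=1.0):
    a = np.atleast_2d(np.asarray(attractions, dtype=float))
    return LearnerState(a, np.full(a.shape[0], float(experience)))


class TestUpdate:
    def test_hand_evaluated_step(self):
        # N_old=1, rho=phi=delta=1: N=2, chosen and unchosen both take
        # half their payoff since the old attractions are zero.
        params = EWAParams(rho=1, phi=1, delta_weight=1, lambda_sens=1)
        state = make_state([0.0, 0.0])
        new = update(state, np.array([[4.0, 2.0]]), np.array([0]), params)
        assert new.experience[0] == pytest.approx(2.0)
        assert new.attractions[0] == pytest.approx([2.0, 1.0])

    def test_zero_delta_leaves_unchosen_unreinforced(self):
        params = EWAParams(rho=1, phi=1, delta_weight=0, lambda_sens=1)
        new = update(make_state([0.0, 0.0]), np.array([[4.0, 2.0]]), np.array([0]), params)
        assert new.attractions[0] == pytest.approx([2.0, 0.0])

    def test_full_forgetting_keeps_only_current_payoff(self):
        params = EWAParams(rho=0, phi=0, delta_weight=0.5, lambda_sens=1)
        new = update(make_state([9.0, 9.0], 5.0), np.array([[4.0, 2.0]]), np.array([1]), params)
        # N collapses to 1; decay term vanishes; weights are delta / 1.
        assert new.experience[0] == pytest.approx(1.0)
        assert new.attractions[0] == pytest.approx([2.0, 2.0])

    def test_experience_recursion_exact(self):
        params = EWAParams(rho=0.8, phi=0.9, delta_weight=1, lambda_sens=1)
        state = make_state([0.0, 0.0], 3.0)
        new = update(state, np.array([[1.0, 1.0]]), np.array([0]), params)
        assert new.experience[0] == pytest.approx(0.8 * 3.0 + 1.0)

    def test_shape_mismatch_rejected(self):
        params = EWAParams()
        with pytest.raises(ValueError, match="shape"):
            update(make_state([0.0, 0.0]), np.zeros((1, 3)), np.array([0]), params)

    @given(
        payoff_seq=st.lists(
            st.tuples(
                st.floats(-5, 5), st.floats(-5, 5), st.integers(0, 1)
            ),
            min_size=1,
            max_size=12,
        ),
        rho=st.floats(0, 1),
        phi=st.floats(0, 1),
        delta=st.floats(0, 1),
    )
    def test_matches_scalar_recurrence_oracle(self, payoff_seq, rho, phi, delta):
        """Vectorised update equals a direct scalar transcription of the
        attraction recurrence over arbitrary payoff sequences."""
        params = EWAParams(rho=rho, phi=phi, delta_weight=delta, lambda_sens=1)
        state = make_state([0.0, 0.0])
        n_ref, a_ref = 1.0, [0.0, 0.0]
        for u0, u1, chosen in payoff_seq:
            state = update(state, np.array([[u0, u1]]), np.array([chosen]), params)
            n_new = rho * n_ref + 1.0
            for j, u in enumerate((u0, u1)):
                w = 1.0 if j == chosen else delta
                a_ref[j] = (n_ref * phi * a_ref[j] + w * u) / n_new
            n_ref = n_new
        assert state.experience[0] == pytest.approx(n_ref)
        assert state.attractions[0] == pytest.approx(a_ref)

    def test_pure_reinforcement_limit_accumulates_chosen_payoffs(self):
        # rho=0, phi=1, delta=0: the recurrence degenerates to adding the
        # chosen strategy's payoff to its attraction, nothing else.
        params = EWAParams(rho=0, phi=1, delta_weight=0, lambda_sens=1)
        rng = np.random.default_rng(0)
        payoffs = rng.normal(size=(30, 2))
        chosen = rng.integers(0, 2, size=30)
        state = make_state([0.0, 0.0])
        totals = np.zeros(2)
        for p, c in zip(payoffs, chosen):
            state = update(state, p[None, :], np.array([c]), params)
            totals[c] += p[c]
        assert state.attractions[0] == pytest.approx(totals)


class TestChoiceProbabilities:
    def test_direct_logit_evaluation(self):
        probs = choice_probabilities(make_state([1.0, 0.0]), 1.0)
        e = math.e
        assert probs[0] == pytest.approx([e / (e + 1), 1 / (e + 1)])

    @pytest.mark.parametrize("lam", [0.0, 0.7, 3.0])
    def test_equal_attractions_give_uniform(self, lam):
        probs = choice_probabilities(make_state([2.2, 2.2, 2.2]), lam)
        assert probs[0] == pytest.approx([1 / 3] * 3)

    def test_zero_sensitivity_ignores_attractions(self):
        probs = choice_probabilities(make_state([5.0, -3.0]), 0.0)
        assert probs[0] == pytest.approx([0.5, 0.5])

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities(make_state([0.0, 1.0]), -0.1)

    def test_overflow_safe_for_huge_attractions(self):
        probs = choice_probabilities(make_state([5000.0, 0.0]), 1.0)
        assert np.isfinite(probs).all()
        assert probs[0, 0] == pytest.approx(1.0)

    @given(
        attrs=st.lists(st.floats(-30, 30), min_size=2, max_size=5),
        lam=st.floats(0, 10),
    )
    def test_normalization(self, attrs, lam):
        probs = choice_probabilities(make_state(attrs), lam)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs > 0).all()

    @given(
        base=st.floats(-5, 5),
        bump=st.floats(0.1, 5),
        lam=st.floats(0.1, 5),
    )
    def test_monotone_in_own_attraction(self, base, bump, lam):
        lo = choice_probabilities(make_state([base, 0.0]), lam)[0, 0]
        hi = choice_probabilities(make_state([base + bump, 0.0]), lam)[0, 0]
        assert hi >= lo

    def test_argmax_limit_at_high_sensitivity(self):
        probs = choice_probabilities(make_state([1.0, 0.5, 0.0]), 1e3)
        assert probs[0, 0] == pytest.approx(1.0)


class TestSampleStrategy:
    def test_degenerate_distribution(self, rng):
        idx = sample_strategy(np.tile([1.0, 0.0], (100, 1)), rng)
        assert (idx == 0).all()

    def test_frequencies_within_binomial_band(self, rng):
        n = 10_000
        idx = sample_strategy(np.tile([0.5, 0.5], (n, 1)), rng)
        freq = (idx == 0).mean()
        sigma = 0.5 / math.sqrt(n)
        assert abs(freq - 0.5) < 3 * sigma

    def test_fixed_seed_reproduces_draws(self):
        p = np.tile([0.3, 0.3, 0.4], (50, 1))
        a = sample_strategy(p, np.random.default_rng(9))
        b = sample_strategy(p, np.random.default_rng(9))
        assert (a == b).all()
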