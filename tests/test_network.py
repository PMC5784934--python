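"""Attractor dynamics, learning rule, and the simulated retrieval protocol."""

import numpy as np
import pytest

from memcoherence import ModelParams
from memcoherence.design import assign_orders, make_encoding_schedule, make_events, make_test_schedule
from memcoherence.network import (
    NetworkState,
    encode_trial,
    enumerate_question_accuracy,
    hebbian_update,
    modulation_factor,
    retrieve_trial,
    run_simulation,
    settle,
    settle_bruteforce,
)

P = ModelParams()


def w3(lp=0.0, lo=0.0, po=0.0):
    """Symmetric 3-neuron weight matrix in (location, person, object) order."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = lp
    w[0, 2] = w[2, 0] = lo
    w[1, 2] = w[2, 1] = po
    return w


class TestSettle:
    def test_isolated_driven_neuron_saturates(self):
        r = settle(np.zeros((3, 3)), np.array([15.0, 0.0, 0.0]), P)
        assert r.tolist() == [10.0, 0.0, 0.0]

    def test_single_weak_link_gives_six_hz(self):
        # cue at 15 nA, target at 5 nA, one 0.6 link: 5 + 0.6*10 - 5 = 6 Hz
        r = settle(w3(lp=0.6), np.array([15.0, 5.0, 0.0]), P)
        assert r[0] == 10.0
        assert r[1] == pytest.approx(6.0)

    def test_weak_two_link_chain_stays_subthreshold(self):
        # completion through two 0.6 links: fixed point r_mid = 1 + 0.36 r_mid
        r = settle(w3(lp=0.6, po=0.6), np.array([15.0, 0.0, 5.0]), P)
        assert r[0] == 10.0
        assert r[1] == pytest.approx(25.0 / 16.0)  # intermediate ~1.56 Hz
        assert r[2] == pytest.approx(25.0 / 16.0 * 0.6)  # target ~0.94 Hz
        assert r[2] < P.theta_ret

    def test_marginal_loop_with_offset_saturates(self):
        # weak cue->mid link plus strong mid<->target link: gain-1 loop climbs to cap
        r = settle(w3(lp=0.6, po=1.0), np.array([15.0, 0.0, 5.0]), P)
        assert r[1] == 10.0 and r[2] == 10.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            settle(np.full((2, 2), np.nan), np.zeros(2), P)

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_bruteforce_exhaustively(self, n):
        """Vectorised settle equals the scalar-loop reference on every
        directed weight configuration over {0, 0.6, 1.0}."""
        from itertools import product

        off_diag = [(i, j) for i in range(n) for j in range(n) if i != j]
        currents = [
            np.array([15.0] + [5.0] * (n - 1)),
            np.array([15.0] + [0.0] * (n - 1)),
        ]
        for combo in product([0.0, 0.6, 1.0], repeat=len(off_diag)):
            w = np.zeros((n, n))
            for (i, j), v in zip(off_diag, combo):
                w[i, j] = v
            for cur in currents:
                fast = settle(w, cur, P)
                slow = settle_bruteforce(w, cur, P)
                assert np.allclose(fast, slow, atol=1e-9)

    def test_matches_bruteforce_sampled_large(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = rng.integers(4, 7)
            w = rng.choice([0.0, 0.6, 1.0], size=(n, n))
            np.fill_diagonal(w, 0.0)
            cur = rng.choice([0.0, 5.0, 15.0], size=n)
            assert np.allclose(settle(w, cur, P), settle_bruteforce(w, cur, P), atol=1e-9)


class TestModulation:
    @pytest.mark.parametrize("rate,expected", [(10.0, 0.6), (1.0, 0.6), (0.99, 1.0), (0.0, 1.0)])
    def test_threshold_is_inclusive(self, rate, expected):
        rates = np.array([10.0, rate, 0.0])
        assert modulation_factor(rates, [1], P) == expected

    def test_no_negative_neurons(self):
        assert modulation_factor(np.full(4, 10.0), [], P) == 1.0


class TestHebbian:
    def test_zero_learning_rate_is_identity(self):
        w = w3(lp=0.3)
        out = hebbian_update(w, np.array([10.0, 10.0, 0.0]), 0.0, 1.0, P)
        assert np.array_equal(out, w)

    def test_copresented_pair_saturates_at_wmax(self):
        out = hebbian_update(np.zeros((3, 3)), np.array([10.0, 10.0, 0.0]), P.k_neut, 1.0, P)
        assert out[0, 1] == out[1, 0] == 1.0
        assert out[0, 2] == out[2, 0] == out[1, 2] == out[2, 1] == 0.0
        assert np.all(np.diagonal(out) == 0.0)

    def test_modulated_pair_caps_at_m_wmax(self):
        out = hebbian_update(np.zeros((3, 3)), np.array([10.0, 10.0, 0.0]), P.k_neut, 0.6, P)
        assert out[0, 1] == out[1, 0] == pytest.approx(0.6)

    def test_modulated_trial_never_decrements_strong_weight(self):
        w = w3(lo=1.0)
        out = hebbian_update(w, np.array([10.0, 0.0, 10.0]), P.k_neut, 0.6, P)
        assert out[0, 2] == out[2, 0] == 1.0

    def test_subthreshold_reactivated_neuron_gains_and_grants_nothing(self):
        # third neuron at 7 Hz < theta_p: no weight change onto or from it
        out = hebbian_update(np.zeros((3, 3)), np.array([10.0, 10.0, 7.0]), P.k_neut, 1.0, P)
        assert np.all(out[2, :] == 0.0) and np.all(out[:, 2] == 0.0)
        assert out[0, 1] == 1.0


class TestEncodeRetrieve:
    def _state(self, n_neutral=0, n_negative=3, seed=0):
        events = make_events(n_neutral, n_negative, seed)
        return events, NetworkState.fresh(events)

    def test_neutral_pair_encodes_symmetric_unit_weight(self):
        events = make_events(3, 0, 0)
        state = NetworkState.fresh(events)
        ev = events.events[0]
        ids = [ev.element("location").element_id, ev.element("object").element_id]
        rng = np.random.default_rng(1)  # first draw succeeds at p_enc=0.65
        assert rng.random() < P.p_enc
        encode_trial(state, ids, P, np.random.default_rng(1))
        i, j = state.index[ids[0]], state.index[ids[1]]
        assert state.weights[i, j] == state.weights[j, i] == 1.0
        assert np.all(state.rates == 0.0)

    def test_negative_person_trial_is_modulated(self):
        events, state = self._state()
        ev = events.events[0]
        ids = [ev.element("person").element_id, ev.element("location").element_id]
        encode_trial(state, ids, P, np.random.default_rng(1))
        i, j = state.index[ids[0]], state.index[ids[1]]
        assert state.weights[i, j] == state.weights[j, i] == pytest.approx(0.6)

    def test_reactivated_negative_element_modulates_neutral_pair(self):
        # person-first: an earlier weak person link reactivates the person
        # at >= 1 Hz during the final location-object trial
        events, state = self._state()
        ev = events.events[0]
        loc, per, obj = (ev.element(c).element_id for c in ("location", "person", "object"))
        encode_trial(state, [obj, per], P, np.random.default_rng(1))
        encode_trial(state, [loc, obj], P, np.random.default_rng(1))
        i, j = state.index[loc], state.index[obj]
        assert state.weights[i, j] == pytest.approx(0.6)

    def test_unlinked_negative_event_encodes_neutral_pair_at_full_strength(self):
        events, state = self._state()
        ev = events.events[0]
        loc, obj = ev.element("location").element_id, ev.element("object").element_id
        encode_trial(state, [loc, obj], P, np.random.default_rng(1))
        i, j = state.index[loc], state.index[obj]
        assert state.weights[i, j] == 1.0

    def test_unknown_element_raises(self):
        _, state = self._state()
        with pytest.raises(ValueError, match="unknown element"):
            encode_trial(state, ["nope"], P, np.random.default_rng(0))

    def test_retrieval_direct_weak_link_succeeds(self):
        events, state = self._state(3, 3)
        ev = events.events[0]
        cue = ev.element("location").element_id
        tgt = ev.element("person").element_id
        i, j = state.index[cue], state.index[tgt]
        state.weights[i, j] = state.weights[j, i] = 0.6
        foils = [e for e in events.element_ids if e not in (cue, tgt)][:5]
        correct, rates = retrieve_trial(state, cue, foils + [tgt], tgt, P)
        assert correct
        assert rates[-1] == pytest.approx(6.0)
        assert np.all(rates[:-1] == 0.0)

    def test_retrieval_without_links_fails_silently(self):
        events, state = self._state(3, 3)
        ev = events.events[0]
        cue = ev.element("location").element_id
        tgt = ev.element("person").element_id
        foils = [e for e in events.element_ids if e not in (cue, tgt)][:5]
        correct, rates = retrieve_trial(state, cue, foils + [tgt], tgt, P)
        assert not correct
        assert np.all(rates == 0.0)

    def test_pattern_completion_through_strong_indirect_links(self):
        events, state = self._state(3, 3)
        ev = events.events[0]
        loc, per, obj = (ev.element(c).element_id for c in ("location", "person", "object"))
        for a, b in [(loc, obj), (obj, per)]:
            i, j = state.index[a], state.index[b]
            state.weights[i, j] = state.weights[j, i] = 1.0
        foils = [e for e in events.element_ids if e not in (loc, per, obj)][:5]
        correct, rates = retrieve_trial(state, loc, foils + [per], per, P)
        assert correct
        assert rates[-1] == 10.0


class TestRunSimulation:
    def test_row_count_and_determinism(self, protocol, model_responses):
        events, enc, test = protocol
        assert len(model_responses) == 26 * 432
        again = run_simulation(events, enc, test, ModelParams(), seed=2024)
        assert model_responses.equals(again)

    def test_requires_pairs_mode(self):
        events = make_events(3, 3, 0)
        orders = assign_orders(events, "triples", 0)
        enc = make_encoding_schedule(events, "triples", orders, 0)
        test = make_test_schedule(events, 0)
        with pytest.raises(ValueError, match="pairs"):
            run_simulation(events, enc, test, ModelParams(), seed=0)

    @pytest.mark.parametrize("p_enc,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_encoding_probabilities(self, p_enc, expected):
        events = make_events(4, 4, 0)
        orders = assign_orders(events, "pairs", 1)
        enc = make_encoding_schedule(events, "pairs", orders, 2)
        test = make_test_schedule(events, 3)
        params = ModelParams(p_enc=p_enc, n_sims=2)
        rt = run_simulation(events, enc, test, params, seed=5)
        if p_enc == 1.0:
            assert rt.loc[rt.condition == "neutral", "correct"].mean() == expected
        else:
            assert rt["correct"].mean() == expected

    def test_weight_symmetry_and_no_cross_event_weights(self):
        events = make_events(4, 4, 1)
        orders = assign_orders(events, "pairs", 2)
        enc = make_encoding_schedule(events, "pairs", orders, 3)
        params = ModelParams(n_sims=1)
        state = NetworkState.fresh(events)
        rng = np.random.default_rng(7)
        for t in enc.trials:
            ev = events.by_id(t.event_id)
            encode_trial(state, [ev.element(c).element_id for c in t.categories], params, rng)
        w = state.weights
        assert np.array_equal(w, w.T)
        allowed = np.zeros_like(w, dtype=bool)
        for ev in events:
            idx = [state.index[e.element_id] for e in ev.elements]
            allowed[np.ix_(idx, idx)] = True
        np.fill_diagonal(allowed, False)
        assert np.all(w[~allowed] == 0.0)
        state.validate(params)


def test_enumerated_accuracies_match_closed_forms():
    """p + (1-p)p^2 for neutral questions; p for weak-link questions."""
    p = P.p_enc
    strong = p + (1 - p) * p * p
    neutral = enumerate_question_accuracy("neutral", "person_last")
    assert all(v == pytest.approx(strong) for v in neutral.values())
    neg_last = enumerate_question_accuracy("negative", "person_last")
    assert neg_last[("location", "object")] == pytest.approx(p)
    assert neg_last[("object", "location")] == pytest.approx(p)
    assert neg_last[("person", "location")] == pytest.approx(strong)
    neg_first = enumerate_question_accuracy("negative", "person_first")
    assert all(v == pytest.approx(p) for v in neg_first.values())
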