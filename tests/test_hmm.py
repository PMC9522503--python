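"""HMM parameter estimation, Viterbi decoding, and windowed fine-tuning."""

import itertools

import numpy as np
import pytest

from sleepstager.hmm import (
    HmmFineTuner,
    HmmParameters,
    estimate_emission,
    estimate_initial,
    estimate_transition,
    fine_tune_sequence,
    path_log_likelihood,
    select_window_length,
    viterbi,
)
from sleepstager.simulate import default_markov_model, sample_hypnogram


def brute_force_viterbi(obs, params, tol=1e-9):
    """Exhaustive enumeration over all state paths (oracle).

    Returns the set of maximum-likelihood paths (distinct paths can tie
    exactly when they use the same multiset of transition/emission factors).
    """
    S = params.n_states
    lls = {
        path: path_log_likelihood(np.array(path), obs, params)
        for path in itertools.product(range(S), repeat=len(obs))
    }
    best = max(lls.values())
    return {path for path, ll in lls.items() if ll >= best - tol}


def random_params(rng, n_states=3, window_length=17):
    tr = rng.random((n_states, n_states)) + 0.05
    em = rng.random((n_states, n_states)) + 0.05
    init = rng.random(n_states) + 0.05
    return HmmParameters(
        tr / tr.sum(1, keepdims=True),
        em / em.sum(1, keepdims=True),
        init / init.sum(),
        window_length,
    )


def self_dominant_params(diag_tr=0.9, diag_em=0.85, window_length=17):
    tr = np.full((5, 5), (1 - diag_tr) / 4) + np.eye(5) * (diag_tr - (1 - diag_tr) / 4)
    em = np.full((5, 5), (1 - diag_em) / 4) + np.eye(5) * (diag_em - (1 - diag_em) / 4)
    return HmmParameters(tr, em, np.full(5, 0.2), window_length)


class TestEstimation:
    def test_constant_sequence_gives_self_transition_one(self):
        tr = estimate_transition([np.zeros(4, dtype=int)])
        assert tr[0, 0] == pytest.approx(1.0, abs=1e-5)
        np.testing.assert_allclose(tr.sum(axis=1), 1.0, atol=1e-12)

    def test_alternating_sequence_counts_by_hand(self):
        tr = estimate_transition([np.array([0, 1, 0, 1, 0])], smoothing=0.0)
        assert tr[0, 1] == 1.0 and tr[1, 0] == 1.0

    def test_bigrams_never_cross_recording_boundaries(self):
        # two constant recordings: no 0->1 bigram despite concatenated order
        tr = estimate_transition([np.zeros(3, dtype=int), np.ones(3, dtype=int)], smoothing=0.0)
        assert tr[0, 1] == 0.0

    def test_no_bigrams_rejected(self):
        with pytest.raises(ValueError, match="bigram"):
            estimate_transition([np.array([2])])

    def test_transition_recovery_from_large_sample(self):
        model = default_markov_model()
        seq = sample_hypnogram(model, 100_000, seed=21)
        tr = estimate_transition([seq])
        assert np.abs(tr - model.transition).max() < 0.01

    def test_diagonal_confusion_gives_identity_emission(self):
        em = estimate_emission(np.eye(5) * 10)
        np.testing.assert_allclose(em, np.eye(5), atol=1e-5)

    def test_emission_row_normalization_by_hand(self):
        cm = np.eye(5)
        cm[0] = [8, 0, 2, 0, 0]
        em = estimate_emission(cm, smoothing=0.0)
        np.testing.assert_allclose(em[0], [0.8, 0, 0.2, 0, 0])
        np.testing.assert_allclose(em.sum(axis=1), 1.0, atol=1e-9)

    def test_initial_matches_stage_frequencies(self):
        init = estimate_initial([np.array([0, 0, 1, 2])], smoothing=0.0)
        np.testing.assert_allclose(init, [0.5, 0.25, 0.25, 0, 0])


class TestViterbi:
    def test_noiseless_channel_decodes_identity(self):
        model = default_markov_model()
        params = HmmParameters(model.transition, np.eye(5), np.full(5, 0.2))
        obs = np.array([0, 0, 1, 2, 2, 2, 4, 4, 0])
        np.testing.assert_array_equal(viterbi(obs, params), obs)

    def test_matches_exhaustive_enumeration_on_short_sequences(self, rng):
        params = random_params(rng, n_states=3)
        for L in (1, 2, 3, 4):
            for obs in itertools.product(range(3), repeat=L):
                obs = np.array(obs)
                optimal = brute_force_viterbi(obs, params)
                decoded = tuple(viterbi(obs, params))
                assert decoded in optimal, f"obs={obs}"
                if len(optimal) == 1:
                    assert decoded == next(iter(optimal))

    def test_agrees_with_hmmlearn_decoder(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = random_params(rng, n_states=5)
        obs = rng.integers(0, 5, 30)
        model = hmmlearn.CategoricalHMM(n_components=5)
        model.startprob_ = params.initial
        model.transmat_ = params.transition
        model.emissionprob_ = params.emission
        _, ref = model.decode(obs.reshape(-1, 1), algorithm="viterbi")
        ours = viterbi(obs, params)
        # both must attain the same (maximal) path likelihood
        assert path_log_likelihood(ours, obs, params) == pytest.approx(
            path_log_likelihood(ref, obs, params), rel=1e-9
        )

    def test_isolated_rem_in_wake_run_corrected(self):
        """A single REM epoch inside 17 Wake epochs is fine-tuned to Wake
        under parameters estimated from synthetic training hypnograms."""
        model = default_markov_model()
        train = [sample_hypnogram(model, 2000, seed=s) for s in range(5)]
        tr = estimate_transition(train)
        # diagonally-dominant emission, as produced by a decent classifier
        em = estimate_emission(np.eye(5) * 80 + 5)
        params = HmmParameters(tr, em, estimate_initial(train), window_length=17)
        obs = np.array([0] * 9 + [4] + [0] * 7)
        assert obs.size == 17
        np.testing.assert_array_equal(viterbi(obs, params), np.zeros(17, dtype=int))

    @pytest.mark.parametrize("position", list(range(1, 16)))
    def test_isolated_outlier_corrected_at_any_interior_position(self, position):
        params = self_dominant_params()
        obs = np.zeros(17, dtype=int)
        obs[position] = 4
        decoded = fine_tune_sequence(obs, params)
        np.testing.assert_array_equal(decoded, np.zeros(17, dtype=int))

    def test_decoded_path_at_least_as_likely_as_identity_path(self, rng):
        for _ in range(25):
            params = random_params(rng, n_states=5)
            obs = rng.integers(0, 5, 20)
            decoded = viterbi(obs, params)
            assert path_log_likelihood(decoded, obs, params) >= path_log_likelihood(
                obs, obs, params
            ) - 1e-9

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            viterbi(np.array([], dtype=int), self_dominant_params())


class TestFineTune:
    def test_window_covering_whole_sequence_equals_single_decode(self, rng):
        params = random_params(rng, n_states=5, window_length=50)
        obs = rng.integers(0, 5, 23)
        np.testing.assert_array_equal(fine_tune_sequence(obs, params), viterbi(obs, params))

    def test_windowed_decode_partitions_consistently(self, rng):
        params = random_params(rng, n_states=5, window_length=7)
        obs = rng.integers(0, 5, 23)
        out = fine_tune_sequence(obs, params)
        assert out.size == obs.size
        for start in range(0, 23, 7):
            np.testing.assert_array_equal(
                out[start : start + 7], viterbi(obs[start : start + 7], params)
            )

    def test_identity_emission_uniform_transitions_is_noop(self, rng):
        params = HmmParameters(np.full((5, 5), 0.2), np.eye(5), np.full(5, 0.2), 6)
        obs = rng.integers(0, 5, 30)
        np.testing.assert_array_equal(fine_tune_sequence(obs, params), obs)

    def test_fine_tuning_improves_accuracy_under_isolated_flips(self):
        """5% isolated single-epoch label flips are mostly repaired."""
        model = default_markov_model()
        rng = np.random.default_rng(17)
        truth = sample_hypnogram(model, 2000, seed=33)
        noisy = truth.copy()
        # ~5% flip sites, spaced >= 20 epochs apart so every flip is isolated
        for i in range(2, truth.size - 1, 20):
            if truth[i - 1] == truth[i] == truth[i + 1]:
                noisy[i] = (truth[i] + rng.integers(1, 5)) % 5
        tr = estimate_transition([sample_hypnogram(model, 5000, seed=s) for s in range(3)])
        em = estimate_emission(np.eye(5) * 90 + 2.5)
        params = HmmParameters(tr, em, np.full(5, 0.2), window_length=17)
        tuned = fine_tune_sequence(noisy, params)
        acc_before = (noisy == truth).mean()
        acc_after = (tuned == truth).mean()
        assert acc_after > acc_before

    def test_fit_predict_estimator_roundtrip(self):
        model = default_markov_model()
        seqs = [sample_hypnogram(model, 500, seed=s) for s in range(3)]
        tuner = HmmFineTuner(window_length=9).fit(seqs, np.eye(5) * 50 + 2)
        out = tuner.predict(seqs[0])
        assert out.shape == seqs[0].shape


class TestWindowLengthSelection:
    def test_single_candidate_returned(self):
        params = self_dominant_params()
        fused = [np.zeros(20, dtype=int)]
        assert select_window_length(fused, fused, params, [5]) == 5

    def test_ties_go_to_smallest_candidate(self):
        params = HmmParameters(np.full((5, 5), 0.2), np.eye(5), np.full(5, 0.2), 1)
        fused = [np.array([0, 1, 2, 3, 4] * 4)]
        # identity emission + uniform transitions: every length is a no-op
        assert select_window_length(fused, fused, params, [9, 3, 6]) == 3

    def test_longer_windows_win_when_errors_fill_short_windows(self):
        """A 3-epoch stage burst aligned with a length-3 window survives short
        decoding but is outvoted inside a long window."""
        params = self_dominant_params(diag_tr=0.897, diag_em=0.7)
        truth = np.zeros(102, dtype=int)
        fused = truth.copy()
        # burst starts are multiples of 3 (filling a short window exactly)
        # but interior to the length-17 windows starting at 17 and 51
        for start in (24, 57):
            fused[start : start + 3] = 4
        chosen = select_window_length([fused], [truth], params, [3, 17])
        assert chosen == 17
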