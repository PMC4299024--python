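import numpy as np
import pytest

from actiseg.decode import (
    brute_force_best,
    build_score_tables,
    constrained_viterbi,
    constrained_viterbi_tables,
    crf_score,
    hmm_score,
    satisfies_min_run,
    viterbi,
    viterbi_tables,
)
from conftest import random_model


class TestPathScoring:
    def test_hand_multiplied_joint_probability(self, toy_model):
        got = hmm_score(toy_model, [1, 2], ["a", "b"])
        assert got == pytest.approx(np.log(0.5 * 0.8 * 0.1 * 0.8))

    def test_single_position_uniform_prior(self, toy_model):
        toy_model.B = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert hmm_score(toy_model, [1], ["a"]) == pytest.approx(np.log(0.5))

    def test_probability_paths_score_nonpositive(self, toy_model):
        rng = np.random.default_rng(0)
        for _ in range(10):
            obs = rng.integers(1, 3, size=5)
            path = rng.choice(["a", "b"], size=5)
            assert hmm_score(toy_model, obs, path) <= 0.0

    def test_unknown_state_rejected(self, toy_model):
        with pytest.raises(KeyError):
            hmm_score(toy_model, [1], ["zz"])
        with pytest.raises(ValueError):
            hmm_score(toy_model, [9], ["a"])


class TestCrfScoring:
    def test_zero_kmer_weight_reduces_to_joint_log_probability(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, n_states=2, M=3)
        model.weights = (1.0, 1.0, 0.0)
        for _ in range(10):
            obs = rng.integers(1, 4, size=6)
            path = rng.choice(model.states, size=6)
            assert crf_score(model, obs, path) == pytest.approx(
                hmm_score(model, obs, path)
            )

    def test_kmer_feature_adds_one_term_per_valid_position(self):
        rng = np.random.default_rng(4)
        model = random_model(rng, n_states=2, M=3)
        model.weights = (1.0, 1.0, 1.0)
        obs = np.array([1, 2])
        path = ["s0", "s1"]
        # with T=2, k=2 only t=1 has a complete k-mer, conditioned on q_1
        expected = hmm_score(model, obs, path) + model.kmer_log_prob(0, (1, 2))
        assert crf_score(model, obs, path) == pytest.approx(expected)

    def test_constant_emission_shift_preserves_argmax(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, n_states=2, M=3)
        obs = rng.integers(1, 4, size=6)
        init, trans, emit = build_score_tables(model, obs, "crf")
        p1, s1 = viterbi_tables(init, trans, emit)
        p2, s2 = viterbi_tables(init, trans, emit + 3.5)
        assert p1.tolist() == p2.tolist()
        assert s2 == pytest.approx(s1 + 3.5 * len(obs))


class TestViterbi:
    def test_single_state_constant_path(self):
        rng = np.random.default_rng(0)
        model = random_model(rng, n_states=1, M=3)
        res = viterbi(model, [1, 2, 3, 1])
        assert res.path.tolist() == ["s0"] * 4

    def test_deterministic_emissions_follow_observations(self):
        rng = np.random.default_rng(0)
        model = random_model(rng, n_states=2, M=2)
        model.B = np.array([[1.0, 0.0], [0.0, 1.0]])
        model.A = np.full((2, 2), 0.5)
        model.pi = np.array([0.5, 0.5])
        res = viterbi(model, [1, 2, 2, 1])
        assert res.path.tolist() == ["s0", "s1", "s1", "s0"]

    @pytest.mark.parametrize("scoring", ["hmm", "crf"])
    def test_matches_exhaustive_enumeration(self, scoring):
        rng = np.random.default_rng(123)
        for trial in range(20):
            model = random_model(rng, n_states=int(rng.integers(2, 4)), M=3)
            T = int(rng.integers(1, 7))
            obs = rng.integers(1, 4, size=T)
            init, trans, emit = build_score_tables(model, obs, scoring)
            path, score = viterbi_tables(init, trans, emit)
            bf_path, bf_score, unique = brute_force_best(init, trans, emit)
            assert score == pytest.approx(bf_score)
            if unique:
                assert path.tolist() == bf_path.tolist()


class TestConstrainedViterbi:
    def test_vacuous_constraint_identical_to_unconstrained(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            model = random_model(rng, n_states=3, M=3, kappa_max=1)
            obs = rng.integers(1, 4, size=8)
            init, trans, emit = build_score_tables(model, obs, "hmm")
            p1, s1 = viterbi_tables(init, trans, emit)
            p2, s2 = constrained_viterbi_tables(init, trans, emit, np.ones(3, int))
            assert p1.tolist() == p2.tolist() and s1 == pytest.approx(s2)

    def test_three_step_feasible_set_is_constant_paths(self):
        rng = np.random.default_rng(1)
        model = random_model(rng, n_states=2, M=3)
        model.kappa = np.array([2, 2])
        obs = rng.integers(1, 4, size=3)
        res = constrained_viterbi(model, obs)
        # only the two constant paths satisfy kappa=[2,2] at T=3
        assert len(set(res.path.tolist())) == 1
        best_const = max(
            hmm_score(model, obs, [s] * 3) for s in model.states
        )
        assert res.score == pytest.approx(best_const)

    @pytest.mark.parametrize("scoring", ["hmm", "crf"])
    def test_matches_run_length_filtered_enumeration(self, scoring):
        rng = np.random.default_rng(321)
        for trial in range(20):
            model = random_model(
                rng, n_states=int(rng.integers(2, 4)), M=3, kappa_max=3
            )
            T = int(rng.integers(int(model.kappa.min()), 9))
            obs = rng.integers(1, 4, size=T)
            init, trans, emit = build_score_tables(model, obs, scoring)
            try:
                bf_path, bf_score, unique = brute_force_best(
                    init, trans, emit, model.kappa
                )
            except ValueError:
                with pytest.raises(ValueError, match="infeasible"):
                    constrained_viterbi_tables(init, trans, emit, model.kappa)
                continue
            path, score = constrained_viterbi_tables(init, trans, emit, model.kappa)
            assert score == pytest.approx(bf_score)
            assert satisfies_min_run(path, model.kappa)
            if unique:
                assert path.tolist() == bf_path.tolist()

    def test_constraint_never_improves_the_optimum(self):
        rng = np.random.default_rng(55)
        for _ in range(15):
            model = random_model(rng, n_states=2, M=3, kappa_max=3)
            T = int(rng.integers(int(model.kappa.max()), 9))
            obs = rng.integers(1, 4, size=T)
            free = viterbi(model, obs)
            try:
                constrained = constrained_viterbi(model, obs)
            except ValueError:
                continue
            assert constrained.score <= free.score + 1e-9

    def test_infeasible_horizon_raises(self):
        rng = np.random.default_rng(2)
        model = random_model(rng, n_states=2, M=3)
        model.kappa = np.array([4, 4])
        with pytest.raises(ValueError, match="infeasible constraint"):
            constrained_viterbi(model, [1, 2, 3])

    def test_decoded_path_always_satisfies_kappa(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            model = random_model(rng, n_states=3, M=4, kappa_max=3)
            T = int(rng.integers(int(model.kappa.max()) * 2, 15))
            obs = rng.integers(1, 5, size=T)
            res = constrained_viterbi(model, obs, scoring="crf")
            idx = np.array([model.state_index(s) for s in res.path])
            assert satisfies_min_run(idx, model.kappa)


def test_crf_with_unit_weights_and_no_kmers_equals_hmm_path():
    """With w=(1,1,0) the CRF scoring telescopes to the HMM joint, so both
    decoders must return the same path under the shared tie rule."""
    rng = np.random.default_rng(1000)
    for _ in range(15):
        model = random_model(rng, n_states=3, M=3, kappa_max=2)
        model.weights = (1.0, 1.0, 0.0)
        T = int(rng.integers(int(model.kappa.max()) * 2, 10))
        obs = rng.integers(1, 4, size=T)
        assert (
            viterbi(model, obs, "crf").path.tolist()
            == viterbi(model, obs, "hmm").path.tolist()
        )
        assert (
            constrained_viterbi(model, obs, "crf").path.tolist()
            == constrained_viterbi(model, obs, "hmm").path.tolist()
        )
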