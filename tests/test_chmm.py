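import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from conftest import make_random_chmm
from signfuse.chmm import (
    CoupledHMM,
    EmissionModel,
    brute_force_loglik,
    classify_word,
    composite_transition_matrix,
    em_fit,
    load_model,
    log_backward,
    log_forward,
    sample_sequence,
    save_model,
    state_scores,
    validate_model,
)
from signfuse.features import ObservationPair
from signfuse.lexicon import CompositeState, Lexicon, LexiconEntry


def _uniform_model(n1=2, n2=2, d1=1, d2=1):
    means = [np.zeros((n1, d1)), np.zeros((n2, d2))]
    means[0][:, 0] = np.arange(n1)
    means[1][:, 0] = np.arange(n2)
    return CoupledHMM(
        n1=n1, n2=n2,
        initial=[np.full(n1, 1 / n1), np.full(n2, 1 / n2)],
        transitions=[
            np.full((n1, n2, n1), 1 / n1),
            np.full((n1, n2, n2), 1 / n2),
        ],
        emissions=EmissionModel(
            means=means,
            vars=[np.ones((n1, d1)), np.ones((n2, d2))],
        ),
    )


def _obs(t, d1=1, d2=1, seed=0):
    rng = np.random.default_rng(seed)
    return ObservationPair(
        gesture=rng.normal(size=(t, d1)), trajectory=rng.normal(size=(t, d2))
    )


class TestValidateModel:
    def test_uniform_ok(self):
        assert validate_model(_uniform_model()) == []

    def test_bad_row_sum_named(self):
        m = _uniform_model()
        m.transitions[0][1, 0] = np.array([0.4, 0.5])
        (v,) = validate_model(m)
        assert "chain 1" in v and "(1,0)" in v.replace(" ", "")

    def test_negative_variance(self):
        m = _uniform_model()
        m.emissions.vars[1][0, 0] = -1.0
        assert any("variance" in v for v in validate_model(m))

    def test_bad_initial(self):
        m = _uniform_model()
        m.initial[0] = np.array([0.7, 0.7])
        assert any("initial" in v for v in validate_model(m))


class TestCompositeTransitionMatrix:
    def test_trivial_single_state(self):
        m = _uniform_model(1, 1)
        assert composite_transition_matrix(m).tolist() == [[1.0]]

    def test_independent_chains_kronecker(self):
        rng = np.random.default_rng(3)
        n1, n2 = 2, 3
        A1_own = rng.dirichlet(np.ones(n1), size=n1)  # depends on own state only
        A2_own = rng.dirichlet(np.ones(n2), size=n2)
        m = _uniform_model(n1, n2)
        m.transitions[0] = np.repeat(A1_own[:, None, :], n2, axis=1)
        m.transitions[1] = np.repeat(A2_own[None, :, :], n1, axis=0)
        M = composite_transition_matrix(m)
        assert np.allclose(M, np.kron(A1_own, A2_own))

    def test_random_rows_sum_to_one(self):
        for seed in range(5):
            m = make_random_chmm(3, 4, seed=seed)
            M = composite_transition_matrix(m)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_model_rejected(self):
        m = _uniform_model()
        m.transitions[0][0, 0] = np.array([0.5, 0.4])
        with pytest.raises(ValueError):
            composite_transition_matrix(m)


class TestLogForward:
    def test_single_frame_closed_form(self):
        m = make_random_chmm(2, 3, seed=1)
        obs = _obs(1, d1=2, d2=2, seed=2)
        ll, _ = log_forward(m, obs)
        total = 0.0
        for i1 in range(2):
            for i2 in range(3):
                b1 = norm.pdf(
                    obs.gesture[0], m.emissions.means[0][i1],
                    np.sqrt(m.emissions.vars[0][i1]),
                ).prod()
                b2 = norm.pdf(
                    obs.trajectory[0], m.emissions.means[1][i2],
                    np.sqrt(m.emissions.vars[1][i2]),
                ).prod()
                total += m.initial[0][i1] * m.initial[1][i2] * b1 * b2
        assert ll == pytest.approx(np.log(total), abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        for seed in range(10):
            m = make_random_chmm(2, 2, seed=seed)
            obs = _obs(4, d1=2, d2=2, seed=100 + seed)
            ll, _ = log_forward(m, obs)
            assert ll == pytest.approx(brute_force_loglik(m, obs), abs=1e-9)

    def test_identical_emissions_marginalize(self):
        # all states share one emission -> log P = sum_t log density_t
        m = _uniform_model(2, 2)
        for c in (0, 1):
            m.emissions.means[c][:] = 0.5
        obs = _obs(5, seed=7)
        ll, _ = log_forward(m, obs)
        expected = (
            norm.logpdf(obs.gesture, 0.5, 1.0).sum()
            + norm.logpdf(obs.trajectory, 0.5, 1.0).sum()
        )
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch(self):
        m = make_random_chmm(2, 2, d1=3, seed=0)
        with pytest.raises(ValueError):
            log_forward(m, _obs(3, d1=2))


class TestBruteForce:
    def test_deterministic_single_path(self):
        m = _uniform_model(2, 2)
        m.initial = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        for c, j in ((0, 0), (1, 1)):
            A = np.zeros_like(m.transitions[c])
            A[..., j] = 1.0
            m.transitions[c] = A
        obs = _obs(3, seed=4)
        expected = (
            norm.logpdf(obs.gesture[:, 0], 0.0, 1.0).sum()
            + norm.logpdf(obs.trajectory[:, 0], 1.0, 1.0).sum()
        )
        assert brute_force_loglik(m, obs) == pytest.approx(expected, abs=1e-9)

    def test_refuses_large_state_space(self):
        m = make_random_chmm(4, 4, seed=0)
        with pytest.raises(ValueError):
            brute_force_loglik(m, _obs(10, d1=2, d2=2))


class TestForwardBackward:
    def test_backward_gives_same_likelihood(self):
        from signfuse.chmm import _composite_log_quantities

        for seed in range(5):
            m = make_random_chmm(3, 2, seed=seed)
            obs = _obs(6, d1=2, d2=2, seed=50 + seed)
            ll, _ = log_forward(m, obs)
            beta = log_backward(m, obs)
            log_pi, _, log_b = _composite_log_quantities(m, obs)
            ll_b = logsumexp(log_pi + log_b[0] + beta[0])
            assert ll_b == pytest.approx(ll, abs=1e-9)

    def test_posteriors_normalize(self):
        m = make_random_chmm(3, 3, seed=2)
        obs = _obs(8, d1=2, d2=2, seed=3)
        ll, alpha = log_forward(m, obs)
        beta = log_backward(m, obs)
        gamma = np.exp(alpha + beta - ll)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestSampleSequence:
    def test_determinism(self):
        m = make_random_chmm(2, 3, seed=5)
        p1, o1 = sample_sequence(m, 20, seed=9)
        p2, o2 = sample_sequence(m, 20, seed=9)
        assert p1 == p2
        assert np.array_equal(o1.gesture, o2.gesture)

    def test_deterministic_model_single_path(self):
        m = _uniform_model(2, 2)
        m.initial = [np.array([0.0, 1.0]), np.array([1.0, 0.0])]
        for c, j in ((0, 1), (1, 0)):
            A = np.zeros_like(m.transitions[c])
            A[..., j] = 1.0
            m.transitions[c] = A
        for seed in range(5):
            path, _ = sample_sequence(m, 6, seed=seed)
            assert path == [(1, 0)] * 6

    def test_empirical_transition_frequencies(self):
        m = make_random_chmm(2, 2, seed=8)
        path, _ = sample_sequence(m, 10000, seed=1)
        # empirical chain-1 transition out of each composite state
        counts = np.zeros((2, 2, 2))
        for (i1, i2), (j1, _) in zip(path, path[1:]):
            counts[i1, i2, j1] += 1
        for i1 in range(2):
            for i2 in range(2):
                n = counts[i1, i2].sum()
                if n < 50:
                    continue
                p_hat = counts[i1, i2, 1] / n
                p = m.transitions[0][i1, i2, 1]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(p_hat - p) <= 3 * se + 1e-9


class TestEmFit:
    def test_single_state_recovers_pooled_means(self):
        rng = np.random.default_rng(0)
        data = [
            ObservationPair(
                gesture=rng.normal(2.0, 1.0, size=(30, 2)),
                trajectory=rng.normal(-1.0, 0.5, size=(30, 3)),
            )
            for _ in range(5)
        ]
        init = CoupledHMM(
            n1=1, n2=1,
            initial=[np.ones(1), np.ones(1)],
            transitions=[np.ones((1, 1, 1)), np.ones((1, 1, 1))],
            emissions=EmissionModel(
                means=[np.zeros((1, 2)), np.zeros((1, 3))],
                vars=[np.ones((1, 2)), np.ones((1, 3))],
            ),
        )
        fitted, _ = em_fit(init, data, max_iter=3, tol=0.0)
        pooled1 = np.vstack([d.gesture for d in data]).mean(axis=0)
        pooled2 = np.vstack([d.trajectory for d in data]).mean(axis=0)
        assert np.allclose(fitted.emissions.means[0][0], pooled1, atol=1e-12)
        assert np.allclose(fitted.emissions.means[1][0], pooled2, atol=1e-12)

    def test_init_at_truth_barely_moves(self):
        true = make_random_chmm(2, 2, seed=11, mean_scale=5.0)
        data = [sample_sequence(true, 40, seed=1000 + k)[1] for k in range(100)]
        _, report = em_fit(true, data, max_iter=2, tol=0.0)
        rel = abs(report.loglik_trace[1] - report.loglik_trace[0]) / abs(
            report.loglik_trace[0]
        )
        assert rel < 0.01

    def test_monotone_loglik(self):
        for seed in range(3):
            true = make_random_chmm(2, 3, seed=seed, mean_scale=2.0)
            data = [sample_sequence(true, 25, seed=seed * 100 + k)[1] for k in range(20)]
            init = make_random_chmm(2, 3, seed=seed + 50, mean_scale=2.0)
            _, report = em_fit(init, data, max_iter=15, tol=0.0)
            diffs = np.diff(report.loglik_trace)
            assert (diffs >= -1e-8).all()

    def test_rows_remain_stochastic(self):
        true = make_random_chmm(3, 2, seed=4)
        data = [sample_sequence(true, 30, seed=k)[1] for k in range(10)]
        init = make_random_chmm(3, 2, seed=99)
        fitted, _ = em_fit(init, data, max_iter=5, tol=0.0)
        assert validate_model(fitted) == []

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            em_fit(_uniform_model(), [], max_iter=1, tol=0.0)


def _align_states(true_means, est_means):
    """Greedy nearest-mean matching; returns perm mapping est index -> true."""
    perm = []
    used = set()
    for j in range(len(est_means)):
        d = np.linalg.norm(true_means - est_means[j], axis=1)
        order = np.argsort(d)
        pick = next(i for i in order if i not in used)
        used.add(int(pick))
        perm.append(int(pick))
    return perm


class TestParameterRecovery:
    def test_coupled_transition_mae(self):
        true = make_random_chmm(3, 3, d1=2, d2=2, seed=21, mean_scale=6.0)
        data = [sample_sequence(true, 50, seed=3000 + k)[1] for k in range(200)]
        # perturb the true model for initialization
        rng = np.random.default_rng(77)
        init = make_random_chmm(3, 3, d1=2, d2=2, seed=22)
        for c in (0, 1):
            init.emissions.means[c] = true.emissions.means[c] + rng.normal(
                0, 1.0, true.emissions.means[c].shape
            )
            init.emissions.vars[c] = np.ones_like(true.emissions.vars[c])
        fitted, _ = em_fit(init, data, max_iter=25, tol=1e-7)
        perm = [
            _align_states(true.emissions.means[c], fitted.emissions.means[c])
            for c in (0, 1)
        ]
        errs = []
        for c in (0, 1):
            for i1 in range(3):
                for i2 in range(3):
                    est_row = fitted.transitions[c][i1, i2]
                    t1, t2 = perm[0][i1], perm[1][i2]
                    true_row = true.transitions[c][t1, t2]
                    reordered = np.empty_like(est_row)
                    for j in range(3):
                        reordered[perm[c][j]] = est_row[j]
                    errs.append(np.abs(reordered - true_row))
        mae = np.concatenate(errs).mean()
        assert mae <= 0.1


class TestStateScores:
    def test_identical_states_identical_scores(self):
        m = _uniform_model(2, 2)
        for c in (0, 1):
            m.emissions.means[c][:] = 0.0
        obs = _obs(4, seed=5)
        scores = state_scores(m, obs)
        assert np.allclose(scores, scores[0])

    def test_dwell_argmax_recovers_state(self):
        m = make_random_chmm(3, 3, d1=2, d2=2, seed=31, mean_scale=6.0)
        # boost self-transitions so dwelling is plausible
        for c in (0, 1):
            A = m.transitions[c] * 0.1
            for i1 in range(3):
                for i2 in range(3):
                    A[i1, i2, (i1, i2)[c]] += 0.9
            m.transitions[c] = A / A.sum(axis=2, keepdims=True)
        rng = np.random.default_rng(0)
        hits = 0
        trials = 50
        for k in range(trials):
            i1, i2 = k % 3, (k // 3) % 3
            obs = ObservationPair(
                gesture=rng.normal(m.emissions.means[0][i1], 1.0, size=(200, 2)),
                trajectory=rng.normal(m.emissions.means[1][i2], 1.0, size=(200, 2)),
            )
            scores = state_scores(m, obs)
            if np.argmax(scores) == i1 * 3 + i2:
                hits += 1
        assert hits >= trials - 1

    def test_single_frame_uniform_ranking_is_emission_ranking(self):
        m = _uniform_model(3, 1)
        m.transitions[0] = np.full((3, 1, 3), 1 / 3)
        obs = ObservationPair(
            gesture=np.array([[0.9]]), trajectory=np.array([[0.0]])
        )
        scores = state_scores(m, obs).reshape(3, 1)[:, 0]
        dens = norm.logpdf(0.9, m.emissions.means[0][:, 0], 1.0)
        assert list(np.argsort(scores)) == list(np.argsort(dens))

    def test_zero_self_transition_gives_minus_inf(self):
        m = _uniform_model(2, 2)
        A = np.zeros((2, 2, 2))
        A[..., 1] = 1.0  # chain 1 always jumps to state 1
        m.transitions[0] = A
        scores = state_scores(m, _obs(3, seed=1)).reshape(2, 2)
        assert np.isinf(scores[0]).all() and (scores[0] < 0).all()


class TestClassifyWord:
    def _lex(self):
        return Lexicon(
            entries=[
                LexiconEntry(1, "a", "SHGV", [CompositeState(1, 0)]),
                LexiconEntry(2, "b", "SHGV", [CompositeState(2, 1)]),
                LexiconEntry(3, "c", "DGV", [CompositeState(1, 1), CompositeState(2, 1)]),
            ],
            n_gestures=2,
            n_movement_states=2,
        )

    def test_single_candidate(self):
        m = _uniform_model(2, 2)
        lex = Lexicon(
            entries=[LexiconEntry(5, "only", "SHGV", [CompositeState(1, 0)])],
            n_gestures=2, n_movement_states=2,
        )
        wid, _ = classify_word(m, [_obs(4, seed=2)], lex)
        assert wid == 5

    def test_stage_count_filter_and_no_candidate(self):
        m = _uniform_model(2, 2)
        with pytest.raises(LookupError):
            classify_word(m, [_obs(3), _obs(3), _obs(3)], self._lex())

    def test_tie_breaks_to_smaller_word_id(self):
        m = _uniform_model(2, 2)
        for c in (0, 1):
            m.emissions.means[c][:] = 0.0
        lex = Lexicon(
            entries=[
                LexiconEntry(4, "x", "SHGV", [CompositeState(1, 0)]),
                LexiconEntry(9, "y", "SHGV", [CompositeState(1, 0)]),
            ],
            n_gestures=2, n_movement_states=2,
        )
        wid, _ = classify_word(m, [_obs(4, seed=3)], lex)
        assert wid == 4

    def test_category_filter(self):
        m = _uniform_model(2, 2)
        for c in (0, 1):
            m.emissions.means[c][:] = 0.0
        lex = Lexicon(
            entries=[
                LexiconEntry(1, "a", "SHGV", [CompositeState(1, 0)]),
                LexiconEntry(2, "b", "DHGV", [CompositeState(1, 0)]),
            ],
            n_gestures=2, n_movement_states=2,
        )
        wid, _ = classify_word(m, [_obs(4, seed=3)], lex, category="DHGV")
        assert wid == 2

    def test_two_stage_word_end_to_end(self):
        m = make_random_chmm(2, 2, d1=2, d2=2, seed=41, mean_scale=6.0)
        rng = np.random.default_rng(7)
        lex = Lexicon(
            entries=[
                LexiconEntry(1, "ab", "DGV", [CompositeState(1, 1), CompositeState(2, 1)]),
                LexiconEntry(2, "ba", "DGV", [CompositeState(2, 1), CompositeState(1, 1)]),
            ],
            n_gestures=2, n_movement_states=2,
        )
        stage_obs = []
        for g in (0, 1):  # 0-based chain states for stages (1,1),(2,1)
            stage_obs.append(
                ObservationPair(
                    gesture=rng.normal(m.emissions.means[0][g], 0.5, size=(30, 2)),
                    trajectory=rng.normal(m.emissions.means[1][0], 0.5, size=(30, 2)),
                )
            )
        wid, _ = classify_word(m, stage_obs, lex)
        assert wid == 1


class TestModelIO:
    def test_roundtrip_exact(self, tmp_path):
        m = make_random_chmm(3, 2, d1=2, d2=4, seed=13)
        p = tmp_path / "model.json"
        save_model(m, p)
        again = load_model(p)
        assert again.n1 == m.n1 and again.n2 == m.n2
        for c in (0, 1):
            assert np.array_equal(again.initial[c], m.initial[c])
            assert np.array_equal(again.transitions[c], m.transitions[c])
            assert np.array_equal(again.emissions.means[c], m.emissions.means[c])
            assert np.array_equal(again.emissions.vars[c], m.emissions.vars[c])
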