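"""HMM machinery: gap statistic, EM, labeling, averaging, Viterbi."""

import itertools

import numpy as np
import pytest
from scipy import stats

from chromstage.hmm import (
    CANONICAL_ORDER,
    ModelError,
    StateHMM,
    align_and_average,
    fit_hmm_em,
    gap_select_k,
    label_states,
    viterbi_decode,
    viterbi_path,
)
from chromstage.simulate import DEFAULT_MARKS


def toy_model(K=3, M=2, seed=0, labels=None, transform="none"):
    rng = np.random.default_rng(seed)
    means = rng.normal(0, 3, (K, M))
    sds = rng.uniform(0.5, 2.0, (K, M))
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    pi = rng.dirichlet(np.ones(K))
    return StateHMM(means, sds, A, pi, [f"m{j}" for j in range(M)],
                    labels=labels, transform=transform)


def brute_force_best_path(model, logB):
    """Exhaustive argmax over all K^n paths (oracle for Viterbi)."""
    n, K = logB.shape
    log_pi = np.log(model.initial)
    log_A = np.log(model.transition)
    best, best_ll = None, -np.inf
    for path in itertools.product(range(K), repeat=n):
        ll = log_pi[path[0]] + logB[0, path[0]]
        for t in range(1, n):
            ll += log_A[path[t - 1], path[t]] + logB[t, path[t]]
        if ll > best_ll:
            best_ll, best = ll, path
    return np.array(best)


class TestEmission:
    def test_log_density_matches_scipy(self):
        m = toy_model(K=2, M=3, seed=1)
        X = np.random.default_rng(2).normal(0, 2, (5, 3))
        got = m.log_emission(X)
        for i in range(5):
            for k in range(2):
                exp = stats.norm.logpdf(X[i], m.means[k], m.sds[k]).sum()
                assert got[i, k] == pytest.approx(exp)

    def test_stationary_distribution_fixed_point(self):
        m = toy_model(seed=3)
        pi = m.stationary_distribution()
        assert np.allclose(pi @ m.transition, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)

    def test_bad_transition_rejected(self):
        with pytest.raises(ModelError):
            StateHMM(np.zeros((2, 1)), np.ones((2, 1)),
                     np.array([[0.5, 0.4], [0.5, 0.5]]), np.array([0.5, 0.5]),
                     ["m0"])

    def test_json_round_trip(self, tmp_path):
        m = toy_model(labels=list(CANONICAL_ORDER))
        m.to_json(tmp_path / "m.json")
        back = StateHMM.from_json(tmp_path / "m.json")
        assert np.allclose(back.means, m.means)
        assert np.allclose(back.transition, m.transition)
        assert back.labels == m.labels
        assert back.transform == m.transform


class TestGap:
    def test_degenerate_data_chooses_one(self):
        X = np.ones((50, 3))
        assert gap_select_k(X, range(1, 5), B=5, seed=0).chosen_k == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_two_well_separated_blobs_choose_two(self, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.3, (80, 2)), rng.normal(8, 0.3, (80, 2))])
        res = gap_select_k(X, range(1, 5), B=20, seed=seed, transform="none")
        assert res.chosen_k == 2

    def test_gap_is_ref_minus_obs(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 2))
        res = gap_select_k(X, range(1, 4), B=10, seed=0, transform="none")
        assert np.allclose(res.gap, res.log_w_ref_mean - res.log_w_obs)


def sample_from_model(model, n, seed):
    rng = np.random.default_rng(seed)
    K = model.K
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(K, p=model.initial)
    for t in range(1, n):
        states[t] = rng.choice(K, p=model.transition[states[t - 1]])
    X = rng.normal(model.means[states], model.sds[states])
    return X, states


class TestEM:
    def test_k1_closed_form(self):
        """With one state EM is a single Gaussian fit: mean and sd of the
        (transformed) data."""
        rng = np.random.default_rng(0)
        X = rng.gamma(2.0, 2.0, (300, 2))
        m, _ = fit_hmm_em(X, K=1, seed=0)
        Xt = np.log1p(X)
        assert np.allclose(m.means[0], Xt.mean(axis=0), atol=1e-6)
        assert np.allclose(m.sds[0], Xt.std(axis=0), atol=1e-6)
        assert m.transition[0, 0] == pytest.approx(1.0)

    def test_loglik_trace_monotone(self):
        gen = toy_model(K=3, M=2, seed=5)
        gen.transition = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        X, _ = sample_from_model(gen, 400, seed=1)
        _, trace = fit_hmm_em(X, K=3, seed=0, transform="none")
        assert np.all(np.diff(trace) >= -1e-7)

    def test_parameter_recovery_within_10pct(self):
        """Means recovered within 10% relative error at n=1000 from a
        well-separated 3-state generator."""
        means = np.array([[0.0, 0.0], [4.0, 1.0], [8.0, 6.0]])
        sds = np.full((3, 2), 0.6)
        A = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        gen = StateHMM(means, sds, A, np.full(3, 1 / 3), ["m0", "m1"],
                       transform="none")
        X, _ = sample_from_model(gen, 1000, seed=7)
        m, _ = fit_hmm_em(X, K=3, seed=0, transform="none")
        # match fitted states to generator states by nearest mean
        order = [int(np.argmin(np.sum((m.means - mu) ** 2, axis=1))) for mu in means]
        assert sorted(order) == [0, 1, 2]
        rel = np.abs(m.means[order] - means) / np.maximum(np.abs(means), 1.0)
        assert rel.max() < 0.10

    def test_agrees_with_hmmlearn_loglik(self):
        """Our fitted model scores the data within a small tolerance of an
        hmmlearn GaussianHMM fitted on the same sequence."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        gen = toy_model(K=2, M=2, seed=9)
        gen.means = np.array([[0.0, 0.0], [5.0, 5.0]])
        gen.sds = np.full((2, 2), 0.8)
        gen.transition = np.array([[0.85, 0.15], [0.2, 0.8]])
        X, _ = sample_from_model(gen, 500, seed=3)
        ours, trace = fit_hmm_em(X, K=2, seed=0, transform="none")
        ref = hmm.GaussianHMM(n_components=2, covariance_type="diag",
                              n_iter=300, tol=1e-6, random_state=0)
        ref.fit(X)
        # compare achieved log-likelihoods of the two fits
        assert trace[-1] == pytest.approx(ref.score(X), abs=2.0)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ModelError):
            fit_hmm_em(np.ones((5, 2)), K=3)


class TestLabeling:
    def make(self, means):
        K = len(means)
        return StateHMM(np.asarray(means, float), np.ones((K, 5)),
                        np.full((K, K), 1 / K), np.full(K, 1 / K),
                        list(DEFAULT_MARKS))

    def test_clear_case(self):
        # marks: K4me1, K4me3, K9ac, K36me3, K27me3
        m = self.make([[0.1, 0.1, 0.1, 0.1, 0.2],    # null
                       [3.0, 8.0, 6.0, 5.0, 0.5],    # active
                       [0.8, 1.5, 0.8, 0.4, 5.0]])   # nonactive
        assert label_states(m) == ["null", "active", "nonactive"]

    def test_tie_warns_and_breaks_by_index(self):
        m = self.make([[0.0, 0.0, 0.0, 0.0, 2.0],
                       [0.0, 0.0, 0.0, 0.0, 2.0],
                       [5.0, 5.0, 5.0, 5.0, 0.0]])
        with pytest.warns(UserWarning, match="tie"):
            labels = label_states(m)
        assert labels[0] == "nonactive"

    def test_requires_three_states(self):
        m = StateHMM(np.zeros((2, 5)), np.ones((2, 5)), np.eye(2),
                     np.array([0.5, 0.5]), list(DEFAULT_MARKS))
        with pytest.raises(ModelError):
            label_states(m)


class TestAveraging:
    def canonical(self, seed=0):
        m = toy_model(K=3, M=5, seed=seed)
        m.marks = list(DEFAULT_MARKS)
        m.labels = list(CANONICAL_ORDER)
        return m

    def test_average_of_identical_models_is_identity(self):
        m = self.canonical()
        avg = align_and_average([m, m, m])
        assert np.allclose(avg.means, m.means)
        assert np.allclose(avg.sds, m.sds)
        assert np.allclose(avg.transition, m.transition)
        assert avg.labels == list(CANONICAL_ORDER)

    def test_permutation_invariance(self):
        """A state-relabeled copy of a model averages back to the canonical
        parameters exactly."""
        m = self.canonical(seed=4)
        p = np.array([2, 0, 1])
        shuffled = StateHMM(m.means[p], m.sds[p], m.transition[np.ix_(p, p)],
                            m.initial[p], m.marks,
                            labels=[m.labels[i] for i in p], transform=m.transform)
        avg = align_and_average([m, shuffled])
        assert np.allclose(avg.means, m.means)
        assert np.allclose(avg.transition, m.transition, atol=1e-12)

    def test_elementwise_mean_of_two(self):
        a, b = self.canonical(1), self.canonical(2)
        avg = align_and_average([a, b])
        assert np.allclose(avg.means, (a.means + b.means) / 2)

    def test_mark_mismatch_rejected(self):
        a = self.canonical()
        b = self.canonical()
        b.marks = list(reversed(DEFAULT_MARKS))
        with pytest.raises(ModelError):
            align_and_average([a, b])


class TestViterbi:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = toy_model(K=3, M=2, seed=seed)
        n = int(rng.integers(2, 9))
        logB = rng.normal(0, 2, (n, 3))
        got = viterbi_path(m, logB)
        assert np.array_equal(got, brute_force_best_path(m, logB))

    def test_transition_dominant_prefers_staying(self):
        """With near-deterministic self-transitions and weak emissions the
        best path is constant in the initial-favored state."""
        A = np.array([[0.999, 0.0005, 0.0005],
                      [0.0005, 0.999, 0.0005],
                      [0.0005, 0.0005, 0.999]])
        m = StateHMM(np.zeros((3, 1)), np.ones((3, 1)), A,
                     np.array([0.98, 0.01, 0.01]), ["m0"], transform="none")
        logB = np.random.default_rng(0).normal(0, 0.01, (20, 3))
        path = viterbi_path(m, logB)
        assert np.all(path == 0)

    def test_k1_trivial(self):
        m = StateHMM(np.zeros((1, 1)), np.ones((1, 1)), np.ones((1, 1)),
                     np.ones(1), ["m0"], transform="none")
        assert np.all(viterbi_path(m, np.zeros((7, 1))) == 0)

    def test_decode_requires_labels_and_no_nan(self):
        m = toy_model(K=3, M=2, seed=0)
        X = np.abs(np.random.default_rng(1).normal(1, 1, (20, 2)))
        with pytest.raises(ModelError, match="labeled"):
            viterbi_decode(m, X)
        m.labels = list(CANONICAL_ORDER)
        bad = X.copy()
        bad[3, 0] = np.nan
        with pytest.raises(ModelError, match="missing"):
            viterbi_decode(m, bad)

    def test_decode_respects_chromosome_breaks(self):
        """The decoded path restarts at each chromosome: a strong first
        observation on the second chromosome is decoded by the initial
        distribution, not carried over from the previous chain."""
        A = np.array([[0.99, 0.01], [0.01, 0.99]])
        m = StateHMM(np.array([[0.0], [5.0]]), np.full((2, 1), 0.5), A,
                     np.array([0.5, 0.5]), ["m0"],
                     labels=["null", "active"], transform="none")
        X = np.array([[0.0]] * 5 + [[5.0]] * 5)
        joint = viterbi_decode(m, X)
        split = viterbi_decode(m, X, chroms=np.array([0] * 5 + [1] * 5))
        assert np.array_equal(split[:5], np.full(5, 1))    # null code
        assert np.array_equal(split[5:], np.full(5, 3))    # active code
        assert np.array_equal(joint, split)  # well-separated either way


class TestEndToEndRecovery:
    def test_state_recovery_on_default_dataset(self, default_dataset,
                                               common_model, decoded_states):
        """The common model decodes >= 99% of the planted true states."""
        ds = default_dataset
        agree = (decoded_states.to_numpy() == ds.true_states.to_numpy()).mean()
        assert agree >= 0.99
        assert common_model.labels == list(CANONICAL_ORDER)
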