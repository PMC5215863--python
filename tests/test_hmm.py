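import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from countseg import synthetic as syn
from countseg.emissions import EmissionGrid, NegBinomParams, PoilogParams
from countseg.hmm import (
    HMMModel,
    baum_welch,
    forward_backward,
    initialize,
    load_model,
    poisson_threshold,
    posterior_decode,
    save_model,
    viterbi,
    PosteriorMatrix,
)
from countseg.io_binning import BinnedGenome, CountMatrix


def random_model(K, D, family, rng):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    params = []
    for _ in range(K):
        row = []
        for _ in range(D):
            if family == "negbinom":
                row.append(NegBinomParams(mu=float(rng.uniform(0.2, 20)),
                                          size=float(rng.uniform(0.5, 20))))
            else:
                row.append(PoilogParams(mu_log=float(rng.uniform(-1, 3)),
                                        sigma=float(rng.uniform(0.2, 1.5))))
        params.append(row)
    tracks = tuple(f"t{d}" for d in range(D))
    return HMMModel(pi, A, EmissionGrid(family, params), tracks, 200)


def brute_force_posteriors(model, counts):
    """Exhaustive path enumeration oracle for tiny instances."""
    s = np.ones(len(model.track_names))
    logB = model.emissions.log_emission_matrix(counts.counts, s)
    T, K = logB.shape
    total = -np.inf
    log_probs = {}
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.initial_probs[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transitions[path[t - 1], path[t]]) + logB[t, path[t]]
        log_probs[path] = lp
        total = np.logaddexp(total, lp)
    gamma = np.zeros((T, K))
    for path, lp in log_probs.items():
        for t in range(T):
            gamma[t, path[t]] += np.exp(lp - total)
    best_path = max(log_probs, key=log_probs.get)
    return gamma, total, np.array(best_path), log_probs[best_path]


def _toy_counts(genome, rng, D):
    return CountMatrix(genome, rng.integers(0, 12, (genome.n_bins, D)),
                       tuple(f"t{d}" for d in range(D)))


class TestPoissonThreshold:
    @pytest.mark.parametrize("lam,expected", [(1.0, 6), (0.01, 1), (0.0, 1)])
    def test_known_values(self, lam, expected):
        assert poisson_threshold(lam) == expected

    def test_matches_brute_force_cdf_search(self):
        for lam in np.linspace(0, 12, 25):
            n = 1
            while 1 - stats.poisson.cdf(n, lam) >= 1e-4:
                n += 1
            assert poisson_threshold(lam) == n


class TestForwardBackward:
    def test_single_state_posterior_is_one(self, rng):
        model = random_model(1, 2, "negbinom", rng)
        genome = BinnedGenome(("c",), (10 * 200,), 200)
        cm = _toy_counts(genome, rng, 2)
        post = forward_backward(model, cm)
        assert np.allclose(post.gamma, 1.0)
        expected = model.emissions.log_emission_matrix(cm.counts, np.ones(2)).sum()
        assert post.log_likelihood == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family", ["negbinom", "poilog"])
    @pytest.mark.parametrize("K,T", [(2, 5), (3, 6)])
    def test_matches_exhaustive_enumeration(self, rng, family, K, T):
        model = random_model(K, 2, family, rng)
        genome = BinnedGenome(("c",), (T * 200,), 200)
        cm = _toy_counts(genome, rng, 2)
        post = forward_backward(model, cm)
        gamma_bf, ll_bf, _, _ = brute_force_posteriors(model, cm)
        assert post.log_likelihood == pytest.approx(ll_bf, abs=1e-10)
        assert np.max(np.abs(post.gamma - gamma_bf)) < 1e-10
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_label_permutation_permutes_gamma(self, rng):
        model = random_model(3, 2, "negbinom", rng)
        genome = BinnedGenome(("c",), (8 * 200,), 200)
        cm = _toy_counts(genome, rng, 2)
        perm = np.array([2, 0, 1])
        permuted = HMMModel(
            model.initial_probs[perm], model.transitions[np.ix_(perm, perm)],
            EmissionGrid("negbinom", [model.emissions.params[k] for k in perm]),
            model.track_names, model.bin_width)
        g1 = forward_backward(model, cm).gamma
        g2 = forward_backward(permuted, cm).gamma
        assert np.allclose(g2, g1[:, perm], atol=1e-12)

    def test_track_mismatch_error(self, rng):
        model = random_model(2, 2, "negbinom", rng)
        genome = BinnedGenome(("c",), (5 * 200,), 200)
        cm = CountMatrix(genome, np.zeros((5, 2), dtype=int), ("x", "y"))
        with pytest.raises(ValueError, match="track"):
            forward_backward(model, cm)


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        model = random_model(1, 1, "negbinom", rng)
        genome = BinnedGenome(("c",), (6 * 200,), 200)
        cm = _toy_counts(genome, rng, 1)
        assert np.all(viterbi(model, cm) == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(2, 2, "negbinom", rng)
        genome = BinnedGenome(("c",), (5 * 200,), 200)
        cm = _toy_counts(genome, rng, 2)
        _, _, best_path, best_score = brute_force_posteriors(model, cm)
        vp = viterbi(model, cm)
        s = np.ones(2)
        logB = model.emissions.log_emission_matrix(cm.counts, s)
        score = np.log(model.initial_probs[vp[0]]) + logB[0, vp[0]]
        for t in range(1, 5):
            score += np.log(model.transitions[vp[t - 1], vp[t]]) + logB[t, vp[t]]
        assert score == pytest.approx(best_score, abs=1e-10)

    def test_score_at_least_posterior_argmax_path(self, rng):
        model = random_model(3, 2, "negbinom", rng)
        genome = BinnedGenome(("c",), (30 * 200,), 200)
        cm = _toy_counts(genome, rng, 2)

        def path_score(p):
            logB = model.emissions.log_emission_matrix(cm.counts, np.ones(2))
            sc = np.log(model.initial_probs[p[0]]) + logB[0, p[0]]
            for t in range(1, len(p)):
                sc += np.log(model.transitions[p[t - 1], p[t]]) + logB[t, p[t]]
            return sc

        vp = viterbi(model, cm)
        pd_path = posterior_decode(forward_backward(model, cm))
        assert path_score(vp) >= path_score(pd_path) - 1e-12


class TestPosteriorDecode:
    def test_row_argmax_with_tie_to_lower_index(self):
        gamma = np.array([[0.5, 0.5], [0.2, 0.8], [0.9, 0.1]])
        post = PosteriorMatrix(gamma=gamma, log_likelihood=0.0)
        assert posterior_decode(post).tolist() == [0, 1, 0]

    def test_agrees_with_viterbi_on_sticky_model(self):
        model = syn.default_model(K=3, D=2, self_prob=0.999)
        genome = BinnedGenome(("c",), (3000 * 200,), 200)
        mats, truth = syn.simulate_hmm_counts(model, genome, seed=5)
        cm = mats["cell0"]
        vp = viterbi(model, cm)
        pd_path = posterior_decode(forward_backward(model, cm))
        assert (vp == pd_path).mean() >= 0.99


class TestInitialize:
    def test_all_zero_matrix_raises(self):
        genome = BinnedGenome(("c",), (100 * 200,), 200)
        cm = CountMatrix(genome, np.zeros((100, 2), dtype=int), ("a", "b"))
        with pytest.raises(ValueError, match="insufficient signal"):
            initialize(cm, 3, seed=0)

    def test_uniform_pi_and_transitions(self, simulated):
        model = initialize(simulated["counts"], 3, seed=0)
        assert np.allclose(model.initial_probs, 1 / 3)
        assert np.allclose(model.transitions, 1 / 3)

    def test_recovers_planted_cluster_means(self):
        truth_model = syn.default_model(K=3, D=2)
        genome = BinnedGenome(("c",), (5000 * 200,), 200)
        mats, truth = syn.simulate_hmm_counts(truth_model, genome, seed=13)
        init = initialize(mats["cell0"], 3, seed=0)
        tm = truth_model.emissions.means()
        im = init.emissions.means()
        # match signal states by best permutation of the non-background rows
        cost = np.array([[np.abs(im[i] - tm[j]).sum() for j in (1, 2)]
                         for i in (1, 2)])
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            signal_track = np.argmax(tm[j + 1])
            assert im[i + 1][signal_track] == pytest.approx(
                tm[j + 1][signal_track], rel=0.10)


class TestBaumWelch:
    @pytest.mark.parametrize("family", ["negbinom", "poilog"])
    @pytest.mark.parametrize("seed", [0, 3])
    def test_loglik_nondecreasing_from_random_init(self, family, seed):
        rng = np.random.default_rng(seed)
        data_model = syn.default_model(K=3, D=2, family=family)
        genome = BinnedGenome(("c",), (400 * 200,), 200)
        mats, _ = syn.simulate_hmm_counts(data_model, genome, seed=seed)
        init = random_model(3, 2, family, rng)
        init = HMMModel(init.initial_probs, init.transitions, init.emissions,
                        data_model.track_names, 200)
        _, trace = baum_welch(init, mats["cell0"], max_iter=15, tol=0.0)
        diffs = np.diff(trace.log_likelihoods)
        assert np.all(diffs >= -1e-6)

    def test_label_permutation_equivariance(self, simulated):
        cm = simulated["counts"]
        init = initialize(cm, 3, seed=0)
        perm = np.array([1, 2, 0])
        init_p = HMMModel(
            init.initial_probs[perm], init.transitions[np.ix_(perm, perm)],
            EmissionGrid(init.family, [init.emissions.params[k] for k in perm]),
            init.track_names, init.bin_width)
        fit1, _ = baum_welch(init, cm, max_iter=5, tol=0.0)
        fit2, _ = baum_welch(init_p, cm, max_iter=5, tol=0.0)
        m1, m2 = fit1.emissions.means(), fit2.emissions.means()
        assert np.allclose(m2, m1[perm], rtol=1e-6)
        assert np.allclose(fit2.transitions, fit1.transitions[np.ix_(perm, perm)],
                           atol=1e-8)

    def test_multi_sequence_pooling(self, nb_model):
        genome = BinnedGenome(("c",), (2000 * 200,), 200)
        mats, _ = syn.simulate_hmm_counts(nb_model, genome,
                                          {"a": 1.0, "b": 1.0}, seed=21)
        init = initialize([mats["a"], mats["b"]], 3, seed=0)
        fit, trace = baum_welch(init, [mats["a"], mats["b"]], max_iter=30)
        assert np.all(np.diff(trace.log_likelihoods) >= -1e-6)
        m = np.sort(fit.emissions.means().sum(axis=1))
        t = np.sort(nb_model.emissions.means().sum(axis=1))
        assert np.allclose(m, t, rtol=0.15)


class TestModelFile:
    @pytest.mark.parametrize("family", ["negbinom", "poilog"])
    def test_roundtrip_identity(self, tmp_path, rng, family):
        model = random_model(3, 2, family, rng)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.array_equal(back.initial_probs, model.initial_probs)
        assert np.array_equal(back.transitions, model.transitions)
        assert back.emissions.params == model.emissions.params
        assert back.track_names == model.track_names

    def test_version_checked(self, tmp_path, rng):
        model = random_model(2, 1, "negbinom", rng)
        save_model(model, tmp_path / "m.json")
        text = (tmp_path / "m.json").read_text().replace('"version": 1',
                                                         '"version": 99')
        (tmp_path / "m.json").write_text(text)
        with pytest.raises(ValueError, match="version"):
            load_model(tmp_path / "m.json")

    def test_corrupted_file_error(self, tmp_path):
        (tmp_path / "m.json").write_text("{not json")
        with pytest.raises(ValueError, match="corrupted"):
            load_model(tmp_path / "m.json")
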