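"""HMM engine correctness: exact-oracle equivalence, EM properties, model
selection, rate conversion, populations, profile-likelihood errors."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import norm

import fretkin.hmm_kinetics as hk
from fretkin.hmm_kinetics import (
    HmmParams,
    HmmSpec,
    compute_bic,
    degenerate_three_state_spec,
    forward_loglik,
    likelihood_ratio_errors,
    pooled_emissions,
    select_model,
    state_population_kd,
    train_global_hmm,
    train_trace_hmm,
    transition_to_rates,
    two_state_spec,
    viterbi_path,
)
from fretkin.synthetic_traces import EmissionModel, simulate_ensemble


def brute_force_loglik(x, params):
    """Enumerate all hidden paths; exact likelihood for tiny traces."""
    spec = params.spec
    comp = list(spec.emission_map)
    total = 0.0
    for path in itertools.product(range(spec.n_states), repeat=len(x)):
        p = params.startprob[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= params.transmat[a, b]
        for t, s in enumerate(path):
            p *= norm.pdf(x[t], params.means[comp[s]], params.sds[comp[s]])
        total += p
    return np.log(total)


def brute_force_viterbi(x, params):
    spec = params.spec
    comp = list(spec.emission_map)
    best, best_path = -np.inf, None
    for path in itertools.product(range(spec.n_states), repeat=len(x)):
        logp = np.log(params.startprob[path[0]] + 1e-300)
        for a, b in zip(path[:-1], path[1:]):
            logp += np.log(params.transmat[a, b] + 1e-300)
        for t, s in enumerate(path):
            logp += norm.logpdf(x[t], params.means[comp[s]], params.sds[comp[s]])
        if logp > best + 1e-12:
            best, best_path = logp, path
    return best, np.array(best_path)


def _random_params(spec, seed):
    rng = np.random.default_rng(seed)
    A = np.where(spec.adjacency, rng.uniform(0.05, 1.0, (spec.n_states,) * 2), 0.0)
    A /= A.sum(axis=1, keepdims=True)
    start = rng.uniform(0.1, 1.0, spec.n_states)
    start /= start.sum()
    means = np.linspace(0.0, 0.75, spec.n_components)
    sds = np.full(spec.n_components, 0.15)
    return HmmParams(startprob=start, transmat=A, means=means, sds=sds, spec=spec)


class TestForwardAlgorithm:
    @pytest.mark.parametrize("spec_fn, seed", [
        (two_state_spec, 0), (two_state_spec, 1),
        (degenerate_three_state_spec, 2), (degenerate_three_state_spec, 3),
    ])
    def test_matches_brute_force_enumeration(self, spec_fn, seed):
        spec = spec_fn()
        params = _random_params(spec, seed)
        rng = np.random.default_rng(seed + 100)
        x = rng.uniform(-0.2, 1.0, 7)
        assert forward_loglik(x, params) == pytest.approx(
            brute_force_loglik(x, params), abs=1e-10
        )

    def test_matches_hmmlearn_score(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        spec = degenerate_three_state_spec()
        params = _random_params(spec, 5)
        rng = np.random.default_rng(6)
        x = rng.uniform(-0.2, 1.0, 200)
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                     init_params="")
        model.startprob_ = params.startprob
        model.transmat_ = params.transmat
        comp = list(spec.emission_map)
        model.means_ = params.means[comp].reshape(-1, 1)
        model.covars_ = (params.sds[comp] ** 2).reshape(-1, 1)
        assert forward_loglik(x, params) == pytest.approx(
            model.score(x.reshape(-1, 1)), abs=1e-6
        )


class TestViterbi:
    def test_matches_brute_force_on_short_traces(self):
        for seed in range(4):
            spec = degenerate_three_state_spec()
            params = _random_params(spec, seed + 20)
            rng = np.random.default_rng(seed)
            x = rng.uniform(-0.2, 1.0, 6)
            best_logp, best_path = brute_force_viterbi(x, params)
            path = viterbi_path(x, params)
            # compare path scores (degenerate emissions allow score ties)
            logp = np.log(params.startprob[path[0]])
            comp = list(spec.emission_map)
            for a, b in zip(path[:-1], path[1:]):
                logp += np.log(params.transmat[a, b])
            for t, s in enumerate(path):
                logp += norm.logpdf(x[t], params.means[comp[s]],
                                    params.sds[comp[s]])
            assert logp == pytest.approx(best_logp, abs=1e-9)

    def test_noiseless_trace_decoded_exactly(self, noiseless_two_state_ensemble):
        traces, _ = noiseless_two_state_ensemble
        tr = traces[0]
        spec = two_state_spec()
        params = HmmParams(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.99, 0.01], [0.02, 0.98]]),
            means=np.array([0.0, 0.75]), sds=np.array([0.02, 0.02]), spec=spec,
        )
        # restrict to frames without camera-blur (pure-level frames)
        pure = np.isin(tr.fret, [0.0, 0.75])
        path = viterbi_path(tr.fret[pure], params)
        np.testing.assert_array_equal(path, (tr.truth_state[pure] > 0).astype(int))

    def test_zero_frames_never_assigned_bound_state(self):
        spec = degenerate_three_state_spec()
        params = _random_params(spec, 9)
        params.means = np.array([0.0, 0.75])
        params.sds = np.array([0.05, 0.05])
        x = np.zeros(20)
        path = viterbi_path(x, params)
        assert np.all(path == 0)


class TestTraining:
    def test_noiseless_trace_count_mle_oracle(self):
        # closed-form MLE on a noiseless two-level trace: emission means are
        # the two levels; A entries are empirical transition frequencies
        rng = np.random.default_rng(3)
        seq = (rng.random(2000) < 0.3).astype(int)
        x = np.where(seq == 1, 0.75, 0.0) + rng.normal(0, 1e-9, 2000)
        params = train_trace_hmm(x, two_state_spec(), seed=0, n_restarts=1)
        order = np.argsort(params.means)
        np.testing.assert_allclose(params.means[order], [0.0, 0.75], atol=1e-6)
        counts = np.zeros((2, 2))
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
        A_mle = counts / counts.sum(axis=1, keepdims=True)
        A = params.transmat[np.ix_(order, order)]
        np.testing.assert_allclose(A, A_mle, atol=1e-3)

    def test_single_state_spec(self):
        spec = HmmSpec(1, np.ones((1, 1), bool), (0,))
        rng = np.random.default_rng(1)
        x = rng.normal(0.4, 0.1, 500)
        params = train_trace_hmm(x, spec, seed=0, n_restarts=1)
        assert params.transmat[0, 0] == pytest.approx(1.0)
        assert params.means[0] == pytest.approx(x.mean(), abs=1e-6)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 300)
        spec = two_state_spec()
        params = _random_params(spec, 11)
        obs = [x]
        groups = hk._group_by_length(obs)
        lls = []
        for _ in range(25):
            ll, sc, xi, emis = hk._e_step(groups, params)
            lls.append(ll)
            params = hk._m_step(params, sc, xi, emis, learn_emissions=True)
        assert np.all(np.diff(lls) > -1e-8)

    def test_global_fit_on_identical_traces_matches_per_trace(self):
        rng = np.random.default_rng(5)
        seq = (rng.random(1000) < 0.4).astype(int)
        x = np.where(seq == 1, 0.75, 0.0) + rng.normal(0, 0.08, 1000)
        emis = (np.array([0.0, 0.75]), np.array([0.08, 0.08]))
        single = train_trace_hmm(x, two_state_spec(), seed=0, n_restarts=1,
                                 learn_emissions=False,
                                 init=HmmParams(
                                     startprob=np.array([0.5, 0.5]),
                                     transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
                                     means=emis[0], sds=emis[1],
                                     spec=two_state_spec()))
        glob = train_global_hmm([x, x, x], two_state_spec(), emis, seed=0,
                                n_restarts=1)
        np.testing.assert_allclose(glob.transmat, single.transmat, atol=2e-3)

    def test_trace_order_invariance(self, noisy_two_state_ensemble):
        traces, _ = noisy_two_state_ensemble
        sub = traces[:10]
        emis = (np.array([0.0, 0.75]), np.array([0.1, 0.1]))
        a = train_global_hmm(sub, two_state_spec(), emis, seed=0, n_restarts=1)
        b = train_global_hmm(sub[::-1], two_state_spec(), emis, seed=0,
                             n_restarts=1)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-6)
        np.testing.assert_allclose(a.transmat, b.transmat, atol=1e-8)

    def test_degenerate_label_permutation_leaves_likelihood_unchanged(
        self, noisy_three_state_ensemble
    ):
        traces, _ = noisy_three_state_ensemble
        x = traces[0].fret
        spec = degenerate_three_state_spec()
        params = _random_params(spec, 30)
        params.means = np.array([0.0, 0.75])
        params.sds = np.array([0.1, 0.1])
        # swapping the two bound states (with matching rate swap) must not
        # change the likelihood when the topology permits it; here we use a
        # fully connected bound pair to make the swap exact
        full = HmmSpec(3, np.ones((3, 3), bool), (0, 1, 1))
        p_full = _random_params(full, 31)
        p_full.means = np.array([0.0, 0.75])
        p_full.sds = np.array([0.1, 0.1])
        perm = [0, 2, 1]
        swapped = HmmParams(
            startprob=p_full.startprob[perm],
            transmat=p_full.transmat[np.ix_(perm, perm)],
            means=p_full.means, sds=p_full.sds, spec=full,
        )
        assert forward_loglik(x, p_full) == pytest.approx(
            forward_loglik(x, swapped), abs=1e-8
        )


class TestBicAndSelection:
    def test_bic_arithmetic(self):
        assert compute_bic(0.0, 0, 100) == 0.0
        n = 1234
        assert compute_bic(-10.0, 3, n) - compute_bic(-10.0, 2, n) == pytest.approx(
            np.log(n)
        )

    def test_true_model_order_selected_both_ways(
        self, noisy_two_state_ensemble, noisy_three_state_ensemble
    ):
        specs = [two_state_spec(), degenerate_three_state_spec()]
        emis = (np.array([0.0, 0.75]), np.array([0.1, 0.1]))
        two, _ = noisy_two_state_ensemble
        ranked2 = select_model(two[:40], specs,
                               fixed_emissions_by_spec=[emis, emis], seed=0,
                               n_restarts=2)
        assert ranked2[0]["spec"].name == "two-state"
        three, _ = noisy_three_state_ensemble
        ranked3 = select_model(three, specs,
                               fixed_emissions_by_spec=[emis, emis], seed=0,
                               n_restarts=2)
        assert ranked3[0]["spec"].name == "sequential-3-state-degenerate"

    def test_identical_specs_identical_bic(self, noisy_two_state_ensemble):
        traces, _ = noisy_two_state_ensemble
        emis = (np.array([0.0, 0.75]), np.array([0.1, 0.1]))
        ranked = select_model(traces[:8], [two_state_spec(), two_state_spec()],
                              fixed_emissions_by_spec=[emis, emis], seed=0,
                              n_restarts=1)
        assert ranked[0]["bic"] == pytest.approx(ranked[1]["bic"], abs=1e-6)


class TestRateConversion:
    def test_linear_arithmetic(self):
        A = np.array([[1 - 0.00592, 0.00592], [0.0102, 1 - 0.0102]])
        K = transition_to_rates(A, 0.2)
        assert K[0, 1] == pytest.approx(2.96e-2)

    def test_identity_matrix_gives_zero_rates(self):
        K = transition_to_rates(np.eye(3), 0.1)
        np.testing.assert_allclose(K, 0.0)

    def test_logm_round_trip(self):
        K_true = np.array([[-0.03, 0.03], [0.05, -0.05]])
        A = expm(K_true * 0.2)
        K = transition_to_rates(A, 0.2, method="logm")
        np.testing.assert_allclose(K, K_true, atol=1e-10)

    def test_warns_on_large_step_probability(self):
        A = np.array([[0.8, 0.2], [0.1, 0.9]])
        with pytest.warns(UserWarning, match="linear"):
            transition_to_rates(A, 0.2)


class TestPopulations:
    def test_equal_populations_give_ligand_concentration(self):
        spec = two_state_spec()
        params = HmmParams(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            means=np.array([0.0, 0.75]), sds=np.array([0.1, 0.1]), spec=spec,
        )
        pops, kd = state_population_kd(params, 35.0)
        np.testing.assert_allclose(pops, [0.5, 0.5])
        assert kd == pytest.approx(35.0)

    def test_two_state_kd_near_rate_ratio(self, noisy_two_state_ensemble):
        traces, _ = noisy_two_state_ensemble
        emis = (np.array([0.0, 0.75]), np.array([0.1, 0.1]))
        params = train_global_hmm(traces, two_state_spec(), emis, seed=0,
                                  n_restarts=1)
        _, kd = state_population_kd(params, 35.0)
        expected = 35.0 * 0.051 / 0.0296  # c * k_off / k'_on ~ 60 nM
        assert kd == pytest.approx(expected, rel=0.15)

    def test_populations_aggregate_degenerate_states(self):
        spec = degenerate_three_state_spec()
        A = np.array([[0.9, 0.1, 0.0], [0.05, 0.85, 0.1], [0.0, 0.1, 0.9]])
        params = HmmParams(
            startprob=np.full(3, 1 / 3), transmat=A,
            means=np.array([0.0, 0.75]), sds=np.array([0.1, 0.1]), spec=spec,
        )
        pops, kd = state_population_kd(params, 35.0)
        assert kd == pytest.approx(pops[0] * 35.0 / (pops[1] + pops[2]))


@pytest.fixture(scope="module")
def clean_fit():
    rng = np.random.default_rng(12)
    A_true = np.array([[0.97, 0.03], [0.06, 0.94]])
    traces = []
    seqs = []
    for _ in range(15):
        s = np.empty(400, int)
        s[0] = rng.integers(2)
        for t in range(1, 400):
            s[t] = rng.random() < A_true[s[t - 1], 1]
        seqs.append(s)
        traces.append(np.where(s == 1, 0.75, 0.0) + rng.normal(0, 0.05, 400))
    emis = (np.array([0.0, 0.75]), np.array([0.05, 0.05]))
    params = train_global_hmm(traces, two_state_spec(), emis, seed=0,
                              n_restarts=1)
    return traces, seqs, params


class TestLikelihoodRatioErrors:
    def test_one_sigma_interval_matches_binomial_curvature(self, clean_fit):
        # with near-noiseless emissions the A01 profile is a binomial
        # likelihood: sd ~ sqrt(p(1-p)/n0)
        traces, seqs, params = clean_fit
        res = likelihood_ratio_errors(traces, params, (0, 1))
        p = params.transmat[0, 1]
        n0 = sum(np.sum(s[:-1] == 0) for s in seqs)
        sd = np.sqrt(p * (1 - p) / n0)
        assert res["lower"] < p < res["upper"]
        assert (res["upper"] - res["lower"]) / 2 == pytest.approx(sd, rel=0.25)

    def test_vanishing_confidence_collapses_interval(self, clean_fit):
        traces, _, params = clean_fit
        res = likelihood_ratio_errors(traces, params, (0, 1), confidence=0.0)
        assert res["lower"] == res["upper"] == params.transmat[0, 1]

    def test_interval_shrinks_with_ensemble_size(self, clean_fit):
        traces, _, params = clean_fit
        res_small = likelihood_ratio_errors(traces[:5], params, (0, 1))
        res_full = likelihood_ratio_errors(traces, params, (0, 1))
        w_small = res_small["upper"] - res_small["lower"]
        w_full = res_full["upper"] - res_full["lower"]
        assert w_full < w_small
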