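import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from hmmc.hmm_core import (
    DEFAULT_STATES,
    HMMParams,
    cluster_delta,
    discretize_to_states,
    emission_logdensity,
    estimate_emission_sd,
    estimate_transition_probs,
    sample_emission_cube,
    viterbi_joint,
)

from conftest import make_matrix


def brute_force_delta(emis, params, chain_starts):
    """Enumerate all K^T state paths; reference for the Viterbi recursion."""
    T, K = emis.shape
    ls, ld = math.log(params.p_same), math.log(params.p_diff)
    li = np.log(params.initial)
    starts = list(chain_starts) + [T]
    total = 0.0
    for a, b in zip(starts[:-1], starts[1:]):
        best = -np.inf
        for path in itertools.product(range(K), repeat=b - a):
            lp = li[path[0]] + emis[a, path[0]]
            for i in range(1, b - a):
                lp += (ls if path[i] == path[i - 1] else ld) + emis[a + i, path[i]]
            best = max(best, lp)
        total += best
    return total


class TestParams:
    def test_transition_normalization(self):
        p = HMMParams(p_same=0.56, sigma=0.3)
        assert p.p_same + (p.K - 1) * p.p_diff == pytest.approx(1.0, abs=1e-12)
        assert p.transition_matrix().sum(axis=1) == pytest.approx(np.ones(6))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_same": 0.0, "sigma": 0.3},
            {"p_same": 0.5, "sigma": 0.0},
            {"p_same": 0.5, "sigma": 0.3, "states": [2.0, 1.0]},
            {"p_same": 0.5, "sigma": 0.3, "initial": [1.0, 0, 0, 0, 0, 0.5]},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HMMParams(**kwargs)


class TestEmission:
    def test_zero_exponent_at_state_value(self):
        sigma = 0.37
        expected = -math.log(2) - math.log(sigma) - 0.5 * math.log(2 * math.pi)
        assert emission_logdensity(2.0, 2.0, sigma) == pytest.approx(expected)

    def test_closed_form_one_log_unit_away(self):
        # y=4 vs state 2 with sigma=ln2: exponent term is exactly 1/2
        sigma = math.log(2)
        expected = (
            -math.log(4) - math.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5
        )
        assert emission_logdensity(4.0, 2.0, sigma) == pytest.approx(expected)

    @pytest.mark.parametrize("state,sigma", [(2.0, 0.3), (0.1, 0.5), (5.0, 1.2)])
    def test_density_integrates_to_one(self, state, sigma):
        val, _ = quad(
            lambda y: math.exp(emission_logdensity(y, state, sigma)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(ValueError):
            emission_logdensity(0.0, 2.0, 0.3)


class TestEmissionSdEstimate:
    def test_degenerate_spread_hits_floor(self, flat_matrix):
        assert estimate_emission_sd(flat_matrix) == pytest.approx(0.05)

    def test_hand_value_one_log_unit_apart(self):
        m = make_matrix([[2.0, 2.0], [2.0 * math.e, 2.0 * math.e]])
        assert estimate_emission_sd(m) == pytest.approx(1 / math.sqrt(2))

    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.5, 5.0, size=(5, 8))
        a = estimate_emission_sd(make_matrix(vals))
        b = estimate_emission_sd(make_matrix(vals * 3.7))
        assert a == pytest.approx(b)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError, match="sigma"):
            estimate_emission_sd(make_matrix([[2.0, 3.0]]))


class TestTransitionEstimate:
    def test_printed_pair_identity(self):
        # p_same = 0.56 with 6 states implies p_diff = 0.088 exactly
        p = HMMParams(p_same=0.56, sigma=0.3)
        assert p.p_diff == pytest.approx((1 - 0.56) / 5)
        assert p.p_diff == pytest.approx(0.088)

    def test_constant_matrix_smoothed_below_one(self, flat_matrix):
        p_same, p_diff = estimate_transition_probs(flat_matrix)
        n_pairs = 4 * 5  # 4 samples x 5 adjacent pairs
        assert p_same == pytest.approx((n_pairs + 1) / (n_pairs + 2))
        assert 0 < p_diff < 1

    def test_alternating_states_near_zero(self):
        m = make_matrix(np.tile([2.0, 4.0], (3, 4))[:, :8])
        p_same, p_diff = estimate_transition_probs(m)
        n_pairs = 3 * 7
        assert p_same == pytest.approx(1 / (n_pairs + 2))
        assert p_same + 5 * p_diff == pytest.approx(1.0)

    def test_chromosome_boundaries_not_counted(self):
        # 2 on chr1, 4 on chr2: the cross-chromosome pair must not count
        m = make_matrix([[2.0, 4.0], [2.0, 4.0]], chroms=("1", "2"))
        p_same, _ = estimate_transition_probs(m)
        assert p_same == pytest.approx(0.5)  # only smoothing pseudo-counts

    def test_discretization_ties_go_to_lower_state(self):
        # 2.5, 0.8 and 1.75 sit exactly between neighbouring states
        idx = discretize_to_states([2.5, 2.4999, 2.5001, 0.8, 1.75])
        assert list(idx) == [2, 2, 3, 0, 1]


class TestClusterDelta:
    def test_single_step_closed_form(self):
        m = make_matrix([[2.0]])
        params = HMMParams(p_same=0.56, sigma=0.3)
        fit = cluster_delta(m, [0], params)
        expected = (
            math.log(1 / 6)
            - math.log(2)
            - math.log(0.3)
            - 0.5 * math.log(2 * math.pi)
        )
        assert fit.delta == pytest.approx(expected)
        assert fit.path[0] == 2  # state value 2 maximizes the emission

    def test_member_order_invariance(self, rng):
        m = make_matrix(rng.uniform(0.5, 5.0, size=(4, 10)))
        params = HMMParams(p_same=0.6, sigma=0.4)
        a = cluster_delta(m, [0, 1, 3], params)
        b = cluster_delta(m, [3, 0, 1], params)
        assert a.delta == pytest.approx(b.delta)
        assert np.array_equal(a.path, b.path)

    def test_duplicating_samples_doubles_emission_part(self, rng):
        vals = rng.uniform(1.0, 4.0, size=(2, 6))
        params = HMMParams(p_same=0.6, sigma=0.4)
        m1 = make_matrix(vals)
        m2 = make_matrix(np.vstack([vals, vals]))
        f1 = cluster_delta(m1, [0, 1], params)
        f2 = cluster_delta(m2, [0, 1, 2, 3], params)
        # same decoded path; transition+initial part unchanged, emission doubled
        assert np.array_equal(f1.path, f2.path)
        emis = sample_emission_cube(vals, params).sum(axis=0)
        em1 = emis[np.arange(6), f1.path].sum()
        assert f2.delta == pytest.approx(f1.delta + em1)

    def test_small_sigma_recovers_planted_states(self):
        states = np.asarray(DEFAULT_STATES)
        path_truth = [2, 2, 4, 4, 2, 1]
        vals = np.tile(states[path_truth], (3, 1))
        m = make_matrix(vals)
        fit = cluster_delta(m, [0, 1, 2], HMMParams(p_same=0.56, sigma=0.05))
        assert list(fit.path) == path_truth

    def test_empty_member_set_rejected(self, flat_matrix):
        with pytest.raises(ValueError):
            cluster_delta(flat_matrix, [], HMMParams(p_same=0.5, sigma=0.3))

    def test_matches_hmmlearn_single_sample(self, rng):
        # independent cross-check: a 1-sample cluster is a plain lognormal
        # HMM, equivalent to a Gaussian HMM on log observations up to the
        # Jacobian sum(log y)
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = HMMParams(p_same=0.56, sigma=0.35)
        y = rng.uniform(0.5, 5.0, size=12)
        model = hmmlearn.GaussianHMM(
            n_components=6, covariance_type="diag", init_params=""
        )
        model.startprob_ = params.initial
        model.transmat_ = params.transition_matrix()
        model.means_ = np.log(params.states)[:, None]
        model.covars_ = np.full((6, 1), params.sigma**2)
        logprob, ref_path = model.decode(np.log(y)[:, None], algorithm="viterbi")
        fit = cluster_delta(make_matrix(y[None, :]), [0], params)
        assert fit.delta == pytest.approx(logprob - np.log(y).sum())
        assert np.array_equal(fit.path, ref_path)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_viterbi_equals_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    T = int(rng.integers(1, 6))
    nsamp = int(rng.integers(1, 4))
    params = HMMParams(
        p_same=float(rng.uniform(0.05, 0.95)), sigma=float(rng.uniform(0.1, 1.5))
    )
    vals = rng.uniform(0.1, 6.0, size=(nsamp, T))
    emis = sample_emission_cube(vals, params).sum(axis=0)
    # occasionally split into two chromosome chains
    chain_starts = np.array([0]) if T < 3 or seed % 3 else np.array([0, T // 2])
    fit = viterbi_joint(emis, params, chain_starts)
    assert fit.delta == pytest.approx(
        brute_force_delta(emis, params, chain_starts), abs=1e-9
    )
    assert len(fit.path) == T
    assert np.isfinite(fit.delta)
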