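"""The per-cluster hidden Markov model and its Viterbi log-likelihood.

Each cluster of tumour samples is modelled by a single HMM over the common
segment grid.  The hidden state x(t) is the true copy number of segment t,
drawn from a small alphabet of copy-number levels (default
0.1, 1.5, 2, 3, 4, 5 — homozygous deletion through high amplification).
Transitions are exchangeable: a single probability ``p_same`` of staying in
the same state between adjacent segments, with the remaining mass shared
uniformly over the other states.  Every member sample of the cluster emits
its observed mean copy number y_j(t) from the shared hidden state through a
lognormal density whose underlying normal has mean ln(state value) and
standard deviation sigma (so the state value is the median copy number).

The cluster's delta value is the Viterbi (maximum-path) log-probability of
the shared chain given all member samples' observations; chromosome
boundaries restart the chain from the initial distribution.  Both transition
and emission parameters are estimated empirically from the data once, not
re-fit per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .segio import CopyNumberMatrix

DEFAULT_STATES = (0.1, 1.5, 2.0, 3.0, 4.0, 5.0)

#: lower bound on the emission sd; keeps the model proper on degenerate data
SIGMA_FLOOR = 0.05

_LOG_2PI = math.log(2.0 * math.pi)


def _uniform(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


@dataclass(frozen=True, eq=False)
class HMMParams:
    """Parameters of the cluster HMM.

    Parameters
    ----------
    p_same:
        Probability of remaining in the same hidden state between adjacent
        segments within a chromosome.
    sigma:
        Standard deviation of the log-scale normal emission.
    states:
        Ordered hidden copy-number values (strictly increasing, positive).
    initial:
        Initial state distribution; uniform when omitted.
    """

    p_same: float
    sigma: float
    states: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_STATES))
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.float64)
        if states.ndim != 1 or len(states) < 2:
            raise ValueError("states must be a vector of at least 2 values")
        if np.any(states <= 0) or np.any(np.diff(states) <= 0):
            raise ValueError("states must be strictly increasing and positive")
        object.__setattr__(self, "states", states)
        if not 0.0 < self.p_same < 1.0:
            raise ValueError(f"p_same must lie in (0, 1), got {self.p_same}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        initial = _uniform(len(states)) if self.initial is None else np.asarray(
            self.initial, dtype=np.float64
        )
        if len(initial) != len(states) or abs(initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial must be a probability vector over the states")
        object.__setattr__(self, "initial", initial)

    @property
    def K(self) -> int:
        return len(self.states)

    @property
    def p_diff(self) -> float:
        """Off-diagonal transition probability, (1 - p_same)/(K - 1)."""
        return (1.0 - self.p_same) / (self.K - 1)

    def transition_matrix(self) -> np.ndarray:
        A = np.full((self.K, self.K), self.p_diff)
        np.fill_diagonal(A, self.p_same)
        return A

    def to_dict(self) -> dict:
        return {
            "states": self.states.tolist(),
            "p_same": self.p_same,
            "p_diff": self.p_diff,
            "sigma": self.sigma,
            "initial": self.initial.tolist(),
        }


@dataclass(frozen=True, eq=False)
class ViterbiFit:
    """Best decoded state path and its total log-probability (delta)."""

    path: np.ndarray
    delta: float


def emission_logdensity(y, state_value, sigma):
    """Log lognormal density of observation(s) y given a hidden state value.

    The underlying normal has mean ln(state_value) and sd sigma, i.e. the
    state value is the median of the emission distribution:

        log f(y) = -ln y - ln sigma - 0.5 ln(2 pi)
                   - (ln y - ln state_value)^2 / (2 sigma^2)
    """
    y = np.asarray(y, dtype=np.float64)
    if np.any(y <= 0):
        raise ValueError("observations must be positive linear copy numbers")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ly = np.log(y)
    z = ly - math.log(state_value)
    out = -ly - math.log(sigma) - 0.5 * _LOG_2PI - z * z / (2.0 * sigma * sigma)
    return float(out) if out.ndim == 0 else out


def estimate_emission_sd(m: CopyNumberMatrix, floor: float = SIGMA_FLOOR) -> float:
    """Mean across segments of the cross-sample sd of log copy number.

    Multiplicative scale changes of the data leave the estimate unchanged.
    """
    if m.n < 2:
        raise ValueError(
            "at least 2 samples are required to estimate sigma; "
            "pass an explicit value instead"
        )
    sds = np.std(np.log(m.values), axis=0, ddof=1)
    return max(float(sds.mean()), floor)


def discretize_to_states(values, states=None) -> np.ndarray:
    """Map copy numbers to the index of the nearest state (ties to lower)."""
    states = np.asarray(DEFAULT_STATES if states is None else states, dtype=np.float64)
    midpoints = (states[:-1] + states[1:]) / 2.0
    # side='left': a value exactly on a midpoint maps to the lower state
    return np.searchsorted(midpoints, np.asarray(values, dtype=np.float64), side="left")


def estimate_transition_probs(
    m: CopyNumberMatrix, states=None
) -> tuple[float, float]:
    """Estimate (p_same, p_diff) from discretized adjacent-segment pairs.

    Cells are snapped to the nearest state; same-state vs different-state
    transitions are counted over all samples and all adjacent segment pairs
    within a chromosome, with add-one smoothing per category.
    """
    if m.T < 2:
        raise ValueError("at least 2 segments are required to estimate transitions")
    states = np.asarray(DEFAULT_STATES if states is None else states, dtype=np.float64)
    idx = discretize_to_states(m.values, states)
    bounds = m.grid.chain_starts
    same = 0
    diff = 0
    starts = list(bounds) + [m.T]
    for a, b in zip(starts[:-1], starts[1:]):
        if b - a < 2:
            continue
        eq = idx[:, a + 1 : b] == idx[:, a : b - 1]
        same += int(eq.sum())
        diff += int(eq.size - eq.sum())
    p_same = (same + 1.0) / (same + diff + 2.0)
    p_diff = (1.0 - p_same) / (len(states) - 1)
    return p_same, p_diff


def sample_emission_cube(values: np.ndarray, params: HMMParams) -> np.ndarray:
    """Per-sample emission log-densities, shape (n, T, K)."""
    if np.any(values <= 0):
        raise ValueError("observations must be positive linear copy numbers")
    ly = np.log(values)[:, :, None]
    ls = np.log(params.states)[None, None, :]
    s2 = params.sigma * params.sigma
    return (
        -ly
        - math.log(params.sigma)
        - 0.5 * _LOG_2PI
        - (ly - ls) ** 2 / (2.0 * s2)
    )


@njit(cache=False)
def _viterbi_kernel(emis, log_same, log_diff, log_init, chain_starts):
    # emis: (T, K) joint emission log-density; chain_starts: sorted, starts at 0.
    # Exchangeable transitions allow an O(K) inner update via max / runner-up.
    T, K = emis.shape
    bp = np.zeros((T, K), dtype=np.int64)
    path = np.empty(T, dtype=np.int64)
    delta = np.empty(K, dtype=np.float64)
    newd = np.empty(K, dtype=np.float64)
    total = 0.0
    nchains = chain_starts.shape[0]
    for c in range(nchains):
        a = chain_starts[c]
        b = chain_starts[c + 1] if c + 1 < nchains else T
        for k in range(K):
            delta[k] = log_init[k] + emis[a, k]
        for t in range(a + 1, b):
            m1 = -np.inf
            m2 = -np.inf
            a1 = 0
            a2 = 0
            for k in range(K):
                if delta[k] > m1:
                    m2 = m1
                    a2 = a1
                    m1 = delta[k]
                    a1 = k
                elif delta[k] > m2:
                    m2 = delta[k]
                    a2 = k
            for k in range(K):
                stay = delta[k] + log_same
                if k != a1:
                    off = m1 + log_diff
                    ko = a1
                else:
                    off = m2 + log_diff
                    ko = a2
                if stay >= off:
                    newd[k] = stay + emis[t, k]
                    bp[t, k] = k
                else:
                    newd[k] = off + emis[t, k]
                    bp[t, k] = ko
            for k in range(K):
                delta[k] = newd[k]
        best = 0
        for k in range(1, K):
            if delta[k] > delta[best]:
                best = k
        total += delta[best]
        path[b - 1] = best
        for t in range(b - 1, a, -1):
            path[t - 1] = bp[t, path[t]]
    return total, path


def viterbi_joint(
    emis: np.ndarray, params: HMMParams, chain_starts: np.ndarray
) -> ViterbiFit:
    """Viterbi decode a (T, K) joint emission log-density array."""
    total, path = _viterbi_kernel(
        np.ascontiguousarray(emis, dtype=np.float64),
        math.log(params.p_same),
        math.log(params.p_diff),
        np.log(params.initial),
        np.asarray(chain_starts, dtype=np.int64),
    )
    return ViterbiFit(path=path, delta=float(total))


def cluster_delta(
    m: CopyNumberMatrix, member_rows: Sequence[int], params: HMMParams
) -> ViterbiFit:
    """Delta value of a cluster: Viterbi log-probability of the shared chain.

    The joint emission log-density at segment t in state k is the sum over
    member samples of their individual lognormal log-densities; the decoded
    path is the cluster's consensus copy-number profile.
    """
    rows = sorted(set(int(r) for r in member_rows))
    if not rows:
        raise ValueError("member_rows must be non-empty")
    cube = sample_emission_cube(m.values[rows], params)
    return viterbi_joint(cube.sum(axis=0), params, m.grid.chain_starts)
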