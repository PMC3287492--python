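"""Stochastic label search maximizing the summed cluster delta values.

Starting from a seed assignment (usually NMF), the search repeatedly picks
two random samples, re-draws their group labels uniformly, and accepts the
proposal iff the total log-likelihood sum(Delta_g) strictly improves.  It
stops after ``m_stop`` consecutive non-improving proposals; m = n^2 is the
default, which suffices for convergence in practice.  Group deltas depend
only on the group's member set, so evaluations are cached by member set —
a proposal touches at most two groups and costs at most two Viterbi runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hmm_core import HMMParams, sample_emission_cube, viterbi_joint
from .nmf_init import ClusterAssignment
from .segio import CopyNumberMatrix

log = logging.getLogger(__name__)


def default_m_stop(n: int) -> int:
    """Default stopping patience: n^2 consecutive non-improving proposals."""
    return n * n


@dataclass
class SearchConfig:
    """Settings for the label search.

    ``m_stop`` and ``max_iters`` default to n^2 and 50*n^2, resolved at
    search time from the matrix.  ``n_workers`` is an evaluation-parallelism
    hint; results with one worker are bit-reproducible for a fixed seed, and
    the serial evaluator is used regardless since per-proposal cost is tiny.
    """

    G: int
    seed: int
    m_stop: int | None = None
    max_iters: int | None = None
    n_workers: int = 1

    def resolve(self, n: int) -> tuple[int, int]:
        m_stop = default_m_stop(n) if self.m_stop is None else self.m_stop
        max_iters = 50 * n * n if self.max_iters is None else self.max_iters
        if m_stop < 1:
            raise ValueError("m_stop must be >= 1")
        if max_iters < m_stop:
            raise ValueError("max_iters must be >= m_stop")
        return m_stop, max_iters


@dataclass(eq=False)
class SearchResult:
    assignment: ClusterAssignment
    deltas: np.ndarray
    total_loglik: float
    trace: list = field(default_factory=list)
    iterations_run: int = 0


class _DeltaCache:
    """Per-group delta evaluations, cached by the group's member set."""

    def __init__(self, m: CopyNumberMatrix, params: HMMParams):
        self._cube = sample_emission_cube(m.values, params)
        self._chain_starts = m.grid.chain_starts
        self._params = params
        self._cache: dict[tuple, float] = {}

    def delta(self, members: tuple) -> float:
        d = self._cache.get(members)
        if d is None:
            emis = self._cube[list(members)].sum(axis=0)
            d = viterbi_joint(emis, self._params, self._chain_starts).delta
            self._cache[members] = d
        return d

    def total(self, labels: np.ndarray, G: int) -> tuple[np.ndarray, float]:
        deltas = np.empty(G)
        for g in range(1, G + 1):
            members = tuple(np.flatnonzero(labels == g).tolist())
            if not members:
                raise ValueError(f"group {g} is empty")
            deltas[g - 1] = self.delta(members)
        return deltas, float(deltas.sum())


def total_loglik(
    m: CopyNumberMatrix, a: ClusterAssignment, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Per-group deltas and their sum for an assignment."""
    return _DeltaCache(m, params).total(a.labels, a.G)


def propose_move(
    a: ClusterAssignment, rng: np.random.Generator, max_retries: int = 1000
) -> ClusterAssignment:
    """Re-draw the group labels of two random samples.

    Both samples receive labels drawn uniformly from 1..G (which includes a
    swap as a special case).  Proposals that would empty a group are redrawn.
    """
    if a.G < 2:
        raise ValueError("proposals require G >= 2")
    if a.n < 2:
        raise ValueError("proposals require n >= 2")
    for _ in range(max_retries):
        labels = a.labels.copy()
        i, j = rng.choice(a.n, size=2, replace=False)
        labels[i] = rng.integers(1, a.G + 1)
        labels[j] = rng.integers(1, a.G + 1)
        if len(np.unique(labels)) == a.G:
            return ClusterAssignment(labels=labels, G=a.G)
    raise RuntimeError("could not draw a proposal keeping all groups non-empty")


def hmmc_search(
    m: CopyNumberMatrix,
    params: HMMParams,
    cfg: SearchConfig,
    init: ClusterAssignment,
) -> SearchResult:
    """Run the strict-improvement label search from an initial assignment.

    Returns the best assignment found, its per-group deltas and total
    log-likelihood, the improvement trace, and the number of proposals
    evaluated.  Deterministic for a fixed seed.
    """
    if init.n != m.n:
        raise ValueError("init assignment length does not match the matrix")
    if init.G != cfg.G:
        raise ValueError("init assignment G does not match the search config")
    m_stop, max_iters = cfg.resolve(m.n)
    rng = np.random.default_rng(cfg.seed)
    cache = _DeltaCache(m, params)

    best = init.copy()
    best_deltas, best_ll = cache.total(best.labels, best.G)
    trace = [(0, best_ll)]
    stall = 0
    iters = 0
    while stall < m_stop and iters < max_iters:
        prop = propose_move(best, rng)
        iters += 1
        deltas, ll = cache.total(prop.labels, prop.G)
        if ll > best_ll:
            best, best_deltas, best_ll = prop, deltas, ll
            trace.append((iters, ll))
            stall = 0
        else:
            stall += 1
    if iters >= max_iters and stall < m_stop:
        log.warning(
            "search hit the max_iters safety cap (%d) before the stopping "
            "patience was exhausted", max_iters,
        )
    return SearchResult(
        assignment=best,
        deltas=best_deltas,
        total_loglik=best_ll,
        trace=trace,
        iterations_run=iters,
    )
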