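"""BIC model selection over the number of groups G.

The model's free parameters are the T hidden states per group (transition
and emission parameters are estimated empirically and not counted), so
k = T x G and

    BIC(G) = -2 * sum_g Delta_g + T * G * ln(n).

G is chosen to minimize BIC; ties break to the smaller G (parsimony).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hmm_core import HMMParams, cluster_delta
from .nmf_init import ClusterAssignment, nmf_cluster, repair_empty_groups
from .search import SearchConfig, SearchResult, hmmc_search
from .segio import CopyNumberMatrix

DEFAULT_G_RANGE = range(2, 7)


@dataclass(frozen=True)
class ModelScore:
    G: int
    total_loglik: float
    k: int
    n: int
    bic: float


def bic(total_loglik: float, T: int, G: int, n: int) -> float:
    """-2 * lnL + T * G * ln(n)."""
    if min(T, G, n) < 1:
        raise ValueError("T, G and n must all be >= 1")
    return -2.0 * total_loglik + T * G * math.log(n)


def select_G(
    m: CopyNumberMatrix,
    params: HMMParams,
    G_range: Sequence[int],
    cfg: SearchConfig,
) -> tuple[int, list[ModelScore], list[SearchResult]]:
    """Search each G in the range and pick the BIC minimizer.

    Each G gets its own seed derived from the config seed so runs are
    independent but reproducible.  G = 1 is scored directly from the single
    all-samples cluster without searching.
    """
    G_range = list(G_range)
    if not G_range or min(G_range) < 1:
        raise ValueError("G_range must be non-empty with all values >= 1")
    scores: list[ModelScore] = []
    results: list[SearchResult] = []
    for G in G_range:
        seed_g = int(
            np.random.SeedSequence([cfg.seed, G]).generate_state(1)[0] % 2**31
        )
        if G == 1:
            fit = cluster_delta(m, range(m.n), params)
            res = SearchResult(
                assignment=ClusterAssignment(
                    labels=np.ones(m.n, dtype=np.int64), G=1
                ),
                deltas=np.array([fit.delta]),
                total_loglik=fit.delta,
                trace=[(0, fit.delta)],
                iterations_run=0,
            )
        else:
            rng = np.random.default_rng(seed_g)
            init = repair_empty_groups(
                nmf_cluster(m, G, seed=seed_g), rng
            )
            g_cfg = SearchConfig(
                G=G,
                seed=seed_g,
                m_stop=cfg.m_stop,
                max_iters=cfg.max_iters,
                n_workers=cfg.n_workers,
            )
            res = hmmc_search(m, params, g_cfg, init)
        results.append(res)
        scores.append(
            ModelScore(
                G=G,
                total_loglik=res.total_loglik,
                k=m.T * G,
                n=m.n,
                bic=bic(res.total_loglik, m.T, G, m.n),
            )
        )
    best = min(scores, key=lambda s: (s.bic, s.G))
    return best.G, scores, results
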