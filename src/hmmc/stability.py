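"""Leave-k%-out cross-validation of clustering stability.

After clustering the full dataset, a random 10% of samples (by default) is
held out, the remaining 90% are re-clustered with the same G, and the
retained samples' new labels are compared with the reference clustering
under the best bijective group relabeling.  Repeated 100 times, the pooled
fraction of retained samples that change subgroup is the instability of
the clustering with respect to sample permutation.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hmm_core import HMMParams
from .nmf_init import ClusterAssignment, nmf_cluster, repair_empty_groups
from .search import SearchConfig, hmmc_search
from .segio import CopyNumberMatrix

log = logging.getLogger(__name__)


def _match_errors(
    reference: np.ndarray, predicted: np.ndarray, G: int
) -> int:
    conf = np.zeros((G, G), dtype=np.int64)
    for a, b in zip(reference, predicted):
        conf[a - 1, b - 1] += 1
    row, col = linear_sum_assignment(conf, maximize=True)
    return int(len(reference) - conf[row, col].sum())


def crossvalidate_stability(
    m: CopyNumberMatrix,
    reference: ClusterAssignment,
    params: HMMParams,
    cfg: SearchConfig,
    n_repeats: int = 100,
    holdout_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[float, list[int]]:
    """Pooled label-disagreement rate over random holdout repeats.

    Per repeat, ceil(holdout_fraction * n) samples are dropped, the rest are
    re-clustered by HMMC (NMF-seeded, same G as the reference), and retained
    samples assigned to a different subgroup than in the reference — under
    the best bijective relabeling — are counted as errors.  Returns
    total errors / total retained assignments and the per-repeat counts.
    A repeat whose subsample loses an entire reference group is redrawn.
    """
    n = m.n
    if not 0.0 < holdout_fraction < 0.5:
        raise ValueError("holdout_fraction must lie in (0, 0.5)")
    if holdout_fraction < 1.0 / n:
        raise ValueError(
            f"holdout_fraction {holdout_fraction} leaves out no sample for "
            f"n={n}; use at least 1/n"
        )
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if reference.n != n:
        raise ValueError("reference assignment does not match the matrix")
    h = math.ceil(holdout_fraction * n)
    G = reference.G

    per_repeat: list[int] = []
    total_retained = 0
    for rep in range(n_repeats):
        for attempt in range(100):
            ss = np.random.SeedSequence([seed, rep, attempt])
            draw_seed, nmf_seed, search_seed = (
                int(x % 2**31) for x in ss.generate_state(3)
            )
            rng = np.random.default_rng(draw_seed)
            holdout = rng.choice(n, size=h, replace=False)
            keep = np.setdiff1d(np.arange(n), holdout)
            ref_kept = reference.labels[keep]
            if len(np.unique(ref_kept)) < G:
                log.info(
                    "repeat %d attempt %d lost a reference group; redrawing",
                    rep, attempt,
                )
                continue
            sub = m.subset(keep)
            init = repair_empty_groups(
                nmf_cluster(sub, G, seed=nmf_seed),
                np.random.default_rng(search_seed),
            )
            sub_cfg = SearchConfig(
                G=G,
                seed=search_seed,
                m_stop=cfg.m_stop,
                max_iters=cfg.max_iters,
                n_workers=cfg.n_workers,
            )
            res = hmmc_search(sub, params, sub_cfg, init)
            per_repeat.append(_match_errors(ref_kept, res.assignment.labels, G))
            total_retained += len(keep)
            break
        else:
            raise RuntimeError(
                "could not draw a subsample retaining every reference group"
            )
    return sum(per_repeat) / total_retained, per_repeat
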