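"""Two-group aCGH simulator and the HMMC-vs-NMF error-rate experiment.

Each simulated dataset holds two groups of samples on one pseudo-chromosome
of T segments.  Every profile is a flat diploid baseline (mean 2) plus
stationary AR(1) noise with marginal standard deviation s and lag-1
autocorrelation rho, mimicking the strong spatial correlation of
high-density SNP arrays.  The second group additionally carries a block of
consecutive amplified segments (mean 4) in the middle of the genome — the
subtype signal.  On top of that, every sample gets a fixed number of
randomly chosen segments amplified by the same shift: shared copy-number
noise that both clustering methods must see through.  Values are floored
just below the lowest HMM state to keep the lognormal emissions proper.

The experiment clusters many replicate datasets with (a) HMMC seeded by NMF
and (b) NMF alone, at G = 2, and reports the mean best-relabeling error
rate per noise level and method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import lfilter

from .hmm_core import HMMParams, estimate_emission_sd, estimate_transition_probs
from .nmf_init import ClusterAssignment, nmf_cluster, repair_empty_groups
from .search import SearchConfig, hmmc_search
from .segio import CopyNumberMatrix, SegmentGrid

VALUE_FLOOR = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the simulation-study conditions."""

    n_per_group: int = 10
    T: int = 100
    baseline_mean: float = 2.0
    s: float = 1.0
    amp_segments: int = 3
    amp_shift: float = 2.0
    noise_amp_count: int = 40
    noise_amp_shift: float = 2.0
    rho: float = 0.9
    seed: int = 0
    shared_noise: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.n_per_group < 1 or self.T < 1:
            raise ValueError("n_per_group and T must be >= 1")
        if self.amp_segments > self.T or self.noise_amp_count > self.T:
            raise ValueError("planted segment counts exceed T")
        if self.amp_segments < 0 or self.noise_amp_count < 0:
            raise ValueError("segment counts must be non-negative")


@dataclass(frozen=True, eq=False)
class SimDataset:
    matrix: CopyNumberMatrix
    truth: ClusterAssignment
    planted_segments: np.ndarray


def ar1_noise(T: int, s: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise: marginal sd s, lag-1 autocorrelation rho.

    e_t = rho * e_{t-1} + eps_t with eps_t ~ N(0, s^2 (1 - rho^2)) and
    e_1 ~ N(0, s^2); rho = 0 degenerates to i.i.d. N(0, s^2).
    """
    eps = rng.standard_normal(T)
    innov = eps * (s * np.sqrt(1.0 - rho * rho))
    innov[0] = eps[0] * s
    return lfilter([1.0], [1.0, -rho], innov)


def _centre_block(T: int, width: int) -> np.ndarray:
    c = T // 2
    start = c - width // 2
    return np.arange(start, start + width)


def generate_dataset(cfg: SimConfig) -> SimDataset:
    """Draw one two-group dataset on a single pseudo-chromosome."""
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_group
    profiles = np.full((n, cfg.T), cfg.baseline_mean, dtype=np.float64)
    planted = _centre_block(cfg.T, cfg.amp_segments)
    profiles[cfg.n_per_group :, planted] += cfg.amp_shift
    for j in range(n):
        profiles[j] += ar1_noise(cfg.T, cfg.s, cfg.rho, rng)
    if cfg.noise_amp_count:
        if cfg.shared_noise:
            idx = rng.choice(cfg.T, size=cfg.noise_amp_count, replace=False)
            profiles[:, idx] += cfg.noise_amp_shift
        else:
            for j in range(n):
                idx = rng.choice(cfg.T, size=cfg.noise_amp_count, replace=False)
                profiles[j, idx] += cfg.noise_amp_shift
    values = np.maximum(profiles, VALUE_FLOOR)

    starts = np.arange(cfg.T, dtype=np.int64) * 1000 + 1
    grid = SegmentGrid(
        chromosomes=tuple("1" for _ in range(cfg.T)),
        starts=starts,
        ends=starts + 999,
    )
    matrix = CopyNumberMatrix(
        sample_ids=[f"S{j + 1:03d}" for j in range(n)], grid=grid, values=values
    )
    labels = np.repeat([1, 2], cfg.n_per_group)
    return SimDataset(
        matrix=matrix,
        truth=ClusterAssignment(labels=labels, G=2),
        planted_segments=planted,
    )


def error_rate(truth: ClusterAssignment, predicted: ClusterAssignment) -> float:
    """Fraction misassigned, minimized over bijective group relabelings."""
    if truth.n != predicted.n:
        raise ValueError("assignments must cover the same samples")
    G = max(truth.G, predicted.G)
    conf = np.zeros((G, G), dtype=np.int64)
    for a, b in zip(truth.labels, predicted.labels):
        conf[a - 1, b - 1] += 1
    row, col = linear_sum_assignment(conf, maximize=True)
    matched = conf[row, col].sum()
    return float(truth.n - matched) / truth.n


def _hmm_params_from(matrix: CopyNumberMatrix) -> HMMParams:
    p_same, _ = estimate_transition_probs(matrix)
    return HMMParams(p_same=p_same, sigma=estimate_emission_sd(matrix))


def cluster_dataset(
    ds: SimDataset,
    nmf_seed: int,
    search_seed: int,
    search_cfg: SearchConfig | None = None,
    n_restarts: int = 10,
) -> tuple[float, float]:
    """Cluster one dataset with NMF and NMF-seeded HMMC; return both errors."""
    params = _hmm_params_from(ds.matrix)
    init = nmf_cluster(ds.matrix, G=2, seed=nmf_seed, n_restarts=n_restarts)
    nmf_err = error_rate(ds.truth, init)
    rng = np.random.default_rng(search_seed)
    init = repair_empty_groups(init, rng)
    cfg = SearchConfig(
        G=2,
        seed=search_seed,
        m_stop=search_cfg.m_stop if search_cfg else None,
        max_iters=search_cfg.max_iters if search_cfg else None,
    )
    res = hmmc_search(ds.matrix, params, cfg, init)
    return error_rate(ds.truth, res.assignment), nmf_err


def run_error_experiment(
    s_grid,
    n_datasets: int,
    base_cfg: SimConfig | None = None,
    search_cfg: SearchConfig | None = None,
) -> pd.DataFrame:
    """Mean HMMC and NMF error rates per noise level s.

    For each s and replicate, one dataset is generated and clustered with
    both methods; seeds are derived deterministically from the base config
    seed, the s index and the replicate index.  Returns a tidy frame with
    columns (s, method, mean_error_rate).
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    base_cfg = SimConfig() if base_cfg is None else base_cfg
    rows = []
    for si, s in enumerate(s_grid):
        hmmc_errs = np.empty(n_datasets)
        nmf_errs = np.empty(n_datasets)
        for rep in range(n_datasets):
            ss = np.random.SeedSequence([base_cfg.seed, si, rep])
            ds_seed, nmf_seed, search_seed = (
                int(x % 2**31) for x in ss.generate_state(3)
            )
            ds = generate_dataset(replace(base_cfg, s=float(s), seed=ds_seed))
            hmmc_errs[rep], nmf_errs[rep] = cluster_dataset(
                ds, nmf_seed, search_seed, search_cfg
            )
        rows.append({"s": float(s), "method": "HMMC",
                     "mean_error_rate": float(hmmc_errs.mean())})
        rows.append({"s": float(s), "method": "NMF",
                     "mean_error_rate": float(nmf_errs.mean())})
    return pd.DataFrame(rows, columns=["s", "method", "mean_error_rate"])
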