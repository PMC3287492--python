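"""NMF preliminary clustering: the search seed and the comparison baseline.

Nonnegative matrix factorization of the samples x segments matrix at inner
rank G; each sample is assigned to the group whose coefficient in its row of
W is largest.  NMF ignores the spatial correlation between segments, which
is exactly the weakness the HMM search stage is designed to correct, so a
mediocre seed is acceptable — the factorization is restarted a few times and
the lowest-loss solution kept purely for reproducibility and stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .segio import CopyNumberMatrix


@dataclass(eq=False)
class ClusterAssignment:
    """Per-sample group labels in 1..G."""

    labels: np.ndarray
    G: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValueError("labels must be a non-empty vector")
        if np.any(self.labels < 1) or np.any(self.labels > self.G):
            raise ValueError("labels must lie in 1..G")

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.labels == g)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.G + 1)[1:]

    def copy(self) -> "ClusterAssignment":
        return ClusterAssignment(labels=self.labels.copy(), G=self.G)


def nmf_cluster(
    m: CopyNumberMatrix, G: int, seed: int, n_restarts: int = 10
) -> ClusterAssignment:
    """Cluster samples by rank-G NMF with max-coefficient assignment.

    Runs ``n_restarts`` random initializations of Frobenius-loss NMF and
    keeps the factorization with the lowest reconstruction error.  Ties in
    a sample's coefficients break to the lowest group index.  G = 1 returns
    all-ones labels without factorizing.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if G > m.n:
        raise ValueError(f"G={G} exceeds the number of samples n={m.n}")
    if np.any(m.values < 0):
        raise ValueError("matrix entries must be nonnegative for NMF")
    if G == 1:
        return ClusterAssignment(labels=np.ones(m.n, dtype=np.int64), G=1)

    rng = np.random.default_rng(seed)
    best_err = np.inf
    best_W = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max(1, n_restarts)):
            rs = int(rng.integers(0, 2**31 - 1))
            model = NMF(
                n_components=G,
                init="random",
                solver="cd",
                max_iter=500,
                tol=1e-6,
                random_state=rs,
            )
            W = model.fit_transform(m.values)
            if model.reconstruction_err_ < best_err:
                best_err = model.reconstruction_err_
                best_W = W
    labels = np.argmax(best_W, axis=1) + 1  # argmax takes the first max: low index
    return ClusterAssignment(labels=labels.astype(np.int64), G=G)


def repair_empty_groups(
    a: ClusterAssignment, rng: np.random.Generator
) -> ClusterAssignment:
    """Ensure every group is non-empty by donating samples from the largest.

    NMF occasionally leaves a component with no max-coefficient sample; the
    HMM search requires every group populated, so a random member of the
    currently largest group is moved into each empty one.
    """
    labels = a.labels.copy()
    for g in range(1, a.G + 1):
        if np.any(labels == g):
            continue
        sizes = np.bincount(labels, minlength=a.G + 1)[1:]
        donor = int(np.argmax(sizes)) + 1
        pool = np.flatnonzero(labels == donor)
        labels[rng.choice(pool)] = g
    return ClusterAssignment(labels=labels, G=a.G)
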