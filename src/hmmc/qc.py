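"""Normal-contamination quality control.

Tumour specimens are often contaminated with adjacent normal tissue, which
flattens their copy-number profile toward diploid and blurs cluster
structure.  The QC stage trains a random-forest classifier to tell apart
clearly aberrant tumours (the samples with the most copy-number-altered
segments) from normal samples, then scores every tumour sample with the
classifier's normal-class probability; samples more likely normal than
tumour (probability > 0.5) are excluded from clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .segio import CopyNumberMatrix

DEFAULT_LO = 1.5
DEFAULT_HI = 2.5


@dataclass(eq=False)
class QCReport:
    sample_ids: list
    contamination_prob: np.ndarray
    excluded: np.ndarray
    oob_error: float

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


def count_alteration_regions(
    m: CopyNumberMatrix, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> np.ndarray:
    """Per-sample count of segments outside the [lo, hi] diploid band."""
    if not lo < 2.0 < hi:
        raise ValueError("thresholds must bracket the diploid level 2")
    return ((m.values < lo) | (m.values > hi)).sum(axis=1)


def qc_filter(
    m: CopyNumberMatrix,
    normals: CopyNumberMatrix,
    top_fraction: float = 0.25,
    seed: int = 0,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
    n_estimators: int = 500,
) -> QCReport:
    """Score tumour samples for normal contamination and flag exclusions.

    The training set pairs the ``top_fraction`` of tumour samples with the
    highest alteration counts (class tumour) against all normal samples
    (class normal); features are the segment mean copy numbers.  Every
    tumour sample is then scored with the forest's normal-class
    probability.  Deterministic for a fixed seed.
    """
    if not 0.0 < top_fraction <= 0.5:
        raise ValueError("top_fraction must lie in (0, 0.5]")
    if m.T != normals.T:
        raise ValueError("tumour and normal matrices must share the segment grid")
    k = math.ceil(top_fraction * m.n)
    if k < 2 or normals.n < 2:
        raise ValueError("need at least 2 training samples per class")

    counts = count_alteration_regions(m, lo, hi)
    # stable sort: ties in the alteration count resolve by sample order
    top = np.argsort(-counts, kind="stable")[:k]
    X = np.vstack([m.values[top], normals.values])
    y = np.concatenate([np.ones(k, dtype=int), np.zeros(normals.n, dtype=int)])

    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    normal_col = int(np.flatnonzero(rf.classes_ == 0)[0])
    prob = rf.predict_proba(m.values)[:, normal_col]
    return QCReport(
        sample_ids=list(m.sample_ids),
        contamination_prob=prob,
        excluded=prob > 0.5,
        oob_error=float(1.0 - rf.oob_score_),
    )
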