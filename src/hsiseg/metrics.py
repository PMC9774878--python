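"""Partition-agreement scores for segmentations: NMI and adjusted Rand.

Both scores are permutation invariant, so no label matching is needed to
compare a segmentation with the ground truth.  `align_labels` exists only
for presentation (confusion matrices, consistently coloured overlays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .patchwork import LabelMap

__all__ = ["Contingency", "EvalReport", "contingency", "nmi", "ars", "align_labels", "evaluate"]


@dataclass
class Contingency:
    counts: np.ndarray  # (r, c) non-negative ints
    row_labels: np.ndarray
    col_labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class EvalReport:
    nmi: float
    ars: float
    contingency: Contingency
    aligned_confusion: np.ndarray


def _flatten(a) -> np.ndarray:
    arr = a.labels if isinstance(a, LabelMap) else np.asarray(a)
    flat = arr.ravel()
    if flat.size == 0:
        raise ValueError("empty labelings cannot be scored")
    return flat


def contingency(a, b) -> Contingency:
    """Cross-tabulation counts[u, v] = #{i : a_i = u, b_i = v}."""
    fa, fb = _flatten(a), _flatten(b)
    if fa.size != fb.size:
        raise ValueError(f"length mismatch: {fa.size} vs {fb.size}")
    counts = contingency_matrix(fa, fb)
    return Contingency(np.asarray(counts), np.unique(fa), np.unique(fb))


def nmi(a, b, average_method: str = "arithmetic") -> float:
    """Normalised mutual information in [0, 1].

    Mutual information of the joint label distribution divided by the mean
    of the two entropies (arithmetic by default; min/geometric/max
    selectable).  Returns 0 when either labeling is constant.
    """
    fa, fb = _flatten(a), _flatten(b)
    if fa.size != fb.size:
        raise ValueError(f"length mismatch: {fa.size} vs {fb.size}")
    if len(np.unique(fa)) == 1 or len(np.unique(fb)) == 1:
        return 0.0
    return float(normalized_mutual_info_score(fa, fb, average_method=average_method))


def ars(a, b) -> float:
    """Adjusted Rand score: pair-counting agreement corrected for chance."""
    fa, fb = _flatten(a), _flatten(b)
    if fa.size != fb.size:
        raise ValueError(f"length mismatch: {fa.size} vs {fb.size}")
    return float(adjusted_rand_score(fa, fb))


def align_labels(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray) -> np.ndarray:
    """Relabel predictions to best match the truth (assignment problem).

    Maximises total agreement over one-to-one class matchings; surplus
    predicted classes (when k_pred > k_truth) keep fresh ids above the truth
    range.  Returns the relabeled prediction with the input's shape.
    """
    parr = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    tarr = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    if parr.shape != tarr.shape:
        raise ValueError(f"shape mismatch {parr.shape} vs {tarr.shape}")
    c = contingency(parr, tarr)
    rows, cols = linear_sum_assignment(c.counts, maximize=True)
    mapping = {}
    next_id = int(tarr.max()) + 1
    for u_idx, u in enumerate(c.row_labels):
        hit = np.flatnonzero(rows == u_idx)
        if hit.size:
            mapping[int(u)] = int(c.col_labels[cols[hit[0]]])
        else:
            mapping[int(u)] = next_id
            next_id += 1
    out = np.vectorize(mapping.__getitem__, otypes=[np.int64])(parr)
    return out


def evaluate(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray) -> EvalReport:
    """Score a segmentation against ground truth (NMI, ARS, confusions)."""
    aligned = align_labels(pred, truth)
    return EvalReport(
        nmi=nmi(pred, truth),
        ars=ars(pred, truth),
        contingency=contingency(pred, truth),
        aligned_confusion=contingency(aligned, truth).counts,
    )
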