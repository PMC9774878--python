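"""Spectral k-means: the spatially blind comparison method.

Pixels are clustered purely by the similarity of their spectra, so two
regions built from the same endmembers but with different spatial patterns
cannot be told apart — the motivation for patch-based spatio-spectral
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import HSICube
from .patchwork import LabelMap

__all__ = ["SpectralKMeansResult", "spectral_kmeans"]


@dataclass
class SpectralKMeansResult:
    labels: LabelMap
    centers: np.ndarray  # (k, B) cluster-mean spectra
    inertia: float


def spectral_kmeans(cube: HSICube, k: int, seed: int = 0, n_init: int = 10) -> SpectralKMeansResult:
    """k-means on the H*W x B matrix of pixel spectra (negatives zeroed).

    Deterministic per seed (best inertia over ``n_init`` restarts).  When the
    cube holds fewer distinct spectra than k the surplus clusters end up
    empty or duplicated; this succeeds with a warning.
    """
    H, W, B = cube.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if H * W < k:
        raise ValueError(f"need at least k={k} pixels, got {H * W}")
    flat = np.clip(cube.data.reshape(H * W, B), 0.0, None)
    n_unique = len(np.unique(flat, axis=0))
    if n_unique < k:
        warnings.warn(
            f"only {n_unique} distinct spectra for k={k}; "
            "some clusters will be degenerate",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(flat)
    labels = LabelMap(
        km.labels_.reshape(H, W).astype(np.int64),
        n_classes=k,
        provenance="spectral_kmeans",
    )
    return SpectralKMeansResult(labels, km.cluster_centers_, float(km.inertia_))
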