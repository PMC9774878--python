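"""Patch decomposition and label-map reconstruction.

A cube is decomposed into overlapping p x p x B patches taken on a raster
scan with step s; the patch count is ``(floor((H-p)/s)+1) * (floor((W-p)/s)+1)``.
Normalisation is global: negatives are zeroed and every patch is divided by
the single maximum over the whole cube, so values land in [0, 1] and the
two-endmember structure of a phantom is preserved across patches.

Per-patch cluster labels are turned back into a pixel map by painting each
patch's label over its footprint in raster order (later patches overwrite
earlier ones), which reproduces the block/smear artefacts of width p at the
bottom and right edges that `crop_edge_artifacts` removes; a majority-vote
mode is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import HSICube

__all__ = [
    "NormalizationRecord",
    "PatchSet",
    "LabelMap",
    "extract_patches",
    "normalize_patches",
    "patch_grid_shape",
    "reconstruct_label_map",
    "crop_edge_artifacts",
]


@dataclass(frozen=True)
class NormalizationRecord:
    global_max: float
    negatives_zeroed: bool


@dataclass
class LabelMap:
    """2-D integer class image with provenance metadata."""

    labels: np.ndarray
    n_classes: int
    provenance: str = "truth"
    crop: tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if self.labels.size and self.labels.max() >= self.n_classes:
            raise ValueError("labels must be < n_classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class PatchSet:
    """Ordered overlapping patches with their top-left coordinates.

    patches: (N, p, p, B); coords: (N, 2) 0-based (row, col) of the top-left
    pixel, raster order (rows outer, cols inner).
    """

    patches: np.ndarray
    coords: np.ndarray
    patch_size: int
    step: int
    source_shape: tuple[int, int, int]
    norm: NormalizationRecord | None = None
    truth: np.ndarray | None = None  # carried along from the source cube

    def __post_init__(self) -> None:
        p = self.patch_size
        if self.patches.shape[1:3] != (p, p):
            raise ValueError("patch array does not match patch_size")
        if len(self.patches) != len(self.coords):
            raise ValueError("coords/patches length mismatch")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return patch_grid_shape(self.source_shape[:2], self.patch_size, self.step)


def patch_grid_shape(spatial: tuple[int, int], p: int, s: int) -> tuple[int, int]:
    """Number of patch start positions along (rows, cols)."""
    H, W = spatial
    return ((H - p) // s + 1, (W - p) // s + 1)


def extract_patches(cube: HSICube, p: int, s: int, dtype=np.float32) -> PatchSet:
    """Decompose a cube into overlapping p x p patches on a step-s raster scan."""
    H, W, B = cube.shape
    if p > H or p > W:
        raise ValueError(f"patch size {p} exceeds spatial extent {(H, W)}")
    if s < 1:
        raise ValueError("step must be >= 1")
    windows = sliding_window_view(cube.data, (p, p), axis=(0, 1))  # (H-p+1, W-p+1, B, p, p)
    strided = windows[::s, ::s]
    nr, nc = strided.shape[:2]
    patches = np.ascontiguousarray(
        strided.transpose(0, 1, 3, 4, 2).reshape(nr * nc, p, p, B), dtype=dtype
    )
    rows, cols = np.meshgrid(np.arange(nr) * s, np.arange(nc) * s, indexing="ij")
    coords = np.stack([rows.ravel(), cols.ravel()], axis=1)
    return PatchSet(
        patches=patches,
        coords=coords,
        patch_size=p,
        step=s,
        source_shape=(H, W, B),
        truth=None if cube.truth is None else cube.truth.copy(),
    )


def normalize_patches(ps: PatchSet) -> PatchSet:
    """Zero negatives, then divide all patches by the global cube maximum."""
    patches = np.clip(ps.patches, 0.0, None)
    gmax = float(patches.max(initial=0.0))
    if gmax <= 0:
        raise ValueError("cannot normalise an all-zero cube")
    return replace(
        ps,
        patches=patches / gmax,
        norm=NormalizationRecord(global_max=gmax, negatives_zeroed=True),
    )


def reconstruct_label_map(
    labels: np.ndarray,
    ps: PatchSet,
    mode: str = "raster_overwrite",
    n_classes: int | None = None,
    provenance: str = "end_to_end",
) -> LabelMap:
    """Rebuild a pixel label map from per-patch cluster labels.

    ``raster_overwrite`` paints each patch's label over its p x p footprint
    in raster order so later patches overwrite earlier ones; ``majority``
    gives every pixel the modal label of the patches covering it, ties going
    to the lowest label id.  Pixels covered by no patch (possible at the far
    edges when s does not divide H-p) keep label 0.
    """
    labels = np.asarray(labels)
    if len(labels) != len(ps):
        raise ValueError(f"{len(labels)} labels for {len(ps)} patches")
    H, W, _ = ps.source_shape
    p = ps.patch_size
    k = int(n_classes if n_classes is not None else labels.max() + 1)
    if mode == "raster_overwrite":
        out = np.zeros((H, W), dtype=np.int64)
        for (r, c), lab in zip(ps.coords, labels):
            out[r : r + p, c : c + p] = lab
    elif mode == "majority":
        votes = np.zeros((H, W, k), dtype=np.int32)
        for (r, c), lab in zip(ps.coords, labels):
            votes[r : r + p, c : c + p, lab] += 1
        out = votes.argmax(axis=2).astype(np.int64)  # argmax ties -> lowest id
    else:
        raise ValueError(f"unknown reconstruction mode {mode!r}")
    return LabelMap(out, n_classes=k, provenance=provenance)


def crop_edge_artifacts(
    m: LabelMap,
    p: int,
    s: int = 0,
    truth: np.ndarray | None = None,
    shift_correction: bool = False,
) -> tuple[LabelMap, np.ndarray | None]:
    """Remove the p-wide smear band at the bottom and right edges.

    An optional extra alignment margin ``s`` (the raster step) is cropped
    from the top and left.  If a truth image is supplied it is cropped
    identically so scores compare like with like.  ``shift_correction``
    additionally translates the retained prediction window by (s, s) to
    compensate the reconstruction's step-related offset; the truth window is
    unchanged.
    """
    H, W = m.shape
    if p + s >= H or p + s >= W:
        raise ValueError(f"crop (p={p}, s={s}) exceeds map size {(H, W)}")
    off = s if shift_correction else 0
    cropped = m.labels[s + off : H - p + off, s + off : W - p + off]
    t0, b0, l0, r0 = m.crop
    out = LabelMap(
        cropped,
        n_classes=m.n_classes,
        provenance=m.provenance,
        crop=(t0 + s, b0 + p, l0 + s, r0 + p),
    )
    if truth is not None:
        if truth.shape != (H, W):
            raise ValueError("truth shape differs from the label map")
        return out, truth[s : H - p, s : W - p]
    return out, None
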