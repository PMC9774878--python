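"""Model/Results surface tying the pipeline together.

`SpatioSpectralSegmentation` is built from an `HSICube` and segmentation
settings; `fit()` runs the chosen method and returns a
`SegmentationResults` carrying the label map, per-patch soft assignments,
training diagnostics and (when the cube has ground truth) agreement scores,
with a `summary()` table.

Methods
-------
``end_to_end``
    Pretrain the CAE on reconstruction, then jointly optimise reconstruction
    + clustering losses (deep embedded clustering) and reconstruct the label
    map from the hard assignments.
``cae_kmeans``
    Pretrain only, then k-means on the concatenated latents.
``spectral_kmeans``
    Pixel-spectrum k-means, ignoring spatial arrangement (the baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import spectral_kmeans
from .cae_models import CAE, ArchitectureConfig, build_cae
from .core import HSICube
from .deep_cluster import TrainConfig, cae_kmeans, pretrain_cae, train_end_to_end
from .metrics import ars as _ars
from .metrics import nmi as _nmi
from .patchwork import (
    LabelMap,
    crop_edge_artifacts,
    extract_patches,
    normalize_patches,
    reconstruct_label_map,
)

__all__ = ["SpatioSpectralSegmentation", "SegmentationResults"]

METHODS = ("end_to_end", "cae_kmeans", "spectral_kmeans")


@dataclass
class SegmentationResults:
    """Fit results: label maps, diagnostics and ground-truth agreement."""

    method: str
    label_map: LabelMap
    label_map_full: LabelMap
    patch_labels: np.ndarray | None
    soft_assignments: np.ndarray | None
    cae: CAE | None
    pretrain_history: dict | None
    joint_history: dict | None
    stop_reason: str | None
    nmi: float | None
    ars: float | None
    k: int
    seed: int
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        rows = [
            ("method", self.method),
            ("clusters (k)", self.k),
            ("seed", self.seed),
            ("label map shape", f"{self.label_map.shape[0]} x {self.label_map.shape[1]}"),
        ]
        for key in ("arch", "patch_size", "step", "latent_total"):
            if key in self.config:
                rows.append((key, self.config[key]))
        if self.pretrain_history is not None:
            rows.append(("pretrain epochs", len(self.pretrain_history["train_loss"])))
            rows.append(("pretrain val loss", f"{self.pretrain_history['val_loss'][-1]:.3e}"))
        if self.joint_history is not None:
            rows.append(("joint epochs", self.joint_history["epochs"]))
            rows.append(("stop reason", self.stop_reason))
        if self.nmi is not None:
            rows.append(("NMI vs truth", f"{self.nmi:.4f}"))
            rows.append(("ARS vs truth", f"{self.ars:.4f}"))
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Spatio-spectral segmentation results", "=" * 38]
        lines += [f"{str(k).ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)


class SpatioSpectralSegmentation:
    """Unsupervised segmentation model for a hyperspectral cube.

    Parameters
    ----------
    cube
        The HSI to segment; an attached ``truth`` image enables scoring.
    k
        Number of clusters (tissue classes), user-chosen.
    method
        One of ``end_to_end`` (default), ``cae_kmeans``, ``spectral_kmeans``.
    arch, latent_total, branches, filter_budget
        CAE architecture settings (see `cae_models`).
    patch_size, step
        Patch geometry of the raster decomposition.
    train_config
        Optimisation settings; architecture-adjusted defaults when omitted.
    crop_edges
        Crop the p-wide reconstruction artefact band (and an s-wide
        alignment margin) before scoring; default True.
    """

    def __init__(
        self,
        cube: HSICube,
        k: int = 3,
        method: str = "end_to_end",
        arch: str = "uwu2d",
        patch_size: int = 20,
        step: int = 4,
        latent_total: int = 100,
        branches: int = 4,
        filter_budget: dict | None = None,
        train_config: TrainConfig | None = None,
        crop_edges: bool = True,
    ):
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.cube = cube
        self.k = k
        self.method = method
        self.arch = arch
        self.patch_size = patch_size
        self.step = step
        self.latent_total = latent_total
        self.branches = branches
        self.filter_budget = filter_budget or {}
        self.train_config = train_config
        self.crop_edges = crop_edges
        self._patches = None
        self._pretrained: CAE | None = None
        self._pretrain_history: dict | None = None

    @classmethod
    def from_phantom(cls, seed: int = 0, n_bands: int = 100, height: int = 240, width: int = 240, **kw):
        """Build the model on a freshly generated default phantom."""
        from .phantom import make_phantom

        cube = make_phantom(height=height, width=width, n_bands=n_bands, seed=seed)
        return cls(cube, **kw)

    # ------------------------------------------------------------------
    @property
    def patches(self):
        if self._patches is None:
            ps = extract_patches(self.cube, self.patch_size, self.step)
            self._patches = normalize_patches(ps)
        return self._patches

    def _train_config(self, seed: int) -> TrainConfig:
        if self.train_config is not None:
            return self.train_config
        return TrainConfig.for_arch(self.arch, seed=seed)

    def pretrain(self, seed: int = 0) -> CAE:
        """Reconstruction-only CAE training; cached for reuse across methods."""
        if self._pretrained is None:
            cfg = ArchitectureConfig(
                arch=self.arch,
                patch_size=self.patch_size,
                bands=self.cube.n_bands,
                latent_total=self.latent_total,
                branches=self.branches,
                filter_budget=self.filter_budget,
                seed=seed,
            )
            cae = build_cae(cfg)
            self._pretrained, self._pretrain_history = pretrain_cae(
                cae, self.patches, self._train_config(seed)
            )
        return self._pretrained

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, method: str | None = None) -> SegmentationResults:
        """Run the segmentation and score it against the cube's truth."""
        method = method or self.method
        if method == "spectral_kmeans":
            res = spectral_kmeans(self.cube, self.k, seed=seed)
            return self._package(
                method, res.labels, None, None, None, None, None, None, seed
            )
        tc = self._train_config(seed)
        cae = self.pretrain(seed)
        if method == "cae_kmeans":
            labels = cae_kmeans(cae, self.patches, self.k, seed=seed)
            q = None
            joint_history = None
            stop = None
        else:
            tr = train_end_to_end(cae, self.patches, self.k, tc)
            labels, q, joint_history, stop = tr.labels, tr.q, tr.history, tr.stop_reason
        full = reconstruct_label_map(
            labels, self.patches, n_classes=self.k, provenance=method
        )
        return self._package(
            method, full, labels, q, cae, self._pretrain_history, joint_history, stop, seed
        )

    def _package(
        self, method, full, patch_labels, q, cae, pre_hist, joint_hist, stop, seed
    ) -> SegmentationResults:
        truth = self.cube.truth
        label_map = full
        if self.crop_edges and method != "spectral_kmeans":
            label_map, truth = crop_edge_artifacts(
                full, self.patch_size, self.step, truth=truth
            )
        nmi_val = ars_val = None
        if truth is not None:
            nmi_val = _nmi(label_map.labels, truth)
            ars_val = _ars(label_map.labels, truth)
        return SegmentationResults(
            method=method,
            label_map=label_map,
            label_map_full=full,
            patch_labels=patch_labels,
            soft_assignments=q,
            cae=cae,
            pretrain_history=pre_hist,
            joint_history=joint_hist,
            stop_reason=stop,
            nmi=nmi_val,
            ars=ars_val,
            k=self.k,
            seed=seed,
            config={
                "arch": self.arch,
                "patch_size": self.patch_size,
                "step": self.step,
                "latent_total": self.latent_total,
            },
        )
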