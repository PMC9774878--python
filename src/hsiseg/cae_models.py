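"""Convolutional autoencoder feature miners for HSI patches.

Three architectures share one encoder/decoder skeleton (front stack ->
branch encoders -> latent -> branch decoders -> tail stack):

``uwu2d``
    A branched 2-D architecture: a front stack of 2-D convolutions reduces
    the B spectral channels to M activation maps (M << B); each map is fed
    to its own branch encoder that compresses it to a latent of length D/M,
    so every branch specialises on features living in its own part of the
    learned spectral decomposition.  Branch decoders mirror the encoders and
    a tail stack maps the re-concatenated maps back to B channels.
``generic2d``
    A plain 2-D convolutional stack treating the B bands as input channels,
    with a dense bottleneck of length D.  Filter counts are chosen so its
    parameter count matches uwu2d within ~20%, isolating the effect of
    branching.
``generic3d``
    A single-channel 3-D convolutional stack over the p x p x B volume with
    a reduced filter budget (3-D convolutions are costlier per filter).

Decoders upsample with nearest-neighbour resizing followed by convolutions;
hidden activations are rectified linear, outputs linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    Conv2D,
    Conv3D,
    Dense,
    Flatten,
    MultiHead,
    ReLU,
    Reshape,
    ResizeNearest,
    Sequential,
    SpatialMoments,
)

__all__ = [
    "ArchitectureConfig",
    "LatentSet",
    "CAE",
    "build_cae",
    "encode",
    "decode",
    "reconstruction_loss",
    "concat_latents",
    "count_parameters",
]

ARCHS = ("uwu2d", "generic2d", "generic3d")


def _ceil_div(n: int, s: int) -> int:
    return -(-n // s)


@dataclass
class ArchitectureConfig:
    """Hyperparameters defining a CAE instance.

    latent_total D is the length of the concatenated latent vector l̄ (default
    100); branches M only applies to uwu2d and must divide D and stay below
    the band count.  filter_budget overrides per-architecture channel counts.
    """

    arch: str = "uwu2d"
    patch_size: int = 20
    bands: int = 100
    latent_total: int = 100
    branches: int = 4
    filter_budget: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}; choose from {ARCHS}")
        if self.latent_total <= 0:
            raise ValueError("latent_total must be positive")
        if self.arch == "uwu2d":
            if self.latent_total % self.branches != 0:
                raise ValueError(
                    f"latent_total {self.latent_total} not divisible by "
                    f"branches {self.branches}"
                )
            if not 1 <= self.branches < self.bands:
                raise ValueError("branch count must satisfy 1 <= M < bands")

    @property
    def n_branches(self) -> int:
        return self.branches if self.arch == "uwu2d" else 1

    @property
    def latent_per_branch(self) -> int:
        return self.latent_total // self.n_branches


@dataclass
class LatentSet:
    """Per-branch latents l_{i,m} and their concatenation l̄_i.

    per_branch holds M arrays of shape (N, D/M); ``concat`` is the ordered
    concatenation of length D per patch.
    """

    per_branch: list[np.ndarray]

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate(self.per_branch, axis=1)

    @property
    def n_branches(self) -> int:
        return len(self.per_branch)

    def __len__(self) -> int:
        return self.per_branch[0].shape[0]


def concat_latents(ls: LatentSet) -> np.ndarray:
    """Concatenate branch latents in branch order -> (N, D)."""
    if not ls.per_branch:
        raise ValueError("latent set has no branches")
    return ls.concat


class CAE:
    """Encoder/decoder pair with the shared front/branch/tail skeleton."""

    def __init__(
        self,
        cfg: ArchitectureConfig,
        front: Sequential,
        branch_encoders: list[Sequential],
        branch_decoders: list[Sequential],
        tail: Sequential,
    ):
        self.cfg = cfg
        self.front = front
        self.branch_encoders = branch_encoders
        self.branch_decoders = branch_decoders
        self.tail = tail

    # -- parameter plumbing -------------------------------------------------
    def param_pairs(self):
        yield from self.front.param_pairs()
        for enc in self.branch_encoders:
            yield from enc.param_pairs()
        for dec in self.branch_decoders:
            yield from dec.param_pairs()
        yield from self.tail.param_pairs()

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.param_pairs(), lr=lr)

    # -- forward / backward -------------------------------------------------
    def _split_front(self, h: np.ndarray) -> list[np.ndarray]:
        if len(self.branch_encoders) == 1:
            return [h]
        return [h[..., m : m + 1] for m in range(len(self.branch_encoders))]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full pass: returns (latent (N, D), reconstruction (N, p, p, B))."""
        h = self.front.forward(x)
        zs = [
            enc.forward(part)
            for enc, part in zip(self.branch_encoders, self._split_front(h))
        ]
        z = np.concatenate(zs, axis=1)
        ys = [dec.forward(zm) for dec, zm in zip(self.branch_decoders, zs)]
        cat = ys[0] if len(ys) == 1 else np.concatenate(ys, axis=-1)
        return z, self.tail.forward(cat)

    def backward(self, d_recon: np.ndarray, d_latent: np.ndarray | None = None) -> None:
        """Backpropagate gradients from the reconstruction and (optionally)
        an extra gradient arriving directly at the latent vector."""
        dcat = self.tail.backward(d_recon)
        m = len(self.branch_decoders)
        dl = self.cfg.latent_per_branch
        dh_parts = []
        for i, (enc, dec) in enumerate(zip(self.branch_encoders, self.branch_decoders)):
            dyi = dcat if m == 1 else dcat[..., i : i + 1]
            dzi = dec.backward(dyi)
            if d_latent is not None:
                dzi = dzi + d_latent[:, i * dl : (i + 1) * dl]
            dh_parts.append(enc.backward(dzi))
        dh = dh_parts[0] if m == 1 else np.concatenate(dh_parts, axis=-1)
        self.front.backward(dh)

    # -- inference-only conveniences ---------------------------------------
    def encode_array(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Encode (N, p, p, B) -> concatenated latents (N, D), batched."""
        outs = []
        for i in range(0, len(x), batch_size):
            z, _ = self.forward(x[i : i + batch_size])
            outs.append(z)
        return np.concatenate(outs, axis=0)


def build_cae(cfg: ArchitectureConfig) -> CAE:
    """Construct a parameterised encoder/decoder pair for the configuration."""
    rng = np.random.default_rng(cfg.seed)
    p, B, D = cfg.patch_size, cfg.bands, cfg.latent_total
    fb = cfg.filter_budget

    if cfg.arch == "uwu2d":
        M = cfg.branches
        f_front = fb.get("front", 16)
        f1, f2 = fb.get("branch", (8, 16))
        h1 = _ceil_div(p, 2)
        h2 = _ceil_div(h1, 2)
        h3 = _ceil_div(h2, 2)
        # spectral 1x1 compression first, then spatial 3x3 reduction to M maps
        front = Sequential(
            [
                Conv2D(B, f_front, 1, 1, rng),
                ReLU(),
                Conv2D(f_front, M, 3, 2, rng),
                ReLU(),
            ]
        )
        # per-branch latent = layout head (dense on the conv grid) +
        # texture head (translation-invariant spatial moments); the texture
        # dims keep pattern classes compact under Euclidean clustering even
        # when the layout dims vary with phase/placement
        t_dims = max(0, min(fb.get("texture", 0), D // M - 1))
        encs, decs = [], []
        for _ in range(M):
            shared = [
                Conv2D(1, f1, 3, 2, rng),
                ReLU(),
                Conv2D(f1, f2, 3, 2, rng),
                ReLU(),
            ]
            if t_dims:
                readout = MultiHead(
                    [
                        Sequential(
                            [Flatten(), Dense(h3 * h3 * f2, D // M - t_dims, rng)]
                        ),
                        Sequential([SpatialMoments(), Dense(2 * f2, t_dims, rng)]),
                    ]
                )
                encs.append(Sequential(shared + [readout]))
            else:
                encs.append(
                    Sequential(
                        shared + [Flatten(), Dense(h3 * h3 * f2, D // M, rng)]
                    )
                )
            decs.append(
                Sequential(
                    [
                        Dense(D // M, h3 * h3 * f2, rng),
                        ReLU(),
                        Reshape((h3, h3, f2)),
                        ResizeNearest((h2, h2)),
                        Conv2D(f2, f1, 3, 1, rng),
                        ReLU(),
                        ResizeNearest((h1, h1)),
                        Conv2D(f1, 1, 3, 1, rng),  # linear: avoid dead branches
                    ]
                )
            )
        tail = Sequential(
            [
                ResizeNearest((p, p)),
                Conv2D(M, f_front, 3, 1, rng),
                ReLU(),
                Conv2D(f_front, B, 1, 1, rng),
            ]
        )
        return CAE(cfg, front, encs, decs, tail)

    if cfg.arch == "generic2d":
        f1 = fb.get("f1", 16)
        f2 = fb.get("f2", 8)
        h1 = _ceil_div(p, 2)
        h2 = _ceil_div(h1, 2)
        t_dims = max(0, min(fb.get("texture", 0), D - 1))
        shared = [
            Conv2D(B, f1, 1, 1, rng),
            ReLU(),
            Conv2D(f1, f1, 3, 2, rng),
            ReLU(),
            Conv2D(f1, f2, 3, 2, rng),
            ReLU(),
        ]
        if t_dims:
            readout = MultiHead(
                [
                    Sequential([Flatten(), Dense(h2 * h2 * f2, D - t_dims, rng)]),
                    Sequential([SpatialMoments(), Dense(2 * f2, t_dims, rng)]),
                ]
            )
            enc = Sequential(shared + [readout])
        else:
            enc = Sequential(shared + [Flatten(), Dense(h2 * h2 * f2, D, rng)])
        dec = Sequential(
            [
                Dense(D, h2 * h2 * f2, rng),
                ReLU(),
                Reshape((h2, h2, f2)),
                ResizeNearest((h1, h1)),
                Conv2D(f2, f1, 3, 1, rng),
                ReLU(),
                ResizeNearest((p, p)),
                Conv2D(f1, B, 1, 1, rng),
            ]
        )
        return CAE(cfg, Sequential([]), [enc], [dec], Sequential([]))

    # generic3d: single-channel volume, reduced filter budget
    f1 = fb.get("f1", 4)
    f2 = fb.get("f2", 8)
    h1 = _ceil_div(p, 2)
    h2 = _ceil_div(h1, 2)
    b1 = _ceil_div(B, 4)
    b2 = _ceil_div(b1, 5)
    front = Sequential([Reshape((p, p, B, 1))])
    enc = Sequential(
        [
            Conv3D(1, f1, (3, 3, 7), (2, 2, 4), rng),
            ReLU(),
            Conv3D(f1, f2, (3, 3, 5), (2, 2, 5), rng),
            ReLU(),
            Flatten(),
            Dense(h2 * h2 * b2 * f2, D, rng),
        ]
    )
    dec = Sequential(
        [
            Dense(D, h2 * h2 * b2 * f2, rng),
            ReLU(),
            Reshape((h2, h2, b2, f2)),
            ResizeNearest((h1, h1, b1)),
            Conv3D(f2, f1, (3, 3, 5), (1, 1, 1), rng),
            ReLU(),
            ResizeNearest((p, p, B)),
            Conv3D(f1, 1, (3, 3, 7), (1, 1, 1), rng),
        ]
    )
    tail = Sequential([Reshape((p, p, B))])
    return CAE(cfg, front, [enc], [dec], tail)


def _as_batch(patch: np.ndarray, cfg: ArchitectureConfig) -> tuple[np.ndarray, bool]:
    patch = np.asarray(patch, dtype=np.float32)
    single = patch.ndim == 3
    if single:
        patch = patch[None]
    expected = (cfg.patch_size, cfg.patch_size, cfg.bands)
    if patch.shape[1:] != expected:
        raise ValueError(f"patch shape {patch.shape[1:]} != expected {expected}")
    return patch, single


def encode(cae: CAE, patch: np.ndarray) -> LatentSet:
    """Encode a patch (p, p, B) or batch (N, p, p, B) into branch latents."""
    x, _ = _as_batch(patch, cae.cfg)
    h = cae.front.forward(x)
    zs = [
        enc.forward(part)
        for enc, part in zip(cae.branch_encoders, cae._split_front(h))
    ]
    return LatentSet(zs)


def decode(cae: CAE, ls: LatentSet | np.ndarray) -> np.ndarray:
    """Decode branch latents (or a concatenated (N, D) array) to patches."""
    if isinstance(ls, LatentSet):
        zs = ls.per_branch
    else:
        z = np.atleast_2d(np.asarray(ls, dtype=np.float32))
        if z.shape[1] != cae.cfg.latent_total:
            raise ValueError(
                f"latent length {z.shape[1]} != configured {cae.cfg.latent_total}"
            )
        dl = cae.cfg.latent_per_branch
        zs = [z[:, m * dl : (m + 1) * dl] for m in range(cae.cfg.n_branches)]
    ys = [dec.forward(zm) for dec, zm in zip(cae.branch_decoders, zs)]
    cat = ys[0] if len(ys) == 1 else np.concatenate(ys, axis=-1)
    return cae.tail.forward(cat)


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared error over all elements; zero iff the patches agree."""
    x, xhat = np.asarray(x), np.asarray(xhat)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xhat.shape}")
    d = (x.astype(np.float64) - xhat.astype(np.float64)).ravel()
    return float(d @ d / d.size)


def count_parameters(cae: CAE) -> int:
    return int(sum(p.size for p, _ in cae.param_pairs()))
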