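"""Deep embedded clustering of patch latents, jointly trained with the CAE.

The clustering head keeps k centres mu_j in latent space and computes soft
assignments with a Student's-t kernel (alpha degrees of freedom, default 1):

    q_ij = (1 + ||z_i - mu_j||^2 / alpha)^(-(alpha+1)/2)  /  (row sum)

Training sharpens these assignments toward a target distribution

    p_ij = (q_ij^2 / f_j) / (row sum),   f_j = sum_i q_ij

by minimising KL(p || q) alongside the reconstruction loss; gradients flow
into both the centres and, through the encoder, the CAE weights, so the
learned features are tuned for the segmentation.  Hard labels are the row
argmax of q; joint training stops once fewer than 0.1% of hard assignments
change in an epoch (or at the epoch cap).  The non-end-to-end variant
("CAE+k-means") simply runs k-means on the latents of the reconstruction-
trained CAE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .cae_models import CAE, build_cae, reconstruction_loss
from .patchwork import PatchSet

__all__ = [
    "ClusterState",
    "TrainConfig",
    "TrainResult",
    "init_centers",
    "soft_assign",
    "target_distribution",
    "clustering_loss",
    "clustering_gradients",
    "pretrain_cae",
    "train_end_to_end",
    "cae_kmeans",
]

_Q_FLOOR = 1e-12


@dataclass
class ClusterState:
    """Cluster centres in latent space plus the Student's-t dof alpha.

    ``scale`` is the kernel-bandwidth conditioning factor: latents are
    divided by it before distances enter the Student's-t kernel, fixed once
    at initialisation so the initial within-cluster RMS distance is ~1
    (otherwise a latent space much smaller than the unit kernel bandwidth
    makes every soft assignment near-uniform and the sharpening loss inert).
    Centres are stored in the scaled space.
    """

    centers: np.ndarray  # (k, D), in scaled latent space
    alpha: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2 or len(self.centers) < 1:
            raise ValueError("centers must be a (k, D) array")
        if not np.isfinite(self.centers).all():
            raise ValueError("centers must be finite")

    @property
    def k(self) -> int:
        return len(self.centers)


@dataclass
class TrainConfig:
    """Optimisation settings for pretraining and joint training.

    Defaults follow the experimental protocol: Adam, batch size 58, learning
    rate 0.001; joint training stops when fewer than ``label_change_tol`` of
    hard assignments change after an epoch or at ``max_joint_epochs``.  The
    3-D architecture uses a fixed 40-epoch pretraining and a 20-epoch joint
    cap; 2-D architectures pretrain with early stopping on a validation
    split.
    """

    learning_rate: float = 0.001
    batch_size: int = 58
    gamma: float = 0.1
    pretrain_patience: int = 5
    max_pretrain_epochs: int = 50
    fixed_pretrain_epochs: int | None = None
    max_joint_epochs: int = 50
    label_change_tol: float = 0.001
    target_update_interval: int = 1
    validation_fraction: float = 0.1
    max_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.gamma + 1e-30) <= 0:
            raise ValueError("learning_rate, batch_size must be positive; gamma >= 0")
        if not 0 < self.label_change_tol < 1:
            raise ValueError("label_change_tol must lie in (0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")

    @classmethod
    def for_arch(cls, arch: str, **kw) -> "TrainConfig":
        """Architecture-adjusted defaults (3-D: fixed 40-epoch pretrain, 20-epoch joint cap)."""
        if arch == "generic3d":
            kw.setdefault("fixed_pretrain_epochs", 40)
            kw.setdefault("max_joint_epochs", 20)
        return cls(**kw)


@dataclass
class TrainResult:
    labels: np.ndarray
    q: np.ndarray
    cae: CAE
    state: ClusterState | None
    history: dict
    stop_reason: str


def init_centers(latents: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> ClusterState:
    """k-means initialisation of the cluster centres (best inertia of n_init runs)."""
    latents = np.asarray(latents, dtype=np.float64)
    if len(latents) < k:
        raise ValueError(f"need at least k={k} latents, got {len(latents)}")
    if k == 1:
        return ClusterState(latents.mean(axis=0, keepdims=True))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(latents)
    return ClusterState(km.cluster_centers_)


def soft_assign(latents: np.ndarray, cs: ClusterState) -> np.ndarray:
    """Student's-t soft assignments q (N, k); rows sum to one."""
    z = np.asarray(latents, dtype=np.float64) / cs.scale
    d2 = ((z[:, None, :] - cs.centers[None, :, :]) ** 2).sum(axis=2)
    s = (1.0 + d2 / cs.alpha) ** (-(cs.alpha + 1.0) / 2.0)
    return s / s.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened targets p_ij = (q_ij^2/f_j) / row-sum with f_j the soft counts."""
    q = np.asarray(q, dtype=np.float64)
    f = q.sum(axis=0)
    dead = f <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} cluster(s) have zero soft count; excluded from targets",
            stacklevel=2,
        )
    w = np.zeros_like(q)
    np.divide(q**2, f, out=w, where=~dead)
    return w / w.sum(axis=1, keepdims=True)


def clustering_loss(q: np.ndarray, p: np.ndarray) -> float:
    """KL(p || q) averaged over patches; >= 0, zero iff p == q."""
    q = np.asarray(q, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if q.shape != p.shape:
        raise ValueError("p and q must have matching shapes")
    qf = np.clip(q, _Q_FLOOR, None)
    pf = np.where(p > 0, p, 1.0)  # p log p -> 0 at p = 0
    terms = p * (np.log(pf) - np.log(qf))
    return float(terms.sum(axis=1).mean())


def clustering_gradients(
    latents: np.ndarray, cs: ClusterState, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of mean-per-patch KL(p||q) w.r.t. latents and centres.

    d/dz_i = (alpha+1)/(alpha N) * sum_j (1 + d_ij^2/alpha)^-1 (p_ij - q_ij)(z_i - mu_j)
    and the centre gradient is its negative, summed over patches.  The latent
    gradient is returned w.r.t. the raw (unscaled) latents; the centre
    gradient is w.r.t. the stored (scaled) centres.
    """
    z = np.asarray(latents, dtype=np.float64) / cs.scale
    n = len(z)
    diff = z[:, None, :] - cs.centers[None, :, :]  # (N, k, D)
    d2 = (diff**2).sum(axis=2)
    inv = 1.0 / (1.0 + d2 / cs.alpha)
    s = inv ** ((cs.alpha + 1.0) / 2.0)
    q = s / s.sum(axis=1, keepdims=True)
    w = (cs.alpha + 1.0) / (cs.alpha * n) * inv * (p - q)  # (N, k)
    dz = (w[:, :, None] * diff).sum(axis=1) / cs.scale
    dmu = -(w[:, :, None] * diff).sum(axis=0)
    return dz, dmu


def _split_validation(n: int, fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * fraction)))
    return idx[n_val:], idx[:n_val]


def pretrain_cae(cae: CAE, ps: PatchSet, tc: TrainConfig) -> tuple[CAE, dict]:
    """Reconstruction-only training of the CAE with Adam and early stopping.

    A held-out validation fraction monitors generalisation; training stops
    when the validation loss has not improved for ``pretrain_patience``
    epochs (or after ``fixed_pretrain_epochs`` when set).  Divergence
    (non-finite loss) triggers a re-initialised restart, at most
    ``max_restarts`` times.
    """
    x = ps.patches
    for restart in range(tc.max_restarts + 1):
        if restart > 0:
            cae = build_cae(replace(cae.cfg, seed=cae.cfg.seed + 1000 * restart))
        rng = np.random.default_rng(tc.seed + restart)
        train_idx, val_idx = _split_validation(len(x), tc.validation_fraction, rng)
        opt = cae.make_optimizer(tc.learning_rate)
        history: dict = {
            "train_loss": [],
            "val_loss": [],
            "batch_size": tc.batch_size,
            "learning_rate": tc.learning_rate,
            "optimizer": "adam",
            "restarts": restart,
        }
        best_val, best_epoch = np.inf, -1
        n_epochs = (
            tc.fixed_pretrain_epochs
            if tc.fixed_pretrain_epochs is not None
            else tc.max_pretrain_epochs
        )
        diverged = False
        for epoch in range(n_epochs):
            order = rng.permutation(train_idx)
            losses = []
            for i in range(0, len(order), tc.batch_size):
                xb = x[order[i : i + tc.batch_size]]
                _, xhat = cae.forward(xb)
                diff = xhat - xb
                losses.append(float(np.mean(diff.astype(np.float64) ** 2)))
                cae.backward((2.0 / diff.size) * diff)
                opt.step()
            train_loss = float(np.mean(losses))
            _, xhat = cae.forward(x[val_idx])
            val_loss = reconstruction_loss(x[val_idx], xhat)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if not np.isfinite(train_loss) or not np.isfinite(val_loss):
                diverged = True
                break
            if val_loss < best_val - 1e-12:
                best_val, best_epoch = val_loss, epoch
            if (
                tc.fixed_pretrain_epochs is None
                and epoch - best_epoch >= tc.pretrain_patience
            ):
                history["stop_reason"] = "early_stopping"
                break
        else:
            history["stop_reason"] = "max_epochs"
        if not diverged:
            return cae, history
    raise RuntimeError(
        f"CAE pretraining diverged after {tc.max_restarts} restarts"
    )


def _encode_and_assign(cae: CAE, x: np.ndarray, cs: ClusterState):
    z = cae.encode_array(x).astype(np.float64)
    q = soft_assign(z, cs)
    return z, q


def train_end_to_end(
    cae: CAE, ps: PatchSet, k: int, tc: TrainConfig
) -> TrainResult:
    """Joint optimisation of reconstruction + gamma * clustering losses.

    Centres are initialised by k-means on the pretrained latents; the target
    distribution is refreshed every ``target_update_interval`` epochs; both
    the CAE weights and the centres follow Adam.  Stops when the fraction of
    changed hard assignments drops below ``label_change_tol`` or at
    ``max_joint_epochs``.
    """
    x = ps.patches
    rng = np.random.default_rng(tc.seed + 17)
    z = cae.encode_array(x).astype(np.float64)
    cs0 = init_centers(z, k, seed=tc.seed)
    # condition the kernel bandwidth: unit within-cluster RMS distance
    d2 = ((z[:, None, :] - cs0.centers[None, :, :]) ** 2).sum(axis=2)
    sigma = float(np.sqrt(max(d2.min(axis=1).mean(), 1e-30)))
    cs = ClusterState(cs0.centers / sigma, alpha=cs0.alpha, scale=sigma)
    center_grad = np.zeros_like(cs.centers)
    opt = cae.make_optimizer(tc.learning_rate)
    opt.pairs.append((cs.centers, center_grad))
    opt.m.append(np.zeros_like(cs.centers))
    opt.v.append(np.zeros_like(cs.centers))

    q = soft_assign(z, cs)
    prev_labels = q.argmax(axis=1)
    p = target_distribution(q)
    history: dict = {"total_loss": [], "recon_loss": [], "cluster_loss": [], "label_change": []}
    stop_reason = "max_epochs"
    for epoch in range(tc.max_joint_epochs):
        order = rng.permutation(len(x))
        rl, cl = [], []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i : i + tc.batch_size]
            xb = x[idx]
            zb, xhat = cae.forward(xb)
            zb64 = zb.astype(np.float64)
            diff = xhat - xb
            rl.append(float(np.mean(diff.astype(np.float64) ** 2)))
            qb = soft_assign(zb64, cs)
            cl.append(clustering_loss(qb, p[idx]))
            dz, dmu = clustering_gradients(zb64, cs, p[idx])
            if (qb.sum(axis=0) <= _Q_FLOOR).any():
                warnings.warn("empty cluster in batch; continuing", stacklevel=2)
            center_grad[...] = tc.gamma * dmu
            cae.backward(
                (2.0 / diff.size) * diff,
                d_latent=(tc.gamma * dz).astype(np.float32),
            )
            opt.step()
        z, q = _encode_and_assign(cae, x, cs)
        labels = q.argmax(axis=1)
        changed = float(np.mean(labels != prev_labels))
        history["recon_loss"].append(float(np.mean(rl)))
        history["cluster_loss"].append(float(np.mean(cl)))
        history["total_loss"].append(history["recon_loss"][-1] + tc.gamma * history["cluster_loss"][-1])
        history["label_change"].append(changed)
        prev_labels = labels
        if changed < tc.label_change_tol:
            stop_reason = "label_change_below_tol"
            break
        if (epoch + 1) % tc.target_update_interval == 0:
            p = target_distribution(q)
    history["stop_reason"] = stop_reason
    history["epochs"] = len(history["total_loss"])
    return TrainResult(prev_labels, q, cae, cs, history, stop_reason)


def cae_kmeans(cae: CAE, ps: PatchSet, k: int, seed: int = 0) -> np.ndarray:
    """Non-end-to-end variant: k-means on the concatenated latents."""
    z = cae.encode_array(ps.patches).astype(np.float64)
    if k == 1:
        return np.zeros(len(z), dtype=np.int64)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
    return km.labels_.astype(np.int64)
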