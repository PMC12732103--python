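"""Stage-1 self-supervised objectives.

Loss stack for multimodal pretraining: intra-modal InfoNCE over augmented
views (with an optional momentum FIFO queue of negatives), symmetric
cross-modal InfoNCE over co-registered MRI-PET pairs, longitudinal
consistency within modality, cross-time cross-modal coupling, a BYOL-style
predictor regression with a stop-gradient target, and a domain-adversarial
site term routed through a gradient-reversal layer.  The overall objective
is the non-negatively weighted sum of the six components.

Conventions: InfoNCE terms average over anchors; the candidate set of each
anchor contains its own positive, every other anchor's positive and the
queue, so the loss is non-negative and equals ln(C) when all similarities
coincide.  Longitudinal sums count unordered visit pairs once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, grad_reverse
from .nn import Module

__all__ = [
    "SSLWeights", "MomentumQueue", "SSLLossReport",
    "intra_modal_infonce", "cross_modal_infonce",
    "longitudinal_consistency", "cross_time_cross_modal",
    "byol_loss", "site_adversarial_loss", "total_ssl_loss",
    "queue_update", "momentum_update",
]


@dataclass(frozen=True)
class SSLWeights:
    """Non-negative component weights, softmax temperature and GRL strength."""

    intra: float = 1.0
    cross: float = 1.0
    byol: float = 0.5
    long: float = 0.1
    long_x: float = 0.1
    site: float = 1.0
    tau: float = 0.1
    grl_strength: float = 2.0

    def validate(self) -> None:
        for name in ("intra", "cross", "byol", "long", "long_x", "site"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.grl_strength < 0:
            raise ValueError("grl_strength must be non-negative")


@dataclass
class SSLLossReport:
    components: dict[str, float]
    total: float


class MomentumQueue:
    """FIFO ring buffer of unit-norm negative keys."""

    def __init__(self, capacity: int, dim: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.dim = dim
        self._buf = np.zeros((0, dim))

    def __len__(self) -> int:
        return self._buf.shape[0]

    def as_array(self) -> np.ndarray:
        return self._buf.copy()

    def enqueue(self, keys: np.ndarray) -> None:
        keys = np.asarray(keys, dtype=np.float64)
        if keys.ndim == 1:
            keys = keys[None, :]
        _check_unit(keys, "queue keys")
        self._buf = np.concatenate([self._buf, keys], axis=0)
        if len(self._buf) > self.capacity:
            self._buf = self._buf[-self.capacity:]


def queue_update(queue: MomentumQueue, new_keys: np.ndarray) -> MomentumQueue:
    queue.enqueue(new_keys)
    return queue


def momentum_update(key_module: Module, online_module: Module, m: float) -> Module:
    """key <- m * key + (1 - m) * online, parameter-wise."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("momentum coefficient must be in [0, 1]")
    key_params = dict(key_module.named_parameters())
    online_params = dict(online_module.named_parameters())
    if set(key_params) != set(online_params):
        raise ValueError("parameter sets differ between key and online modules")
    for name, p in key_params.items():
        p.data = m * p.data + (1.0 - m) * online_params[name].data
    return key_module


def _check_unit(z: np.ndarray, what: str, atol: float = 1e-3) -> None:
    norms = np.linalg.norm(z, axis=-1)
    if z.shape[-1] > 0 and np.any(np.abs(norms - 1.0) > atol):
        raise ValueError(f"{what} must be unit-norm (max deviation "
                         f"{np.abs(norms - 1.0).max():.2e})")


def _directional_infonce(anchors: Tensor, candidates: Tensor, pos_index: np.ndarray,
                         tau: float) -> Tensor:
    logits = (anchors @ candidates.transpose((1, 0))) * (1.0 / tau)
    lse = logits.logsumexp(axis=1)
    n = anchors.shape[0]
    pos = logits[np.arange(n), pos_index]
    return (lse - pos).mean()


def intra_modal_infonce(anchors, positives, queue: MomentumQueue | None = None,
                        tau: float = 0.1) -> Tensor:
    """InfoNCE over augmented views within one modality.

    Anchor i's positive is ``positives[i]``; its candidate set is the whole
    positive batch plus the queue, so with C candidates and all similarities
    equal the loss is exactly ln C.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    anchors, positives = as_tensor(anchors), as_tensor(positives)
    if anchors.shape != positives.shape:
        raise ValueError("anchors and positives must be aligned")
    _check_unit(anchors.data, "anchors")
    _check_unit(positives.data, "positives")
    cands = positives
    if queue is not None and len(queue) > 0:
        cands = concatenate([positives, Tensor(queue.as_array())], axis=0)
    return _directional_infonce(anchors, cands, np.arange(anchors.shape[0]), tau)


def cross_modal_infonce(z_mri, z_pet, queue_mri: MomentumQueue | None = None,
                        queue_pet: MomentumQueue | None = None,
                        tau: float = 0.1) -> Tensor:
    """Symmetric InfoNCE with MRI and PET alternating as anchors.

    The MRI->PET direction scores each MRI anchor against the paired PET
    batch plus the PET queue (and vice versa); the total is the sum of the
    two directional means, hence invariant to swapping the modality roles
    when the queues are swapped accordingly.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    z_mri, z_pet = as_tensor(z_mri), as_tensor(z_pet)
    if z_mri.shape != z_pet.shape:
        raise ValueError("cross-modal batches must be paired (same shape)")
    _check_unit(z_mri.data, "MRI embeddings")
    _check_unit(z_pet.data, "PET embeddings")
    n = z_mri.shape[0]
    idx = np.arange(n)
    cand_pet = z_pet
    if queue_pet is not None and len(queue_pet) > 0:
        cand_pet = concatenate([z_pet, Tensor(queue_pet.as_array())], axis=0)
    cand_mri = z_mri
    if queue_mri is not None and len(queue_mri) > 0:
        cand_mri = concatenate([z_mri, Tensor(queue_mri.as_array())], axis=0)
    return (_directional_infonce(z_mri, cand_pet, idx, tau)
            + _directional_infonce(z_pet, cand_mri, idx, tau))


def _pair_sum(Z: Tensor, idx_a: np.ndarray, idx_b: np.ndarray, reduction: str) -> Tensor:
    if len(idx_a) == 0:
        return Tensor(0.0)
    diff = Z[idx_a] - Z[idx_b]
    total = (diff**2).sum()
    if reduction == "mean":
        return total / len(idx_a)
    return total


def longitudinal_consistency(Z, subjects, modalities, visit_times,
                             reduction: str = "sum") -> Tensor:
    """Sum of squared embedding distances over a subject's visit pairs.

    Pairs are unordered (each counted once) within (subject, modality);
    subjects with fewer than two visits of a modality contribute nothing.
    """
    Z = as_tensor(Z)
    subjects = np.asarray(subjects)
    modalities = np.asarray(modalities)
    visit_times = np.asarray(visit_times, dtype=float)
    ia, ib = [], []
    for key in set(zip(subjects.tolist(), modalities.tolist())):
        members = np.nonzero((subjects == key[0]) & (modalities == key[1]))[0]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if visit_times[members[a]] != visit_times[members[b]]:
                    ia.append(members[a])
                    ib.append(members[b])
    return _pair_sum(Z, np.asarray(ia, dtype=int), np.asarray(ib, dtype=int), reduction)


def cross_time_cross_modal(Z, subjects, modalities, visit_times,
                           reduction: str = "sum") -> Tensor:
    """Couple a subject's MRI at one visit to its PET at a different visit."""
    Z = as_tensor(Z)
    subjects = np.asarray(subjects)
    modalities = np.asarray(modalities)
    visit_times = np.asarray(visit_times, dtype=float)
    ia, ib = [], []
    for p in set(subjects.tolist()):
        mri = np.nonzero((subjects == p) & (modalities == "MRI"))[0]
        pet = np.nonzero((subjects == p) & (modalities == "PET"))[0]
        for a in mri:
            for b in pet:
                if visit_times[a] != visit_times[b]:
                    ia.append(a)
                    ib.append(b)
    return _pair_sum(Z, np.asarray(ia, dtype=int), np.asarray(ib, dtype=int), reduction)


def byol_loss(online, target, predictor: Module) -> Tensor:
    """Mean squared error between q(online) and the stop-gradient target.

    The target branch is detached, so its parameters receive exactly zero
    gradient from this loss.
    """
    online, target = as_tensor(online), as_tensor(target)
    if online.shape != target.shape:
        raise ValueError("online and target batches must be aligned")
    pred = predictor(online)
    diff = pred - target.detach()
    return (diff**2).sum(axis=1).mean()


def site_adversarial_loss(Z, site_ids, discriminator: Module,
                          grl_strength: float = 1.0) -> Tensor:
    """Cross-entropy of the site discriminator on gradient-reversed embeddings.

    The discriminator parameters receive the ordinary CE gradient; the
    embedding (and everything upstream) receives the CE gradient negated and
    scaled by ``grl_strength``.
    """
    Z = as_tensor(Z)
    site_ids = np.asarray(site_ids, dtype=int)
    n_sites = discriminator.n_sites
    if site_ids.min() < 0 or site_ids.max() >= n_sites:
        bad = sorted(set(site_ids[(site_ids < 0) | (site_ids >= n_sites)].tolist()))
        raise ValueError(f"unknown site id(s) {bad} (discriminator has {n_sites} sites)")
    logits = discriminator(grad_reverse(Z, grl_strength))
    lse = logits.logsumexp(axis=1)
    n = Z.shape[0]
    true = logits[np.arange(n), site_ids]
    return (lse - true).mean()


_COMPONENT_ORDER = ("intra", "cross", "byol", "long", "long_x", "site")


def total_ssl_loss(components: dict, weights: SSLWeights) -> tuple[Tensor, SSLLossReport]:
    """Weighted sum of the pretraining components.

    ``components`` maps component names (subset of intra/cross/byol/long/
    long_x/site) to scalar losses (Tensor or float); missing components
    count as zero.
    """
    weights.validate()
    unknown = set(components) - set(_COMPONENT_ORDER)
    if unknown:
        raise ValueError(f"unknown loss components: {sorted(unknown)}")
    total = Tensor(0.0)
    values: dict[str, float] = {}
    for name in _COMPONENT_ORDER:
        if name in components:
            comp = as_tensor(components[name])
            values[name] = comp.item()
            total = total + getattr(weights, name) * comp
        else:
            values[name] = 0.0
    return total, SSLLossReport(components=values, total=total.item())
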