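"""Stage-2 multi-task heads: missing-aware gated fusion, class-weighted
diagnosis cross-entropy, Cox partial likelihood with Breslow ties,
PET-to-MRI distillation, post-hoc temperature scaling, and the joint
fine-tuning objective.

The fusion gate computes alpha = sigmoid(w^T [1_MRI, 1_PET] + b) from the
availability indicators alone; a missing modality's embedding block is the
zero vector, so the fused representation has fixed length 2d + q and the
model degrades gracefully to MRI-only inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import softmax as _softmax

from . import nn
from .autodiff import Tensor, as_tensor, concatenate

__all__ = [
    "FusionGate", "gated_fusion", "fuse_batch", "diagnosis_loss",
    "cox_partial_loglik", "distillation_loss", "TemperatureModel",
    "fit_temperature", "apply_temperature", "joint_finetune_loss",
    "inverse_frequency_weights",
]


class FusionGate(nn.Module):
    """Learned availability gate alpha = sigmoid(w^T [1_MRI, 1_PET] + b)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed + 303)
        self.w = nn.Parameter(rng.normal(0.0, 0.1, size=(2,)))
        self.b = nn.Parameter(np.zeros(1))

    def alpha(self, indicators) -> Tensor:
        ind = as_tensor(np.asarray(indicators, dtype=np.float64))
        return ((ind @ self.w.reshape(2, 1)) + self.b).sigmoid()


def fuse_batch(z_mri, z_pet, indicators, covariates, gate: FusionGate) -> Tensor:
    """Batched gated late fusion.

    ``z_mri`` / ``z_pet`` are (N, d) with zero rows where the modality is
    absent; ``indicators`` is (N, 2) of {0,1}; ``covariates`` is (N, q).
    Returns e = [alpha*z_MRI || (1-alpha)*z_PET || c] of width 2d + q.
    """
    z_mri, z_pet = as_tensor(z_mri), as_tensor(z_pet)
    ind = np.asarray(indicators, dtype=np.float64)
    if ind.ndim != 2 or ind.shape[1] != 2:
        raise ValueError("indicators must be (N, 2)")
    if np.any(ind.sum(axis=1) < 1):
        raise ValueError("at least one modality must be present per sample")
    # zero-imputation contract: absent blocks are exactly zero
    z_mri = z_mri * Tensor(ind[:, :1])
    z_pet = z_pet * Tensor(ind[:, 1:])
    alpha = gate.alpha(ind)          # (N, 1), from indicators only
    parts = [z_mri * alpha, z_pet * (1.0 - alpha)]
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.size:
        parts.append(as_tensor(cov))
    return concatenate(parts, axis=1)


def gated_fusion(z_mri, z_pet, indicators, covariates, gate: FusionGate) -> Tensor:
    """Single-sample convenience wrapper; ``None`` marks an absent modality."""
    ind = np.asarray(indicators, dtype=np.float64).reshape(1, 2)
    d = len(z_mri) if z_mri is not None else (len(z_pet) if z_pet is not None else 0)
    if d == 0:
        raise ValueError("at least one modality must be present")
    zm = np.zeros(d) if z_mri is None else np.asarray(z_mri, dtype=np.float64)
    zp = np.zeros(d) if z_pet is None else np.asarray(z_pet, dtype=np.float64)
    cov = np.asarray(covariates, dtype=np.float64).reshape(1, -1)
    return fuse_batch(Tensor(zm[None, :]), Tensor(zp[None, :]), ind, cov, gate)[0]


def inverse_frequency_weights(labels, n_classes: int) -> np.ndarray:
    """Inverse-class-frequency weights normalized to mean 1."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    w = 1.0 / counts
    return w * n_classes / w.sum()


def diagnosis_loss(logits, labels, class_weights=None) -> Tensor:
    """Class-weighted cross-entropy: -(1/N) sum_n w_{y_n} log softmax(l_n)_{y_n}."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label out of range")
    if class_weights is None:
        class_weights = np.ones(k)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if np.any(class_weights <= 0):
        raise ValueError("class weights must be positive")
    lse = logits.logsumexp(axis=1)
    true = logits[np.arange(n), labels]
    w = Tensor(class_weights[labels])
    return ((lse - true) * w).sum() / n


def cox_partial_loglik(risks, times, events) -> Tensor:
    """Negative Cox partial log-likelihood with Breslow handling of ties.

    Risk sets are {j : T_j >= T_n}; censored subjects appear in risk sets
    only.  With no events the loss is defined as 0 (with a warning).
    """
    risks = as_tensor(risks)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if risks.shape[0] != len(times) or len(times) != len(events):
        raise ValueError("risks, times and events must be aligned")
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        warnings.warn("no events: Cox partial likelihood is vacuous", stacklevel=2)
        return Tensor(0.0)
    shift = float(risks.data.max())  # constant; keeps exp() stable
    exp_r = (risks - shift).exp()
    loss = Tensor(0.0)
    for t in event_times:
        dead = np.nonzero((times == t) & (events == 1))[0]
        at_risk = np.nonzero(times >= t)[0]
        lse = exp_r[at_risk].sum().log() + shift
        loss = loss + len(dead) * lse - risks[dead].sum()
    return loss


def distillation_loss(z_mri, z_pet, pet_indicators) -> Tensor:
    """(1/N) sum_n 1_PET,n ||z_n^MRI - sg(z_n^PET)||^2.

    The PET branch is a stop-gradient teacher; visits without PET
    contribute zero but still count in N.
    """
    z_mri, z_pet = as_tensor(z_mri), as_tensor(z_pet)
    if z_mri.shape != z_pet.shape:
        raise ValueError("batches must be aligned")
    ind = np.asarray(pet_indicators, dtype=np.float64)
    n = z_mri.shape[0]
    diff = z_mri - z_pet.detach()
    per = (diff**2).sum(axis=1) * Tensor(ind)
    return per.sum() / n


@dataclass
class TemperatureModel:
    T: float

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")


def fit_temperature(logits: np.ndarray, labels: np.ndarray) -> TemperatureModel:
    """Fit T minimizing validation NLL of softmax(logits / T).

    One-dimensional bounded minimization over log T; the encoder and heads
    are untouched (this operates on cached logits only).
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if logits.ndim != 2 or len(labels) != logits.shape[0] or len(labels) == 0:
        raise ValueError("need a nonempty aligned validation set")
    if len(np.unique(labels)) < 2:
        raise ValueError("validation set must contain more than one class")

    def nll(log_t: float) -> float:
        t = np.exp(log_t)
        z = logits / t
        lse = np.logaddexp.reduce(z, axis=1)
        return float(np.mean(lse - z[np.arange(len(labels)), labels]))

    res = minimize_scalar(nll, bounds=(np.log(0.05), np.log(20.0)), method="bounded",
                          options={"xatol": 1e-6})
    return TemperatureModel(T=float(np.exp(res.x)))


def apply_temperature(logits: np.ndarray, T: float) -> np.ndarray:
    """Calibrated probabilities softmax(logits / T); T=1 is the plain softmax."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return _softmax(np.asarray(logits, dtype=np.float64) / T, axis=-1)


def joint_finetune_loss(l_diag, l_cox, l_distill, coef_diag: float = 1.0,
                        coef_cox: float = 1.0, coef_distill: float = 0.5) -> Tensor:
    """Weighted fine-tuning objective: a*L_diag + b*L_cox + g*L_distill."""
    for c in (coef_diag, coef_cox, coef_distill):
        if c < 0:
            raise ValueError("coefficients must be non-negative")
    return (coef_diag * as_tensor(l_diag) + coef_cox * as_tensor(l_cox)
            + coef_distill * as_tensor(l_distill))
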