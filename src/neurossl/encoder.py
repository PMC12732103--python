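"""Modality-specific 3D encoders with projection heads.

The backbone is a small configurable 3D residual CNN: a convolutional stem,
then one residual block per stage followed by 2x average-pool downsampling,
global average pooling and a Norm-ReLU-Linear projection head whose output
is l2-normalized.  GroupNorm is the default normalization; DSBN keeps
per-site normalization statistics and requires the site id at forward time.
MRI and PET get disjoint parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor

__all__ = ["EncoderSpec", "VolumeEncoder", "ModalityEncoders", "Embedding",
           "Predictor", "SiteDiscriminator", "embed_batch"]

MODALITIES = ("MRI", "PET")


@dataclass(frozen=True)
class EncoderSpec:
    widths: tuple[int, ...] = (16, 32, 64)
    embed_dim: int = 32
    norm: str = "group"                  # "group" or "dsbn"
    groups: int = 4
    n_sites: int | None = None           # required for DSBN
    seed: int = 0

    def validate(self) -> None:
        if self.norm not in ("group", "dsbn"):
            raise ValueError("norm must be 'group' or 'dsbn'")
        if self.norm == "dsbn" and not self.n_sites:
            raise ValueError("DSBN requires n_sites")
        for w in self.widths:
            if w % self.groups:
                raise ValueError("stage widths must be divisible by the group count")


@dataclass
class Embedding:
    """Unit-norm d-vector with its provenance annotations."""

    z: np.ndarray
    modality: str
    subject_id: int
    visit_time: float
    site_id: int


class _Norm(nn.Module):
    def __init__(self, spec: EncoderSpec, channels: int):
        self.kind = spec.norm
        if spec.norm == "group":
            self.norm = nn.GroupNorm(spec.groups, channels)
        else:
            self.norm = nn.DSBN(channels, spec.n_sites)

    def forward(self, x, sites=None):
        if self.kind == "dsbn":
            if sites is None:
                raise ValueError("DSBN normalization requires site ids at forward time")
            return self.norm(x, sites)
        return self.norm(x)


class _ResBlock(nn.Module):
    def __init__(self, spec: EncoderSpec, c_in: int, c_out: int, rng):
        self.conv1 = nn.Conv3d(c_in, c_out, rng)
        self.n1 = _Norm(spec, c_out)
        self.conv2 = nn.Conv3d(c_out, c_out, rng)
        self.n2 = _Norm(spec, c_out)
        self.proj = nn.Conv3d(c_in, c_out, rng, k=1) if c_in != c_out else None

    def forward(self, x, sites=None):
        h = self.n1(self.conv1(x), sites).relu()
        h = self.n2(self.conv2(h), sites)
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class VolumeEncoder(nn.Module):
    """Residual CNN + projection head mapping a volume batch to unit vectors."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        spec.validate()
        w = spec.widths
        self.stem = nn.Conv3d(1, w[0], rng)
        self.stem_norm = _Norm(spec, w[0])
        self.blocks = [
            _ResBlock(spec, w[i - 1] if i else w[0], w[i], rng) for i in range(len(w))
        ]
        self.head_norm = nn.LayerNorm(w[-1])
        self.head = nn.Linear(w[-1], spec.embed_dim, rng)
        self.spec = spec

    def forward(self, x, sites=None) -> Tensor:
        """x: (B, D, H, W) or (B, 1, D, H, W) array/Tensor -> (B, d), unit rows."""
        x = as_tensor(x)
        if x.ndim == 4:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        h = self.stem_norm(self.stem(x), sites).relu()
        for blk in self.blocks:
            h = blk(h, sites)
            h = nn.avg_pool3d(h, 2)
        feat = nn.global_avg_pool3d(h)
        proj = self.head(self.head_norm(feat).relu())
        return nn.l2_normalize(proj)


class ModalityEncoders(nn.Module):
    """Disjoint parameter sets per modality, sharing one architecture spec.

    Carries the input normalization fitted on the training set (per-modality
    mean volume and a global rescaling): raw scanner-unit volumes are almost
    entirely a shared anatomical pattern, and subtracting the cohort mean
    before encoding puts the informative deviations on an O(1) scale.
    """

    def __init__(self, spec: EncoderSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoders = {m: VolumeEncoder(spec, rng) for m in MODALITIES}
        self.input_center: dict[str, np.ndarray | None] = {m: None for m in MODALITIES}
        self.input_scale: float = 0.01

    def set_input_stats(self, center: dict[str, np.ndarray], scale: float) -> None:
        self.input_center.update(center)
        self.input_scale = float(scale)

    def fit_input_stats(self, volumes) -> None:
        """Per-modality mean volume and 1/SD of the centered residuals."""
        by_mod: dict[str, list[np.ndarray]] = {}
        for v in volumes:
            by_mod.setdefault(v.modality, []).append(np.asarray(v.data, dtype=np.float64))
        resid_var, n_tot = 0.0, 0
        for m, arrs in by_mod.items():
            stackmean = np.mean(arrs, axis=0)
            self.input_center[m] = stackmean
            for a in arrs:
                resid_var += ((a - stackmean) ** 2).sum()
                n_tot += a.size
        sd = np.sqrt(resid_var / max(n_tot, 1))
        self.input_scale = 1.0 / max(sd, 1e-8)

    def _normalize_input(self, x, modality: str):
        x = as_tensor(x)
        center = self.input_center.get(modality)
        if center is not None and tuple(x.shape[-3:]) == center.shape:
            x = x - Tensor(center)
        return x * self.input_scale

    def forward(self, x, modality: str, sites=None) -> Tensor:
        if modality not in self.encoders:
            raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
        return self.encoders[modality](self._normalize_input(x, modality), sites)


def embed_batch(model: ModalityEncoders, volumes, normalize_fn=None,
                chunk: int = 16) -> list[Embedding]:
    """Encode a list of Volumes into annotated embeddings (inference mode,
    chunked to bound memory)."""
    from .autodiff import no_grad

    out: list[Embedding] = []
    by_mod: dict[str, list] = {}
    for i, v in enumerate(volumes):
        by_mod.setdefault(v.modality, []).append(i)
    zs: dict[int, np.ndarray] = {}
    for mod, idxs in by_mod.items():
        arrs, sites = [], []
        for i in idxs:
            v = volumes[i]
            v = normalize_fn(v) if normalize_fn is not None else v
            arrs.append(np.asarray(v.data, dtype=np.float64))
            sites.append(v.site_id)
        with no_grad():
            for lo in range(0, len(idxs), chunk):
                Z = model(np.stack(arrs[lo:lo + chunk]), mod,
                          sites=np.asarray(sites[lo:lo + chunk])).data
                for i, z in zip(idxs[lo:lo + chunk], Z):
                    zs[i] = z
    for i, v in enumerate(volumes):
        out.append(Embedding(z=zs[i], modality=v.modality, subject_id=v.subject_id,
                             visit_time=v.visit_time, site_id=v.site_id))
    return out


class Predictor(nn.Module):
    """BYOL predictor q: a small MLP on the online embedding."""

    def __init__(self, dim: int, hidden: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed + 101)
        hidden = hidden or 2 * dim
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, z) -> Tensor:
        return self.fc2(self.fc1(z).relu())


class SiteDiscriminator(nn.Module):
    """Softmax site classifier on batch-standardized embeddings.

    Per-feature batch standardization in front of the linear layer lets the
    discriminator exploit low-variance embedding directions — otherwise the
    adversary would be systematically weaker than any post-hoc probe fitted
    with feature scaling, and the encoder would never be pressed to remove
    site information hidden in small components.
    """

    def __init__(self, dim: int, n_sites: int, seed: int = 0, eps: float = 1e-6):
        rng = np.random.default_rng(seed + 202)
        self.fc = nn.Linear(dim, n_sites, rng)
        self.n_sites = n_sites
        self.eps = eps

    def forward(self, z) -> Tensor:
        z = as_tensor(z)
        if z.shape[0] > 1:
            mu = z.mean(axis=0, keepdims=True)
            var = ((z - mu) ** 2).mean(axis=0, keepdims=True)
            z = (z - mu) * ((var + self.eps) ** -0.5)
        return self.fc(z)
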