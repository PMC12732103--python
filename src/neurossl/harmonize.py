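"""Offline intensity normalization and multi-site harmonization.

The pipeline order is fixed: per-volume z-score (MRI) or SUVR scaling (PET),
then histogram matching of each volume's within-mask distribution to a
cohort-level reference template, then ComBat on derived feature vectors with
site as the batch variable and age/sex as preserved biological covariates.
The same fitted transforms are applied to every timepoint of a subject, so
harmonization cannot introduce artificial longitudinal change.

ComBat follows the canonical parametric empirical-Bayes location/scale
formulation: feature-wise site means (gamma) are shrunk toward a normal
prior and site variances (delta^2) toward an inverse-gamma prior, with
method-of-moments hyperparameters and the usual iterative conditional-mode
solution for the posterior estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Volume

__all__ = [
    "zscore_volume",
    "suvr_normalize",
    "ReferenceTemplate",
    "build_reference_template",
    "histogram_match",
    "CombatModel",
    "combat_fit",
    "combat_apply",
    "site_drift_report",
]


class DegenerateInputError(ValueError):
    pass


def zscore_volume(v: Volume) -> Volume:
    """Within-mask z-score; voxels outside the mask are set to zero."""
    vals = v.data[v.mask]
    sd = vals.std()
    if sd <= 0:
        raise DegenerateInputError("constant volume: within-mask standard deviation is 0")
    out = np.zeros_like(v.data)
    out[v.mask] = (vals - vals.mean()) / sd
    return replace(v, data=out)


def suvr_normalize(pet: Volume, reference_mask: np.ndarray) -> Volume:
    """Divide by the mean intensity in the reference region (SUVR scaling)."""
    if reference_mask.shape != pet.data.shape:
        raise ValueError("reference mask shape mismatch")
    ref = reference_mask & pet.mask
    if not ref.any():
        raise DegenerateInputError("reference mask is empty or disjoint from the brain mask")
    ref_mean = pet.data[ref].mean()
    if ref_mean <= 0:
        raise DegenerateInputError("non-positive reference-region mean")
    return replace(pet, data=pet.data / ref_mean)


# ---------------------------------------------------------------------------
# histogram matching
# ---------------------------------------------------------------------------

N_QUANTILE_KNOTS = 101


@dataclass
class ReferenceTemplate:
    """Within-mask intensity quantiles of a reference cohort, per modality."""

    probabilities: np.ndarray
    values: np.ndarray
    modality: str

    def validate(self) -> None:
        p = self.probabilities
        if not (np.all(np.diff(p) > 0) and p[0] >= 0 and p[-1] <= 1):
            raise ValueError("probabilities must be strictly increasing in [0, 1]")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("template values must be non-decreasing")

    def to_json(self) -> str:
        return json.dumps({
            "probabilities": self.probabilities.tolist(),
            "values": self.values.tolist(),
            "modality": self.modality,
        })

    @classmethod
    def from_json(cls, s: str) -> "ReferenceTemplate":
        d = json.loads(s)
        t = cls(np.asarray(d["probabilities"]), np.asarray(d["values"]), d["modality"])
        t.validate()
        return t


def build_reference_template(volumes: list[Volume]) -> ReferenceTemplate:
    """Average within-mask quantile functions across the reference volumes."""
    if not volumes:
        raise ValueError("no volumes supplied")
    modality = volumes[0].modality
    if any(v.modality != modality for v in volumes):
        raise ValueError("template volumes must share one modality")
    probs = np.linspace(0.0, 1.0, N_QUANTILE_KNOTS)
    qs = []
    for v in volumes:
        if not v.mask.any():
            raise DegenerateInputError("empty mask in template volume")
        qs.append(np.quantile(v.data[v.mask], probs))
    t = ReferenceTemplate(probs, np.mean(qs, axis=0), modality)
    t.validate()
    return t


def histogram_match(v: Volume, template: ReferenceTemplate) -> Volume:
    """Monotone piecewise-linear quantile transfer to the template.

    Each within-mask intensity is mapped through the transfer function that
    sends the volume's own quantiles onto the template's; the map is
    monotone, so the voxel ranking (subject-level structure) is preserved,
    and values beyond the volume's quantile range clamp to the template
    extremes.
    """
    if v.modality != template.modality:
        raise ValueError(f"modality mismatch: volume {v.modality}, template {template.modality}")
    if not v.mask.any():
        raise DegenerateInputError("empty mask")
    vals = v.data[v.mask]
    src_q = np.quantile(vals, template.probabilities)
    out = np.zeros_like(v.data)
    out[v.mask] = np.interp(vals, src_q, template.values)
    return replace(v, data=out)


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


@dataclass
class CombatModel:
    sites: list
    alpha: np.ndarray            # feature-wise grand mean (p,)
    beta: np.ndarray             # covariate coefficients (q, p)
    gamma_star: np.ndarray       # EB site additive effects (S, p)
    delta_star: np.ndarray       # EB site variance factors (S, p), > 0
    sigma: np.ndarray            # pooled feature SD (p,)

    def to_json(self) -> str:
        d = {k: (v if isinstance(v, list) else np.asarray(v).tolist())
             for k, v in dataclasses.asdict(self).items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CombatModel":
        d = json.loads(s)
        return cls(
            sites=d["sites"], alpha=np.asarray(d["alpha"]), beta=np.asarray(d["beta"]),
            gamma_star=np.asarray(d["gamma_star"]), delta_star=np.asarray(d["delta_star"]),
            sigma=np.asarray(d["sigma"]),
        )


def _eb_site_estimates(Z: np.ndarray, batch_idx: list[np.ndarray]):
    """Iterative parametric empirical-Bayes estimates per site.

    Z is the standardized data (n, p); returns gamma_star, delta_star (S, p).
    """
    S, p = len(batch_idx), Z.shape[1]
    gamma_hat = np.stack([Z[idx].mean(axis=0) for idx in batch_idx])
    delta_hat = np.stack([
        Z[idx].var(axis=0, ddof=1) if len(idx) > 1 else np.ones(p) for idx in batch_idx
    ])
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for s in range(S):
        n_b = len(batch_idx[s])
        g_hat, d_hat = gamma_hat[s], delta_hat[s]
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1) if p > 1 else 0.0
        m, v = d_hat.mean(), d_hat.var(ddof=1) if p > 1 else 0.0
        if t2 < 1e-12 or v < 1e-12:
            # prior degenerate (e.g., features i.i.d. identical): no shrinkage
            gamma_star[s], delta_star[s] = g_hat, d_hat
            continue
        a_prior = (2 * v + m**2) / v
        b_prior = (m * v + m**3) / v
        g_old, d_old = g_hat.copy(), d_hat.copy()
        Zs = Z[batch_idx[s]]
        for _ in range(200):
            g_new = (n_b * t2 * g_hat + d_old * g_bar) / (n_b * t2 + d_old)
            ssd = ((Zs - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * ssd + b_prior) / (n_b / 2.0 + a_prior - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            if change < 1e-10:
                break
        gamma_star[s], delta_star[s] = g_old, d_old
    return gamma_hat, delta_hat, gamma_star, delta_star


def combat_fit(features: np.ndarray, site_labels, covariates: np.ndarray | None = None) -> CombatModel:
    """Fit the location/scale site-effect model on (n_samples, n_features).

    ``covariates`` (n, q), e.g. age and sex, are protected: their fitted
    effects are excluded from the site adjustment and restored on output.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (samples x features)")
    site_labels = np.asarray(site_labels)
    if len(site_labels) != X.shape[0]:
        raise ValueError("site label length mismatch")
    sites = sorted(pd.unique(site_labels).tolist())
    batch_idx = [np.nonzero(site_labels == s)[0] for s in sites]
    for s, idx in zip(sites, batch_idx):
        if len(idx) < 2:
            raise ValueError(f"site {s!r} has fewer than 2 samples")
    n, p = X.shape
    S = len(sites)
    B = np.zeros((n, S))
    for j, idx in enumerate(batch_idx):
        B[idx, j] = 1.0
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        D = np.hstack([B, C])
    else:
        C = np.zeros((n, 0))
        D = B
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    site_coef, beta = coef[:S], coef[S:]
    sizes = np.array([len(i) for i in batch_idx], dtype=float)
    alpha = (sizes / n) @ site_coef
    fitted = B @ site_coef + C @ beta
    sigma = np.sqrt(((X - fitted) ** 2).mean(axis=0))
    sigma = np.maximum(sigma, 1e-12)
    stand_mean = alpha[None, :] + C @ beta
    Z = (X - stand_mean) / sigma[None, :]
    _, _, gamma_star, delta_star = _eb_site_estimates(Z, batch_idx)
    return CombatModel(sites=sites, alpha=alpha, beta=beta,
                       gamma_star=gamma_star, delta_star=np.maximum(delta_star, 1e-12),
                       sigma=sigma)


def combat_apply(model: CombatModel, features: np.ndarray, site_labels,
                 covariates: np.ndarray | None = None) -> np.ndarray:
    """Remove the fitted site effects; covariate effects are restored.

    A model fitted on a single site is an identity by construction (there is
    nothing to remove).
    """
    X = np.asarray(features, dtype=np.float64)
    site_labels = np.asarray(site_labels)
    if len(site_labels) != X.shape[0]:
        raise ValueError("site label length mismatch")
    if len(model.sites) == 1:
        if not np.all(site_labels == model.sites[0]):
            unseen = sorted(set(site_labels.tolist()) - set(model.sites))
            raise ValueError(f"unseen site(s) at apply time: {unseen}")
        return X.copy()
    unseen = sorted(set(site_labels.tolist()) - set(model.sites))
    if unseen:
        raise ValueError(f"unseen site(s) at apply time: {unseen}")
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.zeros((X.shape[0], 0))
    stand_mean = model.alpha[None, :] + C @ model.beta
    Z = (X - stand_mean) / model.sigma[None, :]
    out = np.empty_like(Z)
    site_pos = {s: j for j, s in enumerate(model.sites)}
    for s in pd.unique(site_labels):
        idx = np.nonzero(site_labels == s)[0]
        j = site_pos[s]
        out[idx] = (Z[idx] - model.gamma_star[j][None, :]) / np.sqrt(model.delta_star[j])[None, :]
    return out * model.sigma[None, :] + stand_mean


# ---------------------------------------------------------------------------
# site drift report
# ---------------------------------------------------------------------------


@dataclass
class DriftReport:
    per_site: pd.DataFrame       # site, stage, mean, sd, n
    drift_pre: float             # between-site variance of volume means
    drift_post: float

    @property
    def ratio(self) -> float:
        if self.drift_pre == 0:
            return 1.0 if self.drift_post == 0 else np.inf
        return self.drift_post / self.drift_pre


def _between_site_variance(vol_means: np.ndarray, site_labels: np.ndarray) -> float:
    site_means = [vol_means[site_labels == s].mean() for s in np.unique(site_labels)]
    return float(np.var(site_means))


def site_drift_report(volumes_pre: list[Volume], volumes_post: list[Volume],
                      site_labels) -> DriftReport:
    """Between-site intensity drift before vs after harmonization.

    The scalar drift statistic at each stage is the between-site variance of
    per-volume within-mask means.
    """
    site_labels = np.asarray(site_labels)
    if not (len(volumes_pre) == len(volumes_post) == len(site_labels)):
        raise ValueError("volume lists and site labels must have matching lengths")
    means_pre = np.array([v.data[v.mask].mean() for v in volumes_pre])
    means_post = np.array([v.data[v.mask].mean() for v in volumes_post])
    rows = []
    for stage, means in (("pre", means_pre), ("post", means_post)):
        for s in np.unique(site_labels):
            m = means[site_labels == s]
            rows.append({"site": s, "stage": stage, "mean": m.mean(),
                         "sd": m.std(ddof=1) if len(m) > 1 else 0.0, "n": len(m)})
    return DriftReport(
        per_site=pd.DataFrame(rows),
        drift_pre=_between_site_variance(means_pre, site_labels),
        drift_post=_between_site_variance(means_post, site_labels),
    )


def plot_site_histograms(volumes_pre, volumes_post, site_labels, path) -> None:
    """Write pre/post within-mask intensity histograms per site as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    site_labels = np.asarray(site_labels)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, vols, title in zip(axes, (volumes_pre, volumes_post), ("pre", "post")):
        for s in np.unique(site_labels):
            vals = np.concatenate([v.data[v.mask] for v, lab in zip(vols, site_labels) if lab == s])
            ax.hist(vals, bins=40, histtype="step", density=True, label=f"site {s}")
        ax.set_title(f"{title}-harmonization")
        ax.set_xlabel("intensity")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
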