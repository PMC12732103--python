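"""Reproducible experimental procedure: leakage-free subject-level splits,
the pretraining and fine-tuning loops, linear-probe checkpoint selection,
cross-cohort evaluation and the ablation runner.

All randomness flows from explicit seeds; two runs with identical configs
and seeds produce identical parameter trajectories (single-threaded NumPy).
Every stage that fits anything (SSL, fine-tuning, harmonization templates,
ComBat, temperature scaling) records the subject ids it saw, so the
no-leakage property of a cross-validation run can be audited
programmatically.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import fusion, harmonize, metrics, nn
from .augment import AugmentationPolicy, augment
from .autodiff import Tensor, concatenate, no_grad
from .cohort import Volume
from .encoder import EncoderSpec, ModalityEncoders, Predictor, SiteDiscriminator
from .ssl_losses import (MomentumQueue, SSLLossReport, SSLWeights, byol_loss,
                         cross_modal_infonce, cross_time_cross_modal,
                         intra_modal_infonce, longitudinal_consistency,
                         momentum_update, site_adversarial_loss, total_ssl_loss)

__all__ = [
    "SplitPlan", "make_splits", "linear_probe", "PretrainConfig", "pretrain",
    "FinetuneConfig", "FinetunedModel", "finetune", "predict", "evaluate",
    "VolumeHarmonizer", "run_cv", "cross_cohort_eval", "run_ablation",
    "save_checkpoint", "load_checkpoint",
]

CLASSES = ("CN", "MCI", "AD")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    fold_of: dict[int, int]
    k: int
    seed: int
    stratify_keys: tuple[str, ...]

    def test_subjects(self, fold: int) -> set[int]:
        return {s for s, f in self.fold_of.items() if f == fold}

    def train_subjects(self, fold: int) -> set[int]:
        return {s for s, f in self.fold_of.items() if f != fold}


def make_splits(table: pd.DataFrame, k: int = 5,
                stratify_keys: tuple[str, ...] = ("site_id", "diagnosis"),
                seed: int = 0) -> SplitPlan:
    """Subject-level stratified fold assignment.

    Subjects are grouped by their baseline stratum (site and baseline
    diagnosis by default), shuffled within stratum and dealt round-robin to
    folds, so every visit of a subject shares its fold and per-fold stratum
    proportions track the cohort's.
    """
    base = table.sort_values("visit_time_months").groupby("subject_id").first().reset_index()
    if k > len(base):
        raise ValueError(f"k={k} exceeds the {len(base)} subjects available")
    rng = np.random.default_rng(seed)
    fold_of: dict[int, int] = {}
    strata = base.groupby(list(stratify_keys)) if stratify_keys else [(None, base)]
    offset = 0
    for _, grp in strata:
        subs = grp["subject_id"].to_numpy()
        subs = subs[rng.permutation(len(subs))]
        for i, s in enumerate(subs):
            fold_of[int(s)] = (offset + i) % k
        offset += len(subs)
    return SplitPlan(fold_of=fold_of, k=k, seed=seed, stratify_keys=tuple(stratify_keys))


def linear_probe(embeddings: np.ndarray, labels, train_idx, val_idx,
                 C: float = 1.0, seed: int = 0) -> float:
    """Balanced accuracy of a logistic separator on frozen embeddings.

    The probe follows the standard linear-evaluation protocol: a plain
    logistic regression on the unit-norm embeddings, with fixed
    regularization and no per-feature rescaling.
    """
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("probe training set contains a single class")
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(X[train_idx], y[train_idx])
    return metrics.balanced_accuracy(y[val_idx], clf.predict(X[val_idx]))


# ---------------------------------------------------------------------------
# harmonization pipeline (fit on train only)
# ---------------------------------------------------------------------------


class VolumeHarmonizer:
    """Train-fold harmonization: z-score (MRI) / SUVR (PET), histogram
    matching to templates built from the fitting cohort, optional voxel-wise
    ComBat on the shared mask.  The fitted transforms are visit-independent,
    so all timepoints of a subject are treated identically."""

    def __init__(self, use_combat: bool = False, suvr_reference: np.ndarray | None = None):
        self.use_combat = use_combat
        self.suvr_reference = suvr_reference
        self.templates: dict[str, harmonize.ReferenceTemplate] = {}
        self.combat_models: dict[str, harmonize.CombatModel] = {}
        self.shared_mask: np.ndarray | None = None
        self.fit_subjects: set[int] = set()
        self.cov_map: dict[int, tuple[float, float]] = {}
        self.cov_mean: tuple[float, float] | None = None

    def _normalize(self, v: Volume) -> Volume:
        if v.modality == "MRI":
            return harmonize.zscore_volume(v)
        ref = self.suvr_reference if self.suvr_reference is not None else v.mask
        return harmonize.suvr_normalize(v, ref)

    def fit(self, volumes: list[Volume], table: pd.DataFrame | None = None) -> "VolumeHarmonizer":
        self.fit_subjects = {int(v.subject_id) for v in volumes}
        by_mod: dict[str, list[Volume]] = {}
        for v in volumes:
            by_mod.setdefault(v.modality, []).append(v)
        if table is not None:
            self.cov_map = {int(r.subject_id): (float(r.age), float(r.sex))
                            for r in table.itertuples()}
            vals = np.array(list(self.cov_map.values()))
            self.cov_mean = (float(vals[:, 0].mean()), float(vals[:, 1].mean()))
        for mod, vols in by_mod.items():
            normed = [self._normalize(v) for v in vols]
            self.templates[mod] = harmonize.build_reference_template(normed)
            matched = [harmonize.histogram_match(v, self.templates[mod]) for v in normed]
            if self.use_combat:
                mask = np.logical_and.reduce([v.mask for v in matched])
                self.shared_mask = mask
                feats = np.stack([v.data[mask] for v in matched])
                sites = np.array([v.site_id for v in matched])
                cov = None
                if self.cov_map:
                    cov = np.array([self.cov_map[int(v.subject_id)] for v in matched],
                                   dtype=float)
                self.combat_models[mod] = harmonize.combat_fit(feats, sites, cov)
        return self

    def transform(self, v: Volume, age: float | None = None, sex: float | None = None) -> Volume:
        out = self._normalize(v)
        if v.modality in self.templates:
            out = harmonize.histogram_match(out, self.templates[v.modality])
        if self.use_combat and v.modality in self.combat_models:
            mask = self.shared_mask
            feats = out.data[mask][None, :]
            if age is None and self.cov_map:
                age, sex = self.cov_map.get(int(v.subject_id), self.cov_mean)
            cov = np.array([[age, sex]], dtype=float) if age is not None else None
            adj = harmonize.combat_apply(self.combat_models[v.modality], feats,
                                         np.array([v.site_id]), cov)
            data = out.data.copy()
            data[mask] = adj[0]
            out = replace(out, data=data)
        return out


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 5
    batch_subjects: int = 16
    weights: SSLWeights = field(default_factory=SSLWeights)
    policy: AugmentationPolicy = field(default_factory=lambda: AugmentationPolicy(crop_size=None))
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    queue_size: int = 16
    momentum: float = 0.9
    lr: float = 2e-3
    weight_decay: float = 1e-4
    disc_lr_mult: float = 3.0          # discriminator learns faster than encoder
    disc_steps: int = 5                # discriminator-only steps per batch
    disc_weight_decay: float = 1.0     # keeps the adversary from saturating
    checkpoint_every: int = 0          # 0 = keep only the final state
    seed: int = 0


@dataclass
class PretrainResult:
    model: ModalityEncoders
    predictor: Predictor
    discriminator: SiteDiscriminator
    history: list[SSLLossReport]
    checkpoints: list[tuple[int, dict]]
    longitudinal_enabled: bool
    config: PretrainConfig
    fit_subjects: set[int]


def _site_aware_order(subjects: np.ndarray, sites: dict[int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Interleave shuffled per-site lists so batches mix sites."""
    order = []
    per_site: dict[int, list[int]] = {}
    for s in subjects[rng.permutation(len(subjects))]:
        per_site.setdefault(sites[int(s)], []).append(int(s))
    queues = list(per_site.values())
    i = 0
    while any(queues):
        q = queues[i % len(queues)]
        if q:
            order.append(q.pop())
        i += 1
    return np.asarray(order)


def pretrain(volumes: list[Volume], table: pd.DataFrame, config: PretrainConfig,
             harmonizer: VolumeHarmonizer | None = None) -> PretrainResult:
    """Stage-1 pretraining loop.

    Each step draws a site-aware batch of subjects, encodes two augmented
    views of every available volume (online and momentum key encoders),
    assembles the loss stack and takes one AdamW step; the key encoder and
    per-modality FIFO queues are updated after each step.  Longitudinal
    terms auto-disable when no subject has two visits.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sites = int(table["site_id"].max()) + 1
    spec = cfg.encoder
    if spec.norm == "dsbn" and spec.n_sites is None:
        spec = replace(spec, n_sites=n_sites)
    spec = replace(spec, seed=cfg.seed)
    online = ModalityEncoders(spec)
    key = ModalityEncoders(spec)
    key.load_state_dict(online.state_dict())
    predictor = Predictor(spec.embed_dim, seed=cfg.seed)
    discriminator = SiteDiscriminator(spec.embed_dim, n_sites, seed=cfg.seed)
    params = online.parameters() + predictor.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    # the site discriminator gets its own, faster optimizer so it stays
    # near-optimal; only then does maximizing its loss remove site signal
    # rather than merely inverting it
    opt_disc = nn.AdamW(discriminator.parameters(), lr=cfg.lr * cfg.disc_lr_mult,
                        weight_decay=cfg.disc_weight_decay)
    queues = {m: MomentumQueue(cfg.queue_size, spec.embed_dim) for m in ("MRI", "PET")}

    items = list(range(len(volumes)))
    by_subject: dict[int, list[int]] = {}
    for i, v in enumerate(volumes):
        by_subject.setdefault(int(v.subject_id), []).append(i)
    subjects = np.array(sorted(by_subject))
    site_of = {int(v.subject_id): int(v.site_id) for v in volumes}
    visits_per_subject = table.groupby("subject_id")["visit_time_months"].nunique()
    longitudinal_enabled = bool((visits_per_subject >= 2).any())

    # input normalization fitted on the (harmonized) training volumes
    fit_vols = [harmonizer.transform(v) for v in volumes] if harmonizer is not None else volumes
    online.fit_input_stats(fit_vols)
    key.set_input_stats(online.input_center, online.input_scale)

    def prepare(v: Volume, g: np.random.Generator) -> np.ndarray:
        vol = harmonizer.transform(v) if harmonizer is not None else v
        aug = augment(vol, cfg.policy, g)
        return aug.data

    total_steps = max(1, cfg.epochs * int(np.ceil(len(subjects) / cfg.batch_subjects)))
    step = 0
    history: list[SSLLossReport] = []
    checkpoints: list[tuple[int, dict]] = []
    for epoch in range(cfg.epochs):
        order = _site_aware_order(subjects, site_of, rng)
        epoch_reports: list[SSLLossReport] = []
        for lo in range(0, len(order), cfg.batch_subjects):
            batch_subj = order[lo:lo + cfg.batch_subjects]
            idxs = [i for s in batch_subj for i in by_subject[int(s)]]
            if len(idxs) < 2:
                continue
            metas = [volumes[i] for i in idxs]
            v1 = np.stack([prepare(volumes[i], rng) for i in idxs])
            v2 = np.stack([prepare(volumes[i], rng) for i in idxs])
            mods = np.array([m.modality for m in metas])
            subj = np.array([int(m.subject_id) for m in metas])
            times = np.array([float(m.visit_time) for m in metas])
            sites = np.array([int(m.site_id) for m in metas])

            z_parts, part_rows = [], []
            keys_by_mod: dict[str, np.ndarray] = {}
            z1_rows = np.empty(len(idxs), dtype=int)
            pos = 0
            for mod in ("MRI", "PET"):
                rows = np.nonzero(mods == mod)[0]
                if len(rows) == 0:
                    continue
                z1 = online(v1[rows], mod, sites=sites[rows])
                with no_grad():
                    k2 = key(v2[rows], mod, sites=sites[rows]).data
                keys_by_mod[mod] = k2
                z_parts.append(z1)
                part_rows.append(rows)
                z1_rows[rows] = np.arange(pos, pos + len(rows))
                pos += len(rows)
            Z = concatenate(z_parts, axis=0)
            row_order = np.concatenate(part_rows)
            K2 = np.concatenate([keys_by_mod[m] for m in ("MRI", "PET") if m in keys_by_mod])

            comps: dict[str, Tensor] = {}
            w = cfg.weights
            if w.intra > 0:
                intra_terms = []
                for mod, rows in zip([m for m in ("MRI", "PET") if m in keys_by_mod], part_rows):
                    zr = Z[z1_rows[rows]]
                    intra_terms.append(intra_modal_infonce(
                        zr, Tensor(keys_by_mod[mod]), queue=queues[mod], tau=w.tau))
                comps["intra"] = sum(intra_terms[1:], intra_terms[0]) / len(intra_terms)
            if w.cross > 0 and "MRI" in keys_by_mod and "PET" in keys_by_mod:
                pair_mri, pair_pet = [], []
                pet_lookup = {(subj[r], times[r]): r for r in np.nonzero(mods == "PET")[0]}
                for r in np.nonzero(mods == "MRI")[0]:
                    r2 = pet_lookup.get((subj[r], times[r]))
                    if r2 is not None:
                        pair_mri.append(z1_rows[r])
                        pair_pet.append(z1_rows[r2])
                if pair_mri:
                    # cross-modal negatives are in-batch only: stale queue keys
                    # from the other modality destabilize the pairing task at
                    # small batch counts
                    comps["cross"] = cross_modal_infonce(
                        Z[np.array(pair_mri)], Z[np.array(pair_pet)], tau=w.tau)
            if w.byol > 0:
                comps["byol"] = byol_loss(Z, Tensor(K2), predictor)
            if longitudinal_enabled and w.long > 0:
                comps["long"] = longitudinal_consistency(
                    Z, subj[row_order], mods[row_order], times[row_order], reduction="mean")
            if longitudinal_enabled and w.long_x > 0:
                comps["long_x"] = cross_time_cross_modal(
                    Z, subj[row_order], mods[row_order], times[row_order], reduction="mean")
            if w.site > 0:
                for _ in range(cfg.disc_steps):
                    d_loss = site_adversarial_loss(Z.detach(), sites[row_order],
                                                   discriminator, grl_strength=0.0)
                    opt_disc.zero_grad()
                    d_loss.backward()
                    opt_disc.step()
                comps["site"] = site_adversarial_loss(
                    Z, sites[row_order], discriminator, grl_strength=w.grl_strength)

            total, report = total_ssl_loss(comps, w)
            if not longitudinal_enabled:
                report.components["long"] = 0.0
                report.components["long_x"] = 0.0
            opt.zero_grad()
            if total.requires_grad:
                total.backward()
            opt.lr = nn.cosine_lr(cfg.lr, step, total_steps)
            opt.step()
            momentum_update(key, online, cfg.momentum)
            for mod, k2 in keys_by_mod.items():
                queues[mod].enqueue(k2)
            epoch_reports.append(report)
            step += 1
        if not epoch_reports:
            raise ValueError("cohort too small to form a single pretraining batch")
        mean_comps = {k: float(np.mean([r.components[k] for r in epoch_reports]))
                      for k in epoch_reports[0].components}
        history.append(SSLLossReport(components=mean_comps,
                                     total=float(np.mean([r.total for r in epoch_reports]))))
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            checkpoints.append((epoch + 1, copy.deepcopy(online.state_dict())))
    checkpoints.append((cfg.epochs, copy.deepcopy(online.state_dict())))
    return PretrainResult(model=online, predictor=predictor, discriminator=discriminator,
                          history=history, checkpoints=checkpoints,
                          longitudinal_enabled=longitudinal_enabled, config=cfg,
                          fit_subjects={int(s) for s in subjects})


def select_checkpoint(result: PretrainResult, volumes: list[Volume], table: pd.DataFrame,
                      train_subjects: set[int], val_subjects: set[int],
                      seed: int = 0) -> tuple[int, float]:
    """Linear-probe checkpoint selection: argmax probe BAC on the validation
    subjects; loads the winning weights into the result model."""
    from .encoder import embed_batch
    best = (None, -1.0)
    diag_of = {(int(r.subject_id), float(r.visit_time_months)): r.diagnosis
               for r in table.itertuples()}
    saved = result.model.state_dict()
    for epoch, state in result.checkpoints:
        result.model.load_state_dict(state)
        mri = [v for v in volumes if v.modality == "MRI"]
        embs = embed_batch(result.model, mri)
        X = np.stack([e.z for e in embs])
        y = np.array([CLASSES.index(diag_of[(e.subject_id, e.visit_time)]) for e in embs])
        subs = np.array([e.subject_id for e in embs])
        tr = np.nonzero(np.isin(subs, list(train_subjects)))[0]
        va = np.nonzero(np.isin(subs, list(val_subjects)))[0]
        bac = linear_probe(X, y, tr, va, seed=seed)
        if bac > best[1]:
            best = (epoch, bac)
            saved = copy.deepcopy(state)
    result.model.load_state_dict(saved)
    return best


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 10
    batch_size: int = 32
    lr: float = 3e-4
    head_lr_mult: float = 10.0         # heads learn faster than the backbone
    weight_decay: float = 1e-4
    coef_diag: float = 1.0
    coef_cox: float = 1.0
    coef_distill: float = 0.5
    distill_warmup: float = 0.0        # fraction of epochs before distillation engages
    freeze_encoders: bool = False
    patience: int = 10
    val_fraction: float = 0.2         # of training subjects, for early stop + T
    seed: int = 0


@dataclass
class FinetunedModel:
    encoders: ModalityEncoders
    gate: fusion.FusionGate
    diag_head: nn.Linear
    cox_head: nn.Linear
    temperature: float
    cov_mean: np.ndarray
    cov_std: np.ndarray
    class_weights: np.ndarray
    harmonizer: VolumeHarmonizer | None = None
    fit_subjects: set[int] = field(default_factory=set)
    val_subjects: set[int] = field(default_factory=set)


def _visit_frame(table: pd.DataFrame, subjects: set[int] | None = None) -> pd.DataFrame:
    df = table if subjects is None else table[table["subject_id"].isin(list(subjects))]
    return df.reset_index(drop=True)


def _index_volumes(volumes: list[Volume]):
    return {(int(v.subject_id), float(v.visit_time), v.modality): v for v in volumes}


def _encode_visits(model: ModalityEncoders, vol_index, rows: pd.DataFrame,
                   harmonizer: VolumeHarmonizer | None, grad: bool = True):
    """Encode the MRI (always) and PET (where available) volumes of the given
    visit rows; PET rows without a scan are zero vectors."""
    def fetch(r, mod):
        v = vol_index[(int(r.subject_id), float(r.visit_time_months), mod)]
        if harmonizer is not None:
            v = harmonizer.transform(v, age=r.age, sex=r.sex)
        return v.data

    from .autodiff import no_grad
    import contextlib

    if not grad and len(rows) > 32:
        # chunk inference to bound memory
        parts = [
            _encode_visits(model, vol_index, rows.iloc[lo:lo + 32], harmonizer,
                           grad=False)
            for lo in range(0, len(rows), 32)
        ]
        return (Tensor(np.concatenate([p[0].data for p in parts])),
                Tensor(np.concatenate([p[1].data for p in parts])))

    ctx = contextlib.nullcontext() if grad else no_grad()
    with ctx:
        mri = np.stack([fetch(r, "MRI") for r in rows.itertuples()])
        sites = rows["site_id"].to_numpy()
        z_mri = model(mri, "MRI", sites=sites)
        d = z_mri.shape[1]
        pet_rows = [i for i, r in enumerate(rows.itertuples()) if r.has_pet]
        if pet_rows:
            pet = np.stack([fetch(r, "PET") for r in rows.iloc[pet_rows].itertuples()])
            z_pet_present = model(pet, "PET", sites=sites[pet_rows])
            lift = np.zeros((len(pet_rows), len(rows)))
            for k, i in enumerate(pet_rows):
                lift[k, i] = 1.0
            z_pet = Tensor(lift.T) @ z_pet_present
        else:
            z_pet = Tensor(np.zeros((len(rows), d)))
    return z_mri, z_pet


def finetune(pretrained: ModalityEncoders, volumes: list[Volume], table: pd.DataFrame,
             config: FinetuneConfig, harmonizer: VolumeHarmonizer | None = None,
             train_subjects: set[int] | None = None) -> FinetunedModel:
    """Stage-2 multi-task fine-tuning.

    Optimizes class-weighted diagnosis cross-entropy, the Cox partial
    likelihood on baseline risk scores and PET-to-MRI distillation jointly;
    early-stops on validation balanced accuracy; finally fits the
    calibration temperature on the validation fold's logits.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    all_train = sorted(train_subjects if train_subjects is not None
                       else {int(s) for s in table["subject_id"].unique()})
    all_train = np.array(all_train)
    n_val = max(1, int(round(cfg.val_fraction * len(all_train))))
    val_subjects = set(int(s) for s in rng.permutation(all_train)[:n_val])
    fit_subjects = set(int(s) for s in all_train) - val_subjects

    train_rows = _visit_frame(table, fit_subjects)
    val_rows = _visit_frame(table, val_subjects)
    vol_index = _index_volumes(volumes)

    model = ModalityEncoders(pretrained.spec)
    model.load_state_dict(pretrained.state_dict())
    if any(c is not None for c in pretrained.input_center.values()):
        model.set_input_stats(pretrained.input_center, pretrained.input_scale)
    else:
        fit_vols = [v for v in volumes if int(v.subject_id) in fit_subjects]
        if harmonizer is not None:
            fit_vols = [harmonizer.transform(v) for v in fit_vols]
        model.fit_input_stats(fit_vols)
    d = pretrained.spec.embed_dim
    q = 2  # standardized age, sex
    head_rng = np.random.default_rng(cfg.seed + 404)
    gate = fusion.FusionGate(seed=cfg.seed)
    diag_head = nn.Linear(2 * d + q, len(CLASSES), head_rng)
    cox_head = nn.Linear(2 * d + q, 1, head_rng)
    cov_mean = train_rows[["age", "sex"]].to_numpy(dtype=float).mean(axis=0)
    cov_std = train_rows[["age", "sex"]].to_numpy(dtype=float).std(axis=0)
    cov_std = np.maximum(cov_std, 1e-8)
    y_train = train_rows["diagnosis"].map(lambda d_: CLASSES.index(d_)).to_numpy()
    class_weights = fusion.inverse_frequency_weights(y_train, len(CLASSES))

    head_params = gate.parameters() + diag_head.parameters() + cox_head.parameters()
    opt_head = nn.AdamW(head_params, lr=cfg.lr * cfg.head_lr_mult,
                        weight_decay=cfg.weight_decay)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay) \
        if not cfg.freeze_encoders else None

    def covariates(rows: pd.DataFrame) -> np.ndarray:
        c = rows[["age", "sex"]].to_numpy(dtype=float)
        return (c - cov_mean) / cov_std

    def forward(rows: pd.DataFrame, grad: bool = True):
        z_mri, z_pet = _encode_visits(model, vol_index, rows, harmonizer, grad=grad)
        ind = np.column_stack([np.ones(len(rows)), rows["has_pet"].to_numpy(dtype=float)])
        fused = fusion.fuse_batch(z_mri, z_pet, ind, covariates(rows), gate)
        return z_mri, z_pet, ind, fused

    base_time = train_rows.groupby("subject_id")["visit_time_months"].min().to_dict()
    best_state = None
    best_bac = -1.0
    patience_left = cfg.patience
    n_steps = max(1, cfg.epochs * int(np.ceil(len(train_rows) / cfg.batch_size)))
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_rows))
        for lo in range(0, len(order), cfg.batch_size):
            rows = train_rows.iloc[order[lo:lo + cfg.batch_size]]
            if len(rows) < 2:
                continue
            z_mri, z_pet, ind, fused = forward(rows)
            logits = diag_head(fused)
            y = rows["diagnosis"].map(lambda d_: CLASSES.index(d_)).to_numpy()
            l_diag = fusion.diagnosis_loss(logits, y, class_weights)
            is_base = np.array([
                base_time.get(int(r.subject_id)) == float(r.visit_time_months)
                for r in rows.itertuples()])
            sel = np.nonzero(is_base)[0]
            l_cox = Tensor(0.0)
            if cfg.coef_cox > 0 and len(sel) >= 2 and rows.iloc[sel]["event"].sum() >= 1:
                risks = cox_head(fused[sel]).reshape(len(sel))
                l_cox = fusion.cox_partial_loglik(
                    risks, rows.iloc[sel]["T_months"].to_numpy(),
                    rows.iloc[sel]["event"].to_numpy()) / max(1, int(rows.iloc[sel]["event"].sum()))
            distill_on = epoch >= cfg.distill_warmup * cfg.epochs
            l_dist = fusion.distillation_loss(z_mri, z_pet, ind[:, 1]) \
                if (cfg.coef_distill > 0 and distill_on) else Tensor(0.0)
            loss = fusion.joint_finetune_loss(
                l_diag, l_cox, l_dist, cfg.coef_diag, cfg.coef_cox,
                cfg.coef_distill if distill_on else 0.0)
            opt_head.zero_grad()
            if opt is not None:
                opt.zero_grad()
            if loss.requires_grad:
                loss.backward()
            opt_head.lr = nn.cosine_lr(cfg.lr * cfg.head_lr_mult, step, n_steps)
            opt_head.step()
            if opt is not None:
                opt.lr = nn.cosine_lr(cfg.lr, step, n_steps)
                opt.step()
            step += 1
        # early stopping on validation balanced accuracy
        if len(val_rows) and len(val_rows["diagnosis"].unique()) >= 2:
            _, _, _, fused = forward(val_rows, grad=False)
            logits = diag_head(fused).data
            y_val = val_rows["diagnosis"].map(lambda d_: CLASSES.index(d_)).to_numpy()
            bac = metrics.balanced_accuracy(y_val, logits.argmax(axis=1))
            if bac >= best_bac - 1e-9:
                # refresh the kept state on ties so a flat validation curve
                # does not silently restore the first epoch
                best_state = (copy.deepcopy(model.state_dict()),
                              copy.deepcopy(gate.state_dict()),
                              copy.deepcopy(diag_head.state_dict()),
                              copy.deepcopy(cox_head.state_dict()))
            if bac > best_bac + 1e-9:
                best_bac = bac
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        model.load_state_dict(best_state[0])
        gate.load_state_dict(best_state[1])
        diag_head.load_state_dict(best_state[2])
        cox_head.load_state_dict(best_state[3])

    # post-hoc temperature on validation logits (encoders untouched)
    T = 1.0
    if len(val_rows) and len(val_rows["diagnosis"].unique()) >= 2:
        _, _, _, fused = forward(val_rows, grad=False)
        logits = diag_head(fused).data
        y_val = val_rows["diagnosis"].map(lambda d_: CLASSES.index(d_)).to_numpy()
        T = fusion.fit_temperature(logits, y_val).T

    return FinetunedModel(encoders=model, gate=gate, diag_head=diag_head,
                          cox_head=cox_head, temperature=T, cov_mean=cov_mean,
                          cov_std=cov_std, class_weights=class_weights,
                          harmonizer=harmonizer,
                          fit_subjects=fit_subjects, val_subjects=val_subjects)


def predict(model: FinetunedModel, volumes: list[Volume], table: pd.DataFrame,
            subjects: set[int] | None = None, use_pet: bool = True) -> pd.DataFrame:
    """Per-visit calibrated class probabilities and baseline risk scores.

    With ``use_pet=False`` every visit is scored MRI-only (the PET block of
    the fused representation is zero), exercising the missing-modality path.
    """
    rows = _visit_frame(table, subjects)
    if not use_pet:
        rows = rows.assign(has_pet=False)
    vol_index = _index_volumes(volumes)
    z_mri, z_pet = _encode_visits(model.encoders, vol_index, rows,
                                  model.harmonizer, grad=False)
    ind = np.column_stack([np.ones(len(rows)), rows["has_pet"].to_numpy(dtype=float)])
    cov = (rows[["age", "sex"]].to_numpy(dtype=float) - model.cov_mean) / model.cov_std
    fused = fusion.fuse_batch(z_mri, z_pet, ind, cov, model.gate)
    logits = model.diag_head(fused).data
    probs = fusion.apply_temperature(logits, model.temperature)
    risks = model.cox_head(fused).data.reshape(-1)
    out = rows[["subject_id", "visit_time_months", "site_id", "diagnosis",
                "T_months", "event"]].copy()
    for k, cls in enumerate(CLASSES):
        out[f"p_{cls}"] = probs[:, k]
    out["pred"] = [CLASSES[i] for i in probs.argmax(axis=1)]
    out["risk"] = risks
    return out


def evaluate(model: FinetunedModel, volumes: list[Volume], table: pd.DataFrame,
             subjects: set[int] | None = None, n_boot: int = 200,
             seed: int = 0, use_pet: bool = True) -> metrics.MetricReport:
    """Full metric report on the given subjects, with bootstrap CIs."""
    preds = predict(model, volumes, table, subjects, use_pet=use_pet)
    y = preds["diagnosis"].map(lambda d_: CLASSES.index(d_)).to_numpy()
    yhat = preds["pred"].map(lambda d_: CLASSES.index(d_)).to_numpy()
    prob_mat = preds[[f"p_{c}" for c in CLASSES]].to_numpy()
    conf = prob_mat.max(axis=1)
    correct = (y == yhat).astype(float)
    report = metrics.MetricReport()
    report.values["bac"] = metrics.balanced_accuracy(y, yhat)
    report.intervals["bac"] = metrics.bootstrap_ci(
        metrics.balanced_accuracy, (y, yhat), B=n_boot, seed=seed)
    report.values["f1_macro"] = metrics.f1(y, yhat, average="macro")
    is_ad = (y == CLASSES.index("AD")).astype(int)
    if 0 < is_ad.sum() < len(is_ad):
        p_ad = preds["p_AD"].to_numpy()
        report.values["auc_ad"] = metrics.auc(is_ad, p_ad)
        report.intervals["auc_ad"] = metrics.bootstrap_ci(
            metrics.auc, (is_ad, p_ad), B=n_boot, seed=seed)
    report.values["ece"] = metrics.ece(conf, correct, n_bins=min(10, len(conf)))
    base = preds.sort_values("visit_time_months").groupby("subject_id").head(1)
    try:
        cidx = metrics.c_index(base["risk"].to_numpy(), base["T_months"].to_numpy(),
                               base["event"].to_numpy())
        report.values["c_index"] = cidx
        report.intervals["c_index"] = metrics.bootstrap_ci(
            metrics.c_index,
            (base["risk"].to_numpy(), base["T_months"].to_numpy(), base["event"].to_numpy()),
            B=n_boot, seed=seed)
    except ValueError:
        pass
    return report


# ---------------------------------------------------------------------------
# cross-validation, cross-cohort and ablations
# ---------------------------------------------------------------------------


def run_cv(volumes: list[Volume], table: pd.DataFrame, k: int,
           pretrain_cfg: PretrainConfig, finetune_cfg: FinetuneConfig,
           use_harmonization: bool = True, use_combat: bool = True,
           seed: int = 0, n_boot: int = 50):
    """Subject-level site-stratified k-fold cross-validation.

    Every fitting stage (harmonization templates, ComBat, SSL, fine-tuning,
    temperature) sees only that fold's training subjects; the returned
    provenance maps each stage of each fold to the exact subject sets used,
    for the no-leakage audit.
    """
    plan = make_splits(table, k=k, seed=seed)
    reports, provenance = [], []
    for fold in range(k):
        train_subj = plan.train_subjects(fold)
        test_subj = plan.test_subjects(fold)
        train_vols = [v for v in volumes if int(v.subject_id) in train_subj]
        train_table = _visit_frame(table, train_subj)
        harmonizer = None
        if use_harmonization:
            harmonizer = VolumeHarmonizer(use_combat=use_combat).fit(train_vols, train_table)
        pre = pretrain(train_vols, train_table, replace(pretrain_cfg, seed=seed + fold),
                       harmonizer=harmonizer)
        model = finetune(pre.model, volumes, table,
                         replace(finetune_cfg, seed=seed + fold),
                         harmonizer=harmonizer, train_subjects=train_subj)
        rep = evaluate(model, volumes, table, subjects=test_subj, n_boot=n_boot,
                       seed=seed + fold)
        reports.append(rep)
        provenance.append({
            "fold": fold,
            "test": set(test_subj),
            "harmonization_fit": set(harmonizer.fit_subjects) if harmonizer else set(),
            "ssl_fit": set(pre.fit_subjects),
            "finetune_fit": set(model.fit_subjects),
            "temperature_fit": set(model.val_subjects),
        })
    return reports, provenance, plan


def cross_cohort_eval(train_data: tuple[list[Volume], pd.DataFrame],
                      test_data: tuple[list[Volume], pd.DataFrame],
                      pretrain_cfg: PretrainConfig, finetune_cfg: FinetuneConfig,
                      use_harmonization: bool = False, seed: int = 0,
                      n_boot: int = 50):
    """Train on one cohort, evaluate in-distribution and out-of-distribution.

    Harmonization (when enabled) is fitted on the training cohort only and
    applied unchanged to the test cohort.  Overlapping subject ids between
    cohorts are rejected.
    """
    train_vols, train_table = train_data
    test_vols, test_table = test_data
    tr_ids = {int(s) for s in train_table["subject_id"].unique()}
    te_ids = {int(s) for s in test_table["subject_id"].unique()}
    overlap = tr_ids & te_ids
    if overlap:
        raise ValueError(f"subject id collision across cohorts: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(tr_ids))
    heldout = set(int(s) for s in rng.permutation(ids)[: max(1, len(ids) // 5)])
    fit_ids = tr_ids - heldout
    fit_vols = [v for v in train_vols if int(v.subject_id) in fit_ids]
    fit_table = _visit_frame(train_table, fit_ids)
    harmonizer = None
    if use_harmonization:
        harmonizer = VolumeHarmonizer(use_combat=True).fit(fit_vols, fit_table)
    pre = pretrain(fit_vols, fit_table, pretrain_cfg, harmonizer=harmonizer)
    model = finetune(pre.model, train_vols, train_table, finetune_cfg,
                     harmonizer=harmonizer, train_subjects=fit_ids)
    rep_id = evaluate(model, train_vols, train_table, subjects=heldout,
                      n_boot=n_boot, seed=seed)
    rep_ood = evaluate(model, test_vols, test_table, n_boot=n_boot, seed=seed)
    return rep_id, rep_ood, model


def run_ablation(arms: dict[str, dict], volumes: list[Volume], table: pd.DataFrame,
                 pretrain_cfg: PretrainConfig, finetune_cfg: FinetuneConfig,
                 seed: int = 0, n_boot: int = 25) -> pd.DataFrame:
    """Run named config-override arms with shared seeds and splits.

    ``arms`` maps arm name -> {"weights": {...}, "pretrain": {...},
    "finetune": {...}}; an empty dict is the baseline.  Returns one row per
    arm with the metric set and the logged config diff.
    """
    if not arms:
        arms = {"baseline": {}}
    plan = make_splits(table, k=min(5, table["subject_id"].nunique()), seed=seed)
    train_subj = plan.train_subjects(0)
    test_subj = plan.test_subjects(0)
    rows = []
    for name, overrides in arms.items():
        p_cfg = pretrain_cfg
        if "weights" in overrides:
            p_cfg = replace(p_cfg, weights=replace(p_cfg.weights, **overrides["weights"]))
        if "pretrain" in overrides:
            p_cfg = replace(p_cfg, **overrides["pretrain"])
        f_cfg = finetune_cfg
        if "finetune" in overrides:
            f_cfg = replace(f_cfg, **overrides["finetune"])
        train_vols = [v for v in volumes if int(v.subject_id) in train_subj]
        pre = pretrain(train_vols, _visit_frame(table, train_subj), p_cfg)
        model = finetune(pre.model, volumes, table, f_cfg, train_subjects=train_subj)
        rep = evaluate(model, volumes, table, subjects=test_subj, n_boot=n_boot, seed=seed)
        row = {"arm": name, "config_diff": json.dumps(overrides, sort_keys=True),
               "split_hash": hash(frozenset(plan.fold_of.items()))}
        row.update(rep.values)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoint io
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: ModalityEncoders, extras: dict | None = None,
                    meta: dict | None = None) -> None:
    """Write encoder (and optional extra module) parameters plus JSON metadata."""
    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    for mod_name, module in (extras or {}).items():
        for k, v in module.state_dict().items():
            arrays[f"{mod_name}/{k}"] = v
    spec = model.spec
    meta_all = {"spec": {"widths": list(spec.widths), "embed_dim": spec.embed_dim,
                         "norm": spec.norm, "groups": spec.groups,
                         "n_sites": spec.n_sites, "seed": spec.seed},
                "input_scale": model.input_scale}
    for m, c in model.input_center.items():
        if c is not None:
            arrays[f"__center__/{m}"] = c
    meta_all.update(meta or {})
    arrays["__meta__"] = np.frombuffer(json.dumps(meta_all).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ModalityEncoders, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        spec = EncoderSpec(widths=tuple(spec_d["widths"]), embed_dim=spec_d["embed_dim"],
                           norm=spec_d["norm"], groups=spec_d["groups"],
                           n_sites=spec_d["n_sites"], seed=spec_d["seed"])
        model = ModalityEncoders(spec)
        state = {k[len("model/"):]: data[k] for k in data.files if k.startswith("model/")}
        model.load_state_dict(state)
        center = {k.split("/", 1)[1]: data[k] for k in data.files
                  if k.startswith("__center__/")}
        if center:
            model.set_input_stats(center, meta.get("input_scale", 0.01))
    return model, meta
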