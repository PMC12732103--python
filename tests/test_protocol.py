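"""Splits, probes, training loops, checkpoints, ablations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from neurossl.augment import AugmentationPolicy
from neurossl.cohort import CohortConfig, generate_cohort, generate_volumes
from neurossl.encoder import EncoderSpec, embed_batch
from neurossl.protocol import (FinetuneConfig, PretrainConfig, cross_cohort_eval,
                               evaluate, finetune, linear_probe, load_checkpoint,
                               make_splits, predict, pretrain, run_ablation,
                               save_checkpoint)
from neurossl.ssl_losses import SSLWeights

GENTLE = AugmentationPolicy(flip_prob=0.0, rotation_deg=5.0, blur_sigma=(0.0, 0.3),
                            intensity_jitter=0.10)
SMALL_ENC = EncoderSpec(widths=(4, 8), embed_dim=8, groups=2)


def small_pretrain_cfg(**kw):
    base = dict(epochs=2, batch_subjects=8, queue_size=8, encoder=SMALL_ENC,
                policy=GENTLE, seed=0)
    base.update(kw)
    return PretrainConfig(**base)


# -- splits -----------------------------------------------------------------


def test_splits_partition_subjects(tiny_cohort):
    table, _, _ = tiny_cohort
    plan = make_splits(table, k=3, seed=0)
    all_subj = {int(s) for s in table["subject_id"].unique()}
    seen = set()
    for f in range(3):
        fold = plan.test_subjects(f)
        assert not (fold & seen)
        seen |= fold
    assert seen == all_subj


def test_splits_site_stratified_counts():
    cfg = CohortConfig(n_subjects=100, n_sites=2, visits_range=(1, 1), seed=0)
    table, _ = generate_cohort(cfg)
    plan = make_splits(table, k=5, stratify_keys=("site_id",), seed=1)
    base = table.groupby("subject_id").first().reset_index()
    for f in range(5):
        fold = plan.test_subjects(f)
        per_site = base[base["subject_id"].isin(list(fold))]["site_id"].value_counts()
        for s in (0, 1):
            total = (base["site_id"] == s).sum()
            assert abs(per_site.get(s, 0) - total / 5) <= 1


def test_splits_deterministic(tiny_cohort):
    table, _, _ = tiny_cohort
    a = make_splits(table, k=3, seed=7)
    b = make_splits(table, k=3, seed=7)
    assert a.fold_of == b.fold_of
    with pytest.raises(ValueError):
        make_splits(table, k=999)


# -- linear probe -----------------------------------------------------------


def test_probe_separable_labels_perfect(rng):
    X = rng.normal(size=(100, 6))
    y = rng.integers(0, 2, 100)
    X[:, 2] = np.where(y, 2.0, -2.0) + 0.1 * rng.normal(size=100)
    idx = rng.permutation(100)
    assert linear_probe(X, y, idx[:60], idx[60:]) == 1.0


def test_probe_random_labels_chance(rng):
    X = rng.normal(size=(500, 6))
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    y = rng.integers(0, 2, 500)
    idx = rng.permutation(500)
    bac = linear_probe(X, y, idx[:250], idx[250:])
    assert abs(bac - 0.5) < 0.1


def test_probe_single_class_rejected(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError, match="single class"):
        linear_probe(X, np.zeros(10, int), np.arange(5), np.arange(5, 10))


# -- pretraining loop -------------------------------------------------------


@pytest.fixture(scope="module")
def small_run():
    cfg = CohortConfig(n_subjects=12, n_sites=2, visits_range=(1, 2),
                       pet_missing_prob=0.3, seed=21)
    table, subjects = generate_cohort(cfg)
    vols = generate_volumes(subjects, cfg)
    result = pretrain(vols, table, small_pretrain_cfg())
    return cfg, table, vols, result


def test_pretrain_reports_all_components(small_run):
    _, _, _, result = small_run
    assert len(result.history) == 2
    for rep in result.history:
        assert set(rep.components) == {"intra", "cross", "byol", "long", "long_x", "site"}
        assert np.isfinite(rep.total)
    assert result.longitudinal_enabled


def test_probe_leaves_encoder_untouched(small_run):
    _, table, vols, result = small_run
    before = {k: v.copy() for k, v in result.model.state_dict().items()}
    mri = [v for v in vols if v.modality == "MRI"]
    embs = embed_batch(result.model, mri)
    X = np.stack([e.z for e in embs])
    y = np.array([e.site_id for e in embs])
    idx = np.random.default_rng(0).permutation(len(X))
    try:
        linear_probe(X, y, idx[: len(X) // 2], idx[len(X) // 2:])
    except ValueError:
        pass
    after = result.model.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_single_visit_cohort_disables_longitudinal():
    cfg = CohortConfig(n_subjects=10, visits_range=(1, 1), seed=4)
    table, subjects = generate_cohort(cfg)
    vols = generate_volumes(subjects, cfg)
    result = pretrain(vols, table, small_pretrain_cfg(epochs=1))
    assert not result.longitudinal_enabled
    assert result.history[0].components["long"] == 0.0
    assert result.history[0].components["long_x"] == 0.0


def test_pretrain_deterministic_given_seed():
    cfg = CohortConfig(n_subjects=8, visits_range=(1, 1), seed=13)
    table, subjects = generate_cohort(cfg)
    vols = generate_volumes(subjects, cfg)
    r1 = pretrain(vols, table, small_pretrain_cfg(epochs=1))
    r2 = pretrain(vols, table, small_pretrain_cfg(epochs=1))
    s1, s2 = r1.model.state_dict(), r2.model.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)
    assert r1.history[0].total == pytest.approx(r2.history[0].total, abs=1e-12)


# -- fine-tuning + prediction ----------------------------------------------


@pytest.fixture(scope="module")
def finetuned(small_run):
    cfg, table, vols, result = small_run
    model = finetune(result.model, vols, table,
                     FinetuneConfig(epochs=2, batch_size=8, seed=0))
    return cfg, table, vols, model


def test_predictions_are_valid_probabilities(finetuned):
    _, table, vols, model = finetuned
    preds = predict(model, vols, table)
    probs = preds[["p_CN", "p_MCI", "p_AD"]].to_numpy()
    assert np.allclose(probs.sum(axis=1), 1.0)
    assert (probs >= 0).all()
    assert len(preds) == len(table)


def test_mri_only_inference_path(finetuned):
    _, table, vols, model = finetuned
    preds = predict(model, vols, table, use_pet=False)
    assert np.isfinite(preds[["p_CN", "p_MCI", "p_AD", "risk"]].to_numpy()).all()


def test_temperature_fitted_positive(finetuned):
    *_, model = finetuned
    assert model.temperature > 0


def test_checkpoint_round_trip(tmp_path, finetuned):
    _, table, vols, model = finetuned
    path = tmp_path / "enc.npz"
    save_checkpoint(path, model.encoders)
    loaded, meta = load_checkpoint(path)
    mri = [v for v in vols if v.modality == "MRI"][:4]
    a = np.stack([e.z for e in embed_batch(model.encoders, mri)])
    b = np.stack([e.z for e in embed_batch(loaded, mri)])
    assert np.allclose(a, b, atol=1e-12)


def test_evaluate_emits_core_metrics(finetuned):
    _, table, vols, model = finetuned
    rep = evaluate(model, vols, table, n_boot=10)
    assert "bac" in rep.values
    assert "ece" in rep.values
    assert 0.0 <= rep.values["bac"] <= 1.0
    lo, hi = rep.intervals["bac"]
    assert lo <= hi


# -- ablations + cross-cohort ----------------------------------------------


def test_ablation_baseline_and_controlled_arms(small_run):
    cfg, table, vols, _ = small_run
    df = run_ablation({}, vols, table, small_pretrain_cfg(epochs=1),
                      FinetuneConfig(epochs=1, batch_size=8, seed=0), n_boot=5)
    assert list(df["arm"]) == ["baseline"]
    arms = {"base": {}, "no_site": {"weights": {"site": 0.0}}}
    df2 = run_ablation(arms, vols, table, small_pretrain_cfg(epochs=1),
                       FinetuneConfig(epochs=1, batch_size=8, seed=0), n_boot=5)
    assert len(df2) == 2
    assert df2["split_hash"].nunique() == 1
    assert df2["config_diff"].nunique() == 2


def test_cross_cohort_rejects_id_collision(small_run):
    cfg, table, vols, _ = small_run
    with pytest.raises(ValueError, match="collision"):
        cross_cohort_eval((vols, table), (vols, table),
                          small_pretrain_cfg(epochs=1),
                          FinetuneConfig(epochs=1, seed=0))
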