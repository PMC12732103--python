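"""Closed forms, hand oracles, invariances and gradient contracts of the
pretraining loss stack."""

import numpy as np
import pytest

from neurossl import nn
from neurossl.autodiff import Tensor
from neurossl.encoder import Predictor, SiteDiscriminator
from neurossl.ssl_losses import (MomentumQueue, SSLWeights, byol_loss,
                                 cross_modal_infonce, cross_time_cross_modal,
                                 intra_modal_infonce, longitudinal_consistency,
                                 momentum_update, site_adversarial_loss,
                                 total_ssl_loss)


def unit_rows(rng, n, d):
    z = rng.normal(size=(n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


def softmax_oracle(anchors, cands, pos_idx, tau):
    total = 0.0
    for i, a in enumerate(anchors):
        logits = cands @ a / tau
        p = np.exp(logits - logits.max())
        p /= p.sum()
        total += -np.log(p[pos_idx[i]])
    return total / len(anchors)


# -- intra-modal InfoNCE ----------------------------------------------------


def test_intra_uniform_similarity_is_log_candidates():
    z = np.tile([1.0, 0.0], (5, 1))
    q = MomentumQueue(8, 2)
    q.enqueue(np.tile([1.0, 0.0], (3, 1)))
    loss = intra_modal_infonce(z, z, queue=q, tau=0.1)
    assert loss.item() == pytest.approx(np.log(8), abs=1e-12)


def test_intra_orthogonal_negatives_closed_form():
    # positive similarity 1, C-1 negatives at similarity 0, tau = 0.1
    d = 8
    anchors = np.eye(d)[:4]
    positives = anchors.copy()
    q = MomentumQueue(8, d)
    q.enqueue(np.eye(d)[4:8])
    loss = intra_modal_infonce(anchors[:1], positives[:1], queue=q, tau=0.1)
    C = 1 + 4
    assert loss.item() == pytest.approx(np.log(1 + (C - 1) * np.exp(-10.0)), abs=1e-12)


def test_intra_matches_scalar_softmax_oracle(rng):
    anchors = unit_rows(rng, 4, 2)
    positives = unit_rows(rng, 4, 2)
    q = MomentumQueue(4, 2)
    q.enqueue(unit_rows(rng, 3, 2))
    got = intra_modal_infonce(anchors, positives, queue=q, tau=0.13).item()
    cands = np.vstack([positives, q.as_array()])
    want = softmax_oracle(anchors, cands, np.arange(4), 0.13)
    assert got == pytest.approx(want, abs=1e-12)


def test_intra_rejects_bad_inputs(rng):
    z = unit_rows(rng, 3, 4)
    with pytest.raises(ValueError, match="temperature"):
        intra_modal_infonce(z, z, tau=0.0)
    with pytest.raises(ValueError, match="unit-norm"):
        intra_modal_infonce(z * 2.0, z)


def test_infonce_permutation_invariance(rng):
    anchors = unit_rows(rng, 6, 4)
    positives = unit_rows(rng, 6, 4)
    base = intra_modal_infonce(anchors, positives, tau=0.1).item()
    perm = rng.permutation(6)
    shuffled = intra_modal_infonce(anchors[perm], positives[perm], tau=0.1).item()
    assert shuffled == pytest.approx(base, abs=1e-12)


# -- cross-modal InfoNCE ----------------------------------------------------


def test_cross_perfect_orthogonal_alignment_closed_form():
    d, n, tau = 8, 5, 0.1
    z = np.eye(d)[:n]
    loss = cross_modal_infonce(z, z, tau=tau).item()
    assert loss == pytest.approx(2 * np.log(1 + (n - 1) * np.exp(-1 / tau)), abs=1e-12)


def test_cross_single_pair_is_zero(rng):
    zm, zp = unit_rows(rng, 1, 4), unit_rows(rng, 1, 4)
    assert cross_modal_infonce(zm, zp, tau=0.07).item() == pytest.approx(0.0)


def test_cross_matches_two_directional_oracles(rng):
    zm, zp = unit_rows(rng, 3, 2), unit_rows(rng, 3, 2)
    got = cross_modal_infonce(zm, zp, tau=0.2).item()
    want = (softmax_oracle(zm, zp, np.arange(3), 0.2)
            + softmax_oracle(zp, zm, np.arange(3), 0.2))
    assert got == pytest.approx(want, abs=1e-12)


def test_cross_symmetric_under_role_swap(rng):
    zm, zp = unit_rows(rng, 4, 3), unit_rows(rng, 4, 3)
    qm, qp = MomentumQueue(4, 3), MomentumQueue(4, 3)
    qm.enqueue(unit_rows(rng, 2, 3))
    qp.enqueue(unit_rows(rng, 2, 3))
    a = cross_modal_infonce(zm, zp, queue_mri=qm, queue_pet=qp, tau=0.1).item()
    b = cross_modal_infonce(zp, zm, queue_mri=qp, queue_pet=qm, tau=0.1).item()
    assert a == pytest.approx(b, abs=1e-12)


# -- longitudinal consistency ----------------------------------------------


def test_longitudinal_single_pair_and_zero_cases(rng):
    z = unit_rows(rng, 2, 4)
    z[1] = z[0]
    val = longitudinal_consistency(z, [1, 1], ["MRI", "MRI"], [0.0, 12.0]).item()
    assert val == pytest.approx(0.0)
    z2 = unit_rows(rng, 2, 4)
    want = np.sum((z2[0] - z2[1]) ** 2)
    got = longitudinal_consistency(z2, [1, 1], ["MRI", "MRI"], [0.0, 12.0]).item()
    assert got == pytest.approx(want, abs=1e-12)
    # singleton visits contribute nothing
    assert longitudinal_consistency(z2, [1, 2], ["MRI", "MRI"], [0.0, 0.0]).item() == 0.0


def test_longitudinal_matches_pair_enumeration(rng):
    n_subj, n_vis, d = 3, 3, 5
    Z, subs, mods, times = [], [], [], []
    for p in range(n_subj):
        for t in range(n_vis):
            Z.append(unit_rows(rng, 1, d)[0])
            subs.append(p)
            mods.append("MRI")
            times.append(float(t))
    Z = np.asarray(Z)
    got = longitudinal_consistency(Z, subs, mods, times).item()
    want = 0.0
    for p in range(n_subj):
        idx = [i for i in range(len(subs)) if subs[i] == p]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                want += np.sum((Z[idx[a]] - Z[idx[b]]) ** 2)
    assert got == pytest.approx(want, abs=1e-10)


def test_cross_time_cross_modal_oracle(rng):
    # one subject: MRI@0 and PET@12 -> single squared distance
    Z = unit_rows(rng, 2, 4)
    got = cross_time_cross_modal(Z, [0, 0], ["MRI", "PET"], [0.0, 12.0]).item()
    assert got == pytest.approx(np.sum((Z[0] - Z[1]) ** 2), abs=1e-12)
    # same-visit MRI/PET pairs are excluded
    assert cross_time_cross_modal(Z, [0, 0], ["MRI", "PET"], [0.0, 0.0]).item() == 0.0
    # random cohort vs brute-force loop
    n = 8
    Z = unit_rows(rng, n, 3)
    subs = rng.integers(0, 3, n).tolist()
    mods = [["MRI", "PET"][i] for i in rng.integers(0, 2, n)]
    times = rng.integers(0, 3, n).astype(float).tolist()
    got = cross_time_cross_modal(Z, subs, mods, times).item()
    want = 0.0
    for a in range(n):
        for b in range(n):
            if (subs[a] == subs[b] and mods[a] == "MRI" and mods[b] == "PET"
                    and times[a] != times[b]):
                want += np.sum((Z[a] - Z[b]) ** 2)
    assert got == pytest.approx(want, abs=1e-10)


# -- BYOL -------------------------------------------------------------------


class IdentityPredictor(nn.Module):
    def __init__(self, d):
        self.w = nn.Parameter(np.eye(d))

    def forward(self, z):
        return z @ self.w


def test_byol_zero_and_single_pair(rng):
    d = 4
    pred = IdentityPredictor(d)
    z = unit_rows(rng, 3, d)
    assert byol_loss(z, z, pred).item() == pytest.approx(0.0)
    z2 = unit_rows(rng, 1, d)
    z3 = unit_rows(rng, 1, d)
    want = np.sum((z2 - z3) ** 2)
    assert byol_loss(z2, z3, pred).item() == pytest.approx(want, abs=1e-12)


def test_byol_target_branch_receives_zero_gradient(rng):
    d = 4
    pred = Predictor(d, seed=0)
    online = Tensor(unit_rows(rng, 5, d), requires_grad=True)
    target = Tensor(unit_rows(rng, 5, d), requires_grad=True)
    loss = byol_loss(online, target, pred)
    loss.backward()
    assert target.grad is None or np.all(target.grad == 0)
    assert online.grad is not None and np.any(online.grad != 0)
    # finite-difference: perturbing the target leaves the loss unchanged only
    # through sg, so d loss / d target must be 0
    eps = 1e-6
    t0 = target.data.copy()
    base = byol_loss(Tensor(online.data), Tensor(t0), pred).item()
    t1 = t0.copy()
    t1[0, 0] += eps
    up = byol_loss(Tensor(online.data), Tensor(t1), pred).item()
    # the loss DOES depend on the target value itself; the stop-gradient
    # contract is about the computational graph, checked above via .grad
    assert np.isfinite(up - base)


# -- site adversarial -------------------------------------------------------


class RawDiscriminator(nn.Module):
    """Plain linear discriminator (no batch standardization) for exact
    closed-form and finite-difference checks."""

    def __init__(self, dim, n_sites, W=None):
        rng = np.random.default_rng(1)
        self.fc = nn.Linear(dim, n_sites, rng)
        if W is not None:
            self.fc.weight.data = W
        self.n_sites = n_sites

    def forward(self, z):
        return self.fc(z)


def test_site_uniform_discriminator_gives_log_s(rng):
    d, S = 4, 3
    disc = RawDiscriminator(d, S, W=np.zeros((d, S)))
    z = unit_rows(rng, 6, d)
    sites = rng.integers(0, S, 6)
    loss = site_adversarial_loss(z, sites, disc, grl_strength=1.0)
    assert loss.item() == pytest.approx(np.log(S), abs=1e-12)


def test_site_perfect_discriminator_near_zero(rng):
    d, S = 2, 2
    disc = RawDiscriminator(d, S, W=np.array([[50.0, -50.0], [-50.0, 50.0]]))
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    loss = site_adversarial_loss(z, np.array([0, 1]), disc)
    assert loss.item() < 1e-6


def test_site_unknown_site_rejected(rng):
    disc = RawDiscriminator(2, 2)
    with pytest.raises(ValueError, match="unknown site"):
        site_adversarial_loss(unit_rows(rng, 2, 2), np.array([0, 5]), disc)


def test_grl_gives_negated_scaled_encoder_gradient(rng):
    """Embedding gradient equals -strength times the plain CE gradient."""
    d, S, lam = 3, 2, 1.7
    disc = RawDiscriminator(d, S)
    z0 = unit_rows(rng, 4, d)
    sites = np.array([0, 1, 0, 1])

    z = Tensor(z0.copy(), requires_grad=True)
    site_adversarial_loss(z, sites, disc, grl_strength=lam).backward()
    got = z.grad.copy()

    def plain_ce(arr):
        logits = arr @ disc.fc.weight.data + disc.fc.bias.data
        lse = np.log(np.exp(logits - logits.max(1, keepdims=True)).sum(1)) \
            + logits.max(1)
        return float(np.mean(lse - logits[np.arange(len(arr)), sites]))

    eps = 1e-6
    num = np.zeros_like(z0)
    it = np.nditer(z0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        up, dn = z0.copy(), z0.copy()
        up[i] += eps
        dn[i] -= eps
        num[i] = (plain_ce(up) - plain_ce(dn)) / (2 * eps)
    assert np.abs(got - (-lam) * num).max() < 1e-4


def test_discriminator_receives_ordinary_ce_gradient(rng):
    d, S = 3, 2
    disc = RawDiscriminator(d, S)
    z = unit_rows(rng, 4, d)
    sites = np.array([0, 1, 1, 0])
    disc.zero_grad()
    site_adversarial_loss(z, sites, disc, grl_strength=5.0).backward()
    with_grl = disc.fc.weight.grad.copy()
    disc.zero_grad()
    site_adversarial_loss(z, sites, disc, grl_strength=0.0).backward()
    without = disc.fc.weight.grad.copy()
    assert np.allclose(with_grl, without, atol=1e-12)


# -- total + queue + momentum ----------------------------------------------


def test_total_is_weighted_dot_product(rng):
    comps = {k: float(v) for k, v in zip(
        ("intra", "cross", "byol", "long", "long_x", "site"), rng.random(6))}
    w = SSLWeights(intra=0.3, cross=1.2, byol=0.1, long=0.7, long_x=0.0, site=2.0)
    total, report = total_ssl_loss(comps, w)
    want = sum(getattr(w, k) * v for k, v in comps.items())
    assert total.item() == pytest.approx(want, abs=1e-12)
    assert report.total == pytest.approx(want)
    zero, rep0 = total_ssl_loss({}, SSLWeights())
    assert zero.item() == 0.0
    with pytest.raises(ValueError, match="non-negative"):
        total_ssl_loss({"intra": 1.0}, SSLWeights(intra=-1.0))


def test_queue_fifo_eviction(rng):
    q = MomentumQueue(4, 3)
    first = unit_rows(rng, 4, 3)
    q.enqueue(first)
    extra = unit_rows(rng, 2, 3)
    q.enqueue(extra)
    assert len(q) == 4
    arr = q.as_array()
    assert np.allclose(arr[:2], first[2:])
    assert np.allclose(arr[2:], extra)
    with pytest.raises(ValueError, match="unit-norm"):
        q.enqueue(np.array([[3.0, 0.0, 0.0]]))


@pytest.mark.parametrize("m,expect", [(1.0, "key"), (0.0, "online")])
def test_momentum_update_endpoints(rng, m, expect):
    a = nn.Linear(3, 2, rng)
    b = nn.Linear(3, 2, rng)
    key_before = {k: v.copy() for k, v in a.state_dict().items()}
    momentum_update(a, b, m)
    ref = key_before if expect == "key" else b.state_dict()
    for k, v in a.state_dict().items():
        assert np.allclose(v, ref[k])
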