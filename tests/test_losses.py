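"""Loss correctness: naive-loop oracles, gradients, and target semantics."""

import math

import numpy as np
import pytest

from polypclip._autodiff import Tensor, l2_normalize_rows
from polypclip.losses import (
    ClassifierHead,
    EmbeddingBatch,
    cmpm_graph,
    cmpm_loss,
    id_graph,
    id_loss,
    infonce_graph,
    infonce_loss,
    match_distribution,
    total_loss,
)

CMPM_EPS = 1e-8


def random_batch(rng, n=8, d=16, tau=0.02, n_classes=3):
    V = rng.normal(size=(n, d))
    T = rng.normal(size=(n, d))
    labels = rng.integers(0, n_classes, size=n)
    return EmbeddingBatch.from_raw(V, T, labels, tau=tau)


# -- independent naive-loop oracles -------------------------------------------

def naive_infonce(batch):
    n = batch.V.shape[0]
    total = 0.0
    for i in range(n):
        num = math.exp(batch.V[i] @ batch.T[i] / batch.tau)
        den = sum(math.exp(batch.V[i] @ batch.T[j] / batch.tau) for j in range(n))
        total += math.log(num / den)
        num_t = math.exp(batch.T[i] @ batch.V[i] / batch.tau)
        den_t = sum(math.exp(batch.T[i] @ batch.V[j] / batch.tau) for j in range(n))
        total += math.log(num_t / den_t)
    return -total / (2 * n)


def naive_cmpm(batch, mode):
    n = batch.V.shape[0]

    def softmax_row(anchor, others):
        logits = [anchor @ o / batch.tau for o in others]
        m = max(logits)
        exps = [math.exp(l - m) for l in logits]
        z = sum(exps)
        return [e / z for e in exps]

    def direction(A, B):
        acc = 0.0
        for i in range(n):
            p = softmax_row(A[i], B)
            if mode == "instance_softmax":
                acc += -math.log(p[i])
            else:
                same = [j for j in range(n) if batch.labels[j] == batch.labels[i]]
                q = [1.0 / len(same) if j in same else 0.0 for j in range(n)]
                acc += sum(
                    p[j] * (math.log(p[j]) - math.log(q[j] + CMPM_EPS))
                    for j in range(n)
                )
        return acc / n

    return 0.5 * (direction(batch.V, batch.T) + direction(batch.T, batch.V))


def naive_id(V, labels, head):
    n = V.shape[0]
    total = 0.0
    for i in range(n):
        logits = V[i] @ head.W + head.b
        m = logits.max()
        lse = m + math.log(np.exp(logits - m).sum())
        total += logits[labels[i]] - lse
    return -total / n


# -- oracle equivalence --------------------------------------------------------

def test_losses_match_naive_loop_oracles_on_random_batches():
    rng = np.random.default_rng(0)
    for trial in range(100):
        n = int(rng.integers(2, 17))
        d = int(rng.integers(3, 33))
        batch = random_batch(rng, n=n, d=d, tau=float(rng.uniform(0.02, 1.0)))
        assert infonce_loss(batch) == pytest.approx(
            naive_infonce(batch), rel=1e-6
        ), trial
        for mode in ("instance_softmax", "label_aware_kl"):
            assert cmpm_loss(batch, mode=mode) == pytest.approx(
                naive_cmpm(batch, mode), rel=1e-6, abs=1e-9
            ), (trial, mode)
        head = ClassifierHead(W=rng.normal(size=(d, 3)), b=rng.normal(size=3))
        assert id_loss(batch.V, batch.labels, head) == pytest.approx(
            naive_id(batch.V, batch.labels, head), rel=1e-6
        ), trial


def test_single_pair_infonce_is_zero():
    rng = np.random.default_rng(1)
    batch = random_batch(rng, n=1)
    assert infonce_loss(batch) == pytest.approx(0.0, abs=1e-12)


def test_infonce_invariant_to_joint_row_permutation():
    rng = np.random.default_rng(2)
    batch = random_batch(rng, n=6)
    perm = rng.permutation(6)
    permuted = EmbeddingBatch(
        V=batch.V[perm], T=batch.T[perm], labels=batch.labels[perm], tau=batch.tau
    )
    assert infonce_loss(batch) == pytest.approx(infonce_loss(permuted), rel=1e-10)


def test_uniform_batch_label_aware_kl_is_near_zero():
    v = np.ones(8) / math.sqrt(8)
    V = np.tile(v, (4, 1))
    batch = EmbeddingBatch(V=V, T=V.copy(), labels=np.zeros(4, dtype=int), tau=0.02)
    assert abs(cmpm_loss(batch, mode="label_aware_kl")) < 1e-6


def test_id_loss_uniform_and_saturated_logits():
    V = np.eye(3)
    labels = np.array([0, 1, 2])
    zero_head = ClassifierHead(W=np.zeros((3, 3)), b=np.zeros(3))
    assert id_loss(V, labels, zero_head) == pytest.approx(math.log(3), rel=1e-12)
    hot_head = ClassifierHead(W=np.eye(3) * 2000.0, b=np.zeros(3))
    assert id_loss(V, labels, hot_head) < 1e-6


def test_id_loss_rejects_out_of_range_labels():
    head = ClassifierHead(W=np.zeros((4, 3)), b=np.zeros(3))
    with pytest.raises(ValueError, match="label"):
        id_loss(np.eye(4), np.array([0, 1, 3, 2]), head)


def test_temperature_must_be_positive():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="tau"):
        random_batch(rng, tau=0.0)
    batch = random_batch(rng)
    with pytest.raises(ValueError, match="positive"):
        infonce_graph(Tensor(batch.V), Tensor(batch.T), tau=-1.0)


def test_embedding_batch_requires_unit_rows():
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError, match="unit-normalized"):
        EmbeddingBatch(
            V=rng.normal(size=(4, 8)) * 3,
            T=rng.normal(size=(4, 8)),
            labels=np.zeros(4, dtype=int),
        )


def test_total_loss_weighting():
    rng = np.random.default_rng(5)
    batch = random_batch(rng)
    head = ClassifierHead(W=rng.normal(size=(16, 3)), b=np.zeros(3))
    full = total_loss(batch, head, weights=(1.0, 1.0))
    assert full.total == pytest.approx(full.cmpm + full.id, rel=1e-12)
    only_cmpm = total_loss(batch, head, weights=(1.0, 0.0))
    assert only_cmpm.total == pytest.approx(only_cmpm.cmpm, rel=1e-12)
    assert total_loss(batch, head, weights=(0.0, 0.0)).total == 0.0
    with pytest.raises(ValueError, match="non-negative"):
        total_loss(batch, head, weights=(-1.0, 1.0))


def test_losses_are_bounded_below_by_tiny_epsilon_slack():
    rng = np.random.default_rng(6)
    for _ in range(50):
        batch = random_batch(rng, n=int(rng.integers(2, 12)))
        assert infonce_loss(batch) >= -1e-6
        assert cmpm_loss(batch, mode="instance_softmax") >= -1e-6
        assert cmpm_loss(batch, mode="label_aware_kl") >= -1e-6


# -- gradients -----------------------------------------------------------------

def _grad_check(loss_fn, X0, rel_tol=1e-4):
    leaf = Tensor(X0, requires_grad=True)
    loss_fn(leaf).backward()
    num = np.zeros_like(X0)
    h = 1e-6
    it = np.nditer(X0, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = X0.copy(), X0.copy()
        xp[idx] += h
        xm[idx] -= h
        num[idx] = (float(loss_fn(Tensor(xp))) - float(loss_fn(Tensor(xm)))) / (2 * h)
    scale = max(np.abs(num).max(), 1e-8)
    assert np.abs(leaf.grad - num).max() / scale < rel_tol


def test_all_loss_gradients_match_finite_differences():
    rng = np.random.default_rng(7)
    n, d, c = 6, 5, 3
    Y = rng.normal(size=(n, d))
    labels = rng.integers(0, c, size=n)
    W = rng.normal(size=(d, c))
    b = rng.normal(size=c)
    tau = 0.1

    _grad_check(
        lambda X: infonce_graph(
            l2_normalize_rows(X), l2_normalize_rows(Tensor(Y)), tau
        ),
        rng.normal(size=(n, d)),
    )
    for mode in ("instance_softmax", "label_aware_kl"):
        _grad_check(
            lambda X, m=mode: cmpm_graph(
                l2_normalize_rows(X), l2_normalize_rows(Tensor(Y)), labels, tau,
                mode=m,
            ),
            rng.normal(size=(n, d)),
        )
        # gradient w.r.t. the text side as well
        _grad_check(
            lambda X, m=mode: cmpm_graph(
                l2_normalize_rows(Tensor(Y)), l2_normalize_rows(X), labels, tau,
                mode=m,
            ),
            rng.normal(size=(n, d)),
        )
    _grad_check(
        lambda X: id_graph(l2_normalize_rows(X), labels, Tensor(W), Tensor(b)),
        rng.normal(size=(n, d)),
    )
    _grad_check(
        lambda Wt: id_graph(
            l2_normalize_rows(Tensor(Y)), labels, Wt, Tensor(b)
        ),
        rng.normal(size=(d, c)),
    )


# -- target semantics ----------------------------------------------------------

def test_label_aware_target_spreads_mass_over_same_class_columns():
    labels = np.array([0, 0, 1])
    q = match_distribution(labels)
    assert np.allclose(q[0], [0.5, 0.5, 0.0])
    assert np.allclose(q[1], [0.5, 0.5, 0.0])
    assert np.allclose(q[2], [0.0, 0.0, 1.0])


def test_distinct_labels_reduce_label_aware_target_to_identity():
    q = match_distribution(np.array([2, 0, 1]))
    assert np.array_equal(q, np.eye(3))


def test_increasing_diagonal_similarity_never_increases_instance_cmpm():
    rng = np.random.default_rng(8)
    n, d = 6, 8
    logits = rng.normal(size=(n, n))
    labels = np.arange(n)

    def loss_from_logits(lg):
        # same computation as instance_softmax on precomputed logits
        from polypclip._autodiff import log_softmax as ls
        t = Tensor(lg)
        eye = np.eye(n)
        a = -(ls(t, axis=1).data * eye).sum() / n
        b = -(ls(t.T, axis=1).data * eye).sum() / n
        return 0.5 * (a + b)

    base = loss_from_logits(logits)
    for bump in (0.1, 0.5, 2.0):
        boosted = logits + np.eye(n) * bump
        assert loss_from_logits(boosted) <= base + 1e-12
        base = loss_from_logits(boosted)
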