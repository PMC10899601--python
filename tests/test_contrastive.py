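"""Contrastive pretraining mechanics: similarity, InfoNCE closed forms,
momentum/queue semantics, determinism and learning progress."""

import numpy as np
import pytest

from wsimil import contrastive, prep, synthetic
from wsimil.contrastive import (AugmentationPolicy, MemoryQueue,
                                PretrainConfig, cosine_sim, info_nce_loss,
                                momentum_update)
from conftest import quick_params


def make_bag(params=None, slide_seed=0, min_frac=0.25):
    params = params or quick_params(slide_px=256, tumor_prevalence=1.0, seed=5)
    s = synthetic.make_slide(params, slide_seed)
    slide = prep.SlideRaster(pixels=s.raster, slide_id=s.slide_id)
    mask = prep.segment_tissue(slide, downsample=4)
    return prep.tessellate(slide, mask, tile_px=params.tile_px,
                           min_tissue_frac=min_frac), s


# ------------------------------------------------------- similarity
def test_cosine_self_orthogonal_and_hand_case():
    v = np.array([3.0, 4.0])
    assert cosine_sim(v, v, 1.0) == pytest.approx(1.0)
    assert cosine_sim([1.0, 0.0], [0.0, 1.0], 0.5) == pytest.approx(0.0)
    assert cosine_sim([1.0, 1.0], [1.0, 0.0], 1.0) == pytest.approx(1 / np.sqrt(2))


def test_cosine_temperature_scaling_and_errors():
    assert cosine_sim([1.0, 0.0], [1.0, 0.0], 0.1) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        cosine_sim([0.0, 0.0], [1.0, 0.0], 1.0)
    with pytest.raises(ValueError):
        cosine_sim([1.0], [1.0], 0.0)


# ------------------------------------------------------- InfoNCE
def queue_from(vectors):
    v = np.asarray(vectors, dtype=float)
    q = MemoryQueue(K=len(v), dim=v.shape[1])
    q.enqueue(v)
    return q


def test_info_nce_identical_positive_orthogonal_negatives():
    z = np.array([1.0, 0.0, 0.0])
    q = queue_from([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    # -log(e / (e + 2)) = 0.551444...
    got = info_nce_loss(z, z, q, tau=1.0)
    assert got == pytest.approx(-np.log(np.e / (np.e + 2)), abs=1e-12)


def test_info_nce_all_orthogonal_is_log_k_plus_1():
    dim = 8
    z = np.eye(dim)[0]
    q = queue_from(np.eye(dim)[2:7])            # K = 5 orthogonal negatives
    got = info_nce_loss(z, np.eye(dim)[1], q, tau=1.0)
    assert got == pytest.approx(np.log(5 + 1), abs=1e-12)


def test_info_nce_literal_denominator_variant():
    dim = 4
    z = np.eye(dim)[0]
    q = queue_from(np.eye(dim)[2:4])
    got = info_nce_loss(z, np.eye(dim)[1], q, tau=1.0, include_positive=False)
    assert got == pytest.approx(np.log(2), abs=1e-12)       # -log(1/K)


def test_info_nce_monte_carlo_high_dimension(rng):
    """Random unit vectors in high dim are near-orthogonal, so the expected
    loss approaches log(K+1)."""
    dim, K, n = 256, 64, 200
    vecs = rng.standard_normal((K, dim))
    q = queue_from(vecs)
    losses = []
    for _ in range(n):
        z = rng.standard_normal(dim)
        zp = rng.standard_normal(dim)
        losses.append(info_nce_loss(z, zp, q, tau=1.0))
    assert np.mean(losses) == pytest.approx(np.log(K + 1), abs=0.15)


# ------------------------------------------------------- momentum / queue
def test_momentum_zero_copies_online_params():
    state = contrastive.EncoderState(PretrainConfig(queue_size=8))
    for p in state.parameters():
        p.data += 0.37                      # desynchronize branches
    momentum_update(state, m=0.0)
    for p, pm in zip(state.parameters(), state.momentum_parameters()):
        assert np.allclose(p.data, pm.data)


def test_momentum_fixed_point_with_frozen_online():
    state = contrastive.EncoderState(PretrainConfig(queue_size=8))
    before = [pm.data.copy() for pm in state.momentum_parameters()]
    momentum_update(state, m=0.999)
    momentum_update(state, m=0.999)
    for pm, b in zip(state.momentum_parameters(), before):
        assert np.allclose(pm.data, b)      # branches equal at init -> EMA no-op
    with pytest.raises(ValueError):
        momentum_update(state, m=1.0)


def test_queue_fifo_replay(rng):
    b, B = 4, 3
    K = b * B
    q = MemoryQueue(K=K, dim=5)
    batches = [rng.standard_normal((b, 5)) for _ in range(2 * B)]
    for batch in batches:
        q.enqueue(batch)
    expect = np.concatenate(batches[B:], axis=0)
    expect = expect / np.linalg.norm(expect, axis=1, keepdims=True)
    assert np.allclose(q.snapshot(), expect)
    assert np.allclose(np.linalg.norm(q.buffer, axis=1), 1.0)


# ------------------------------------------------------- augmentation
def test_augmentation_draws_are_independent(rng):
    bag, _ = make_bag()
    policy = AugmentationPolicy()
    a = policy(bag.pixels[0], 32, np.random.default_rng(1))
    b = policy(bag.pixels[0], 32, np.random.default_rng(2))
    assert a.shape == (3, 32, 32)
    assert not np.allclose(a, b)


# ------------------------------------------------------- pretrain/embed
@pytest.fixture(scope="module")
def toy_pretrained():
    bags = [make_bag(slide_seed=i)[0] for i in range(4)]
    cfg = PretrainConfig(epochs=4, queue_size=64, batch_size=32, seed=7)
    return bags, contrastive.pretrain(bags, cfg)


def test_pretrain_deterministic_under_fixed_seed():
    bag, _ = make_bag()
    cfg = PretrainConfig(epochs=1, queue_size=32, batch_size=16, seed=3)
    s1 = contrastive.pretrain([bag], cfg)
    s2 = contrastive.pretrain([bag], cfg)
    assert s1.history == s2.history
    for p1, p2 in zip(s1.parameters(), s2.parameters()):
        assert np.array_equal(p1.data, p2.data)


@pytest.fixture(scope="module")
def separable_pretrained():
    """Pretraining on tiles that are individually distinguishable (one base
    color per tile), where instance discrimination is learnable."""
    rng = np.random.default_rng(0)
    colors = rng.integers(30, 225, (48, 3))
    tiles = (colors[:, None, None, :]
             + rng.normal(0, 8, (48, 64, 64, 3))).clip(0, 255).astype(np.uint8)
    bag = prep.TileBag(slide_id="x", coords=np.zeros((48, 2), int),
                       pixels=tiles, tile_px=64, magnification=40)
    cfg = PretrainConfig(epochs=24, queue_size=64, batch_size=24, seed=7)
    return bag, contrastive.pretrain([bag], cfg)


def test_pretrain_loss_decreases_on_separable_tiles(separable_pretrained):
    _, state = separable_pretrained
    assert np.mean(state.history[-6:]) < state.history[0]


def test_pretrain_config_echoes_stated_defaults():
    cfg = PretrainConfig()
    assert cfg.lr == 0.03
    assert cfg.weight_decay == 1e-4
    assert cfg.momentum == 0.9


def test_pretrain_requires_tiles():
    bag, _ = make_bag()
    bag.pixels = bag.pixels[:1]
    bag.coords = bag.coords[:1]
    with pytest.raises(ValueError):
        contrastive.pretrain([bag], PretrainConfig(epochs=1))


def test_embed_purity_and_empty_bag(toy_pretrained):
    bags, state = toy_pretrained
    bag = bags[0]
    H = contrastive.embed(bag, state)
    assert H.shape == (len(bag), state.config.embed_dim)
    dup = prep.TileBag(slide_id="d", coords=np.zeros((2, 2), int),
                       pixels=np.stack([bag.pixels[0], bag.pixels[0]]),
                       tile_px=bag.tile_px, magnification=40)
    Hd = contrastive.embed(dup, state)
    assert np.array_equal(Hd[0], Hd[1])
    empty = prep.TileBag(slide_id="e", coords=np.zeros((0, 2), int),
                         pixels=np.empty((0, 64, 64, 3), np.uint8),
                         tile_px=64, magnification=40)
    assert contrastive.embed(empty, state).shape == (0, state.config.embed_dim)


def test_positive_pairs_more_similar_than_random(separable_pretrained):
    """After pretraining, augmented views of one tile embed closer together
    than views of different tiles."""
    bag, state = separable_pretrained
    tiles = bag.pixels[:40]
    policy = AugmentationPolicy()
    rng = np.random.default_rng(0)
    zs = []
    for t in tiles:
        pair = np.stack([policy(t, state.config.in_px, rng) for _ in range(2)])
        z = state.project(contrastive.Tensor(pair)).data
        zs.append(z)
    zs = np.array(zs)                               # (n, 2, d_z)
    pos = np.mean([z[0] @ z[1] for z in zs])
    rand = np.mean([zs[i, 0] @ zs[j, 1]
                    for i in range(len(zs)) for j in range(len(zs)) if i != j])
    assert pos > rand + 0.05


def test_checkpoint_roundtrip(tmp_path, toy_pretrained):
    bags, state = toy_pretrained
    path = tmp_path / "enc.npz"
    contrastive.save_checkpoint(state, path)
    loaded = contrastive.load_checkpoint(path)
    H1 = contrastive.embed(bags[0], state)
    H2 = contrastive.embed(bags[0], loaded)
    assert np.array_equal(H1, H2)
    assert loaded.queue.head == state.queue.head


def test_queue_size_constant_after_warmup(toy_pretrained):
    _, state = toy_pretrained
    assert state.queue.buffer.shape == (state.config.queue_size,
                                        state.config.proj_dim)
    assert np.allclose(np.linalg.norm(state.queue.buffer, axis=1), 1.0)


def test_subsample_bags_fraction_and_cap():
    bags = [make_bag(slide_seed=i)[0] for i in range(4)]
    out = contrastive.subsample_bags(bags, fraction=0.2, max_slides=2, seed=0)
    assert len(out) == 2
    for pixels, _ in out:
        full = next(len(b) for b in bags if b.slide_id == _)
        assert len(pixels) == max(1, round(0.2 * full))
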