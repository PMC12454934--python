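"""Fragmentation, overlap-mean merging, the token contract, and PEFT."""

import numpy as np
import pytest

from targetpep._autodiff import Tensor
from targetpep.alphabet import encode_tokens
from targetpep.encoder import (
    AdapterTuning,
    FullFineTune,
    LastK,
    LoRA,
    TransformerBackbone,
    apply_peft,
    merge_fragment_embeddings,
    plan_fragments,
)
from targetpep.nnet import Adam


def merge_oracle(plan, blocks):
    """Per-position oracle: list covering fragments, average their rows."""
    D = blocks[0].shape[1]
    out = np.zeros((plan.length, D))
    for pos in range(plan.length):
        rows = [
            blocks[k][pos - off]
            for k, (off, flen) in enumerate(plan.fragments)
            if off <= pos < off + flen
        ]
        out[pos] = np.mean(rows, axis=0)
    return out


def small_backbone(**kw):
    defaults = dict(d_model=16, n_layers=3, n_heads=2, d_ff=32,
                    fragment_length=40, overlap=10, seed=0)
    defaults.update(kw)
    return TransformerBackbone(**defaults)


# ---------------------------------------------------------------------------
# fragmentation plans
# ---------------------------------------------------------------------------

def test_plan_single_fragment_cases():
    assert plan_fragments(1022).fragments == ((0, 1022),)
    assert plan_fragments(500).fragments == ((0, 500),)
    assert plan_fragments(1).fragments == ((0, 1),)


def test_plan_two_fragments_share_exactly_the_overlap():
    plan = plan_fragments(1844)
    assert plan.fragments == ((0, 1022), (822, 1022))
    # shared region = positions 822..1021, exactly 200 positions
    assert 1022 - 822 == 200
    counts = plan.coverage_counts()
    assert (counts[822:1022] == 2).all()
    assert (counts[:822] == 1).all() and (counts[1022:] == 1).all()


def test_plan_rejects_bad_overlap():
    with pytest.raises(ValueError):
        plan_fragments(100, fragment_length=50, overlap=50)
    with pytest.raises(ValueError):
        plan_fragments(0)


def test_plan_covers_every_position_for_all_lengths():
    for L in range(1, 3001):
        plan = plan_fragments(L, fragment_length=1022, overlap=200)
        counts = plan.coverage_counts()
        assert counts.min() >= 1
        assert counts.size == L
        for (o1, l1), (o2, l2) in zip(plan.fragments, plan.fragments[1:]):
            shared = (o1 + l1) - o2
            assert shared == 200 or o2 + l2 == L and shared >= 0


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_mean_of_constant_blocks():
    plan = plan_fragments(30, fragment_length=20, overlap=10)
    blocks = [np.full((l, 4), v) for (_, l), v in
              zip(plan.fragments, [1.0, 3.0])]
    merged = merge_fragment_embeddings(plan, blocks)
    assert merged.shape == (30, 4)
    np.testing.assert_allclose(merged[:10], 1.0)
    np.testing.assert_allclose(merged[10:20], 2.0)  # overlap mean
    np.testing.assert_allclose(merged[20:], 3.0)


def test_merge_matches_per_position_oracle(rng):
    for L in (1, 2, 35, 40, 41, 73, 95, 130):
        plan = plan_fragments(L, fragment_length=40, overlap=10)
        blocks = [rng.normal(size=(l, 5)) for (_, l) in plan.fragments]
        merged = merge_fragment_embeddings(plan, blocks)
        np.testing.assert_allclose(merged, merge_oracle(plan, blocks),
                                   atol=1e-12)


def test_merge_rejects_wrong_block_shape():
    plan = plan_fragments(50, fragment_length=40, overlap=10)
    blocks = [np.zeros((40, 4)), np.zeros((19, 4))]
    with pytest.raises(ValueError, match="fragment length"):
        merge_fragment_embeddings(plan, blocks)


# ---------------------------------------------------------------------------
# backbone token contract
# ---------------------------------------------------------------------------

def test_backbone_strips_special_tokens():
    backbone = small_backbone()
    block = backbone.encode(encode_tokens("ACDEFGHIKL"))
    assert block.shape == (10, 16)


def test_backbone_padded_batch_strips_pads():
    backbone = small_backbone()
    frags = [encode_tokens("ACDEF"), encode_tokens("ACDEFGHIK")]
    blocks = backbone.encode_fragment_batch(frags)
    assert blocks[0].shape[0] == 5
    assert blocks[1].shape[0] == 9
    # padding must not change the result of the shorter fragment
    solo = backbone.encode(frags[0])
    np.testing.assert_allclose(blocks[0].data, solo, atol=1e-10)


def test_backbone_deterministic_in_eval():
    backbone = small_backbone().eval()
    tokens = encode_tokens("MKTAYIAKQR")
    np.testing.assert_array_equal(backbone.encode(tokens),
                                  backbone.encode(tokens))


def test_backbone_rejects_out_of_vocab_and_long_fragment():
    backbone = small_backbone()
    with pytest.raises(ValueError, match="vocabulary"):
        backbone.encode(np.array([999]))
    with pytest.raises(ValueError, match="exceeds"):
        backbone.encode(np.zeros(41, dtype=int) + 3)


def test_encode_sequences_merges_to_sequence_length():
    backbone = small_backbone()
    seqs = ["ACDEFGHIKL" * 9, "ACDEF"]  # 90 -> multi-fragment, 5 -> single
    outs = backbone.encode_sequences(seqs)
    assert outs[0].shape == (90, 16)
    assert outs[1].shape == (5, 16)
    # single-fragment path is the identity on the encoded block
    solo = backbone.encode(encode_tokens("ACDEF"))
    np.testing.assert_allclose(outs[1].data, solo, atol=1e-10)


# ---------------------------------------------------------------------------
# PEFT
# ---------------------------------------------------------------------------

def _train_step(backbone, lr=1e-2):
    params = backbone.parameters()
    opt = Adam(params, lr=lr)
    tokens = encode_tokens("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    (block,) = backbone.encode_fragment_batch([tokens])
    loss = (block ** 2).sum()
    opt.zero_grad()
    loss.backward()
    opt.step()


@pytest.mark.parametrize("strategy", [
    LastK(k=2),
    LoRA(r=2, n_layers=2),
    AdapterTuning(bottleneck=4, n_layers=2),
])
def test_frozen_parameters_unchanged_after_training_step(strategy):
    backbone = small_backbone()
    apply_peft(backbone, strategy, seed=1)
    frozen_before = {
        name: p.data.copy()
        for name, p in backbone.named_parameters()
        if not p.requires_grad
    }
    assert frozen_before
    _train_step(backbone)
    for name, p in backbone.named_parameters():
        if name in frozen_before:
            np.testing.assert_array_equal(p.data, frozen_before[name])


def test_last_k_unfreezes_only_the_last_layers():
    backbone = small_backbone()
    report = apply_peft(backbone, LastK(k=2), seed=0)
    layers = list(backbone.layers)
    assert not any(p.requires_grad for p in layers[0].parameters())
    assert all(p.requires_grad for p in layers[1].parameters())
    assert all(p.requires_grad for p in layers[2].parameters())
    assert not backbone.token_embed.weight.requires_grad
    assert 0 < report["trainable_parameters"] < report["total_parameters"]


def test_lora_identity_at_init_and_parameter_count():
    backbone = small_backbone()
    tokens = encode_tokens("MKTAYIAKQRQISFVKSHF")
    before = backbone.encode(tokens).copy()
    r, n_layers = 2, 2
    report = apply_peft(backbone, LoRA(r=r, n_layers=n_layers), seed=1)
    after = backbone.encode(tokens)
    np.testing.assert_array_equal(before, after)  # B = 0 at init, bitwise
    d = 16
    expected = n_layers * 3 * r * (d + d)  # Q,K,V wrapped per layer
    assert report["trainable_parameters"] == expected
    full = report["total_parameters"]
    assert expected < full


def test_adapter_identity_at_init_bitwise():
    backbone = small_backbone()
    tokens = encode_tokens("MKTAYIAKQRQISFVKSHF")
    before = backbone.encode(tokens).copy()
    apply_peft(backbone, AdapterTuning(bottleneck=4, n_layers=3), seed=2)
    np.testing.assert_array_equal(before, backbone.encode(tokens))


def test_apply_peft_depth_validation_and_full():
    backbone = small_backbone()
    with pytest.raises(ValueError, match="exceeds depth"):
        apply_peft(backbone, LastK(k=9))
    with pytest.raises(ValueError):
        apply_peft(backbone, LoRA(r=2, n_layers=99))
    report = apply_peft(backbone, FullFineTune())
    assert report["trainable_parameters"] == report["total_parameters"]


def test_lora_rank_warning():
    backbone = small_backbone()
    with pytest.warns(UserWarning, match="rank"):
        apply_peft(backbone, LoRA(r=16, n_layers=1), seed=0)


def test_external_backbone_satisfies_the_contract():
    # a stand-in pretrained encoder: one-hot of token ids, D = 24
    def fake_encoder(tokens):
        out = np.zeros((tokens.size, 24))
        out[np.arange(tokens.size), tokens] = 1.0
        return out

    from targetpep.encoder import ExternalBackbone

    backbone = ExternalBackbone(fake_encoder, d_model=24,
                                fragment_length=30, overlap=10)
    seq = "ACDEFGHIKL" * 5  # 50 residues -> multiple fragments
    (merged,) = backbone.encode_sequences([seq])
    assert merged.shape == (50, 24)
    # deterministic encoder + mean merge: merged rows remain one-hot
    np.testing.assert_allclose(merged.data.sum(axis=1), 1.0)

    def bad_encoder(tokens):
        return np.zeros((tokens.size + 1, 24))

    bad = ExternalBackbone(bad_encoder, d_model=24, fragment_length=30,
                           overlap=10)
    with pytest.raises(ValueError, match="expected"):
        bad.encode(np.zeros(5, dtype=int))
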