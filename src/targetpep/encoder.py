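"""Fragment-based sequence encoding with overlap-mean reassembly.

A protein of any length is cut into fixed-length fragments (default 1022
residues) with a fixed overlap (default 200) between consecutive fragments;
each fragment is encoded independently by a transformer backbone under the
usual protein-language-model token contract (a BEGIN ``<cls>`` token, an
END ``<eos>`` token, ``<pad>`` for short fragments, all stripped from the
returned per-residue embeddings), and positions covered by several
fragments get the arithmetic mean of their embeddings.  The backbone here
is a small trainable transformer; the fragment/merge contract is
encoder-agnostic, so a pretrained protein language model can stand behind
the same interface.

Three parameter-efficient fine-tuning strategies operate on the backbone:
training only the last K transformer layers, LoRA low-rank updates on the
query/key/value projections of the last N layers, and bottleneck adapters
inserted twice per layer (after attention and after the feed-forward block)
in the last N layers.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import Tensor, concat, stack
from .alphabet import CLS_ID, EOS_ID, PAD_ID, VOCAB, encode_tokens
from .nnet import (
    Adapter,
    Embedding,
    LayerNorm,
    LoRALinear,
    Module,
    ModuleList,
    TransformerLayer,
)

__all__ = [
    "FragmentationPlan",
    "plan_fragments",
    "merge_fragment_embeddings",
    "FragmentEncoderBase",
    "ExternalBackbone",
    "TransformerBackbone",
    "LastK",
    "LoRA",
    "AdapterTuning",
    "FullFineTune",
    "apply_peft",
]


@dataclasses.dataclass(frozen=True)
class FragmentationPlan:
    length: int
    fragment_length: int
    overlap: int
    fragments: tuple[tuple[int, int], ...]  # (offset, length), 0-based

    def coverage_counts(self) -> np.ndarray:
        counts = np.zeros(self.length, dtype=int)
        for offset, flen in self.fragments:
            counts[offset : offset + flen] += 1
        return counts


def plan_fragments(L: int, fragment_length: int = 1022,
                   overlap: int = 200) -> FragmentationPlan:
    """Tile positions 0..L-1 with overlapping fixed-stride fragments.

    Offsets advance by ``stride = fragment_length - overlap``; the final
    fragment is truncated at the sequence end (not re-anchored), so every
    consecutive pair shares exactly ``overlap`` positions.
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    if not 0 <= overlap < fragment_length:
        raise ValueError("need 0 <= overlap < fragment_length")
    stride = fragment_length - overlap
    fragments: list[tuple[int, int]] = []
    offset = 0
    while True:
        flen = min(fragment_length, L - offset)
        fragments.append((offset, flen))
        if offset + fragment_length >= L:
            break
        offset += stride
    return FragmentationPlan(L, fragment_length, overlap, tuple(fragments))


def merge_fragment_embeddings(
    plan: FragmentationPlan, fragment_embeddings: list[np.ndarray]
) -> np.ndarray:
    """Overlap-mean reassembly of per-fragment blocks into an L x D matrix."""
    if len(fragment_embeddings) != len(plan.fragments):
        raise ValueError("one embedding block required per fragment")
    blocks = [np.asarray(b, dtype=float) for b in fragment_embeddings]
    for (offset, flen), block in zip(plan.fragments, blocks):
        if block.ndim != 2 or block.shape[0] != flen:
            raise ValueError(
                f"block shape {block.shape} does not match fragment length {flen}"
            )
    D = blocks[0].shape[1]
    total = np.zeros((plan.length, D))
    for (offset, flen), block in zip(plan.fragments, blocks):
        total[offset : offset + flen] += block
    return total / plan.coverage_counts()[:, None]


class FragmentEncoderBase(Module):
    """Shared fragment/merge plumbing for any per-residue encoder.

    Subclasses implement :meth:`encode_fragment_batch`; everything above it
    (single-fragment contract, whole-sequence fragment/merge) is generic.
    """

    fragment_length: int
    overlap: int

    def encode(self, tokens: np.ndarray) -> np.ndarray:
        """Contract entry point: one fragment in, one (len x D) block out."""
        (block,) = self.encode_fragment_batch([tokens])
        return block.data

    def encode_sequences(self, sequences: list[str]) -> list[Tensor]:
        """Fragment, encode and merge each sequence; differentiable path."""
        plans = [plan_fragments(len(s), self.fragment_length, self.overlap)
                 for s in sequences]
        all_fragments: list[np.ndarray] = []
        for seq, plan in zip(sequences, plans):
            tokens = encode_tokens(seq)
            for offset, flen in plan.fragments:
                all_fragments.append(tokens[offset : offset + flen])
        blocks = self.encode_fragment_batch(all_fragments)
        out: list[Tensor] = []
        cursor = 0
        for plan in plans:
            n = len(plan.fragments)
            out.append(self._merge(plan, blocks[cursor : cursor + n]))
            cursor += n
        return out

    @staticmethod
    def _merge(plan: FragmentationPlan, blocks: list[Tensor]) -> Tensor:
        if len(blocks) == 1:
            return blocks[0]
        D = blocks[0].shape[1]
        total = None
        for (offset, flen), block in zip(plan.fragments, blocks):
            before = Tensor(np.zeros((offset, D)))
            after = Tensor(np.zeros((plan.length - offset - flen, D)))
            padded = concat([before, block, after], axis=0)
            total = padded if total is None else total + padded
        counts = plan.coverage_counts().astype(float)[:, None]
        return total * (1.0 / counts)


class ExternalBackbone(FragmentEncoderBase):
    """Adapter putting a pretrained per-residue encoder behind the contract.

    ``encode_fn`` receives one fragment's token ids (no special tokens; the
    callee applies its own BEGIN/END/pad discipline and strips them) and
    returns a (fragment length x D) array.  The adapter is non-trainable;
    it exists so a protein language model can replace the built-in
    transformer without touching the rest of the pipeline.
    """

    def __init__(self, encode_fn, d_model: int,
                 fragment_length: int = 1022, overlap: int = 200):
        super().__init__()
        self.encode_fn = encode_fn
        self.d_model = d_model
        self.fragment_length = fragment_length
        self.overlap = overlap

    def encode_fragment_batch(self, fragments: list[np.ndarray]) -> list[Tensor]:
        blocks = []
        for frag in fragments:
            block = np.asarray(self.encode_fn(np.asarray(frag)), dtype=float)
            if block.ndim != 2 or block.shape != (frag.size, self.d_model):
                raise ValueError(
                    f"external encoder returned shape {block.shape}, "
                    f"expected ({frag.size}, {self.d_model})"
                )
            blocks.append(Tensor(block))
        return blocks


class TransformerBackbone(FragmentEncoderBase):
    """Small trainable transformer encoder with the PLM token contract."""

    def __init__(self, d_model: int = 64, n_layers: int = 2, n_heads: int = 4,
                 d_ff: int = 128, fragment_length: int = 1022,
                 overlap: int = 200, local_conv_kernel: int = 7,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.d_model = d_model
        self.fragment_length = fragment_length
        self.overlap = overlap
        self.config = dict(d_model=d_model, n_layers=n_layers,
                           n_heads=n_heads, d_ff=d_ff,
                           fragment_length=fragment_length, overlap=overlap,
                           local_conv_kernel=local_conv_kernel,
                           seed=seed)
        self.token_embed = Embedding(len(VOCAB), d_model, rng)
        self.pos_embed = Embedding(fragment_length + 2, d_model, rng)
        # distance-from-fragment-end embedding: terminus-anchored signals
        # (ER/PTS at the C-terminus, cleavage boundaries) need "how far from
        # the end" as much as "how far from the start"
        self.rev_pos_embed = Embedding(fragment_length + 2, d_model, rng)
        self.layers = ModuleList(
            TransformerLayer(d_model, n_heads, d_ff, rng)
            for _ in range(n_layers)
        )
        # residual local-context block: attention is poor at exact
        # relative-offset pattern matching, so a depth-preserving
        # convolution gives every residue a crisp view of its k-window
        # (short motifs such as the C-terminal tri/tetrapeptides need it)
        from .nnet import Conv1d

        self.local_conv = (
            Conv1d(d_model, d_model, local_conv_kernel, rng)
            if local_conv_kernel else None
        )
        self.ln_final = LayerNorm(d_model)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    # -- token handling -------------------------------------------------------
    def _validate_tokens(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.size and (tokens.min() < 0 or tokens.max() >= len(VOCAB)):
            raise ValueError("token id out of vocabulary")
        if tokens.size > self.fragment_length:
            raise ValueError(
                f"fragment of {tokens.size} tokens exceeds fragment_length "
                f"{self.fragment_length}"
            )
        return tokens

    def encode_fragment_batch(self, fragments: list[np.ndarray]) -> list[Tensor]:
        """Encode token fragments jointly; returns stripped per-residue blocks.

        Fragments are padded to a common length for batching; the CLS/EOS
        rows and all pad rows are stripped, so block i has exactly
        ``len(fragments[i])`` rows.
        """
        fragments = [self._validate_tokens(f) for f in fragments]
        lengths = [f.size for f in fragments]
        width = max(lengths) + 2
        B = len(fragments)
        ids = np.full((B, width), PAD_ID, dtype=np.int64)
        mask = np.zeros((B, width), dtype=bool)
        rev = np.zeros((B, width), dtype=np.int64)
        for i, frag in enumerate(fragments):
            ids[i, 0] = CLS_ID
            ids[i, 1 : 1 + frag.size] = frag
            ids[i, 1 + frag.size] = EOS_ID
            mask[i, : frag.size + 2] = True
            n = frag.size + 2
            rev[i, :n] = np.arange(n - 1, -1, -1)  # EOS at distance 0
        pos = np.broadcast_to(np.arange(width), (B, width))
        x = (self.token_embed(ids) + self.pos_embed(pos)
             + self.rev_pos_embed(rev))
        for layer in self.layers:
            x = layer(x, mask)
        if self.local_conv is not None:
            # zero padded rows first so batch padding cannot leak into the
            # conv windows of shorter fragments
            x = x * mask[:, :, None]
            x = x + self.local_conv(x).gelu()
        x = self.ln_final(x)
        return [x[i, 1 : 1 + lengths[i], :] for i in range(B)]

def backbone_encode(backbone: FragmentEncoderBase,
                    tokens: np.ndarray) -> np.ndarray:
    """Functional alias for the single-fragment encoding contract."""
    return backbone.encode(tokens)


# ---------------------------------------------------------------------------
# PEFT strategies
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LastK:
    k: int = 2


@dataclasses.dataclass(frozen=True)
class LoRA:
    r: int = 4
    n_layers: int = 2


@dataclasses.dataclass(frozen=True)
class AdapterTuning:
    bottleneck: int | None = None  # default d_model // 4
    n_layers: int = 2


@dataclasses.dataclass(frozen=True)
class FullFineTune:
    """Train every backbone parameter (for from-scratch backbones)."""


def apply_peft(backbone: TransformerBackbone, strategy,
               seed: int = 0) -> dict:
    """Configure trainability of the backbone under one PEFT strategy.

    Mutates the backbone in place (freezing parameters; for LoRA/adapters
    also inserting the new trainable modules) and returns a report with
    trainable/total parameter counts.
    """
    rng = np.random.default_rng(seed)
    depth = backbone.n_layers
    layers = list(backbone.layers)

    if isinstance(strategy, FullFineTune):
        backbone.unfreeze()
        name = "full"
    elif isinstance(strategy, LastK):
        if not 1 <= strategy.k <= depth:
            raise ValueError(f"last_k K={strategy.k} exceeds depth {depth}")
        backbone.freeze()
        for layer in layers[depth - strategy.k :]:
            layer.unfreeze()
        backbone.ln_final.unfreeze()
        name = f"last_{strategy.k}"
    elif isinstance(strategy, LoRA):
        if not 1 <= strategy.n_layers <= depth:
            raise ValueError(
                f"lora n_layers={strategy.n_layers} exceeds depth {depth}"
            )
        backbone.freeze()
        for layer in layers[depth - strategy.n_layers :]:
            attn = layer.attn
            attn.q_proj = LoRALinear(attn.q_proj, strategy.r, rng)
            attn.k_proj = LoRALinear(attn.k_proj, strategy.r, rng)
            attn.v_proj = LoRALinear(attn.v_proj, strategy.r, rng)
        name = f"lora_r{strategy.r}"
    elif isinstance(strategy, AdapterTuning):
        if not 1 <= strategy.n_layers <= depth:
            raise ValueError(
                f"adapter n_layers={strategy.n_layers} exceeds depth {depth}"
            )
        backbone.freeze()
        bottleneck = strategy.bottleneck or max(1, backbone.d_model // 4)
        for layer in layers[depth - strategy.n_layers :]:
            layer.adapter_attn = Adapter(backbone.d_model, bottleneck, rng)
            layer.adapter_ffn = Adapter(backbone.d_model, bottleneck, rng)
        name = f"adapter_b{bottleneck}"
    else:
        raise TypeError(f"unknown PEFT strategy {strategy!r}")

    total = backbone.num_parameters()
    trainable = backbone.num_parameters(trainable_only=True)
    return {
        "strategy": name,
        "total_parameters": int(total),
        "trainable_parameters": int(trainable),
        "frozen_parameters": int(total - trainable),
    }
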