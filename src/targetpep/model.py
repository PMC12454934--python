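"""Eight task-specific heads over a shared sequence encoder.

Every head maps the shared L x D embedding matrix to a per-residue signal
strength in [0, 1] through an independent logistic output (independence
across classes is what permits multi-label proteins such as CH+TH; a joint
softmax would forbid coexistence).  NLS and NES use stacked same-padded 1-D
convolutions, because those signals are variable-length local patterns that
can sit anywhere; the six terminus-anchored classes use position-wise
multi-layer perceptrons.  The eight per-residue strength vectors stack into
the 8 x L signal matrix that inference and the losses consume.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._autodiff import Tensor, concat
from .alphabet import N_CLASSES, SIGNAL_CLASSES
from .encoder import TransformerBackbone
from .nnet import Conv1d, Dropout, Linear, Module, ModuleList
from .seqio import ProteinRecord

__all__ = ["SignalMatrix", "ModelConfig", "InternalHead", "TerminalHead",
           "SignalModel"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclasses.dataclass
class SignalMatrix:
    """The model's raw output: per-class, per-residue signal strengths."""

    protein_id: str
    matrix: np.ndarray  # (8, L), values in [0, 1]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != N_CLASSES:
            raise ValueError(f"signal matrix must be 8 x L, got {m.shape}")
        if m.size and (m.min() < 0.0 or m.max() > 1.0):
            raise ValueError("signal strengths must lie in [0, 1]")
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    fragment_length: int = 1022
    overlap: int = 200
    local_conv_kernel: int = 7  # backbone local-context block; 0 disables
    conv_channels: int = 32
    conv_kernels: tuple[int, ...] = (7, 11, 15)
    mlp_hidden: int = 128
    dropout: float = 0.0
    zero_init_output: bool = False
    #: prior bias of each head's logistic output; -2 starts strengths near
    #: the background rate (~0.12) instead of 0.5, so early gradients come
    #: from the rare positives rather than from pushing negatives down
    output_bias: float = -2.0
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["conv_kernels"] = list(d["conv_kernels"])
        return json.dumps(d)

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        d = json.loads(s)
        d["conv_kernels"] = tuple(d["conv_kernels"])
        return ModelConfig(**d)


class InternalHead(Module):
    """CNN head for variable-length internal signals (NLS, NES)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c = config.conv_channels
        widths = [config.d_model] + [c] * (len(config.conv_kernels) - 1) + [1]
        self.convs = ModuleList(
            Conv1d(widths[i], widths[i + 1], k, rng,
                   zero_init=(config.zero_init_output
                              and i == len(config.conv_kernels) - 1))
            for i, k in enumerate(config.conv_kernels)
        )
        if not config.zero_init_output:
            list(self.convs)[-1].bias.data[:] = config.output_bias

    def forward(self, x: Tensor) -> Tensor:
        convs = list(self.convs)
        for conv in convs[:-1]:
            x = conv(x).relu()
        return convs[-1](x).sigmoid()

    __call__ = forward


class TerminalHead(Module):
    """Position-wise MLP head for terminus-anchored signals."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(config.d_model, config.mlp_hidden, rng)
        self.fc2 = Linear(config.mlp_hidden, 1, rng,
                          zero_init=config.zero_init_output)
        if not config.zero_init_output:
            self.fc2.bias.data[:] = config.output_bias

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu()).sigmoid()

    __call__ = forward


class SignalModel(Module):
    """Shared encoder plus one head per targeting-peptide class."""

    def __init__(self, config: ModelConfig | None = None,
                 backbone: TransformerBackbone | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed + 1)
        if backbone is None:
            backbone = TransformerBackbone(
                d_model=self.config.d_model,
                n_layers=self.config.n_layers,
                n_heads=self.config.n_heads,
                d_ff=self.config.d_ff,
                fragment_length=self.config.fragment_length,
                overlap=self.config.overlap,
                local_conv_kernel=self.config.local_conv_kernel,
                seed=self.config.seed,
            )
        self.backbone = backbone
        self.dropout = Dropout(self.config.dropout, rng)
        heads = []
        for cls in SIGNAL_CLASSES:
            if cls in ("NLS", "NES"):
                heads.append(InternalHead(self.config, rng))
            else:
                heads.append(TerminalHead(self.config, rng))
        self.heads = ModuleList(heads)

    def head(self, signal_class: str) -> Module:
        return self.heads[SIGNAL_CLASSES.index(signal_class)]

    # -- forward passes --------------------------------------------------------
    def forward_batch(self, sequences: list[str]
                      ) -> tuple[Tensor, np.ndarray]:
        """Batched forward: returns strengths (B, Lmax, 8) and a valid mask.

        All eight heads consume the identical shared embedding tensor.
        """
        embeddings = self.backbone.encode_sequences(sequences)
        lengths = [e.shape[0] for e in embeddings]
        Lmax = max(lengths)
        D = embeddings[0].shape[1]
        padded = []
        for emb in embeddings:
            L = emb.shape[0]
            if L < Lmax:
                emb = concat([emb, Tensor(np.zeros((Lmax - L, D)))], axis=0)
            padded.append(emb.reshape(1, Lmax, D))
        shared = concat(padded, axis=0)
        shared = self.dropout(shared)
        outputs = [head(shared) for head in self.heads]  # each (B, Lmax, 1)
        strengths = concat(outputs, axis=2)
        mask = np.zeros((len(sequences), Lmax), dtype=bool)
        for i, L in enumerate(lengths):
            mask[i, :L] = True
        return strengths, mask

    def predict(self, record: ProteinRecord) -> SignalMatrix:
        """Inference-mode 8 x L signal matrix for one protein."""
        was_training = self.training
        self.eval()
        try:
            strengths, _ = self.forward_batch([record.sequence])
        finally:
            self.train(was_training)
        return SignalMatrix(record.id, strengths.data[0].T.copy())

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        state = {f"param:{k}": v for k, v in self.state_dict().items()}
        np.savez(
            path,
            __config__=np.array(self.config.to_json()),
            __classes__=np.array(",".join(SIGNAL_CLASSES)),
            __format__=np.array(CHECKPOINT_FORMAT_VERSION),
            **state,
        )

    @classmethod
    def load(cls, path) -> "SignalModel":
        with np.load(path, allow_pickle=False) as data:
            version = int(data["__format__"])
            if version != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint format {version}")
            classes = str(data["__classes__"]).split(",")
            if tuple(classes) != SIGNAL_CLASSES:
                raise ValueError("checkpoint class order mismatch")
            config = ModelConfig.from_json(str(data["__config__"]))
            model = cls(config)
            state = {
                k[len("param:"):]: data[k]
                for k in data.files
                if k.startswith("param:")
            }
        model.load_state_dict(state)
        return model
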