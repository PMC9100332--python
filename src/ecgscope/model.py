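"""The sequence-pair identification/verification network.

One forward pass maps a classification scope J = (G1..Gh) and a query
segment Gq to (a) h individual-verification probabilities P(q=k) and
(b) an identification distribution Pq(k) over the scope, computed from
the same pair-encoder features:

1. feature-space expansion — a 1-D convolution (512 filters, kernel 33,
   stride 1, ReLU) and 16/16 max-pooling turn each 384-sample segment
   into a 22-token sequence of width d_model;
2. pairing — the query sequence is duplicated against every enrolled
   sequence; learned segment embeddings Ee/Eq mark origin, and two
   learned classification tokens clsVE and clsID are prepended, giving h
   composite sequences of length 2 + 22 + 22 = 46;
3. the ECG pair encoder (4 transformer encoder layers) yields, per pair,
   the final hidden states at the two classification tokens: L_VE feeds
   the verification head (sigmoid), L_ID feeds the scope path;
4. the ID encoder (4 more encoder layers, no positional encoding, hence
   permutation-equivariant over scope positions) relates the h pair
   features to each other, and a shared per-position head plus softmax
   produces Pq(k).

Because no parameter depends on h, one trained parameter set serves any
scope size — identities can be enrolled or removed without retraining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, concat, no_grad
from .preprocessing import SEGMENT_SAMPLES

__all__ = [
    "ModelConfig", "ModelOutputs", "ECGPairClassifier",
    "save_checkpoint", "load_checkpoint",
    "N_TOKENS_PER_SEGMENT", "COMPOSITE_LENGTH",
]

#: tokens per expanded segment: (384 - 33 + 1) // 16 with valid conv, 16/16 pool
N_TOKENS_PER_SEGMENT = (SEGMENT_SAMPLES - 33 + 1) // 16
#: composite sequence: clsVE + clsID + enrolled 22 + query 22
COMPOSITE_LENGTH = 2 + 2 * N_TOKENS_PER_SEGMENT


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the full-scale network."""

    d_model: int = 512
    conv_filters: int = 512
    conv_kernel: int = 33
    conv_stride: int = 1
    pool_kernel: int = 16
    pool_stride: int = 16
    pair_encoder_layers: int = 4
    id_encoder_layers: int = 4
    attention_heads: int = 8
    feedforward_dim: int = 2048
    dropout_p: float = 0.1
    verification_head_widths: tuple[int, ...] = (512, 512, 512, 512, 256, 128)
    id_head_width: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.attention_heads:
            raise ValueError("d_model must be divisible by attention_heads")
        if self.conv_filters != self.d_model:
            raise ValueError("conv_filters must equal d_model (tokens feed "
                             "the encoder directly)")
        if min(self.verification_head_widths) <= 0 or self.id_head_width <= 0:
            raise ValueError("head widths must be positive")
        if self.conv_stride != 1 or self.pool_kernel != self.pool_stride:
            raise ValueError("supported geometry: conv stride 1, pool kernel == stride")

    @classmethod
    def scaled(cls, width_multiplier: float, seed: int = 0, **overrides) -> "ModelConfig":
        """Jointly scale all widths (desk-scale models); the token geometry
        (22 tokens, length-46 composites) is unchanged."""
        w = width_multiplier
        d = int(512 * w)
        return cls(d_model=d, conv_filters=d,
                   feedforward_dim=int(2048 * w),
                   verification_head_widths=tuple(
                       max(int(x * w), 1) for x in (512, 512, 512, 512, 256, 128)),
                   id_head_width=max(int(256 * w), 1),
                   seed=seed, **overrides)


@dataclass
class ModelOutputs:
    """Per-identity verification probabilities and the identification
    distribution, for a batch of examples (batch axis first)."""

    verification_probs: np.ndarray   # (B, h) in (0, 1)
    id_distribution: np.ndarray      # (B, h), rows sum to 1
    h: int
    verification_probs_t: Tensor | None = None
    id_log_probs_t: Tensor | None = None


class _HeadBlock(nn.Module):
    """FC -> BatchNorm -> ReLU."""

    def __init__(self, d_in, d_out, rng, dtype):
        super().__init__()
        self.fc = nn.Linear(d_in, d_out, rng, dtype)
        self.bn = nn.BatchNorm1d(d_out, dtype)

    def __call__(self, x):
        return self.bn(self.fc(x)).relu()


class ECGPairClassifier(nn.Module):
    """The full network; construction is deterministic in config.seed."""

    def __init__(self, config: ModelConfig = ModelConfig(), dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        d = config.d_model

        self.conv = nn.Conv1d(config.conv_filters, config.conv_kernel, rng, dtype)
        self.pool = nn.MaxPool1d(config.pool_kernel, config.pool_stride)

        def emb(*shape):
            return Tensor(rng.normal(0.0, 0.02, size=shape).astype(dtype),
                          requires_grad=True)

        self.cls_ve = emb(d)
        self.cls_id = emb(d)
        self.emb_enrolled = emb(d)
        self.emb_query = emb(d)
        # learned absolute position embeddings over the 46 composite positions
        self.pos_emb = emb(COMPOSITE_LENGTH, d)

        self.pair_encoder = nn.TransformerEncoder(
            config.pair_encoder_layers, d, config.attention_heads,
            config.feedforward_dim, config.dropout_p, rng, dtype)

        blocks = []
        d_in = d
        for width in config.verification_head_widths:
            blocks.append(_HeadBlock(d_in, width, rng, dtype))
            d_in = width
        blocks.append(nn.Linear(d_in, 1, rng, dtype))
        blocks.append(nn.BatchNorm1d(1, dtype))
        self.verify_layers = blocks

        # the ID encoder adds no positional encoding: scope order is
        # arbitrary and the map stays permutation-equivariant
        self.id_encoder = nn.TransformerEncoder(
            config.id_encoder_layers, d, config.attention_heads,
            config.feedforward_dim, config.dropout_p, rng, dtype)
        self.id_head_block = _HeadBlock(d, config.id_head_width, rng, dtype)
        self.id_head_out = nn.Linear(config.id_head_width, 1, rng, dtype)
        self.id_head_bn = nn.BatchNorm1d(1, dtype)

        for dropout in self._dropouts():
            dropout.rng = self._dropout_rng

    def _dropouts(self):
        found = []

        def walk(m):
            if isinstance(m, nn.Dropout):
                found.append(m)
            for child in m._children.values():
                walk(child)

        walk(self)
        return found

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)
        for dropout in self._dropouts():
            dropout.rng = self._dropout_rng

    # ------------------------------------------------------------ components
    def feature_space_expansion(self, segments: Tensor) -> Tensor:
        """(B, 384) standardized segments -> (B, 22, d_model) tokens."""
        if segments.shape[-1] != SEGMENT_SAMPLES:
            raise ValueError(f"segments must have {SEGMENT_SAMPLES} samples, "
                             f"got {segments.shape}")
        y = self.conv(segments).relu()      # (B, 352, filters), valid conv
        return self.pool(y)                 # (B, 22, filters)

    def build_composite_sequence(self, xk: Tensor, xq: Tensor) -> Tensor:
        """Pair enrolled/query token sequences: (N, 22, d) x2 -> (N, 46, d).

        Token 0 is clsVE, token 1 clsID, tokens 2-23 the enrolled sequence
        plus Ee, tokens 24-45 the query sequence plus Eq; learned position
        embeddings are added over all 46 positions.
        """
        n = xk.shape[0]
        if xk.shape != xq.shape or xk.shape[1] != N_TOKENS_PER_SEGMENT:
            raise ValueError(f"expected (N, {N_TOKENS_PER_SEGMENT}, d) pairs, "
                             f"got {xk.shape} and {xq.shape}")
        zeros_cls = Tensor(np.zeros((n, 1, self.config.d_model), dtype=self.dtype))
        tok_ve = zeros_cls + self.cls_ve
        tok_id = zeros_cls + self.cls_id
        seq = concat([tok_ve, tok_id, xk + self.emb_enrolled,
                      xq + self.emb_query], axis=1)
        return seq + self.pos_emb

    def ecg_pair_encode(self, seq: Tensor) -> tuple[Tensor, Tensor]:
        """(N, 46, d) composites -> final hidden states (L_VE, L_ID)."""
        if seq.shape[1] != COMPOSITE_LENGTH:
            raise ValueError(f"composite length must be {COMPOSITE_LENGTH}")
        out = self.pair_encoder(seq)
        return out[:, 0, :], out[:, 1, :]

    def verify_head(self, l_ve: Tensor) -> Tensor:
        """(N, d) pair features -> (N,) verification probabilities."""
        x = l_ve
        for layer in self.verify_layers:
            x = layer(x)
        return x.sigmoid().reshape(x.shape[0])

    def id_encode(self, features: Tensor) -> Tensor:
        """(B, h, d) ordered pair features -> (B, h, d) hidden sequence."""
        if features.ndim != 3 or features.shape[1] == 0:
            raise ValueError("id_encode needs a non-empty (B, h, d) sequence")
        return self.id_encoder(features)

    def id_classify(self, hidden: Tensor) -> Tensor:
        """(B, h, d) hidden sequence -> (B, h) softmax distribution."""
        b, h, d = hidden.shape
        flat = hidden.reshape(b * h, d)
        logits = self.id_head_bn(self.id_head_out(self.id_head_block(flat)))
        return logits.reshape(b, h).softmax(axis=-1)

    # ---------------------------------------------------------------- forward
    def forward_tensors(self, scope: np.ndarray, query: np.ndarray
                        ) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass.

        scope: (B, h, 384), query: (B, 384); returns the verification
        probabilities (B, h) and identification distribution (B, h) as
        graph tensors.
        """
        scope = np.asarray(scope, dtype=self.dtype)
        query = np.asarray(query, dtype=self.dtype)
        if scope.ndim != 3 or query.ndim != 2:
            raise ValueError("scope must be (B, h, 384), query (B, 384)")
        b, h, _ = scope.shape
        if h < 1:
            raise ValueError("empty scope")
        flat = np.concatenate([scope.reshape(b * h, SEGMENT_SAMPLES), query])
        expanded = self.feature_space_expansion(Tensor(flat))
        d = self.config.d_model
        xk = expanded[: b * h]                                     # (B*h, 22, d)
        xq_base = expanded[b * h:].reshape(b, 1, N_TOKENS_PER_SEGMENT, d)
        # duplicate the query tokens against every enrolled sequence
        xq = (xq_base + Tensor(np.zeros((1, h, 1, 1), dtype=self.dtype))
              ).reshape(b * h, N_TOKENS_PER_SEGMENT, d)
        seq = self.build_composite_sequence(xk, xq)
        l_ve, l_id = self.ecg_pair_encode(seq)
        ver = self.verify_head(l_ve).reshape(b, h)
        hidden = self.id_encode(l_id.reshape(b, h, d))
        dist = self.id_classify(hidden)
        return ver, dist

    def forward(self, scope: np.ndarray, query: np.ndarray) -> ModelOutputs:
        ver, dist = self.forward_tensors(scope, query)
        return ModelOutputs(verification_probs=ver.data, id_distribution=dist.data,
                            h=scope.shape[1] if np.ndim(scope) == 3 else scope.shape[0],
                            verification_probs_t=ver, id_log_probs_t=None)

    def predict(self, scope: np.ndarray, query: np.ndarray) -> ModelOutputs:
        """Inference-mode forward (no tape, dropout off, BN running stats)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                ver, dist = self.forward_tensors(scope, query)
        finally:
            self.train(was_training)
        return ModelOutputs(verification_probs=ver.data,
                            id_distribution=dist.data, h=scope.shape[1])

    def predict_single(self, scope_segments: np.ndarray,
                       query_segment: np.ndarray) -> ModelOutputs:
        """Convenience: one example (h, 384) + (384,)."""
        out = self.predict(scope_segments[None], np.asarray(query_segment)[None])
        return ModelOutputs(out.verification_probs[0], out.id_distribution[0], out.h)

    # ------------------------------------------------------------------ info
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def describe(self) -> str:
        lines = [f"{'parameter':50s} {'shape':>18s} {'count':>10s}"]
        for name, p in self.named_parameters().items():
            lines.append(f"{name:50s} {str(p.data.shape):>18s} {p.data.size:>10d}")
        lines.append(f"{'TOTAL':50s} {'':>18s} {self.parameter_count():>10d}")
        return "\n".join(lines)


def save_checkpoint(model: ECGPairClassifier, path, extra: dict | None = None) -> Path:
    """Single-file parameter archive with the JSON config embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = {"config": asdict(model.config),
            "format": "ecgscope-checkpoint-v1", "extra": extra or {}}
    state["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_checkpoint(path) -> tuple[ECGPairClassifier, dict]:
    with np.load(Path(path), allow_pickle=False) as arc:
        meta = json.loads(bytes(arc["__meta__"].tobytes()).decode())
        state = {k: arc[k] for k in arc.files if k != "__meta__"}
    cfg_dict = dict(meta["config"])
    cfg_dict["verification_head_widths"] = tuple(cfg_dict["verification_head_widths"])
    model = ECGPairClassifier(ModelConfig(**cfg_dict))
    model.load_state_dict(state)
    model.eval()
    return model, meta.get("extra", {})
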