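"""The attention-MIL bag classifier.

A transcript's bag of fixed-length windows is encoded instance-by-instance
with an embedding (15 symbols -> 4 dims) followed by a two-layer
bidirectional LSTM; the concatenated final states of both directions pass
through a two-layer fully connected encoder to give the instance feature
c_i (dimension M, 100 by default).  The bag is pooled by gated attention

    alpha = softmax( w^T tanh(V C^T) ),   z = sum_i alpha_i c_i

with V in R^{L x M} and w in R^{L} trainable, softmax taken across the
instances of one bag.  A final affine map plus sigmoid on z yields the
bag probability (circRNA vs other lncRNA).

For pre-vectorized instances (e.g. 28x28 glyph images read as length-28
sequences of 28-dim rows) the embedding is bypassed and the same
architecture applies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from ._tensor import (Tensor, bce_with_logits, no_grad, segment_max,
                      segment_softmax, segment_weighted_sum,
                      softmax_cross_entropy)
from .instancing import Bag
from .seqio import ALPHABET, encode_sequence

__all__ = [
    "ModelConfig",
    "BagOutput",
    "BagNet",
    "attention_pool",
    "classify_bag",
    "encode_instance",
    "encode_prevectorized_bag",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """All layer sizes of the bag classifier.

    Defaults reproduce the full-scale architecture; every size can be
    shrunk for desk-scale experiments.  ``use_embedding=False`` switches
    to pre-vectorized instances of width ``input_dim``.
    """

    alphabet_size: int = len(ALPHABET)
    embed_dim: int = 4
    rnn_hidden: int = 150          # per direction
    rnn_layers: int = 2
    fcn_hidden: int = 300          # first encoder FCN width
    feature_dim: int = 100         # M, the instance feature width
    attention_hidden: int = 30     # L in the attention layers
    use_embedding: bool = True
    input_dim: int = 0             # instance row width when embedding is off

    def encoder_input_dim(self) -> int:
        return self.embed_dim if self.use_embedding else self.input_dim

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


@dataclass
class BagOutput:
    """Full forward-pass record for one bag."""

    instance_features: np.ndarray   # (k, M)
    attention: np.ndarray           # (k,), sums to 1
    weighted_feature: np.ndarray    # (M,)
    probability: float
    label: int

    @property
    def k(self) -> int:
        return len(self.attention)


def attention_pool(C: np.ndarray, V: np.ndarray, w: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Gated-attention MIL pooling on plain arrays.

    Parameters
    ----------
    C : (k, M) instance features.
    V : (L, M) first attention layer.
    w : (L,) or (L, 1) second attention layer.

    Returns ``(alpha, z)`` with ``alpha`` the softmax-normalized attention
    over the k instances and ``z = alpha @ C`` the weighted bag feature.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] < 1:
        raise ValueError("C must be a non-empty (k, M) matrix")
    w = np.asarray(w, dtype=np.float64).reshape(-1)
    logits = np.tanh(C @ np.asarray(V, dtype=np.float64).T) @ w
    logits -= logits.max()
    e = np.exp(logits)
    alpha = e / e.sum()
    return alpha, alpha @ C


class BagNet(nn.Module):
    """Instance encoder + attention pooling + sigmoid classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.config = config
        self._dtype = dtype
        if config.use_embedding:
            self.embedding = nn.Embedding(config.alphabet_size,
                                          config.embed_dim, rng, dtype)
        elif config.input_dim < 1:
            raise ValueError("input_dim required when embedding is disabled")
        self.rnn = nn.BiLSTMStack(config.encoder_input_dim(), config.rnn_hidden,
                                  config.rnn_layers, rng, dtype)
        d_cat = 2 * config.rnn_hidden
        self.enc1 = nn.Linear(d_cat, config.fcn_hidden, rng, dtype)
        self.enc2 = nn.Linear(config.fcn_hidden, config.feature_dim, rng, dtype)
        L, M = config.attention_hidden, config.feature_dim
        self.att_V = Tensor(rng.uniform(-1, 1, (L, M)).astype(dtype) / np.sqrt(M),
                            requires_grad=True)
        self.att_w = Tensor(rng.uniform(-1, 1, (L, 1)).astype(dtype) / np.sqrt(L),
                            requires_grad=True)
        self.classifier = nn.Linear(M, 1, rng, dtype)
        if config.use_embedding:
            # masked-base prediction head for self-supervised pretraining
            self.lm_head = nn.Linear(d_cat, config.alphabet_size, rng, dtype)

    # -- forward passes ----------------------------------------------------

    def instance_features(self, x: np.ndarray) -> Tensor:
        """Encode a batch of instances.

        ``x`` is (N, T) integer codes when the embedding is on, else
        (N, T, D) floats.  Returns the (N, M) feature matrix.
        """
        if self.config.use_embedding:
            emb = self.embedding(np.asarray(x))
        else:
            arr = np.asarray(x, dtype=self._dtype)
            if arr.ndim != 3 or arr.shape[2] != self.config.input_dim:
                raise ValueError(f"expected (N, T, {self.config.input_dim}) input, "
                                 f"got {arr.shape}")
            emb = Tensor(arr)
        h = self.rnn(emb)                       # (N, 2*hidden)
        return self.enc2(self.enc1(h).tanh())   # (N, M)

    def forward(self, x: np.ndarray, segment_ids: np.ndarray, n_bags: int
                ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Joint forward over several bags.

        ``segment_ids`` assigns each instance row of ``x`` to its bag.
        Returns (C, alpha, Z, logits): instance features (N, M), attention
        (N,) normalized within each bag, weighted bag features (n_bags, M)
        and classifier logits (n_bags,).
        """
        C = self.instance_features(x)
        att_logits = ((C @ _t(self.att_V)).tanh() @ self.att_w).reshape(x.shape[0])
        alpha = segment_softmax(att_logits, segment_ids, n_bags)
        Z = segment_weighted_sum(alpha, C, segment_ids, n_bags)
        logits = self.classifier(Z).reshape(n_bags)
        return C, alpha, Z, logits

    def masked_lm_loss(self, x_masked: np.ndarray, targets: np.ndarray,
                       mask: np.ndarray) -> Tensor:
        """Masked-base prediction loss for encoder pretraining.

        ``x_masked`` is (N, T) integer codes with masked positions replaced
        by N; ``targets`` the original codes; ``mask`` marks the positions
        to predict.  Per-position predictions come from the top recurrent
        layer's outputs.
        """
        if not self.config.use_embedding:
            raise ValueError("masked-base pretraining needs the embedding layer")
        emb = self.embedding(np.asarray(x_masked))
        seq_out = self.rnn(emb, return_sequence=True)      # (N, T, 2H)
        N, T, D = seq_out.shape
        logits = self.lm_head(seq_out.reshape(N * T, D))
        return softmax_cross_entropy(logits, np.asarray(targets).reshape(N * T),
                                     np.asarray(mask).reshape(N * T))

    def forward_maxpool(self, x: np.ndarray, segment_ids: np.ndarray,
                        n_bags: int) -> Tensor:
        """Max-pooling variant: bag logit = max over per-instance logits.

        Used as an optional warm-up at small data scales, where attention
        pooling's 1/k gradient dilution can stall the cold start; the
        instance encoder and classifier are the same parameters either way.
        """
        C = self.instance_features(x)
        inst_logits = self.classifier(C).reshape(x.shape[0])
        return segment_max(inst_logits, segment_ids, n_bags)

    def loss(self, x: np.ndarray, segment_ids: np.ndarray, n_bags: int,
             labels: np.ndarray, pooling: str = "attention"
             ) -> tuple[Tensor, np.ndarray]:
        """Mean BCE over the bags plus the detached bag probabilities."""
        if pooling == "attention":
            _, _, _, logits = self.forward(x, segment_ids, n_bags)
        elif pooling == "max":
            logits = self.forward_maxpool(x, segment_ids, n_bags)
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        loss = bce_with_logits(logits, labels)
        probs = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        return loss, probs


def _t(t: Tensor) -> Tensor:
    """Transpose a 2-D parameter tensor (graph-aware)."""
    out_data = t.data.T

    def bw(g):
        t._accum(g.T)

    return Tensor._make(out_data, (t,), bw)


# -- convenience single-bag API -------------------------------------------


def _bag_arrays(bag: Bag) -> np.ndarray:
    return np.stack([encode_sequence(inst) for inst in bag.instances])


def encode_instance(instance: str, net: BagNet) -> np.ndarray:
    """Feature vector (M,) of a single window; deterministic per net."""
    x = encode_sequence(instance)[None, :]
    with no_grad():
        return net.instance_features(x).data[0].copy()


def classify_bag(net: BagNet, bag: Bag, threshold: float = 0.5) -> BagOutput:
    """Full forward pass for one transcript's bag."""
    if len(bag) < 1:
        raise ValueError("empty bag")
    x = _bag_arrays(bag)
    return _classify_encoded(net, x, threshold)


def encode_prevectorized_bag(net: BagNet, instances: np.ndarray,
                             threshold: float = 0.5) -> BagOutput:
    """Classify a bag of pre-vectorized (k, T, D) instances (embedding off)."""
    if net.config.use_embedding:
        raise ValueError("net was built with an embedding layer; "
                         "use a config with use_embedding=False")
    arr = np.asarray(instances, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("instances must be a (k, T, D) array of equal shapes")
    return _classify_encoded(net, arr, threshold)


def _classify_encoded(net: BagNet, x: np.ndarray, threshold: float) -> BagOutput:
    k = x.shape[0]
    seg = np.zeros(k, dtype=np.int64)
    with no_grad():
        C, alpha, Z, logits = net.forward(x, seg, 1)
    prob = float(1.0 / (1.0 + np.exp(-float(logits.data[0]))))
    return BagOutput(
        instance_features=C.data.copy(),
        attention=alpha.data.astype(np.float64).copy(),
        weighted_feature=Z.data[0].copy(),
        probability=prob,
        label=int(prob >= threshold),
    )


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(net: BagNet, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON sidecar of the configuration."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.state_dict())
    path.with_suffix(".json").write_text(net.config.to_json())


def load_checkpoint(path: str | Path) -> BagNet:
    path = Path(path)
    config = ModelConfig.from_json(path.with_suffix(".json").read_text())
    net = BagNet(config)
    with np.load(path.with_suffix(".npz")) as npz:
        net.load_state_dict({k: npz[k] for k in npz.files})
    return net
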