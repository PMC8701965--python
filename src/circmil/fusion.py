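"""Fusion head: an MLP over concatenated sequence / RCM / conservation
features.

The sequence branch contributes the 100-dim weighted bag feature z (the
classifier's penultimate representation); reverse-complement-matching (40)
and conservation (23) descriptor vectors are consumed pre-computed from a
TSV.  The fusion model is a 163-80-20-1 MLP with rectifier hidden units
and a sigmoid output, trained with the same BCE/Adam recipe as the main
model while the sequence branch stays frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from ._tensor import Tensor, bce_with_logits, no_grad
from .instancing import Bag
from .model import BagNet, classify_bag
from .training import TrainConfig

__all__ = [
    "FeatureRow",
    "FusionNet",
    "extract_seq_feature",
    "build_feature_rows",
    "train_fusion",
    "fusion_predict",
    "write_feature_table",
    "read_feature_table",
]

SEQ_DIM, RCM_DIM, CONS_DIM = 100, 40, 23


@dataclass
class FeatureRow:
    """One transcript's fused feature vector (100 + 40 + 23 = 163)."""

    record_id: str
    seq_feature: np.ndarray
    rcm_feature: np.ndarray
    cons_feature: np.ndarray
    label: int

    def concat(self) -> np.ndarray:
        return np.concatenate([self.seq_feature, self.rcm_feature,
                               self.cons_feature])


class FusionNet(nn.Module):
    """MLP with sigmoid output; widths default to 163-80-20-1."""

    def __init__(self, d_in: int = SEQ_DIM + RCM_DIM + CONS_DIM,
                 hidden: tuple[int, int] = (80, 20), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d_in = d_in
        self.fc1 = nn.Linear(d_in, hidden[0], rng, np.float64)
        self.fc2 = nn.Linear(hidden[0], hidden[1], rng, np.float64)
        self.fc3 = nn.Linear(hidden[1], 1, rng, np.float64)

    def logits(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.d_in:
            raise ValueError(f"expected (n, {self.d_in}) features, got {x.shape}")
        t = Tensor(x)
        return self.fc3(self.fc2(self.fc1(t).relu()).relu()).reshape(x.shape[0])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        with no_grad():
            z = self.logits(np.atleast_2d(x)).data
        return 1.0 / (1.0 + np.exp(-z))


def extract_seq_feature(net: BagNet, bag: Bag) -> np.ndarray:
    """The weighted bag feature z used as the 100-dim sequence descriptor."""
    return classify_bag(net, bag).weighted_feature


def build_feature_rows(net: BagNet, bags: list[Bag],
                       descriptors: pd.DataFrame) -> list[FeatureRow]:
    """Join sequence features with a descriptor table indexed by record_id.

    ``descriptors`` must carry columns rcm_0..rcm_39, cons_0..cons_22 and
    label, one row per record_id.
    """
    desc = descriptors.set_index("record_id")
    rcm_cols = [f"rcm_{i}" for i in range(RCM_DIM)]
    cons_cols = [f"cons_{i}" for i in range(CONS_DIM)]
    rows = []
    for bag in bags:
        if bag.record_id not in desc.index:
            raise KeyError(f"no descriptor row for {bag.record_id}")
        d = desc.loc[bag.record_id]
        rows.append(FeatureRow(
            record_id=bag.record_id,
            seq_feature=extract_seq_feature(net, bag),
            rcm_feature=d[rcm_cols].to_numpy(dtype=float),
            cons_feature=d[cons_cols].to_numpy(dtype=float),
            label=int(d["label"]),
        ))
    return rows


def train_fusion(rows: list[FeatureRow], config: TrainConfig = TrainConfig(),
                 net: FusionNet | None = None) -> FusionNet:
    """Train the fusion MLP (full-batch Adam) on fused feature rows."""
    labels = {r.label for r in rows}
    if labels != {0, 1}:
        raise ValueError(f"fusion training needs both classes, got {labels}")
    X = np.stack([r.concat() for r in rows])
    y = np.array([r.label for r in rows], dtype=np.float64)
    if net is None:
        net = FusionNet(d_in=X.shape[1], seed=config.seed)
    opt = nn.Adam(net.parameters(), lr=config.lr, betas=config.betas,
                  weight_decay=config.weight_decay)
    for _ in range(config.epochs):
        opt.zero_grad()
        loss = bce_with_logits(net.logits(X), y)
        loss.backward()
        opt.step()
    return net


def fusion_predict(net: FusionNet, rows: list[FeatureRow]) -> np.ndarray:
    X = np.stack([r.concat() for r in rows])
    return net.predict_proba(X)


def write_feature_table(rows: list[FeatureRow], path: str | Path) -> None:
    data = {}
    data["record_id"] = [r.record_id for r in rows]
    for i in range(len(rows[0].seq_feature)):
        data[f"seq_{i}"] = [r.seq_feature[i] for r in rows]
    for i in range(RCM_DIM):
        data[f"rcm_{i}"] = [r.rcm_feature[i] for r in rows]
    for i in range(CONS_DIM):
        data[f"cons_{i}"] = [r.cons_feature[i] for r in rows]
    data["label"] = [r.label for r in rows]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> list[FeatureRow]:
    df = pd.read_csv(path, sep="\t")
    seq_cols = sorted((c for c in df.columns if c.startswith("seq_")),
                      key=lambda c: int(c.split("_")[1]))
    rcm_cols = [f"rcm_{i}" for i in range(RCM_DIM)]
    cons_cols = [f"cons_{i}" for i in range(CONS_DIM)]
    rows = []
    for _, r in df.iterrows():
        rows.append(FeatureRow(
            record_id=str(r["record_id"]),
            seq_feature=r[seq_cols].to_numpy(dtype=float),
            rcm_feature=r[rcm_cols].to_numpy(dtype=float),
            cons_feature=r[cons_cols].to_numpy(dtype=float),
            label=int(r["label"]),
        ))
    return rows
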