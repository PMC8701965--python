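"""Model / Results objects tying the pipeline together.

:class:`CircMIL` holds the data and all configuration; ``fit()`` runs the
training recipe and returns :class:`CircMILResults`, which carries the
trained network, the per-epoch history, prediction / evaluation methods,
attention profiles and splice extraction, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attention_map import (AttentionProfile, Splice, collapse_attention,
                            extract_splices)
from .instancing import Bag, WindowGeometry, extract_instances
from .model import BagNet, ModelConfig, classify_bag, load_checkpoint, save_checkpoint
from .seqio import (DatasetSplit, SequenceRecord, encode_sequence,
                    filter_min_length, read_fasta, split_dataset)
from .training import (EncodedBag, EvalReport, TrainConfig, encode_bags,
                       evaluate, predict_probs, train)

__all__ = ["CircMIL", "CircMILResults"]


class CircMIL:
    """The circRNA-vs-lncRNA attention-MIL model, bound to a dataset.

    Parameters
    ----------
    train_records, val_records : labeled sequence records.
    geometry : sliding-window geometry (70 nt windows, 5 nt steps by
        default, on the circularized sequence).
    model_config, train_config : architecture and optimization settings.
    """

    def __init__(self, train_records: list[SequenceRecord],
                 val_records: list[SequenceRecord] | None = None,
                 geometry: WindowGeometry = WindowGeometry(),
                 model_config: ModelConfig = ModelConfig(),
                 train_config: TrainConfig = TrainConfig()):
        self.train_records = train_records
        self.val_records = val_records
        self.geometry = geometry
        self.model_config = model_config
        self.train_config = train_config

    @classmethod
    def from_fasta(cls, positives: str | Path, negatives: str | Path,
                   min_len: int = 200,
                   fractions: tuple[float, float, float] = (0.75, 0.10, 0.15),
                   seed: int = 0, **kwargs) -> tuple["CircMIL", DatasetSplit]:
        """Build from two FASTA files (positive / negative class) using the
        standard >=200 nt filter and 75/10/15 split.  Returns the model and
        the full split (the held-out test set is the caller's to keep).
        """
        records = read_fasta(positives, label=1) + read_fasta(negatives, label=0)
        records = filter_min_length(records, min_len)
        split = split_dataset(records, fractions, seed)
        return cls(split.train, split.validation, **kwargs), split

    def bags(self, records: list[SequenceRecord]) -> list[Bag]:
        return [extract_instances(r, self.geometry) for r in records]

    def fit(self, seed: int | None = None) -> "CircMILResults":
        cfg = self.train_config
        if seed is not None:
            import dataclasses
            cfg = dataclasses.replace(cfg, seed=seed)
        net = BagNet(self.model_config, seed=cfg.seed)
        train_enc = encode_bags(self.bags(self.train_records))
        val_enc = encode_bags(self.bags(self.val_records)) if self.val_records else None
        result = train(net, train_enc, val_enc, cfg)
        return CircMILResults(model=self, net=result.net,
                              history=result.history,
                              best_epoch=result.best_epoch)


@dataclass
class CircMILResults:
    """Fit results: trained parameters, history and analysis methods."""

    model: CircMIL
    net: BagNet
    history: pd.DataFrame
    best_epoch: int

    # -- prediction --------------------------------------------------------

    def predict_proba(self, records: list[SequenceRecord]) -> np.ndarray:
        enc = [EncodedBag(x=np.stack([encode_sequence(s) for s in b.instances]),
                          label=0, record_id=b.record_id)
               for b in self.model.bags(records)]
        return predict_probs(self.net, enc)

    def predict(self, records: list[SequenceRecord],
                threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(records) >= threshold).astype(int)

    def evaluate(self, records: list[SequenceRecord],
                 threshold: float = 0.5) -> EvalReport:
        labels = np.array([r.label for r in records])
        return evaluate(labels, self.predict_proba(records), threshold)

    # -- attention ---------------------------------------------------------

    def bag_output(self, record: SequenceRecord):
        return classify_bag(self.net, extract_instances(record, self.model.geometry))

    def attention_profile(self, record: SequenceRecord,
                          aggregate: str = "mean") -> AttentionProfile:
        bag = extract_instances(record, self.model.geometry)
        out = classify_bag(self.net, bag)
        return collapse_attention(bag, out.attention, aggregate)

    def splices(self, record: SequenceRecord, min_len: int = 8,
                threshold: float = 0.6) -> list[Splice]:
        return extract_splices(self.attention_profile(record), record.seq,
                               min_len, threshold)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        last = self.history.iloc[-1]
        lines = [
            "Attention-MIL bag classifier",
            "=" * 60,
            f"window/step:        {self.model.geometry.window}/{self.model.geometry.step} nt",
            f"instance feature M: {self.model.model_config.feature_dim}",
            f"attention width L:  {self.model.model_config.attention_hidden}",
            f"parameters:         {self.net.n_parameters()}",
            f"epochs run:         {len(self.history)}",
            f"selected epoch:     {self.best_epoch}",
            f"final train loss:   {last['train_loss']:.4f}",
            f"final train acc:    {last['train_acc']:.4f}",
        ]
        if not np.isnan(last["val_acc"]):
            lines.append(f"final val acc:      {last['val_acc']:.4f}")
            lines.append(f"final val AUC:      {last['val_auc']:.4f}")
        return "\n".join(lines)

    def save(self, prefix: str | Path) -> None:
        save_checkpoint(self.net, prefix)
        self.history.to_csv(Path(prefix).with_suffix(".history.tsv"),
                            sep="\t", index=False)
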