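"""Reading, normalizing, filtering and splitting transcript sequence sets.

Sequences are handled on the 15-symbol DNA-letter alphabet
``{A,T,G,C,N,H,B,D,V,R,M,S,W,Y,K}`` (the four bases, N, and the remaining
IUPAC ambiguity codes).  RNA input is accepted: U is transcribed to T on
read.  Any character outside the alphabet becomes N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: the model alphabet, in fixed encoding order
ALPHABET = "ATGCNHBDVRMSWYK"
SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "SYMBOL_INDEX",
    "SequenceRecord",
    "DatasetSplit",
    "normalize_sequence",
    "encode_sequence",
    "read_fasta",
    "write_fasta",
    "filter_min_length",
    "split_dataset",
]


@dataclass
class SequenceRecord:
    """One transcript: identifier, normalized sequence, optional label.

    ``label`` is 1 for circRNA (positive class), 0 for other lncRNA,
    ``None`` when unlabeled.
    """

    id: str
    seq: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DatasetSplit:
    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    test: list[SequenceRecord]
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


_NORMALIZE_TABLE = str.maketrans("u", "t")


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, transcribe U→T, replace out-of-alphabet symbols by N.

    Returns the normalized sequence and the number of substituted
    characters.
    """
    s = raw.strip().upper().replace("U", "T")
    if all(ch in SYMBOL_INDEX for ch in s):
        return s, 0
    out = []
    n_bad = 0
    for ch in s:
        if ch in SYMBOL_INDEX:
            out.append(ch)
        else:
            out.append("N")
            n_bad += 1
    return "".join(out), n_bad


def encode_sequence(seq: str) -> np.ndarray:
    """Map a normalized sequence to integer codes over :data:`ALPHABET`."""
    try:
        return np.fromiter((SYMBOL_INDEX[c] for c in seq), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:  # pragma: no cover - guarded by normalization
        raise ValueError(f"symbol outside the model alphabet: {exc}") from exc


def read_fasta(path: str | Path, label: int | None = None) -> list[SequenceRecord]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Sequences are normalized on read; a single warning totals any
    out-of-alphabet substitutions.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    n_sub = 0
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq, bad = normalize_sequence(str(rec.seq))
        n_sub += bad
        records.append(SequenceRecord(id=rec.id, seq=seq, label=label))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_sub:
        logger.warning("%d out-of-alphabet characters replaced by N while reading %s",
                       n_sub, path)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path,
                wrap: int = 60) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def filter_min_length(records: list[SequenceRecord],
                      min_len: int = 200) -> list[SequenceRecord]:
    """Drop records shorter than ``min_len`` (boundary inclusive)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if len(r.seq) >= min_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filtered %d/%d records shorter than %d nt",
                    removed, len(records), min_len)
    return kept


def split_dataset(records: list[SequenceRecord],
                  fractions: tuple[float, float, float] = (0.75, 0.10, 0.15),
                  seed: int = 0) -> DatasetSplit:
    """Shuffle deterministically and partition into train/validation/test.

    Sizes are floor(n*f_train) and floor(n*f_val); the remainder goes to
    the test set, so the partition is always exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]
    n = len(records)
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        seed=seed,
    )
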