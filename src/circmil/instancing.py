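"""Sliding-window instance extraction on circularized sequences.

A transcript is treated as a bag of fixed-length windows.  The sequence is
circularized (5' end joined to 3' end) and a window of ``window`` nt is
slid from position 0 in steps of ``step`` nt; each window is one instance.
The number of instances is the sequence length divided by the step,
rounded half-up, so windows near the tail wrap through the origin while
start offsets themselves never exceed the sequence length.

The module also provides the exact inverse mapping (which instances cover
which sequence position) needed to project instance attention back onto
the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "WindowGeometry",
    "Bag",
    "count_instances",
    "extract_instances",
    "coverage_map",
    "write_instance_bed",
]


@dataclass(frozen=True)
class WindowGeometry:
    """Window length and slide step, in nucleotides."""

    window: int = 70
    step: int = 5

    def __post_init__(self):
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")


@dataclass
class Bag:
    """All instances of one transcript plus the geometry to invert them."""

    record_id: str
    seq_len: int
    geometry: WindowGeometry
    instances: list[str]
    starts: list[int]
    label: int | None = None

    def __len__(self) -> int:
        return len(self.instances)


def count_instances(seq_len: int, step: int) -> int:
    """Number of windows: ``round_half_up(seq_len / step)``, always >= 1.

    Computed in integer arithmetic as ``(2*seq_len + step) // (2*step)``.
    Equivalently: a window is emitted at start ``s = 0, step, 2*step, ...``
    while at least half a step of sequence remains, i.e. while
    ``s + step/2 <= seq_len``.
    """
    if seq_len < 1 or step < 1:
        raise ValueError("seq_len and step must be >= 1")
    return max(1, (2 * seq_len + step) // (2 * step))


def extract_instances(record: SequenceRecord, geometry: WindowGeometry) -> Bag:
    """Slice one transcript into its bag of circular windows."""
    seq = record.seq
    L = len(seq)
    if L < 1:
        raise ValueError(f"empty sequence for record {record.id}")
    w, step = geometry.window, geometry.step
    k = count_instances(L, step)
    # doubled (or repeated) sequence so every window is one slice
    reps = 2 + (w - 1) // L
    ring = seq * reps
    starts = [i * step for i in range(k)]
    instances = [ring[s:s + w] for s in starts]
    return Bag(record_id=record.id, seq_len=L, geometry=geometry,
               instances=instances, starts=starts, label=record.label)


def coverage_map(bag: Bag) -> list[list[int]]:
    """For each sequence position, the instance indices covering it.

    Coverage is computed on the circular coordinate: instance ``i`` covers
    positions ``(starts[i] + j) mod seq_len`` for ``j in 0..window-1``.
    An instance is listed at most once per position even when the window
    wraps around the sequence more than once.
    """
    L = bag.seq_len
    cov: list[list[int]] = [[] for _ in range(L)]
    w = bag.geometry.window
    for i, s in enumerate(bag.starts):
        if w >= L:
            for p in range(L):
                cov[p].append(i)
            continue
        end = s + w
        if end <= L:
            rng = range(s, end)
        else:
            rng = list(range(s, L)) + list(range(0, end - L))
        for p in rng:
            cov[p].append(i)
    return cov


def coverage_arrays(bag: Bag) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized coverage: (flat position index array per instance-window
    cell, matching instance index array).  Positions are unique per
    instance.  Used by the attention collapse for speed.
    """
    L = bag.seq_len
    w = min(bag.geometry.window, L)
    starts = np.asarray(bag.starts)[:, None]
    pos = (starts + np.arange(w)[None, :]) % L
    inst = np.repeat(np.arange(len(bag.starts)), w)
    return pos.ravel(), inst


def write_instance_bed(bags: list[Bag], path: str | Path) -> None:
    """Dump instance coordinates as a BED-like TSV (1-based inclusive).

    Wrapping windows carry wraps=1 and an end column past the sequence
    length (positions continue on the circular coordinate).
    """
    with open(path, "w") as fh:
        fh.write("record_id\tstart\tend\twraps\n")
        for bag in bags:
            w = bag.geometry.window
            for s in bag.starts:
                wraps = int(s + w > bag.seq_len)
                fh.write(f"{bag.record_id}\t{s + 1}\t{s + w}\t{wraps}\n")
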