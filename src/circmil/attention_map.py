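"""Projecting instance attention back onto the sequence and extracting
high-attention splices for motif discovery.

Each instance's attention weight is assigned to every position its window
covers on the circular coordinate; a position's raw score is the mean over
the instances covering it (mean rather than sum, so unevenly covered
positions are not inflated; a sum variant is available).  Raw scores are
min-max scaled to [0, 1] per transcript, and maximal circular runs of
positions scoring strictly above 0.6 and at least 8 nt long are reported
as splices.  A run crossing the artificial head-tail junction is reported
as its two linear fragments sharing a group id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .instancing import Bag, coverage_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "AttentionProfile",
    "Splice",
    "collapse_attention",
    "extract_splices",
    "export_for_meme",
    "meme_command",
    "splice_summary",
    "write_profiles",
    "write_splice_bed",
]

MEME_FLAGS = "-rna -nostatus -mod zoops -minw 6 -maxw 50 -objfun classic -markov_order 0"


@dataclass
class AttentionProfile:
    """Per-base attention for one transcript (raw and [0,1]-scaled)."""

    record_id: str
    seq_len: int
    raw: np.ndarray
    scaled: np.ndarray


@dataclass
class Splice:
    """One high-attention fragment on the linear sequence.

    ``start``/``end`` are 0-based half-open.  Fragments of a run that
    crosses the head-tail junction share a ``group_id``.
    """

    record_id: str
    start: int
    end: int
    subsequence: str
    mean_scaled_score: float
    group_id: str

    def __len__(self) -> int:
        return self.end - self.start


def collapse_attention(bag: Bag, alpha: np.ndarray,
                       aggregate: str = "mean") -> AttentionProfile:
    """Invert the slider: per-position attention from instance attention.

    ``raw[p]`` is the mean (or sum) of attention over all instances whose
    window covers position ``p`` circularly; ``scaled`` is the per-transcript
    min-max rescaling, all zeros when the raw profile is flat.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape[0] != len(bag):
        raise ValueError(f"alpha has {alpha.shape[0]} entries for a bag of "
                         f"{len(bag)} instances")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    L = bag.seq_len
    pos, inst = coverage_arrays(bag)
    raw = np.zeros(L)
    np.add.at(raw, pos, alpha[inst])
    if aggregate == "mean":
        counts = np.zeros(L)
        np.add.at(counts, pos, 1.0)
        raw = raw / np.maximum(counts, 1.0)
    lo, hi = raw.min(), raw.max()
    scaled = (raw - lo) / (hi - lo) if hi > lo else np.zeros(L)
    return AttentionProfile(record_id=bag.record_id, seq_len=L,
                            raw=raw, scaled=scaled)


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True on a circular mask as (start, length) pairs.

    A run crossing the origin is returned once, with start near the end of
    the array and length counted through the wrap.
    """
    L = len(mask)
    if mask.all():
        return [(0, L)]
    if not mask.any():
        return []
    edges = np.flatnonzero(mask & ~np.roll(mask, 1))   # run starts
    runs = []
    for s in edges:
        length = 0
        while mask[(s + length) % L]:
            length += 1
        runs.append((int(s), length))
    return runs


def extract_splices(profile: AttentionProfile, bag_or_seq,
                    min_len: int = 8, threshold: float = 0.6) -> list[Splice]:
    """High-attention splices: circular runs with scaled score strictly
    above ``threshold`` and length >= ``min_len``.

    ``bag_or_seq`` supplies the sequence characters (a Bag is not enough:
    it stores windows), either as the transcript string or any object with
    a ``seq`` attribute.
    """
    seq = bag_or_seq if isinstance(bag_or_seq, str) else bag_or_seq.seq
    if len(seq) != profile.seq_len:
        raise ValueError("sequence length does not match the profile")
    mask = profile.scaled > threshold
    splices: list[Splice] = []
    group_n = 0
    for s, length in _circular_runs(mask):
        if length < min_len:
            continue
        gid = f"{profile.record_id}:g{group_n}"
        group_n += 1
        end = s + length
        if end <= profile.seq_len:
            frags = [(s, end)]
        else:  # run crosses the head-tail junction: two linear fragments
            frags = [(s, profile.seq_len), (0, end - profile.seq_len)]
        for a, b in frags:
            splices.append(Splice(
                record_id=profile.record_id, start=a, end=b,
                subsequence=seq[a:b],
                mean_scaled_score=float(profile.scaled[a:b].mean()),
                group_id=gid,
            ))
    return splices


def meme_command(fasta_path: str | Path) -> str:
    """The motif-enrichment command for the exported splices."""
    return f"meme {fasta_path} {MEME_FLAGS}"


def export_for_meme(splices: list[Splice], path: str | Path) -> str | None:
    """Write splices as FASTA and return the MEME command to run on them.

    Record ids are ``record_id:start-end`` (1-based inclusive), unique by
    construction per fragment.  Empty input writes nothing.
    """
    if not splices:
        logger.warning("no splices to export; %s not written", path)
        return None
    path = Path(path)
    with open(path, "w") as fh:
        for sp in splices:
            fh.write(f">{sp.record_id}:{sp.start + 1}-{sp.end}\n{sp.subsequence}\n")
    cmd = meme_command(path)
    print(cmd)
    return cmd


def splice_summary(splices_by_transcript: dict[str, list[Splice]]
                   ) -> tuple[dict[int, int], dict[int, int]]:
    """Histogram data: splice length distribution and per-transcript counts.

    Returns ``(length_counts, per_transcript_counts)`` as sparse
    ``{value: count}`` dicts.
    """
    length_counts: dict[int, int] = {}
    per_transcript: dict[int, int] = {}
    for splices in splices_by_transcript.values():
        groups: dict[str, int] = {}
        for sp in splices:
            groups[sp.group_id] = groups.get(sp.group_id, 0) + len(sp)
        for glen in groups.values():
            length_counts[glen] = length_counts.get(glen, 0) + 1
        n = len(groups)
        per_transcript[n] = per_transcript.get(n, 0) + 1
    return length_counts, per_transcript


def write_profiles(profiles: list[AttentionProfile], path: str | Path) -> None:
    """Per-position scores as a wig-like TSV (record_id, pos, raw, scaled)."""
    with open(path, "w") as fh:
        fh.write("record_id\tpos\traw\tscaled\n")
        for pr in profiles:
            for p in range(pr.seq_len):
                fh.write(f"{pr.record_id}\t{p + 1}\t{pr.raw[p]:.8g}\t{pr.scaled[p]:.6g}\n")


def write_splice_bed(splices: list[Splice], path: str | Path) -> None:
    """Splices as a 1-based inclusive BED-like TSV."""
    with open(path, "w") as fh:
        fh.write("record_id\tstart\tend\tgroup_id\tmean_scaled_score\n")
        for sp in splices:
            fh.write(f"{sp.record_id}\t{sp.start + 1}\t{sp.end}\t{sp.group_id}"
                     f"\t{sp.mean_scaled_score:.6g}\n")
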