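"""Overlap-based assembly of paired-end reads into a single insert.

Mate 2 is reverse-complemented and slid over the 3' end of mate 1; among
overlaps of at least ``min_overlap`` bases whose mismatch fraction does not
exceed ``max_mismatch_frac`` the one maximizing matches-minus-mismatches is
chosen (longer overlap on ties).  In the overlap the higher-quality base is
kept (mate 1 on quality ties); consensus quality is the maximum of the two
qualities on agreement and their absolute difference on conflict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from . import _kernels
from .model import revcomp

_CODE = np.full(256, 255, np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes 0..4."""
    arr = _CODE[np.frombuffer(seq.encode(), np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-ACGTN symbol in sequence {seq[:30]!r}...")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: np.ndarray
    overlap_len: int
    n_overlap_mismatches: int


def merge_pair(pair: ReadPair, min_overlap: int = 10,
               max_mismatch_frac: float = 0.1) -> MergedRead | None:
    """Merge one read pair; returns None when no admissible overlap exists."""
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"read {pair.id}: empty mate")
    a = encode(pair.seq1)
    b = encode(revcomp(pair.seq2))
    qa = np.asarray(pair.qual1, np.uint8)
    qb = np.asarray(pair.qual2, np.uint8)[::-1].copy()
    o, mm = _kernels.best_overlap(a, b, min_overlap, max_mismatch_frac)
    if o < 0:
        return None
    seq, qual = _kernels.merge_consensus(a, qa, b, qb, o)
    return MergedRead(id=pair.id, seq=decode(seq), qual=qual,
                      overlap_len=int(o), n_overlap_mismatches=int(mm))


def merge_batch(pairs: Iterable[ReadPair], min_overlap: int = 10,
                max_mismatch_frac: float = 0.1) -> tuple[list[MergedRead], float]:
    """Merge a batch, preserving order; returns (merged, merge_rate)."""
    merged: list[MergedRead] = []
    total = 0
    for pair in pairs:
        total += 1
        m = merge_pair(pair, min_overlap, max_mismatch_frac)
        if m is not None:
            merged.append(m)
    rate = len(merged) / total if total else 0.0
    return merged, rate


def merge_stream(pairs: Iterable[ReadPair], min_overlap: int = 10,
                 max_mismatch_frac: float = 0.1,
                 counts: dict | None = None) -> Iterator[MergedRead]:
    """Streaming variant used by the pipeline; tallies into ``counts``."""
    for pair in pairs:
        if counts is not None:
            counts["pairs_in"] = counts.get("pairs_in", 0) + 1
        m = merge_pair(pair, min_overlap, max_mismatch_frac)
        if m is None:
            continue
        if counts is not None:
            counts["merged"] = counts.get("merged", 0) + 1
        yield m
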