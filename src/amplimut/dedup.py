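"""Quality trimming, N filtering, end-tag extraction and PCR-duplicate-aware
collapse to unique sequences.

Each sequencing insert is flanked by a random 5-nt tag on both ends
(introduced by the PCR primers).  Reads with identical insert AND identical
(tag5, tag3) pair are PCR duplicates of one founder molecule; the
``adjusted_count`` of a unique sequence is therefore the number of distinct
tag pairs observed for it, while ``raw_count`` is the plain number of reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .merge import MergedRead


@dataclass
class TaggedInsert:
    id: str
    insert: str
    tag5: str
    tag3: str


@dataclass
class UniqueSequence:
    insert: str
    raw_count: int
    adjusted_count: int
    tag_pairs: Counter = field(default_factory=Counter)


def quality_trim(read: MergedRead, q_threshold: int = 20,
                 min_len: int = 50) -> MergedRead | None:
    """Trim low-quality flanks; drop the read if it becomes too short.

    Bases are removed from each end until the terminal base has quality
    >= ``q_threshold``.
    """
    qual = read.qual
    n = len(qual)
    lo = 0
    while lo < n and qual[lo] < q_threshold:
        lo += 1
    hi = n
    while hi > lo and qual[hi - 1] < q_threshold:
        hi -= 1
    if hi - lo < min_len:
        return None
    if lo == 0 and hi == n:
        return read
    return MergedRead(id=read.id, seq=read.seq[lo:hi], qual=qual[lo:hi],
                      overlap_len=read.overlap_len,
                      n_overlap_mismatches=read.n_overlap_mismatches)


def drop_n_reads(reads: Iterable[MergedRead]) -> tuple[list[MergedRead], int]:
    """Remove reads containing undetermined nucleotides (N)."""
    kept = []
    dropped = 0
    for r in reads:
        if "N" in r.seq:
            dropped += 1
        else:
            kept.append(r)
    return kept, dropped


def extract_tags(read: MergedRead, tag_len: int = 5) -> TaggedInsert | None:
    """Strip the random end tags and annotate the read id with them.

    Returns None (drop) when the read is too short to contain an insert
    between the two tags.
    """
    if len(read.seq) <= 2 * tag_len:
        return None
    tag5 = read.seq[:tag_len]
    tag3 = read.seq[-tag_len:]
    insert = read.seq[tag_len:-tag_len]
    return TaggedInsert(id=f"{read.id};{tag5}:{tag3}", insert=insert,
                        tag5=tag5, tag3=tag3)


def collapse(inserts: Iterable[TaggedInsert]) -> list[UniqueSequence]:
    """Collapse to unique insert sequences with duplicate-corrected counts.

    ``adjusted_count`` is the number of distinct (tag5, tag3) pairs per
    insert; output is ordered by descending adjusted count, then insert.
    """
    groups: dict[str, Counter] = {}
    for t in inserts:
        groups.setdefault(t.insert, Counter())[(t.tag5, t.tag3)] += 1
    out = [
        UniqueSequence(insert=seq, raw_count=sum(tags.values()),
                       adjusted_count=len(tags), tag_pairs=tags)
        for seq, tags in groups.items()
    ]
    out.sort(key=lambda u: (-u.adjusted_count, u.insert))
    return out


def preprocess_stream(reads: Iterable[MergedRead], q_threshold: int = 20,
                      min_len: int = 50, tag_len: int = 5,
                      counts: dict | None = None) -> Iterator[TaggedInsert]:
    """Trim -> N-filter -> tag extraction as one pass, tallying into ``counts``."""
    def bump(key):
        if counts is not None:
            counts[key] = counts.get(key, 0) + 1

    for read in reads:
        trimmed = quality_trim(read, q_threshold, min_len)
        if trimmed is None:
            bump("dropped_short")
            continue
        if "N" in trimmed.seq:
            bump("dropped_n")
            continue
        tagged = extract_tags(trimmed, tag_len)
        if tagged is None:
            bump("dropped_short")
            continue
        bump("inserts")
        yield tagged
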