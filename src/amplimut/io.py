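"""FASTQ/FASTA input and output.

FASTQ is Sanger-encoded (Phred+33); gzipped files are recognized by the
``.gz`` suffix.  Collapsed unique sequences are written as FASTA with raw
and tag-adjusted counts encoded in the header
(``>seq{rank};raw={n};adj={m}``).
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO import parse as seqio_parse
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dedup import UniqueSequence
from .merge import ReadPair


def _open(path: str, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in seqio_parse(path, "fasta")}


def phred_from_string(qual: str) -> np.ndarray:
    arr = np.frombuffer(qual.encode(), np.uint8).astype(np.uint8) - 33
    return arr


def phred_to_string(qual: np.ndarray) -> str:
    return (np.asarray(qual, np.uint8) + 33).tobytes().decode()


def read_pairs(fastq1: str, fastq2: str) -> Iterator[ReadPair]:
    """Iterate paired-end reads from two synchronized FASTQ files."""
    with _open(fastq1) as f1, _open(fastq2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2):
            name1 = id1.split()[0]
            name2 = id2.split()[0]
            if name1.rstrip("/12") != name2.rstrip("/12"):
                raise ValueError(
                    f"FASTQ files out of sync: {name1!r} vs {name2!r}")
            yield ReadPair(id=name1, seq1=s1.upper(),
                           qual1=phred_from_string(q1),
                           seq2=s2.upper(), qual2=phred_from_string(q2))


def read_merged(fastq: str) -> Iterator:
    """Pre-merged single-end FASTQ entry point (merger run upstream)."""
    from .merge import MergedRead
    with _open(fastq) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield MergedRead(id=rid.split()[0], seq=seq.upper(),
                             qual=phred_from_string(qual), overlap_len=0,
                             n_overlap_mismatches=0)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str,
                      path2: str) -> int:
    n = 0
    with _open(path1, "wt") as f1, _open(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{phred_to_string(p.qual1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{phred_to_string(p.qual2)}\n")
            n += 1
    return n


def write_collapsed_fasta(uniques: Iterable[UniqueSequence], path: str) -> None:
    with _open(path, "wt") as fh:
        for rank, u in enumerate(uniques, 1):
            fh.write(f">seq{rank};raw={u.raw_count};adj={u.adjusted_count}\n")
            fh.write(u.insert + "\n")
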