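"""Global pairwise alignment of unique sequences to the amplicon reference.

Needleman-Wunsch with EMBOSS-needle-style scoring: for A/C/G/T data the
EDNAFULL matrix reduces to match +5 / mismatch -4; a gap of length L costs
``gap_open + L * gap_extend`` and end gaps are free by default (needle's
endweight=false), which tolerates truncated inserts.  Tie-breaking prefers
the diagonal, then gap-in-query, then gap-in-ref, so indels are placed at
their leftmost equivalent position — this anchoring is what makes downstream
insertion/deletion labels reproducible.

Alignments scoring below ``min_score`` (default 200, i.e. 40 matched bases
with no penalty) are discarded as unrelated to the target amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .merge import encode


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


DEFAULT_SCHEME = ScoringScheme()
#: default retention threshold for the alignment score
DEFAULT_MIN_SCORE = 200.0


@dataclass
class Alignment:
    aligned_ref: str
    aligned_query: str
    score: float
    query_id: str = ""
    weight: int = 1
    raw_weight: int = 1

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned rows must have equal length")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")


def needleman_wunsch(ref: str, query: str,
                     scheme: ScoringScheme = DEFAULT_SCHEME,
                     query_id: str = "", weight: int = 1,
                     raw_weight: int | None = None) -> Alignment:
    """Optimal global alignment of ``query`` against ``ref``."""
    if not ref or not query:
        raise ValueError("sequences must be non-empty")
    r = encode(ref)
    q = encode(query)
    if (r == 4).any() or (q == 4).any():
        raise ValueError("sequences must contain only A/C/G/T")
    score, moves = _kernels.nw_affine(
        r, q, float(scheme.match), float(scheme.mismatch),
        float(scheme.gap_open), float(scheme.gap_extend),
        scheme.end_gaps_free)
    ar = []
    aq = []
    i = j = 0
    for mv in moves:
        if mv == _kernels.MOVE_DIAG:
            ar.append(ref[i])
            aq.append(query[j])
            i += 1
            j += 1
        elif mv == _kernels.MOVE_DEL:
            ar.append(ref[i])
            aq.append("-")
            i += 1
        else:
            ar.append("-")
            aq.append(query[j])
            j += 1
    return Alignment(aligned_ref="".join(ar), aligned_query="".join(aq),
                     score=float(score), query_id=query_id, weight=weight,
                     raw_weight=weight if raw_weight is None else raw_weight)


def filter_by_score(alignments: Sequence[Alignment],
                    min_score: float = DEFAULT_MIN_SCORE,
                    ) -> tuple[list[Alignment], list[Alignment], float]:
    """Partition alignments at the score threshold (inclusive retention).

    The discard fraction is per unique sequence, not weighted by read count.
    """
    kept = [a for a in alignments if a.score >= min_score]
    discarded = [a for a in alignments if a.score < min_score]
    frac = len(discarded) / len(alignments) if alignments else 0.0
    return kept, discarded, frac


def brute_force_score(ref: str, query: str,
                      scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Optimal score by exhaustive enumeration of all global alignments.

    Independent of the DP: enumerates every move string recursively and
    scores maximal gap runs at ``gap_open + L * gap_extend`` (terminal runs
    free when ``end_gaps_free``).  Exponential — intended for sequences of
    length <= ~8 as a cross-check oracle.
    """
    n, m = len(ref), len(query)
    best = -np.inf

    def score_moves(moves: list[int]) -> float:
        total = 0.0
        i = j = 0
        k = 0
        nmv = len(moves)
        while k < nmv:
            mv = moves[k]
            if mv == 0:
                total += scheme.match if ref[i] == query[j] else scheme.mismatch
                i += 1
                j += 1
                k += 1
            else:
                run = 0
                start = k
                while k < nmv and moves[k] == mv:
                    run += 1
                    if mv == 1:
                        i += 1
                    else:
                        j += 1
                    k += 1
                terminal = start == 0 or k == nmv
                if not (terminal and scheme.end_gaps_free):
                    total -= scheme.gap_open + run * scheme.gap_extend
        return total

    moves: list[int] = []

    def rec(i: int, j: int):
        nonlocal best
        if i == n and j == m:
            s = score_moves(moves)
            if s > best:
                best = s
            return
        if i < n and j < m:
            moves.append(0)
            rec(i + 1, j + 1)
            moves.pop()
        if i < n:
            moves.append(1)
            rec(i + 1, j)
            moves.pop()
        if j < m:
            moves.append(2)
            rec(i, j + 1)
            moves.pop()

    rec(0, 0)
    return float(best)
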