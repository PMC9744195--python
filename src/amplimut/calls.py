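"""Mutation calling from alignments and per-position aggregation.

Each alignment yields typed events: a maximal run of gap-in-query columns is
one deletion (reference interval), a maximal run of gap-in-ref columns is
one insertion anchored at the first reference base to its right, and every
substituted column is a single-base mismatch.  Applying the events of an
alignment to the reference reconstructs the query exactly.

Per-position tallies exclude the primer regions; a deletion increments every
reference position it covers, an insertion only its anchor.  Both
duplicate-corrected (adjusted) and raw read counts are carried so the effect
of the tag correction stays measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Alignment
from .model import AmpliconSpec, GuideTarget, cut_relative_position

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class MutationEvent:
    kind: str                 # deletion | insertion | mismatch
    ref_start: int = -1       # deletion/mismatch: 0-based half-open interval
    ref_end: int = -1
    anchor: int = -1          # insertion: ref index of first base to its right
    bases: str = ""           # inserted bases, or the observed mismatch base
    weight: int = 1           # adjusted count of the source unique sequence
    raw_weight: int = 1
    source: str = ""


def call_mutations(aln: Alignment, weight: int = 1,
                   raw_weight: int | None = None,
                   source: str = "") -> list[MutationEvent]:
    """Extract typed mutation events from one alignment."""
    if raw_weight is None:
        raw_weight = weight
    events: list[MutationEvent] = []
    ref_pos = 0
    del_start = -1
    ins_bases: list[str] = []

    def close_runs():
        nonlocal del_start, ins_bases
        if del_start >= 0:
            events.append(MutationEvent("deletion", ref_start=del_start,
                                        ref_end=ref_pos, weight=weight,
                                        raw_weight=raw_weight, source=source))
            del_start = -1
        if ins_bases:
            events.append(MutationEvent("insertion", anchor=ref_pos,
                                        bases="".join(ins_bases), weight=weight,
                                        raw_weight=raw_weight, source=source))
            ins_bases = []

    for rb, qb in zip(aln.aligned_ref, aln.aligned_query):
        if rb != "-" and qb != "-":
            close_runs()
            if rb != qb:
                events.append(MutationEvent("mismatch", ref_start=ref_pos,
                                            ref_end=ref_pos + 1, bases=qb,
                                            weight=weight, raw_weight=raw_weight,
                                            source=source))
            ref_pos += 1
        elif qb == "-":
            if ins_bases:  # insertion run ends where a deletion begins
                events.append(MutationEvent("insertion", anchor=ref_pos,
                                            bases="".join(ins_bases),
                                            weight=weight, raw_weight=raw_weight,
                                            source=source))
                ins_bases = []
            if del_start < 0:
                del_start = ref_pos
            ref_pos += 1
        else:
            if del_start >= 0:
                events.append(MutationEvent("deletion", ref_start=del_start,
                                            ref_end=ref_pos, weight=weight,
                                            raw_weight=raw_weight, source=source))
                del_start = -1
            ins_bases.append(qb)
    close_runs()
    return events


def apply_events(ref: str, events: list[MutationEvent]) -> str:
    """Rebuild the query sequence by applying events to the reference.

    Inverse of :func:`call_mutations` for events originating from a single
    alignment (non-overlapping; an insertion anchored at the start of a
    deletion precedes the deleted bases, as in the alignment).
    """
    ins_at: dict[int, str] = {}
    sub_at: dict[int, str] = {}
    deleted = np.zeros(len(ref), bool)
    for ev in events:
        if ev.kind == "insertion":
            ins_at[ev.anchor] = ins_at.get(ev.anchor, "") + ev.bases
        elif ev.kind == "mismatch":
            sub_at[ev.ref_start] = ev.bases
        elif ev.kind == "deletion":
            deleted[ev.ref_start:ev.ref_end] = True
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    out = []
    for i in range(len(ref) + 1):
        if i in ins_at:
            out.append(ins_at[i])
        if i < len(ref) and not deleted[i]:
            out.append(sub_at.get(i, ref[i]))
    return "".join(out)


class PositionTally:
    """Per-position, per-class mutation counts in primer-excluded coordinates.

    Parallel adjusted (tag-corrected) and raw tallies; mismatches are broken
    down by observed base and insertions additionally by their first inserted
    base (used for logo glyphs).
    """

    def __init__(self, spec: AmpliconSpec, total_adjusted: int,
                 total_raw: int):
        self.spec = spec
        self.positions = np.array(spec.nonprimer_positions, int)
        self._row = {p: i for i, p in enumerate(self.positions)}
        n = len(self.positions)
        self.total_adjusted = total_adjusted
        self.total_raw = total_raw
        self.deletion = np.zeros((n, 2), np.int64)       # cols: adjusted, raw
        self.insertion = np.zeros((n, 2), np.int64)
        self.mismatch = np.zeros((n, 4, 2), np.int64)    # per observed base
        self.ins_base = np.zeros((n, 4, 2), np.int64)    # first inserted base

    def add_event(self, ev: MutationEvent) -> None:
        w = np.array([ev.weight, ev.raw_weight], np.int64)
        if ev.kind == "deletion":
            if ev.ref_start < 0 or ev.ref_end > len(self.spec.ref_seq):
                raise RuntimeError(f"deletion event outside amplicon: {ev}")
            for p in range(ev.ref_start, ev.ref_end):
                r = self._row.get(p)
                if r is not None:
                    self.deletion[r] += w
        elif ev.kind == "insertion":
            if not 0 <= ev.anchor <= len(self.spec.ref_seq):
                raise RuntimeError(f"insertion event outside amplicon: {ev}")
            r = self._row.get(ev.anchor)
            if r is not None:
                self.insertion[r] += w
                b = _BASE_IDX.get(ev.bases[0])
                if b is not None:
                    self.ins_base[r, b] += w
        elif ev.kind == "mismatch":
            if not 0 <= ev.ref_start < len(self.spec.ref_seq):
                raise RuntimeError(f"mismatch event outside amplicon: {ev}")
            r = self._row.get(ev.ref_start)
            if r is not None:
                self.mismatch[r, _BASE_IDX[ev.bases]] += w
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    # -- accessors ---------------------------------------------------------
    def _col(self, raw: bool) -> int:
        return 1 if raw else 0

    def denominator(self, raw: bool = False) -> int:
        return self.total_raw if raw else self.total_adjusted

    def mismatch_total(self, raw: bool = False) -> np.ndarray:
        return self.mismatch[:, :, self._col(raw)].sum(axis=1)

    def frequencies(self, raw: bool = False) -> pd.DataFrame:
        c = self._col(raw)
        denom = max(self.denominator(raw), 1)
        df = self.to_dataframe(raw=raw)
        for col in ["deletion", "insertion"] + [f"mismatch_{b}" for b in BASES]:
            df[f"freq_{col}"] = df[col] / denom
        return df

    def region_flags(self, target: GuideTarget) -> np.ndarray:
        w = target.window
        return np.array([p in w for p in self.positions])

    def labels(self, target: GuideTarget) -> np.ndarray:
        return np.array([cut_relative_position(target, p)
                         for p in self.positions])

    def to_dataframe(self, raw: bool = False) -> pd.DataFrame:
        c = self._col(raw)
        data = {
            "position": self.positions,
            "ref_base": [self.spec.ref_seq[p] for p in self.positions],
            "deletion": self.deletion[:, c],
            "insertion": self.insertion[:, c],
        }
        for i, b in enumerate(BASES):
            data[f"mismatch_{b}"] = self.mismatch[:, i, c]
        df = pd.DataFrame(data)
        for t in self.spec.targets:
            df[f"label_{t.name}"] = self.labels(t)
            df[f"in_target_{t.name}"] = self.region_flags(t)
        return df


def tally(events: list[MutationEvent], spec: AmpliconSpec,
          total_adjusted: int, total_raw: int) -> PositionTally:
    """Aggregate score-filtered events into a per-position tally."""
    t = PositionTally(spec, total_adjusted, total_raw)
    for ev in events:
        t.add_event(ev)
    return t


def interval_spectrum(events: list[MutationEvent], target: GuideTarget,
                      total_reads: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deletion-interval and insertion-anchor spectra in cut-relative labels.

    Frequencies are reported both relative to the weighted number of events
    of the same class and relative to all retained reads.
    """
    del_w: dict[tuple[int, int], int] = {}
    ins_w: dict[int, int] = {}
    for ev in events:
        if ev.kind == "deletion":
            key = (cut_relative_position(target, ev.ref_start),
                   cut_relative_position(target, ev.ref_end - 1))
            if target.strand == "-":
                key = (key[1], key[0])
            del_w[key] = del_w.get(key, 0) + ev.weight
        elif ev.kind == "insertion":
            key = cut_relative_position(target, ev.anchor)
            ins_w[key] = ins_w.get(key, 0) + ev.weight
    tot_del = sum(del_w.values())
    tot_ins = sum(ins_w.values())
    denom = max(total_reads, 1)
    del_df = pd.DataFrame(
        [{"start_label": k[0], "end_label": k[1],
          "interval": f"{k[0]} to {k[1]}", "count": w,
          "freq_of_deletions": w / tot_del if tot_del else 0.0,
          "freq_of_reads": w / denom}
         for k, w in del_w.items()],
        columns=["start_label", "end_label", "interval", "count",
                 "freq_of_deletions", "freq_of_reads"])
    ins_df = pd.DataFrame(
        [{"anchor_label": k, "count": w,
          "freq_of_insertions": w / tot_ins if tot_ins else 0.0,
          "freq_of_reads": w / denom}
         for k, w in ins_w.items()],
        columns=["anchor_label", "count", "freq_of_insertions",
                 "freq_of_reads"])
    del_df = del_df.sort_values("count", ascending=False, kind="stable",
                                ignore_index=True)
    ins_df = ins_df.sort_values("count", ascending=False, kind="stable",
                                ignore_index=True)
    return del_df, ins_df
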