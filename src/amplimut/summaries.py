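"""Dataset-level statistics over the per-position tallies and event tables.

Covers the comparisons a pooled-editing experiment reports: per-base
mutation enrichment inside the 20-nt protospacer window versus the flanks,
large deletions spanning two guide targets, per-position substitution
profiles for cytidine base editing (C->T fraction and editing window), the
effect of the PCR-duplicate tag correction, and descriptive fold changes
between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import BASES, MutationEvent, PositionTally
from .model import (AmpliconSpec, GuideTarget, cut_relative_position,
                    ref_index_of, target_window)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

EVENT_CLASSES = ("deletion", "insertion", "mismatch")


@dataclass
class ClassEnrichment:
    inside_count: float
    outside_count: float
    inside_rate: float      # weighted events per base inside the 20-nt window
    outside_rate: float     # per base outside (primer-excluded)
    fold: float             # inside/outside; +inf when outside is zero


def region_enrichment(events: list[MutationEvent], spec: AmpliconSpec,
                      target: GuideTarget,
                      raw: bool = False) -> dict[str, ClassEnrichment]:
    """Per-base mutation rate inside vs outside the protospacer window.

    An event counts as inside when it starts or ends within the 20-nt
    window (insertions: their anchor).
    """
    window = target_window(target)
    nonprimer = set(spec.nonprimer_positions)
    inside_len = len(window)
    outside_len = len(nonprimer - window)
    counts = {k: [0.0, 0.0] for k in EVENT_CLASSES}
    for ev in events:
        w = ev.raw_weight if raw else ev.weight
        if ev.kind == "insertion":
            inside = ev.anchor in window
        else:
            inside = ev.ref_start in window or (ev.ref_end - 1) in window
        counts[ev.kind][0 if inside else 1] += w
    report = {}
    for k, (cin, cout) in counts.items():
        rin = cin / inside_len
        rout = cout / outside_len if outside_len else 0.0
        if rout > 0:
            fold = rin / rout
        else:
            fold = math.inf if rin > 0 else 1.0
        report[k] = ClassEnrichment(inside_count=cin, outside_count=cout,
                                    inside_rate=rin, outside_rate=rout,
                                    fold=fold)
    return report


def large_deletions(events: list[MutationEvent], target1: GuideTarget,
                    target2: GuideTarget) -> pd.DataFrame:
    """Deletions spanning both cleavage sites of a dual-guide amplicon.

    Endpoints are reported as cut-relative labels per target; the length is
    the reference interval length, which equals the distance between the two
    cut sites plus the absolute values of the two endpoint labels.
    """
    if target1.cut_site > target2.cut_site:
        target1, target2 = target2, target1
    cut1, cut2 = target1.cut_site, target2.cut_site
    rows: dict[tuple[int, int], dict] = {}
    total_del = 0
    for ev in events:
        if ev.kind != "deletion":
            continue
        total_del += ev.weight
        if not (ev.ref_start < cut1 and ev.ref_end > cut2):
            continue
        key = (ev.ref_start, ev.ref_end)
        if key not in rows:
            rows[key] = {
                "label_target1": cut_relative_position(target1, ev.ref_start),
                "label_target2": cut_relative_position(target2, ev.ref_end - 1),
                "length_bp": ev.ref_end - ev.ref_start,
                "ref_start": ev.ref_start,
                "ref_end": ev.ref_end,
                "count": 0,
            }
        rows[key]["count"] += ev.weight
    df = pd.DataFrame(list(rows.values()),
                      columns=["label_target1", "label_target2", "length_bp",
                               "ref_start", "ref_end", "count"])
    df["freq_of_deletions"] = (df["count"] / total_del if total_del
                               else 0.0)
    return df.sort_values("count", ascending=False, kind="stable",
                          ignore_index=True)


@dataclass
class SubstitutionMatrix:
    """Per-position substitution counts around a guide target.

    Rows are cut-relative labels over the 20-nt window plus ``flank`` nt on
    each side; counts are reference-base -> observed-base (diagonal empty).
    """

    target: GuideTarget
    labels: np.ndarray          # cut-relative labels, guide orientation
    ref_bases: list[str]        # on the plus strand of the reference
    counts: np.ndarray          # (n_positions, 4) observed-base counts
    denominator: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "ref_base", self.ref_bases)
        df.insert(0, "label", self.labels)
        return df

    def in_window(self) -> np.ndarray:
        return np.array([-17 <= l <= -1 or 1 <= l <= 3 for l in self.labels])


def substitution_profile(tally: PositionTally, target: GuideTarget,
                         flank: int = 10) -> SubstitutionMatrix:
    """Mismatch counts for the protospacer window plus ``flank`` nt each side."""
    n = len(tally.spec.ref_seq)
    labels = [l for l in range(-(17 + flank), 4 + flank) if l != 0]
    keep, rows, bases = [], [], []
    for l in labels:
        p = ref_index_of(target, l)
        if not 0 <= p < n:
            continue
        r = tally._row.get(p)
        if r is None:
            continue
        keep.append(l)
        rows.append(tally.mismatch[r, :, 0])
        bases.append(tally.spec.ref_seq[p])
    return SubstitutionMatrix(target=target, labels=np.array(keep, int),
                              ref_bases=bases,
                              counts=np.array(rows, np.int64).reshape(-1, 4),
                              denominator=tally.total_adjusted)


def _guide_base(base: str, strand: str) -> str:
    return base if strand == "+" else _COMP[base]


def ct_fraction(matrix: SubstitutionMatrix) -> float:
    """Fraction of window mismatches that are C->T on the guide strand.

    NaN when the window carries no mismatches at all.
    """
    strand = matrix.target.strand
    mask = matrix.in_window()
    ct = 0
    total = 0
    for i in np.flatnonzero(mask):
        row = matrix.counts[i]
        total += int(row.sum())
        ref_g = _guide_base(matrix.ref_bases[i], strand)
        if ref_g == "C":
            alt_plus = "T" if strand == "+" else "A"   # T on the guide strand
            ct += int(row[BASES.index(alt_plus)])
    return ct / total if total else math.nan


def editing_window(matrix: SubstitutionMatrix, min_freq: float) -> set[int]:
    """Cut-relative labels of guide-strand C positions edited to T at a
    frequency of at least ``min_freq`` (relative to all retained reads)."""
    strand = matrix.target.strand
    denom = max(matrix.denominator, 1)
    out = set()
    for i, label in enumerate(matrix.labels):
        if _guide_base(matrix.ref_bases[i], strand) != "C":
            continue
        alt_plus = "T" if strand == "+" else "A"
        if matrix.counts[i, BASES.index(alt_plus)] / denom >= min_freq:
            out.add(int(label))
    return out


def tag_effect(tally: PositionTally, min_adjusted: int = 10) -> tuple[pd.DataFrame, float]:
    """Per-position-class ratio of raw to tag-adjusted mutation frequency.

    Positions with an adjusted count below ``min_adjusted`` are excluded
    from the max to avoid ratio blow-ups on near-empty cells.
    """
    adj_denom = max(tally.total_adjusted, 1)
    raw_denom = max(tally.total_raw, 1)
    recs = []
    classes = {
        "deletion": (tally.deletion[:, 0], tally.deletion[:, 1]),
        "insertion": (tally.insertion[:, 0], tally.insertion[:, 1]),
        "mismatch": (tally.mismatch[:, :, 0].sum(axis=1),
                     tally.mismatch[:, :, 1].sum(axis=1)),
    }
    for cls, (adj, raw) in classes.items():
        for i, p in enumerate(tally.positions):
            if adj[i] == 0 and raw[i] == 0:
                continue
            f_adj = adj[i] / adj_denom
            f_raw = raw[i] / raw_denom
            fold = f_raw / f_adj if f_adj > 0 else math.inf
            recs.append({"position": int(p), "class": cls,
                         "adjusted_count": int(adj[i]), "raw_count": int(raw[i]),
                         "freq_adjusted": f_adj, "freq_raw": f_raw,
                         "fold": fold})
    df = pd.DataFrame(recs, columns=["position", "class", "adjusted_count",
                                     "raw_count", "freq_adjusted", "freq_raw",
                                     "fold"])
    eligible = df[(df["adjusted_count"] >= min_adjusted)
                  & np.isfinite(df["fold"])]
    max_fold = float(eligible["fold"].max()) if len(eligible) else math.nan
    return df, max_fold


def compare_conditions(runs: dict[str, dict], keys: list | None = None,
                       baseline: str | None = None) -> pd.DataFrame:
    """Descriptive fold changes of frequencies between condition runs.

    ``runs`` maps a condition name to a mapping of spectrum keys (deletion
    intervals, insertion anchors, positions...) to frequencies.  Folds are
    reported relative to ``baseline`` (default: first run); the returned
    frame carries one row per key plus a ``mean`` row over the key set.
    """
    if len(runs) < 2:
        raise ValueError("need at least two condition runs to compare")
    names = list(runs)
    if baseline is None:
        baseline = names[0]
    if keys is None:
        keys = sorted(set.intersection(*(set(r) for r in runs.values())),
                      key=repr)
        if not keys:
            raise ValueError(
                "condition runs share no spectrum keys; got "
                + "; ".join(f"{n}: {sorted(map(repr, r))}"
                            for n, r in runs.items()))
    else:
        for n, r in runs.items():
            missing = [k for k in keys if k not in r]
            if missing:
                raise ValueError(f"condition {n!r} lacks keys {missing}")
    rows = []
    for k in keys:
        base = runs[baseline][k]
        row = {"key": k}
        for n in names:
            row[n] = runs[n][k] / base if base > 0 else math.inf
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"key": "mean"}
    for n in names:
        finite = [r[n] for r in rows if math.isfinite(r[n])]
        mean_row[n] = sum(finite) / len(finite) if finite else math.nan
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
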