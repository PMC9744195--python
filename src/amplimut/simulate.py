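"""Synthetic amplicon-sequencing data with ground truth.

Emulates the experimental inputs of a pooled editing assay: founder
molecules drawn from a generative spectrum of editing outcomes (deletion
intervals, insertions and substitutions in cut-relative coordinates, plus an
unedited fraction), 5-nt random primer tags on both ends, PCR duplication of
each founder (same tags), per-read substitution/N sequencing errors, and
overlapping paired-end reads.

Defaults mirror the study conditions: ~15-fold mean duplication per founder
molecule, a 0.1% per-base substitution error floor (PCR + sequencing), a
0.02% N rate, 150-nt reads and 5-nt tags.  Everything is deterministic under
a fixed seed, and the truth table names the template applied to every
founder so each pipeline stage can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .align import ScoringScheme, needleman_wunsch
from .calls import MutationEvent, call_mutations
from .merge import ReadPair, encode, decode
from .model import AmpliconSpec, GuideTarget, ref_index_of, revcomp


@dataclass(frozen=True)
class EventTemplate:
    """One editing outcome, located by cut-relative labels.

    * deletion: removes labels ``start_label..end_label`` inclusive (guide
      orientation).
    * insertion: inserts ``bases`` (plus-strand) immediately left of the base
      labelled ``anchor_label``.
    * substitution: replaces the base at ``position_label`` with ``alt``
      (plus-strand).
    * unedited: the reference molecule.
    """

    id: str
    kind: str
    start_label: int = 0
    end_label: int = 0
    anchor_label: int = 0
    position_label: int = 0
    bases: str = ""
    alt: str = ""


def unedited(template_id: str = "unedited") -> EventTemplate:
    return EventTemplate(id=template_id, kind="unedited")


@dataclass
class EventSpectrum:
    """Editing-outcome templates with their probabilities (must sum to 1)."""

    entries: list[tuple[EventTemplate, float]]

    def __post_init__(self):
        probs = [p for _, p in self.entries]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {sum(probs)}, not 1")
        ids = [t.id for t, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("template ids must be unique")

    @property
    def templates(self) -> list[EventTemplate]:
        return [t for t, _ in self.entries]

    def probability(self, template_id: str) -> float:
        for t, p in self.entries:
            if t.id == template_id:
                return p
        raise KeyError(template_id)


@dataclass
class SimConfig:
    n_molecules: int = 20_000
    pcr_dup_mean: float = 15.0
    seq_error_rate: float = 0.001
    n_rate: float = 0.0002
    read_len: int = 150
    tag_len: int = 5
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self):
        for name in ("seq_error_rate", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_len <= 2 * self.tag_len:
            raise ValueError("read_len must exceed twice the tag length")
        if self.pcr_dup_mean < 1.0:
            raise ValueError("pcr_dup_mean must be >= 1")


def apply_template(spec: AmpliconSpec, target: GuideTarget,
                   template: EventTemplate) -> str:
    """The molecule sequence produced by one editing outcome."""
    ref = spec.ref_seq
    t = template
    if t.kind == "unedited":
        return ref
    if t.kind == "deletion":
        i = ref_index_of(target, t.start_label)
        j = ref_index_of(target, t.end_label)
        lo, hi = min(i, j), max(i, j) + 1
        if lo < 0 or hi > len(ref):
            raise ValueError(f"template {t.id}: deletion outside amplicon")
        return ref[:lo] + ref[hi:]
    if t.kind == "insertion":
        k = ref_index_of(target, t.anchor_label)
        if not 0 <= k <= len(ref) or not t.bases:
            raise ValueError(f"template {t.id}: invalid insertion")
        return ref[:k] + t.bases + ref[k:]
    if t.kind == "substitution":
        k = ref_index_of(target, t.position_label)
        if not 0 <= k < len(ref) or t.alt not in "ACGT":
            raise ValueError(f"template {t.id}: invalid substitution")
        if ref[k] == t.alt:
            raise ValueError(f"template {t.id}: alt equals the reference base")
        return ref[:k] + t.alt + ref[k + 1:]
    raise ValueError(f"unknown template kind {t.kind!r}")


def canonical_events(spec: AmpliconSpec, target: GuideTarget,
                     template: EventTemplate,
                     scheme: ScoringScheme = ScoringScheme(),
                     ) -> frozenset[tuple]:
    """The event signature the aligner assigns to a template's molecule.

    Aligning the templated molecule back to the reference canonicalizes
    ambiguous indel placement (e.g. insertions into repeats) under the
    pipeline's own left-shifting tie-break.
    """
    seq = apply_template(spec, target, template)
    events = call_mutations(needleman_wunsch(spec.ref_seq, seq, scheme))
    return frozenset(_event_key(e) for e in events)


def _event_key(ev: MutationEvent) -> tuple:
    if ev.kind == "insertion":
        return ("insertion", ev.anchor, ev.bases)
    if ev.kind == "deletion":
        return ("deletion", ev.ref_start, ev.ref_end)
    return ("mismatch", ev.ref_start, ev.bases)


_TAG_BASES = np.frombuffer(b"ACGT", np.uint8)


def simulate_molecules(spec: AmpliconSpec, target: GuideTarget,
                       spectrum: EventSpectrum, n: int,
                       rng: np.random.Generator,
                       tag_len: int = 5) -> tuple[list[str], pd.DataFrame]:
    """Draw founder molecules and their end tags; returns (sequences, truth)."""
    seqs = {t.id: apply_template(spec, target, t) for t in spectrum.templates}
    ids = [t.id for t in spectrum.templates]
    probs = np.array([p for _, p in spectrum.entries])
    choice = rng.choice(len(ids), size=n, p=probs)
    tags = _TAG_BASES[rng.integers(0, 4, size=(n, 2, tag_len))]
    molecules = []
    rows = []
    for i in range(n):
        tid = ids[choice[i]]
        molecules.append(seqs[tid])
        rows.append({"molecule": f"m{i}", "template": tid,
                     "tag5": tags[i, 0].tobytes().decode(),
                     "tag3": tags[i, 1].tobytes().decode()})
    return molecules, pd.DataFrame(rows)


def simulate_reads(molecules: list[str], truth: pd.DataFrame,
                   config: SimConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Duplicate founders, apply sequencing errors and cut paired reads.

    Returns the read pairs and the truth table extended with a
    ``dup_count`` column.  PCR duplicates share the founder's tags; errors
    are drawn independently per copy and mate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(molecules)
    L = config.read_len
    dup = 1 + rng.poisson(config.pcr_dup_mean - 1.0, size=n)
    truth = truth.assign(dup_count=dup)

    inserts = []
    for i, mol in enumerate(molecules):
        ins = truth.at[i, "tag5"] + mol + truth.at[i, "tag3"]
        if len(ins) < L:
            raise ValueError(
                f"read_len {L} exceeds tagged insert length {len(ins)}")
        if len(ins) > 2 * L - 10:
            raise ValueError(
                "amplicon too long for overlapping paired reads "
                f"({len(ins)} > 2*{L} - 10)")
        inserts.append(encode(ins))

    total = int(dup.sum())
    r1 = np.empty((total, L), np.uint8)
    r2 = np.empty((total, L), np.uint8)
    owner = np.empty(total, np.int64)
    row = 0
    for i, ins in enumerate(inserts):
        rc = (3 - ins)[::-1]           # A<->T, C<->G on 0..3 codes
        a = ins[:L]
        b = rc[:L]
        for _ in range(dup[i]):
            r1[row] = a
            r2[row] = b
            owner[row] = i
            row += 1

    for mat in (r1, r2):
        err_mask = rng.random(mat.shape) < config.seq_error_rate
        offsets = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        n_mask = rng.random(mat.shape) < config.n_rate
        _kernels.apply_substitution_errors(mat, err_mask, offsets, n_mask)

    qual = np.full(L, config.base_quality, np.uint8)
    pairs = []
    for k in range(total):
        i = owner[k]
        pairs.append(ReadPair(id=f"m{i}:c{k}", seq1=decode(r1[k]),
                              qual1=qual, seq2=decode(r2[k]), qual2=qual))
    return pairs, truth


def simulate_dataset(spec: AmpliconSpec, target: GuideTarget,
                     spectrum: EventSpectrum, config: SimConfig,
                     ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Molecules + reads in one call, all randomness from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    molecules, truth = simulate_molecules(spec, target, spectrum,
                                          config.n_molecules, rng,
                                          tag_len=config.tag_len)
    return simulate_reads(molecules, truth, config, rng)


def spectrum_from_config(entries: list[dict]) -> EventSpectrum:
    """Build an :class:`EventSpectrum` from run-config mappings.

    Each entry carries ``id``, ``kind``, ``p`` and the kind's coordinates:
    ``start``/``end`` labels for deletions, ``anchor``+``bases`` for
    insertions, ``position``+``alt`` for substitutions.
    """
    out = []
    for e in entries:
        kind = e["kind"]
        tid = e.get("id") or kind
        p = float(e["p"])
        if kind == "deletion":
            t = EventTemplate(id=tid, kind=kind, start_label=int(e["start"]),
                              end_label=int(e["end"]))
        elif kind == "insertion":
            t = EventTemplate(id=tid, kind=kind, anchor_label=int(e["anchor"]),
                              bases=str(e["bases"]).upper())
        elif kind == "substitution":
            t = EventTemplate(id=tid, kind=kind,
                              position_label=int(e["position"]),
                              alt=str(e["alt"]).upper())
        elif kind == "unedited":
            t = unedited(tid)
        else:
            raise ValueError(f"unknown spectrum kind {kind!r}")
        out.append((t, p))
    return EventSpectrum(out)


def truth_frequencies(truth: pd.DataFrame,
                      spectrum: EventSpectrum) -> dict[str, float]:
    """Realized per-template founder fractions from the truth table."""
    counts = truth["template"].value_counts()
    n = len(truth)
    return {t.id: counts.get(t.id, 0) / n for t in spectrum.templates}


def recovered_frequencies(spec: AmpliconSpec, target: GuideTarget,
                          spectrum: EventSpectrum,
                          events_by_source: dict[str, list[MutationEvent]],
                          weights: dict[str, int],
                          scheme: ScoringScheme = ScoringScheme(),
                          exact: bool = False) -> dict[str, float]:
    """Template frequencies recovered from the pipeline's mutation calls.

    Each unique sequence is assigned to the template whose canonical event
    signature its called events match (exactly when ``exact``; otherwise the
    most specific template whose signature is a subset of the calls, so that
    extra mismatch events from sequencing noise do not shed reads).
    Frequencies are weighted fractions over all retained unique sequences.
    """
    canon = {t.id: canonical_events(spec, target, t, scheme)
             for t in spectrum.templates}
    order = sorted(canon, key=lambda tid: -len(canon[tid]))
    totals = {tid: 0 for tid in canon}
    denom = 0
    for src, events in events_by_source.items():
        w = weights[src]
        denom += w
        sig = frozenset(_event_key(e) for e in events)
        if exact:
            for tid in order:
                if sig == canon[tid]:
                    totals[tid] += w
                    break
        else:
            for tid in order:
                if canon[tid] <= sig:
                    totals[tid] += w
                    break
    if denom == 0:
        return {tid: 0.0 for tid in canon}
    return {tid: totals[tid] / denom for tid in canon}
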