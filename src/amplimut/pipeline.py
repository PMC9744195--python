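"""End-to-end orchestration of the seven pipeline steps.

merge -> quality trim -> N filter -> tag extraction -> collapse to unique
sequences -> global alignment + score filter -> mutation calls, tallies and
summaries -> logo.  Every step's input/output counts are recorded in the run
report together with all parameters, so reads are conserved and reruns are
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable

import pandas as pd
import yaml

from . import __version__
from .align import (Alignment, DEFAULT_MIN_SCORE, ScoringScheme,
                    filter_by_score, needleman_wunsch)
from .calls import (MutationEvent, PositionTally, call_mutations,
                    interval_spectrum, tally)
from .dedup import UniqueSequence, collapse, preprocess_stream
from .logo import build_logo, logo_json, render_svg
from .merge import MergedRead, ReadPair, merge_stream
from .model import AmpliconSpec, AmpliconError, locate_target, revcomp
from .summaries import (ct_fraction, editing_window, large_deletions,
                        region_enrichment, substitution_profile, tag_effect)
from . import io as amio
from .summaries import SubstitutionMatrix


@dataclass
class RunParams:
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    q_threshold: int = 20
    min_len: int = 50
    tag_len: int = 5
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_score: float = DEFAULT_MIN_SCORE
    logo_max_alt: int = 4
    editing_min_freq: float = 0.05
    substitution_flank: int = 10
    tag_fold_floor: int = 10

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scoring"] = asdict(self.scoring)
        return d


@dataclass
class RunResult:
    spec: AmpliconSpec
    params: RunParams
    counts: dict
    uniques: list[UniqueSequence]
    kept: list[Alignment]
    discarded: list[Alignment]
    events: list[MutationEvent]
    events_by_source: dict[str, list[MutationEvent]]
    tally: PositionTally
    spectra: dict
    enrichment: dict
    substitution: dict[str, SubstitutionMatrix]
    report: dict
    logo: object = None


class PipelineError(RuntimeError):
    pass


def run_pipeline(spec: AmpliconSpec, pairs: Iterable[ReadPair] | None = None,
                 merged: Iterable[MergedRead] | None = None,
                 params: RunParams | None = None,
                 output_dir: str | None = None) -> RunResult:
    """Run the full pipeline over paired (or pre-merged) reads.

    Exactly one of ``pairs``/``merged`` must be given.  When ``output_dir``
    is set, TSV/FASTA/SVG/JSON artifacts are written there.
    """
    if (pairs is None) == (merged is None):
        raise PipelineError("provide exactly one of pairs= or merged=")
    params = params or RunParams()
    counts: dict = {}

    if merged is None:
        merged = merge_stream(pairs, params.min_overlap,
                              params.max_mismatch_frac, counts=counts)
    else:
        def _count(ms):
            for m in ms:
                counts["pairs_in"] = counts.get("pairs_in", 0) + 1
                counts["merged"] = counts.get("merged", 0) + 1
                yield m
        merged = _count(merged)

    inserts = preprocess_stream(merged, params.q_threshold, params.min_len,
                                params.tag_len, counts=counts)
    uniques = collapse(inserts)
    if counts.get("pairs_in", 0) == 0:
        raise PipelineError("empty input: no reads found")
    counts.setdefault("merged", 0)
    counts.setdefault("dropped_short", 0)
    counts.setdefault("dropped_n", 0)
    counts.setdefault("inserts", 0)
    counts["unique_sequences"] = len(uniques)

    alignments = []
    for rank, u in enumerate(uniques, 1):
        aln = needleman_wunsch(spec.ref_seq, u.insert, params.scoring,
                               query_id=f"seq{rank}", weight=u.adjusted_count,
                               raw_weight=u.raw_count)
        alignments.append(aln)
    kept, discarded, discard_frac = filter_by_score(alignments,
                                                    params.min_score)
    counts["retained_unique"] = len(kept)
    counts["discarded_unique"] = len(discarded)

    total_adjusted = sum(a.weight for a in kept)
    total_raw = sum(a.raw_weight for a in kept)
    events: list[MutationEvent] = []
    events_by_source: dict[str, list[MutationEvent]] = {}
    for aln in kept:
        evs = call_mutations(aln, weight=aln.weight, raw_weight=aln.raw_weight,
                             source=aln.query_id)
        events_by_source[aln.query_id] = evs
        events.extend(evs)

    pos_tally = tally(events, spec, total_adjusted, total_raw)

    spectra = {}
    enrichment = {}
    substitution = {}
    for t in spec.targets:
        dels, inss = interval_spectrum(events, t, total_adjusted)
        spectra[t.name] = {"deletions": dels, "insertions": inss}
        enrichment[t.name] = region_enrichment(events, spec, t)
        substitution[t.name] = substitution_profile(
            pos_tally, t, params.substitution_flank)
    spanning = None
    if len(spec.targets) == 2:
        spanning = large_deletions(events, spec.targets[0], spec.targets[1])

    tag_df, max_tag_fold = tag_effect(pos_tally, params.tag_fold_floor)
    logo_model = build_logo(pos_tally, spec, params.logo_max_alt)

    def _fold(x):
        return None if not math.isfinite(x) else x

    report = {
        "software": {"name": "amplimut", "version": __version__},
        "amplicon": {"name": spec.name, "length": len(spec.ref_seq),
                     "fwd_primer": list(spec.fwd_primer),
                     "rev_primer": list(spec.rev_primer),
                     "targets": [
                         {"name": t.name, "strand": t.strand,
                          "proto_start": t.proto_start,
                          "cut_site": t.cut_site, "pam": t.pam}
                         for t in spec.targets]},
        "parameters": params.to_dict(),
        "conventions": {
            "coordinates": "cut-relative signed labels, no position 0; "
                           "minus-strand guides labelled in guide orientation",
            "insertion_anchor": "first reference base right of the insertion, "
                                "after left-shifting gap placement",
            "end_gaps_free": params.scoring.end_gaps_free,
        },
        "counts": dict(counts),
        "rates": {
            "merge_rate": (counts["merged"] / counts["pairs_in"]
                           if counts["pairs_in"] else 0.0),
            "trim_pass_rate": (counts["inserts"] / counts["merged"]
                               if counts["merged"] else 0.0),
            "unique_fraction": (len(uniques) / counts["inserts"]
                                if counts["inserts"] else 0.0),
            "score_filter_discard_fraction": discard_frac,
        },
        "totals": {"adjusted_reads": total_adjusted, "raw_reads": total_raw},
        "summaries": {
            "max_tag_fold": None if math.isnan(max_tag_fold) else max_tag_fold,
            "targets": {
                t.name: {
                    "enrichment_fold": {
                        k: _fold(v.fold) for k, v in enrichment[t.name].items()},
                    "ct_fraction": (None if math.isnan(
                        ct_fraction(substitution[t.name]))
                        else ct_fraction(substitution[t.name])),
                    "editing_window": sorted(editing_window(
                        substitution[t.name], params.editing_min_freq)),
                } for t in spec.targets},
        },
    }
    if spanning is not None:
        report["summaries"]["spanning_deletions"] = {
            "n_rows": int(len(spanning)),
            "total_frequency": float(spanning["freq_of_deletions"].sum())
            if len(spanning) else 0.0,
        }

    result = RunResult(spec=spec, params=params, counts=counts,
                       uniques=uniques, kept=kept, discarded=discarded,
                       events=events, events_by_source=events_by_source,
                       tally=pos_tally, spectra=spectra,
                       enrichment=enrichment, substitution=substitution,
                       report=report)
    if output_dir:
        _write_artifacts(result, spanning, tag_df, logo_model, output_dir)
    result.logo = logo_model
    return result


def _write_artifacts(result: RunResult, spanning, tag_df, logo_model,
                     output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    j = lambda *p: os.path.join(output_dir, *p)
    amio.write_collapsed_fasta(result.uniques, j("collapsed.fasta"))
    result.tally.frequencies().to_csv(j("per_position.tsv"), sep="\t",
                                      index=False)
    ev = pd.DataFrame([{
        "source": e.source, "kind": e.kind, "ref_start": e.ref_start,
        "ref_end": e.ref_end, "anchor": e.anchor, "bases": e.bases,
        "weight": e.weight, "raw_weight": e.raw_weight}
        for e in result.events])
    ev.to_csv(j("events.tsv"), sep="\t", index=False)
    for name, sp in result.spectra.items():
        sp["deletions"].to_csv(j(f"deletions_{name}.tsv"), sep="\t",
                               index=False)
        sp["insertions"].to_csv(j(f"insertions_{name}.tsv"), sep="\t",
                                index=False)
    for name, mat in result.substitution.items():
        mat.to_dataframe().to_csv(j(f"substitutions_{name}.tsv"), sep="\t",
                                  index=False)
    enr_rows = []
    for name, rep in result.enrichment.items():
        for cls, e in rep.items():
            enr_rows.append({"target": name, "class": cls, **asdict(e)})
    pd.DataFrame(enr_rows).to_csv(j("enrichment.tsv"), sep="\t", index=False)
    if spanning is not None:
        spanning.to_csv(j("spanning_deletions.tsv"), sep="\t", index=False)
    tag_df.to_csv(j("tag_effect.tsv"), sep="\t", index=False)
    render_svg(logo_model, j("logo.svg"))
    logo_json(logo_model, j("logo.json"))
    with open(j("report.json"), "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- run-config file -------------------------------------------------------

def _resolve_primer(ref: str, value, reverse: bool) -> tuple[int, int]:
    """A primer given as an interval [start, end) or as its sequence.

    The reverse primer sequence is given 5'->3' on the opposite strand and
    located via its reverse complement.
    """
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return int(value[0]), int(value[1])
    seq = str(value).upper()
    probe = revcomp(seq) if reverse else seq
    i = ref.find(probe)
    if i < 0:
        raise AmpliconError(f"primer sequence {seq} not found in reference")
    if ref.find(probe, i + 1) >= 0:
        raise AmpliconError(f"primer sequence {seq} is ambiguous in reference")
    return i, i + len(probe)


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"run config {path} is not a mapping")
    return cfg


def spec_from_config(cfg: dict, base_dir: str = ".") -> AmpliconSpec:
    amp = cfg["amplicon"]
    if "sequence" in amp:
        ref = str(amp["sequence"]).upper().replace("\n", "")
    else:
        fasta = os.path.join(base_dir, amp["fasta"])
        seqs = amio.read_fasta(fasta)
        ref = seqs[amp["contig"]] if "contig" in amp else next(iter(seqs.values()))
    fwd = _resolve_primer(ref, amp["fwd_primer"], reverse=False)
    rev = _resolve_primer(ref, amp["rev_primer"], reverse=True)
    spec = AmpliconSpec(name=amp.get("name", "amplicon"), ref_seq=ref,
                        fwd_primer=fwd, rev_primer=rev, targets=[])
    for g in cfg.get("guides", []):
        spec.targets.append(locate_target(spec, g["protospacer"],
                                          g.get("pam", "NGG"),
                                          name=g.get("name", "")))
    spec.__post_init__()
    return spec


def params_from_config(cfg: dict) -> RunParams:
    p = dict(cfg.get("params", {}))
    scoring_keys = {f.name for f in dataclasses.fields(ScoringScheme)}
    scheme = ScoringScheme(**{k: p.pop(k) for k in list(p)
                              if k in scoring_keys})
    allowed = {f.name for f in dataclasses.fields(RunParams)} - {"scoring"}
    unknown = set(p) - allowed
    if unknown:
        raise PipelineError(f"unknown parameters in config: {sorted(unknown)}")
    return RunParams(scoring=scheme, **p)
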