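"""Logo model construction and deterministic SVG rendering."""

import xml.etree.ElementTree as ET

import pytest

from amplimut.calls import MutationEvent, tally
from amplimut.logo import build_logo, logo_json, render_svg
from amplimut.model import ref_index_of


def _mm(pos, base, w):
    return MutationEvent("mismatch", ref_start=pos, ref_end=pos + 1,
                         bases=base, weight=w, raw_weight=w)


class TestBuildLogo:
    def test_zero_mutations_consensus_equals_reference(self, spec):
        model = build_logo(tally([], spec, 10, 10), spec)
        assert len(model.columns) == len(spec.nonprimer_positions)
        for col in model.columns:
            assert col.consensus_base == col.ref_base
            assert col.alternatives == []

    def test_majority_deletion_tops_column(self, spec, target):
        cut = target.cut_site
        evs = [MutationEvent("deletion", ref_start=cut - 1, ref_end=cut,
                             weight=6),
               _mm(cut - 1, "T" if spec.ref_seq[cut - 1] != "T" else "G", 2)]
        model = build_logo(tally(evs, spec, 10, 10), spec)
        col = next(c for c in model.columns if c.position == cut - 1)
        assert col.alternatives[0].glyph == "D"
        assert col.consensus_base == "D"  # 6 deleted vs 4 reference

    def test_consensus_flips_only_when_alt_beats_ref(self, spec, target):
        pos = ref_index_of(target, -13)  # ref C
        for w, expect in ((4, "C"), (5, "C"), (6, "T")):
            model = build_logo(tally([_mm(pos, "T", w)], spec, 10, 10), spec)
            col = next(c for c in model.columns if c.position == pos)
            # modal base: ref keeps 10-w observations, alt has w; ref wins ties
            assert col.consensus_base == expect, w

    def test_alternatives_ranked_and_capped(self, spec, target):
        pos = ref_index_of(target, -5)
        base = spec.ref_seq[pos]
        alts = [b for b in "ACGT" if b != base]
        evs = [_mm(pos, alts[0], 5), _mm(pos, alts[1], 3), _mm(pos, alts[2], 1),
               MutationEvent("deletion", ref_start=pos, ref_end=pos + 1,
                             weight=2),
               MutationEvent("insertion", anchor=pos, bases="TT", weight=4)]
        model = build_logo(tally(evs, spec, 20, 20), spec, max_alt=4)
        col = next(c for c in model.columns if c.position == pos)
        freqs = [g.frequency for g in col.alternatives]
        assert freqs == sorted(freqs, reverse=True)
        assert len(col.alternatives) == 4  # capped, five outcomes present


class TestRenderSvg:
    def test_byte_identical_across_reruns(self, spec, target, tmp_path):
        evs = [_mm(ref_index_of(target, -13), "T", 3),
               MutationEvent("deletion", ref_start=target.cut_site - 2,
                             ref_end=target.cut_site, weight=2)]
        model = build_logo(tally(evs, spec, 10, 10), spec)
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        render_svg(model, str(p1))
        render_svg(model, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_glyph_count_matches_model(self, spec, target, tmp_path):
        evs = [_mm(ref_index_of(target, -13), "T", 3),
               _mm(ref_index_of(target, -7), "A", 1),
               MutationEvent("deletion", ref_start=target.cut_site - 2,
                             ref_end=target.cut_site, weight=2)]
        model = build_logo(tally(evs, spec, 10, 10), spec)
        path = tmp_path / "logo.svg"
        render_svg(model, str(path))
        root = ET.parse(path).getroot()
        texts = root.findall(".//{http://www.w3.org/2000/svg}text")
        expected = 2 * len(model.columns) + sum(len(c.alternatives)
                                                for c in model.columns)
        assert len(texts) == expected

    def test_cut_arrow_present_only_in_range(self, spec, tmp_path):
        model = build_logo(tally([], spec, 10, 10), spec)
        path = tmp_path / "logo.svg"
        render_svg(model, str(path))
        root = ET.parse(path).getroot()
        assert len(root.findall(".//{http://www.w3.org/2000/svg}path")) == 1
        model.cut_sites = [2]  # inside the fwd primer, not rendered
        render_svg(model, str(path))
        root = ET.parse(path).getroot()
        assert len(root.findall(".//{http://www.w3.org/2000/svg}path")) == 0

    def test_consensus_matches_independent_majority(self, spec, target,
                                                    tmp_path):
        """Consensus row equals a per-column majority vote recomputed
        directly from the tally, independent of build_logo internals."""
        import numpy as np
        rng = np.random.default_rng(9)
        evs = []
        for p in spec.nonprimer_positions:
            w = int(rng.integers(0, 9))
            if w:
                alt = "ACGT"[rng.integers(0, 4)]
                if alt != spec.ref_seq[p]:
                    evs.append(_mm(p, alt, w))
            if rng.random() < 0.2:
                evs.append(MutationEvent("deletion", ref_start=p,
                                         ref_end=p + 1,
                                         weight=int(rng.integers(1, 9))))
        t = tally(evs, spec, 16, 16)
        model = build_logo(t, spec)
        for i, col in enumerate(model.columns):
            votes = {b: int(t.mismatch[i, j, 0])
                     for j, b in enumerate("ACGT")}
            votes["D"] = int(t.deletion[i, 0])
            votes[col.ref_base] = 16 - sum(votes.values()) + votes.get(
                col.ref_base, 0)
            top = max(votes.values())
            winners = {b for b, v in votes.items() if v == top}
            if col.ref_base in winners:
                assert col.consensus_base == col.ref_base
            else:
                assert votes[col.consensus_base] == top

    def test_logo_json_roundtrip(self, spec, tmp_path):
        model = build_logo(tally([], spec, 5, 5), spec)
        path = tmp_path / "logo.json"
        logo_json(model, str(path))
        import json
        raw = json.loads(path.read_text())
        assert raw["name"] == spec.name
        assert len(raw["columns"]) == len(model.columns)
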