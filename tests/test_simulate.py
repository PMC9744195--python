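"""Simulator: determinism, template application, truth statistics."""

import numpy as np
import pytest

from amplimut.dedup import collapse, preprocess_stream
from amplimut.merge import merge_stream
from amplimut.model import ref_index_of
from amplimut.simulate import (EventSpectrum, EventTemplate, SimConfig,
                               apply_template, canonical_events,
                               simulate_dataset, simulate_molecules,
                               spectrum_from_config, truth_frequencies,
                               unedited)


class TestApplyTemplate:
    def test_deletion_removes_labelled_bases(self, spec, target):
        t = EventTemplate(id="d", kind="deletion", start_label=-2,
                          end_label=-1)
        seq = apply_template(spec, target, t)
        cut = target.cut_site
        assert seq == spec.ref_seq[:cut - 2] + spec.ref_seq[cut:]

    def test_insertion_before_anchor(self, spec, target):
        t = EventTemplate(id="i", kind="insertion", anchor_label=1, bases="GG")
        seq = apply_template(spec, target, t)
        cut = target.cut_site
        assert seq == spec.ref_seq[:cut] + "GG" + spec.ref_seq[cut:]

    def test_substitution_must_change_base(self, spec, target):
        pos = ref_index_of(target, -13)
        t = EventTemplate(id="s", kind="substitution", position_label=-13,
                          alt=spec.ref_seq[pos])
        with pytest.raises(ValueError, match="alt equals"):
            apply_template(spec, target, t)

    def test_canonical_events_leftshift_repeat_insertion(self, spec, target):
        # inserting a base identical to its left neighbour is relocated to
        # the leftmost equivalent anchor by the aligner; canonical_events
        # must reflect that placement, not the template's nominal anchor
        cut = target.cut_site
        dup = spec.ref_seq[cut]  # duplicate the base right of the cut
        t = EventTemplate(id="i", kind="insertion", anchor_label=2, bases=dup)
        (ev,) = canonical_events(spec, target, t)
        assert ev[0] == "insertion"
        assert ev[1] <= cut + 1


class TestSpectrum:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError, match="sum"):
            EventSpectrum([(unedited(), 0.5)])
        with pytest.raises(ValueError, match="unique"):
            EventSpectrum([(unedited("a"), 0.5), (unedited("a"), 0.5)])

    def test_from_config_mapping(self):
        sp = spectrum_from_config([
            {"id": "d", "kind": "deletion", "start": -2, "end": -1, "p": 0.3},
            {"id": "i", "kind": "insertion", "anchor": -1, "bases": "t",
             "p": 0.2},
            {"id": "s", "kind": "substitution", "position": -13, "alt": "T",
             "p": 0.1},
            {"kind": "unedited", "p": 0.4},
        ])
        assert [t.id for t in sp.templates] == ["d", "i", "s", "unedited"]
        assert sp.probability("i") == 0.2


class TestSimulateMolecules:
    def test_unedited_only(self, spec, target):
        sp = EventSpectrum([(unedited(), 1.0)])
        rng = np.random.default_rng(0)
        mols, truth = simulate_molecules(spec, target, sp, 50, rng)
        assert set(mols) == {spec.ref_seq}
        assert (truth["template"] == "unedited").all()
        assert truth["tag5"].str.len().eq(5).all()

    def test_truth_fraction_within_3_sigma(self, spec, target):
        sp = EventSpectrum([
            (EventTemplate(id="d", kind="deletion", start_label=-2,
                           end_label=-1), 0.25),
            (unedited(), 0.75)])
        rng = np.random.default_rng(1)
        n = 20_000
        _, truth = simulate_molecules(spec, target, sp, n, rng)
        frac = (truth["template"] == "d").mean()
        sigma = (0.25 * 0.75 / n) ** 0.5
        assert abs(frac - 0.25) <= 3 * sigma

    def test_same_seed_identical(self, spec, target, spectrum):
        cfg = SimConfig(n_molecules=200, pcr_dup_mean=2, seed=5)
        p1, t1 = simulate_dataset(spec, target, spectrum, cfg)
        p2, t2 = simulate_dataset(spec, target, spectrum, cfg)
        assert t1.equals(t2)
        assert all(a.seq1 == b.seq1 and a.seq2 == b.seq2
                   for a, b in zip(p1, p2))


class TestSimulateReads:
    def test_duplication_shares_tags_and_counts(self, spec, target, spectrum):
        cfg = SimConfig(n_molecules=300, pcr_dup_mean=4,
                        seq_error_rate=0.0, n_rate=0.0, seed=2)
        pairs, truth = simulate_dataset(spec, target, spectrum, cfg)
        assert len(pairs) == truth["dup_count"].sum()

    def test_n_drop_fraction_matches_binomial(self, spec, target):
        """At an N rate of 0.02% the fraction of merged reads carrying an N
        is within 3 sigma of 1-(1-rate)^L for merged length L (mate-2 Ns in
        the overlap are outvoted by mate 1, leaving one draw per position)."""
        sp = EventSpectrum([(unedited(), 1.0)])
        cfg = SimConfig(n_molecules=4000, pcr_dup_mean=1.0,
                        seq_error_rate=0.0, n_rate=0.002, seed=3)
        pairs, _ = simulate_dataset(spec, target, sp, cfg)
        counts = {}
        merged = list(merge_stream(iter(pairs), counts=counts))
        with_n = sum("N" in m.seq for m in merged)
        L = len(spec.ref_seq) + 10
        p = 1 - (1 - 0.002) ** L
        sigma = (p * (1 - p) / len(merged)) ** 0.5
        assert abs(with_n / len(merged) - p) <= 3 * sigma

    def test_adjusted_counts_match_founder_grouping_oracle(self, spec, target,
                                                           spectrum):
        """After dedup, total adjusted count equals the number of distinct
        (molecule sequence, tag pair) founder groups in the truth table."""
        cfg = SimConfig(n_molecules=800, pcr_dup_mean=15.0,
                        seq_error_rate=0.0, n_rate=0.0, seed=4)
        pairs, truth = simulate_dataset(spec, target, spectrum, cfg)
        merged = merge_stream(iter(pairs))
        uniques = collapse(preprocess_stream(merged, min_len=10))
        from amplimut.simulate import apply_template
        seqs = {t.id: apply_template(spec, target, t)
                for t in spectrum.templates}
        founders = {(seqs[r.template], r.tag5, r.tag3)
                    for r in truth.itertuples()}
        assert sum(u.adjusted_count for u in uniques) == len(founders)
        assert sum(u.raw_count for u in uniques) == len(pairs)

    def test_read_geometry_validated(self, spec, target, spectrum):
        # reads too short to guarantee an overlap (188-nt tagged insert)
        cfg = SimConfig(n_molecules=5, read_len=80, seed=1)
        with pytest.raises(ValueError, match="too long"):
            simulate_dataset(spec, target, spectrum, cfg)
        # reads longer than the tagged insert cannot be cut from it
        cfg = SimConfig(n_molecules=5, read_len=250, seed=1)
        with pytest.raises(ValueError, match="read_len"):
            simulate_dataset(spec, target, spectrum, cfg)
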