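"""Dataset-level statistics: enrichment, spanning deletions, base-editing
profiles, tag effect, condition comparison."""

import math

import numpy as np
import pytest

from amplimut.calls import MutationEvent, tally
from amplimut.model import ref_index_of
from amplimut.summaries import (compare_conditions, ct_fraction,
                                editing_window, large_deletions,
                                region_enrichment, substitution_profile,
                                tag_effect)


def _mm(pos, base, w=1, raw=None):
    return MutationEvent("mismatch", ref_start=pos, ref_end=pos + 1,
                         bases=base, weight=w, raw_weight=raw or w)


class TestRegionEnrichment:
    def test_uniform_rates_give_fold_one(self, spec, target):
        # one deletion start per non-primer position -> identical per-base
        # rates inside and outside the window
        evs = [MutationEvent("deletion", ref_start=p, ref_end=p + 1)
               for p in spec.nonprimer_positions[:-1]]
        rep = region_enrichment(evs, spec, target)
        assert rep["deletion"].fold == pytest.approx(1.0, rel=0.05)

    def test_all_inside_gives_infinity(self, spec, target):
        evs = [MutationEvent("deletion", ref_start=target.cut_site - 1,
                             ref_end=target.cut_site + 1, weight=7)]
        rep = region_enrichment(evs, spec, target)
        assert rep["deletion"].fold == math.inf
        assert rep["deletion"].inside_count == 7
        assert rep["deletion"].outside_count == 0

    def test_start_or_end_within_window_counts_inside(self, spec, target):
        w0 = target.proto_start
        # starts before the window, ends inside it
        ev = MutationEvent("deletion", ref_start=w0 - 10, ref_end=w0 + 2)
        rep = region_enrichment([ev], spec, target)
        assert rep["deletion"].inside_count == 1

    def test_tenfold_rate_recovered(self, spec, target):
        rng = np.random.default_rng(0)
        window = sorted(target.window)
        outside = [p for p in spec.nonprimer_positions
                   if p not in target.window][:100]
        evs = [MutationEvent("insertion", anchor=int(rng.choice(window)))
               for _ in range(400)]
        evs += [MutationEvent("insertion", anchor=int(rng.choice(outside)))
                for _ in range(200)]
        rep = region_enrichment(evs, spec, target)
        # inside rate 400/20 vs outside 200/114 (full outside length is the
        # per-base denominator); counts are deterministic here
        n_out = len(spec.nonprimer_positions) - 20
        assert rep["insertion"].fold == pytest.approx(
            (400 / 20) / (200 / n_out))


class TestLargeDeletions:
    def test_spanning_deletion_length_and_labels(self, dual_spec):
        t1, t2 = dual_spec.targets
        # cuts 83 bp apart; -1 on target 1 through +2 on target 2 -> 86 bp
        start = ref_index_of(t1, -1)
        end = ref_index_of(t2, +2) + 1
        ev = MutationEvent("deletion", ref_start=start, ref_end=end, weight=2)
        small = MutationEvent("deletion", ref_start=t1.cut_site - 2,
                              ref_end=t1.cut_site, weight=38)
        df = large_deletions([ev, small], t1, t2)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["length_bp"] == 86
        assert (row["label_target1"], row["label_target2"]) == (-1, 2)
        assert row["length_bp"] == 83 + 1 + 2
        assert row["freq_of_deletions"] == pytest.approx(2 / 40)

    def test_single_target_deletions_excluded(self, dual_spec):
        t1, t2 = dual_spec.targets
        ev = MutationEvent("deletion", ref_start=t1.cut_site - 3,
                           ref_end=t1.cut_site + 3, weight=1)
        assert len(large_deletions([ev], t1, t2)) == 0


class TestSubstitutionProfile:
    def test_single_ct_cell(self, spec, target):
        pos = ref_index_of(target, -13)
        assert spec.ref_seq[pos] == "C"
        t = tally([_mm(pos, "T", w=4)], spec, 10, 10)
        mat = substitution_profile(t, target)
        df = mat.to_dataframe().set_index("label")
        assert df.loc[-13, "T"] == 4
        assert int(mat.counts.sum()) == 4
        assert ct_fraction(mat) == 1.0

    def test_window_plus_flank_extent(self, spec, target):
        mat = substitution_profile(tally([], spec, 1, 1), target, flank=10)
        assert list(mat.labels) == [l for l in range(-27, 14) if l != 0]

    def test_flank_truncated_at_primers(self, spec, target):
        mat = substitution_profile(tally([], spec, 1, 1), target, flank=80)
        # labels stop at the primer boundaries (non-primer positions only)
        assert len(mat.labels) == len(spec.nonprimer_positions)

    def test_empty_tally_zero_matrix(self, spec, target):
        mat = substitution_profile(tally([], spec, 1, 1), target)
        assert mat.counts.sum() == 0
        assert math.isnan(ct_fraction(mat))


class TestCtFractionAndWindow:
    def test_equal_ct_and_cg_gives_half(self, spec, target):
        pos = ref_index_of(target, -13)
        t = tally([_mm(pos, "T", 3), _mm(pos, "G", 3)], spec, 10, 10)
        assert ct_fraction(substitution_profile(t, target)) == 0.5

    def test_editing_window_thresholds(self, spec, target):
        p13 = ref_index_of(target, -13)
        p3 = ref_index_of(target, 3)  # C at +3 in the example protospacer
        assert spec.ref_seq[p3] == "C"
        t = tally([_mm(p13, "T", 40), _mm(p3, "T", 2)], spec, 100, 100)
        mat = substitution_profile(t, target)
        assert editing_window(mat, min_freq=0.05) == {-13}
        assert editing_window(mat, min_freq=0.01) == {-13, 3}

    def test_min_freq_zero_returns_all_c_positions(self, spec, target):
        mat = substitution_profile(tally([], spec, 10, 10), target)
        expected = {int(l) for i, l in enumerate(mat.labels)
                    if mat.ref_bases[i] == "C"}
        assert editing_window(mat, min_freq=0.0) == expected


class TestTagEffect:
    def test_no_duplicates_all_folds_one(self, spec, target):
        evs = [_mm(ref_index_of(target, -1), "A", w=20, raw=20)]
        t = tally(evs, spec, total_adjusted=100, total_raw=100)
        df, max_fold = tag_effect(t, min_adjusted=10)
        assert (df["fold"] == 1.0).all()
        assert max_fold == 1.0

    def test_twofold_amplified_sequence(self, spec, target):
        # one unique sequence amplified 2x with the same tag pair: raw=2,
        # adjusted=1, among 2 other unamplified reads
        evs = [_mm(ref_index_of(target, -1), "A", w=12, raw=24)]
        t = tally(evs, spec, total_adjusted=36, total_raw=48)
        df, max_fold = tag_effect(t, min_adjusted=10)
        assert max_fold == pytest.approx((24 / 48) / (12 / 36))

    def test_low_count_cells_excluded_from_max(self, spec, target):
        evs = [_mm(ref_index_of(target, -1), "A", w=2, raw=20)]
        t = tally(evs, spec, total_adjusted=100, total_raw=200)
        df, max_fold = tag_effect(t, min_adjusted=10)
        assert math.isnan(max_fold)


class TestCompareConditions:
    def test_identical_runs_unit_folds(self):
        run = {"-1 to -1": 0.2, "-2 to -1": 0.1}
        df = compare_conditions({"a": dict(run), "b": dict(run)})
        assert (df[df["key"] != "mean"]["b"] == 1.0).all()

    def test_tenfold_scaled_run(self):
        a = {"-1 to -1": 0.2, "-2 to -1": 0.1}
        b = {k: v / 10 for k, v in a.items()}
        df = compare_conditions({"a": a, "b": b})
        assert df[df["key"] == "mean"]["b"].iloc[0] == pytest.approx(0.1)

    def test_disjoint_keys_error(self):
        with pytest.raises(ValueError, match="no spectrum keys"):
            compare_conditions({"a": {"x": 1.0}, "b": {"y": 1.0}})

    def test_missing_requested_key_error(self):
        with pytest.raises(ValueError, match="lacks keys"):
            compare_conditions({"a": {"x": 1.0}, "b": {"x": 2.0}},
                               keys=["x", "z"])
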